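"""DVH construction and dosimetric comparison statistics.

Evaluates a treatment plan's dose grid on a structure set: cumulative
dose-volume histograms, prescription dose coverage (PDC) of targets, and
Dmax / Dmean / D1cc summaries for organs at risk, with serial organs judged
by peak dose (Dmax or D1cc) and parallel organs by mean dose (Dmean or
D1cc).  The relative dose difference dD_diff compares an observer plan's
summary dose against the gold-standard plan's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import DoseGrid, MetricRecord, StructureMask, StructureSet, resample_to

__all__ = [
    "DVH",
    "DoseSummary",
    "compute_dvh",
    "pdc",
    "dose_summary",
    "delta_d_diff",
    "map_plan_to_standard",
]


@dataclass
class DVH:
    """Cumulative dose-volume histogram of one structure.

    ``cum_volume_frac[i]`` is the fraction of the structure volume receiving
    at least ``dose_edges_gy[i]``; it is non-increasing, starts at 1 at
    0 Gy and ends at 0.  The exact voxel doses are retained so EUD and D1cc
    can be computed without binning error.
    """

    structure_label: str
    dose_edges_gy: np.ndarray
    cum_volume_frac: np.ndarray
    total_volume_cc: float
    voxel_doses_gy: np.ndarray
    voxel_volume_cc: float

    def coverage_fraction(self, dose_gy: float) -> float:
        """Exact fraction of structure volume receiving >= dose_gy."""
        return float(np.count_nonzero(self.voxel_doses_gy >= dose_gy)) / self.voxel_doses_gy.size

    def binned_fraction(self, dose_gy: float) -> float:
        """Cumulative fraction at the nearest DVH bin edge at or below dose."""
        i = int(np.searchsorted(self.dose_edges_gy, dose_gy, side="right")) - 1
        i = max(0, min(i, len(self.dose_edges_gy) - 1))
        return float(self.cum_volume_frac[i])


@dataclass
class DoseSummary:
    structure_label: str
    Dmax_gy: float
    Dmean_gy: float
    D1cc_gy: float
    organ_class: str  # serial | parallel | target


def _doses_in_mask(dose: DoseGrid, mask: StructureMask) -> np.ndarray:
    """Voxel doses within the mask, resampling dose to the mask grid if needed.

    The structure voxelization defines the integration domain: dose is
    trilinearly resampled onto the mask grid, never the reverse.
    """
    if mask.is_empty():
        raise ValueError(f"structure {mask.label!r} is empty")
    if dose.grid != mask.grid:
        dose = resample_to(dose, mask.grid)
    return dose.dose_gy[mask.occupancy]


def compute_dvh(dose: DoseGrid, mask: StructureMask, bin_width_gy: float = 0.01) -> DVH:
    """Cumulative DVH over the structure's occupied voxels."""
    if bin_width_gy <= 0:
        raise ValueError("bin width must be positive")
    doses = _doses_in_mask(dose, mask)
    dmax = float(doses.max())
    edges = np.arange(0.0, dmax + 2 * bin_width_gy, bin_width_gy)
    # fraction of voxels with dose >= edge
    counts = np.count_nonzero(doses[None, :] >= edges[:, None], axis=1) if doses.size < 200_000 else np.array(
        [np.count_nonzero(doses >= e) for e in edges]
    )
    frac = counts / doses.size
    vox_cc = mask.grid.voxel_volume_mm3 / 1000.0
    return DVH(
        structure_label=mask.label,
        dose_edges_gy=edges,
        cum_volume_frac=frac.astype(float),
        total_volume_cc=doses.size * vox_cc,
        voxel_doses_gy=doses,
        voxel_volume_cc=vox_cc,
    )


def pdc(dose: DoseGrid, ptv: StructureMask, prescription_gy: float) -> float:
    """Prescription dose coverage (%): percent of PTV voxels with dose >=
    the prescription.  Whole-voxel counting; "100% of the prescribed dose"
    is read literally as dose >= prescription."""
    if prescription_gy <= 0:
        raise ValueError("prescription must be positive")
    doses = _doses_in_mask(dose, ptv)
    return 100.0 * float(np.count_nonzero(doses >= prescription_gy)) / doses.size


def dose_summary(dose: DoseGrid, mask: StructureMask, organ_class: str = "serial") -> DoseSummary:
    """Dmax / Dmean / D1cc of a structure.

    D1cc is the highest dose d such that at least 1 cc of the structure
    receives >= d, computed on the exactly sorted voxel doses with linear
    interpolation at the 1 cc boundary (no DVH binning).  Structures smaller
    than 1 cc report D1cc = Dmin with a warning.
    """
    if organ_class not in ("serial", "parallel", "target"):
        raise ValueError(f"unknown organ class {organ_class!r}")
    doses = _doses_in_mask(dose, mask)
    vox_cc = mask.grid.voxel_volume_mm3 / 1000.0
    total_cc = doses.size * vox_cc
    dsorted = np.sort(doses)[::-1]  # hottest first
    if total_cc < 1.0:
        warnings.warn(
            f"structure {mask.label!r} is {total_cc:.3f} cc (<1 cc); D1cc = Dmin",
            stacklevel=2,
        )
        d1cc = float(dsorted[-1])
    else:
        cum_cc = np.arange(1, doses.size + 1) * vox_cc
        d1cc = float(np.interp(1.0, cum_cc, dsorted))
    return DoseSummary(
        structure_label=mask.label,
        Dmax_gy=float(dsorted[0]),
        Dmean_gy=float(doses.mean()),
        D1cc_gy=d1cc,
        organ_class=organ_class,
    )


def delta_d_diff(dm: float, ds: float) -> float:
    """Relative dose difference (%): 100 * (D_observer - D_standard) / D_standard."""
    if ds <= 0:
        raise ValueError("standard dose must be positive")
    return 100.0 * (dm - ds) / ds


def map_plan_to_standard(
    observer_dose: DoseGrid,
    standard_set: StructureSet,
    prescriptions_gy: dict[str, float],
    organ_classes: dict[str, str],
    patient_id: str = "",
    observer_id: str = "",
    skip_unclassified: bool = False,
) -> list[MetricRecord]:
    """Evaluate an observer's dose grid on the gold-standard structures.

    Targets (labels present in ``prescriptions_gy``) get a PDC row; OARs get
    their class-primary summary (serial -> Dmax, parallel -> Dmean).  One
    record per structure: #targets + #OARs rows per observer.  A structure
    in neither map is an error unless ``skip_unclassified``.
    """
    rows: list[MetricRecord] = []
    for label, mask in standard_set.masks.items():
        if label in prescriptions_gy:
            rx = prescriptions_gy[label]
            rows.append(
                MetricRecord(patient_id, observer_id, label, "PDC_pct",
                             pdc(observer_dose, mask, rx), "%")
            )
        else:
            klass = organ_classes.get(label)
            if klass is None:
                if skip_unclassified:
                    continue
                raise ValueError(
                    f"structure {label!r} has neither a prescription nor an organ class"
                )
            summ = dose_summary(observer_dose, mask, klass)
            if klass == "serial":
                rows.append(MetricRecord(patient_id, observer_id, label, "Dmax_gy", summ.Dmax_gy, "Gy"))
            else:
                rows.append(MetricRecord(patient_id, observer_id, label, "Dmean_gy", summ.Dmean_gy, "Gy"))
    return rows
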
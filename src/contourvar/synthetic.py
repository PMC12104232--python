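"""Synthetic cohort generator: gold-standard anatomy, simulated observers,
and conformal dose surrogates.

The generator reproduces the statistical structure the downstream analysis
assumes, without clinical data:

* a gold-standard head-and-neck-like phantom — an ellipsoidal nasopharyngeal
  target (GTVnx, ~30 cc), a tubular spinal cord (serial organ), paired
  ellipsoidal parotids (parallel organs) and paired small optic nerves
  (~0.2 cc, the small-organ regime where relative inter-observer
  variability is largest);
* K simulated observers, each perturbing every structure by a systematic
  boundary offset (volume bias, mm), a spatially smooth random surface
  displacement field, and a small rigid shift, all applied in the
  signed-distance domain so contours stay anatomically plausible;
* a per-observer dose grid conformal to that observer's own expanded
  target: full prescription inside the planned PTV and a Gaussian falloff
  with penumbra scale sigma outside it, so under-contouring produces cold
  spots on the gold-standard target while over-contouring preserves its
  coverage.

Perturbation magnitudes are scaled per structure by its equivalent-sphere
radius (capped at 1 for target-sized structures), so a millimetre-scale
bias on a 30 cc target maps to a proportionally smaller absolute — but much
larger relative — perturbation on a 0.2 cc optic nerve, matching the
observed pattern that small organs show the largest relative variability.

All randomness flows from a single master seed through
``numpy.random.SeedSequence`` spawning (one stream per patient, one per
observer within a patient), so cohorts are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (
    DoseGrid,
    StructureMask,
    StructureSet,
    VoxelGrid,
    bbox_slices,
    expand_margin,
    signed_distance_mm,
    write_dose,
    write_mask,
)

__all__ = [
    "ObserverModel",
    "DoseModel",
    "PatientData",
    "DEFAULT_GRID",
    "DEFAULT_OBSERVERS",
    "ORGAN_CLASSES",
    "TARGET_LABEL",
    "PTV_LABEL",
    "make_phantom",
    "simulate_observer",
    "synthesize_dose",
    "simulate_patient",
    "simulate_cohort",
    "generate_cohort",
]

TARGET_LABEL = "GTVnx"
PTV_LABEL = "PTVnx"

#: organ classes of the phantom's organs at risk
ORGAN_CLASSES = {
    "SpinalCord": "serial",
    "Parotid_L": "parallel",
    "Parotid_R": "parallel",
    "OpticNerve_L": "serial",
    "OpticNerve_R": "serial",
}

#: default grid: 1 x 1 mm in-plane, 2.5 mm slices (dose-grid scale)
DEFAULT_GRID = VoxelGrid((128, 128, 96), (1.0, 1.0, 2.5))

#: standard nasopharyngeal simultaneous-integrated-boost prescription levels
#: (Gy, delivered in 33 fractions); the phantom models the primary target
#: only, so its dose model uses just PTVnx by default
STANDARD_PRESCRIPTIONS_GY = {
    "PTVnx": 70.0,
    "PTVnd": 66.0,
    "PTV1": 60.0,
    "PTV2": 54.0,
}

#: reference equivalent-sphere radius (mm) at which perturbations are unscaled
_R_REF_MM = 15.0

#: correlation length (mm) of the smooth surface-noise field
_NOISE_CORR_MM = 10.0


@dataclass(frozen=True)
class ObserverModel:
    """Systematic + random contouring behaviour of one simulated observer.

    ``volume_bias_mm`` is the signed boundary offset applied to
    target-sized structures (positive dilates, negative erodes);
    ``surface_noise_mm`` the SD of the smooth random boundary displacement;
    ``shift_mm`` the per-axis SD of a rigid offset.
    """

    observer_id: str
    volume_bias_mm: float = 0.0
    surface_noise_mm: float = 0.0
    shift_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.surface_noise_mm < 0 or self.shift_mm < 0:
            raise ValueError("noise magnitudes must be nonnegative")


#: four observers spanning systematic under- to over-contouring
DEFAULT_OBSERVERS = (
    ObserverModel("A", volume_bias_mm=-4.0, surface_noise_mm=1.0, shift_mm=0.5),
    ObserverModel("B", volume_bias_mm=-2.0, surface_noise_mm=1.0, shift_mm=0.5),
    ObserverModel("C", volume_bias_mm=+1.0, surface_noise_mm=1.0, shift_mm=0.5),
    ObserverModel("D", volume_bias_mm=+3.0, surface_noise_mm=1.0, shift_mm=0.5),
)


@dataclass(frozen=True)
class DoseModel:
    """Analytic conformal-dose surrogate for an IMRT plan.

    Inside the planned PTV the dose equals the prescription; outside it
    falls off as a Gaussian of the Euclidean distance to the PTV with scale
    ``penumbra_sigma_mm``.
    """

    prescriptions_gy: dict[str, float] = field(
        default_factory=lambda: {PTV_LABEL: 70.0}
    )
    penumbra_sigma_mm: float = 3.0
    background_gy: float = 0.0

    def __post_init__(self) -> None:
        if any(rx <= 0 for rx in self.prescriptions_gy.values()):
            raise ValueError("prescriptions must be positive")
        if self.penumbra_sigma_mm <= 0:
            raise ValueError("penumbra sigma must be positive")
        if self.background_gy < 0:
            raise ValueError("background dose must be nonnegative")


@dataclass
class PatientData:
    """One simulated patient: gold standard, observers, and their doses."""

    patient_id: str
    standard: StructureSet
    standard_dose: DoseGrid
    observers: dict[str, StructureSet]
    observer_doses: dict[str, DoseGrid]


# ---------------------------------------------------------------------------
# Phantom


def _coords(grid: VoxelGrid):
    sx, sy, sz = grid.spacing_mm
    ox, oy, oz = grid.origin_mm
    x = ox + np.arange(grid.shape[0]) * sx
    y = oy + np.arange(grid.shape[1]) * sy
    z = oz + np.arange(grid.shape[2]) * sz
    return np.meshgrid(x, y, z, indexing="ij", sparse=True)


def _ellipsoid(grid: VoxelGrid, center, semi_axes) -> np.ndarray:
    X, Y, Z = _coords(grid)
    cx, cy, cz = center
    ax, ay, az = semi_axes
    return ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2 <= 1.0


def _tube_z(grid: VoxelGrid, center_xy, radius_mm, z_range) -> np.ndarray:
    X, Y, Z = _coords(grid)
    cx, cy = center_xy
    in_plane = (X - cx) ** 2 + (Y - cy) ** 2 <= radius_mm**2
    return in_plane & (Z >= z_range[0]) & (Z <= z_range[1])


def make_phantom(
    grid: VoxelGrid = DEFAULT_GRID,
    seed: int | np.random.Generator = 0,
    jitter: bool = True,
) -> StructureSet:
    """Deterministic-given-seed gold-standard anatomy on the given grid.

    Per-patient jitter perturbs structure sizes (+-7%) and centers
    (+-~1.5 mm) so a cohort of phantoms has realistic between-patient
    volume spread.  The GTV and the spinal cord are disjoint by
    construction and this is asserted.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = grid.extent_mm()
    mid = (lo + hi) / 2.0

    def jscale():
        return rng.uniform(0.93, 1.07) if jitter else 1.0

    def jpos(sd=1.5, clip=2.0):
        return float(np.clip(rng.normal(0, sd), -clip, clip)) if jitter else 0.0

    cx, cz = mid[0], mid[2]
    structures: dict[str, np.ndarray] = {}

    # target: ~30 cc ellipsoid, slightly anterior of center
    gtv_center = (cx + jpos(), 58.0 + jpos(1.0, 1.5), cz + jpos())
    gtv_axes = (24.0 * jscale(), 19.0 * jscale(), 15.0 * jscale())
    structures[TARGET_LABEL] = _ellipsoid(grid, gtv_center, gtv_axes)

    # serial organ: posterior tube along z, ~10 cc
    cord_y = 88.0
    structures["SpinalCord"] = _tube_z(
        grid, (cx + jpos(1.0, 1.5), cord_y), 4.5 * jscale(), (lo[2] + 20.0, hi[2] - 20.0)
    )

    # parallel organs: lateral ellipsoids, ~12 cc each
    for name, sign in (("Parotid_L", -1.0), ("Parotid_R", +1.0)):
        center = (cx + sign * 36.0 + jpos(), 64.0 + jpos(), cz + jpos())
        axes = (10.0 * jscale(), 13.0 * jscale(), 22.0 * jscale())
        structures[name] = _ellipsoid(grid, center, axes)

    # small organs: ~0.2 cc ellipsoids superior to the target
    for name, sign in (("OpticNerve_L", -1.0), ("OpticNerve_R", +1.0)):
        center = (cx + sign * 10.0 + jpos(0.8, 1.2), 52.0 + jpos(0.8, 1.2), cz + 22.5)
        axes = (6.0 * jscale(), 2.6 * jscale(), 2.8 * jscale())
        structures[name] = _ellipsoid(grid, center, axes)

    sset = StructureSet(observer_id="standard")
    for label, occ in structures.items():
        if not occ.any():
            raise ValueError(f"structure {label!r} does not fit in the grid")
        # structures must not touch the grid faces (margin room for expansion)
        edge = np.zeros(grid.shape, dtype=bool)
        edge[0, :, :] = edge[-1, :, :] = True
        edge[:, 0, :] = edge[:, -1, :] = True
        edge[:, :, 0] = edge[:, :, -1] = True
        if (occ & edge).any():
            raise ValueError(f"structure {label!r} touches the grid boundary")
        sset.add(StructureMask(grid=grid, occupancy=occ, label=label))

    if (sset[TARGET_LABEL].occupancy & sset["SpinalCord"].occupancy).any():
        raise AssertionError("GTV and spinal cord overlap; phantom invalid")
    return sset


# ---------------------------------------------------------------------------
# Observer simulation


def _perturbation_scale(mask: StructureMask) -> float:
    """Size scaling of perturbation magnitudes: equivalent-sphere radius
    over the reference radius, capped at 1."""
    vol_mm3 = mask.n_voxels * mask.grid.voxel_volume_mm3
    r_eq = (3.0 * vol_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    return min(1.0, r_eq / _R_REF_MM)


def _smooth_noise_field(
    shape, spacing_mm, rng: np.random.Generator, sd_mm: float
) -> np.ndarray:
    """Zero-mean Gaussian random field with ~10 mm correlation length,
    normalized to the requested pointwise SD (mm)."""
    white = rng.standard_normal(shape)
    sigma_vox = [_NOISE_CORR_MM / s for s in spacing_mm]
    f = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="nearest")
    s = f.std()
    if s <= 0:
        return np.zeros(shape)
    return f * (sd_mm / s)


def simulate_observer(
    standard: StructureSet,
    model: ObserverModel,
    rng: int | np.random.Generator = 0,
    sdf_cache: dict[str, np.ndarray] | None = None,
) -> StructureSet:
    """Perturb every structure of the gold standard per the observer model.

    Each mask's signed distance field is rigidly shifted (per-axis offsets
    ~ N(0, shift_mm)), then re-thresholded at volume_bias + a smooth noise
    field, both scaled by the structure's size factor.  A perturbation that
    annihilates a structure is an error naming it.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    grid = standard.grid
    # the perturbation can only move the boundary by |bias| plus a few noise
    # SDs plus the rigid shift: working on a padded bounding box is exact as
    # long as nothing reaches the box border (asserted below)
    pad_mm = abs(model.volume_bias_mm) + 5.0 * model.surface_noise_mm + 5.0 * model.shift_mm + 5.0
    out = StructureSet(observer_id=model.observer_id)
    for label, mask in standard.masks.items():
        pad = tuple(int(np.ceil(pad_mm / s)) + 1 for s in grid.spacing_mm)
        box = bbox_slices(mask.occupancy, pad)
        cached = sdf_cache.get(label) if sdf_cache is not None else None
        if cached is not None and cached[0] == box:
            sdf = cached[1]
        else:
            sub = StructureMask(
                grid=VoxelGrid(mask.occupancy[box].shape, grid.spacing_mm),
                occupancy=mask.occupancy[box],
                label=label,
            )
            sdf = signed_distance_mm(sub)
            if sdf_cache is not None:
                sdf_cache[label] = (box, sdf)
        scale = _perturbation_scale(mask)
        if model.shift_mm > 0:
            offset_mm = rng.normal(0.0, model.shift_mm, size=3)
            offset_vox = offset_mm / np.asarray(grid.spacing_mm)
            sdf = ndimage.shift(sdf, offset_vox, order=1, mode="nearest")
        if model.surface_noise_mm > 0:
            noise = _smooth_noise_field(
                sdf.shape, grid.spacing_mm, rng, model.surface_noise_mm * scale
            )
        else:
            noise = 0.0
        occ_box = sdf <= model.volume_bias_mm * scale + noise
        if _touches_border(occ_box):
            raise ValueError(
                f"observer {model.observer_id!r} perturbation of {label!r} "
                "reached the working-box border; increase the grid margin"
            )
        occ = np.zeros(grid.shape, dtype=bool)
        occ[box] = occ_box
        if not occ.any():
            raise ValueError(
                f"observer {model.observer_id!r} perturbation annihilated "
                f"structure {label!r}"
            )
        out.add(StructureMask(grid=grid, occupancy=occ, label=label))
    return out


def _touches_border(occ: np.ndarray) -> bool:
    return bool(
        occ[0].any() or occ[-1].any()
        or occ[:, 0].any() or occ[:, -1].any()
        or occ[:, :, 0].any() or occ[:, :, -1].any()
    )


# ---------------------------------------------------------------------------
# Dose surrogate


def synthesize_dose(planned_set: StructureSet, dose_model: DoseModel) -> DoseGrid:
    """Conformal dose surrogate for a plan built on ``planned_set``.

    dose(x) = max over targets of prescription * exp(-d(x)^2 / 2 sigma^2),
    where d is the Euclidean distance outside the planned target (0 inside),
    plus a uniform background.  Coverage of the planning structure itself is
    100% by construction.
    """
    grid = planned_set.grid
    dose = np.zeros(grid.shape)
    for label, rx in dose_model.prescriptions_gy.items():
        if label not in planned_set:
            raise ValueError(f"planned set has no target labelled {label!r}")
        occ = planned_set[label].occupancy
        d_out = ndimage.distance_transform_edt(~occ, sampling=grid.spacing_mm)
        field_gy = rx * np.exp(-(d_out**2) / (2.0 * dose_model.penumbra_sigma_mm**2))
        np.maximum(dose, field_gy, out=dose)
    dose += dose_model.background_gy
    return DoseGrid(grid=grid, dose_gy=dose)


# ---------------------------------------------------------------------------
# Cohort assembly


def simulate_patient(
    patient_id: str,
    observers=DEFAULT_OBSERVERS,
    dose_model: DoseModel = DoseModel(),
    grid: VoxelGrid = DEFAULT_GRID,
    seed: int | np.random.SeedSequence = 0,
    ptv_margin_mm: float = 3.0,
    jitter: bool = True,
) -> PatientData:
    """Simulate one patient: phantom, PTV, observer sets and conformal doses.

    The PTV of every structure set (standard and observer) is derived from
    that set's own target by isotropic margin expansion, and each dose is
    conformal to its own set's PTV — the causal chain that lets target
    under-contouring create cold spots on the gold-standard PTV.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child_seqs = ss.spawn(1 + len(observers))
    phantom_rng = np.random.default_rng(child_seqs[0])
    standard = make_phantom(grid, phantom_rng, jitter=jitter)
    standard.add(_ptv_of(standard, ptv_margin_mm))
    standard_dose = synthesize_dose(standard, dose_model)

    sdf_cache: dict[str, np.ndarray] = {}
    obs_sets: dict[str, StructureSet] = {}
    obs_doses: dict[str, DoseGrid] = {}
    base = StructureSet(observer_id="standard")
    for label, m in standard.masks.items():
        if label != PTV_LABEL:
            base.add(m)
    for model, sq in zip(observers, child_seqs[1:]):
        obs_rng = np.random.default_rng(sq)
        oset = simulate_observer(base, model, obs_rng, sdf_cache=sdf_cache)
        oset.add(_ptv_of(oset, ptv_margin_mm))
        obs_sets[model.observer_id] = oset
        obs_doses[model.observer_id] = synthesize_dose(oset, dose_model)
    return PatientData(
        patient_id=patient_id,
        standard=standard,
        standard_dose=standard_dose,
        observers=obs_sets,
        observer_doses=obs_doses,
    )


def _ptv_of(sset: StructureSet, margin_mm: float) -> StructureMask:
    ptv = expand_margin(sset[TARGET_LABEL], margin_mm)
    return StructureMask(grid=ptv.grid, occupancy=ptv.occupancy, label=PTV_LABEL)


def simulate_cohort(
    n_patients: int = 12,
    observers=DEFAULT_OBSERVERS,
    dose_model: DoseModel = DoseModel(),
    grid: VoxelGrid = DEFAULT_GRID,
    seed: int = 0,
    ptv_margin_mm: float = 3.0,
):
    """Yield PatientData for a cohort, one patient at a time (memory-lean)."""
    if n_patients < 1:
        raise ValueError("need at least 1 patient")
    if len(observers) < 2:
        raise ValueError("need at least 2 observers")
    ss = np.random.SeedSequence(seed)
    patient_seqs = ss.spawn(n_patients)
    for i, psq in enumerate(patient_seqs):
        yield simulate_patient(
            patient_id=f"patient_{i + 1:03d}",
            observers=observers,
            dose_model=dose_model,
            grid=grid,
            seed=psq,
            ptv_margin_mm=ptv_margin_mm,
        )


def generate_cohort(
    out_dir,
    n_patients: int = 12,
    observers=DEFAULT_OBSERVERS,
    dose_model: DoseModel = DoseModel(),
    grid: VoxelGrid = DEFAULT_GRID,
    seed: int = 0,
    ptv_margin_mm: float = 3.0,
) -> dict:
    """Write a cohort to disk in the layout the CLI stages consume.

    Layout: ``<dir>/patient_###/{standard,observer_X}/<label>.nii.gz``,
    ``<dir>/patient_###/dose_{standard,observer_X}.nii.gz`` and a
    ``manifest.json`` recording the seed and every model parameter.
    Regeneration with the same seed is byte-identical.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": seed,
        "n_patients": n_patients,
        "ptv_margin_mm": ptv_margin_mm,
        "grid": {
            "shape": list(grid.shape),
            "spacing_mm": list(grid.spacing_mm),
            "origin_mm": list(grid.origin_mm),
        },
        "observers": [
            {
                "observer_id": m.observer_id,
                "volume_bias_mm": m.volume_bias_mm,
                "surface_noise_mm": m.surface_noise_mm,
                "shift_mm": m.shift_mm,
            }
            for m in observers
        ],
        "dose_model": {
            "prescriptions_gy": dict(dose_model.prescriptions_gy),
            "penumbra_sigma_mm": dose_model.penumbra_sigma_mm,
            "background_gy": dose_model.background_gy,
        },
        "patients": [],
    }
    for pdata in simulate_cohort(
        n_patients, observers, dose_model, grid, seed, ptv_margin_mm
    ):
        pdir = out / pdata.patient_id
        sdir = pdir / "standard"
        sdir.mkdir(parents=True, exist_ok=True)
        for label, m in pdata.standard.masks.items():
            write_mask(m, sdir / f"{label}.nii.gz")
        write_dose(pdata.standard_dose, pdir / "dose_standard.nii.gz")
        for oid, oset in pdata.observers.items():
            odir = pdir / f"observer_{oid}"
            odir.mkdir(parents=True, exist_ok=True)
            for label, m in oset.masks.items():
                write_mask(m, odir / f"{label}.nii.gz")
            write_dose(pdata.observer_doses[oid], pdir / f"dose_observer_{oid}.nii.gz")
        manifest["patients"].append(pdata.patient_id)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
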
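"""End-to-end orchestration: simulate (or load) a cohort, compute geometric
variability, dosimetric and radiobiological endpoints versus the gold
standard, and run the correlation-based risk-predictor selection.

Outputs mirror the clinical reporting convention: a geometric-metrics table
(volumes, DSC, HD95, MMR, CV), a dose-metrics table (PDC and organ summary
doses with their deltas), a radiobiology table (EUD, TCP, NTCP and their
deltas), a correlation table and the selected predictors, plus a JSON run
manifest sufficient to regenerate every output byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MetricRecord, StructureSet, VoxelGrid, read_dose, read_mask
from .dosimetry import delta_d_diff, dose_summary, pdc
from .geometry import ObserverGroup, group_report
from .radiobiology import RadiobioParams, eud, ntcp, tcp
from .statistics import correlation_matrix, results_frame, select_predictors
from .synthetic import (
    DEFAULT_GRID,
    DEFAULT_OBSERVERS,
    ORGAN_CLASSES,
    PTV_LABEL,
    TARGET_LABEL,
    DoseModel,
    ObserverModel,
    PatientData,
    simulate_cohort,
)

logger = logging.getLogger("contourvar")

__all__ = ["RunConfig", "run_all", "report", "DEFAULT_NTCP_PARAMS", "records_to_frame"]

#: synthetic placeholder NTCP parameter sets (no published per-organ values
#: are bundled; supply your own for clinical use)
DEFAULT_NTCP_PARAMS: dict[str, RadiobioParams] = {
    "SpinalCord": RadiobioParams(
        organ_class="serial", n0=10.0, k=0.5, alpha=0.055, alpha_beta_gy=2.0, summary="dmax"
    ),
    "Parotid_L": RadiobioParams(
        organ_class="parallel", n0=6.0, k=1.0, alpha=0.08, alpha_beta_gy=3.0, summary="dmean"
    ),
    "Parotid_R": RadiobioParams(
        organ_class="parallel", n0=6.0, k=1.0, alpha=0.08, alpha_beta_gy=3.0, summary="dmean"
    ),
    "OpticNerve_L": RadiobioParams(
        organ_class="serial", n0=8.0, k=0.25, alpha=0.06, alpha_beta_gy=3.0, summary="dmax"
    ),
    "OpticNerve_R": RadiobioParams(
        organ_class="serial", n0=8.0, k=0.25, alpha=0.06, alpha_beta_gy=3.0, summary="dmax"
    ),
}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str | Path = "contourvar_run"
    cohort_dir: str | Path | None = None  # load from disk instead of simulating
    n_patients: int = 12
    observers: tuple[ObserverModel, ...] = DEFAULT_OBSERVERS
    dose_model: DoseModel = field(default_factory=DoseModel)
    grid: VoxelGrid = DEFAULT_GRID
    seed: int = 0
    ptv_margin_mm: float = 3.0
    pooling: str = "pooled"  # pooled | per_observer
    gamma_mode: str = "per_fraction"
    target_a_exponent: float = -8.0
    ntcp_params: dict[str, RadiobioParams] = field(
        default_factory=lambda: dict(DEFAULT_NTCP_PARAMS)
    )
    organ_classes: dict[str, str] = field(default_factory=lambda: dict(ORGAN_CLASSES))
    write_outputs: bool = True

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "n_patients": self.n_patients,
                "seed": self.seed,
                "ptv_margin_mm": self.ptv_margin_mm,
                "pooling": self.pooling,
                "gamma_mode": self.gamma_mode,
                "a": self.target_a_exponent,
                "grid": [self.grid.shape, self.grid.spacing_mm],
                "observers": [
                    (m.observer_id, m.volume_bias_mm, m.surface_noise_mm, m.shift_mm)
                    for m in self.observers
                ],
                "dose": [
                    sorted(self.dose_model.prescriptions_gy.items()),
                    self.dose_model.penumbra_sigma_mm,
                    self.dose_model.background_gy,
                ],
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def records_to_frame(records: list[MetricRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "observer_id": r.observer_id,
                "structure_label": r.structure_label,
                "metric_name": r.metric_name,
                "value": r.value,
                "units": r.units,
            }
            for r in records
        ]
    )


def _load_patient_from_disk(pdir: Path, manifest: dict) -> PatientData:
    observers = [m["observer_id"] for m in manifest["observers"]]
    std = StructureSet(observer_id="standard")
    for f in sorted((pdir / "standard").glob("*.nii*")):
        std.add(read_mask(f))
    std_dose = read_dose(pdir / "dose_standard.nii.gz")
    obs_sets, obs_doses = {}, {}
    for oid in observers:
        oset = StructureSet(observer_id=oid)
        for f in sorted((pdir / f"observer_{oid}").glob("*.nii*")):
            oset.add(read_mask(f))
        obs_sets[oid] = oset
        obs_doses[oid] = read_dose(pdir / f"dose_observer_{oid}.nii.gz")
    return PatientData(pdir.name, std, std_dose, obs_sets, obs_doses)


def _iter_cohort(config: RunConfig):
    if config.cohort_dir is not None:
        root = Path(config.cohort_dir)
        manifest = json.loads((root / "manifest.json").read_text())
        for pid in manifest["patients"]:
            yield _load_patient_from_disk(root / pid, manifest)
    else:
        yield from simulate_cohort(
            n_patients=config.n_patients,
            observers=config.observers,
            dose_model=config.dose_model,
            grid=config.grid,
            seed=config.seed,
            ptv_margin_mm=config.ptv_margin_mm,
        )


def _geometric_stage(pdata: PatientData) -> list[MetricRecord]:
    rows: list[MetricRecord] = []
    observer_ids = list(pdata.observers)
    for label in pdata.standard.labels:
        if label == PTV_LABEL:
            continue
        group = ObserverGroup(
            structure_label=label,
            masks=[pdata.observers[oid][label] for oid in observer_ids],
            reference=pdata.standard[label],
        )
        rows.extend(group_report(group, patient_id=pdata.patient_id, observer_ids=observer_ids))
    return rows


def _dose_stage(pdata: PatientData, config: RunConfig) -> list[MetricRecord]:
    """PDC of the gold-standard PTV and OAR summary doses, for the standard
    plan and every observer plan, plus the observer-minus-standard deltas."""
    rows: list[MetricRecord] = []
    pid = pdata.patient_id
    rx = config.dose_model.prescriptions_gy[PTV_LABEL]
    std_ptv = pdata.standard[PTV_LABEL]
    std_pdc = pdc(pdata.standard_dose, std_ptv, rx)
    rows.append(MetricRecord(pid, "standard", PTV_LABEL, "PDC_pct", std_pdc, "%"))
    std_summary = {}
    for label, klass in config.organ_classes.items():
        summ = dose_summary(pdata.standard_dose, pdata.standard[label], klass)
        params = config.ntcp_params.get(label)
        which = params.summary if params is not None else ("dmax" if klass == "serial" else "dmean")
        d = {"dmax": summ.Dmax_gy, "dmean": summ.Dmean_gy, "d1cc": summ.D1cc_gy}[which]
        std_summary[label] = d
        name = {"dmax": "Dmax_gy", "dmean": "Dmean_gy", "d1cc": "D1cc_gy"}[which]
        rows.append(MetricRecord(pid, "standard", label, name, d, "Gy"))
    for oid, odose in pdata.observer_doses.items():
        o_pdc = pdc(odose, std_ptv, rx)
        rows.append(MetricRecord(pid, oid, PTV_LABEL, "PDC_pct", o_pdc, "%"))
        rows.append(MetricRecord(pid, oid, PTV_LABEL, "dPDC_pct", o_pdc - std_pdc, "%"))
        for label, klass in config.organ_classes.items():
            summ = dose_summary(odose, pdata.standard[label], klass)
            params = config.ntcp_params.get(label)
            which = params.summary if params is not None else ("dmax" if klass == "serial" else "dmean")
            d = {"dmax": summ.Dmax_gy, "dmean": summ.Dmean_gy, "d1cc": summ.D1cc_gy}[which]
            name = {"dmax": "Dmax_gy", "dmean": "Dmean_gy", "d1cc": "D1cc_gy"}[which]
            rows.append(MetricRecord(pid, oid, label, name, d, "Gy"))
            if std_summary[label] > 0:
                rows.append(
                    MetricRecord(pid, oid, label, "dDdiff_pct",
                                 delta_d_diff(d, std_summary[label]), "%")
                )
    return rows


def _radbio_stage(pdata: PatientData, config: RunConfig) -> list[MetricRecord]:
    """EUD/TCP on the gold-standard PTV under each plan; NTCP per OAR;
    signed deltas versus the standard plan (percentage points)."""
    rows: list[MetricRecord] = []
    pid = pdata.patient_id
    std_ptv = pdata.standard[PTV_LABEL]
    tparams = RadiobioParams(a_exponent=config.target_a_exponent)

    def plan_tcp(dose) -> tuple[float, float]:
        doses = dose.dose_gy[std_ptv.occupancy]
        e = eud(doses, a_exponent=config.target_a_exponent)
        return e, tcp(e, tparams)

    std_eud, std_tcp = plan_tcp(pdata.standard_dose)
    rows.append(MetricRecord(pid, "standard", PTV_LABEL, "EUD_gy", std_eud, "Gy"))
    rows.append(MetricRecord(pid, "standard", PTV_LABEL, "TCP", std_tcp, ""))
    std_ntcp = {}
    for label, params in config.ntcp_params.items():
        summ = dose_summary(pdata.standard_dose, pdata.standard[label], params.organ_class)
        d = {"dmax": summ.Dmax_gy, "dmean": summ.Dmean_gy, "d1cc": summ.D1cc_gy}[params.summary]
        std_ntcp[label] = ntcp(d, 1.0, params, gamma_mode=config.gamma_mode)
        rows.append(MetricRecord(pid, "standard", label, "NTCP", std_ntcp[label], ""))
    for oid, odose in pdata.observer_doses.items():
        o_eud, o_tcp = plan_tcp(odose)
        rows.append(MetricRecord(pid, oid, PTV_LABEL, "EUD_gy", o_eud, "Gy"))
        rows.append(MetricRecord(pid, oid, PTV_LABEL, "TCP", o_tcp, ""))
        rows.append(MetricRecord(pid, oid, PTV_LABEL, "dTCP", 100.0 * (o_tcp - std_tcp), "%"))
        for label, params in config.ntcp_params.items():
            summ = dose_summary(odose, pdata.standard[label], params.organ_class)
            d = {"dmax": summ.Dmax_gy, "dmean": summ.Dmean_gy, "d1cc": summ.D1cc_gy}[params.summary]
            o_ntcp = ntcp(d, 1.0, params, gamma_mode=config.gamma_mode)
            rows.append(MetricRecord(pid, oid, label, "NTCP", o_ntcp, ""))
            rows.append(
                MetricRecord(pid, oid, label, "dNTCP", 100.0 * (o_ntcp - std_ntcp[label]), "%")
            )
    return rows


DEFAULT_X_METRICS = [
    (TARGET_LABEL, "dV_cc"),
    (TARGET_LABEL, "DSC"),
    (TARGET_LABEL, "HD95_mm"),
]
DEFAULT_Y_METRICS = [
    (PTV_LABEL, "dPDC_pct"),
    (PTV_LABEL, "dTCP"),
]


def run_all(config: RunConfig) -> dict:
    """Run the full analysis and return the output tables.

    Returns a dict with DataFrames ``metrics`` (geometric), ``dose_metrics``,
    ``radbio``, ``correlations``, ``predictors`` and the ``manifest`` dict.
    With ``write_outputs`` (default) the tables are also written as CSV under
    ``config.out_dir`` along with ``manifest.json``.
    """
    geo_rows: list[MetricRecord] = []
    dose_rows: list[MetricRecord] = []
    rad_rows: list[MetricRecord] = []
    n_patients = 0
    for pdata in _iter_cohort(config):
        n_patients += 1
        logger.info("patient %s: %d structures", pdata.patient_id, len(pdata.standard.masks))
        try:
            geo_rows.extend(_geometric_stage(pdata))
        except Exception as exc:  # noqa: BLE001 - annotate the failing stage
            raise RuntimeError(f"geometric stage failed for {pdata.patient_id}: {exc}") from exc
        try:
            dose_rows.extend(_dose_stage(pdata, config))
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"dose stage failed for {pdata.patient_id}: {exc}") from exc
        try:
            rad_rows.extend(_radbio_stage(pdata, config))
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"radiobiology stage failed for {pdata.patient_id}: {exc}") from exc

    metrics = records_to_frame(geo_rows)
    dose_metrics = records_to_frame(dose_rows)
    radbio = records_to_frame(rad_rows)
    pooled = pd.concat([metrics, dose_metrics, radbio], ignore_index=True)
    pooled = pooled[pooled["observer_id"] != "standard"]

    corr_results = correlation_matrix(
        pooled, DEFAULT_X_METRICS, DEFAULT_Y_METRICS, pooling=config.pooling
    )
    correlations = results_frame(corr_results)
    predictors = results_frame(select_predictors(corr_results))

    manifest = {
        "seed": config.seed,
        "n_patients": n_patients,
        "config_hash": config.config_hash(),
        "pooling": config.pooling,
        "gamma_mode": config.gamma_mode,
        "target_a_exponent": config.target_a_exponent,
        "eud_cold_clamp_gy": 0.01,
        "prescriptions_gy": dict(config.dose_model.prescriptions_gy),
        "ptv_margin_mm": config.ptv_margin_mm,
    }
    outputs = {
        "metrics": metrics,
        "dose_metrics": dose_metrics,
        "radbio": radbio,
        "correlations": correlations,
        "predictors": predictors,
        "manifest": manifest,
    }
    if config.write_outputs:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        metrics.to_csv(out / "metrics.csv", index=False)
        dose_metrics.to_csv(out / "dose_metrics.csv", index=False)
        radbio.to_csv(out / "radbio.csv", index=False)
        correlations.to_csv(out / "corr.csv", index=False)
        predictors.to_csv(out / "predictors.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outputs


def report(outputs: dict) -> pd.DataFrame:
    """Mean +- sample-SD summary per structure and metric across the cohort,
    with the selected-predictor list appended as an attribute.

    Returns a DataFrame with columns structure_label, metric_name, mean, sd,
    n; ``report(...).attrs["predictors"]`` holds the predictors table and
    ``attrs["markdown"]`` a rendered text table.
    """
    for key in ("metrics", "dose_metrics", "radbio", "predictors"):
        if key not in outputs:
            raise ValueError(f"missing pipeline output {key!r}")
    pooled = pd.concat(
        [outputs["metrics"], outputs["dose_metrics"], outputs["radbio"]],
        ignore_index=True,
    )
    pooled = pooled[pooled["observer_id"] != "standard"]
    grp = pooled.groupby(["structure_label", "metric_name"])["value"]
    summary = grp.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    lines = ["| structure | metric | mean | sd | n |", "|---|---|---|---|---|"]
    for _, row in summary.iterrows():
        lines.append(
            f"| {row.structure_label} | {row.metric_name} "
            f"| {row['mean']:.4g} | {row.sd:.4g} | {int(row.n)} |"
        )
    summary.attrs["predictors"] = outputs["predictors"]
    summary.attrs["markdown"] = "\n".join(lines)
    return summary
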
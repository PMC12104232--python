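"""Radiobiological endpoints: EUD, logistic TCP and modified-LQ NTCP.

The equivalent uniform dose (EUD) is the generalized power mean of the
voxel doses, EUD = (sum_i v_i d_i^a)^(1/a); a strongly negative exponent
(a = -8 for targets) makes cold spots dominate, which is the mechanism
coupling target under-contouring to loss of tumor control.

Tumor control probability follows the Schultheiss logistic model

    TCP = 1 / (1 + (TCD50 / EUD)^(4*gamma50))

with TCD50 = 61.69 Gy, gamma50 = 3.38 and a = -8 by default (Okunieff
parameters for nasopharyngeal targets).  Normal-tissue complication
probability follows a modified linear-quadratic (Zaider-style) model

    NTCP(D, V) = exp[ -N0 * V^(-k) * exp(-alpha * D * Gamma) ]

where Gamma carries the LQ fractionation correction.  The printed form of
Gamma is ambiguous between a per-fraction and a total-dose reading; the
default is Gamma = 1 + d_f / (alpha/beta) with d_f = D / n_fractions
(33 fractions), with ``gamma_mode="total_dose"`` giving
Gamma = 1 + D / (alpha/beta).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MetricRecord

__all__ = ["RadiobioParams", "eud", "tcp", "ntcp", "endpoint_deltas"]

#: cold-voxel clamp for negative EUD exponents (Gy)
EUD_EPS_GY = 0.01


@dataclass
class RadiobioParams:
    """Parameters of the TCP and NTCP models for one structure.

    Target parameters (tcd50_gy, gamma50, a_exponent) default to the
    published nasopharyngeal values; NTCP parameters (n0, k, alpha,
    alpha_beta_gy) have no published defaults here and must be supplied per
    organ.
    """

    organ_class: str = "target"  # target | serial | parallel
    tcd50_gy: float = 61.69
    gamma50: float = 3.38
    a_exponent: float = -8.0
    n0: float | None = None
    k: float | None = None
    alpha: float | None = None  # per Gy
    alpha_beta_gy: float | None = None
    n_fractions: int = 33
    summary: str = "dmax"  # which dose summary drives NTCP: dmax|dmean|d1cc

    def __post_init__(self) -> None:
        if self.tcd50_gy <= 0:
            raise ValueError("tcd50_gy must be positive")
        if self.a_exponent == 0:
            raise ValueError("a_exponent must be nonzero")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        for name in ("n0", "k", "alpha", "alpha_beta_gy"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be nonnegative")
        # N0 = 0 would force NTCP = 1 regardless of dose, which is
        # biologically meaningless; reject it at validation time.
        if self.n0 is not None and self.n0 == 0:
            raise ValueError("n0 must be strictly positive")
        if self.alpha_beta_gy is not None and self.alpha_beta_gy == 0:
            raise ValueError("alpha_beta_gy must be strictly positive")

    def require_ntcp(self) -> None:
        missing = [n for n in ("n0", "k", "alpha", "alpha_beta_gy") if getattr(self, n) is None]
        if missing:
            raise ValueError(f"NTCP parameters missing: {missing}")


def eud(voxel_doses_gy, volumes_frac=None, a_exponent: float = -8.0) -> float:
    """Equivalent uniform dose (Gy): generalized power mean of voxel doses.

    ``volumes_frac`` are relative volume weights summing to 1 (uniform if
    omitted).  For negative exponents, doses below 0.01 Gy are clamped to
    0.01 Gy so d^a does not diverge; the clamp makes a single near-zero
    voxel collapse the EUD, which is the intended cold-spot sensitivity.
    """
    if a_exponent == 0:
        raise ValueError("a_exponent must be nonzero")
    d = np.asarray(voxel_doses_gy, dtype=float)
    if d.size == 0:
        raise ValueError("no voxel doses")
    if np.any(d < 0):
        raise ValueError("doses must be nonnegative")
    if volumes_frac is None:
        v = np.full(d.size, 1.0 / d.size)
    else:
        v = np.asarray(volumes_frac, dtype=float)
        if v.shape != d.shape:
            raise ValueError("volumes and doses must have matching shapes")
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError("volume fractions must sum to 1")
    if a_exponent < 0:
        d = np.maximum(d, EUD_EPS_GY)
    # power mean in log space for numerical stability at large |a|
    with np.errstate(divide="raise"):
        logd = np.log(d) if a_exponent < 0 else np.log(np.maximum(d, 1e-300))
    from scipy.special import logsumexp

    lse = logsumexp(a_exponent * logd, b=v)
    return float(np.exp(lse / a_exponent))


def tcp(eud_gy: float, params: RadiobioParams | None = None) -> float:
    """Schultheiss logistic tumor control probability in (0, 1).

    TCP = 1 / (1 + (TCD50/EUD)^(4*gamma50)); the exponent is literally
    4*gamma50, so TCP(TCD50) = 0.5 exactly for any slope.
    """
    if params is None:
        params = RadiobioParams()
    if eud_gy <= 0:
        raise ValueError("EUD must be positive")
    return float(1.0 / (1.0 + (params.tcd50_gy / eud_gy) ** (4.0 * params.gamma50)))


def ntcp(
    dose_gy: float,
    rel_volume: float = 1.0,
    params: RadiobioParams | None = None,
    gamma_mode: str = "per_fraction",
) -> float:
    """Modified linear-quadratic NTCP in (0, 1].

    NTCP = exp[-N0 * V^(-k) * exp(-alpha * D * Gamma)] where D is the
    organ's class-appropriate summary dose (serial: Dmax or D1cc; parallel:
    Dmean or D1cc) and V the relative irradiated volume (1 in the default
    uniform-summary mode).  Gamma = 1 + d_f/(alpha/beta) with
    d_f = D/n_fractions, or 1 + D/(alpha/beta) with
    ``gamma_mode="total_dose"``.
    """
    if params is None:
        raise ValueError("NTCP requires organ parameters")
    params.require_ntcp()
    if dose_gy < 0:
        raise ValueError("dose must be nonnegative")
    if not 0 < rel_volume <= 1:
        raise ValueError("relative volume must be in (0, 1]")
    if gamma_mode == "per_fraction":
        d_f = dose_gy / params.n_fractions
        gamma = 1.0 + d_f / params.alpha_beta_gy
    elif gamma_mode == "total_dose":
        gamma = 1.0 + dose_gy / params.alpha_beta_gy
    else:
        raise ValueError(f"unknown gamma_mode {gamma_mode!r}")
    surviving = np.exp(-params.alpha * dose_gy * gamma)
    return float(np.exp(-params.n0 * rel_volume ** (-params.k) * surviving))


def endpoint_deltas(
    observer_endpoints: dict[str, float],
    standard_endpoints: dict[str, float],
    patient_id: str = "",
    observer_id: str = "",
    metric: str = "dTCP",
) -> list[MetricRecord]:
    """Signed observer-minus-standard endpoint differences, in percentage
    points, one record per structure label.

    ``metric`` is ``"dTCP"`` or ``"dNTCP"``; endpoint dicts map structure
    label -> probability in [0, 1].
    """
    if metric not in ("dTCP", "dNTCP"):
        raise ValueError("metric must be dTCP or dNTCP")
    obs_labels = set(observer_endpoints)
    std_labels = set(standard_endpoints)
    if obs_labels != std_labels:
        raise ValueError(
            f"label mismatch: only-observer={sorted(obs_labels - std_labels)}, "
            f"only-standard={sorted(std_labels - obs_labels)}"
        )
    rows = []
    for label in observer_endpoints:
        d = 100.0 * (observer_endpoints[label] - standard_endpoints[label])
        rows.append(MetricRecord(patient_id, observer_id, label, metric, d, "%"))
    return rows
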
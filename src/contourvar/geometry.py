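"""Inter-observer geometric variability metrics and the STAPLE consensus.

Five metrics quantify how much independently delineated structures differ:
the signed volume difference versus a gold standard (dV), the max-to-min
volume ratio (MMR), the coefficient of variation of observer volumes (CV),
the Dice similarity coefficient (DSC) and the 95th-percentile Hausdorff
distance (HD95).  A STAPLE expectation-maximization consensus turns a panel
of observer masks into a probabilistic gold standard with per-observer
sensitivity/specificity estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import MetricRecord, StructureMask, VoxelGrid

__all__ = [
    "ObserverGroup",
    "delta_v",
    "mmr",
    "cv",
    "dsc",
    "hd95",
    "hd95_directed",
    "boundary_voxels",
    "staple",
    "StapleResult",
    "group_report",
]


@dataclass
class ObserverGroup:
    """Masks of one structure from >=2 observers, with an optional reference."""

    structure_label: str
    masks: list[StructureMask]
    reference: StructureMask | None = None

    def __post_init__(self) -> None:
        if len(self.masks) < 2:
            raise ValueError("need at least 2 observer masks")
        grid = self.masks[0].grid
        for m in self.masks[1:]:
            if m.grid != grid:
                raise ValueError("all observer masks must share one grid")
        if self.reference is not None and self.reference.grid != grid:
            raise ValueError("reference mask must share the observer grid")


def delta_v(vm: float, vs: float) -> float:
    """Signed volume difference (cc): observer volume minus standard volume.

    Negative values mean the observer under-contoured relative to the
    gold standard.
    """
    if vm < 0 or vs < 0:
        raise ValueError("volumes must be nonnegative")
    return vm - vs


def mmr(volumes) -> float:
    """Max-to-min ratio of observer volumes (dimensionless, >= 1)."""
    v = np.asarray(volumes, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 volumes")
    if np.any(v <= 0):
        raise ValueError("all volumes must be positive for MMR")
    return float(v.max() / v.min())


def cv(volumes) -> float:
    """Coefficient of variation of observer volumes: sample SD / mean.

    The sample standard deviation (n-1 denominator) is used, the usual
    convention for small observer panels.
    """
    v = np.asarray(volumes, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 volumes")
    mean = v.mean()
    if mean <= 0:
        raise ValueError("mean volume must be positive for CV")
    return float(v.std(ddof=1) / mean)


def _check_same_grid(a: StructureMask, b: StructureMask) -> None:
    if a.grid != b.grid:
        raise ValueError("masks must share the same grid")


def dsc(a: StructureMask, b: StructureMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|), in [0, 1]."""
    _check_same_grid(a, b)
    na, nb = a.n_voxels, b.n_voxels
    if na == 0 and nb == 0:
        raise ValueError("DSC undefined for two empty masks")
    inter = int(np.count_nonzero(a.occupancy & b.occupancy))
    return 2.0 * inter / (na + nb)


def boundary_voxels(mask: StructureMask) -> np.ndarray:
    """Boolean boundary map: occupied voxels with an unoccupied 6-neighbor.

    Voxels touching the volume edge count as boundary (the outside is
    treated as unoccupied).
    """
    occ = mask.occupancy
    struct = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    interior = ndimage.binary_erosion(occ, structure=struct, border_value=0)
    return occ & ~interior


def hd95_directed(a: StructureMask, b: StructureMask) -> float:
    """Directed HD95 (mm): 95th percentile of distances from A's boundary
    voxels to the nearest boundary voxel of B."""
    _check_same_grid(a, b)
    if a.is_empty() or b.is_empty():
        raise ValueError("HD95 undefined for an empty mask")
    # boundary distances are local: crop to the union bounding box (+1 voxel
    # so interior/boundary classification at the crop border is unchanged)
    from .core import bbox_slices

    box = bbox_slices(a.occupancy | b.occupancy, (1, 1, 1))
    sub = lambda m: StructureMask(  # noqa: E731
        grid=VoxelGrid(m.occupancy[box].shape, m.grid.spacing_mm),
        occupancy=m.occupancy[box],
        label=m.label,
    )
    ba = boundary_voxels(sub(a))
    bb = boundary_voxels(sub(b))
    # distance from every voxel to the nearest B-boundary voxel center
    dt = ndimage.distance_transform_edt(~bb, sampling=a.grid.spacing_mm)
    d = dt[ba]
    return float(np.percentile(d, 95))  # linear interpolation between order stats


def hd95(a: StructureMask, b: StructureMask) -> float:
    """Symmetric HD95 (mm): max of the two directed 95th-percentile distances.

    Distances are between boundary-voxel centers with anisotropic spacing;
    the percentile uses linear interpolation between order statistics.
    """
    return max(hd95_directed(a, b), hd95_directed(b, a))


# ---------------------------------------------------------------------------
# STAPLE


@dataclass
class StapleResult:
    consensus: StructureMask
    sensitivity: np.ndarray  # p, per observer
    specificity: np.ndarray  # q, per observer
    posterior: np.ndarray  # per-voxel probability of foreground
    prior: float
    n_iter: int
    converged: bool


def staple(
    masks: list[StructureMask],
    max_iter: int = 100,
    tol: float = 1e-6,
    prior: float | None = None,
    init_p: float = 0.99,
    init_q: float = 0.99,
    threshold: float = 0.5,
    estimate_performance: bool = True,
) -> StapleResult:
    """Simultaneous Truth and Performance Level Estimation (EM consensus).

    Binary performance model: each observer j labels voxels with sensitivity
    p_j and specificity q_j given an unknown true segmentation T.  The
    E-step computes the per-voxel posterior W_i = P(T_i=1 | votes, p, q)
    under a global foreground prior; the M-step re-estimates (p, q).
    Convergence when max |Δp|, |Δq| < tol.  The consensus mask is
    W >= threshold (default 0.5; posterior ties fall into the consensus).

    The default prior is the mean observer foreground fraction; it is
    recorded in the result for the run manifest.

    With ``estimate_performance=False`` the performance rates stay fixed at
    (init_p, init_q) for every observer and only one E-step is taken: this
    is the equally-reliable-observers special case, in which the posterior
    with a uniform prior reduces exactly to majority vote.
    """
    if len(masks) < 2:
        raise ValueError("need at least 2 observer masks")
    grid = masks[0].grid
    for m in masks[1:]:
        if m.grid != grid:
            raise ValueError("all masks must share one grid")
    D = np.stack([m.occupancy.ravel() for m in masks]).astype(float)  # (K, N)
    K, N = D.shape
    eps = 1e-6
    if np.any(D.sum(axis=1) == 0):
        warnings.warn(
            "an observer mask is all-empty; its sensitivity is undefined and "
            "its performance rates are clamped",
            stacklevel=2,
        )
    if prior is None:
        prior = float(D.mean())
    prior = float(np.clip(prior, eps, 1 - eps))
    p = np.full(K, float(init_p))
    q = np.full(K, float(init_q))
    W = np.empty(N)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        # E-step in log space for numerical safety
        log_a = np.log(prior) + (
            D.T @ np.log(p) + (1 - D).T @ np.log(1 - p)
        )
        log_b = np.log(1 - prior) + (
            (1 - D).T @ np.log(q) + D.T @ np.log(1 - q)
        )
        m = np.maximum(log_a, log_b)
        W = np.exp(log_a - m) / (np.exp(log_a - m) + np.exp(log_b - m))
        if not estimate_performance:
            converged = True
            break
        # M-step
        sw = W.sum()
        swc = (1 - W).sum()
        p_new = np.clip((D @ W) / max(sw, eps), eps, 1 - eps)
        q_new = np.clip(((1 - D) @ (1 - W)) / max(swc, eps), eps, 1 - eps)
        delta = max(np.abs(p_new - p).max(), np.abs(q_new - q).max())
        p, q = p_new, q_new
        if delta < tol:
            converged = True
            break
    consensus = StructureMask(
        grid=grid,
        occupancy=(W >= threshold).reshape(grid.shape),
        label=masks[0].label or "consensus",
    )
    return StapleResult(
        consensus=consensus,
        sensitivity=p,
        specificity=q,
        posterior=W.reshape(grid.shape),
        prior=prior,
        n_iter=n_iter,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Report


def group_report(
    group: ObserverGroup,
    patient_id: str = "",
    observer_ids: list[str] | None = None,
) -> list[MetricRecord]:
    """Per-observer dV / DSC / HD95 versus the reference, plus group MMR / CV.

    MMR and CV are computed over the observer volumes only (the gold
    standard is excluded, mirroring the per-physician versus group-dispersion
    column convention).  Emits 3K + 2 records for K observers.
    """
    if group.reference is None:
        raise ValueError("group_report requires a reference (gold standard) mask")
    ref = group.reference
    vs = ref.volume_cc
    if observer_ids is None:
        observer_ids = [f"observer_{i + 1}" for i in range(len(group.masks))]
    rows: list[MetricRecord] = []
    label = group.structure_label
    for oid, m in zip(observer_ids, group.masks):
        rows.append(MetricRecord(patient_id, oid, label, "dV_cc", delta_v(m.volume_cc, vs), "cc"))
        rows.append(MetricRecord(patient_id, oid, label, "DSC", dsc(m, ref), ""))
        rows.append(MetricRecord(patient_id, oid, label, "HD95_mm", hd95(m, ref), "mm"))
    vols = [m.volume_cc for m in group.masks]
    rows.append(MetricRecord(patient_id, "group", label, "MMR", mmr(vols), ""))
    rows.append(MetricRecord(patient_id, "group", label, "CV", cv(vols), ""))
    return rows
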
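"""Statistical layer: paired observer-vs-standard tests, Spearman
correlation matrices between geometric variability and dosimetric /
prognostic deltas, and the risk-predictor selection rule
(|R| > 0.4 and P < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedSample",
    "PairedTestResult",
    "CorrelationResult",
    "paired_compare",
    "spearman",
    "correlation_matrix",
    "select_predictors",
    "R_THRESHOLD",
    "P_THRESHOLD",
]

R_THRESHOLD = 0.4
P_THRESHOLD = 0.05

#: sample size at or below which the Spearman p-value is exact-permutation
SPEARMAN_EXACT_N = 10


@dataclass
class PairedSample:
    """Matched observer/standard vectors of one metric (one entry per patient)."""

    metric_name: str
    observer_values: np.ndarray
    standard_values: np.ndarray

    def __post_init__(self) -> None:
        self.observer_values = np.asarray(self.observer_values, dtype=float)
        self.standard_values = np.asarray(self.standard_values, dtype=float)
        if self.observer_values.shape != self.standard_values.shape:
            raise ValueError("paired vectors must have equal length")
        if self.observer_values.size < 3:
            raise ValueError("need at least 3 pairs")


@dataclass
class PairedTestResult:
    test_name: str  # "paired_t" | "wilcoxon" | "no_difference"
    statistic: float
    p_value: float
    normal: bool
    no_difference: bool = False


@dataclass
class CorrelationResult:
    x_name: str
    y_name: str
    r: float
    p_value: float
    n: int

    @property
    def selected(self) -> bool:
        return self.p_value < P_THRESHOLD and abs(self.r) > R_THRESHOLD


def paired_compare(sample: PairedSample, alpha_normality: float = 0.05) -> PairedTestResult:
    """Paired t-test or Wilcoxon signed-rank, chosen by normality of the
    paired differences.

    Shapiro-Wilk at ``alpha_normality`` on the differences decides: normal
    differences use the paired t-test, otherwise the Wilcoxon signed-rank
    test (exact for n < 25 where ties permit; zero differences excluded).
    All-zero differences short-circuit to a flagged "no difference" result
    with p = 1.
    """
    diffs = sample.observer_values - sample.standard_values
    if np.allclose(diffs, 0.0):
        return PairedTestResult("no_difference", 0.0, 1.0, normal=True, no_difference=True)
    if np.ptp(diffs) == 0:
        normal = False  # constant nonzero shift: normality test degenerate
    else:
        try:
            _, p_norm = stats.shapiro(diffs)
            normal = p_norm > alpha_normality
        except ValueError:
            normal = False
    if normal:
        t, p = stats.ttest_rel(sample.observer_values, sample.standard_values)
        return PairedTestResult("paired_t", float(t), float(p), normal=True)
    nz = diffs[diffs != 0]
    method = "exact" if (nz.size < 25 and np.unique(np.abs(nz)).size == nz.size) else "auto"
    res = stats.wilcoxon(nz, zero_method="wilcox", method=method)
    return PairedTestResult("wilcoxon", float(res.statistic), float(res.pvalue), normal=False)


def _spearman_r(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)  # average ranks on ties
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def _exact_spearman_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact permutation p-value: enumerate all n! pairings of the rank
    vectors (ties kept as average ranks), two-sided on |r|.

    Only the cross-product term varies under permutation, so each pairing
    costs one dot product; enumeration is chunked to bound memory.
    """
    import itertools

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
    r_obs = float((rxc * ryc).sum() / denom)
    n_ge = 0
    n_total = 0
    perms = itertools.permutations(rxc)
    while True:
        chunk = list(itertools.islice(perms, 200_000))
        if not chunk:
            break
        rs = np.asarray(chunk) @ ryc / denom
        n_ge += int(np.sum(np.abs(rs) >= abs(r_obs) - 1e-12))
        n_total += len(chunk)
    return n_ge / n_total


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties.

    The p-value is from exact permutation of pairings for n <= 10 and the
    t-approximation otherwise.  A constant input vector has undefined rank
    correlation and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman r undefined for a constant vector")
    if n <= SPEARMAN_EXACT_N:
        return _spearman_r(x, y), _exact_spearman_p(x, y)
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def correlation_matrix(
    records: pd.DataFrame,
    x_metrics: list[tuple[str, str]],
    y_metrics: list[tuple[str, str]],
    pooling: str = "pooled",
) -> list[CorrelationResult]:
    """Spearman correlations between geometric metrics and dose/prognosis deltas.

    ``records`` is a long table with columns patient_id, observer_id,
    structure_label, metric_name, value.  Each metric is addressed as a
    (structure_label, metric_name) pair.  In the default ``pooled`` mode all
    (patient, observer) pairs are pooled into one vector per metric (the
    12 patients x 4 observers = 48-pair convention); ``per_observer``
    averages over observers first, correlating per-patient means.
    Missing cells are excluded pairwise with a warning.
    """
    if pooling not in ("pooled", "per_observer"):
        raise ValueError(f"unknown pooling mode {pooling!r}")

    def metric_series(label: str, name: str) -> pd.Series:
        sub = records[
            (records["structure_label"] == label) & (records["metric_name"] == name)
        ]
        if sub.empty:
            raise ValueError(f"no records for metric ({label}, {name})")
        s = sub.set_index(["patient_id", "observer_id"])["value"]
        if pooling == "per_observer":
            s = s.groupby(level="patient_id").mean()
        return s

    results: list[CorrelationResult] = []
    for xl, xm in x_metrics:
        xs = metric_series(xl, xm)
        for yl, ym in y_metrics:
            ys = metric_series(yl, ym)
            joined = pd.concat({"x": xs, "y": ys}, axis=1).dropna()
            if len(joined) < len(xs) or len(joined) < len(ys):
                import warnings

                warnings.warn(
                    f"missing cells for ({xl}/{xm}) vs ({yl}/{ym}); "
                    f"{len(joined)} complete pairs used",
                    stacklevel=2,
                )
            try:
                r, p = spearman(joined["x"].to_numpy(), joined["y"].to_numpy())
            except ValueError:
                # a constant metric (nothing varies) has undefined rank
                # correlation; report it as an unselected NaN row
                r, p = float("nan"), float("nan")
            results.append(
                CorrelationResult(
                    x_name=f"{xm}({xl})",
                    y_name=f"{ym}({yl})",
                    r=r,
                    p_value=p,
                    n=len(joined),
                )
            )
    return results


def select_predictors(results: list[CorrelationResult]) -> list[CorrelationResult]:
    """Risk-predictor selection: keep correlations with p < 0.05 and
    |r| > 0.4, sorted by |r| descending."""
    chosen = [c for c in results if c.selected]
    return sorted(chosen, key=lambda c: abs(c.r), reverse=True)


def results_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "x_name": c.x_name,
                "y_name": c.y_name,
                "n": c.n,
                "r": c.r,
                "p": c.p_value,
                "selected": c.selected,
            }
            for c in results
        ]
    )
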
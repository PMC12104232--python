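import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from contourvar.statistics import (
    CorrelationResult,
    PairedSample,
    correlation_matrix,
    paired_compare,
    select_predictors,
    spearman,
)


class TestPairedCompare:
    def test_identical_vectors_flagged_no_difference(self):
        s = PairedSample("Dmax_gy", [1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        res = paired_compare(s)
        assert res.no_difference
        assert res.p_value == 1.0

    def test_constant_shift_uses_wilcoxon(self):
        # degenerate (constant) differences defeat the normality test;
        # the signed-rank p then agrees with the exact sign-test null 2^-n
        n = 10
        obs = np.arange(n, dtype=float) + 1.0
        res = paired_compare(PairedSample("dV_cc", obs, obs - 1.0))
        assert res.test_name == "wilcoxon"
        assert res.p_value == pytest.approx(2.0 * 0.5**n, rel=1e-9)

    def test_normal_data_chooses_paired_t_and_matches_reference(self):
        rng = np.random.default_rng(12)
        a = rng.normal(10, 1, 20)
        b = a + rng.normal(0.5, 0.3, 20)
        res = paired_compare(PairedSample("TCP", a, b))
        assert res.test_name == "paired_t"
        t_ref, p_ref = stats.ttest_rel(a, b)
        assert res.p_value == pytest.approx(p_ref)

    def test_skewed_data_chooses_wilcoxon(self):
        rng = np.random.default_rng(13)
        a = rng.normal(10, 1, 30)
        b = a + rng.exponential(1.0, 30) ** 3  # heavily skewed differences
        res = paired_compare(PairedSample("NTCP", a, b))
        assert res.test_name == "wilcoxon"

    def test_detects_simulated_shift_with_calibrated_rate(self):
        # shift delta=1, sigma=1, n=12: rejection rate within a few percent
        # of the paired t-test's theoretical power (~85%)
        rng = np.random.default_rng(99)
        n_reject = 0
        reps = 400
        for _ in range(reps):
            a = rng.normal(0, 1, 12)
            b = a + rng.normal(1.0, 1.0, 12)
            if paired_compare(PairedSample("x", b, a)).p_value < 0.05:
                n_reject += 1
        power = stats.nct(11, 1.0 * np.sqrt(12)).sf(stats.t(11).ppf(0.975))
        assert n_reject / reps == pytest.approx(power, abs=0.05)


def hand_spearman(x, y):
    """Rank-formula oracle: Pearson correlation of hand-assigned ranks."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rxm, rym = rx - rx.mean(), ry - ry.mean()
    return float((rxm * rym).sum() / np.sqrt((rxm**2).sum() * (rym**2).sum()))


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 12.0])
        r, _ = spearman(x, np.exp(x))
        assert r == pytest.approx(1.0)
        r, _ = spearman(x, -(x**3))
        assert r == pytest.approx(-1.0)

    def test_hand_ranked_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        r, _ = spearman(x, y)
        assert r == pytest.approx(hand_spearman(x, y), abs=1e-12)
        # classic d^2 formula: 1 - 6*4/(5*24) = 0.8
        assert r == pytest.approx(0.8)

    def test_exact_permutation_p_small_n(self):
        # n=5: enumerate all 120 pairings explicitly as the oracle
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        r_obs, p = spearman(x, y)
        rs = [hand_spearman(x, np.array(perm)) for perm in itertools.permutations(y)]
        p_exact = np.mean([abs(r) >= abs(r_obs) - 1e-12 for r in rs])
        assert p == pytest.approx(p_exact, abs=1e-9)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(4)
        x = rng.random(40)
        y = x + rng.random(40)
        r, p = spearman(x, y)
        r_ref, p_ref = stats.spearmanr(x, y)
        assert r == pytest.approx(r_ref)
        assert p == pytest.approx(p_ref)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.random(15)
        y = rng.random(15)
        r0, _ = spearman(x, y)
        r1, _ = spearman(np.exp(3 * x), y)
        r2, _ = spearman(x, y**3 + 5)
        assert r0 == pytest.approx(r1, abs=1e-12)
        assert r0 == pytest.approx(r2, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


def make_records(values: dict) -> pd.DataFrame:
    """Long-format metric table from {(label, metric): {(pat, obs): value}}."""
    rows = []
    for (label, metric), cells in values.items():
        for (pat, obs), v in cells.items():
            rows.append(
                {
                    "patient_id": pat,
                    "observer_id": obs,
                    "structure_label": label,
                    "metric_name": metric,
                    "value": v,
                }
            )
    return pd.DataFrame(rows)


class TestCorrelationMatrix:
    def _paired_metric_table(self, n_pat=6, n_obs=4, seed=0, y_of_x=None):
        rng = np.random.default_rng(seed)
        xs, ys = {}, {}
        for p in range(n_pat):
            for o in range(n_obs):
                x = rng.random()
                xs[(f"p{p}", f"o{o}")] = x
                ys[(f"p{p}", f"o{o}")] = y_of_x(x, rng) if y_of_x else rng.random()
        return make_records({("GTV", "dV_cc"): xs, ("PTV", "dTCP"): ys})

    def test_monotone_relation_is_selected(self):
        records = self._paired_metric_table(y_of_x=lambda x, rng: x**3 + 1)
        res = correlation_matrix(records, [("GTV", "dV_cc")], [("PTV", "dTCP")])
        assert len(res) == 1
        assert res[0].r == pytest.approx(1.0)
        assert res[0].n == 24
        assert res[0].selected

    def test_matrix_shape_is_product(self):
        records = self._paired_metric_table()
        extra = records.copy()
        extra["metric_name"] = extra["metric_name"].replace(
            {"dV_cc": "HD95_mm", "dTCP": "dPDC_pct"}
        )
        full = pd.concat([records, extra])
        res = correlation_matrix(
            full,
            [("GTV", "dV_cc"), ("GTV", "HD95_mm")],
            [("PTV", "dTCP"), ("PTV", "dPDC_pct")],
        )
        assert len(res) == 4

    def test_duplicated_records_leave_r_unchanged(self):
        records = self._paired_metric_table(seed=5)
        res1 = correlation_matrix(records, [("GTV", "dV_cc")], [("PTV", "dTCP")])
        # duplicating every (patient, observer) pair preserves rank structure
        dup = records.copy()
        dup["observer_id"] = dup["observer_id"] + "_dup"
        res2 = correlation_matrix(
            pd.concat([records, dup]), [("GTV", "dV_cc")], [("PTV", "dTCP")]
        )
        assert res2[0].r == pytest.approx(res1[0].r, abs=1e-12)

    def test_constant_metric_yields_unselected_nan(self):
        records = self._paired_metric_table(y_of_x=lambda x, rng: 0.0)
        res = correlation_matrix(records, [("GTV", "dV_cc")], [("PTV", "dTCP")])
        assert np.isnan(res[0].r)
        assert not res[0].selected

    def test_missing_metric_raises(self):
        records = self._paired_metric_table()
        with pytest.raises(ValueError, match="no records"):
            correlation_matrix(records, [("GTV", "MMR")], [("PTV", "dTCP")])

    def test_null_selection_rate_is_conservative(self):
        # independent x, y at n=48: the double gate (|r|>0.4 and p<0.05)
        # fires in well under 5% of simulations
        rng = np.random.default_rng(2)
        hits = 0
        reps = 300
        for _ in range(reps):
            x = rng.random(48)
            y = rng.random(48)
            r, p = spearman(x, y)
            if p < 0.05 and abs(r) > 0.4:
                hits += 1
        assert hits / reps < 0.05


class TestSelectPredictors:
    def test_selection_rule(self):
        res = [
            CorrelationResult("dV", "dPDC", 0.686, 0.001, 48),
            CorrelationResult("CV", "dPDC", 0.35, 0.001, 48),
            CorrelationResult("MMR", "dPDC", 0.9, 0.2, 48),
            CorrelationResult("HD95", "dTCP", -0.75, 0.004, 48),
        ]
        chosen = select_predictors(res)
        assert [c.x_name for c in chosen] == ["HD95", "dV"]  # sorted by |r|

    def test_empty_input_allowed(self):
        assert select_predictors([]) == []
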
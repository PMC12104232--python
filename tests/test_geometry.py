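import numpy as np
import pytest
from scipy.spatial.distance import cdist

from contourvar.core import StructureMask, VoxelGrid
from contourvar.geometry import (
    ObserverGroup,
    boundary_voxels,
    cv,
    delta_v,
    dsc,
    group_report,
    hd95,
    hd95_directed,
    mmr,
    staple,
)
from conftest import box_mask


class TestVolumeMetrics:
    @pytest.mark.parametrize(
        "vm,vs,expected",
        [(30.0, 30.0, 0.0), (52.47, 29.93, 22.54), (10.0, 25.0, -15.0)],
    )
    def test_delta_v(self, vm, vs, expected):
        assert delta_v(vm, vs) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "vols,expected", [([4, 4, 4], 1.0), ([4, 6], 1.5), ([1.1, 2.0, 3.3, 5.5], 5.0)]
    )
    def test_mmr(self, vols, expected):
        assert mmr(vols) == pytest.approx(expected)

    def test_mmr_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            mmr([1.0, 0.0])

    @pytest.mark.parametrize(
        "vols,expected", [([5, 5, 5, 5], 0.0), ([4, 6], np.sqrt(2) / 5)]
    )
    def test_cv(self, vols, expected):
        assert cv(vols) == pytest.approx(expected)

    @pytest.mark.parametrize("scale", [0.1, 3.0, 250.0])
    def test_mmr_and_cv_scale_invariant(self, scale):
        vols = [2.1, 4.4, 3.3, 9.0]
        scaled = [v * scale for v in vols]
        assert mmr(scaled) == pytest.approx(mmr(vols))
        assert cv(scaled) == pytest.approx(cv(vols))
        assert mmr(scaled) >= 1.0


class TestDSC:
    def test_identical_masks(self, iso_grid):
        m = box_mask(iso_grid, (3, 3, 3), (10, 10, 10))
        assert dsc(m, m) == 1.0

    def test_disjoint_masks(self, iso_grid):
        a = box_mask(iso_grid, (1, 1, 1), (4, 4, 4))
        b = box_mask(iso_grid, (10, 10, 10), (14, 14, 14))
        assert dsc(a, b) == 0.0

    def test_half_overlapping_cubes(self, iso_grid):
        # two 2x2x2 cubes sharing a 2x2x1 face-slab: 2*4/16 = 0.5
        a = box_mask(iso_grid, (5, 5, 5), (7, 7, 7))
        b = box_mask(iso_grid, (5, 5, 6), (7, 7, 8))
        assert dsc(a, b) == pytest.approx(0.5)

    def test_both_empty_raises(self, iso_grid):
        e = box_mask(iso_grid, (0, 0, 0), (0, 0, 0))
        with pytest.raises(ValueError):
            dsc(e, e)

    def test_symmetry_on_random_masks(self, iso_grid):
        rng = np.random.default_rng(11)
        for _ in range(5):
            a = StructureMask(iso_grid, rng.random(iso_grid.shape) < 0.3, "a")
            b = StructureMask(iso_grid, rng.random(iso_grid.shape) < 0.3, "b")
            assert dsc(a, b) == dsc(b, a)

    def test_monotone_under_nested_erosion(self, iso_grid):
        # shrinking one mask inside a fixed superset never increases overlap
        full = box_mask(iso_grid, (4, 4, 4), (14, 14, 14))
        prev = 1.0
        for shrink in range(1, 5):
            inner = box_mask(iso_grid, (4, 4, 4), (14 - shrink, 14, 14))
            score = dsc(inner, full)
            assert score <= prev + 1e-12
            prev = score


def brute_force_hd95(a: StructureMask, b: StructureMask) -> float:
    """O(n^2) oracle: explicit all-pairs distances between boundary centers."""
    pa = a.grid.physical_coords(np.argwhere(boundary_voxels(a)))
    pb = b.grid.physical_coords(np.argwhere(boundary_voxels(b)))
    d = cdist(pa, pb)
    return max(
        float(np.percentile(d.min(axis=1), 95)),
        float(np.percentile(d.min(axis=0), 95)),
    )


class TestHD95:
    def test_identical_masks_zero(self, aniso_grid):
        m = box_mask(aniso_grid, (4, 4, 2), (10, 10, 6))
        assert hd95(m, m) == 0.0

    def test_single_voxels_five_slices_apart(self):
        g = VoxelGrid((5, 5, 12), (1.0, 1.0, 2.0))
        a = np.zeros(g.shape, bool)
        b = np.zeros(g.shape, bool)
        a[2, 2, 3] = True
        b[2, 2, 8] = True
        assert hd95(StructureMask(g, a, "a"), StructureMask(g, b, "b")) == pytest.approx(10.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2024)
        g = VoxelGrid((14, 14, 10), (1.0, 1.3, 2.5))
        for _ in range(25):
            a = StructureMask(g, rng.random(g.shape) < 0.25, "a")
            b = StructureMask(g, rng.random(g.shape) < 0.25, "b")
            if a.is_empty() or b.is_empty():
                continue
            assert hd95(a, b) == pytest.approx(brute_force_hd95(a, b), abs=1e-9)
            assert hd95(a, b) == hd95(b, a)

    def test_empty_mask_rejected(self, iso_grid):
        m = box_mask(iso_grid, (3, 3, 3), (6, 6, 6))
        e = box_mask(iso_grid, (0, 0, 0), (0, 0, 0))
        with pytest.raises(ValueError):
            hd95(m, e)

    def test_directed_values_bracket_symmetric(self, iso_grid):
        a = box_mask(iso_grid, (3, 3, 3), (10, 10, 10))
        b = box_mask(iso_grid, (5, 5, 5), (12, 12, 12))
        assert hd95(a, b) == max(hd95_directed(a, b), hd95_directed(b, a))


class TestStaple:
    def test_identical_observers_reproduce_input(self, iso_grid):
        m = box_mask(iso_grid, (4, 4, 4), (12, 12, 12))
        res = staple([m, m, m])
        np.testing.assert_array_equal(res.consensus.occupancy, m.occupancy)
        assert np.all(res.sensitivity > 0.99)
        assert np.all(res.specificity > 0.99)

    def test_two_of_three_vote_hand_computed_estep(self):
        # 4 voxels, votes per voxel: (1,1,1), (1,1,0), (1,0,0), (0,0,0);
        # equal reliabilities p=q=0.99, prior 0.5.  Hand-computed posterior:
        # W = pi*p^c(1-p)^(K-c) / [pi*p^c(1-p)^(K-c) + (1-pi)*(1-q)^c q^(K-c)]
        g = VoxelGrid((4, 1, 1), (1, 1, 1))
        votes = np.array([[1, 1, 1, 0], [1, 1, 0, 0], [1, 0, 0, 0]], dtype=bool)
        masks = [StructureMask(g, v.reshape(4, 1, 1), "m") for v in votes]
        res = staple(masks, prior=0.5, estimate_performance=False)
        p = 0.99
        for i, c in enumerate([3, 2, 1, 0]):
            a = p**c * (1 - p) ** (3 - c)
            b = (1 - p) ** c * p ** (3 - c)
            assert res.posterior.ravel()[i] == pytest.approx(a / (a + b), abs=1e-12)
        # the 2-of-3 voxel lands in the consensus, the 1-of-3 voxel does not
        np.testing.assert_array_equal(
            res.consensus.occupancy.ravel(), [True, True, False, False]
        )

    def test_consensus_invariant_to_observer_order(self, iso_grid):
        rng = np.random.default_rng(5)
        masks = [
            StructureMask(iso_grid, rng.random(iso_grid.shape) < 0.3, "m")
            for _ in range(4)
        ]
        res1 = staple(masks)
        res2 = staple(masks[::-1])
        np.testing.assert_array_equal(res1.consensus.occupancy, res2.consensus.occupancy)

    def test_all_empty_observer_warns(self, iso_grid):
        m = box_mask(iso_grid, (4, 4, 4), (10, 10, 10))
        e = box_mask(iso_grid, (0, 0, 0), (0, 0, 0))
        with pytest.warns(UserWarning, match="all-empty"):
            staple([m, m, e])

    def test_agrees_with_simpleitk_on_clear_consensus(self):
        # independent implementation cross-check on overlapping shifted boxes
        sitk = pytest.importorskip("SimpleITK")
        g = VoxelGrid((16, 16, 16), (1, 1, 1))
        masks = [
            box_mask(g, (3 + i, 3, 3), (11 + i, 11, 11), "m") for i in range(3)
        ]
        ours = staple(masks).consensus.occupancy
        imgs = [sitk.GetImageFromArray(m.occupancy.astype(np.uint8)) for m in masks]
        prob = sitk.GetArrayFromImage(sitk.STAPLE(imgs, 1.0))
        theirs = (prob >= 0.5).astype(bool)
        agreement = (ours == theirs).mean()
        assert agreement > 0.99


class TestGroupReport:
    def test_identical_copies_of_reference(self, iso_grid):
        ref = box_mask(iso_grid, (4, 4, 4), (12, 12, 12))
        group = ObserverGroup("GTV", [ref] * 4, reference=ref)
        rows = group_report(group)
        by_metric = {}
        for r in rows:
            by_metric.setdefault(r.metric_name, []).append(r.value)
        assert all(v == 0.0 for v in by_metric["dV_cc"])
        assert all(v == 1.0 for v in by_metric["DSC"])
        assert all(v == 0.0 for v in by_metric["HD95_mm"])
        assert by_metric["MMR"] == [1.0]
        assert by_metric["CV"] == [0.0]

    def test_eroded_observer_is_the_only_negative_delta(self, iso_grid):
        ref = box_mask(iso_grid, (4, 4, 4), (14, 14, 14))
        small = box_mask(iso_grid, (5, 5, 5), (13, 13, 13))
        big = box_mask(iso_grid, (3, 3, 3), (15, 15, 15))
        rows = group_report(ObserverGroup("GTV", [ref, small, big], reference=ref))
        dv = [r.value for r in rows if r.metric_name == "dV_cc"]
        assert sum(v < 0 for v in dv) == 1

    @pytest.mark.parametrize("k", [2, 4])
    def test_record_count_schema(self, iso_grid, k):
        ref = box_mask(iso_grid, (4, 4, 4), (12, 12, 12))
        rows = group_report(ObserverGroup("GTV", [ref] * k, reference=ref))
        assert len(rows) == 3 * k + 2

    def test_requires_reference(self, iso_grid):
        m = box_mask(iso_grid, (4, 4, 4), (12, 12, 12))
        with pytest.raises(ValueError, match="reference"):
            group_report(ObserverGroup("GTV", [m, m]))
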
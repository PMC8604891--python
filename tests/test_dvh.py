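"""DVH engine: trivial cases, brute-force oracles, and curve properties."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pqmchal.dvh import (
    compute_dvh,
    conformation_number,
    dose_at_volume_cc,
    dose_at_volume_percent,
    extract_metrics,
    mean_dose,
    ring,
    volume_at_dose_percent,
)
from pqmchal.errors import AlignmentError, EmptyStructureError

from .conftest import (
    make_dose,
    make_mask,
    oracle_cn,
    oracle_dose_at_fraction,
    oracle_volume_at_dose,
)


def uniform_case(value=50.0, shape=(4, 4, 4)):
    dose = make_dose(np.full(shape, value))
    mask = make_mask(np.ones(shape))
    return dose, mask


def two_voxel_case():
    vals = np.zeros((2, 1, 1))
    vals[0] = 40.0
    vals[1] = 60.0
    return make_dose(vals), make_mask(np.ones((2, 1, 1)))


class TestCurve:
    def test_uniform_dose_is_a_step_function(self):
        dose, mask = uniform_case(50.0)
        dvh = compute_dvh(dose, mask)
        below = dvh.dose_edges <= 50.0
        assert np.all(dvh.cum_volume_fraction[below] == 1.0)
        assert np.all(dvh.cum_volume_fraction[~below] == 0.0)

    def test_two_voxel_plateaus(self):
        dose, mask = two_voxel_case()
        dvh = compute_dvh(dose, mask)
        e, c = dvh.dose_edges, dvh.cum_volume_fraction
        assert np.all(c[e <= 40.0] == 1.0)
        assert np.all(c[(e > 40.0) & (e <= 60.0)] == 0.5)
        assert np.all(c[e > 60.0] == 0.0)

    def test_empty_mask_raises(self):
        dose, _ = uniform_case()
        with pytest.raises(EmptyStructureError):
            compute_dvh(dose, make_mask(np.zeros((4, 4, 4))))

    def test_shape_mismatch_raises(self):
        dose, _ = uniform_case()
        with pytest.raises(AlignmentError):
            compute_dvh(dose, make_mask(np.ones((3, 3, 3))))

    @given(st.integers(0, 2**31 - 1))
    def test_cumulative_fraction_monotone_on_random_grids(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(2, 7, size=3))
        dose = make_dose(rng.uniform(0, 75, size=shape))
        mask = make_mask(rng.random(shape) < 0.7)
        if not mask.voxels.any():
            return
        dvh = compute_dvh(dose, mask)
        assert np.all(np.diff(dvh.cum_volume_fraction) <= 1e-12)
        assert dvh.cum_volume_fraction[0] == 1.0


class TestInverseQueries:
    def test_uniform_d95(self):
        dose, mask = uniform_case(54.0)
        dvh = compute_dvh(dose, mask)
        assert dose_at_volume_percent(dvh, 95) == pytest.approx(54.0, abs=0.006)

    def test_d100_is_structure_minimum(self):
        dose, mask = two_voxel_case()
        dvh = compute_dvh(dose, mask)
        assert dose_at_volume_percent(dvh, 100) == pytest.approx(40.0, abs=0.01)

    def test_ten_voxel_d95_matches_sorted_oracle(self):
        doses = np.arange(1.0, 11.0)
        dose = make_dose(doses.reshape(10, 1, 1))
        mask = make_mask(np.ones((10, 1, 1)))
        dvh = compute_dvh(dose, mask)
        assert dose_at_volume_percent(dvh, 95) == pytest.approx(
            oracle_dose_at_fraction(doses, 0.95), abs=0.01
        )

    def test_full_volume_cc_query_is_minimum_dose(self):
        dose, mask = two_voxel_case()
        dvh = compute_dvh(dose, mask)
        assert dose_at_volume_cc(dvh, mask.volume_cc) == pytest.approx(40.0, abs=0.01)

    def test_hottest_voxel_cc_query(self):
        doses = np.arange(10.0, 90.0, 10.0)  # 8 voxels, 0.008 cc each
        dose = make_dose(doses.reshape(8, 1, 1))
        mask = make_mask(np.ones((8, 1, 1)))
        dvh = compute_dvh(dose, mask)
        assert dose_at_volume_cc(dvh, 0.008) == pytest.approx(
            oracle_dose_at_fraction(doses, 0.008 / mask.volume_cc), abs=0.01
        )

    def test_oversized_volume_query_names_both_volumes(self):
        dose, mask = two_voxel_case()
        dvh = compute_dvh(dose, mask)
        with pytest.raises(ValueError, match="exceeds structure volume"):
            dose_at_volume_cc(dvh, mask.volume_cc * 2)

    @pytest.mark.parametrize("x", [-5.0, 0.0, 101.0])
    def test_percent_out_of_range(self, x):
        dose, mask = uniform_case()
        dvh = compute_dvh(dose, mask)
        with pytest.raises(ValueError):
            dose_at_volume_percent(dvh, x)

    @given(st.integers(0, 2**31 - 1))
    def test_random_grids_match_sorted_voxel_oracle(self, seed):
        """Engine vs brute-force sorted-voxel counting, within one bin."""
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(3, 12, size=3))
        bin_w = 0.01
        # doses snapped to bin multiples so the oracle comparison is sharp
        vals = np.round(rng.uniform(0, 70, size=shape) / bin_w) * bin_w
        dose = make_dose(vals)
        mask = make_mask(rng.random(shape) < 0.6)
        if not mask.voxels.any():
            return
        doses = vals[mask.voxels]
        dvh = compute_dvh(dose, mask, bin_w)
        for x in (2.0, 35.0, 50.0, 95.0, 100.0):
            got = dose_at_volume_percent(dvh, x)
            want = oracle_dose_at_fraction(doses, x / 100)
            assert abs(got - want) <= bin_w + 1e-12
        for d_gy in (0.0, 20.0, 55.0):
            assert volume_at_dose_percent(dvh, d_gy) == pytest.approx(
                oracle_volume_at_dose(doses, d_gy), abs=1e-9
            )

    def test_bin_width_convergence(self):
        rng = np.random.default_rng(11)
        vals = rng.uniform(0, 70, size=(10, 10, 10))
        dose = make_dose(vals)
        mask = make_mask(np.ones((10, 10, 10)))
        for w in (0.08, 0.04, 0.02):
            a = dose_at_volume_percent(compute_dvh(dose, mask, w), 95)
            b = dose_at_volume_percent(compute_dvh(dose, mask, w / 2), 95)
            assert abs(a - b) < w


class TestMeanAndVolume:
    def test_uniform_mean(self):
        dose, mask = uniform_case(22.0)
        assert mean_dose(dose, mask) == 22.0

    def test_two_voxel_mean(self):
        dose, mask = two_voxel_case()
        assert mean_dose(dose, mask) == 50.0

    def test_random_mask_matches_direct_summation(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 70, size=(8, 8, 8))
        sel = rng.random((8, 8, 8)) < 0.25
        dose, mask = make_dose(vals), make_mask(sel)
        assert mean_dose(dose, mask) == pytest.approx(vals[sel].mean(), rel=1e-12)

    @pytest.mark.parametrize(
        "value,query,expected", [(54.0, 56.7, 0.0), (60.0, 56.7, 100.0)]
    )
    def test_uniform_volume_queries(self, value, query, expected):
        dose, mask = uniform_case(value)
        dvh = compute_dvh(dose, mask)
        assert volume_at_dose_percent(dvh, query) == pytest.approx(expected, abs=1e-9)

    def test_two_voxel_half_volume(self):
        dose, mask = two_voxel_case()
        dvh = compute_dvh(dose, mask)
        assert volume_at_dose_percent(dvh, 50.0) == pytest.approx(50.0, abs=1e-9)


class TestRing:
    def test_nested_ring_volume_is_difference(self):
        outer = make_mask(np.ones((4, 4, 4)), "outer")
        inner_v = np.zeros((4, 4, 4), bool)
        inner_v[1:3, 1:3, 1:3] = True
        inner = make_mask(inner_v, "inner")
        r = ring(outer, inner)
        assert r.voxel_count == outer.voxel_count - inner.voxel_count
        assert r.name == "outer-inner"

    def test_identical_masks_give_empty_ring(self):
        m = make_mask(np.ones((3, 3, 3)))
        assert ring(m, m).voxel_count == 0

    def test_disjoint_inner_leaves_outer(self):
        a = np.zeros((4, 4, 4), bool)
        a[:2] = True
        b = np.zeros((4, 4, 4), bool)
        b[3:] = True
        assert ring(make_mask(a), make_mask(b)).voxel_count == a.sum()

    def test_mismatched_grids_raise(self):
        with pytest.raises(AlignmentError):
            ring(make_mask(np.ones((3, 3, 3))), make_mask(np.ones((4, 4, 4))))


class TestConformationNumber:
    def test_perfect_conformity(self):
        vals = np.zeros((6, 6, 6))
        vals[2:4, 2:4, 2:4] = 60.0
        target = np.zeros((6, 6, 6), bool)
        target[2:4, 2:4, 2:4] = True
        res = conformation_number(make_dose(vals), make_mask(target), 54.0)
        assert res.cn == pytest.approx(1.0)
        assert not res.degenerate_isodose

    def test_voxel_count_example(self):
        # TV 1000 voxels, VRI 1200, overlap 900 -> CN = 900^2/(1000*1200)
        vals = np.zeros((20, 20, 20))
        target = np.zeros((20, 20, 20), bool)
        flat_t = np.arange(1000)  # target voxels 0..999
        flat_v = np.arange(100, 1300)  # isodose voxels 100..1299 (overlap 900)
        target.ravel()[flat_t] = True
        vals.ravel()[flat_v] = 60.0
        res = conformation_number(make_dose(vals), make_mask(target), 54.0)
        assert res.cn == pytest.approx(0.675, abs=1e-12)
        assert res.tvri_cc <= min(res.tv_cc, res.vri_cc)

    def test_cold_plan_degenerates_with_flag(self):
        vals = np.full((4, 4, 4), 10.0)
        res = conformation_number(make_dose(vals), make_mask(np.ones((4, 4, 4))), 54.0)
        assert res.cn == 0.0
        assert res.degenerate_isodose

    @given(st.integers(0, 2**31 - 1))
    def test_decomposition_on_random_grids(self, seed):
        rng = np.random.default_rng(seed)
        shape = (8, 8, 8)
        vals = rng.uniform(0, 70, size=shape)
        target = rng.random(shape) < 0.4
        if not target.any():
            return
        dose, mask = make_dose(vals), make_mask(target)
        res = conformation_number(dose, mask, 40.0)
        assert 0.0 <= res.cn <= 1.0
        assert res.cn == pytest.approx(res.coverage * res.selectivity, abs=1e-12)
        assert 0.0 <= res.coverage <= 1.0 and 0.0 <= res.selectivity <= 1.0
        assert res.cn == pytest.approx(
            oracle_cn(vals.ravel(), target.ravel(), 40.0, dose.voxel_volume_cc), abs=1e-12
        )


class TestExtractMetrics:
    def test_all_sixteen_metrics_on_a_painted_plan(self, phantom, scheme, painter, small_cohort):
        _, masks, _ = phantom
        dose = painter.paint(small_cohort[0])
        values = extract_metrics(dose, masks, [m for m, _ in scheme.metrics])
        assert len(values) == 16
        assert all(np.isfinite(v) for v in values.values())

    def test_unknown_structure_raises(self, scheme):
        dose, mask = uniform_case()
        with pytest.raises(KeyError):
            extract_metrics(dose, {"other": mask}, [m for m, _ in scheme.metrics])
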
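import numpy as np
import pytest

from gammaqa import (
    DoseGrid,
    EmptyMaskError,
    IGMode,
    RequirementKind,
    RequirementMap,
    SearchSettings,
    SearchStatus,
    ceil_to_step,
    gamma_map,
    GammaCriteria,
    ig_search,
    per_point_min_dd,
    per_point_min_dta,
    per_point_min_scale,
    per_point_requirements,
    quantile_fast_path,
    required_count,
    requirement_histogram,
    shift_field,
    square_field,
)
from conftest import smooth_random_pair, uniform_grid

NATIVE = SearchSettings(interp_step_mm=1.0)  # no resampling on 1 mm grids


def row_grid(values, spacing=1.0):
    return DoseGrid(np.asarray(values, dtype=float)[:, None], (spacing, 1.0))


class TestPerPointMinDta:
    def test_single_hot_pixel_needs_one_mm(self):
        # positions 0,1,2 mm; reference uniform 100, evaluated [110,100,100]:
        # point 0's nearest in-tolerance candidate is 1 mm away with delta=0
        ref = row_grid([100.0, 100.0, 100.0])
        ev = row_grid([110.0, 100.0, 100.0])
        req = per_point_min_dta(ref, ev, 3.0, NATIVE)
        assert req.values[:, 0].tolist() == [1.0, 0.0, 0.0]
        assert req.kind is RequirementKind.MIN_DTA_MM

    def test_identical_grids_need_nothing(self, rng):
        ref, _ = smooth_random_pair(rng, n=8)
        req = per_point_min_dta(ref, ref, 3.0, NATIVE)
        assert np.all(req.included_values == 0.0)

    def test_global_overdose_is_unreachable(self):
        req = per_point_min_dta(uniform_grid(100.0), uniform_grid(105.0), 3.0, NATIVE)
        assert np.all(np.isinf(req.included_values))
        assert req.n_unreachable == req.n_included


class TestPerPointMinDd:
    def test_uniform_offset_needs_its_dose_difference(self):
        for dta in [0.0, 1.0, 3.0]:
            req = per_point_min_dd(uniform_grid(100.0), uniform_grid(105.0), dta, NATIVE)
            assert np.allclose(req.included_values, 5.0)

    def test_identical_grids_need_nothing(self, rng):
        ref, _ = smooth_random_pair(rng, n=8)
        req = per_point_min_dd(ref, ref, 2.0, NATIVE)
        assert np.all(req.included_values == 0.0)

    def test_candidate_exactly_at_dta_with_dose_error_is_unreachable(self):
        # lone reference point at x=0; evaluated points only at x=+-1 with a
        # dose error: at r = dta the distance term alone saturates Gamma
        ref = DoseGrid([[100.0]], (1.0, 1.0), (0.0, 0.0))
        ev = DoseGrid([[90.0], [90.0]], (2.0, 1.0), (-1.0, 0.0))
        req = per_point_min_dd(ref, ev, 1.0, SearchSettings(interp_step_mm=2.0))
        assert np.isinf(req.values[0, 0])

    def test_candidate_exactly_at_dta_with_exact_dose_passes_free(self):
        ref = DoseGrid([[100.0]], (1.0, 1.0), (0.0, 0.0))
        ev = DoseGrid([[100.0], [90.0]], (2.0, 1.0), (-1.0, 0.0))
        req = per_point_min_dd(ref, ev, 1.0, SearchSettings(interp_step_mm=2.0))
        assert req.values[0, 0] == 0.0


class TestPerPointMinScale:
    def test_uniform_3pct_offset_with_ratio_3_needs_1mm(self):
        req = per_point_min_scale(uniform_grid(100.0), uniform_grid(103.0), 3.0, NATIVE)
        assert np.allclose(req.included_values, 1.0)  # pair (3%, 1 mm)

    def test_identical_grids_need_nothing(self, rng):
        ref, _ = smooth_random_pair(rng, n=8)
        req = per_point_min_scale(ref, ref, 3.0, NATIVE)
        assert np.all(req.included_values == 0.0)

    def test_pure_shift_requirement_is_the_shift(self):
        # with a small ratio the dose term is expensive, so the best
        # candidate in steep regions is the shifted twin (delta = 0, r = s)
        ref = square_field(extent_mm=60.0, spacing_mm=1.0, field_width_mm=40.0)
        ev = shift_field(ref, 2.0, 0.0)
        req = per_point_min_scale(ref, ev, 1.0, SearchSettings(interp_step_mm=0.2))
        # in the steep penumbra the in-dose-tolerance candidate is the twin
        grad = np.abs(np.gradient(ref.values, axis=0))
        steep = req.included_mask & (grad > 0.03 * ref.values.max())
        assert np.all(req.values[steep] <= 2.05)
        assert np.median(req.values[steep]) > 1.5


class TestIgSearch:
    def test_identity_converges_at_zero(self, rng):
        ref, _ = smooth_random_pair(rng, n=8)
        res = ig_search(ref, ref, "fixed_dd", 3.0, 100.0, NATIVE)
        assert res.converged
        assert res.found_dta_mm == 0.0
        assert res.achieved_gai_pct == 100.0
        assert res.n_iterations == 1
        assert res.trace[0] == (0.0, 100.0)

    def test_hot_pixel_row_needs_one_mm(self):
        ref = row_grid([100.0, 100.0, 100.0])
        ev = row_grid([110.0, 100.0, 100.0])
        res = ig_search(ref, ev, "fixed_dd", 3.0, 100.0, NATIVE)
        assert res.converged
        assert res.found_dta_mm == pytest.approx(1.0)
        # trace visits 0.0 .. 1.0 in 0.1 steps with 2/3 passing until the end
        assert res.n_iterations == 11
        assert res.trace[0][1] == pytest.approx(100.0 * 2 / 3)

    def test_global_overdose_hits_cap_with_zero_gai(self):
        st = SearchSettings(interp_step_mm=1.0, max_dta_mm=20.0)
        res = ig_search(uniform_grid(100.0), uniform_grid(105.0),
                        "fixed_dd", 3.0, 95.0, st)
        assert res.status is SearchStatus.CAP_REACHED
        assert res.achieved_gai_pct == 0.0
        assert res.found_dta_mm == pytest.approx(20.0)

    def test_fixed_dta_mode_finds_dose_criterion(self):
        res = ig_search(uniform_grid(100.0), uniform_grid(104.05),
                        "fixed_dta", 2.0, 100.0, NATIVE)
        assert res.converged
        assert res.found_dd_pct == pytest.approx(4.1)
        assert res.found_dta_mm is None

    def test_fixed_ratio_mode_reports_linked_pair(self):
        res = ig_search(uniform_grid(100.0), uniform_grid(103.0),
                        "fixed_ratio", 3.0, 100.0, NATIVE)
        assert res.converged
        assert res.found_dta_mm == pytest.approx(1.0)
        assert res.found_dd_pct == pytest.approx(3.0)

    def test_invalid_parameters_rejected(self, rng):
        ref, ev = smooth_random_pair(rng, n=6)
        from gammaqa import SearchError
        with pytest.raises(SearchError):
            ig_search(ref, ev, "fixed_dd", 0.0, 95.0)
        with pytest.raises(SearchError):
            ig_search(ref, ev, "fixed_dd", 3.0, 0.0)
        with pytest.raises(ValueError):
            ig_search(ref, ev, "no_such_mode", 3.0, 95.0)

    def test_empty_inclusion_mask_raises(self):
        # the reference maximum always survives its own threshold, so an
        # empty mask needs an external normalization dose
        ref = DoseGrid([[100.0, 1.0], [1.0, 1.0]], (1.0, 1.0))
        ev = DoseGrid([[100.0, 1.0], [1.0, 1.0]], (1.0, 1.0))
        with pytest.raises(EmptyMaskError):
            ig_search(ref, ev, "fixed_dd", 3.0, 95.0, NATIVE,
                      ldt_pct=50.0, norm_dose=1000.0)


class TestQuantileFastPath:
    def test_mth_smallest_rounded_to_lattice(self):
        req = RequirementMap(
            RequirementKind.MIN_DTA_MM, np.array([[1.0, 0.0, 0.0]]),
            np.ones((1, 3), dtype=bool), 3.0, 100.0,
        )
        assert quantile_fast_path(req, 100.0, 0.1) == pytest.approx(1.0)

    def test_all_zero_map(self):
        req = RequirementMap(
            RequirementKind.MIN_DTA_MM, np.zeros((2, 2)),
            np.ones((2, 2), dtype=bool), 3.0, 100.0,
        )
        assert quantile_fast_path(req, 37.5, 0.1) == 0.0

    def test_sentinel_hits_cap_only_when_target_requires_it(self):
        req = RequirementMap(
            RequirementKind.MIN_DTA_MM, np.array([[0.0, 0.0, np.inf]]),
            np.ones((1, 3), dtype=bool), 3.0, 100.0,
        )
        assert np.isinf(quantile_fast_path(req, 100.0, 0.1))  # m=3 is the sentinel
        assert quantile_fast_path(req, 200.0 / 3.0, 0.1) == 0.0  # m=2 is not

    def test_count_rule(self):
        assert required_count(100.0, 3) == 3
        assert required_count(95.0, 53) == 51
        assert required_count(99.5, 400) == 398
        assert required_count(200.0 / 3.0, 3) == 2

    def test_ceil_to_step_lands_on_the_search_lattice(self):
        assert ceil_to_step(0.0, 0.1) == 0.0
        assert ceil_to_step(1.0, 0.1) == pytest.approx(1.0)
        # 3*0.1 in floats is slightly above 0.3; its own lattice value is itself
        v = 3 * 0.1
        assert ceil_to_step(v, 0.1) == v
        assert ceil_to_step(0.2500001, 0.1) == pytest.approx(0.3)


class TestRequirementHistogram:
    def test_cumulative_gai_readoff(self):
        req = RequirementMap(
            RequirementKind.MIN_DTA_MM, np.array([[1.0, 0.0, 0.0]]),
            np.ones((1, 3), dtype=bool), 3.0, 100.0,
        )
        h = requirement_histogram(req)
        assert h["value"].tolist() == [0.0, 1.0]
        assert h["cumulative_gai_pct"].tolist() == pytest.approx([200.0 / 3.0, 100.0])

    def test_all_zero_is_single_bin(self):
        req = RequirementMap(
            RequirementKind.MIN_DTA_MM, np.zeros((2, 2)),
            np.ones((2, 2), dtype=bool), 3.0, 100.0,
        )
        h = requirement_histogram(req)
        assert len(h) == 1 and h["cumulative_gai_pct"].iloc[0] == 100.0

    def test_unreachable_points_cap_the_cumulative_gai(self):
        req = RequirementMap(
            RequirementKind.MIN_DTA_MM, np.array([[0.0, 1.0, 2.0, np.inf]]),
            np.ones((1, 4), dtype=bool), 3.0, 100.0,
        )
        h = requirement_histogram(req)
        assert h["cumulative_gai_pct"].max() == 75.0


class TestSearchQuantileEquivalence:
    """The iterative search and the closed-form quantile must agree exactly."""

    @pytest.mark.parametrize("mode,fixed", [
        (IGMode.FIXED_DD, 3.0),
        (IGMode.FIXED_DTA, 2.0),
        (IGMode.FIXED_RATIO, 1.5),
    ])
    def test_modes_agree_on_noisy_pairs(self, mode, fixed):
        st = SearchSettings(interp_step_mm=1.0)
        for k in range(5):
            ref, ev = smooth_random_pair(
                np.random.default_rng(500 + k), n=12, spacing=2.0, noise_pct=1.5
            )
            for target in (90.0, 99.5, 100.0):
                res = ig_search(ref, ev, mode, fixed, target, st)
                req = per_point_requirements(ref, ev, mode, fixed, st)
                step = st.dd_step_pct if mode is IGMode.FIXED_DTA else st.dta_step_mm
                cap = st.max_dd_pct if mode is IGMode.FIXED_DTA else st.max_dta_mm
                q = quantile_fast_path(req, target, step, cap=cap)
                if res.converged:
                    assert res.found_value == q
                else:
                    assert np.isinf(q)
                fast = ig_search(ref, ev, mode, fixed, target, st, use_fast_path=True)
                assert fast.status == res.status
                assert fast.found_value == res.found_value
                assert fast.achieved_gai_pct == pytest.approx(res.achieved_gai_pct)

    def test_consistency_recheck_fixed_dd(self):
        # gamma at (dD, found) meets the count target; one step below does not
        st = SearchSettings(interp_step_mm=1.0)
        for k in range(3):
            ref, ev = smooth_random_pair(
                np.random.default_rng(700 + k), n=12, spacing=2.0, noise_pct=1.5
            )
            res = ig_search(ref, ev, "fixed_dd", 3.0, 99.0, st)
            if not res.converged:
                continue
            m = required_count(99.0, gamma_map(ref, ev, GammaCriteria(3.0, max(res.found_dta_mm, 0.1), 5.0), st).n_included)
            at = gamma_map(ref, ev, GammaCriteria(3.0, res.found_dta_mm, 5.0), st)
            assert at.n_passed >= m
            if res.found_dta_mm > 0:
                below = gamma_map(
                    ref, ev,
                    GammaCriteria(3.0, res.found_dta_mm - st.dta_step_mm, 5.0), st,
                )
                assert below.n_passed < m


class TestShiftAndNoiseBehaviour:
    def test_shift_recovery_one_mm(self):
        ref = square_field(extent_mm=80.0, spacing_mm=1.0, field_width_mm=60.0,
                           penumbra_sigma_mm=3.0)
        ev = shift_field(ref, 1.0, 0.0)
        res = ig_search(ref, ev, "fixed_dd", 3.0, 100.0)
        assert res.converged
        assert 1.0 - 0.2 <= res.found_dta_mm <= 1.0 + 0.1

    def test_target_relaxation_never_increases_found_dta(self):
        st = SearchSettings(interp_step_mm=1.0)
        for k in range(5):
            ref, ev = smooth_random_pair(
                np.random.default_rng(900 + k), n=12, spacing=2.0, noise_pct=2.0
            )
            r95 = ig_search(ref, ev, "fixed_dd", 3.0, 95.0, st)
            r100 = ig_search(ref, ev, "fixed_dd", 3.0, 100.0, st)
            if r95.converged and r100.converged:
                assert r95.found_dta_mm <= r100.found_dta_mm

    def test_single_corrupt_reference_pixel_drives_full_gai_to_cap(self):
        from gammaqa import corrupt_pixel
        ref = corrupt_pixel(uniform_grid(100.0, n=20), 7, 11, 10.0)
        ev = uniform_grid(100.0, n=20)
        st = SearchSettings(interp_step_mm=1.0)
        full = ig_search(ref, ev, "fixed_dd", 3.0, 100.0, st)
        assert full.status is SearchStatus.CAP_REACHED
        near = ig_search(ref, ev, "fixed_dd", 3.0, 99.5, st)
        assert near.converged
        assert near.found_dta_mm == 0.0
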
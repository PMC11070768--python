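"""Unit tests for the scalar model blocks and the session driver."""
import math

import numpy as np
import pytest

from hrdrift import (
    ActivitySegment,
    EmptyInputError,
    ExertionState,
    HrBounds,
    InvalidBoundsError,
    ModelParameters,
    SessionSeries,
    SubjectProfile,
    compute_correction,
    compute_delay,
    compute_trimp,
    correct_series,
    decrease_factors,
    estimate_hr_max,
    estimate_hr_rest,
    hr_above_rest,
    hr_below_max,
    hr_reserve_hat,
    increase_deltas,
    resolve_bounds,
    sigmoid_gate,
    step,
    trimp_decr,
    trimp_max,
    update_exertion,
)


class TestHrBoundsEstimation:
    @pytest.mark.parametrize(
        "age,pa,expected",
        [(28, 3, 192.0), (25, 7, 205.0), (40, 5, 180.0), (40, 6, 190.0)],
    )
    def test_age_prediction_switches_on_activity_rating(self, age, pa, expected):
        assert estimate_hr_max(SubjectProfile(age=age, vo2max=45.0, pa_rating=pa)) == expected

    def test_measured_max_wins(self):
        prof = SubjectProfile(age=28, vo2max=45.0, hr_max_measured=182.0)
        assert estimate_hr_max(prof) == 182.0

    @pytest.mark.parametrize(
        "hr,expected",
        [
            (np.full(100, 60.0), 60.0),            # constant series
            (np.arange(1.0, 101.0), 10.0),         # nearest rank: ceil(10) -> 10th value
            (np.array([60.0, 180.0]), 60.0),       # ceil(0.2) = 1 -> first value
            (np.arange(1.0, 12.0), 2.0),           # n=11: ceil(1.1) = 2 -> second value
        ],
    )
    def test_rest_is_nearest_rank_tenth_percentile(self, hr, expected):
        series = SessionSeries(time=np.arange(float(hr.size)), hr=hr)
        assert estimate_hr_rest(series) == expected

    def test_rest_estimate_order_insensitive(self):
        rng = np.random.default_rng(3)
        hr = rng.uniform(50, 180, 97)
        s1 = SessionSeries(time=np.arange(97.0), hr=hr)
        s2 = SessionSeries(time=np.arange(97.0), hr=hr[::-1].copy())
        assert estimate_hr_rest(s1) == estimate_hr_rest(s2)

    def test_resolve_bounds_prefers_measured_rest(self):
        prof = SubjectProfile(age=30, vo2max=50.0, hr_rest_measured=55.0)
        b = resolve_bounds(prof)
        assert (b.hr_rest, b.hr_max) == (55.0, 190.0)

    def test_resolve_bounds_needs_rest_source(self):
        with pytest.raises(InvalidBoundsError):
            resolve_bounds(SubjectProfile(age=30, vo2max=50.0))


class TestBoundaryDistances:
    @pytest.mark.parametrize("hr_hat,expected", [(120.0, 60.0), (55.0, 0.0), (60.0, 0.0)])
    def test_above_rest(self, bounds, hr_hat, expected):
        assert hr_above_rest(hr_hat, bounds) == expected

    @pytest.mark.parametrize("hr_hat,expected", [(150.0, 40.0), (195.0, 0.0), (190.0, 0.0)])
    def test_below_max(self, bounds, hr_hat, expected):
        assert hr_below_max(hr_hat, bounds) == expected

    def test_reserve(self, bounds):
        assert hr_reserve_hat(0.0, bounds) == 0.0
        assert hr_reserve_hat(130.0, bounds) == 1.0
        assert hr_reserve_hat(65.0, bounds) == 0.5


class TestDelay:
    def test_infinite_at_rest(self, subject, params):
        assert compute_delay(subject, 0.0, 60.0, params) == math.inf

    def test_zero_at_max(self, subject, params):
        assert compute_delay(subject, 60.0, 0.0, params) == 0.0

    def test_direct_value(self, params):
        prof = SubjectProfile(age=28, vo2max=50.0)
        assert compute_delay(prof, 60.0, 60.0, params) == pytest.approx(1000.0)


class TestTrimp:
    def test_zero_reserve(self, params):
        assert compute_trimp(0.0, params) == 0.0

    def test_direct_values(self, params):
        assert compute_trimp(1.0, params) == pytest.approx(0.64 * math.exp(1.92), abs=1e-12)
        assert compute_trimp(1.0, params) == pytest.approx(4.3663, abs=1e-3)
        assert compute_trimp(0.5, params) == pytest.approx(0.32 * math.exp(0.96), abs=1e-12)
        assert compute_trimp(0.5, params) == pytest.approx(0.8357, abs=1e-3)

    def test_trimp_max_is_trimp_at_full_reserve(self, params):
        assert trimp_max(params) == compute_trimp(1.0, params)
        flat = ModelParameters(k=1.0, b=1e-12)
        assert trimp_max(flat) == pytest.approx(1.0)

    def test_linear_in_k(self):
        p1, p2 = ModelParameters(k=0.5), ModelParameters(k=1.0)
        assert trimp_max(p2) == pytest.approx(2 * trimp_max(p1))


class TestSigmoidGate:
    def test_midpoint_at_fraction_of_max(self, params):
        tmax = trimp_max(params)
        assert sigmoid_gate(0.8 * tmax, tmax, params) == pytest.approx(0.5)

    def test_saturates(self, params):
        assert sigmoid_gate(1e6, trimp_max(params), params) == pytest.approx(1.0)

    def test_nearly_closed_at_zero_trimp(self, params):
        tmax = trimp_max(params)
        expected = 1.0 / (1.0 + math.exp(0.8 * tmax))
        assert sigmoid_gate(0.0, tmax, params) == pytest.approx(expected, abs=1e-12)
        assert sigmoid_gate(0.0, tmax, params) == pytest.approx(0.0295, abs=1e-3)


class TestIncreaseDecrease:
    def test_increase_deltas(self):
        assert increase_deltas(0.0, 0.3) == (0.0, 0.0)
        assert increase_deltas(2.0, 0.5) == (2.0, 1.0)
        low, high = increase_deltas(1.7, 1.0)
        assert low == high == 1.7

    def test_trimp_decr_floors_at_average(self, bounds, params):
        trimp10 = compute_trimp(params.rest_offset / bounds.reserve_range, params)
        assert trimp_decr(trimp10, bounds, params) == pytest.approx(trimp10)
        assert trimp_decr(0.0, bounds, params) == pytest.approx(trimp10 / 2)
        assert trimp_decr(5.0, bounds, params) == 5.0

    def test_decrease_factors_direct(self, params):
        prof = SubjectProfile(age=28, vo2max=50.0)
        low, high = decrease_factors(1.0, prof, params)
        assert high == pytest.approx(math.exp(-50.0 / 86400.0), abs=1e-12)
        assert high == pytest.approx(0.999421, abs=1e-5)
        assert low == pytest.approx(math.exp(-50.0 / 864000.0), abs=1e-12)
        assert low == pytest.approx(0.9999421, abs=1e-6)

    def test_no_decay_at_zero(self, params):
        prof = SubjectProfile(age=28, vo2max=50.0)
        assert decrease_factors(0.0, prof, params) == (1.0, 1.0)


class TestExertionUpdate:
    def test_pure_decay_branch_with_unit_factors(self):
        state = ExertionState(ei_low=3.0, ei_high=1.0, activity_elapsed=5.0)
        assert update_exertion(state, (2.0, 1.0), (1.0, 1.0), 10.0) == (3.0, 1.0)

    def test_pure_accumulation(self):
        state = ExertionState(activity_elapsed=100.0)
        assert update_exertion(state, (2.0, 1.0), (1.0, 1.0), 10.0) == (2.0, 1.0)

    def test_decay_then_add(self):
        state = ExertionState(ei_low=10.0, ei_high=4.0, activity_elapsed=100.0)
        assert update_exertion(state, (2.0, 1.0), (0.5, 0.5), 10.0) == (7.0, 3.0)

    def test_infinite_delay_never_gates_on(self):
        state = ExertionState(ei_low=10.0, ei_high=4.0, activity_elapsed=1e12)
        got = update_exertion(state, (2.0, 1.0), (0.9, 0.8), math.inf)
        assert got == (9.0, 3.2)


class TestCorrection:
    def test_cap(self, params):
        state = ExertionState(ei_low=25.0, ei_high=10.0)
        assert compute_correction(state, 0.0, params) == 30.0

    def test_zero_branch_at_full_reserve(self, params):
        state = ExertionState(ei_low=25.0, ei_high=10.0)
        assert compute_correction(state, 1.0, params) == 0.0
        assert compute_correction(state, 1.3, params) == 0.0

    def test_scaled_by_reserve(self, params):
        state = ExertionState(ei_low=15.0, ei_high=5.0)
        assert compute_correction(state, 0.5, params) == pytest.approx(10.0)


class TestStepAndSeries:
    def test_zero_state_passes_hr_through(self, subject, bounds, params):
        corrected, _ = step(150.0, ExertionState(), subject, bounds, params)
        assert corrected == 150.0

    def test_carried_correction_subtracted(self, subject, bounds, params):
        corrected, _ = step(150.0, ExertionState(delta_hr_correction=8.0),
                            subject, bounds, params)
        assert corrected == 142.0

    def test_constant_rest_hr_is_fixed_point(self, subject, params):
        n = 3000
        series = SessionSeries(
            time=np.arange(float(n)),
            hr=np.full(n, 60.0),
            segments=(ActivitySegment(0.0, float(n), "run"),),
        )
        res = correct_series(series, subject, params,
                             bounds=HrBounds(hr_rest=60.0, hr_max=190.0))
        assert np.array_equal(res.series.hr, series.hr)
        assert not res.ei_low.any() and not res.ei_high.any()

    def test_all_rest_session_unchanged(self, subject, params, flat_series):
        res = correct_series(flat_series, subject, params)
        assert np.array_equal(res.series.hr, flat_series.hr)

    def test_adding_back_correction_recovers_input(self, bte_session):
        # exact up to one rounding step: (hr - c) + c re-rounds once
        res = correct_series(bte_session.series, bte_session.config.subject)
        np.testing.assert_allclose(
            res.series.hr + res.correction, bte_session.series.hr, rtol=0, atol=1e-12
        )

    def test_batch_equals_stream_of_steps(self, subject, params, bte_session):
        from dataclasses import replace

        from hrdrift import activity_elapsed_trace

        series = bte_session.series
        bounds = resolve_bounds(subject, series)
        res = correct_series(series, subject, params, bounds=bounds)
        elapsed = activity_elapsed_trace(series.time, series.segments)
        state = ExertionState()
        for i in range(len(series)):
            state = replace(state, activity_elapsed=float(elapsed[i]))
            corrected, state = step(float(series.hr[i]), state, subject, bounds, params)
            assert corrected == res.series.hr[i]
            assert state.ei_low == res.ei_low[i]
            assert state.ei_high == res.ei_high[i]

    def test_empty_series_rejected(self, subject):
        with pytest.raises(EmptyInputError):
            SessionSeries(time=np.array([]), hr=np.array([]))
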
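"""The instantaneous heart-rate-drift correction model.

The model removes the cardiovascular-drift component from a 1 Hz HR signal
using two recursively accumulated exertion indexes:

* ``EI_low`` tracks the low-intensity (below anaerobic threshold) drift
  driver and grows with the instantaneous training impulse (TRIMP);
* ``EI_high`` tracks the high-intensity driver and grows with the TRIMP
  gated by a logistic function that opens only once the TRIMP exceeds a
  fraction (default 80%) of the subject's maximal TRIMP, mimicking the
  nonlinear lactate accumulation above the anaerobic threshold.

Accumulation is delayed at exercise onset: the indexes start growing only
once the time spent in the current activity exceeds a fitness-dependent
delay, so that the correction onsets together with the physiological drift
rather than with the exercise itself. Each index also decays multiplicatively
with its own time constant (10 days for the low index, 1 day for the high
one). The correction subtracted from the next HR sample is the capped sum
of the indexes scaled by (1 - heart-rate-reserve fraction): drift is most
visible at low cardiac load, so the correction vanishes as HR approaches
its maximum.

All scalar block functions below operate on plain floats; ``correct_series``
drives them sample by sample and is bit-identical to folding :func:`step`
over the samples.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .errors import EmptyInputError, InvalidBoundsError, InvalidProfileError
from .types import (
    ExertionState,
    HrBounds,
    ModelParameters,
    SessionSeries,
    SubjectProfile,
    activity_elapsed_trace,
)


def estimate_hr_max(profile: SubjectProfile) -> float:
    """Maximal HR in bpm: measured value if available, else age-predicted.

    The age prediction is 220 - age, or 230 - age for subjects with a
    physical-activity rating above 5.
    """
    if profile.hr_max_measured is not None:
        return float(profile.hr_max_measured)
    base = 230.0 if profile.pa_rating > 5 else 220.0
    hr_max = base - profile.age
    if hr_max <= 0:
        raise InvalidProfileError(f"age-predicted maximal HR is non-positive ({hr_max})")
    return hr_max


def estimate_hr_rest(series: SessionSeries) -> float:
    """Resting HR as the nearest-rank 10th percentile of the trial's HR.

    Nearest-rank: sort ascending and take the value at 1-based rank
    ``ceil(0.10 * n)``; ties are kept as-is.
    """
    hr = np.asarray(series.hr, dtype=float)
    if hr.size == 0:
        raise EmptyInputError("cannot estimate resting HR from an empty series")
    rank = math.ceil(0.10 * hr.size)
    return float(np.sort(hr)[max(rank, 1) - 1])


def resolve_bounds(
    profile: SubjectProfile, series: Optional[SessionSeries] = None
) -> HrBounds:
    """HR bounds: measured values win; hr_rest falls back to the trial's
    10th percentile (requires the full series, i.e. offline two-pass use)."""
    hr_max = estimate_hr_max(profile)
    if profile.hr_rest_measured is not None:
        hr_rest = float(profile.hr_rest_measured)
    elif series is not None:
        hr_rest = estimate_hr_rest(series)
    else:
        raise InvalidBoundsError(
            "resting HR unavailable: supply hr_rest_measured or the full series"
        )
    return HrBounds(hr_rest=hr_rest, hr_max=hr_max)


def hr_above_rest(hr_hat: float, bounds: HrBounds) -> float:
    """Distance of the (lag-corrected) HR above resting HR, clamped at 0."""
    return hr_hat - bounds.hr_rest if hr_hat > bounds.hr_rest else 0.0


def hr_below_max(hr_hat_corrected: float, bounds: HrBounds) -> float:
    """Distance of the corrected HR below maximal HR, clamped at 0."""
    return bounds.hr_max - hr_hat_corrected if hr_hat_corrected < bounds.hr_max else 0.0


def compute_delay(
    profile: SubjectProfile,
    above_rest: float,
    below_max: float,
    params: ModelParameters,
) -> float:
    """Fitness-dependent onset delay in seconds.

    delay = delay_constant * vo2max * below_max / above_rest. At resting HR
    (above_rest = 0) the delay is infinite: the exertion indexes can never
    start accumulating. Fitter subjects (higher vo2max) get longer delays.
    """
    if above_rest <= 0.0:
        return math.inf
    return params.delay_constant * profile.vo2max * below_max / above_rest


def hr_reserve_hat(above_rest: float, bounds: HrBounds) -> float:
    """Heart-rate-reserve fraction (above_rest / (hr_max - hr_rest)).

    May exceed 1 when the raw HR overshoots an estimated hr_max; the
    correction's zero branch handles that case downstream.
    """
    rng = bounds.reserve_range
    if rng <= 0:
        raise InvalidBoundsError("hr_max must exceed hr_rest")
    return above_rest / rng


def compute_trimp(reserve: float, params: ModelParameters) -> float:
    """Instantaneous training impulse: reserve * k * exp(b * reserve)."""
    return reserve * params.k * math.exp(params.b * reserve)


def trimp_max(params: ModelParameters) -> float:
    """TRIMP at maximal HR (reserve = 1); the sigmoid gate's reference."""
    return compute_trimp(1.0, params)


def sigmoid_gate(trimp: float, trimp_max_val: float, params: ModelParameters) -> float:
    """Logistic gate in (0, 1), midpoint at sigmoid_fraction * trimp_max.

    Below ~80% of the maximal TRIMP the gate is nearly closed, so the
    high-intensity index accumulates substantially only above that
    threshold — a proxy for crossing the anaerobic threshold.
    """
    z = params.sigmoid_steepness * (params.sigmoid_fraction * trimp_max_val - trimp)
    return 1.0 / (1.0 + math.exp(z))


def increase_deltas(trimp: float, gate: float) -> Tuple[float, float]:
    """Per-sample increments of (EI_low, EI_high): (TRIMP, gate * TRIMP)."""
    return trimp, gate * trimp


def trimp_decr(trimp: float, bounds: HrBounds, params: ModelParameters) -> float:
    """TRIMP value driving the decay: floored at the average of the current
    TRIMP and the TRIMP at 10 bpm above rest.

    The floor prevents the low index from decaying too slowly at rest and
    the high index from decaying too little between bouts.
    """
    trimp10 = compute_trimp(params.rest_offset / bounds.reserve_range, params)
    trimp_min = (trimp + trimp10) / 2.0
    return trimp if trimp > trimp_min else trimp_min


def decrease_factors(
    trimp_decr_val: float, profile: SubjectProfile, params: ModelParameters
) -> Tuple[float, float]:
    """Multiplicative decay factors (low, high), each in (0, 1].

    factor = exp(-vo2max * TRIMP_decr / tau); tau_high < tau_low, so the
    high-intensity index always decays at least as fast as the low one.
    """
    low = math.exp(-profile.vo2max * trimp_decr_val / params.tau_low)
    high = math.exp(-profile.vo2max * trimp_decr_val / params.tau_high)
    return low, high


def update_exertion(
    state: ExertionState,
    deltas_plus: Tuple[float, float],
    factors_minus: Tuple[float, float],
    delay_val: float,
) -> Tuple[float, float]:
    """One recursion step of the exertion indexes.

    Both indexes always decay; the increments are added only when the time
    already spent in the current activity exceeds the onset delay.
    """
    ei_low = factors_minus[0] * state.ei_low
    ei_high = factors_minus[1] * state.ei_high
    if state.activity_elapsed > delay_val:
        ei_low = ei_low + deltas_plus[0]
        ei_high = ei_high + deltas_plus[1]
    return ei_low, ei_high


def compute_correction(state: ExertionState, reserve: float, params: ModelParameters) -> float:
    """Correction (bpm) to subtract from the next sample.

    The summed indexes are capped (30 bpm by default) and scaled by
    (1 - reserve): drift is inversely proportional to cardiac load, so the
    correction fades out as HR approaches maximum and is zero at or above
    full reserve.
    """
    ei_corr = state.ei_low + state.ei_high
    if ei_corr > params.correction_cap:
        ei_corr = params.correction_cap
    if reserve < 1.0:
        return (1.0 - reserve) * ei_corr
    return 0.0


def step(
    hr_sample: float,
    state: ExertionState,
    profile: SubjectProfile,
    bounds: HrBounds,
    params: ModelParameters,
) -> Tuple[float, ExertionState]:
    """Process one HR sample; returns (corrected_hr, new_state).

    The corrected HR is the measured sample minus the correction carried
    from the previous sample (one-sample lag). All blocks are then
    re-evaluated from the corrected value to produce the next state.
    The caller must have set ``state.activity_elapsed`` for this sample.
    """
    hr_hat = hr_sample - state.delta_hr_correction

    above = hr_above_rest(hr_hat, bounds)
    below = hr_below_max(hr_hat, bounds)
    delay_val = compute_delay(profile, above, below, params)
    reserve = hr_reserve_hat(above, bounds)
    trimp = compute_trimp(reserve, params)
    gate = sigmoid_gate(trimp, trimp_max(params), params)
    deltas_plus = increase_deltas(trimp, gate)
    t_decr = trimp_decr(trimp, bounds, params)
    factors_minus = decrease_factors(t_decr, profile, params)
    ei_low, ei_high = update_exertion(state, deltas_plus, factors_minus, delay_val)

    new_state = ExertionState(
        ei_low=ei_low,
        ei_high=ei_high,
        delta_hr_correction=0.0,
        activity_elapsed=state.activity_elapsed,
    )
    correction = compute_correction(new_state, reserve, params)
    new_state = ExertionState(
        ei_low=ei_low,
        ei_high=ei_high,
        delta_hr_correction=correction,
        activity_elapsed=state.activity_elapsed,
    )
    return hr_hat, new_state


@dataclass
class CorrectionResult:
    """Output of :func:`correct_series`: corrected series plus per-sample traces."""

    series: SessionSeries
    ei_low: np.ndarray
    ei_high: np.ndarray
    correction: np.ndarray
    bounds: HrBounds

    def to_frame(self, original: SessionSeries):
        """DataFrame with the output-CSV columns."""
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": original.time,
                "hr_bpm": original.hr,
                "hr_corrected_bpm": self.series.hr,
                "ei_low": self.ei_low,
                "ei_high": self.ei_high,
                "correction_bpm": self.correction,
            }
        )


def correct_series(
    series: SessionSeries,
    profile: SubjectProfile,
    params: Optional[ModelParameters] = None,
    bounds: Optional[HrBounds] = None,
) -> CorrectionResult:
    """Apply the drift correction to a whole session.

    Resolves HR bounds (measured profile values, else the 10th-percentile
    rest estimate over this series), derives per-sample activity-elapsed
    times from the segment annotations, and folds :func:`step` over the
    samples starting from the all-zero state. The ``correction`` trace holds
    the correction actually subtracted at each sample (i.e. the value
    carried from the previous one), so ``hr - correction`` reproduces the
    corrected channel exactly.
    """
    if params is None:
        params = ModelParameters()
    if bounds is None:
        bounds = resolve_bounds(profile, series)
    if len(series) == 0:
        raise EmptyInputError("cannot correct an empty series")

    elapsed = activity_elapsed_trace(series.time, series.segments)
    n = len(series)
    corrected = np.empty(n)
    ei_low = np.empty(n)
    ei_high = np.empty(n)
    applied = np.empty(n)

    state = ExertionState()
    from dataclasses import replace as _replace

    for i in range(n):
        state = _replace(state, activity_elapsed=float(elapsed[i]))
        applied[i] = state.delta_hr_correction
        corrected[i], state = step(float(series.hr[i]), state, profile, bounds, params)
        ei_low[i] = state.ei_low
        ei_high[i] = state.ei_high

    return CorrectionResult(
        series=series.with_hr(corrected),
        ei_low=ei_low,
        ei_high=ei_high,
        correction=applied,
        bounds=bounds,
    )


__all__ = [
    "estimate_hr_max", "estimate_hr_rest", "resolve_bounds",
    "hr_above_rest", "hr_below_max", "compute_delay", "hr_reserve_hat",
    "compute_trimp", "trimp_max", "sigmoid_gate", "increase_deltas",
    "trimp_decr", "decrease_factors", "update_exertion", "compute_correction",
    "step", "correct_series", "CorrectionResult",
]
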
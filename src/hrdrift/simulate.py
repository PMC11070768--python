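"""Seeded, protocol-faithful exercise-session simulator with known drift.

The simulator produces 1 Hz HR and V̇O2 channels for the two laboratory
protocols:

* ``MAX`` — seated rest (7 min), self-selected-speed (SSS) treadmill walk
  (3 min), rest (3 min), a graded run to exhaustion (default 12 min, HR
  ramping to the subject's maximal HR), and 1 h of seated recovery.
* ``BTE`` — rest (7 min), SSS walk (3 min), rest (3 min), a 30-min
  constant-speed run below the anaerobic threshold, then rest (3 min),
  SSS walk (3 min), rest (3 min), SSS + 1 km/h walk (3 min), rest (3 min).

Drift-free HR and V̇O2 follow first-order on/off kinetics toward
per-segment steady targets. A ground-truth cardiovascular-drift component
is then added to the HR channel only: within run segments it grows linearly
after a configurable onset, and outside them it decays exponentially. V̇O2
receives no drift, which is precisely what creates the V̇O2–HR hysteresis
the correction model is meant to remove. Gaussian sensor noise is added to
both channels from a seeded generator (numpy PCG64), so identical configs
give bit-identical sessions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np

from .errors import HrDriftError
from .model import estimate_hr_max
from .types import ActivitySegment, SessionSeries, SubjectProfile

PROTOCOLS = ("MAX", "BTE")

_MIN = 60.0


def default_subject() -> SubjectProfile:
    """A subject matching the study cohort's mean age and fitness."""
    return SubjectProfile(age=28, vo2max=50.0, pa_rating=3)


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to generate one session.

    Intensity targets are expressed as heart-rate-reserve fractions against
    the subject's (rest_hr, age-predicted max) range, and as fractions of
    vo2max for the V̇O2 channel. Defaults emulate the study conditions:
    a ~0.70-reserve constant run below the anaerobic threshold, walking
    probes at ~0.25 reserve (+0.04 for the SSS + 1 km/h walk), and a drift
    component calibrated so the uncorrected post-vs-pre walk HR delta of a
    BTE session lands in the low-20s bpm.
    """

    protocol: str = "BTE"
    subject: SubjectProfile = field(default_factory=default_subject)
    seed: int = 0
    # steady-state targets
    rest_hr: float = 65.0
    walk_reserve: float = 0.25
    run_reserve: float = 0.70
    walk_boost_reserve: float = 0.04
    vo2_rest: float = 5.0
    walk_vo2_frac: float = 0.28
    walk_boost_vo2_frac: float = 0.04
    run_vo2_frac: float = 0.73
    # kinetics
    hr_tau: float = 30.0
    vo2_tau: float = 30.0
    # drift phenomenology
    drift_onset: float = 600.0
    drift_rate: float = 1.2  # bpm per minute of exercise past onset
    recovery_drift_half_life: float = 2400.0
    # sensor noise
    noise_sd: float = 2.0
    vo2_noise_sd: float = 1.0
    # protocol durations
    max_run_duration: float = 720.0
    bte_run_duration: float = 1800.0
    sample_period: float = 1.0

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise HrDriftError(f"protocol must be one of {PROTOCOLS}")
        for name in ("drift_rate", "noise_sd", "vo2_noise_sd", "drift_onset"):
            if getattr(self, name) < 0:
                raise HrDriftError(f"{name} must be non-negative")
        if self.recovery_drift_half_life <= 0:
            raise HrDriftError("recovery_drift_half_life must be positive")


@dataclass
class SimulatedSession:
    """A generated session together with its ground-truth drift channel."""

    series: SessionSeries
    drift_truth: np.ndarray
    config: SimulationConfig

    @property
    def hr_clean(self) -> np.ndarray:
        """Drift-free HR (still carries the sensor noise)."""
        return self.series.hr - self.drift_truth


def protocol_timeline(
    protocol: str,
    max_run_duration: float = 720.0,
    bte_run_duration: float = 1800.0,
) -> List[ActivitySegment]:
    """Ordered, gapless segment list for a protocol.

    MAX: 7 min rest, 3 min SSS walk, 3 min rest, graded run, 1 h rest.
    BTE: 7 min rest, 3 min SSS walk, 3 min rest, 30 min run, then
    3 min rest, 3 min SSS walk, 3 min rest, 3 min SSS+1 km/h walk,
    3 min rest.
    """
    if protocol == "MAX":
        durations = [
            (7 * _MIN, "rest"),
            (3 * _MIN, "walk"),
            (3 * _MIN, "rest"),
            (max_run_duration, "run"),
            (3600.0, "rest"),
        ]
    elif protocol == "BTE":
        durations = [
            (7 * _MIN, "rest"),
            (3 * _MIN, "walk"),
            (3 * _MIN, "rest"),
            (bte_run_duration, "run"),
            (3 * _MIN, "rest"),
            (3 * _MIN, "walk"),
            (3 * _MIN, "rest"),
            (3 * _MIN, "walk"),
            (3 * _MIN, "rest"),
        ]
    else:
        raise HrDriftError(f"protocol must be one of {PROTOCOLS}")
    segments, t = [], 0.0
    for dur, label in durations:
        segments.append(ActivitySegment(start=t, end=t + dur, label=label))
        t += dur
    return segments


def _steady_targets(config: SimulationConfig, segments: Sequence[ActivitySegment]):
    """Per-segment (hr_target, vo2_target); run targets for MAX mean 'ramp'."""
    hr_max = estimate_hr_max(config.subject)
    rng_hr = hr_max - config.rest_hr
    vo2max = config.subject.vo2max
    targets = []
    walk_seen = 0
    for seg in segments:
        if seg.label == "rest":
            targets.append((config.rest_hr, config.vo2_rest))
        elif seg.label == "walk":
            boost_r = config.walk_boost_reserve if walk_seen == 2 else 0.0
            boost_v = config.walk_boost_vo2_frac if walk_seen == 2 else 0.0
            targets.append(
                (
                    config.rest_hr + (config.walk_reserve + boost_r) * rng_hr,
                    (config.walk_vo2_frac + boost_v) * vo2max,
                )
            )
            walk_seen += 1
        else:  # run
            if config.protocol == "MAX":
                targets.append(("ramp", "ramp"))
            else:
                targets.append(
                    (
                        config.rest_hr + config.run_reserve * rng_hr,
                        config.run_vo2_frac * vo2max,
                    )
                )
    return targets, hr_max


def simulate_session(config: SimulationConfig) -> SimulatedSession:
    """Generate one session; identical configs give bit-identical output.

    Clean channels follow first-order kinetics toward the per-segment
    targets; the MAX run's target ramps linearly from the walking level up
    to the subject's maximal HR (and vo2max) at exhaustion. The drift truth
    grows at ``drift_rate`` bpm/min inside run segments once the time in
    the bout exceeds ``drift_onset``, and decays with the configured
    half-life everywhere else. HR = clean + drift + noise; V̇O2 gets noise
    but no drift.
    """
    segments = protocol_timeline(
        config.protocol, config.max_run_duration, config.bte_run_duration
    )
    targets, hr_max = _steady_targets(config, segments)
    dt = config.sample_period
    total = segments[-1].end
    time = np.arange(0.0, total, dt)
    n = time.size

    hr_clean = np.empty(n)
    vo2_clean = np.empty(n)
    drift = np.zeros(n)

    hr_state = config.rest_hr
    vo2_state = config.vo2_rest
    drift_state = 0.0
    a_hr = 1.0 - np.exp(-dt / config.hr_tau)
    a_vo2 = 1.0 - np.exp(-dt / config.vo2_tau)
    decay = 0.5 ** (dt / config.recovery_drift_half_life)

    walk_hr = config.rest_hr + config.walk_reserve * (hr_max - config.rest_hr)
    walk_vo2 = config.walk_vo2_frac * config.subject.vo2max

    seg_idx = 0
    for i, t in enumerate(time):
        while t >= segments[seg_idx].end:
            seg_idx += 1
        seg = segments[seg_idx]
        hr_t, vo2_t = targets[seg_idx]
        if hr_t == "ramp":
            frac = (t - seg.start) / seg.duration
            hr_t = walk_hr + frac * (hr_max - walk_hr)
            vo2_t = walk_vo2 + frac * (config.subject.vo2max - walk_vo2)
        hr_state += (hr_t - hr_state) * a_hr
        vo2_state += (vo2_t - vo2_state) * a_vo2
        if seg.label == "run" and (t - seg.start) >= config.drift_onset:
            drift_state += config.drift_rate / 60.0 * dt
        elif drift_state > 0.0:
            drift_state *= decay
        hr_clean[i] = hr_state
        vo2_clean[i] = vo2_state
        drift[i] = drift_state

    rng = np.random.default_rng(config.seed)
    hr = hr_clean + drift + rng.normal(0.0, config.noise_sd, n)
    vo2 = vo2_clean + rng.normal(0.0, config.vo2_noise_sd, n)
    vo2 = np.maximum(vo2, 0.1)  # metabolic floor; noise must not go negative

    series = SessionSeries(time=time, hr=hr, vo2=vo2, segments=segments)
    return SimulatedSession(series=series, drift_truth=drift, config=config)


def oracle_drift_removed(session: SimulatedSession, corrected: SessionSeries) -> float:
    """Mean absolute mismatch (bpm) between removed and injected drift.

    Computed over the samples where the injected drift is positive:
    ``mean | (original - corrected) - drift_truth |``. Zero means the model
    removed exactly what the simulator injected.
    """
    if (
        len(session.series) != len(corrected)
        or not np.array_equal(session.series.time, corrected.time)
    ):
        raise HrDriftError("original and corrected series must share timestamps")
    mask = session.drift_truth > 0
    if not mask.any():
        raise HrDriftError("session contains no injected drift")
    removed = session.series.hr[mask] - corrected.hr[mask]
    return float(np.mean(np.abs(removed - session.drift_truth[mask])))


__all__ = [
    "PROTOCOLS", "SimulationConfig", "SimulatedSession", "default_subject",
    "protocol_timeline", "simulate_session", "oracle_drift_removed",
]
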
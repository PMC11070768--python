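"""Core domain types: subject, parameters, bounds, segments, series, state.

All containers are lightweight dataclasses with eager validation; the time
series itself lives in numpy arrays so the per-sample recursion and the
window statistics can stay vectorised where possible.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional, Sequence

import numpy as np

from .errors import EmptyInputError, HrDriftError, InvalidBoundsError, InvalidProfileError

SEGMENT_LABELS = ("rest", "walk", "run")

#: Classical sex-specific training-impulse weighting constants
#: (k scales, b is the exponential steepness on the heart-rate-reserve fraction).
MALE_K, MALE_B = 0.64, 1.92
FEMALE_K, FEMALE_B = 0.86, 1.67


@dataclass(frozen=True)
class SubjectProfile:
    """Anthropometric / fitness inputs of the correction model.

    Parameters
    ----------
    age : int
        Age in years; drives the age-predicted maximal heart rate.
    vo2max : float
        Maximal oxygen uptake in mL/kg/min; scales the onset delay and the
        exertion-index decay.
    pa_rating : int
        Physical-activity rating (0-7 habitual activity scale). Ratings
        above 5 switch the maximal-HR prediction from 220 - age to
        230 - age, as active subjects tend to exceed the common estimate.
    hr_rest_measured, hr_max_measured : float, optional
        Measured bounds in bpm; when present they override the estimates.
    """

    age: int
    vo2max: float
    pa_rating: int = 3
    hr_rest_measured: Optional[float] = None
    hr_max_measured: Optional[float] = None

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise InvalidProfileError(f"age must be positive, got {self.age}")
        if self.vo2max <= 0:
            raise InvalidProfileError(f"vo2max must be positive, got {self.vo2max}")
        if self.pa_rating < 0:
            raise InvalidProfileError(f"pa_rating must be >= 0, got {self.pa_rating}")
        if (
            self.hr_rest_measured is not None
            and self.hr_max_measured is not None
            and self.hr_max_measured <= self.hr_rest_measured
        ):
            raise InvalidProfileError(
                "hr_max_measured must exceed hr_rest_measured "
                f"({self.hr_max_measured} <= {self.hr_rest_measured})"
            )


@dataclass(frozen=True)
class ModelParameters:
    """Constants of the five-block drift-correction model.

    Attributes
    ----------
    delay_constant : float
        Dimensionless scale of the exertion-onset delay (default 20).
    k, b : float
        Training-impulse weighting constants; defaults are the classical
        male values (0.64, 1.92). Use :meth:`for_sex` for the female pair.
    tau_low, tau_high : float
        Decay time constants, in seconds, of the low- and high-intensity
        exertion indexes (10 days and 1 day by default). ``tau_high`` must
        be the smaller one: the high-intensity index decays faster.
    sigmoid_fraction : float
        Fraction of the subject's maximal TRIMP at which the logistic gate
        for the high-intensity index sits at 0.5 (default 0.8).
    sigmoid_steepness : float
        Slope of the logistic gate in TRIMP units (default 1).
    correction_cap : float
        Upper bound, in bpm, on the summed exertion indexes used for the
        correction (default 30), preventing over-correction.
    rest_offset : float
        The "10 bpm above rest" reference used by the decrease block.
    sample_period : float
        Sampling period in seconds (default 1, i.e. 1 Hz).
    """

    delay_constant: float = 20.0
    k: float = MALE_K
    b: float = MALE_B
    tau_low: float = 864_000.0
    tau_high: float = 86_400.0
    sigmoid_fraction: float = 0.8
    sigmoid_steepness: float = 1.0
    correction_cap: float = 30.0
    rest_offset: float = 10.0
    sample_period: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise HrDriftError(f"{f.name} must be strictly positive")
        if not self.tau_high < self.tau_low:
            raise HrDriftError("tau_high must be smaller than tau_low")
        if not 0 < self.sigmoid_fraction < 1:
            raise HrDriftError("sigmoid_fraction must lie in (0, 1)")

    @classmethod
    def for_sex(cls, sex: str, **overrides) -> "ModelParameters":
        """Parameters with the classical sex-specific TRIMP constants."""
        sex = sex.lower()
        if sex in ("m", "male"):
            kb = {"k": MALE_K, "b": MALE_B}
        elif sex in ("f", "female"):
            kb = {"k": FEMALE_K, "b": FEMALE_B}
        else:
            raise HrDriftError(f"unknown sex {sex!r}")
        kb.update(overrides)
        return cls(**kb)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        """Build from a config mapping; keys mirror the field names exactly."""
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise HrDriftError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class HrBounds:
    """Resting and maximal heart rate, bpm. hr_max > hr_rest > 0."""

    hr_rest: float
    hr_max: float

    def __post_init__(self) -> None:
        if not (self.hr_max > self.hr_rest > 0):
            raise InvalidBoundsError(
                f"need hr_max > hr_rest > 0, got ({self.hr_rest}, {self.hr_max})"
            )

    @property
    def reserve_range(self) -> float:
        return self.hr_max - self.hr_rest


@dataclass(frozen=True)
class ExertionState:
    """Carried state of the per-sample recursion.

    ``delta_hr_correction`` is the correction (bpm) computed at the previous
    sample and applied, with a one-sample lag, to the next measured HR.
    ``activity_elapsed`` is seconds spent inside the current non-rest
    segment (0 while resting).
    """

    ei_low: float = 0.0
    ei_high: float = 0.0
    delta_hr_correction: float = 0.0
    activity_elapsed: float = 0.0

    def __post_init__(self) -> None:
        if self.ei_low < 0 or self.ei_high < 0:
            raise HrDriftError("exertion indexes must be non-negative")
        if self.delta_hr_correction < 0:
            raise HrDriftError("carried correction must be non-negative")


@dataclass(frozen=True)
class ActivitySegment:
    """Half-open annotated interval [start, end) in seconds."""

    start: float
    end: float
    label: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise HrDriftError(f"segment end must exceed start ({self.start}, {self.end})")
        if self.label not in SEGMENT_LABELS:
            raise HrDriftError(f"segment label must be one of {SEGMENT_LABELS}, got {self.label!r}")

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def is_active(self) -> bool:
        return self.label != "rest"


@dataclass
class SessionSeries:
    """A 1 Hz (by default) exercise session: time, HR, optional V̇O2, segments."""

    time: np.ndarray
    hr: np.ndarray
    vo2: Optional[np.ndarray] = None
    segments: Sequence[ActivitySegment] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.hr = np.asarray(self.hr, dtype=float)
        if self.vo2 is not None:
            self.vo2 = np.asarray(self.vo2, dtype=float)
        if self.time.size == 0:
            raise EmptyInputError("series has no samples")
        if self.time.shape != self.hr.shape:
            raise HrDriftError("time and hr must have the same length")
        if self.vo2 is not None and self.vo2.shape != self.time.shape:
            raise HrDriftError("vo2 must have the same length as time")
        if np.any(np.diff(self.time) <= 0):
            raise HrDriftError("timestamps must be strictly increasing")
        if np.any(self.hr <= 0):
            raise HrDriftError("heart rate must be positive everywhere")
        segs = tuple(self.segments)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise HrDriftError(f"segments overlap or are unordered at t={b.start}")
        self.segments = segs

    def __len__(self) -> int:
        return int(self.time.size)

    @property
    def has_vo2(self) -> bool:
        return self.vo2 is not None

    def with_hr(self, hr: np.ndarray) -> "SessionSeries":
        """Copy of the series with a replaced HR channel."""
        return SessionSeries(time=self.time.copy(), hr=np.asarray(hr, dtype=float),
                             vo2=None if self.vo2 is None else self.vo2.copy(),
                             segments=self.segments)


def activity_elapsed_trace(time: np.ndarray, segments: Sequence[ActivitySegment]) -> np.ndarray:
    """Seconds elapsed within the current non-rest segment, per sample.

    Elapsed time resets at every segment boundary (a walk followed by a run
    restarts the clock) and is 0 throughout rest segments and outside any
    annotated segment.
    """
    time = np.asarray(time, dtype=float)
    out = np.zeros_like(time)
    for seg in segments:
        if not seg.is_active:
            continue
        mask = (time >= seg.start) & (time < seg.end)
        out[mask] = time[mask] - seg.start
    return out


__all__ = [
    "SEGMENT_LABELS", "MALE_K", "MALE_B", "FEMALE_K", "FEMALE_B",
    "SubjectProfile", "ModelParameters", "HrBounds", "ExertionState",
    "ActivitySegment", "SessionSeries", "activity_elapsed_trace",
]
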
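"""V̇O2–HR hysteresis curves, areas, drift deltas and the paired comparison.

Cardiovascular drift makes HR rise while V̇O2 stays flat, so plotting
normalized V̇O2 against normalized HR over the course of a session traces a
loop (hysteresis) instead of a line. Each protocol is summarised by six
anchor points A–F (rest/walk/exercise phases); both channels are normalized
to 0 at a protocol-specific offset point and to 1 at the end-of-exercise
point, and the enclosed area of the closed A→…→F→A polygon quantifies the
drift. An effective correction collapses the loop and shrinks the area.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import (
    DegenerateNormalizationError,
    DegenerateTestError,
    HrDriftError,
    InvalidPolygonError,
    ProtocolMismatchError,
)
from .types import ActivitySegment, SessionSeries

POINT_LABELS = ("A", "B", "C", "D", "E", "F")

Window = Tuple[float, float]


@dataclass(frozen=True)
class HysteresisPoint:
    label: str
    hr_norm: float
    vo2_norm: float


@dataclass(frozen=True)
class HysteresisCurve:
    """Ordered six-point loop on normalized axes with its enclosed area."""

    points: Tuple[HysteresisPoint, ...]
    area: float

    def __post_init__(self) -> None:
        labels = [p.label for p in self.points]
        if len(set(labels)) != len(labels):
            raise HrDriftError("hysteresis point labels must be unique")


@dataclass(frozen=True)
class ProtocolWindows:
    """Per-label [start, end) time windows plus the normalization anchors.

    ``offset_label`` names the point whose aggregate maps to 0 on both axes
    and ``end_label`` the end-of-exercise point that maps to 1.
    ``drift_pre``/``drift_post`` name the default pre/post windows for the
    drift-delta comparison.
    """

    windows: Dict[str, Window]
    offset_label: str = "A"
    end_label: str = "E"
    drift_pre: str = "A"
    drift_post: str = "F"


def _select_segment(
    segments: Sequence[ActivitySegment], label: str, occurrence: int
) -> ActivitySegment:
    hits = [s for s in segments if s.label == label]
    if occurrence >= len(hits):
        raise ProtocolMismatchError(
            f"protocol needs {label!r} segment #{occurrence}, "
            f"but the session has only {len(hits)}"
        )
    return hits[occurrence]


def _resolve_rule(segments: Sequence[ActivitySegment], rule: dict) -> Window:
    seg = _select_segment(segments, rule["segment_label"], rule.get("occurrence", 0))
    origin = rule.get("origin", "start")
    if origin == "start":
        anchor = seg.start
    elif origin == "end":
        anchor = seg.end
    elif origin == "mid":
        anchor = (seg.start + seg.end) / 2.0
    else:
        raise HrDriftError(f"unknown window origin {origin!r}")
    start = anchor + rule.get("offset_s", 0.0)
    duration = rule.get("duration_s")
    if duration is None:
        end = seg.end - rule.get("end_trim_s", 0.0)
    else:
        end = start + duration
    if end <= start:
        raise ProtocolMismatchError(f"empty window for rule {rule}")
    return (start, end)


def load_protocol_template(protocol: str) -> dict:
    """Load the shipped window-rule template for 'max' or 'bte'."""
    name = f"{protocol.lower()}_protocol.json"
    ref = resources.files("hrdrift.protocols").joinpath(name)
    try:
        return json.loads(ref.read_text())
    except FileNotFoundError as exc:  # pragma: no cover
        raise ProtocolMismatchError(f"no protocol template {name!r}") from exc


def build_windows(
    segments: Sequence[ActivitySegment], template: dict
) -> ProtocolWindows:
    """Resolve a rule template against a session's segment annotations."""
    windows = {
        label: _resolve_rule(segments, rule)
        for label, rule in template["points"].items()
    }
    dd = template.get("drift_delta", {})
    return ProtocolWindows(
        windows=windows,
        offset_label=template.get("offset_label", "A"),
        end_label=template.get("end_label", "E"),
        drift_pre=dd.get("pre", "A"),
        drift_post=dd.get("post", "F"),
    )


def protocol_windows(series: SessionSeries, protocol: str) -> ProtocolWindows:
    """Shortcut: shipped template for ``protocol`` resolved on ``series``."""
    return build_windows(series.segments, load_protocol_template(protocol))


def _window_mean(time: np.ndarray, values: np.ndarray, window: Window) -> float:
    mask = (time >= window[0]) & (time < window[1])
    if not mask.any():
        raise ProtocolMismatchError(f"no samples in window [{window[0]}, {window[1]})")
    return float(values[mask].mean())


def normalize_value(x: float, offset: float, end_value: float) -> float:
    """(x - offset) / (end_value - offset): offset maps to 0, end to 1."""
    delta = end_value - offset
    if delta == 0:
        raise DegenerateNormalizationError("normalization delta is zero")
    return (x - offset) / delta


def extract_points(
    series: SessionSeries, windows: ProtocolWindows
) -> Dict[str, Tuple[float, Optional[float]]]:
    """Per-label (hr_mean, vo2_mean) aggregates over the protocol windows.

    vo2 means are ``None`` when the series carries no V̇O2 channel.
    """
    out: Dict[str, Tuple[float, Optional[float]]] = {}
    for label in POINT_LABELS:
        if label not in windows.windows:
            raise ProtocolMismatchError(f"no window defined for point {label}")
        w = windows.windows[label]
        hr_mean = _window_mean(series.time, series.hr, w)
        vo2_mean = (
            _window_mean(series.time, series.vo2, w) if series.has_vo2 else None
        )
        out[label] = (hr_mean, vo2_mean)
    return out


def polygon_area(points: Sequence[Tuple[float, float]]) -> float:
    """Absolute shoelace area of the closed polygon through ``points``.

    Invariant under cyclic rotation and orientation reversal. For a
    self-intersecting loop this is the absolute value of the signed sum,
    i.e. regions of opposite orientation cancel.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
        raise InvalidPolygonError("polygon area needs at least 3 (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def hysteresis_auc(series: SessionSeries, windows: ProtocolWindows) -> HysteresisCurve:
    """Six-point normalized hysteresis curve and its enclosed area.

    Both channels are normalized with the protocol's offset point mapped to
    0 and its end-of-exercise point mapped to 1, then the shoelace area of
    the closed A→…→F→A polygon is returned.
    """
    if not series.has_vo2:
        raise HrDriftError("hysteresis analysis requires a V̇O2 channel")
    raw = extract_points(series, windows)
    hr_off, vo2_off = raw[windows.offset_label]
    hr_end, vo2_end = raw[windows.end_label]
    pts = tuple(
        HysteresisPoint(
            label=label,
            hr_norm=normalize_value(raw[label][0], hr_off, hr_end),
            vo2_norm=normalize_value(raw[label][1], vo2_off, vo2_end),
        )
        for label in POINT_LABELS
    )
    area = polygon_area([(p.hr_norm, p.vo2_norm) for p in pts])
    return HysteresisCurve(points=pts, area=area)


def drift_delta(series: SessionSeries, pre_window: Window, post_window: Window) -> float:
    """Signed post-minus-pre mean-HR difference in bpm.

    Positive residual deltas between matched pre/post probes (same walking
    speed or seated rest) expose uncorrected drift.
    """
    pre = _window_mean(series.time, series.hr, pre_window)
    post = _window_mean(series.time, series.hr, post_window)
    return post - pre


def paired_t_one_tailed(
    x: Sequence[float], y: Sequence[float], alternative: str = "greater"
) -> Tuple[float, float, int]:
    """One-tailed paired t-test of x against y.

    Returns (t, p, df) with df = n - 1; ``alternative='greater'`` tests
    mean(x - y) > 0. Zero-variance differences are rejected rather than
    returning an undefined statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise HrDriftError("paired test needs two equal-length samples, n >= 2")
    d = x - y
    if float(np.var(d, ddof=1)) == 0.0:
        raise DegenerateTestError("paired differences have zero variance")
    res = stats.ttest_rel(x, y, alternative=alternative)
    return float(res.statistic), float(res.pvalue), int(x.size - 1)


__all__ = [
    "POINT_LABELS", "HysteresisPoint", "HysteresisCurve", "ProtocolWindows",
    "load_protocol_template", "build_windows", "protocol_windows",
    "normalize_value", "extract_points", "polygon_area", "hysteresis_auc",
    "drift_delta", "paired_t_one_tailed",
]
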
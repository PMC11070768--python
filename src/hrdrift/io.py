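"""CSV / JSON input and output.

Contracts (comma separator, dot decimal, UTF-8, header required):

* series CSV      — ``time_s,hr_bpm[,vo2_mlkgmin]``, one row per sample;
* segments CSV    — ``start_s,end_s,label`` with labels rest/walk/run;
* correction CSV  — ``time_s,hr_bpm,hr_corrected_bpm,ei_low,ei_high,correction_bpm``;
* parameter JSON  — keys mirroring :class:`~hrdrift.types.ModelParameters`.

Floats are written with ``repr`` so a write/read round trip preserves every
value exactly; malformed input is reported with the offending line number.
"""
from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import List, Sequence, Union

import numpy as np

from .errors import SeriesParseError
from .model import CorrectionResult
from .types import ActivitySegment, ModelParameters, SessionSeries

PathLike = Union[str, Path]

SERIES_COLUMNS = ("time_s", "hr_bpm")
SERIES_VO2_COLUMN = "vo2_mlkgmin"
SEGMENT_COLUMNS = ("start_s", "end_s", "label")


def _parse_float(cell: str, column: str, lineno: int) -> float:
    try:
        return float(cell)
    except ValueError:
        raise SeriesParseError(
            f"line {lineno}: non-numeric value {cell!r} in column {column!r}"
        ) from None


def read_series(
    path: PathLike, segments: Sequence[ActivitySegment] = ()
) -> SessionSeries:
    """Read a series CSV; attach ``segments`` if given.

    Raises :class:`SeriesParseError` naming the offending line for missing
    columns, non-numeric cells or non-monotone timestamps.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SeriesParseError(f"{path}: empty file") from None
        header = [h.strip() for h in header]
        for col in SERIES_COLUMNS:
            if col not in header:
                raise SeriesParseError(f"{path}: missing required column {col!r}")
        it = header.index("time_s")
        ih = header.index("hr_bpm")
        iv = header.index(SERIES_VO2_COLUMN) if SERIES_VO2_COLUMN in header else None

        time: List[float] = []
        hr: List[float] = []
        vo2: List[float] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) < len(header):
                raise SeriesParseError(f"line {lineno}: expected {len(header)} cells, got {len(row)}")
            t = _parse_float(row[it], "time_s", lineno)
            if time and t <= time[-1]:
                raise SeriesParseError(
                    f"line {lineno}: timestamp {t} not greater than previous {time[-1]}"
                )
            time.append(t)
            hr.append(_parse_float(row[ih], "hr_bpm", lineno))
            if iv is not None:
                vo2.append(_parse_float(row[iv], SERIES_VO2_COLUMN, lineno))
    if not time:
        raise SeriesParseError(f"{path}: no data rows")
    return SessionSeries(
        time=np.array(time),
        hr=np.array(hr),
        vo2=np.array(vo2) if iv is not None else None,
        segments=tuple(segments),
    )


def write_series(series: SessionSeries, path: PathLike) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        if series.has_vo2:
            writer.writerow([*SERIES_COLUMNS, SERIES_VO2_COLUMN])
            for t, h, v in zip(series.time, series.hr, series.vo2):
                writer.writerow([repr(float(t)), repr(float(h)), repr(float(v))])
        else:
            writer.writerow(SERIES_COLUMNS)
            for t, h in zip(series.time, series.hr):
                writer.writerow([repr(float(t)), repr(float(h))])


def read_segments(path: PathLike) -> List[ActivitySegment]:
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = [h.strip() for h in next(reader)]
        except StopIteration:
            raise SeriesParseError(f"{path}: empty file") from None
        for col in SEGMENT_COLUMNS:
            if col not in header:
                raise SeriesParseError(f"{path}: missing required column {col!r}")
        idx = [header.index(c) for c in SEGMENT_COLUMNS]
        segments = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            start = _parse_float(row[idx[0]], "start_s", lineno)
            end = _parse_float(row[idx[1]], "end_s", lineno)
            label = row[idx[2]].strip()
            try:
                segments.append(ActivitySegment(start=start, end=end, label=label))
            except ValueError as exc:
                raise SeriesParseError(f"line {lineno}: {exc}") from None
    return segments


def write_segments(segments: Sequence[ActivitySegment], path: PathLike) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SEGMENT_COLUMNS)
        for seg in segments:
            writer.writerow([repr(float(seg.start)), repr(float(seg.end)), seg.label])


def read_params(path: PathLike) -> ModelParameters:
    """Model parameters from a JSON config; absent keys keep their defaults."""
    with Path(path).open(encoding="utf-8") as fh:
        data = json.load(fh)
    return ModelParameters.from_dict(data)


def write_correction(
    result: CorrectionResult,
    original: SessionSeries,
    path: PathLike,
    round_bpm: bool = False,
) -> None:
    """Write the correction output CSV (optionally with integer-rounded HR)."""
    frame = result.to_frame(original)
    if round_bpm:
        frame["hr_corrected_bpm"] = frame["hr_corrected_bpm"].round().astype(int)
    frame.to_csv(Path(path), index=False)


def write_truth_drift(time: np.ndarray, drift: np.ndarray, path: PathLike) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s", "drift_bpm"])
        for t, d in zip(time, drift):
            writer.writerow([repr(float(t)), repr(float(d))])


__all__ = [
    "read_series", "write_series", "read_segments", "write_segments",
    "read_params", "write_correction", "write_truth_drift",
    "SERIES_COLUMNS", "SEGMENT_COLUMNS",
]
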
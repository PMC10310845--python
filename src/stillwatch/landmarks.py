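"""Facial-landmark stream I/O, validation and time normalisation.

A landmark stream is what an in-browser face tracker emits: per frame, a
timestamp and 68 planar points (pixels, origin top-left, y down) in the
standard iBUG-68 layout, optionally accompanied by 7 facial-expression
scores which this package carries through but never analyses.

On disk a stream is JSON-lines: line 1 is a header object
``{"format_version": 1, "participant_id": ..., "condition": ...,
"time_unit": "s"|"ms"}``; every further line is
``{"t": number, "pts": [[x, y] × 68], "expr": [7 numbers]?}``.
Millisecond timestamps are converted to seconds at read time.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParseError, ValidationError

N_LANDMARKS = 68
N_EXPRESSIONS = 7
FORMAT_VERSION = 1

CONDITIONS = ("control", "experience_sampling")

#: Default inclusion threshold: participants with fewer retained 1 Hz
#: samples than this are excluded from analysis.
MIN_TRACKING_POINTS = 600


def landmark_index(one_based: int) -> int:
    """Map a 1-based landmark number (the convention used in the iBUG-68
    scheme and throughout user-facing docs) to the internal 0-based index.

    This is the single place where the two conventions meet.
    """
    if not 1 <= one_based <= N_LANDMARKS:
        raise ValidationError(f"landmark number {one_based} outside 1..{N_LANDMARKS}")
    return one_based - 1


@dataclass
class LandmarkFrame:
    """One tracked video frame.

    Parameters
    ----------
    timestamp:
        Seconds from stream start. After 1 Hz downsampling this is the
        integer second index (as a float).
    points:
        ``(68, 2)`` array of pixel coordinates.
    expressions:
        Optional 7 scores in [0, 1]; carried through, never analysed.
    source_timestamp:
        Original (pre-downsampling) timestamp, set by :func:`downsample_1hz`.
    """

    timestamp: float
    points: np.ndarray
    expressions: np.ndarray | None = None
    source_timestamp: float | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (N_LANDMARKS, 2):
            raise ValidationError(
                f"expected {N_LANDMARKS} planar points, got shape {self.points.shape}"
            )
        if not np.all(np.isfinite(self.points)):
            raise ValidationError("non-finite landmark coordinate")
        if not (math.isfinite(self.timestamp) and self.timestamp >= 0):
            raise ValidationError(f"bad timestamp {self.timestamp!r}")
        if self.expressions is not None:
            self.expressions = np.asarray(self.expressions, dtype=float)
            if self.expressions.shape != (N_EXPRESSIONS,):
                raise ValidationError(
                    f"expected {N_EXPRESSIONS} expression scores, got {self.expressions.shape}"
                )
            if np.any((self.expressions < 0) | (self.expressions > 1)):
                raise ValidationError("expression score outside [0, 1]")


@dataclass
class LandmarkSeries:
    """A participant's landmark stream with strictly increasing timestamps."""

    participant_id: str
    condition: str
    frames: list[LandmarkFrame] = field(default_factory=list)

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"condition {self.condition!r} not in {CONDITIONS}"
            )
        ts = [f.timestamp for f in self.frames]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValidationError("frame timestamps not strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)


def read_landmark_series(path) -> LandmarkSeries:
    """Read and validate a JSON-lines landmark file.

    Raises :class:`ParseError` (naming the line) for malformed JSON and
    :class:`ValidationError` for invariant violations (wrong point count,
    non-monotone timestamps, unknown condition). Frames are required to be
    in order already; they are never silently re-sorted.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError("empty file", line_number=1)
    try:
        header = json.loads(lines[0])
    except json.JSONDecodeError as exc:
        raise ParseError(f"bad header: {exc.msg}", line_number=1) from exc
    for key in ("participant_id", "condition", "time_unit"):
        if key not in header:
            raise ParseError(f"header missing {key!r}", line_number=1)
    unit = header["time_unit"]
    if unit not in ("s", "ms"):
        raise ParseError(f"unknown time_unit {unit!r}", line_number=1)
    scale = 1.0 if unit == "s" else 1e-3

    frames = []
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        try:
            obj = json.loads(raw)
        except json.JSONDecodeError as exc:
            raise ParseError(f"bad frame: {exc.msg}", line_number=lineno) from exc
        if "t" not in obj or "pts" not in obj:
            raise ParseError("frame missing 't' or 'pts'", line_number=lineno)
        try:
            frame = LandmarkFrame(
                timestamp=float(obj["t"]) * scale,
                points=obj["pts"],
                expressions=obj.get("expr"),
                source_timestamp=obj.get("t0"),
            )
        except ValidationError as exc:
            raise ValidationError(f"line {lineno}: {exc}") from exc
        frames.append(frame)
    return LandmarkSeries(
        participant_id=str(header["participant_id"]),
        condition=header["condition"],
        frames=frames,
    )


def write_landmark_series(series: LandmarkSeries, path) -> None:
    """Write a series in the JSON-lines dialect read by
    :func:`read_landmark_series`. Output is byte-stable for identical input.
    """
    header = {
        "format_version": FORMAT_VERSION,
        "participant_id": series.participant_id,
        "condition": series.condition,
        "time_unit": "s",
    }
    with open(path, "w") as fh:
        fh.write(json.dumps(header, sort_keys=True) + "\n")
        for f in series.frames:
            obj = {"t": f.timestamp, "pts": f.points.tolist()}
            if f.expressions is not None:
                obj["expr"] = f.expressions.tolist()
            if f.source_timestamp is not None:
                obj["t0"] = f.source_timestamp
            fh.write(json.dumps(obj) + "\n")


def downsample_1hz(series: LandmarkSeries) -> LandmarkSeries:
    """Downsample to one frame per second.

    Second bins are half-open ``[s, s+1)``; the retained frame for bin ``s``
    is the earliest frame with timestamp ≥ s ("the first or next available
    frame for every second"). Seconds with no frame are simply absent —
    gaps are never interpolated. Retained frames are re-labelled with their
    integer second index; the original timestamp survives as
    ``source_timestamp``, so the operation is idempotent.
    """
    out: list[LandmarkFrame] = []
    seen: int | None = None
    for f in series.frames:
        sec = math.floor(f.timestamp)
        if seen is not None and sec <= seen:
            continue
        src = f.source_timestamp if f.source_timestamp is not None else f.timestamp
        out.append(replace(f, timestamp=float(sec), source_timestamp=src))
        seen = sec
    return LandmarkSeries(series.participant_id, series.condition, out)


def meets_min_points(series: LandmarkSeries, min_points: int = MIN_TRACKING_POINTS) -> bool:
    """Cohort inclusion filter: at least ``min_points`` retained 1 Hz samples
    (participants with fewer motion-tracking points are excluded).
    """
    return len(downsample_1hz(series)) >= min_points
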
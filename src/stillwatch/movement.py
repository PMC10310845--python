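"""The head-movement metric: landmark frames → cm/s.

Head movement is operationalised as the second-by-second planar displacement
of the nose-tip landmark. Pixel units are converted to centimetres with the
interocular distance (IOD): each eye's centre is the mean of its six
landmarks (numbers 37–42 left, 43–48 right, 1-based), and the pixel IOD is
rescaled against the adult average of 6.3 cm. Movement on the first retained
sample is defined as 0; samples above 20 cm/s are excluded as outliers
(strict inequality) before any aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateFrameError, ValidationError
from .landmarks import LandmarkFrame, LandmarkSeries, landmark_index

#: Average adult interocular distance used for pixel → cm conversion.
REFERENCE_IOD_CM = 6.3
#: 1-based landmark number of the nose tip in the iBUG-68 layout.
NOSE_TIP_MARKER = 31
#: Outlier threshold in cm/s; samples strictly above are excluded.
OUTLIER_THRESHOLD_CM_S = 20.0

_LEFT_EYE_MARKERS = tuple(range(37, 43))
_RIGHT_EYE_MARKERS = tuple(range(43, 49))


def eye_centers(frame: LandmarkFrame) -> tuple[np.ndarray, np.ndarray]:
    """Centre of each eye: componentwise mean of the six eye landmarks
    (37–42 left, 43–48 right, 1-based). Returns ``(left, right)``.
    """
    left = frame.points[[landmark_index(i) for i in _LEFT_EYE_MARKERS]].mean(axis=0)
    right = frame.points[[landmark_index(i) for i in _RIGHT_EYE_MARKERS]].mean(axis=0)
    return left, right


def interocular_distance_px(frame: LandmarkFrame) -> float:
    """Euclidean distance between the two eye centres, in pixels.

    Raises :class:`DegenerateFrameError` when the centres coincide; callers
    treat such frames as missing.
    """
    left, right = eye_centers(frame)
    iod = float(np.hypot(*(right - left)))
    if iod <= 0.0:
        raise DegenerateFrameError("coincident eye centers (IOD = 0)")
    return iod


@dataclass(frozen=True)
class MovementSample:
    """One second of the movement series.

    ``movement_cm`` is the displacement over the preceding 1 s step in cm
    (NaN when missing: first-of-gap or degenerate frame); ``iod_px`` is the
    frame's interocular distance (NaN for degenerate frames).
    """

    second: int
    movement_cm: float
    iod_px: float


@dataclass
class MovementSeries:
    """Per-second head movement for one participant.

    Backed by aligned arrays (``seconds`` strictly increasing ints,
    ``movement_cm`` with NaN for missing, ``iod_px``).
    ``excluded_fraction`` is the fraction of present samples removed by the
    outlier rule (0 until :func:`filter_outliers` runs).
    """

    participant_id: str
    condition: str
    seconds: np.ndarray
    movement_cm: np.ndarray
    iod_px: np.ndarray
    excluded_fraction: float = 0.0

    def __post_init__(self):
        self.seconds = np.asarray(self.seconds, dtype=int)
        self.movement_cm = np.asarray(self.movement_cm, dtype=float)
        self.iod_px = np.asarray(self.iod_px, dtype=float)
        if not (len(self.seconds) == len(self.movement_cm) == len(self.iod_px)):
            raise ValidationError("misaligned movement arrays")
        if np.any(np.diff(self.seconds) <= 0):
            raise ValidationError("seconds not strictly increasing")
        if not 0.0 <= self.excluded_fraction <= 1.0:
            raise ValidationError("excluded_fraction outside [0, 1]")
        present = self.movement_cm[~np.isnan(self.movement_cm)]
        if np.any(present < 0):
            raise ValidationError("negative movement")

    def __len__(self) -> int:
        return len(self.seconds)

    @property
    def samples(self) -> list[MovementSample]:
        return [
            MovementSample(int(s), float(m), float(i))
            for s, m, i in zip(self.seconds, self.movement_cm, self.iod_px)
        ]

    @property
    def n_present(self) -> int:
        return int(np.sum(~np.isnan(self.movement_cm)))

    def present_values(self) -> np.ndarray:
        return self.movement_cm[~np.isnan(self.movement_cm)]


def head_movement_series(
    series: LandmarkSeries,
    reference_iod_cm: float = REFERENCE_IOD_CM,
    nose_marker: int = NOSE_TIP_MARKER,
    iod_policy: str = "later",
) -> MovementSeries:
    """Compute the head-movement metric from a 1 Hz landmark series.

    For each retained second after the first,

    ``movement_cm = |nose(t) − nose(prev)| × reference_iod_cm / iod_px``

    where ``prev`` is the immediately preceding retained second and
    ``iod_px`` is the later frame's IOD (``iod_policy="later"``, the default)
    or the mean of the two frames' (``"mean"``). The first sample's movement
    is 0 by definition. A step across a gap (> 1 s between retained frames)
    is recorded as missing, never divided by elapsed time. Degenerate frames
    (zero IOD) yield missing samples.

    The input must already be on the integer-second grid produced by
    :func:`stillwatch.landmarks.downsample_1hz`.
    """
    if iod_policy not in ("later", "mean"):
        raise ConfigError(f"unknown iod_policy {iod_policy!r}")
    nose = landmark_index(nose_marker)

    secs, movs, iods = [], [], []
    prev_sec: int | None = None
    prev_nose: np.ndarray | None = None
    prev_iod = np.nan
    for f in series.frames:
        if f.timestamp != int(f.timestamp):
            raise ValidationError(
                "non-integer timestamp; run downsample_1hz before the metric"
            )
        sec = int(f.timestamp)
        try:
            iod = interocular_distance_px(f)
        except DegenerateFrameError:
            iod = np.nan
        pos = f.points[nose]
        if prev_sec is None:
            mov = 0.0  # first sample defined as 0
        elif sec - prev_sec != 1:
            mov = np.nan  # gap: displacement not attributable to one second
        else:
            step_iod = iod if iod_policy == "later" else np.nanmean([iod, prev_iod])
            if np.isnan(step_iod) or prev_nose is None:
                mov = np.nan
            else:
                mov = float(np.hypot(*(pos - prev_nose))) * reference_iod_cm / step_iod
        secs.append(sec)
        movs.append(mov)
        iods.append(iod)
        prev_sec, prev_iod, prev_nose = sec, iod, pos

    return MovementSeries(series.participant_id, series.condition, secs, movs, iods)


def filter_outliers(
    series: MovementSeries, threshold_cm_s: float = OUTLIER_THRESHOLD_CM_S
) -> MovementSeries:
    """Drop samples with movement strictly greater than ``threshold_cm_s``.

    Applied once, before any aggregation. ``excluded_fraction`` is the
    number removed over the number of present (non-missing) samples.
    """
    present = ~np.isnan(series.movement_cm)
    outlier = present & (series.movement_cm > threshold_cm_s)
    keep = ~outlier
    n_present = int(present.sum())
    frac = float(outlier.sum()) / n_present if n_present else 0.0
    return MovementSeries(
        series.participant_id,
        series.condition,
        series.seconds[keep],
        series.movement_cm[keep],
        series.iod_px[keep],
        excluded_fraction=frac,
    )


def aggregate_window(
    series: MovementSeries, start_s: float, stop_s: float
) -> tuple[float | None, int]:
    """Mean movement over the half-open window ``[start_s, stop_s)``.

    Returns ``(mean, n)`` over present samples; ``(None, 0)`` when the
    window holds no present sample. Movement is averaged across the seconds
    actually present in the period.
    """
    if stop_s <= start_s:
        raise ConfigError(f"inverted window [{start_s}, {stop_s})")
    mask = (series.seconds >= start_s) & (series.seconds < stop_s)
    vals = series.movement_cm[mask]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return None, 0
    return float(vals.mean()), int(vals.size)


def aggregate_by_minute(series: MovementSeries, bin_s: int = 60) -> pd.DataFrame:
    """Per-minute (or other fixed-bin) means over consecutive ``[b·k, b·(k+1))``
    windows, as a DataFrame with columns ``minute``, ``mean_cm``, ``n``.
    Bins with no present data appear with NaN mean and n = 0.
    """
    if len(series) == 0:
        return pd.DataFrame(columns=["minute", "mean_cm", "n"])
    n_bins = int(series.seconds.max() // bin_s) + 1
    rows = []
    for m in range(n_bins):
        mean, n = aggregate_window(series, m * bin_s, (m + 1) * bin_s)
        rows.append((m, np.nan if mean is None else mean, n))
    return pd.DataFrame(rows, columns=["minute", "mean_cm", "n"])


def write_movement_csv(
    series: MovementSeries, path, threshold_cm_s: float | None = OUTLIER_THRESHOLD_CM_S
) -> None:
    """Export an (unfiltered) series with the outlier rule marked in an
    ``excluded`` column rather than applied.
    """
    excluded = (
        (~np.isnan(series.movement_cm)) & (series.movement_cm > threshold_cm_s)
        if threshold_cm_s is not None
        else np.zeros(len(series), dtype=bool)
    )
    pd.DataFrame(
        {
            "participant_id": series.participant_id,
            "second": series.seconds,
            "movement_cm": series.movement_cm,
            "iod_px": series.iod_px,
            "excluded": excluded,
        }
    ).to_csv(path, index=False)


def read_movement_csv(path, condition: str = "control") -> MovementSeries:
    """Read a series written by :func:`write_movement_csv`, applying the
    recorded exclusions (excluded rows are dropped)."""
    df = pd.read_csv(path)
    pid = str(df["participant_id"].iloc[0]) if len(df) else ""
    keep = ~df["excluded"].astype(bool)
    n_present = int((~df["movement_cm"].isna()).sum())
    n_excl = int((~keep).sum())
    return MovementSeries(
        pid,
        condition,
        df.loc[keep, "second"].to_numpy(),
        df.loc[keep, "movement_cm"].to_numpy(),
        df.loc[keep, "iod_px"].to_numpy(),
        excluded_fraction=n_excl / n_present if n_present else 0.0,
    )
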
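"""Probe-caught experience sampling: schedules, categorical responses, and
probe-aligned movement aggregates.

During viewing, participants in the experience-sampling condition hear 23
audio probes roughly a minute apart and report their momentary state with
one of four categories: *distracted*, *engaged*, *reflecting*, *immersed*.
This module aligns the movement series to the probe schedule and builds the
per-probe aggregates that the stillness analysis consumes.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateDataError, ValidationError
from .movement import MovementSeries, aggregate_window


class EngagementCategory(str, enum.Enum):
    """The four momentary engagement states, in fixed report order."""

    DISTRACTED = "distracted"
    ENGAGED = "engaged"
    REFLECTING = "reflecting"
    IMMERSED = "immersed"


CATEGORIES: tuple[EngagementCategory, ...] = tuple(EngagementCategory)

#: Minimum number of probe responses for a participant to be included.
MIN_PROBE_RESPONSES = 10
#: Minimum participants backing a (probe, category) cell.
MIN_CELL_DATAPOINTS = 3


@dataclass
class ProbeSchedule:
    """Probe onset times (seconds from performance start), strictly increasing."""

    probe_times: np.ndarray
    duration_s: float | None = None

    def __post_init__(self):
        self.probe_times = np.asarray(self.probe_times, dtype=float)
        if np.any(np.diff(self.probe_times) <= 0):
            raise ValidationError("probe times not strictly increasing")
        if self.duration_s is not None and len(self.probe_times):
            if self.probe_times[-1] >= self.duration_s or self.probe_times[0] < 0:
                raise ValidationError("probe outside performance duration")

    def __len__(self) -> int:
        return len(self.probe_times)

    def onset_second(self, probe_index: int) -> int:
        return math.floor(self.probe_times[probe_index])


@dataclass
class ProbeResponseSeries:
    """A participant's responses, keyed by probe index (missing = absent)."""

    participant_id: str
    responses: dict[int, EngagementCategory] = field(default_factory=dict)
    n_probes: int = 23

    def __post_init__(self):
        for idx, cat in self.responses.items():
            if not 0 <= idx < self.n_probes:
                raise ValidationError(f"probe index {idx} outside schedule range")
            if not isinstance(cat, EngagementCategory):
                self.responses[idx] = EngagementCategory(cat)

    @property
    def n_responses(self) -> int:
        return len(self.responses)


def meets_min_responses(
    series: ProbeResponseSeries, min_responses: int = MIN_PROBE_RESPONSES
) -> bool:
    """Inclusion filter: at least ``min_responses`` non-missing responses."""
    return series.n_responses >= min_responses


def probe_aligned_traces(
    movement: MovementSeries,
    schedule: ProbeSchedule,
    pre_s: int = 30,
    post_s: int = 30,
) -> tuple[np.ndarray, np.ndarray]:
    """Movement in a window around each probe, with no averaging.

    Returns ``(offsets, traces)`` where ``offsets`` runs −pre_s … +post_s
    and ``traces`` has one row per probe holding the participant's
    ``movement_cm`` at ``onset_second + offset`` (NaN where the second is
    missing or outside the recording). Values are copied verbatim from the
    movement series — no smoothing or interpolation.
    """
    offsets = np.arange(-pre_s, post_s + 1)
    traces = np.full((len(schedule), offsets.size), np.nan)
    if len(movement) == 0:
        return offsets, traces
    max_sec = int(movement.seconds.max())
    dense = np.full(max_sec + 1, np.nan)
    dense[movement.seconds] = movement.movement_cm
    for p in range(len(schedule)):
        onset = schedule.onset_second(p)
        secs = onset + offsets
        valid = (secs >= 0) & (secs <= max_sec)
        traces[p, valid] = dense[secs[valid]]
    return offsets, traces


def pre_probe_mean(
    movement: MovementSeries,
    schedule: ProbeSchedule,
    probe_index: int,
    window_policy: str = "inter_probe",
    pre_s: int = 30,
) -> tuple[float | None, int]:
    """Mean movement preceding one probe, ``(mean, n)``.

    Policies:

    * ``"inter_probe"`` (default): from just after the previous probe's
      onset second (or from 0 for the first probe) up to, but excluding,
      this probe's onset second. Probes are ~1 min apart, so these windows
      form a natural non-overlapping partition; the onset second itself is
      excluded because the keypress response contaminates it.
    * ``"fixed"``: the ``pre_s`` seconds immediately before onset.
    """
    onset = schedule.onset_second(probe_index)
    if window_policy == "inter_probe":
        start = 0 if probe_index == 0 else schedule.onset_second(probe_index - 1) + 1
    elif window_policy == "fixed":
        start = onset - pre_s
    else:
        raise ConfigError(f"unknown window_policy {window_policy!r}")
    start = max(start, 0)
    if onset <= start:
        return None, 0
    return aggregate_window(movement, start, onset)


@dataclass
class PerProbeCategoryMeans:
    """Per-(probe, category) cohort means of participants' pre-probe means.

    ``means`` and ``counts`` are probe × category DataFrames; cells backed
    by fewer than the minimum number of participants are NaN in ``means``
    and counted in ``n_excluded_cells``.
    """

    means: pd.DataFrame
    counts: pd.DataFrame
    n_excluded_cells: int
    min_datapoints: int


def per_probe_category_means(
    responses: dict[str, ProbeResponseSeries],
    movements: dict[str, MovementSeries],
    schedule: ProbeSchedule,
    min_datapoints: int = MIN_CELL_DATAPOINTS,
    window_policy: str = "inter_probe",
    pre_s: int = 30,
) -> PerProbeCategoryMeans:
    """Aggregate responses by probe: for each probe and category, the mean of
    the pre-probe movement means of participants who gave that category at
    that probe. Cells with fewer than ``min_datapoints`` contributing
    participants are excluded (their means would be outlier-dominated).

    Inclusion filters (minimum tracking points / responses) are assumed to
    have been applied upstream; only participants present in both
    collections contribute.
    """
    cats = [c.value for c in CATEGORIES]
    n_probes = len(schedule)
    cells: dict[tuple[int, str], list[float]] = {}
    for pid in sorted(set(responses) & set(movements)):
        mov = movements[pid]
        resp = responses[pid]
        for p, cat in resp.responses.items():
            if p >= n_probes:
                continue
            mean, n = pre_probe_mean(mov, schedule, p, window_policy, pre_s)
            if mean is not None:
                cells.setdefault((p, cat.value), []).append(mean)

    means = pd.DataFrame(np.nan, index=range(n_probes), columns=cats)
    counts = pd.DataFrame(0, index=range(n_probes), columns=cats)
    n_excluded = 0
    for (p, cat), vals in cells.items():
        counts.loc[p, cat] = len(vals)
        if len(vals) >= min_datapoints:
            means.loc[p, cat] = float(np.mean(vals))
        else:
            n_excluded += 1
    return PerProbeCategoryMeans(means, counts, n_excluded, min_datapoints)


def category_proportions(
    responses: dict[str, ProbeResponseSeries] | list[ProbeResponseSeries],
) -> dict[EngagementCategory, float]:
    """Proportion of each category over all non-missing responses in the
    cohort (sums to 1). Raises when there are no responses at all.
    """
    series = responses.values() if isinstance(responses, dict) else responses
    tally = {c: 0 for c in CATEGORIES}
    for s in series:
        for cat in s.responses.values():
            tally[cat] += 1
    total = sum(tally.values())
    if total == 0:
        raise DegenerateDataError("no responses in cohort")
    return {c: tally[c] / total for c in CATEGORIES}


def write_probe_responses_csv(
    responses: dict[str, ProbeResponseSeries], schedule: ProbeSchedule, path
) -> None:
    """Probe-response file: one row per (participant, probe); empty response
    marks a missed probe."""
    rows = []
    for pid in sorted(responses):
        s = responses[pid]
        for p in range(len(schedule)):
            cat = s.responses.get(p)
            rows.append(
                (pid, p, float(schedule.probe_times[p]), "" if cat is None else cat.value)
            )
    pd.DataFrame(
        rows, columns=["participant_id", "probe_index", "probe_time_s", "response"]
    ).to_csv(path, index=False)


def read_probe_responses_csv(path) -> tuple[dict[str, ProbeResponseSeries], ProbeSchedule]:
    df = pd.read_csv(path, keep_default_na=False)
    times = (
        df.drop_duplicates("probe_index").sort_values("probe_index")["probe_time_s"]
    ).to_numpy(dtype=float)
    schedule = ProbeSchedule(times)
    out: dict[str, ProbeResponseSeries] = {}
    for pid, grp in df.groupby("participant_id"):
        resp = {
            int(r.probe_index): EngagementCategory(r.response)
            for r in grp.itertuples()
            if r.response
        }
        out[str(pid)] = ProbeResponseSeries(str(pid), resp, n_probes=len(schedule))
    return out, schedule
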
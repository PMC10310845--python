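"""Inter-subject correlation (ISC).

ISC measures the consistency of responses to a shared naturalistic stimulus:
a correlation is computed for every unordered pair of participants on the
seconds (or probes) both answered, and the distribution of pair
coefficients is tested against a zero mean with a one-sample t-test.
Continuous ISC operates on movement series; categorical ISC dummy-codes one
response category (target → 1, any other response → 0) and uses a
rank-based coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import numpy as np
from scipy import stats

from .errors import ConfigError, DegenerateDataError, InsufficientDataError
from .movement import MovementSeries
from .probes import CATEGORIES, EngagementCategory, ProbeResponseSeries

#: Minimum overlapping seconds for a continuous-ISC pair to count.
MIN_OVERLAP_S = 100


@dataclass
class PairwiseISCResult:
    """All pair coefficients plus the one-sample test of their mean."""

    pairs: list[tuple[str, str, float, int]]
    mean_r: float
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    n_pairs: int
    dropped_pairs: dict[str, int] = field(default_factory=dict)
    alternative: str = "two-sided"

    @property
    def r_values(self) -> np.ndarray:
        return np.array([p[2] for p in self.pairs])


def test_mean_above_zero(
    r_values, alternative: str = "two-sided"
) -> tuple[float, int, float]:
    """One-sample t-test of correlation coefficients against zero.

    Returns ``(t, df, p)`` with ``df = n − 1``. ``alternative`` is
    ``"two-sided"`` or ``"greater"`` (the directional reading of the
    synchrony hypothesis).
    """
    r = np.asarray(r_values, dtype=float)
    if r.size < 2:
        raise InsufficientDataError("need at least 2 correlation values")
    if np.ptp(r) == 0:
        raise DegenerateDataError("all correlation values identical")
    if alternative not in ("two-sided", "greater"):
        raise ConfigError(f"unknown alternative {alternative!r}")
    res = stats.ttest_1samp(r, 0.0, alternative=alternative)
    return float(res.statistic), r.size - 1, float(res.pvalue)


def _pair_result(
    pairs, dropped, alternative
) -> PairwiseISCResult:
    if len(pairs) < 2:
        raise InsufficientDataError(
            f"only {len(pairs)} usable pair(s); need at least 2"
        )
    r = np.array([p[2] for p in pairs])
    t, df, p = test_mean_above_zero(r, alternative)
    return PairwiseISCResult(
        pairs=pairs,
        mean_r=float(r.mean()),
        t_statistic=t,
        degrees_of_freedom=df,
        p_value=p,
        n_pairs=len(pairs),
        dropped_pairs=dropped,
        alternative=alternative,
    )


def continuous_isc(
    movements: Mapping[str, MovementSeries],
    min_overlap: int = MIN_OVERLAP_S,
    method: str = "pearson",
    alternative: str = "two-sided",
    drop_first_sample: bool = True,
) -> PairwiseISCResult:
    """Moment-by-moment movement ISC over all unordered participant pairs.

    Each pair is correlated over the seconds where both have a present
    sample. Pairs with overlap below ``min_overlap`` (guards against
    spurious high |r| from tiny overlaps) or zero variance in either series
    are dropped and counted, not set to 0. ``method`` is ``"pearson"``
    (standard ISC practice, default) or ``"spearman"``.

    Each series' first sample is excluded by default: its movement value is
    0 by definition (no preceding frame), a deterministic artifact shared
    by every participant, and leaving it in biases the synchrony null
    upward.
    """
    if method not in ("pearson", "spearman"):
        raise ConfigError(f"unknown method {method!r}")
    ids = sorted(movements)
    if len(ids) < 2:
        raise InsufficientDataError("need at least 2 participants")
    max_sec = max(int(movements[i].seconds.max()) for i in ids if len(movements[i]))
    grid = np.full((len(ids), max_sec + 1), np.nan)
    for k, pid in enumerate(ids):
        s = movements[pid]
        if len(s):
            grid[k, s.seconds] = s.movement_cm
            if drop_first_sample:
                grid[k, s.seconds[0]] = np.nan
    pairs: list[tuple[str, str, float, int]] = []
    dropped = {"low_overlap": 0, "zero_variance": 0}
    for a, b in combinations(range(len(ids)), 2):
        both = ~np.isnan(grid[a]) & ~np.isnan(grid[b])
        n = int(both.sum())
        if n < max(min_overlap, 2):
            dropped["low_overlap"] += 1
            continue
        x, y = grid[a, both], grid[b, both]
        if method == "spearman":
            x, y = stats.rankdata(x), stats.rankdata(y)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            dropped["zero_variance"] += 1
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        pairs.append((ids[a], ids[b], r, n))
    return _pair_result(pairs, dropped, alternative)


def dummy_code(
    series: ProbeResponseSeries, category: EngagementCategory, n_probes: int
) -> np.ndarray:
    """Indicator over probes: target category → 1, any other response → 0,
    unanswered → NaN."""
    out = np.full(n_probes, np.nan)
    for p, cat in series.responses.items():
        out[p] = 1.0 if cat == category else 0.0
    return out


def categorical_isc(
    responses: Mapping[str, ProbeResponseSeries],
    category: EngagementCategory,
    min_overlap: int = 3,
    alternative: str = "two-sided",
) -> PairwiseISCResult:
    """Dummy-coded categorical ISC for one response category.

    Each participant's response sequence is recoded to an indicator and
    pairs are correlated with Spearman's coefficient over the probes both
    answered. Pairs where either indicator has no variance on the common
    probes (e.g. a participant who never used the category) are dropped.
    """
    if not isinstance(category, EngagementCategory):
        try:
            category = EngagementCategory(category)
        except ValueError as exc:
            raise ConfigError(f"unknown category {category!r}") from exc
    ids = sorted(responses)
    if len(ids) < 2:
        raise InsufficientDataError("need at least 2 participants")
    n_probes = max(responses[i].n_probes for i in ids)
    coded = np.vstack([dummy_code(responses[i], category, n_probes) for i in ids])

    pairs: list[tuple[str, str, float, int]] = []
    dropped = {"low_overlap": 0, "zero_variance": 0}
    for a, b in combinations(range(len(ids)), 2):
        both = ~np.isnan(coded[a]) & ~np.isnan(coded[b])
        n = int(both.sum())
        if n < max(min_overlap, 2):
            dropped["low_overlap"] += 1
            continue
        x, y = coded[a, both], coded[b, both]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            dropped["zero_variance"] += 1
            continue
        r = float(stats.spearmanr(x, y).statistic)
        pairs.append((ids[a], ids[b], r, n))
    return _pair_result(pairs, dropped, alternative)


@dataclass
class QuartileExclusionReport:
    """Outcome of the low-movement robustness exclusion."""

    retained: list[str]
    excluded: list[str]
    flagged_low_mean: list[str]
    flagged_low_sd: list[str]
    mode: str


def lowest_quartile_exclusion(
    movements: Mapping[str, MovementSeries], mode: str = "union"
) -> QuartileExclusionReport:
    """Robustness check: exclude participants in the lowest quartile of mean
    and/or standard deviation of movement (the very still participants whose
    near-constant series could distort the ISC).

    Participants strictly below the 25th percentile of the cohort's mean
    distribution and of its SD distribution are flagged; ``mode="union"``
    (default) excludes either flag, ``"intersection"`` requires both.
    """
    if mode not in ("union", "intersection"):
        raise ConfigError(f"unknown mode {mode!r}")
    ids = sorted(movements)
    if len(ids) < 4:
        raise InsufficientDataError("need at least 4 participants for quartiles")
    means = np.array([movements[i].present_values().mean() for i in ids])
    sds = np.array([movements[i].present_values().std(ddof=1) for i in ids])
    low_mean = means < np.quantile(means, 0.25)
    low_sd = sds < np.quantile(sds, 0.25)
    flagged = (low_mean | low_sd) if mode == "union" else (low_mean & low_sd)
    return QuartileExclusionReport(
        retained=[i for i, f in zip(ids, flagged) if not f],
        excluded=[i for i, f in zip(ids, flagged) if f],
        flagged_low_mean=[i for i, f in zip(ids, low_mean) if f],
        flagged_low_sd=[i for i, f in zip(ids, low_sd) if f],
        mode=mode,
    )


def isc_summary(result: PairwiseISCResult) -> dict:
    """JSON-ready summary of an ISC run."""
    return {
        "mean_r": result.mean_r,
        "t": result.t_statistic,
        "df": result.degrees_of_freedom,
        "p": result.p_value,
        "n_pairs": result.n_pairs,
        "dropped_pairs": result.dropped_pairs,
        "alternative": result.alternative,
    }
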
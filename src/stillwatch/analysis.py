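"""The stillness-hypothesis statistical battery.

The stillness hypothesis holds that reduced body movement in a seated
audience indicates higher cognitive engagement. This module tests it on
three fronts: momentary (paired contrasts of per-probe movement between
response categories, Bonferroni-corrected, with a Shapiro–Wilk gate
choosing between the paired t-test and the Wilcoxon signed-rank test),
retrospective (Spearman correlations between overall movement and
questionnaire scores; minute-by-minute comparison by behavioural
intention), and experimental (Welch test of the experience-sampling
manipulation on retrospective engagement). It also forms the median-split
quadrant groups that explain the movement–enjoyment null.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigError,
    DegenerateDataError,
    InsufficientDataError,
    ValidationError,
)
from .movement import MovementSeries, aggregate_by_minute
from .probes import CATEGORIES, PerProbeCategoryMeans

#: Quadrant groups smaller than this are flagged as not analysable.
MIN_GROUP_SIZE = 6


@dataclass
class RetrospectiveScores:
    """Post-viewing questionnaire outcomes for one participant."""

    participant_id: str
    condition: str
    narrative_engagement: float  # mean questionnaire score, 1–5
    enjoyment: float  # 0–100
    behavioural_intention: bool  # wanted to continue watching

    def __post_init__(self):
        if not 1.0 <= self.narrative_engagement <= 5.0:
            raise ValidationError(
                f"narrative_engagement {self.narrative_engagement} outside [1, 5]"
            )
        if not 0.0 <= self.enjoyment <= 100.0:
            raise ValidationError(f"enjoyment {self.enjoyment} outside [0, 100]")


class QuadrantLabel(str, enum.Enum):
    """Median-split groups on retrospective engagement × enjoyment."""

    ENGAGED_ENJOYED = "engaged_enjoyed"
    DISENGAGED_DISLIKED = "disengaged_disliked"
    DISENGAGED_ENJOYED = "disengaged_enjoyed"
    ENGAGED_DISLIKED = "engaged_disliked"


@dataclass
class PairedTestResult:
    statistic: float
    p_value: float
    n: int
    test_name: str
    adjusted_p: float | None = None
    label: str = ""
    note: str = ""
    computable: bool = True

    def __post_init__(self):
        if self.computable and not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")
        if self.adjusted_p is not None and self.adjusted_p < self.p_value:
            raise ValidationError("adjusted p below raw p")


@dataclass
class GateResult:
    """Outcome of the normality gate (test chosen plus the Shapiro–Wilk evidence)."""

    test_name: str  # "wilcoxon_signed_rank" or "parametric_paired_t"
    shapiro_w: float
    shapiro_p: float
    warning: str = ""


@dataclass
class WelchResult:
    t: float
    df: float
    p_value: float
    group_means: dict[str, float]
    intention_proportion: dict[str, float]


def score_questionnaire(
    item_scores: Sequence[float], scale_min: float, scale_max: float
) -> float:
    """Single score for a questionnaire scale: the arithmetic mean of its
    (pre-oriented) items. Items must lie within the scale range."""
    items = np.asarray(item_scores, dtype=float)
    if items.size == 0:
        raise ConfigError("empty item list")
    if np.any((items < scale_min) | (items > scale_max)):
        raise ValidationError("item outside scale range")
    return float(items.mean())


def normality_gate(values, alpha: float = 0.05) -> GateResult:
    """Choose a paired test from the distribution of the values (typically
    paired differences): Shapiro–Wilk p < alpha → Wilcoxon signed-rank,
    otherwise the parametric paired t-test. Constant input cannot be tested
    for normality; the nonparametric path is selected with a warning.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise InsufficientDataError("normality gate needs at least 3 values")
    if np.ptp(v) == 0:
        return GateResult(
            "wilcoxon_signed_rank", np.nan, np.nan, warning="constant values"
        )
    w, p = stats.shapiro(v)
    name = "wilcoxon_signed_rank" if p < alpha else "parametric_paired_t"
    return GateResult(name, float(w), float(p))


def bonferroni(p: float, family_size: int) -> float:
    """Bonferroni-adjusted p: multiplied by the family size, capped at 1."""
    if family_size < 1:
        raise ConfigError("family size must be >= 1")
    return min(1.0, p * family_size)


def signed_rank_test(
    diffs, alternative: str = "two-sided", method: str = "auto"
) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (standard signed-rank convention). The
    two-sided statistic is ``min(W+, W−)`` with
    ``p = min(1, 2·min(P(W+ ≤ w), P(W+ ≥ w)))`` under the exact null;
    one-sided alternatives use W+ directly. ``method="auto"`` uses the
    exact distribution for small samples without ties and the normal
    approximation otherwise.
    """
    res = stats.wilcoxon(
        np.asarray(diffs, dtype=float),
        zero_method="wilcox",
        alternative=alternative,
        method=method,
    )
    return float(res.statistic), float(res.pvalue)


def paired_test(
    x, y, label: str = "", alpha: float = 0.05
) -> tuple[PairedTestResult, GateResult]:
    """Normality-gated paired comparison of two matched samples.

    The gate runs on the paired differences. Zero-difference pairs are
    dropped inside the Wilcoxon path (standard signed-rank convention,
    scipy's ``zero_method="wilcox"``); the exact distribution is used for
    small samples without ties, the normal approximation otherwise
    (scipy's ``method="auto"``). All-zero differences are reported as a
    degenerate no-effect result rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ConfigError("paired samples differ in length")
    d = x - y
    gate = normality_gate(d, alpha=alpha)
    if np.all(d == 0):
        return (
            PairedTestResult(
                0.0, 1.0, int(d.size), gate.test_name, label=label,
                note="all paired differences zero; no effect",
            ),
            gate,
        )
    if gate.test_name == "wilcoxon_signed_rank":
        stat, p = signed_rank_test(d)
    else:
        res = stats.ttest_rel(x, y)
        stat, p = float(res.statistic), float(res.pvalue)
    return PairedTestResult(stat, p, int(d.size), gate.test_name, label=label), gate


def momentary_contrasts(
    table: PerProbeCategoryMeans, min_probes: int = 3
) -> list[PairedTestResult]:
    """Pairwise category contrasts of per-probe movement means.

    For each of the six unordered category pairs, probes with both cells
    present are paired and tested through the normality gate; p-values are
    Bonferroni-adjusted over the family of six. A contrast with fewer than
    ``min_probes`` usable probes is reported as not computable, never
    silently dropped.
    """
    pairs = list(combinations([c.value for c in CATEGORIES], 2))
    family = len(pairs)
    results = []
    for a, b in pairs:
        sub = table.means[[a, b]].dropna()
        label = f"{a}_vs_{b}"
        if len(sub) < min_probes:
            results.append(
                PairedTestResult(
                    np.nan, np.nan, len(sub), "none", label=label,
                    note=f"only {len(sub)} usable probes (< {min_probes})",
                    computable=False,
                )
            )
            continue
        res, _ = paired_test(sub[a].to_numpy(), sub[b].to_numpy(), label=label)
        res.adjusted_p = bonferroni(res.p_value, family)
        results.append(res)
    return results


def participant_mean_movement(
    movements: Mapping[str, MovementSeries],
) -> dict[str, float]:
    """Overall mean movement (cm/s) per participant over present samples."""
    return {
        pid: float(s.present_values().mean())
        for pid, s in movements.items()
        if s.n_present
    }


def retrospective_correlation(
    movement_means: Mapping[str, float],
    scores: Sequence[RetrospectiveScores],
    outcome: str = "narrative_engagement",
) -> tuple[float, float]:
    """Spearman rank correlation between overall movement and a retrospective
    outcome; returns ``(rho, p)``."""
    if outcome not in ("narrative_engagement", "enjoyment"):
        raise ConfigError(f"unknown outcome {outcome!r}")
    ids = [s.participant_id for s in scores if s.participant_id in movement_means]
    if len(ids) < 4:
        raise InsufficientDataError("need at least 4 participants with both measures")
    by_id = {s.participant_id: s for s in scores}
    x = np.array([movement_means[i] for i in ids])
    y = np.array([getattr(by_id[i], outcome) for i in ids])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("zero variance in movement or outcome")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def _group_minute_profile(
    movements: Mapping[str, MovementSeries], ids: Sequence[str], bin_s: int
) -> pd.Series:
    """Per-bin mean over the group members' per-bin means (equal weighting)."""
    per_member = [
        aggregate_by_minute(movements[i], bin_s=bin_s).set_index("minute")["mean_cm"]
        for i in ids
        if i in movements
    ]
    if not per_member:
        raise InsufficientDataError("group with no movement data")
    return pd.concat(per_member, axis=1).mean(axis=1)


def intention_comparison(
    movements: Mapping[str, MovementSeries],
    scores: Sequence[RetrospectiveScores],
    bin_s: int = 60,
) -> PairedTestResult:
    """Minute-by-minute movement comparison between participants who did and
    did not want to continue watching, paired by time bin.

    ``bin_s`` is configurable (60 s default; 30 s doubles the number of
    paired bins for a 30-minute piece).
    """
    yes = [s.participant_id for s in scores if s.behavioural_intention]
    no = [s.participant_id for s in scores if not s.behavioural_intention]
    if not yes or not no:
        raise InsufficientDataError("one intention group is empty")
    prof_yes = _group_minute_profile(movements, yes, bin_s)
    prof_no = _group_minute_profile(movements, no, bin_s)
    common = prof_yes.dropna().index.intersection(prof_no.dropna().index)
    if len(common) < 3:
        raise InsufficientDataError("fewer than 3 common time bins")
    res, _ = paired_test(
        prof_yes[common].to_numpy(), prof_no[common].to_numpy(), label="intention_yes_vs_no"
    )
    diff = float(np.mean(prof_yes[common].to_numpy() - prof_no[common].to_numpy()))
    res.note = "yes group moves less" if diff < 0 else "yes group moves more"
    return res


def condition_effect(scores: Sequence[RetrospectiveScores]) -> WelchResult:
    """Welch two-sample t-test of narrative engagement between the control
    and experience-sampling conditions, plus the per-condition proportion of
    participants wanting to continue watching."""
    groups: dict[str, list[RetrospectiveScores]] = {}
    for s in scores:
        groups.setdefault(s.condition, []).append(s)
    if set(groups) != {"control", "experience_sampling"}:
        raise InsufficientDataError("both conditions must be represented")
    if any(len(g) < 2 for g in groups.values()):
        raise InsufficientDataError("a condition has fewer than 2 participants")
    a = np.array([s.narrative_engagement for s in groups["control"]])
    b = np.array([s.narrative_engagement for s in groups["experience_sampling"]])
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(
        t=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        group_means={"control": float(a.mean()), "experience_sampling": float(b.mean())},
        intention_proportion={
            c: float(np.mean([s.behavioural_intention for s in g]))
            for c, g in groups.items()
        },
    )


@dataclass
class QuadrantAssignment:
    labels: dict[str, QuadrantLabel]
    group_sizes: dict[QuadrantLabel, int]
    analysable: list[QuadrantLabel]
    median_engagement: float
    median_enjoyment: float
    min_group_size: int


def quadrant_groups(
    scores: Sequence[RetrospectiveScores], min_group_size: int = MIN_GROUP_SIZE
) -> QuadrantAssignment:
    """Median-split participants on engagement × enjoyment.

    "High" means strictly above the pooled median (ties go low), so a
    participant exactly at both medians lands in disengaged-disliked.
    Groups below ``min_group_size`` are flagged as not analysable.
    """
    if len(scores) < 4:
        raise InsufficientDataError("need at least 4 participants")
    eng = np.array([s.narrative_engagement for s in scores])
    enj = np.array([s.enjoyment for s in scores])
    med_eng, med_enj = float(np.median(eng)), float(np.median(enj))
    labels = {}
    for s in scores:
        hi_eng = s.narrative_engagement > med_eng
        hi_enj = s.enjoyment > med_enj
        labels[s.participant_id] = {
            (True, True): QuadrantLabel.ENGAGED_ENJOYED,
            (False, False): QuadrantLabel.DISENGAGED_DISLIKED,
            (False, True): QuadrantLabel.DISENGAGED_ENJOYED,
            (True, False): QuadrantLabel.ENGAGED_DISLIKED,
        }[(hi_eng, hi_enj)]
    sizes = {q: sum(1 for v in labels.values() if v == q) for q in QuadrantLabel}
    analysable = [q for q in QuadrantLabel if sizes[q] >= min_group_size]
    return QuadrantAssignment(labels, sizes, analysable, med_eng, med_enj, min_group_size)


def group_movement_comparison(
    assignment: QuadrantAssignment,
    movements: Mapping[str, MovementSeries],
    bin_s: int = 60,
) -> tuple[list[PairedTestResult], list[str]]:
    """Pairwise minute-paired movement comparisons between analysable
    quadrant groups. Returns ``(results, exclusions)`` where exclusions
    records groups left out and why."""
    exclusions = [
        f"{q.value}: below minimum size ({assignment.group_sizes[q]} < "
        f"{assignment.min_group_size})"
        for q in QuadrantLabel
        if q not in assignment.analysable
    ]
    if len(assignment.analysable) < 2:
        raise InsufficientDataError("fewer than 2 analysable quadrant groups")
    profiles = {}
    for q in assignment.analysable:
        ids = [pid for pid, lab in assignment.labels.items() if lab == q]
        profiles[q] = _group_minute_profile(movements, ids, bin_s)
    results = []
    for qa, qb in combinations(assignment.analysable, 2):
        common = profiles[qa].dropna().index.intersection(profiles[qb].dropna().index)
        label = f"{qa.value}_vs_{qb.value}"
        if len(common) < 3:
            results.append(
                PairedTestResult(
                    np.nan, np.nan, len(common), "none", label=label,
                    note="fewer than 3 common bins", computable=False,
                )
            )
            continue
        res, _ = paired_test(
            profiles[qa][common].to_numpy(), profiles[qb][common].to_numpy(), label=label
        )
        results.append(res)
    return results, exclusions


def write_retrospective_csv(scores: Sequence[RetrospectiveScores], path) -> None:
    pd.DataFrame(
        [
            (
                s.participant_id,
                s.condition,
                s.narrative_engagement,
                s.enjoyment,
                "yes" if s.behavioural_intention else "no",
            )
            for s in scores
        ],
        columns=[
            "participant_id",
            "condition",
            "narrative_engagement",
            "enjoyment",
            "intention",
        ],
    ).to_csv(path, index=False)


def read_retrospective_csv(path) -> list[RetrospectiveScores]:
    df = pd.read_csv(path)
    return [
        RetrospectiveScores(
            str(r.participant_id),
            str(r.condition),
            float(r.narrative_engagement),
            float(r.enjoyment),
            str(r.intention).lower() in ("yes", "true", "1"),
        )
        for r in df.itertuples()
    ]
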
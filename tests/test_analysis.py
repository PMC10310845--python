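"""Stillness-hypothesis battery: gates, contrasts, correlations, quadrants."""

import itertools

import numpy as np
import pytest
from scipy import stats

from stillwatch.analysis import (
    MIN_GROUP_SIZE,
    PairedTestResult,
    QuadrantLabel,
    RetrospectiveScores,
    bonferroni,
    condition_effect,
    group_movement_comparison,
    intention_comparison,
    momentary_contrasts,
    normality_gate,
    paired_test,
    quadrant_groups,
    read_retrospective_csv,
    retrospective_correlation,
    score_questionnaire,
    signed_rank_test,
    write_retrospective_csv,
)
from stillwatch.errors import (
    ConfigError,
    DegenerateDataError,
    InsufficientDataError,
    ValidationError,
)
from stillwatch.movement import MovementSeries
from stillwatch.probes import PerProbeCategoryMeans

import pandas as pd


def scores_of(rows):
    return [RetrospectiveScores(f"P{i:02d}", cond, eng, enj, intent)
            for i, (cond, eng, enj, intent) in enumerate(rows)]


def const_series(value, n=300, pid="P", condition="control"):
    return MovementSeries(pid, condition, np.arange(n),
                          np.full(n, float(value)), np.full(n, 63.0))


class TestScoreQuestionnaire:
    @pytest.mark.parametrize("items,expected", [([3, 3, 3], 3.0), ([1, 5], 3.0)])
    def test_mean(self, items, expected):
        assert score_questionnaire(items, 1, 5) == expected

    def test_random_items_match_mean(self, rng):
        items = rng.uniform(1, 5, 12)
        assert score_questionnaire(items, 1, 5) == pytest.approx(items.mean())

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            score_questionnaire([0.5, 3], 1, 5)

    def test_empty_rejected(self):
        with pytest.raises(ConfigError):
            score_questionnaire([], 1, 5)


class TestNormalityGate:
    def test_skewed_sample_selects_wilcoxon(self, rng):
        gate = normality_gate(rng.lognormal(0, 1, 50))
        assert gate.test_name == "wilcoxon_signed_rank"
        assert gate.shapiro_p < 0.05

    def test_normal_sample_selects_t(self):
        # exact normal quantiles cannot fail a normality test
        values = stats.norm.ppf(np.linspace(0.01, 0.99, 50))
        gate = normality_gate(values)
        assert gate.test_name == "parametric_paired_t"
        assert gate.shapiro_p > 0.05

    def test_too_few_values(self):
        with pytest.raises(InsufficientDataError):
            normality_gate([1.0, 2.0])

    def test_constant_values_warn_and_pick_wilcoxon(self):
        gate = normality_gate([1.0, 1.0, 1.0, 1.0])
        assert gate.test_name == "wilcoxon_signed_rank"
        assert gate.warning


def enumerate_signed_rank(d, alternative):
    """Exhaustive 2^n null distribution of the signed-rank statistic."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    n = len(d)
    total = n * (n + 1) / 2
    w_plus = ranks[d > 0].sum()
    dist = np.array([
        sum(r for r, m in zip(ranks, mask) if m)
        for mask in itertools.product([0, 1], repeat=n)
    ])
    if alternative == "greater":
        return w_plus, float(np.mean(dist >= w_plus))
    if alternative == "less":
        return w_plus, float(np.mean(dist <= w_plus))
    p = min(1.0, 2 * min(np.mean(dist >= w_plus), np.mean(dist <= w_plus)))
    return min(w_plus, total - w_plus), float(p)


class TestSignedRankOracle:
    @pytest.mark.parametrize("n", range(3, 11))
    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_matches_exhaustive_enumeration(self, n, alternative):
        rng = np.random.default_rng(n)
        d = rng.normal(0.4, 1.0, n)
        while len(np.unique(np.abs(d))) < n or np.any(d == 0):
            d = rng.normal(0.4, 1.0, n)
        stat, p = signed_rank_test(d, alternative=alternative, method="exact")
        o_stat, o_p = enumerate_signed_rank(d, alternative)
        assert stat == pytest.approx(o_stat)
        assert p == pytest.approx(o_p, abs=1e-12)

    def test_zero_differences_dropped(self):
        d = [0.0, 1.0, -2.0, 3.0, 0.0, 4.0]
        stat, p = signed_rank_test(d, method="exact")
        o_stat, o_p = enumerate_signed_rank(d, "two-sided")
        assert stat == pytest.approx(o_stat)
        assert p == pytest.approx(o_p, abs=1e-12)


class TestBonferroni:
    def test_multiplication_and_cap(self):
        assert bonferroni(0.01, 6) == pytest.approx(0.06)
        assert bonferroni(0.4, 6) == 1.0

    def test_monotone(self, rng):
        for p in rng.uniform(0, 1, 20):
            assert bonferroni(p, 6) >= p

    def test_adjusted_below_raw_rejected(self):
        with pytest.raises(ValidationError):
            PairedTestResult(1.0, 0.5, 10, "t", adjusted_p=0.2)


class TestMomentaryContrasts:
    def _table(self, means):
        df = pd.DataFrame(means,
                          columns=["distracted", "engaged", "reflecting", "immersed"])
        counts = df.notna().astype(int) * 5
        return PerProbeCategoryMeans(df, counts, 0, 3)

    def test_six_contrasts_with_bonferroni_family(self, rng):
        means = rng.uniform(0.2, 1.5, size=(20, 4))
        results = momentary_contrasts(self._table(means))
        assert len(results) == 6
        for r in results:
            assert r.computable
            assert r.adjusted_p == pytest.approx(min(1.0, r.p_value * 6))
            assert r.n == 20

    def test_identical_columns_reported_as_no_effect(self, rng):
        means = rng.uniform(0.2, 1.5, size=(10, 4))
        means[:, 3] = means[:, 1]  # immersed == engaged everywhere
        results = momentary_contrasts(self._table(means))
        ei = [r for r in results if r.label == "engaged_vs_immersed"][0]
        assert ei.p_value == 1.0
        assert "no effect" in ei.note

    def test_sparse_contrast_not_computable(self, rng):
        means = rng.uniform(0.2, 1.5, size=(10, 4))
        means[2:, 0] = np.nan  # distracted present at only 2 probes
        results = momentary_contrasts(self._table(means))
        for r in results:
            if "distracted" in r.label:
                assert not r.computable
                assert "usable probes" in r.note
            else:
                assert r.computable


class TestRetrospectiveCorrelation:
    def test_perfect_inverse_ranks(self):
        movement = {f"P{i:02d}": float(i + 1) for i in range(6)}
        scores = scores_of([("control", 5.0 - i * 0.5, 50.0, True) for i in range(6)])
        rho, p = retrospective_correlation(movement, scores)
        assert rho == pytest.approx(-1.0)

    def test_permutation_null_is_uniform(self, rng):
        movement = {f"P{i:02d}": float(v) for i, v in enumerate(rng.uniform(0, 2, 20))}
        pvals = []
        for _ in range(200):
            engs = rng.permutation(np.linspace(1.5, 4.5, 20))
            scores = [RetrospectiveScores(f"P{i:02d}", "control", engs[i], 50.0, True)
                      for i in range(20)]
            pvals.append(retrospective_correlation(movement, scores)[1])
        # under independence p is ~uniform: KS test should not reject hard
        assert stats.kstest(pvals, "uniform").pvalue > 0.001

    def test_ties_match_tie_corrected_spearman(self, rng):
        mv = np.round(rng.uniform(0, 2, 12), 1)
        eng = np.round(rng.uniform(1, 5, 12), 0)
        movement = {f"P{i:02d}": float(v) for i, v in enumerate(mv)}
        scores = [RetrospectiveScores(f"P{i:02d}", "control", float(eng[i]), 50.0, True)
                  for i in range(12)]
        rho, _ = retrospective_correlation(movement, scores)
        # oracle: Pearson correlation of midranks (the tie-corrected form)
        expected = np.corrcoef(stats.rankdata(mv), stats.rankdata(eng))[0, 1]
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        movement = {f"P{i:02d}": 1.0 for i in range(6)}
        scores = scores_of([("control", 3.0, 50.0, True)] * 6)
        with pytest.raises(DegenerateDataError):
            retrospective_correlation(movement, scores)


class TestIntentionComparison:
    def test_identical_groups_null(self, rng):
        vals = rng.uniform(0, 2, 300)
        movements, scores = {}, []
        for i in range(8):
            pid = f"P{i:02d}"
            movements[pid] = MovementSeries(pid, "control", np.arange(300), vals,
                                            np.full(300, 63.0))
            scores.append(RetrospectiveScores(pid, "control", 3.0, 50.0, i % 2 == 0))
        res = intention_comparison(movements, scores)
        assert res.p_value == 1.0

    def test_uniform_shift_detected_with_direction(self, rng):
        movements, scores = {}, []
        for i in range(12):
            pid = f"P{i:02d}"
            base = rng.uniform(0.8, 1.2, 600)
            intent = i < 6
            if intent:
                base -= 0.3
            movements[pid] = MovementSeries(pid, "control", np.arange(600),
                                            np.clip(base, 0, None),
                                            np.full(600, 63.0))
            scores.append(RetrospectiveScores(pid, "control", 3.0, 50.0, intent))
        res = intention_comparison(movements, scores)
        assert res.p_value < 0.01
        assert res.note == "yes group moves less"

    def test_empty_group_rejected(self):
        movements = {"P00": const_series(0.5, pid="P00")}
        scores = scores_of([("control", 3.0, 50.0, True)])
        with pytest.raises(InsufficientDataError):
            intention_comparison(movements, scores)


class TestConditionEffect:
    def test_identical_groups_t_zero(self):
        rows = [("control", 3.0, 50.0, True), ("control", 3.5, 50.0, True),
                ("experience_sampling", 3.0, 50.0, False),
                ("experience_sampling", 3.5, 50.0, True)]
        res = condition_effect(scores_of(rows))
        assert res.t == pytest.approx(0.0)
        assert res.intention_proportion["control"] == 1.0
        assert res.intention_proportion["experience_sampling"] == 0.5

    def test_welch_df_matches_direct_formula(self, rng):
        a = rng.normal(3.4, 0.8, 58)
        b = rng.normal(3.3, 0.7, 74)
        rows = [("control", float(np.clip(x, 1, 5)), 50.0, True) for x in a]
        rows += [("experience_sampling", float(np.clip(x, 1, 5)), 50.0, True)
                 for x in b]
        scores = scores_of(rows)
        res = condition_effect(scores)
        x = np.array([s.narrative_engagement for s in scores if s.condition == "control"])
        y = np.array([s.narrative_engagement for s in scores
                      if s.condition == "experience_sampling"])
        va, vb = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
        df = (va + vb) ** 2 / (va**2 / (x.size - 1) + vb**2 / (y.size - 1))
        t = (x.mean() - y.mean()) / np.sqrt(va + vb)
        assert res.t == pytest.approx(t, abs=1e-12)
        assert res.df == pytest.approx(df, abs=1e-9)
        assert res.p_value == pytest.approx(2 * stats.t.sf(abs(t), df), abs=1e-12)

    def test_missing_condition_rejected(self):
        with pytest.raises(InsufficientDataError):
            condition_effect(scores_of([("control", 3.0, 50.0, True)] * 4))


class TestQuadrantGroups:
    def test_corner_construction_one_per_quadrant(self):
        rows = [("control", 4.5, 90.0, True), ("control", 1.5, 10.0, False),
                ("control", 1.6, 80.0, True), ("control", 4.4, 20.0, False)]
        qa = quadrant_groups(scores_of(rows), min_group_size=1)
        assert sorted(qa.group_sizes.values()) == [1, 1, 1, 1]

    def test_exactly_at_both_medians_goes_low_low(self):
        rows = [("control", 3.0, 50.0, True), ("control", 4.0, 80.0, True),
                ("control", 2.0, 20.0, False), ("control", 3.0, 50.0, False),
                ("control", 5.0, 90.0, True)]
        qa = quadrant_groups(scores_of(rows), min_group_size=1)
        # P00 sits exactly at both medians (3.0, 50.0): ties go low
        assert qa.labels["P00"] == QuadrantLabel.DISENGAGED_DISLIKED

    def test_undersized_group_flagged_not_analysable(self):
        # balanced 15/15 high–low on both axes so the medians fall between
        # the clusters and each group lands in its intended quadrant
        rows = []
        rows += [("control", 4.5, 90.0, True)] * 10   # engaged-enjoyed
        rows += [("control", 1.5, 10.0, False)] * 10  # disengaged-disliked
        rows += [("control", 1.6, 80.0, True)] * 5    # disengaged-enjoyed, n=5
        rows += [("control", 4.4, 20.0, False)] * 5   # engaged-disliked, n=5
        qa = quadrant_groups(scores_of(rows))
        assert qa.group_sizes[QuadrantLabel.DISENGAGED_ENJOYED] == 5
        assert QuadrantLabel.DISENGAGED_ENJOYED not in qa.analysable
        assert QuadrantLabel.ENGAGED_ENJOYED in qa.analysable


class TestGroupMovementComparison:
    def _cohort(self, rng, group_movement):
        movements, rows = {}, []
        i = 0
        for (eng, enj, level, size) in group_movement:
            for _ in range(size):
                pid = f"P{i:02d}"
                vals = np.clip(rng.normal(level, 0.05, 600), 0, None)
                movements[pid] = MovementSeries(pid, "control", np.arange(600),
                                                vals, np.full(600, 63.0))
                rows.append((pid, eng, enj))
                i += 1
        scores = [RetrospectiveScores(pid, "control", eng, enj, True)
                  for pid, eng, enj in rows]
        return movements, scores

    def test_size_five_group_excluded_with_reason(self, rng):
        movements, scores = self._cohort(rng, [
            (4.5, 90.0, 0.4, 10), (1.5, 10.0, 0.9, 10),
            (1.6, 80.0, 1.4, 5), (4.4, 20.0, 0.7, 5),
        ])
        qa = quadrant_groups(scores)
        results, exclusions = group_movement_comparison(qa, movements)
        assert any("disengaged_enjoyed" in e and "below minimum size" in e
                   for e in exclusions)
        assert all("disengaged_enjoyed" not in r.label for r in results)

    def test_identical_profiles_null(self, rng):
        # both groups get byte-identical movement: exact no-effect result
        vals = rng.uniform(0.4, 0.8, 600)
        movements, scores = {}, []
        for i in range(16):
            pid = f"P{i:02d}"
            movements[pid] = MovementSeries(pid, "control", np.arange(600),
                                            vals, np.full(600, 63.0))
            eng, enj = (4.5, 90.0) if i < 8 else (1.5, 10.0)
            scores.append(RetrospectiveScores(pid, "control", eng, enj, True))
        results, _ = group_movement_comparison(quadrant_groups(scores), movements)
        assert len(results) == 1
        assert results[0].p_value == 1.0

    def test_planted_ordering_recovered(self, rng):
        movements, scores = self._cohort(rng, [
            (4.5, 90.0, 0.4, 8), (1.5, 10.0, 0.9, 8),
            (1.6, 80.0, 1.5, 8), (4.4, 20.0, 0.7, 8),
        ])
        qa = quadrant_groups(scores)
        results, _ = group_movement_comparison(qa, movements)
        de_ee = [r for r in results
                 if set(r.label.split("_vs_"))
                 == {"engaged_enjoyed", "disengaged_enjoyed"}]
        assert de_ee and de_ee[0].p_value < 0.01

    def test_fewer_than_two_groups_rejected(self, rng):
        movements, scores = self._cohort(rng, [(4.5, 90.0, 0.4, 8)])
        with pytest.raises(InsufficientDataError):
            group_movement_comparison(quadrant_groups(scores), movements)


class TestRetrospectiveCSV:
    def test_round_trip(self, tmp_path):
        scores = scores_of([("control", 3.2, 61.0, True),
                            ("experience_sampling", 2.1, 20.5, False)])
        path = tmp_path / "retro.csv"
        write_retrospective_csv(scores, path)
        back = read_retrospective_csv(path)
        assert [vars(s) for s in back] == [vars(s) for s in scores]
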
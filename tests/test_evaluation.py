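import itertools

import numpy as np
import pytest

from deltabind.evaluation import (
    ContingencyCounts,
    auroc,
    bootstrap_pvalue,
    contingency_stats,
    evaluate_ranking,
    group_compare,
    load_ctcf_snp_counts,
    precision_at_recall,
    precision_recall,
)


class TestPrecisionRecall:
    def test_perfect_ranking_has_unit_aupr(self):
        y = np.array([1, 1, 0, 0, 0], bool)
        assert precision_recall(np.array([5, 4, 3, 2, 1.0]), y).aupr == 1.0

    def test_single_positive_at_rank_k_gives_one_over_k(self):
        # one positive ranked last among 100: average precision = 1/100
        y = np.zeros(100, bool)
        y[0] = True
        scores = np.arange(100, dtype=float)  # positive has the lowest score
        assert precision_recall(scores, y).aupr == pytest.approx(1 / 100)

    def test_all_tied_scores_give_prevalence(self):
        y = np.zeros(50, bool)
        y[:5] = True
        assert precision_recall(np.ones(50), y).aupr == pytest.approx(0.1)

    def test_requires_both_classes(self):
        with pytest.raises(ValueError, match="positive"):
            precision_recall(np.arange(4.0), np.zeros(4, bool))
        with pytest.raises(ValueError, match="negative"):
            precision_recall(np.arange(4.0), np.ones(4, bool))

    def test_matches_threshold_sweep_oracle(self, rng):
        scores = rng.integers(0, 20, 200).astype(float)  # many ties
        y = rng.random(200) < 0.1
        if not y.any():
            y[0] = True
        aupr = precision_recall(scores, y).aupr
        # brute force: process tied blocks jointly, AP = sum over positives of
        # the precision at their block threshold / n_pos
        oracle = 0.0
        n_pos = y.sum()
        for t in np.unique(scores)[::-1]:
            called = scores >= t
            block_pos = (y & (scores == t)).sum()
            if block_pos:
                oracle += block_pos * y[called].mean()
        oracle /= n_pos
        assert aupr == pytest.approx(oracle, abs=1e-12)


class TestPrecisionAtRecall:
    def test_perfect_ranking_precision_one_everywhere(self):
        y = np.array([1, 1, 0, 0, 0], bool)
        curve = precision_recall(np.array([5, 4, 3, 2, 1.0]), y)
        for r in (0.0, 0.1, 0.5, 1.0):
            assert precision_at_recall(curve, r) == 1.0

    def test_matches_exhaustive_sweep_oracle(self, rng):
        n, level = 1000, 0.10
        scores = rng.normal(size=n)
        y = np.zeros(n, bool)
        y[rng.choice(n, 10, replace=False)] = True
        curve = precision_recall(scores, y)
        got = precision_at_recall(curve, level)
        order = np.argsort(-scores)
        tp = np.cumsum(y[order])
        recall = tp / y.sum()
        k = int(np.argmax(recall >= level))  # first crossing down the list
        assert got == pytest.approx(tp[k] / (k + 1))

    def test_recall_zero_is_top_ranked_site(self):
        scores = np.array([3.0, 2.0, 1.0])
        y = np.array([0, 1, 1], bool)
        curve = precision_recall(scores, y)
        assert precision_at_recall(curve, 0.0) == 0.0  # top site is a negative

    def test_unreachable_recall_rejected(self):
        y = np.array([1, 0], bool)
        curve = precision_recall(np.array([1.0, 2.0]), y)
        with pytest.raises(ValueError):
            precision_at_recall(curve, 1.5)


class TestAuroc:
    def test_perfect_and_antiperfect(self):
        y = np.array([1, 1, 0, 0], bool)
        assert auroc(np.array([4, 3, 2, 1.0]), y) == 1.0
        assert auroc(np.array([1, 2, 3, 4.0]), y) == 0.0

    def test_matches_all_pairs_oracle_with_ties(self, rng):
        scores = rng.integers(0, 10, 200).astype(float)
        y = rng.random(200) < 0.3
        y[:2] = [True, False]
        got = auroc(scores, y)
        pos, neg = scores[y], scores[~y]
        wins = sum(
            1.0 if p > q else 0.5 if p == q else 0.0
            for p in pos
            for q in neg
        )
        assert got == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_invariant_under_increasing_transform(self, rng):
        scores = rng.normal(size=300)
        y = rng.random(300) < 0.2
        y[0] = True
        y[1] = False
        assert auroc(np.exp(scores), y) == pytest.approx(auroc(scores, y))


class TestBootstrap:
    def test_perfect_ranking_attains_minimum_pvalue(self):
        n, n_pos = 2000, 20
        y = np.zeros(n, bool)
        y[:n_pos] = True
        scores = -np.arange(n, dtype=float)
        p = bootstrap_pvalue(scores, y, "aupr", n_resamples=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_null_pvalues_are_calibrated(self):
        n = 500
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            y = np.zeros(n, bool)
            y[rng.choice(n, 25, replace=False)] = True
            scores = rng.normal(size=n)
            p = bootstrap_pvalue(scores, y, "auroc", n_resamples=199, seed=seed)
            hits += p > 0.05
        assert hits >= 45  # >= 90% of null runs not significant

    def test_zero_resamples_rejected(self):
        y = np.array([1, 0], bool)
        with pytest.raises(ValueError, match="at least 100"):
            bootstrap_pvalue(np.array([1.0, 0.0]), y, n_resamples=0)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(4)
        y = rng.random(300) < 0.1
        y[0] = True
        scores = rng.normal(size=300)
        p1 = bootstrap_pvalue(scores, y, "aupr", n_resamples=199, seed=7)
        p2 = bootstrap_pvalue(scores, y, "aupr", n_resamples=199, seed=7)
        assert p1 == p2


class TestContingency:
    def test_packaged_fixture_statistics(self):
        stats = contingency_stats(load_ctcf_snp_counts())
        assert round(100 * stats["ppv"]) == 18
        assert round(100 * stats["npv"]) == 97
        assert round(100 * stats["prevalence_event"]) == 7
        assert round(100 * stats["prevalence_signal"]) == 27

    def test_saturated_table_gives_all_hundred_percent(self):
        # everything differential and everything signalled except one site,
        # so the no-signal cell stays defined
        counts = ContingencyCounts(n_total=10, n_signal=9, n_event=9, n_both=9)
        stats = contingency_stats(counts)
        assert stats["ppv"] == 1.0 and stats["npv"] == 1.0

    def test_impossible_counts_rejected(self):
        with pytest.raises(ValueError, match="n_both"):
            ContingencyCounts(n_total=10, n_signal=2, n_event=2, n_both=5)

    def test_zero_denominator_named(self):
        counts = ContingencyCounts(n_total=5, n_signal=0, n_event=1, n_both=0)
        with pytest.raises(ValueError, match="n_signal"):
            contingency_stats(counts)


class TestGroupCompare:
    def test_identical_groups(self):
        diff, p = group_compare([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert diff == 0.0
        assert p >= 0.5

    def test_fully_separated_groups_attain_exact_minimum(self):
        diff, p = group_compare([1, 1, 1], [0, 0, 0])
        assert diff == 1.0
        assert p == pytest.approx(1 / 20)  # 1 / C(6,3)

    def test_matches_exhaustive_enumeration(self, rng):
        a = rng.integers(0, 10, 4).astype(float)
        b = rng.integers(0, 10, 4).astype(float)
        _, p = group_compare(a, b)
        pooled = np.concatenate([a, b])
        obs = a.mean() - b.mean()
        count = total = 0
        for idx in itertools.combinations(range(8), 4):
            sel = np.zeros(8, bool)
            sel[list(idx)] = True
            stat = pooled[sel].mean() - pooled[~sel].mean()
            count += stat >= obs - 1e-12
            total += 1
        assert p == pytest.approx(count / total)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            group_compare([1.0], [0.0, 1.0])


class TestEvaluateRanking:
    def test_random_ranking_metrics_near_null_expectations(self):
        rng = np.random.default_rng(0)
        n = 100_000
        y = np.zeros(n, bool)
        y[:400] = True
        result = evaluate_ranking(rng.random(n), y)
        assert result.prevalence == pytest.approx(0.004)
        assert result.aupr == pytest.approx(0.004, abs=0.003)
        assert result.auroc == pytest.approx(0.5, abs=0.05)
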
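"""Compliance, retest agreement, and the nonparametric battery vs. oracles."""

import itertools
import math

import numpy as np
import pytest

from soundportraits import consistency as cons
from soundportraits import design as dsg
from soundportraits import raters as rat
from soundportraits import scoring as sco
from conftest import simulate_shared_weight_cell

TRIAL = dsg.Trial(0, "brightness", ("A", "B", "C", "D"))


def judgment(best, worst, idx=0, pid="p"):
    return rat.JudgmentRecord(pid, "brightness", idx, best, worst)


def score_table(scores):
    return sco.ScoreTable("brightness", "g", dict(scores), {}, None, 0)


class TestCompliance:
    def test_consensus_responder_scores_one(self):
        table = score_table({"A": 4.0, "B": 3.0, "C": 2.0, "D": 1.0})
        rec = cons.compliance([judgment("A", "D")], {0: TRIAL}, table)
        assert rec.compliance == 1.0
        assert rec.n_duels_scored == 5

    def test_fully_inverted_responder_scores_zero(self):
        table = score_table({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})
        rec = cons.compliance([judgment("A", "D")], {0: TRIAL}, table)
        assert rec.compliance == 0.0

    def test_tied_scores_drop_from_denominator(self):
        table = score_table({"A": 2.0, "B": 1.0, "C": 1.0, "D": 0.0})
        # duels A>B, A>C, A>D, B>D, C>D all orderable; but make B==C==1 tie
        # irrelevant (that pair is undetermined anyway); tie A with D instead
        table2 = score_table({"A": 1.0, "B": 0.5, "C": 0.5, "D": 1.0})
        rec = cons.compliance([judgment("A", "D")], {0: TRIAL}, table2)
        assert rec.n_duels_scored == 4  # the A-D duel dropped

    def test_retest_judgments_excluded_by_default(self):
        retest = dsg.Trial(1, "brightness", ("A", "B", "C", "D"),
                           is_retest=True, source_trial_index=0)
        table = score_table({"A": 4.0, "B": 3.0, "C": 2.0, "D": 1.0})
        judgments = [
            judgment("A", "D"),
            rat.JudgmentRecord("p", "brightness", 1, "D", "A",
                               is_retest=True, source_trial_index=0),
        ]
        rec = cons.compliance(judgments, {0: TRIAL, 1: retest}, table)
        assert rec.compliance == 1.0  # the inverted retest pass is ignored

    def test_no_scorable_duels_raises(self):
        table = score_table({"A": 1.0, "B": 1.0, "C": 1.0, "D": 1.0})
        with pytest.raises(ValueError):
            cons.compliance([judgment("A", "D")], {0: TRIAL}, table)


class TestRetestAgreement:
    def test_identical_passes_agree_fully(self):
        a, c = cons.retest_agreement(judgment("A", "D"), judgment("A", "D", 1), TRIAL)
        assert (a, c) == (5, 5)

    def test_swapped_best_worst_all_five_flip(self):
        a, c = cons.retest_agreement(judgment("A", "D"), judgment("D", "A", 1), TRIAL)
        assert (a, c) == (0, 5)

    def test_partial_overlap_three_of_four(self):
        # test best=A worst=D; retest best=A worst=C: comparable pairs are
        # A-B, A-C, A-D and C-D; only C-D flips
        a, c = cons.retest_agreement(judgment("A", "D"), judgment("A", "C", 1), TRIAL)
        assert (a, c) == (3, 4)

    def test_mismatched_id_set_raises(self):
        other = dsg.Trial(0, "brightness", ("A", "B", "C", "E"))
        with pytest.raises(ValueError):
            cons.retest_agreement(judgment("A", "D"), judgment("A", "C", 1), other)

    def test_record_aggregates_over_plan(self):
        ids = [f"s{i}" for i in range(8)]
        plan = dsg.build_design(ids, k=4, participants=["p"], n_retest=2, seed=1)["p"]
        judgments = [
            rat.JudgmentRecord(
                "p", "brightness", t.trial_index,
                min(t.stimulus_ids), max(t.stimulus_ids),
                is_retest=t.is_retest, source_trial_index=t.source_trial_index,
            )
            for t in plan.trials
        ]
        rec = cons.retest_record(judgments, plan)
        assert rec.agreement == 1.0  # deterministic id-based answers repeat
        assert rec.n_comparable_duels == 2 * 5


# ---------------------------------------------------------------------------
# Exhaustive oracles for the scipy-backed tests
# ---------------------------------------------------------------------------


def rankdata_simple(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def kruskal_h_oracle(groups):
    """Independent H computation: rank formula with tie correction."""
    flat = [v for g in groups for v in g]
    ranks = rankdata_simple(flat)
    n = len(flat)
    idx = 0
    h = 0.0
    for g in groups:
        r = ranks[idx : idx + len(g)]
        idx += len(g)
        h += sum(r) ** 2 / len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    ties = 0.0
    for v in set(flat):
        t = flat.count(v)
        ties += t**3 - t
    return h / (1 - ties / (n**3 - n))


class TestKruskalWallis:
    def test_identical_groups_degenerate(self):
        res = cons.kruskal_wallis([[1.0, 1.0], [1.0, 1.0], [1.0]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_h_matches_independent_formula(self):
        groups = [[2.1, 3.5, 1.0], [4.2, 5.1, 0.5], [2.2, 2.2, 6.0]]
        res = cons.kruskal_wallis(groups)
        assert res.statistic == pytest.approx(kruskal_h_oracle(groups), abs=1e-10)
        assert res.df == 2

    def test_exact_permutation_distribution_small_sample(self):
        """Chi-square p is close to the exhaustive permutation p at n=3x3."""
        groups = [[1.0, 7.0, 3.0], [6.0, 5.0, 9.0], [2.0, 8.0, 4.0]]
        res = cons.kruskal_wallis(groups)
        flat = [v for g in groups for v in g]
        h_obs = kruskal_h_oracle(groups)
        count = total = 0
        for first in itertools.combinations(range(9), 3):
            rest = [i for i in range(9) if i not in first]
            for second in itertools.combinations(rest, 3):
                third = [i for i in rest if i not in second]
                g = [[flat[i] for i in first], [flat[i] for i in second], [flat[i] for i in third]]
                total += 1
                if kruskal_h_oracle(g) >= h_obs - 1e-12:
                    count += 1
        exact_p = count / total
        assert res.p_value == pytest.approx(exact_p, abs=0.06)

    def test_two_group_case_consistent_with_mann_whitney(self):
        a = [1.0, 4.0, 2.5, 7.0, 3.0]
        b = [5.0, 6.0, 8.0, 9.0, 2.0]
        kw = cons.kruskal_wallis([a, b])
        mw = cons.mann_whitney_u(a, b)
        assert kw.p_value == pytest.approx(mw.p_value, abs=0.05)

    def test_needs_two_nonempty_groups(self):
        with pytest.raises(ValueError):
            cons.kruskal_wallis([[1.0]])
        with pytest.raises(ValueError):
            cons.kruskal_wallis([[1.0], []])


class TestMannWhitney:
    def test_complete_separation_gives_full_u(self):
        res = cons.mann_whitney_u([10.0, 11.0, 12.0], [1.0, 2.0, 3.0])
        assert res.statistic == 9.0  # n_a * n_b

    def test_identical_samples_p_one(self):
        res = cons.mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_exact_p_matches_labeling_enumeration(self):
        rng = np.random.default_rng(3)
        a = list(rng.normal(0.8, 1, 4))
        b = list(rng.normal(0.0, 1, 4))
        res = cons.mann_whitney_u(a, b, alternative="greater")
        # oracle: U statistic for every C(8,4) relabeling
        def u_stat(x, y):
            return sum(xi > yi for xi in x for yi in y)
        u_obs = u_stat(a, b)
        pool = a + b
        hits = total = 0
        for pick in itertools.combinations(range(8), 4):
            x = [pool[i] for i in pick]
            y = [pool[i] for i in range(8) if i not in pick]
            total += 1
            if u_stat(x, y) >= u_obs:
                hits += 1
        assert res.p_value == pytest.approx(hits / total, abs=1e-12)


class TestWilcoxon:
    def test_equal_samples_degenerate(self):
        res = cons.wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert res.degenerate
        assert res.p_value == 1.0

    def test_exact_p_matches_sign_pattern_enumeration(self):
        rng = np.random.default_rng(5)
        a = list(rng.normal(0.5, 1, 6))
        b = list(rng.normal(0.0, 1, 6))
        res = cons.wilcoxon_signed_rank(a, b)
        d = [x - y for x, y in zip(a, b)]
        ranks = rankdata_simple([abs(v) for v in d])
        w_obs = min(
            sum(r for r, v in zip(ranks, d) if v > 0),
            sum(r for r, v in zip(ranks, d) if v < 0),
        )
        hits = 0
        for signs in itertools.product([1, -1], repeat=6):
            w_plus = sum(r for r, s in zip(ranks, signs) if s > 0)
            w = min(w_plus, sum(ranks) - w_plus)
            if w <= w_obs:
                hits += 1
        assert res.p_value == pytest.approx(hits / 64, abs=1e-12)

    def test_sign_flip_symmetry(self):
        a = [1.0, 3.0, 2.0, 5.0, 4.0, 7.0]
        b = [0.5, 3.5, 1.0, 4.0, 4.5, 6.0]
        p1 = cons.wilcoxon_signed_rank(a, b).p_value
        p2 = cons.wilcoxon_signed_rank(b, a).p_value
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            cons.wilcoxon_signed_rank([1.0], [1.0, 2.0])


def friedman_q_oracle(matrix):
    """Independent Q computation with average ranks and tie correction."""
    n, k = len(matrix), len(matrix[0])
    ranks = [rankdata_simple(row) for row in matrix]
    col_sums = [sum(r[j] for r in ranks) for j in range(k)]
    q = 12.0 / (n * k * (k + 1)) * sum(c**2 for c in col_sums) - 3 * n * (k + 1)
    # tie correction per block
    ties = 0.0
    for row in matrix:
        for v in set(row):
            t = row.count(v)
            ties += t**3 - t
    c = 1 - ties / (n * k * (k**2 - 1))
    return q / c if c > 0 else float("nan")


class TestFriedman:
    def test_constant_rows_degenerate(self):
        res = cons.friedman([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_q_matches_independent_formula(self):
        m = [[1.0, 3.0, 2.0], [2.0, 3.0, 1.0], [1.5, 2.5, 3.5], [3.0, 1.0, 2.0]]
        res = cons.friedman(m)
        assert res.statistic == pytest.approx(friedman_q_oracle(m), abs=1e-10)

    def test_statistic_matches_oracle_over_whole_permutation_distribution(self):
        """Our Q agrees with the independent oracle not just at the observed
        table but across every within-row permutation of it."""
        m = [[1.0, 5.0, 3.0], [4.0, 6.0, 2.0], [7.0, 9.0, 8.0]]
        for perms in itertools.product(itertools.permutations(range(3)), repeat=3):
            pm = [[m[i][j] for j in p] for i, p in enumerate(perms)]
            assert cons.friedman(pm).statistic == pytest.approx(
                friedman_q_oracle(pm), abs=1e-10
            )

    def test_column_permutation_invariance(self):
        m = np.array([[1.0, 3.0, 2.0], [2.0, 3.0, 1.0], [1.5, 2.5, 3.5]])
        q1 = cons.friedman(m).statistic
        q2 = cons.friedman(m[:, [2, 0, 1]]).statistic
        assert q1 == pytest.approx(q2, abs=1e-10)

    def test_incomplete_blocks_rejected(self):
        with pytest.raises(ValueError):
            cons.friedman(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestBonferroni:
    def test_arithmetic_and_clipping(self):
        assert cons.bonferroni_adjust([0.01], m=4) == [0.04]
        assert cons.bonferroni_adjust([0.5], m=4) == [1.0]
        assert cons.bonferroni_adjust([0.001, 0.02, 0.2]) == pytest.approx(
            [0.003, 0.06, 0.6]
        )

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            cons.bonferroni_adjust([1.2])


def test_mean_compliance_decreases_with_rater_noise():
    """Group compliance degrades strictly as judgment noise grows."""
    means = []
    for noise in (0.1, 1.0, 10.0):
        vals = []
        for seed in range(3):
            ids, _, duels, plans, judgments = simulate_shared_weight_cell(
                100 + seed, n_stimuli=40, n_raters=4, noise_fraction=noise
            )
            table = sco.score_rescorla_wagner(duels, ids, sco.RWConfig(seed=0))
            for pid, plan in plans.items():
                pj = [j for j in judgments if j.participant_id == pid]
                trials = {t.trial_index: t for t in plan.trials}
                vals.append(cons.compliance(pj, trials, table).compliance)
        means.append(np.mean(vals))
    assert means[0] > means[1] > means[2]
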
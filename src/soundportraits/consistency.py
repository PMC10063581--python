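"""Inter- and intra-participant consistency metrics and nonparametric tests.

Compliance measures inter-participant consistency: the proportion of a
participant's implied duels whose winner also has the higher group-level
score.  A participant who always answers with the group consensus scores 1;
a uniformly random responder scores 0.5 in expectation.  Duels whose two
group scores tie exactly are dropped from the denominator (a tie carries no
information either way), and retest trials are excluded by default.

Retest agreement measures intra-participant consistency: over the pairs
whose order is determined in *both* a trial and its retest, the proportion
with the same winner.

The nonparametric battery (Kruskal-Wallis, Mann-Whitney U, Friedman,
Wilcoxon signed-rank, Bonferroni adjustment) wraps scipy.stats with exact
small-sample p-values where available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignPlan, Trial
from .raters import JudgmentRecord
from .scoring import ScoreTable, deduce_duels

#: exact p-value enumeration is used at or below this total sample size
EXACT_N_MAX = 12


@dataclass
class ComplianceRecord:
    participant_id: str
    group: str
    concept: str
    compliance: float
    n_duels_scored: int


@dataclass
class RetestRecord:
    participant_id: str
    concept: str
    agreement: float
    n_comparable_duels: int


@dataclass
class TestResult:
    statistic_name: str  # H, U, Q or W
    statistic: float
    p_value: float
    n_per_group: list[int]
    df: int | None = None
    adjusted: bool = False
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Compliance
# ---------------------------------------------------------------------------


def compliance(
    participant_judgments: Sequence[JudgmentRecord],
    trials: Mapping[int, Trial],
    group_scores: ScoreTable,
    include_retests: bool = False,
) -> ComplianceRecord:
    """Proportion of the participant's duels matching the group score order."""
    matches = 0
    scored = 0
    pid = participant_judgments[0].participant_id
    group = participant_judgments[0].group
    concept = participant_judgments[0].concept
    for j in participant_judgments:
        if j.is_retest and not include_retests:
            continue
        for duel in deduce_duels(j, trials[j.trial_index]):
            sw = group_scores.scores[duel.winner_id]
            sl = group_scores.scores[duel.loser_id]
            if sw == sl:
                continue  # tied group scores are uninformative
            scored += 1
            if sw > sl:
                matches += 1
    if scored == 0:
        raise ValueError(f"participant {pid!r} has no scorable duels")
    return ComplianceRecord(pid, group, concept, matches / scored, scored)


# ---------------------------------------------------------------------------
# Retest agreement
# ---------------------------------------------------------------------------


def retest_agreement(
    test_judgment: JudgmentRecord,
    retest_judgment: JudgmentRecord,
    trial: Trial,
) -> tuple[int, int]:
    """(agreements, comparable) over pairs determined in both passes."""
    ids = set(trial.stimulus_ids)
    for j in (test_judgment, retest_judgment):
        if j.best_id not in ids or j.worst_id not in ids:
            raise ValueError("retest id set does not match its source trial")
    first = {
        frozenset((d.winner_id, d.loser_id)): d.winner_id
        for d in deduce_duels(test_judgment, trial)
    }
    second = {
        frozenset((d.winner_id, d.loser_id)): d.winner_id
        for d in deduce_duels(retest_judgment, trial)
    }
    comparable = set(first) & set(second)
    agreements = sum(1 for p in comparable if first[p] == second[p])
    return agreements, len(comparable)


def retest_record(
    participant_judgments: Sequence[JudgmentRecord],
    plan: DesignPlan,
) -> RetestRecord:
    """Aggregate retest agreement over all of one participant's retest trials."""
    by_index = {j.trial_index: j for j in participant_judgments}
    trials = {t.trial_index: t for t in plan.trials}
    agree = comparable = 0
    pid = participant_judgments[0].participant_id
    concept = participant_judgments[0].concept
    for t in plan.retest_trials:
        test_j = by_index.get(t.source_trial_index)
        retest_j = by_index.get(t.trial_index)
        if test_j is None or retest_j is None:
            continue
        a, c = retest_agreement(test_j, retest_j, trials[t.source_trial_index])
        agree += a
        comparable += c
    agreement = agree / comparable if comparable else float("nan")
    return RetestRecord(pid, concept, agreement, comparable)


# ---------------------------------------------------------------------------
# Nonparametric tests (scipy-backed)
# ---------------------------------------------------------------------------


def kruskal_wallis(samples: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H with tie correction; p from chi-square, df = g - 1."""
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        raise ValueError("need >= 2 nonempty groups")
    ns = [len(s) for s in samples]
    flat = np.concatenate([np.asarray(s, float) for s in samples])
    if np.all(flat == flat[0]):
        return TestResult("H", 0.0, 1.0, ns, df=len(samples) - 1, degenerate=True)
    h, p = stats.kruskal(*samples)
    return TestResult("H", float(h), float(p), ns, df=len(samples) - 1)


def mann_whitney_u(
    a: Sequence[float], b: Sequence[float], alternative: str = "two-sided"
) -> TestResult:
    """Mann-Whitney U (U of the first sample; exact p for small tie-free data).

    Convention: U = n_a * n_b when every value of ``a`` exceeds every value
    of ``b``.  Exact enumeration is used when n_a + n_b <= 12 and there are
    no ties; otherwise the normal approximation with tie and continuity
    corrections.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) + len(b) <= EXACT_N_MAX and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return TestResult("U", float(res.statistic), float(res.pvalue), [len(a), len(b)])


def friedman(blocks: np.ndarray | pd.DataFrame) -> TestResult:
    """Friedman Q over a complete participants x conditions block matrix."""
    m = np.asarray(blocks, float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a complete matrix with >= 2 rows and >= 3 columns")
    if np.isnan(m).any():
        raise ValueError("incomplete blocks")
    if np.all([np.all(row == row[0]) for row in m]):
        return TestResult("Q", 0.0, 1.0, [m.shape[0]] * m.shape[1], df=m.shape[1] - 1, degenerate=True)
    if m.shape[1] == 2:
        # scipy requires >= 3 conditions; fall back to the rank formula
        ranks = np.apply_along_axis(stats.rankdata, 1, m)
        n, kc = m.shape
        q = 12.0 * n / (kc * (kc + 1)) * np.sum((ranks.mean(axis=0) - (kc + 1) / 2) ** 2)
        p = float(stats.chi2.sf(q, kc - 1))
        return TestResult("Q", float(q), p, [n] * kc, df=kc - 1)
    q, p = stats.friedmanchisquare(*m.T)
    return TestResult("Q", float(q), float(p), [m.shape[0]] * m.shape[1], df=m.shape[1] - 1)


def wilcoxon_signed_rank(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Paired Wilcoxon signed-rank; zero differences are dropped.

    Exact p for n <= 12 nonzero tie-free differences, normal approximation
    otherwise; if every difference is zero the result is degenerate (p = 1).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) != len(b):
        raise ValueError("samples must have equal length")
    d = a - b
    nz = d[d != 0]
    if len(nz) == 0:
        return TestResult("W", 0.0, 1.0, [len(a)], degenerate=True)
    ties = len(np.unique(np.abs(nz))) < len(nz)
    method = "exact" if (len(nz) <= EXACT_N_MAX and not ties) else "approx"
    res = stats.wilcoxon(a, b, zero_method="wilcox", method=method)
    return TestResult("W", float(res.statistic), float(res.pvalue), [len(a)])


def bonferroni_adjust(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni family-wise correction: p_adj = min(1, p * m)."""
    ps = list(p_values)
    if any(not 0.0 <= p <= 1.0 for p in ps):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(ps) if m is None else m
    return [min(1.0, p * m) for p in ps]


# ---------------------------------------------------------------------------
# Tabulation helpers
# ---------------------------------------------------------------------------


def compliance_frame(records: Iterable[ComplianceRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def retest_frame(records: Iterable[RetestRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])
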
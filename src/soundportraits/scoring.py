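"""Tournament scoring of best/worst judgments.

A best/worst choice on a k-tuple determines 2k-3 pairwise duels: the best
sound beats every other sound in the trial, and every non-worst sound beats
the worst (pairs between the two middle items stay undetermined).  Duels
collected across all raters of a group are then turned into per-stimulus
scores by an iterative Rescorla-Wagner / Elo-style value-updating rule:

    p_hat = logistic(s_winner - s_loser)        expected win probability
    delta = 1 - p_hat                           prediction error
    s_winner += alpha * delta;  s_loser -= alpha * delta

run for several epochs over the (optionally shuffled) duel list.  The
update is zero-sum, so the mean score is conserved and only score
*differences* matter; because the duels link overlapping trials, score
information propagates across the whole corpus even though each pair is
presented at most once.  A classical count-based best-worst score
((wins - losses) / duels) is provided as an independent baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import Trial
from .raters import JudgmentRecord


@dataclass(frozen=True)
class Duel:
    winner_id: str
    loser_id: str
    participant_id: str = ""
    trial_index: int = -1

    def __post_init__(self):
        if self.winner_id == self.loser_id:
            raise ValueError("winner and loser must differ")


@dataclass(frozen=True)
class RWConfig:
    learning_rate: float = 0.05
    n_epochs: int = 50
    initial_score: float = 0.0
    shuffle: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.learning_rate <= 1.0:
            raise ValueError("learning_rate must lie in (0, 1]")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")


@dataclass
class ScoreTable:
    concept: str
    group: str
    scores: dict[str, float]
    scores_normalized: dict[str, float]
    config: RWConfig | None
    n_duels: int

    def series(self) -> pd.Series:
        return pd.Series(self.scores).sort_index()

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "stimulus_id": sorted(self.scores),
                "score": [self.scores[s] for s in sorted(self.scores)],
                "score_normalized": [self.scores_normalized[s] for s in sorted(self.scores)],
            }
        )
        df.to_csv(path, index=False)
        if self.config is not None:
            sidecar = Path(path).with_suffix(".config.json")
            sidecar.write_text(json.dumps(asdict(self.config), indent=1))


# ---------------------------------------------------------------------------
# Duels
# ---------------------------------------------------------------------------


def deduce_duels(judgment: JudgmentRecord, trial: Trial) -> list[Duel]:
    """The 2k-3 pairwise relations determined by one best/worst choice."""
    ids = trial.stimulus_ids
    best, worst = judgment.best_id, judgment.worst_id
    if best == worst:
        raise ValueError("best and worst must differ")
    if best not in ids or worst not in ids:
        raise ValueError("judgment inconsistent with trial")
    duels = [Duel(best, x, judgment.participant_id, trial.trial_index) for x in ids if x != best]
    duels += [
        Duel(x, worst, judgment.participant_id, trial.trial_index)
        for x in ids
        if x not in (best, worst)
    ]
    return duels


def duels_from_judgments(
    judgments: Iterable[JudgmentRecord],
    plans_trials: Mapping[str, Mapping[int, Trial]],
    include_retests: bool = False,
) -> list[Duel]:
    """Deduce duels for many judgments; ``plans_trials[participant][index]``
    looks up each judgment's trial.  Retest trials are excluded by default
    (they repeat pairs and are reserved for the retest metric)."""
    duels: list[Duel] = []
    for j in judgments:
        if j.is_retest and not include_retests:
            continue
        duels.extend(deduce_duels(j, plans_trials[j.participant_id][j.trial_index]))
    return duels


def duels_to_frame(duels: Iterable[Duel]) -> pd.DataFrame:
    return pd.DataFrame([asdict(d) for d in duels])


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def _normalize(scores: np.ndarray) -> np.ndarray:
    lo, hi = float(scores.min()), float(scores.max())
    if hi == lo:
        return np.zeros_like(scores)
    return (scores - lo) / (hi - lo)


def score_rescorla_wagner(
    duels: Sequence[Duel],
    corpus_ids: Iterable[str],
    config: RWConfig = RWConfig(),
    concept: str = "",
    group: str = "",
) -> ScoreTable:
    """Rescorla-Wagner tournament scores over the corpus.

    Stimuli that appear in no duel keep ``config.initial_score``.  Returns
    raw scores plus a min-max-normalized companion; downstream analyses use
    the raw scores.
    """
    ids = sorted(set(map(str, corpus_ids)))
    if not ids:
        raise ValueError("empty corpus")
    index = {sid: i for i, sid in enumerate(ids)}
    s = np.full(len(ids), float(config.initial_score))
    w = np.array([index[d.winner_id] for d in duels], dtype=np.intp)
    l = np.array([index[d.loser_id] for d in duels], dtype=np.intp)
    order = np.arange(len(duels))
    rng = np.random.default_rng(config.seed)
    alpha = config.learning_rate
    for _ in range(config.n_epochs):
        if config.shuffle:
            rng.shuffle(order)
        for i in order:
            wi, li = w[i], l[i]
            delta = alpha * (1.0 - 1.0 / (1.0 + np.exp(s[li] - s[wi])))
            s[wi] += delta
            s[li] -= delta
    norm = _normalize(s)
    return ScoreTable(
        concept=concept,
        group=group,
        scores={sid: float(s[i]) for sid, i in index.items()},
        scores_normalized={sid: float(norm[i]) for sid, i in index.items()},
        config=config,
        n_duels=len(duels),
    )


def score_count_baseline(
    duels: Sequence[Duel],
    corpus_ids: Iterable[str],
    concept: str = "",
    group: str = "",
) -> ScoreTable:
    """Classical best-worst count score: (wins - losses) / duels played."""
    ids = sorted(set(map(str, corpus_ids)))
    wins = {sid: 0 for sid in ids}
    losses = {sid: 0 for sid in ids}
    for d in duels:
        wins[d.winner_id] += 1
        losses[d.loser_id] += 1
    raw = {
        sid: (wins[sid] - losses[sid]) / max(1, wins[sid] + losses[sid]) for sid in ids
    }
    arr = np.array([raw[sid] for sid in ids])
    norm = _normalize(arr)
    return ScoreTable(
        concept=concept,
        group=group,
        scores=raw,
        scores_normalized={sid: float(v) for sid, v in zip(ids, norm)},
        config=None,
        n_duels=len(duels),
    )


def rank_of(table: ScoreTable) -> dict[str, int]:
    """Dense ranks (1 = highest score); tied scores share a rank."""
    distinct = sorted(set(table.scores.values()), reverse=True)
    rank_by_score = {v: r for r, v in enumerate(distinct, start=1)}
    return {sid: rank_by_score[v] for sid, v in sorted(table.scores.items())}
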
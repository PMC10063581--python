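"""Randomized best-worst-scaling trial plans with a pair-uniqueness constraint.

Each participant evaluates the whole corpus once per concept, in trials of
``k`` sounds.  Within a configurable scope (one participant, one
group-and-concept, or everything pooled) no unordered pair of stimuli may
co-occur in more than one non-retest trial — repeating a pair would waste a
comparison the tournament scorer could have spent elsewhere.  A fraction of
trials is duplicated later in the sequence as retest trials to measure
intra-participant consistency; retests are exempt from the constraint since
they repeat pairs by design.

The constraint is satisfied by randomized greedy construction with
backtracking: trials are filled one stimulus at a time, always seeding a
trial with the unused stimulus that has the fewest remaining compatible
partners, and the whole build restarts with a fresh sub-seed after a bounded
number of dead ends.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import derive_seed

CONCEPTS = ("brightness", "warmth", "roundness", "roughness")
SCOPES = ("per_participant", "per_group_concept", "global")

#: study defaults: 4-sound trials, 13 retests per 130-trial plan
DEFAULT_K = 4
DEFAULT_N_RETEST = 13


@dataclass(frozen=True)
class Trial:
    trial_index: int
    concept: str
    stimulus_ids: tuple[str, ...]
    is_retest: bool = False
    source_trial_index: int | None = None

    def __post_init__(self):
        if len(set(self.stimulus_ids)) != len(self.stimulus_ids):
            raise ValueError("trial stimulus ids must be distinct")
        if self.is_retest != (self.source_trial_index is not None):
            raise ValueError("source_trial_index is set iff is_retest")

    def pairs(self) -> set[frozenset]:
        return {frozenset(p) for p in itertools.combinations(self.stimulus_ids, 2)}


@dataclass
class DesignPlan:
    participant_id: str
    concept: str
    trials: list[Trial]
    seed: int

    @property
    def non_retest_trials(self) -> list[Trial]:
        return [t for t in self.trials if not t.is_retest]

    @property
    def retest_trials(self) -> list[Trial]:
        return [t for t in self.trials if t.is_retest]


class DesignInfeasibleError(RuntimeError):
    """Raised when no pair-unique plan could be found within the search budget."""

    def __init__(self, message: str, remaining_pairs: int):
        super().__init__(f"{message} (remaining pair budget: {remaining_pairs})")
        self.remaining_pairs = remaining_pairs


# ---------------------------------------------------------------------------
# Greedy backtracking construction
# ---------------------------------------------------------------------------


def _build_partition(
    ids: list[str],
    k: int,
    used_pairs: set[frozenset],
    rng: np.random.Generator,
    node_budget: int = 50_000,
) -> list[tuple[str, ...]] | None:
    """Partition ``ids`` into trials of size k (last may be smaller, >= 2)
    avoiding ``used_pairs``; returns None if the node budget is exhausted."""
    remaining = set(ids)
    trials: list[list[str]] = []
    added_pairs: list[list[frozenset]] = []
    nodes = 0
    # number of used pairs touching each id: cheap most-constrained proxy
    load: dict[str, int] = {x: 0 for x in ids}
    for p in used_pairs:
        for x in p:
            if x in load:
                load[x] += 1

    def compatible(cand: str, members: list[str]) -> bool:
        return all(frozenset((cand, m)) not in used_pairs for m in members)

    def extend() -> bool:
        nonlocal nodes
        if not remaining:
            return True
        nodes += 1
        if nodes > node_budget:
            return False
        size = k if len(remaining) >= k else len(remaining)
        if size < 2:
            return False
        # most-constrained seed first
        seed_stim = max(remaining, key=lambda x: (load[x], x))
        members = [seed_stim]
        remaining.discard(seed_stim)
        trials.append(members)
        added_pairs.append([])
        ok = fill(size)
        if ok:
            return True
        trials.pop()
        added_pairs.pop()
        remaining.add(seed_stim)
        return False

    def fill(size: int) -> bool:
        nonlocal nodes
        members = trials[-1]
        if len(members) == size:
            return extend()
        nodes += 1
        if nodes > node_budget:
            return False
        # sort before the seeded shuffle: set iteration order depends on the
        # interpreter's hash seed and would break cross-process determinism
        cands = sorted(x for x in remaining if compatible(x, members))
        rng.shuffle(cands)
        for cand in cands:
            new_pairs = [frozenset((cand, m)) for m in members]
            members.append(cand)
            remaining.discard(cand)
            used_pairs.update(new_pairs)
            added_pairs[-1].extend(new_pairs)
            for p in new_pairs:
                for x in p:
                    load[x] += 1
            if fill(size):
                return True
            members.pop()
            remaining.add(cand)
            for p in new_pairs:
                used_pairs.discard(p)
                added_pairs[-1].remove(p)
                for x in p:
                    load[x] -= 1
            if nodes > node_budget:
                return False
        return False

    if extend():
        return [tuple(t) for t in trials]
    # roll back any pairs left registered by partial construction
    for plist in added_pairs:
        for p in plist:
            used_pairs.discard(p)
    return None


def build_design(
    stimulus_ids: Iterable[str],
    k: int = DEFAULT_K,
    participants: Sequence[str] = ("p0",),
    n_retest: int = 0,
    uniqueness_scope: str = "per_group_concept",
    seed: int = 0,
    concept: str = "brightness",
    max_restarts: int = 200,
) -> dict[str, DesignPlan]:
    """Build one pair-unique plan per participant.

    Every plan partitions the corpus into ceil(N/k) non-retest trials (a
    final short trial of size N mod k, at least 2, is permitted), shuffled
    in order and within trials.  Under ``per_group_concept`` or ``global``
    scope the pair constraint is shared across all participants of this
    call; under ``per_participant`` each plan only avoids its own repeats.
    """
    ids = sorted(set(map(str, stimulus_ids)))
    n = len(ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError("need at least k stimuli")
    if n % k == 1:
        raise ValueError("N mod k == 1 leaves a final trial of size 1")
    if uniqueness_scope not in SCOPES:
        raise ValueError(f"unknown scope {uniqueness_scope!r}")

    n_trials = -(-n // k)
    trial_sizes = [k] * (n // k) + ([n % k] if n % k else [])
    pairs_per_plan = sum(c * (c - 1) // 2 for c in trial_sizes)
    total_pairs = n * (n - 1) // 2
    shared = uniqueness_scope in ("per_group_concept", "global")
    needed = pairs_per_plan * (len(participants) if shared else 1)
    if needed > total_pairs:
        raise DesignInfeasibleError(
            f"{needed} distinct pairs required but only {total_pairs} exist",
            total_pairs - needed,
        )

    for attempt in range(max_restarts):
        rng = np.random.default_rng(derive_seed(seed, "design", attempt))
        used_pairs: set[frozenset] = set()
        plans: dict[str, DesignPlan] = {}
        ok = True
        for pid in participants:
            scope_pairs = used_pairs if shared else set()
            partition = _build_partition(list(ids), k, scope_pairs, rng)
            if partition is None:
                ok = False
                break
            rng.shuffle(partition)
            trials = [
                Trial(i, concept, tuple(t)) for i, t in enumerate(partition)
            ]
            plan = DesignPlan(str(pid), concept, trials, seed=derive_seed(seed, "plan", str(pid)))
            if n_retest:
                plan = insert_retests(plan, n_retest, seed=derive_seed(seed, "retest", str(pid)))
            plans[str(pid)] = plan
        if ok:
            return plans
    raise DesignInfeasibleError(
        f"no pair-unique design found after {max_restarts} restarts",
        total_pairs - needed,
    )


def insert_retests(plan: DesignPlan, n_retest: int, seed: int = 0) -> DesignPlan:
    """Duplicate ``n_retest`` randomly chosen trials into the second half.

    Each retest re-presents its source trial's stimuli in a fresh within-
    trial order, at a random position that is both in the second half of the
    sequence and after the source trial.
    """
    base = plan.non_retest_trials
    if n_retest > len(base):
        raise ValueError(f"n_retest={n_retest} exceeds {len(base)} source trials")
    if n_retest == 0:
        return plan
    rng = np.random.default_rng(seed)
    sources = rng.choice(len(base), size=n_retest, replace=False)
    sequence: list[Trial] = list(base)
    half = len(base) // 2
    for src in sorted(sources):
        src_pos = next(
            i for i, t in enumerate(sequence) if not t.is_retest and t.trial_index == src
        )
        lo = max(half, src_pos + 1)
        pos = int(rng.integers(lo, len(sequence) + 1))
        ids = list(base[src].stimulus_ids)
        rng.shuffle(ids)
        sequence.insert(
            pos,
            Trial(-1, plan.concept, tuple(ids), is_retest=True, source_trial_index=src),
        )
    renumbered = []
    for i, t in enumerate(sequence):
        if t.is_retest:
            renumbered.append(replace(t, trial_index=i))
        else:
            renumbered.append(replace(t, trial_index=i) if t.trial_index != i else t)
    # keep source_trial_index pointing at the source's *final* index
    old_to_new = {
        t_old.trial_index: t_new.trial_index
        for t_old, t_new in zip(sequence, renumbered)
        if not t_old.is_retest
    }
    final = [
        replace(t, source_trial_index=old_to_new[t.source_trial_index])
        if t.is_retest
        else t
        for t in renumbered
    ]
    return DesignPlan(plan.participant_id, plan.concept, final, plan.seed)


# ---------------------------------------------------------------------------
# Verification and I/O
# ---------------------------------------------------------------------------


@dataclass
class PairUniquenessReport:
    ok: bool
    violations: list[tuple[frozenset, list[tuple[str, int]]]]


def verify_pair_uniqueness(
    plans: Iterable[DesignPlan], scope: str = "per_group_concept"
) -> PairUniquenessReport:
    """Exhaustively count pair co-occurrences over non-retest trials."""
    if scope not in SCOPES:
        raise ValueError(f"unknown scope {scope!r}")
    buckets: dict[str, list[DesignPlan]] = {}
    for plan in plans:
        key = plan.participant_id if scope == "per_participant" else "all"
        buckets.setdefault(key, []).append(plan)
    violations = []
    for bucket in buckets.values():
        seen: dict[frozenset, list[tuple[str, int]]] = {}
        for plan in bucket:
            for t in plan.non_retest_trials:
                for p in t.pairs():
                    seen.setdefault(p, []).append((plan.participant_id, t.trial_index))
        violations.extend((p, locs) for p, locs in seen.items() if len(locs) > 1)
    return PairUniquenessReport(ok=not violations, violations=violations)


def plans_to_frame(plans: Iterable[DesignPlan]) -> pd.DataFrame:
    rows = []
    for plan in plans:
        for t in plan.trials:
            row = {
                "participant_id": plan.participant_id,
                "concept": plan.concept,
                "trial_index": t.trial_index,
                "is_retest": t.is_retest,
                "source_trial_index": t.source_trial_index,
            }
            for j, sid in enumerate(t.stimulus_ids, start=1):
                row[f"id_{j}"] = sid
            rows.append(row)
    return pd.DataFrame(rows)


def plans_from_frame(df: pd.DataFrame) -> list[DesignPlan]:
    id_cols = sorted(c for c in df.columns if c.startswith("id_"))
    plans = []
    for (pid, concept), grp in df.groupby(["participant_id", "concept"], sort=True):
        trials = []
        for _, row in grp.sort_values("trial_index").iterrows():
            ids = tuple(row[c] for c in id_cols if pd.notna(row[c]))
            src = row["source_trial_index"]
            trials.append(
                Trial(
                    int(row["trial_index"]),
                    concept,
                    ids,
                    bool(row["is_retest"]),
                    None if pd.isna(src) else int(src),
                )
            )
        plans.append(DesignPlan(str(pid), concept, trials, seed=0))
    return plans
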
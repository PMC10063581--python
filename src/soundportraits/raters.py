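"""Simulated raters whose best/worst choices follow latent concept utilities.

A rater carries, per concept, a weight vector over named latent stimulus
attributes (ground-truth synthesis parameters such as the spectral slope or
noise level, plus a derived spectral-centroid proxy).  On each trial the
rater perceives a noisy utility u_i = w . z_i + Normal(0, noise_sd) for each
presented stimulus — a Thurstonian choice model — and picks the arg-max as
best and the arg-min as worst.  Groups are populations of raters drawn
around a shared mean weight vector with Gaussian dispersion; a uniformly
random responder is also provided as the null rater.

Noise draws are deterministic per (rater seed, concept, trial index), so a
judgment does not depend on the order in which trials are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import CorpusManifest, StimulusSpec, note_to_freq, derive_seed
from .design import DesignPlan, Trial


@dataclass
class LatentRater:
    rater_id: str
    group: str
    concept_weights: dict[str, dict[str, float]]
    noise_sd: float
    seed: int

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class JudgmentRecord:
    participant_id: str
    concept: str
    trial_index: int
    best_id: str
    worst_id: str
    group: str = ""
    is_retest: bool = False
    source_trial_index: int | None = None

    def __post_init__(self):
        if self.best_id == self.worst_id:
            raise ValueError("best and worst must differ")


@dataclass
class GroupConfig:
    """Population-level description of one participant group."""

    name: str
    n_raters: int
    concept_weights_mean: dict[str, dict[str, float]]
    weight_dispersion: float = 0.0
    noise_sd: float = 0.0


# ---------------------------------------------------------------------------
# Latent attribute table
# ---------------------------------------------------------------------------


def attribute_table(manifest: CorpusManifest) -> pd.DataFrame:
    """Ground-truth latent attributes per stimulus, indexed by id (raw units).

    ``centroid_proxy`` is the energy-weighted mean frequency of the
    generating harmonic series (log2 Hz) — a closed-form stand-in for the
    measured spectral centroid.
    """
    rows = []
    for e in manifest.entries:
        f0 = note_to_freq(e.note)
        k = np.arange(1, max(e.n_harmonics, 1) + 1)
        a = 10.0 ** (e.spectral_slope_db_per_oct * np.log2(k) / 20.0)
        centroid = float(np.sum(k * f0 * a**2) / np.sum(a**2))
        rows.append(
            {
                "stimulus_id": e.stimulus_id,
                "log2_f0": float(np.log2(f0)),
                "centroid_proxy": float(np.log2(centroid)),
                "spectral_slope": e.spectral_slope_db_per_oct,
                "noise_level": e.noise_level,
                "am_depth": e.am_depth,
                "log10_attack": float(np.log10(e.attack_s)),
                "duration_s": e.duration_s,
            }
        )
    return pd.DataFrame(rows).set_index("stimulus_id")


def zscore_attributes(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score each attribute over the corpus (constant columns become 0)."""
    sd = table.std(ddof=0).replace(0.0, 1.0)
    return (table - table.mean()) / sd


# ---------------------------------------------------------------------------
# Judging
# ---------------------------------------------------------------------------


def utility(rater: LatentRater, concept: str, attributes: Mapping[str, float]) -> float:
    """Deterministic utility: dot product of concept weights and attributes."""
    weights = rater.concept_weights.get(concept)
    if weights is None:
        raise KeyError(f"rater has no weights for concept {concept!r}")
    try:
        return float(sum(w * attributes[name] for name, w in weights.items()))
    except KeyError as err:
        raise KeyError(f"attribute missing from table: {err}") from None


def judge_trial(
    rater: LatentRater,
    concept: str,
    trial: Trial,
    attribute_table: pd.DataFrame,
) -> JudgmentRecord:
    """One noisy best/worst judgment (deterministic per rater/concept/trial).

    Ties in the noisy utilities are broken toward the lexicographically
    lowest stimulus id; with k >= 2 best and worst are always distinct.
    """
    ids = trial.stimulus_ids
    if len(ids) < 2:
        raise ValueError("trial must present at least 2 stimuli")
    rng = np.random.default_rng(derive_seed(rater.seed, concept, trial.trial_index, trial.is_retest))
    noise = rng.normal(0.0, rater.noise_sd, size=len(ids)) if rater.noise_sd > 0 else np.zeros(len(ids))
    u = {
        sid: utility(rater, concept, attribute_table.loc[sid]) + eps
        for sid, eps in zip(ids, noise)
    }
    best = min(ids, key=lambda s: (-u[s], s))
    worst = min((s for s in ids if s != best), key=lambda s: (u[s], s))
    return JudgmentRecord(
        rater.rater_id, concept, trial.trial_index, best, worst,
        group=rater.group, is_retest=trial.is_retest,
        source_trial_index=trial.source_trial_index,
    )


def random_rater_judgment(trial: Trial, seed: int) -> JudgmentRecord:
    """Null responder: best uniform over k, worst uniform over the rest."""
    ids = trial.stimulus_ids
    if len(ids) < 2:
        raise ValueError("trial must present at least 2 stimuli")
    rng = np.random.default_rng(seed)
    best = ids[rng.integers(len(ids))]
    rest = [s for s in ids if s != best]
    worst = rest[rng.integers(len(rest))]
    return JudgmentRecord(
        "random", trial.concept, trial.trial_index, best, worst,
        is_retest=trial.is_retest, source_trial_index=trial.source_trial_index,
    )


# ---------------------------------------------------------------------------
# Groups
# ---------------------------------------------------------------------------


def draw_raters(config: GroupConfig, seed: int) -> list[LatentRater]:
    """Draw the group's raters: weights = group mean + Gaussian dispersion."""
    rng = np.random.default_rng(derive_seed(seed, "raters", config.name))
    raters = []
    for i in range(config.n_raters):
        weights = {
            concept: {
                name: float(mean + config.weight_dispersion * rng.standard_normal())
                for name, mean in wmean.items()
            }
            for concept, wmean in config.concept_weights_mean.items()
        }
        raters.append(
            LatentRater(
                rater_id=f"{config.name}_r{i}",
                group=config.name,
                concept_weights=weights,
                noise_sd=config.noise_sd,
                seed=derive_seed(seed, "rater-stream", config.name, i),
            )
        )
    return raters


def simulate_group(
    config: GroupConfig,
    plans_by_concept: Mapping[str, Mapping[str, DesignPlan]],
    attribute_table: pd.DataFrame,
    seed: int = 0,
) -> tuple[list[JudgmentRecord], list[LatentRater]]:
    """Judge every trial of every plan with freshly drawn group raters.

    ``plans_by_concept[concept][rater_id]`` must hold one plan per rater per
    concept; rater ids are ``{group}_r{i}``.
    """
    raters = draw_raters(config, seed)
    judgments: list[JudgmentRecord] = []
    for concept, plans in plans_by_concept.items():
        for rater in raters:
            plan = plans.get(rater.rater_id)
            if plan is None:
                raise ValueError(f"no plan for rater {rater.rater_id!r}, concept {concept!r}")
            for trial in plan.trials:
                judgments.append(judge_trial(rater, concept, trial, attribute_table))
    return judgments, raters


def judgments_to_frame(judgments: Iterable[JudgmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant_id": j.participant_id,
                "group": j.group,
                "concept": j.concept,
                "trial_index": j.trial_index,
                "is_retest": j.is_retest,
                "source_trial_index": j.source_trial_index,
                "best_id": j.best_id,
                "worst_id": j.worst_id,
            }
            for j in judgments
        ]
    )
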
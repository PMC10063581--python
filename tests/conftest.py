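"""Shared fixtures: tiny synthetic corpora and tone builders."""

from __future__ import annotations

import numpy as np
import pytest

from soundportraits import corpus as corp
from soundportraits import design as dsg
from soundportraits import raters as rat
from soundportraits import scoring as sco
from soundportraits.corpus import derive_seed


def make_tone(
    freq: float = 1000.0,
    fs: int = 16_000,
    duration_s: float = 1.0,
    amplitude: float = 0.5,
    am: tuple[float, float] | None = None,
    extra_freq: float | None = None,
) -> corp.SoundStimulus:
    """A bare sine (optionally AM-modulated / two-component) test stimulus."""
    t = np.arange(int(fs * duration_s)) / fs
    x = np.sin(2 * np.pi * freq * t)
    if extra_freq is not None:
        x = x + np.sin(2 * np.pi * extra_freq * t)
    if am is not None:
        rate, depth = am
        x = x * (1 + depth * np.sin(2 * np.pi * rate * t)) / (1 + depth)
    x = amplitude * x / np.max(np.abs(x))
    spec = corp.StimulusSpec(
        stimulus_id="tone", family="strings", technique="ordinario", note="C4",
        dynamics="mf", duration_s=duration_s, n_harmonics=1,
        spectral_slope_db_per_oct=0.0, noise_level=0.0, am_rate_hz=0.0,
        am_depth=0.0, attack_s=0.01, seed=0,
    )
    return corp.SoundStimulus("tone", fs, x, spec)


@pytest.fixture(scope="session")
def tone():
    return make_tone()


@pytest.fixture(scope="session")
def noise_stimulus():
    rng = np.random.default_rng(0)
    x = 0.1 * rng.standard_normal(16_000)
    return corp.SoundStimulus("noise", 16_000, x, make_tone().spec)


@pytest.fixture(scope="session")
def small_manifest():
    """A 20-stimulus manifest spanning several families."""
    return corp.make_manifest(
        {"strings": 6, "woodwinds": 5, "brass": 4, "keyboards": 3, "harp": 2},
        seed=11,
        duration_range=(0.5, 1.5),
    )


@pytest.fixture(scope="session")
def small_corpus(small_manifest):
    stims = corp.generate_corpus(small_manifest, sample_rate_hz=16_000)
    return corp.normalize_loudness(stims, -23.0)


def simulate_shared_weight_cell(
    seed: int,
    n_stimuli: int = 100,
    n_raters: int = 8,
    noise_fraction: float = 0.0,
    k: int = 4,
    scope: str = "per_group_concept",
    weights: dict[str, float] | None = None,
):
    """One group-by-concept cell: corpus, plans, judgments, duels.

    All raters share one latent weight vector; judgment noise is the given
    fraction of the utility SD over the corpus.  Returns (ids, utilities,
    duels, plans, judgments).
    """
    total = 520
    base = {"strings": 140, "woodwinds": 172, "brass": 102, "keyboards": 67,
            "harp": 16, "guitar": 9, "accordion": 14}
    counts = {f: max(1, round(n_stimuli * c / total)) for f, c in base.items()}
    counts = {f: c for f, c in counts.items() if c > 0}
    # absorb the rounding remainder into the largest family for an exact size
    counts["woodwinds"] = counts.get("woodwinds", 0) + n_stimuli - sum(counts.values())
    if counts["woodwinds"] <= 0:
        counts = {"strings": max(n_stimuli // 2, 1), "woodwinds": max(n_stimuli - n_stimuli // 2, 1)}
    manifest = corp.make_manifest(counts, seed=derive_seed(seed, "cell-manifest"))
    ids = [e.stimulus_id for e in manifest.entries]
    attr_z = rat.zscore_attributes(rat.attribute_table(manifest))
    weights = dict(weights or {"centroid_proxy": 1.0})
    u = sum(attr_z[a] * v for a, v in weights.items())
    noise_sd = noise_fraction * float(np.std(u))
    rater_ids = [f"r{i}" for i in range(n_raters)]
    plans = dsg.build_design(
        ids, k=k, participants=rater_ids, uniqueness_scope=scope,
        seed=derive_seed(seed, "cell-design"), concept="brightness",
    )
    judgments = []
    for i, rid in enumerate(rater_ids):
        rater = rat.LatentRater(
            rid, "group", {"brightness": weights}, noise_sd,
            derive_seed(seed, "cell-rater", i),
        )
        for trial in plans[rid].trials:
            judgments.append(rat.judge_trial(rater, "brightness", trial, attr_z))
    lookup = {pid: {t.trial_index: t for t in p.trials} for pid, p in plans.items()}
    duels = sco.duels_from_judgments(judgments, lookup)
    return ids, u, duels, plans, judgments
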
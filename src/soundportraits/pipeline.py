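"""End-to-end simulated annotation study.

One :class:`StudyConfig` drives the whole chain: synthesize and loudness-
equalize a corpus, build pair-unique best-worst trial plans per rater and
concept, simulate the rater groups' judgments, deduce duels and compute
Rescorla-Wagner score tables, measure compliance and retest consistency,
extract the acoustic feature matrix, fit cross-validated gradient-boosted
models with Shapley portraits, and correlate concept score tables.  Every
stage seeds its randomness from the master seed and a stage label, so any
stage can be re-run in isolation and two runs of the same config produce
byte-identical tabular outputs.

The default configuration is a desk-scale version of a three-population
listening study: three groups of eight raters judging four metaphorical
sound concepts (brightness, warmth, roundness, roughness) over a
100-stimulus corpus in trials of four.  The groups share qualitatively
sensible concept weights (e.g. brightness loads on spectral centroid for
engineers but on pitch and noise for non-experts) and differ in judgment
noise, which makes group-level consistency differences emerge downstream.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import consistency as cons
from . import corpus as corp
from . import design as dsg
from . import features as feat
from . import portraits as port
from . import raters as rat
from . import relations as rel
from . import scoring as sco
from .corpus import derive_seed

logger = logging.getLogger("soundportraits")

CONCEPTS = dsg.CONCEPTS

#: ~520-corpus family proportions scaled to 100 stimuli
SCALED_FAMILY_COUNTS = {
    "strings": 27, "woodwinds": 33, "brass": 20, "keyboards": 13,
    "harp": 3, "guitar": 2, "accordion": 2,
}

#: latent concept weights per group; qualitative presets for demonstration
#: (engineer brightness ~ spectral centroid; non-expert brightness ~ high
#: pitch and low noise), not estimates fitted to any real population
GROUP_WEIGHT_PRESETS: dict[str, dict[str, dict[str, float]]] = {
    "engineers": {
        "brightness": {"centroid_proxy": 1.0},
        "warmth": {"log2_f0": -0.8, "centroid_proxy": -0.6, "noise_level": -0.3},
        "roundness": {"centroid_proxy": -1.0, "noise_level": -0.5},
        "roughness": {"noise_level": 1.0, "am_depth": 0.6, "centroid_proxy": 0.2},
    },
    "conductors": {
        "brightness": {"centroid_proxy": 0.7, "log2_f0": 0.4, "log10_attack": -0.3},
        "warmth": {"log2_f0": -0.9, "centroid_proxy": -0.4, "noise_level": -0.4},
        "roundness": {"centroid_proxy": -0.9, "noise_level": -0.6},
        "roughness": {"noise_level": 1.0, "am_depth": 0.7},
    },
    "nonexperts": {
        "brightness": {"log2_f0": 0.9, "noise_level": -0.5},
        "warmth": {"log2_f0": -1.0, "centroid_proxy": -0.2},
        "roundness": {"centroid_proxy": -0.8, "noise_level": -0.4},
        "roughness": {"noise_level": 1.0, "am_depth": 0.5},
    },
}

#: judgment noise per group, as a fraction of the group's utility SD;
#: ordered so engineers are the most consistent population
GROUP_NOISE_FRACTIONS = {"engineers": 0.3, "conductors": 0.5, "nonexperts": 0.8}


@dataclass
class StudyConfig:
    family_counts: dict[str, int] = field(default_factory=lambda: dict(SCALED_FAMILY_COUNTS))
    concepts: tuple[str, ...] = CONCEPTS
    k: int = 4
    n_raters: int = 8
    n_retest: int | None = None  # default: scaled 10% of trials
    group_weights: dict[str, dict[str, dict[str, float]]] = field(
        default_factory=lambda: {g: {c: dict(w) for c, w in ws.items()} for g, ws in GROUP_WEIGHT_PRESETS.items()}
    )
    group_noise_fractions: dict[str, float] = field(
        default_factory=lambda: dict(GROUP_NOISE_FRACTIONS)
    )
    weight_dispersion: float = 0.15
    sample_rate_hz: int = 16_000
    duration_range: tuple[float, float] = (0.5, 3.0)
    target_lufs: float = -23.0
    rw: sco.RWConfig = field(default_factory=sco.RWConfig)
    frame: feat.FrameConfig = field(default_factory=feat.FrameConfig)
    model_params: dict = field(default_factory=lambda: dict(port.DEFAULT_MODEL_PARAMS))
    n_folds: int = 5
    prune_r_threshold: float = 0.9
    top_k: int = 5
    master_seed: int = 0
    write_audio: bool = False

    def resolved(self) -> dict:
        d = asdict(self)
        d["rw"] = asdict(self.rw)
        d["frame"] = asdict(self.frame)
        return d

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyConfig":
        d = json.loads(Path(path).read_text())
        if "rw" in d:
            d["rw"] = sco.RWConfig(**d["rw"])
        if "frame" in d:
            d["frame"] = feat.FrameConfig(**d["frame"])
        if "concepts" in d:
            d["concepts"] = tuple(d["concepts"])
        if "duration_range" in d:
            d["duration_range"] = tuple(d["duration_range"])
        return cls(**d)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and artifacts so far."""

    def __init__(self, stage: str, cause: Exception, artifacts: dict):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.artifacts = dict(artifacts)


@dataclass
class StudyResult:
    config: StudyConfig
    summary: dict
    paths: dict[str, str]
    score_tables: dict[tuple[str, str], sco.ScoreTable]
    compliance: pd.DataFrame
    retest: pd.DataFrame
    feature_matrix: feat.FeatureMatrix
    regressions: dict[tuple[str, str], port.RegressionReport]
    correlations: dict[str, rel.ConceptCorrelations]


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _group_configs(config: StudyConfig, attr_z: pd.DataFrame) -> list[rat.GroupConfig]:
    """Translate noise fractions into absolute utility-noise SDs per group.

    The reference scale is the SD over the corpus of the group's mean-weight
    utility, averaged over concepts, so "0.5 x utility SD" means the same
    thing regardless of how many attributes a concept loads on.
    """
    groups = []
    for name, weights in config.group_weights.items():
        sds = []
        for concept in config.concepts:
            w = weights[concept]
            u = sum(attr_z[a] * v for a, v in w.items())
            sds.append(float(np.std(u)))
        noise_sd = config.group_noise_fractions[name] * float(np.mean(sds))
        groups.append(
            rat.GroupConfig(
                name=name,
                n_raters=config.n_raters,
                concept_weights_mean={c: dict(weights[c]) for c in config.concepts},
                weight_dispersion=config.weight_dispersion,
                noise_sd=noise_sd,
            )
        )
    return groups


def run_study(config: StudyConfig, out_dir: str | Path | None = None) -> StudyResult:
    """Execute every stage of the simulated study; see the module docstring."""
    artifacts: dict[str, str] = {}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def fail(stage: str, err: Exception):
        raise StageError(stage, err, artifacts) from err

    # --- corpus ------------------------------------------------------------
    try:
        manifest = corp.make_manifest(
            config.family_counts,
            seed=derive_seed(config.master_seed, "manifest"),
            duration_range=config.duration_range,
            target_loudness_lufs=config.target_lufs,
        )
        stimuli = corp.generate_corpus(manifest, sample_rate_hz=config.sample_rate_hz)
        stimuli = corp.normalize_loudness(stimuli, config.target_lufs)
        meta = manifest.metadata_frame()
        if out is not None:
            paths = corp.export_corpus(stimuli, manifest, out, write_audio=config.write_audio)
            artifacts.update({k: str(v) for k, v in paths.items()})
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001 - re-raised with stage context
        fail("corpus", e)

    # --- latent attributes and groups --------------------------------------
    attr_raw = rat.attribute_table(manifest)
    attr_z = rat.zscore_attributes(attr_raw)
    groups = _group_configs(config, attr_z)
    n_trials = -(-len(manifest.entries) // config.k)
    n_retest = config.n_retest if config.n_retest is not None else max(1, round(0.1 * n_trials))

    # --- designs and judgments ---------------------------------------------
    try:
        all_plans: dict[str, dict[str, dict[str, dsg.DesignPlan]]] = {}
        judgments: list[rat.JudgmentRecord] = []
        raters_by_group: dict[str, list[rat.LatentRater]] = {}
        ids = [e.stimulus_id for e in manifest.entries]
        for g in groups:
            rater_ids = [f"{g.name}_r{i}" for i in range(g.n_raters)]
            plans_by_concept = {}
            for concept in config.concepts:
                plans = dsg.build_design(
                    ids, k=config.k, participants=rater_ids, n_retest=n_retest,
                    uniqueness_scope="per_group_concept",
                    seed=derive_seed(config.master_seed, "design", g.name, concept),
                    concept=concept,
                )
                plans_by_concept[concept] = plans
            all_plans[g.name] = plans_by_concept
            gj, graters = rat.simulate_group(
                g, plans_by_concept, attr_z,
                seed=derive_seed(config.master_seed, "group", g.name),
            )
            judgments.extend(gj)
            raters_by_group[g.name] = graters
        jdf = rat.judgments_to_frame(judgments)
        if out is not None:
            plans_flat = [p for g in all_plans.values() for c in g.values() for p in c.values()]
            dsg.plans_to_frame(plans_flat).to_csv(out / "plans.csv", index=False)
            jdf.to_csv(out / "judgments.csv", index=False)
            artifacts["plans"] = str(out / "plans.csv")
            artifacts["judgments"] = str(out / "judgments.csv")
    except StageError:
        raise
    except Exception as e:
        fail("judgments", e)

    # --- scoring ------------------------------------------------------------
    try:
        score_tables: dict[tuple[str, str], sco.ScoreTable] = {}
        for g in groups:
            for concept in config.concepts:
                trials_lookup = {
                    pid: {t.trial_index: t for t in plan.trials}
                    for pid, plan in all_plans[g.name][concept].items()
                }
                cell = [j for j in judgments if j.group == g.name and j.concept == concept]
                duels = sco.duels_from_judgments(cell, trials_lookup)
                rw_cfg = dataclasses.replace(
                    config.rw, seed=derive_seed(config.master_seed, "rw", g.name, concept)
                )
                table = sco.score_rescorla_wagner(duels, ids, rw_cfg, concept=concept, group=g.name)
                score_tables[(g.name, concept)] = table
                if out is not None:
                    p = out / f"scores_{g.name}_{concept}.csv"
                    table.to_csv(p)
                    artifacts[f"scores_{g.name}_{concept}"] = str(p)
    except StageError:
        raise
    except Exception as e:
        fail("scoring", e)

    # --- consistency ---------------------------------------------------------
    try:
        comp_records, retest_records = [], []
        for g in groups:
            for concept in config.concepts:
                table = score_tables[(g.name, concept)]
                for pid, plan in all_plans[g.name][concept].items():
                    pj = [j for j in judgments
                          if j.participant_id == pid and j.concept == concept]
                    trials = {t.trial_index: t for t in plan.trials}
                    comp_records.append(cons.compliance(pj, trials, table))
                    retest_records.append(cons.retest_record(pj, plan))
        comp_df = cons.compliance_frame(comp_records)
        retest_df = cons.retest_frame(retest_records)
        retest_df["group"] = retest_df["participant_id"].str.rsplit("_", n=1).str[0]
        tests = _consistency_tests(comp_df, retest_df, config)
        if out is not None:
            comp_df.to_csv(out / "compliance.csv", index=False)
            retest_df.to_csv(out / "retest.csv", index=False)
            artifacts["compliance"] = str(out / "compliance.csv")
            artifacts["retest"] = str(out / "retest.csv")
    except StageError:
        raise
    except Exception as e:
        fail("consistency", e)

    # --- features ------------------------------------------------------------
    try:
        fm = feat.build_feature_matrix(stimuli, meta, config.frame)
        fm = feat.prune_multicollinear(fm, config.prune_r_threshold)
        if out is not None:
            fm.to_csv(out / "features.csv")
            artifacts["features"] = str(out / "features.csv")
    except StageError:
        raise
    except Exception as e:
        fail("features", e)

    # --- portraits -----------------------------------------------------------
    try:
        regressions: dict[tuple[str, str], port.RegressionReport] = {}
        portraits_rows = []
        for (gname, concept), table in score_tables.items():
            rep = port.fit_cv_gbt(
                fm, table, n_folds=config.n_folds, params=config.model_params,
                seed=derive_seed(config.master_seed, "cv", gname, concept),
            )
            att = port.attributions(rep, fm)
            top = port.top_features(att, fm, k=config.top_k)
            regressions[(gname, concept)] = rep
            for rank, row in enumerate(top.itertuples(), start=1):
                portraits_rows.append(
                    {
                        "group": gname, "concept": concept, "rank": rank,
                        "feature": row.feature, "importance": row.importance,
                        "direction": row.direction, "mean_r2": rep.mean_r2,
                    }
                )
        portraits_df = pd.DataFrame(portraits_rows)
        if out is not None:
            portraits_df.to_csv(out / "portraits.csv", index=False)
            artifacts["portraits"] = str(out / "portraits.csv")
    except StageError:
        raise
    except Exception as e:
        fail("portraits", e)

    # --- relations -----------------------------------------------------------
    try:
        correlations = {
            g.name: rel.concept_correlations(
                {c: score_tables[(g.name, c)] for c in config.concepts}, group=g.name
            )
            for g in groups
        }
        steiger_rows = _steiger_battery(correlations, score_tables, config)
        compliance_by_cell = {
            (g, c): float(
                comp_df.loc[(comp_df.group == g) & (comp_df.concept == c), "compliance"].mean()
            )
            for g, c in score_tables
        }
        r2_by_cell = {gc: regressions[gc].mean_r2 for gc in score_tables}
        acc_r, acc_p, acc_n = rel.consistency_accuracy_correlation(compliance_by_cell, r2_by_cell)
    except StageError:
        raise
    except Exception as e:
        fail("relations", e)

    # --- summary -------------------------------------------------------------
    cells = {}
    for (gname, concept), table in score_tables.items():
        sel_c = comp_df[(comp_df.group == gname) & (comp_df.concept == concept)]
        sel_r = retest_df[(retest_df.group == gname) & (retest_df.concept == concept)]
        top = portraits_df[(portraits_df.group == gname) & (portraits_df.concept == concept)]
        cells[f"{gname}|{concept}"] = {
            "mean_compliance": round(float(sel_c.compliance.mean()), 6),
            "mean_retest": round(float(sel_r.agreement.mean()), 6),
            "mean_r2": round(regressions[(gname, concept)].mean_r2, 6),
            "top_features": list(top.feature),
        }
    summary = {
        "n_stimuli": len(manifest.entries),
        "n_trials_per_plan": n_trials,
        "n_retest_per_plan": n_retest,
        "cells": cells,
        "tests": tests,
        "correlations": {
            g: {f"{a}~{b}": round(r, 6) for (a, b), (r, _, _) in cc.pairs.items()}
            for g, cc in correlations.items()
        },
        "steiger": steiger_rows,
        "consistency_accuracy": {"r": round(acc_r, 6), "p": round(acc_p, 6), "n": acc_n},
    }
    if out is not None:
        (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        (out / "resolved_config.json").write_text(
            json.dumps(config.resolved(), indent=1, sort_keys=True)
        )
        artifacts["summary"] = str(out / "summary.json")
        artifacts["resolved_config"] = str(out / "resolved_config.json")

    result = StudyResult(
        config=config, summary=summary, paths=artifacts,
        score_tables=score_tables, compliance=comp_df, retest=retest_df,
        feature_matrix=fm, regressions=regressions, correlations=correlations,
    )
    if out is not None:
        (out / "report.md").write_text(report(result))
        result.paths["report"] = str(out / "report.md")
    return result


def _consistency_tests(comp_df: pd.DataFrame, retest_df: pd.DataFrame, config: StudyConfig) -> dict:
    """The nonparametric battery over compliance and retest tables."""
    out: dict[str, dict] = {}
    by_group = [g["compliance"].to_numpy() for _, g in comp_df.groupby("group", sort=True)]
    by_concept = [g["compliance"].to_numpy() for _, g in comp_df.groupby("concept", sort=True)]
    out["compliance_by_group"] = vars(cons.kruskal_wallis(by_group))
    out["compliance_by_concept"] = vars(cons.kruskal_wallis(by_concept))
    rt = retest_df.dropna(subset=["agreement"])
    out["retest_by_group"] = vars(
        cons.kruskal_wallis([g["agreement"].to_numpy() for _, g in rt.groupby("group", sort=True)])
    )
    blocks = rt.pivot_table(index="participant_id", columns="concept", values="agreement")
    if not blocks.isna().any().any() and blocks.shape[1] >= 2:
        out["retest_by_concept_friedman"] = vars(cons.friedman(blocks))
    # post hoc pairwise group comparisons on compliance, Bonferroni-adjusted
    groups = sorted(comp_df.group.unique())
    pairs, ps = [], []
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            res = cons.mann_whitney_u(
                comp_df.loc[comp_df.group == a, "compliance"],
                comp_df.loc[comp_df.group == b, "compliance"],
            )
            pairs.append((f"{a}~{b}", res))
            ps.append(res.p_value)
    for (name, res), p_adj in zip(pairs, cons.bonferroni_adjust(ps)):
        d = vars(res)
        d["p_adjusted"] = p_adj
        d["adjusted"] = True
        out[f"compliance_posthoc_{name}"] = d
    return out


def _steiger_battery(
    correlations: Mapping[str, rel.ConceptCorrelations],
    score_tables: Mapping[tuple[str, str], sco.ScoreTable],
    config: StudyConfig,
) -> list[dict]:
    """Within-group dependent-correlation comparisons (shared-variable case).

    For every group, each pair of concept-pair correlations that shares a
    concept is compared with the overlapping-variant Steiger Z.
    """
    rows = []
    for gname, cc in correlations.items():
        n = len(next(iter(score_tables.values())).scores)
        pair_list = list(cc.pairs)
        for i, pa in enumerate(pair_list):
            for pb in pair_list[i + 1 :]:
                shared = set(pa) & set(pb)
                if len(shared) != 1:
                    continue
                s = shared.pop()
                a = next(x for x in pa if x != s)
                b = next(x for x in pb if x != s)
                r_sa = cc.pairs[tuple(sorted((s, a)))][0]
                r_sb = cc.pairs[tuple(sorted((s, b)))][0]
                r_ab = cc.pairs[tuple(sorted((a, b)))][0]
                res = rel.steiger_compare(r_sa, r_sb, {"r_bc": r_ab}, n, "overlapping")
                rows.append(
                    {
                        "group": gname, "shared": s, "a": a, "b": b,
                        "z": round(res.z, 4), "p": round(res.p, 6), "n": n,
                    }
                )
    return rows


# ---------------------------------------------------------------------------
# Null-rater calibration experiment
# ---------------------------------------------------------------------------


def random_responder_compliance(
    seed: int,
    n_stimuli: int = 100,
    k: int = 4,
    n_informative: int = 7,
    noise_fraction: float = 0.5,
    weights: Mapping[str, float] | None = None,
    rw: sco.RWConfig | None = None,
    include_self: bool = False,
) -> float:
    """Compliance of one uniformly random responder vs. an informative group.

    Simulates a corpus of ``n_stimuli``, ``n_informative`` raters sharing
    one latent weight vector (judgment noise = ``noise_fraction`` times the
    utility SD over the corpus) plus one random responder; computes group
    Rescorla-Wagner scores from the informative raters' duels and returns
    the random responder's compliance against them.  In expectation this is
    0.5: a random duel is equally likely to agree or disagree with any
    ordering that is independent of the responder.

    With ``include_self=True`` the responder's own duels also enter the
    score table.  Because the design presents each pair of stimuli only
    once, the responder's duel is then the only direct evidence on that
    pair and compliance is structurally inflated well above the 0.5 null
    (about 0.62 at this scale, for the count-based scorer as much as for
    the Rescorla-Wagner one); the null calibration therefore defaults to
    the independent reference.
    """
    total = sum(SCALED_FAMILY_COUNTS.values())
    counts = {f: max(1, round(n_stimuli * c / total)) for f, c in SCALED_FAMILY_COUNTS.items()}
    manifest = corp.make_manifest(counts, seed=derive_seed(seed, "null-manifest"))
    ids = [e.stimulus_id for e in manifest.entries]
    attr_z = rat.zscore_attributes(rat.attribute_table(manifest))
    weights = dict(weights or {"centroid_proxy": 1.0})
    concept = "brightness"
    u = sum(attr_z[a] * v for a, v in weights.items())
    noise_sd = noise_fraction * float(np.std(u))

    rater_ids = [f"r{i}" for i in range(n_informative)] + ["random"]
    plans = dsg.build_design(
        ids, k=k, participants=rater_ids, uniqueness_scope="per_group_concept",
        seed=derive_seed(seed, "null-design"), concept=concept,
    )
    judgments: list[rat.JudgmentRecord] = []
    for i in range(n_informative):
        rater = rat.LatentRater(
            rater_id=f"r{i}", group="informative",
            concept_weights={concept: weights}, noise_sd=noise_sd,
            seed=derive_seed(seed, "null-rater", i),
        )
        for trial in plans[f"r{i}"].trials:
            judgments.append(rat.judge_trial(rater, concept, trial, attr_z))
    random_judgments = [
        rat.random_rater_judgment(trial, derive_seed(seed, "null-random", trial.trial_index))
        for trial in plans["random"].trials
    ]
    if include_self:
        judgments.extend(random_judgments)

    trials_lookup = {pid: {t.trial_index: t for t in plan.trials} for pid, plan in plans.items()}
    duels = sco.duels_from_judgments(judgments, trials_lookup)
    rw_cfg = rw if rw is not None else dataclasses.replace(
        sco.RWConfig(), seed=derive_seed(seed, "null-rw")
    )
    table = sco.score_rescorla_wagner(duels, ids, rw_cfg, concept=concept, group="null")
    rec = cons.compliance(random_judgments, trials_lookup["random"], table)
    return rec.compliance


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------


def report(result: StudyResult) -> str:
    """Markdown summary: consistency tables, correlations, and portraits."""
    s = result.summary
    if not s["cells"]:
        raise ValueError("empty study summary")
    lines = ["# Simulated best-worst annotation study", ""]
    lines += [f"Corpus: {s['n_stimuli']} stimuli; "
              f"{s['n_trials_per_plan']} trials/plan (+{s['n_retest_per_plan']} retests)", ""]
    lines += ["## Consistency (mean compliance / mean retest agreement)", ""]
    lines += ["| group | concept | compliance | retest | CV R2 |", "|---|---|---|---|---|"]
    for key in sorted(s["cells"]):
        g, c = key.split("|")
        cell = s["cells"][key]
        lines.append(
            f"| {g} | {c} | {cell['mean_compliance']:.3f} | "
            f"{cell['mean_retest']:.3f} | {cell['mean_r2']:.3f} |"
        )
    lines += ["", "## Concept score correlations", ""]
    for g, pairs in sorted(s["correlations"].items()):
        lines.append(f"**{g}**: " + ", ".join(f"r({k}) = {v:.2f}" for k, v in sorted(pairs.items())))
    lines += ["", "## Acoustic portraits (top features)", ""]
    for key in sorted(s["cells"]):
        g, c = key.split("|")
        feats = ", ".join(s["cells"][key]["top_features"])
        lines.append(f"- **{g} / {c}**: {feats}")
    lines += [
        "",
        f"Consistency-accuracy coupling: r = {s['consistency_accuracy']['r']:.2f} "
        f"(p = {s['consistency_accuracy']['p']:.3g}, n = {s['consistency_accuracy']['n']})",
        "",
    ]
    return "\n".join(lines)
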
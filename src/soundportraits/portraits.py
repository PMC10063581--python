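"""Cross-validated gradient-boosted regression of scores on acoustic features,
explained with exact tree Shapley attributions ("acoustic portraits").

For each concept and rater group, BWS scores are predicted from the feature
matrix with gradient-boosted regression trees in a shuffled k-fold scheme
(default fivefold); accuracy is the coefficient of determination R^2 on each
held-out fold.  Every stimulus is then attributed exactly once, on the fold
where it was held out, using exact tree-path Shapley values, which satisfy
local accuracy: the base value plus a row's contributions reconstructs the
model's prediction for that stimulus.  A portrait is the ranked list of
features by global importance (mean absolute contribution), each tagged with
a direction: the sign of the correlation between feature value and
contribution, a scalar rendering of the usual SHAP summary-plot hue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold

from .features import FeatureMatrix
from .scoring import ScoreTable

#: default tree-ensemble hyperparameters (modest capacity for ~500 rows)
DEFAULT_MODEL_PARAMS = {
    "n_estimators": 300,
    "max_depth": 4,
    "learning_rate": 0.05,
    "subsample": 0.8,
}


@dataclass
class RegressionReport:
    concept: str
    group: str
    fold_r2: list[float]
    mean_r2: float
    fold_assignments: dict[str, int]
    model_params: dict
    seed: int
    models: list[xgb.XGBRegressor] = field(repr=False, default_factory=list)
    feature_names: list[str] = field(default_factory=list)
    stimulus_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "concept": self.concept,
            "group": self.group,
            "fold_r2": self.fold_r2,
            "mean_r2": self.mean_r2,
            "fold_assignments": self.fold_assignments,
            "model_params": self.model_params,
            "seed": self.seed,
        }


@dataclass
class AttributionReport:
    per_sound: pd.DataFrame  # stimuli x features, signed contributions
    base_value: list[float]  # per fold
    importance: pd.Series  # mean |contribution| per feature, descending
    predictions: pd.Series
    fold_of: pd.Series

    def local_accuracy_error(self) -> float:
        """max over stimuli of |prediction - (base + sum of contributions)|."""
        base = self.fold_of.map(lambda f: self.base_value[f])
        recon = base + self.per_sound.sum(axis=1)
        return float(np.abs(self.predictions - recon).max())


def _align(features: FeatureMatrix, scores: ScoreTable) -> tuple[pd.DataFrame, pd.Series]:
    x = features.data
    y = pd.Series(scores.scores)
    if set(x.index) != set(y.index):
        raise ValueError("feature matrix and score table cover different stimuli")
    y = y.loc[x.index]
    return x, y


def fit_cv_gbt(
    features: FeatureMatrix,
    scores: ScoreTable,
    n_folds: int = 5,
    params: Mapping | None = None,
    seed: int = 0,
) -> RegressionReport:
    """Shuffled k-fold gradient-boosted regression; R^2 per held-out fold."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    x, y = _align(features, scores)
    params = dict(DEFAULT_MODEL_PARAMS, **(params or {}))
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_r2: list[float] = []
    fold_assignments: dict[str, int] = {}
    models: list[xgb.XGBRegressor] = []
    xv = x.to_numpy(dtype=np.float32)
    yv = y.to_numpy(dtype=np.float64)
    for fold, (train, test) in enumerate(kf.split(xv)):
        model = xgb.XGBRegressor(
            **params, random_state=seed, n_jobs=1, tree_method="hist", verbosity=0
        )
        model.fit(xv[train], yv[train])
        pred = model.predict(xv[test])
        fold_r2.append(float(r2_score(yv[test], pred)))
        models.append(model)
        for i in test:
            fold_assignments[x.index[i]] = fold
    return RegressionReport(
        concept=scores.concept,
        group=scores.group,
        fold_r2=fold_r2,
        mean_r2=float(np.mean(fold_r2)),
        fold_assignments=fold_assignments,
        model_params=params,
        seed=seed,
        models=models,
        feature_names=list(x.columns),
        stimulus_ids=list(x.index),
    )


# ---------------------------------------------------------------------------
# Exact path-dependent tree Shapley values (float64)
#
# xgboost's built-in pred_contribs implements the same algorithm but returns
# float32, whose rounding can exceed the 1e-6 local-accuracy budget on
# hundreds of trees; this implementation walks the dumped trees in float64
# so that base + sum(contributions) reconstructs the traversal prediction to
# machine precision.  The two implementations cross-check each other in the
# test suite.
# ---------------------------------------------------------------------------


class _Tree:
    __slots__ = ("feat", "thresh", "left", "right", "value", "cover", "is_leaf")

    def __init__(self, node_dict: dict, n_nodes: int):
        self.feat = [0] * n_nodes
        self.thresh = [0.0] * n_nodes
        self.left = [0] * n_nodes
        self.right = [0] * n_nodes
        self.value = [0.0] * n_nodes
        self.cover = [0.0] * n_nodes
        self.is_leaf = [False] * n_nodes
        self._fill(node_dict)

    def _fill(self, nd: dict):
        i = nd["nodeid"]
        self.cover[i] = float(nd["cover"])
        if "leaf" in nd:
            self.is_leaf[i] = True
            self.value[i] = float(nd["leaf"])
            return
        name = nd["split"]
        self.feat[i] = int(name[1:]) if name.startswith("f") and name[1:].isdigit() else name
        # dumped thresholds are float32 printed at 9 digits; re-round so
        # comparisons agree bit-for-bit with the booster's own
        self.thresh[i] = float(np.float32(nd["split_condition"]))
        self.left[i] = nd["yes"]
        self.right[i] = nd["no"]
        for child in nd["children"]:
            self._fill(child)

    def expected_value(self) -> float:
        return sum(
            v * c for v, c, leaf in zip(self.value, self.cover, self.is_leaf) if leaf
        ) / self.cover[0]

    def predict_one(self, x) -> float:
        i = 0
        while not self.is_leaf[i]:
            i = self.left[i] if x[self.feat[i]] < self.thresh[i] else self.right[i]
        return self.value[i]


def _parse_trees(booster: xgb.Booster) -> tuple[list[_Tree], float]:
    import json as _json

    trees = []
    for dump in booster.get_dump(with_stats=True, dump_format="json"):
        nd = _json.loads(dump)

        def count(d):
            return 1 + sum(count(c) for c in d.get("children", []))

        trees.append(_Tree(nd, count(nd)))
    cfg = _json.loads(booster.save_config())
    base_score = float(cfg["learner"]["learner_model_param"]["base_score"])
    return trees, base_score


def _tree_shap_single(tree: _Tree, x, phi: np.ndarray) -> None:
    """Lundberg-style path-dependent Shapley contributions of one tree."""

    def extend(m, pz, po, pi):
        l = len(m)
        m = [row[:] for row in m]
        m.append([pi, pz, po, 1.0 if l == 0 else 0.0])
        for i in range(l - 1, -1, -1):
            m[i + 1][3] += po * m[i][3] * (i + 1) / (l + 1)
            m[i][3] = pz * m[i][3] * (l - i) / (l + 1)
        return m

    def unwind(m, i):
        l = len(m) - 1
        zi, oi = m[i][1], m[i][2]
        n = m[l][3]
        out = [row[:] for row in m[:l]]
        for j in range(l - 1, -1, -1):
            if oi != 0:
                t = out[j][3]
                out[j][3] = n * (l + 1) / ((j + 1) * oi)
                n = t - out[j][3] * zi * (l - j) / (l + 1)
            else:
                out[j][3] = out[j][3] * (l + 1) / (zi * (l - j))
        for j in range(i, l):
            out[j][0], out[j][1], out[j][2] = m[j + 1][0], m[j + 1][1], m[j + 1][2]
        return out

    def unwound_sum(m, i):
        l = len(m) - 1
        zi, oi = m[i][1], m[i][2]
        total = 0.0
        if oi != 0:
            n = m[l][3]
            for j in range(l - 1, -1, -1):
                t = n * (l + 1) / ((j + 1) * oi)
                total += t
                n = m[j][3] - t * zi * (l - j) / (l + 1)
        else:
            for j in range(l - 1, -1, -1):
                total += m[j][3] * (l + 1) / (zi * (l - j))
        return total

    def recurse(node, m, pz, po, pi):
        m = extend(m, pz, po, pi)
        if tree.is_leaf[node]:
            v = tree.value[node]
            for i in range(1, len(m)):
                w = unwound_sum(m, i)
                phi[m[i][0]] += w * (m[i][2] - m[i][1]) * v
            return
        f = tree.feat[node]
        hot = tree.left[node] if x[f] < tree.thresh[node] else tree.right[node]
        cold = tree.right[node] if hot == tree.left[node] else tree.left[node]
        iz = io = 1.0
        k = next((idx for idx in range(1, len(m)) if m[idx][0] == f), None)
        if k is not None:
            iz, io = m[k][1], m[k][2]
            m = unwind(m, k)
        rj = tree.cover[node]
        recurse(hot, m, iz * tree.cover[hot] / rj, io, f)
        recurse(cold, m, iz * tree.cover[cold] / rj, 0.0, f)

    recurse(0, [], 1.0, 1.0, -1)


def shap_contributions(model: xgb.XGBRegressor, x: np.ndarray) -> tuple[np.ndarray, float]:
    """(contributions matrix rows x features, base value) in float64."""
    trees, base_score = _parse_trees(model.get_booster())
    base = base_score + sum(t.expected_value() for t in trees)
    # round through float32 so threshold comparisons match the booster's own
    x = np.asarray(x, dtype=np.float32).astype(np.float64)
    phi = np.zeros((len(x), x.shape[1]), dtype=np.float64)
    for r, row in enumerate(x):
        for t in trees:
            _tree_shap_single(t, row, phi[r])
    return phi, base


def shap_predict(model: xgb.XGBRegressor, x: np.ndarray) -> np.ndarray:
    """Float64 traversal prediction consistent with shap_contributions."""
    trees, base_score = _parse_trees(model.get_booster())
    x = np.asarray(x, dtype=np.float32).astype(np.float64)
    out = np.full(len(x), base_score, dtype=np.float64)
    for r, row in enumerate(x):
        out[r] += sum(t.predict_one(row) for t in trees)
    return out


def attributions(report: RegressionReport, features: FeatureMatrix) -> AttributionReport:
    """Exact tree Shapley contributions, computed on each stimulus's test fold."""
    if not report.models:
        raise ValueError("report does not retain fitted fold models")
    x = features.data
    if list(x.columns) != report.feature_names:
        raise ValueError("feature columns differ from the fitted ones")
    contrib = pd.DataFrame(
        np.nan, index=x.index, columns=report.feature_names, dtype=float
    )
    preds = pd.Series(np.nan, index=x.index, dtype=float)
    fold_of = pd.Series(report.fold_assignments).loc[x.index]
    base: list[float] = []
    for fold, model in enumerate(report.models):
        ids = fold_of.index[fold_of == fold]
        xv = x.loc[ids].to_numpy(dtype=np.float64)
        phi, b = shap_contributions(model, xv)
        contrib.loc[ids, :] = phi
        base.append(b)
        preds.loc[ids] = shap_predict(model, xv)
    importance = contrib.abs().mean(axis=0).sort_values(ascending=False)
    return AttributionReport(
        per_sound=contrib,
        base_value=base,
        importance=importance,
        predictions=preds,
        fold_of=fold_of,
    )


def top_features(
    attr: AttributionReport,
    features: FeatureMatrix,
    k: int = 5,
) -> pd.DataFrame:
    """Top-k features by importance with a direction summary.

    ``direction`` is the sign of the Pearson correlation between a feature's
    values and its contributions (+1: high values push scores up; -1: down;
    0: no consistent direction or constant feature).
    """
    if k > len(attr.importance):
        raise ValueError("k exceeds the number of features")
    rows = []
    for name in attr.importance.index[:k]:
        vals = features.data[name].astype(float)
        phi = attr.per_sound[name]
        if vals.std() == 0 or phi.std() == 0:
            direction = 0
        else:
            direction = int(np.sign(np.corrcoef(vals, phi)[0, 1]))
        rows.append(
            {
                "feature": name,
                "importance": float(attr.importance[name]),
                "direction": direction,
            }
        )
    return pd.DataFrame(rows)
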
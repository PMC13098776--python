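"""Multi-horizon risk-score ensemble.

One classifier is trained per prediction horizon (1, 2, 4, 6, 8 and 12
hours before the event) on snapshots taken that far ahead of confirmed
deterioration events plus shared control snapshots; the deployed risk
index is the arithmetic mean of the six member probabilities.

Hyperparameters are chosen by mean held-out AUROC over stratified,
patient-grouped cross-validation folds (one patient never spans train and
held-out folds).  Parsimonious variants keep only the top-k features per
horizon ranked by a plug-in mutual-information estimate against the
label.
"""

from __future__ import annotations

import base64
import hashlib
import itertools
import json
import pickle
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .cohort import HORIZONS

LEARNER_FAMILIES = ("xgboost", "random_forest", "lasso_logistic")

#: Small default grid (depth, learning rate, trees, min child weight);
#: expand via LearnerSpec.grid for a serious search.
DEFAULT_XGB_GRID = {
    "max_depth": [3, 5],
    "learning_rate": [0.1],
    "n_estimators": [150],
    "min_child_weight": [1, 5],
}
DEFAULT_RF_GRID = {"n_estimators": [300], "max_depth": [None, 8]}
DEFAULT_LASSO_GRID = {"C": [0.1, 1.0]}


@dataclass(frozen=True)
class LearnerSpec:
    """Learner family, hyperparameter grid and CV layout."""

    family: str = "xgboost"
    grid: dict | None = None
    cv_folds: int = 10
    group_by: str = "patient"  # or "admission"

    def resolved_grid(self) -> dict:
        if self.grid is not None:
            return self.grid
        return {"xgboost": DEFAULT_XGB_GRID,
                "random_forest": DEFAULT_RF_GRID,
                "lasso_logistic": DEFAULT_LASSO_GRID}[self.family]


def make_learner(family: str, params: dict, seed: int):
    """Instantiate a classifier of the given family with ``params``.

    Tree learners consume NaN natively (XGBoost) or behind a median
    imputer (random forest); the L1 logistic model is imputed and
    standardized.
    """
    if family == "xgboost":
        from xgboost import XGBClassifier
        return XGBClassifier(random_state=seed, n_jobs=1,
                             eval_metric="logloss", **params)
    if family == "random_forest":
        rf = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
        return Pipeline([("impute", SimpleImputer(strategy="median")),
                         ("model", rf)])
    if family == "lasso_logistic":
        lr = LogisticRegression(l1_ratio=1.0, solver="liblinear",
                                random_state=seed, max_iter=2000, **params)
        return Pipeline([("impute", SimpleImputer(strategy="median")),
                         ("scale", StandardScaler()),
                         ("model", lr)])
    raise ValueError(f"unknown learner family {family!r}; "
                     f"choose from {LEARNER_FAMILIES}")


@dataclass
class HorizonModel:
    """A fitted classifier for one prediction horizon."""

    horizon: int
    model: object
    family: str
    params: dict
    feature_names: list[str]
    cv_scores: list[float] = field(default_factory=list)
    feature_subset: list[str] | None = None

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"feature matrix has {X.shape[1]} columns, model schema "
                f"has {len(self.feature_names)}")
        if self.feature_subset is not None:
            cols = [self.feature_names.index(f) for f in self.feature_subset]
            X = X[:, cols]
        return np.clip(self.model.predict_proba(X)[:, 1], 0.0, 1.0)


def _grid_combinations(grid: dict):
    keys = sorted(grid)
    for combo in itertools.product(*(grid[k] for k in keys)):
        yield dict(zip(keys, combo))


def train_horizon(X: np.ndarray, y: np.ndarray, groups: np.ndarray,
                  horizon: int, spec: LearnerSpec, seed: int,
                  feature_names: list[str],
                  feature_subset: list[str] | None = None) -> HorizonModel:
    """Fit one horizon model with grouped, stratified CV model selection.

    The grid point with the best mean held-out AUROC wins (ties broken by
    grid order); the winner is refit on all data.  Deterministic given
    ``seed``.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("horizon training requires both classes present")
    groups = np.asarray(groups)
    X_full = X
    if feature_subset is not None:
        cols = [feature_names.index(f) for f in feature_subset]
        X = X[:, cols]

    n_groups = len(np.unique(groups))
    folds = spec.cv_folds
    if n_groups < folds:
        warnings.warn(f"only {n_groups} groups; reducing CV folds "
                      f"from {folds} to {n_groups}")
        folds = max(2, n_groups)
    cv = StratifiedGroupKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(cv.split(X, y, groups))

    best = None
    for params in _grid_combinations(spec.resolved_grid()):
        scores = []
        for tr, te in splits:
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
                continue
            m = make_learner(spec.family, params, seed)
            m.fit(X[tr], y[tr])
            scores.append(roc_auc_score(y[te], m.predict_proba(X[te])[:, 1]))
        mean_score = float(np.mean(scores)) if scores else -np.inf
        if best is None or mean_score > best[0]:
            best = (mean_score, params, scores)

    _, params, scores = best
    final = make_learner(spec.family, params, seed)
    final.fit(X, y)
    return HorizonModel(horizon=horizon, model=final, family=spec.family,
                        params=params, feature_names=list(feature_names),
                        cv_scores=[float(s) for s in scores],
                        feature_subset=(list(feature_subset)
                                        if feature_subset else None))


@dataclass
class EnsembleModel:
    """Mean-aggregated collection of horizon models."""

    members: list[HorizonModel]

    @property
    def horizons(self) -> list[int]:
        return [m.horizon for m in self.members]

    @property
    def feature_names(self) -> list[str]:
        return self.members[0].feature_names

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Risk index: arithmetic mean of the member probabilities."""
        probs = np.stack([m.predict_proba(np.asarray(X, dtype=float))
                          for m in self.members])
        return probs.mean(axis=0)

    def schema_hash(self) -> str:
        payload = json.dumps([self.feature_names, sorted(self.horizons)])
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_json(self) -> str:
        """Portable JSON envelope with pickled learner blobs."""
        members = []
        for m in self.members:
            members.append({
                "horizon": m.horizon, "family": m.family, "params": m.params,
                "cv_scores": m.cv_scores, "feature_subset": m.feature_subset,
                "blob": base64.b64encode(pickle.dumps(m.model)).decode(),
            })
        return json.dumps({"format": "cdewatch-ensemble/1",
                           "schema_hash": self.schema_hash(),
                           "feature_names": self.feature_names,
                           "members": members})

    @classmethod
    def from_json(cls, text: str) -> "EnsembleModel":
        doc = json.loads(text)
        if doc.get("format") != "cdewatch-ensemble/1":
            raise ValueError("not a cdewatch ensemble envelope")
        members = [HorizonModel(
            horizon=m["horizon"], family=m["family"], params=m["params"],
            feature_names=doc["feature_names"], cv_scores=m["cv_scores"],
            feature_subset=m["feature_subset"],
            model=pickle.loads(base64.b64decode(m["blob"])),
        ) for m in doc["members"]]
        out = cls(members=members)
        if out.schema_hash() != doc["schema_hash"]:
            raise ValueError("ensemble schema hash mismatch")
        return out


def horizon_training_sets(samples: pd.DataFrame, X: np.ndarray,
                          y: np.ndarray, horizons=HORIZONS):
    """Per-horizon row masks: controls are shared, positives horizon-specific."""
    h = samples["horizon"]
    control = h.isna().to_numpy(dtype=bool)
    for horizon in horizons:
        mask = control | (h == horizon).fillna(False).to_numpy(dtype=bool)
        yield horizon, mask


def train_ensemble(samples: pd.DataFrame, X: np.ndarray, y: np.ndarray,
                   groups: np.ndarray, spec: LearnerSpec, seed: int,
                   feature_names: list[str], horizons=HORIZONS,
                   feature_subsets: dict | None = None) -> EnsembleModel:
    """Train all horizon members on their snapshot subsets."""
    members = []
    for horizon, mask in horizon_training_sets(samples, X, y, horizons):
        subset = feature_subsets.get(horizon) if feature_subsets else None
        members.append(train_horizon(
            X[mask], y[mask], groups[mask], horizon, spec,
            seed + horizon, feature_names, feature_subset=subset))
    return EnsembleModel(members=members)


# --- mutual information ranking -------------------------------------------

def mutual_information(x: np.ndarray, y: np.ndarray, bins: int = 10) -> float:
    """Plug-in mutual information in bits between one feature and the label.

    Continuous features are discretized into ``bins`` equal-frequency bins
    (NaN forms its own bin, so informative missingness counts as signal).
    Maximum-likelihood cell frequencies; adequate for ranking.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    finite = np.isfinite(x)
    codes = np.full(len(x), -1)
    if finite.any():
        edges = np.unique(np.quantile(x[finite],
                                      np.linspace(0, 1, bins + 1)[1:-1]))
        codes[finite] = np.searchsorted(edges, x[finite], side="right")
    joint = pd.crosstab(codes, y).to_numpy().astype(float)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px @ py))
    return float(np.nansum(terms))


def rank_features_mi(X: np.ndarray, y: np.ndarray, names: list[str],
                     bins: int = 10) -> list[str]:
    """Feature names in decreasing MI order (stable for ties)."""
    mi = np.array([mutual_information(X[:, j], y, bins)
                   for j in range(X.shape[1])])
    order = np.argsort(-mi, kind="stable")
    return [names[j] for j in order]


def select_parsimonious(samples: pd.DataFrame, X: np.ndarray, y: np.ndarray,
                        names: list[str], k: int, horizons=HORIZONS,
                        bins: int = 10) -> tuple[list[str], dict]:
    """Union over horizons of each horizon's top-k MI-ranked features.

    Returns the sorted union and the per-horizon top-k lists; restricting
    the ensemble to these subsets yields the parsimonious model.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(names):
        warnings.warn(f"k={k} exceeds feature count {len(names)}; using all")
        k = len(names)
    per_horizon = {}
    for horizon, mask in horizon_training_sets(samples, X, y, horizons):
        ranked = rank_features_mi(X[mask], y[mask], names, bins)
        per_horizon[horizon] = ranked[:k]
    union = sorted(set().union(*per_horizon.values()))
    return union, per_horizon
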
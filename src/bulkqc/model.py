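"""Random-forest sample-quality classifier and its interpretation.

A bagged ensemble of classification trees is trained on the 18 pipeline
QC metrics against binary high/low quality labels (one model per
labeling stringency).  Out-of-bag (OOB) votes give every training
sample an unbiased quality score in [0, 1] — the fraction of trees that
did not see the sample during training and vote "high quality" — whose
AUC against the labels estimates performance on unseen data.  Variable
importance is reported three ways: Gini impurity decrease, the fraction
of trees that use the variable, and the average absolute ALE effect.
A shallow single decision tree distills the forest into an auditable
set of thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .ale import ale_effect_1d, ale_effect_2d

__all__ = [
    "QualityModel",
    "train_quality_forest",
    "oob_auc",
    "rank_auc",
    "single_metric_logistic_auc",
    "importance_report",
    "predict_quality",
    "fit_simplified_tree",
    "save_model",
    "load_model",
]

FORMAT_VERSION = 1


@dataclass
class QualityModel:
    """A trained quality forest plus the metadata needed to reuse it."""

    forest: RandomForestClassifier
    feature_names: list[str]
    stringency: str
    seed: int
    oob_scores: pd.Series  # per training sample, fraction of OOB trees voting high
    train_labels: pd.Series  # "high"/"low" per training sample
    imputation_medians: pd.Series = field(default=None)


def _impute(features: pd.DataFrame, medians: pd.Series | None = None):
    """Median imputation fitted on training data and reused at prediction."""
    if medians is None:
        medians = features.median()
    return features.fillna(medians), medians


def train_quality_forest(
    features: pd.DataFrame,
    labels: pd.Series,
    n_trees: int = 500,
    seed: int = 0,
    max_features: int | str = 4,
    stringency: str = "base",
) -> QualityModel:
    """Train the quality forest with OOB scoring.

    ``features`` is samples x metrics (conventionally the 18 pipeline
    metrics); ``labels`` holds "high"/"low" per sample.  Missing feature
    values are median-imputed; the medians are stored for prediction.
    Deterministic given ``seed``.
    """
    labels = labels.reindex(features.index)
    classes = set(labels.dropna().unique())
    if len(classes) < 2:
        raise ValueError(f"need both quality classes in labels, got {sorted(classes)}")
    X, medians = _impute(features)
    y = (labels == "high").astype(int)
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max_features,
        oob_score=True,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X.to_numpy(), y.to_numpy())
    # column for class 1 ("high") of the OOB-averaged vote
    high_col = list(forest.classes_).index(1)
    oob = pd.Series(forest.oob_decision_function_[:, high_col], index=features.index,
                    name="oob_quality_score")
    return QualityModel(forest, list(features.columns), stringency, seed, oob, labels,
                        medians)


def rank_auc(scores, positives) -> float:
    """AUC by the Mann-Whitney rank statistic.

    ``positives`` is a boolean array marking the positive class; ties in
    scores contribute 1/2, matching pairwise concordance counting.
    """
    s = np.asarray(scores, dtype=float)
    pos = np.asarray(positives, dtype=bool)
    n1, n0 = pos.sum(), (~pos).sum()
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined with a single class")
    ranks = rankdata(s)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def oob_auc(model: QualityModel, labels: pd.Series | None = None) -> float:
    """AUC of the OOB quality score against the high/low labels."""
    labels = model.train_labels if labels is None else labels.reindex(model.oob_scores.index)
    return rank_auc(model.oob_scores.to_numpy(), (labels == "high").to_numpy())


def single_metric_logistic_auc(
    metric_values: pd.Series,
    labels: pd.Series,
    k_folds: int = 5,
    seed: int = 0,
) -> float:
    """Cross-validated AUC of a one-metric logistic baseline.

    Stratified k-fold; held-out predicted probabilities are pooled and
    scored with a single AUC.  Deterministic given ``seed``.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    x = metric_values.to_numpy(dtype=float).reshape(-1, 1)
    y = (labels.reindex(metric_values.index) == "high").to_numpy().astype(int)
    if len(set(y)) < 2:
        raise ValueError("both classes required")
    # standardize for solver stability; AUC is scale-invariant
    mu, sd = x.mean(), x.std()
    xs = (x - mu) / (sd if sd > 0 else 1.0)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    pooled = np.empty(len(y))
    for train_idx, test_idx in skf.split(xs, y):
        if len(set(y[train_idx])) < 2:  # pragma: no cover - stratification prevents this
            raise ValueError("training fold with a single class")
        clf = LogisticRegression(max_iter=1000)
        clf.fit(xs[train_idx], y[train_idx])
        pooled[test_idx] = clf.predict_proba(xs[test_idx])[:, list(clf.classes_).index(1)]
    return rank_auc(pooled, y == 1)


def _selection_frequency(forest: RandomForestClassifier, n_features: int) -> np.ndarray:
    """Fraction of trees in which each feature appears in at least one split."""
    used = np.zeros(n_features)
    for est in forest.estimators_:
        feats = est.tree_.feature
        present = np.unique(feats[feats >= 0])
        used[present] += 1
    return used / len(forest.estimators_)


def importance_report(
    model: QualityModel,
    features: pd.DataFrame,
    n_intervals: int = 40,
    normalize: bool = False,
) -> pd.DataFrame:
    """Gini, selection-frequency and ALE importance for every feature.

    With ``normalize`` each column is min-max scaled to [0, 1] for
    display; raw values otherwise.
    """
    X, _ = _impute(features, model.imputation_medians)
    gini = pd.Series(model.forest.feature_importances_, index=model.feature_names)
    sel = pd.Series(_selection_frequency(model.forest, len(model.feature_names)),
                    index=model.feature_names)
    predict = _proba_fn(model)
    ale_imp = pd.Series(
        {v: ale_effect_1d(predict, X, v, n_intervals).importance
         for v in model.feature_names}
    )
    rep = pd.DataFrame(
        {"gini_importance": gini, "selection_frequency": sel, "ale_importance": ale_imp}
    )
    if normalize:
        rep = (rep - rep.min()) / (rep.max() - rep.min()).replace(0, 1)
    rep.index.name = "metric"
    return rep


def _proba_fn(model: QualityModel):
    high_col = list(model.forest.classes_).index(1)

    def predict(X: pd.DataFrame):
        return model.forest.predict_proba(X[model.feature_names].to_numpy())[:, high_col]

    return predict


def ale_1d(model: QualityModel, features: pd.DataFrame, variable: str, n_intervals: int = 40):
    """First-order ALE of the model quality score for one metric."""
    X, _ = _impute(features, model.imputation_medians)
    return ale_effect_1d(_proba_fn(model), X, variable, n_intervals)


def ale_2d(model: QualityModel, features: pd.DataFrame, pair: tuple[str, str],
           n_intervals: int = 10):
    """Second-order ALE (interaction) of the quality score for a pair."""
    X, _ = _impute(features, model.imputation_medians)
    return ale_effect_2d(_proba_fn(model), X, pair, n_intervals)


def predict_quality(model: QualityModel, external_features: pd.DataFrame) -> pd.Series:
    """Full-ensemble quality score in [0, 1] for external samples.

    External features must share the training metric schema; missing
    columns raise a feature-alignment error, missing values are imputed
    with the training medians.
    """
    missing = [c for c in model.feature_names if c not in external_features.columns]
    if missing:
        raise ValueError(f"external features missing columns {missing}")
    X, _ = _impute(external_features[model.feature_names], model.imputation_medians)
    return pd.Series(_proba_fn(model)(X), index=external_features.index,
                     name="quality_score")


def fit_simplified_tree(
    features: pd.DataFrame,
    labels: pd.Series,
    max_depth: int = 3,
    seed: int = 0,
    test_features: pd.DataFrame | None = None,
    test_labels: pd.Series | None = None,
):
    """A shallow CART tree distilling the forest into explicit thresholds.

    Returns ``(tree, report)`` where report holds train (and optional
    test) accuracy plus per-node class counts in a readable frame.
    """
    X, medians = _impute(features)
    y = (labels.reindex(features.index) == "high").astype(int).to_numpy()
    if len(set(y)) < 2:
        raise ValueError("both classes required")
    tree = DecisionTreeClassifier(max_depth=max_depth, criterion="gini", random_state=seed)
    tree.fit(X.to_numpy(), y)
    report = {"train_accuracy": float((tree.predict(X.to_numpy()) == y).mean())}
    if test_features is not None and test_labels is not None:
        Xt, _ = _impute(test_features[list(features.columns)], medians)
        yt = (test_labels.reindex(test_features.index) == "high").astype(int).to_numpy()
        report["test_accuracy"] = float((tree.predict(Xt.to_numpy()) == yt).mean())
    t = tree.tree_
    nodes = pd.DataFrame(
        {
            "feature": [features.columns[f] if f >= 0 else "leaf" for f in t.feature],
            "threshold": t.threshold,
            "n_low": t.value[:, 0, 0] * t.n_node_samples,
            "n_high": t.value[:, 0, 1] * t.n_node_samples,
        }
    )
    report["nodes"] = nodes
    return tree, report


def save_model(model: QualityModel, path) -> None:
    """Persist a quality model (versioned joblib archive)."""
    import joblib

    joblib.dump(
        {
            "format_version": FORMAT_VERSION,
            "forest": model.forest,
            "feature_names": model.feature_names,
            "stringency": model.stringency,
            "seed": model.seed,
            "oob_scores": model.oob_scores,
            "train_labels": model.train_labels,
            "imputation_medians": model.imputation_medians,
        },
        path,
    )


def load_model(path) -> QualityModel:
    import joblib

    blob = joblib.load(path)
    if blob.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"unsupported model archive version {blob.get('format_version')}")
    return QualityModel(
        blob["forest"], blob["feature_names"], blob["stringency"], blob["seed"],
        blob["oob_scores"], blob["train_labels"], blob["imputation_medians"],
    )
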
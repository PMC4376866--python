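"""The two random-forest classifiers.

* The **pair classifier** decides whether two small molecules are likely
  to bind the same target binding site; its probability becomes the
  weight of query-to-cluster edges.
* The **meta-classifier** combines a prediction's raw score, Global
  Z-score and Local Z-score (optionally plus the query compound's
  identity) into a single binder / non-binder call.  Two variants are
  trained: id-aware (known compounds) and anonymous (novel compounds).

Both are scikit-learn random forests with class-balanced weighting;
training and inference are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import precision_score, recall_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .model_io import Compound
from .similarity import PAIR_FEATURE_NAMES, ligand_pair_features

log = logging.getLogger(__name__)

DEFAULT_FOREST_PARAMS = {
    "n_estimators": 500,
    "max_features": "sqrt",
    "class_weight": "balanced",
}

#: inclusive probability threshold for a positive call
CLASSIFY_THRESHOLD = 0.5

#: modulus for the hashed compound-id feature of the id-aware model
ID_HASH_BUCKETS = 1024

META_FEATURES = ("score", "global_z", "local_z")


def _forest(params: dict | None, seed: int) -> RandomForestClassifier:
    kwargs = dict(DEFAULT_FOREST_PARAMS)
    if params:
        kwargs.update(params)
    return RandomForestClassifier(random_state=seed, **kwargs)


def hash_compound_id(compound_id: str, buckets: int = ID_HASH_BUCKETS) -> int:
    """Stable (process-independent) hash bucket for a compound identifier."""
    return zlib.crc32(str(compound_id).encode()) % buckets


# ---------------------------------------------------------------------------
# pair classifier


@dataclass
class PairModel:
    clf: RandomForestClassifier
    feature_names: tuple[str, ...] = PAIR_FEATURE_NAMES
    seed: int = 0
    cv_accuracy: float | None = None

    def predict_proba_pair(self, a: Compound, b: Compound) -> float:
        x = ligand_pair_features(a, b).reshape(1, -1)
        return float(self.clf.predict_proba(x)[0, 1])

    def __call__(self, a: Compound, b: Compound) -> float:
        return self.predict_proba_pair(a, b)


def train_pair_classifier(
    labeled_pairs: list[tuple[Compound, Compound, int]],
    params: dict | None = None,
    seed: int = 0,
    cv_folds: int = 5,
) -> PairModel:
    """Fit the compound-pair similarity classifier.

    ``labeled_pairs`` holds (compound, compound, label) with label 1 when
    the two molecules are expected to share a binding site.  A
    cross-validated accuracy is logged; training is deterministic given
    the seed.
    """
    X = np.array([ligand_pair_features(a, b) for a, b, _ in labeled_pairs])
    y = np.array([int(lbl) for _, _, lbl in labeled_pairs])
    if len(np.unique(y)) < 2:
        raise ValueError("pair-classifier training set has a single class")
    clf = _forest(params, seed)

    acc = None
    if cv_folds and cv_folds >= 2:
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        accs = []
        for tr, te in skf.split(X, y):
            m = _forest(params, seed)
            m.fit(X[tr], y[tr])
            accs.append(float((m.predict(X[te]) == y[te]).mean()))
        acc = float(np.mean(accs))
        log.info("pair classifier %d-fold CV accuracy: %.3f", cv_folds, acc)

    clf.fit(X, y)
    return PairModel(clf=clf, seed=seed, cv_accuracy=acc)


# ---------------------------------------------------------------------------
# meta-classifier


@dataclass
class CVReport:
    """Mean and standard deviation of the fold metrics of a 10-fold CV."""

    precision: tuple[float, float]
    recall: tuple[float, float]
    auc: tuple[float, float]
    n_folds: int

    def as_dict(self) -> dict:
        return {
            "precision_mean": self.precision[0], "precision_sd": self.precision[1],
            "recall_mean": self.recall[0], "recall_sd": self.recall[1],
            "auc_mean": self.auc[0], "auc_sd": self.auc[1],
            "n_folds": self.n_folds,
        }


@dataclass
class MetaModel:
    clf: RandomForestClassifier
    use_compound_id: bool
    seed: int = 0
    cv: CVReport | None = None
    feature_names: tuple[str, ...] = field(default_factory=tuple)


def _meta_matrix(df: pd.DataFrame, use_compound_id: bool) -> np.ndarray:
    cols = [df[c].to_numpy(float) for c in META_FEATURES]
    if use_compound_id:
        cols.append(
            df["query_id"].map(hash_compound_id).to_numpy(float)
        )
    return np.column_stack(cols)


def train_meta_classifier(
    labeled: pd.DataFrame,
    use_compound_id: bool = False,
    params: dict | None = None,
    seed: int = 0,
    cv_folds: int = 10,
) -> MetaModel:
    """Fit the binder / non-binder meta-classifier on labeled predictions.

    ``labeled`` needs columns ``score, global_z, local_z, label`` and,
    when ``use_compound_id`` is set, ``query_id`` (entered as a hashed
    categorical feature).  The model is evaluated by stratified 10-fold
    cross-validation; precision, recall and AUC are reported as mean and
    standard deviation across folds.
    """
    for col in META_FEATURES + ("label",):
        if col not in labeled.columns:
            raise ValueError(f"labeled predictions missing column {col!r}")
    if use_compound_id and "query_id" not in labeled.columns:
        raise ValueError("use_compound_id=True but no query_id column")
    y = labeled["label"].astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("meta-classifier training set has a single class")
    X = _meta_matrix(labeled, use_compound_id)

    cv = None
    if cv_folds and cv_folds >= 2:
        n_splits = min(cv_folds, int(np.bincount(y).min()))
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        precs, recs, aucs = [], [], []
        for tr, te in skf.split(X, y):
            m = _forest(params, seed)
            m.fit(X[tr], y[tr])
            prob = m.predict_proba(X[te])[:, 1]
            pred = (prob >= CLASSIFY_THRESHOLD).astype(int)
            precs.append(precision_score(y[te], pred, zero_division=0))
            recs.append(recall_score(y[te], pred, zero_division=0))
            aucs.append(roc_auc_score(y[te], prob)
                        if len(np.unique(y[te])) > 1 else np.nan)
        cv = CVReport(
            precision=(float(np.mean(precs)), float(np.std(precs))),
            recall=(float(np.mean(recs)), float(np.std(recs))),
            auc=(float(np.nanmean(aucs)), float(np.nanstd(aucs))),
            n_folds=n_splits,
        )
        log.info("meta-classifier (%s) CV: precision %.3f±%.3f recall %.3f±%.3f "
                 "AUC %.3f±%.3f",
                 "id-aware" if use_compound_id else "anonymous",
                 *cv.precision, *cv.recall, *cv.auc)

    clf = _forest(params, seed)
    clf.fit(X, y)
    names = META_FEATURES + (("query_id_hash",) if use_compound_id else ())
    return MetaModel(clf=clf, use_compound_id=use_compound_id, seed=seed,
                     cv=cv, feature_names=names)


def classify(
    model: MetaModel,
    rows: pd.DataFrame,
    threshold: float = CLASSIFY_THRESHOLD,
) -> pd.DataFrame:
    """Attach ``classifier_prob`` and ``classifier_label`` to prediction rows.

    The label is positive when the probability is >= ``threshold``
    (inclusive at the boundary).  Row order is preserved; an empty input
    yields an empty output.
    """
    out = rows.copy()
    if out.empty:
        out["classifier_prob"] = pd.Series(dtype=float)
        out["classifier_label"] = pd.Series(dtype=bool)
        return out
    for col in META_FEATURES:
        if col not in out.columns:
            raise ValueError(f"prediction rows missing feature column {col!r}")
    if model.use_compound_id and "query_id" not in out.columns:
        raise ValueError("id-aware model needs a query_id column")
    X = _meta_matrix(out, model.use_compound_id)
    prob = model.clf.predict_proba(X)[:, 1]
    out["classifier_prob"] = prob
    out["classifier_label"] = prob >= threshold
    return out


def single_score_cv_auc(
    labeled: pd.DataFrame,
    score_col: str,
    seed: int = 0,
    cv_folds: int = 10,
) -> tuple[float, float]:
    """Fold-mean AUC of ranking by one raw score, on the same stratified
    folds the meta-classifier is evaluated on (no training involved)."""
    y = labeled["label"].astype(int).to_numpy()
    s = labeled[score_col].to_numpy(float)
    n_splits = min(cv_folds, int(np.bincount(y).min()))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    aucs = [roc_auc_score(y[te], s[te])
            for _, te in skf.split(s.reshape(-1, 1), y)
            if len(np.unique(y[te])) > 1]
    return float(np.mean(aucs)), float(np.std(aucs))


def oof_probabilities(
    labeled: pd.DataFrame,
    use_compound_id: bool = False,
    params: dict | None = None,
    seed: int = 0,
    cv_folds: int = 10,
) -> np.ndarray:
    """Out-of-fold positive-class probabilities from a stratified K-fold.

    Every row is scored by a forest that never saw it during training, so
    thresholding these probabilities gives honest cross-validated calls.
    """
    y = labeled["label"].astype(int).to_numpy()
    X = _meta_matrix(labeled, use_compound_id)
    n_splits = min(cv_folds, int(np.bincount(y).min()))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    prob = np.zeros(len(y))
    for tr, te in skf.split(X, y):
        m = _forest(params, seed)
        m.fit(X[tr], y[tr])
        prob[te] = m.predict_proba(X[te])[:, 1]
    return prob


# ---------------------------------------------------------------------------
# persistence


def save_model(model: PairModel | MetaModel, path) -> None:
    """Persist a model as a joblib artifact with a JSON sidecar describing
    the feature schema, seed and forest parameters."""
    import joblib

    path = Path(path)
    joblib.dump(model, path)
    sidecar = {
        "format_version": 1,
        "model_type": type(model).__name__,
        "feature_names": list(model.feature_names),
        "seed": model.seed,
        "params": model.clf.get_params(),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True, default=str)
    )


def load_model(path):
    import joblib

    return joblib.load(path)
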
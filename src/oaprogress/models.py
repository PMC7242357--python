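"""Classifier strategies over the four progression classes.

Four interchangeable strategies share one fit/predict contract:

* ``single``     -- one cost-sensitive 4-class learner;
* ``one_vs_rest``-- four binary learners, one per class;
* ``multi_label``-- one learner assigning the P and S labels independently;
* ``duo``        -- two independent binary learners, one for the P label and
  one for the S label, whose joint vote maps to the four classes while
  exposing independent progression probabilities p(P) and p(S).

Cost sensitivity uses per-class weights inversely proportional to class
frequency (the "balanced" convention w_c = n/(k*n_c); for tree learners any
positive rescaling is equivalent).  The base learner is pluggable; standard
algorithms are exposed as named presets, with random forest the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .data import CLASSES
from .labeling import assign_label

STRATEGIES = ("single", "one_vs_rest", "multi_label", "duo")

BASE_LEARNERS = (
    "random_forest",
    "logistic_regression",
    "multinomial_logistic",
    "knn",
    "svc_linear",
    "svc_rbf",
)


@dataclass(frozen=True)
class ModelConfig:
    """Training configuration shared by all strategies.

    ``n_trees``/``max_depth``/``criterion`` apply to forest learners;
    ``class_weight_source`` decides whether cost weights come from the full
    dataset or the current training fold; ``duo_weight_basis`` picks whether
    duo sub-models weight by their own binary label distribution (default) or
    by the 4-class one.
    """

    strategy: str = "duo"
    n_trees: int = 100
    max_depth: int = 8
    criterion: str = "gini"
    class_weight_source: str = "full_dataset"
    base_learner: str = "random_forest"
    duo_weight_basis: str = "binary"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.base_learner not in BASE_LEARNERS:
            raise ValueError(f"unknown base learner {self.base_learner!r}")
        if self.n_trees < 1 or self.max_depth < 1:
            raise ValueError("n_trees and max_depth must be at least 1")
        if self.criterion not in ("gini", "entropy"):
            raise ValueError("criterion must be 'gini' or 'entropy'")

    @property
    def id(self) -> str:
        return (f"{self.strategy}-{self.base_learner}-t{self.n_trees}"
                f"-d{self.max_depth}-{self.criterion}")


def class_weights(labels, classes=None) -> dict:
    """Weights inversely proportional to class frequency.

    w_c = n_total / (n_classes * n_c) over the reference label set; balanced
    classes all get weight 1.  Raises if a requested class is absent.
    """
    labels = pd.Series(list(labels))
    counts = labels.value_counts()
    if classes is None:
        classes = list(counts.index)
    missing = [c for c in classes if c not in counts.index]
    if missing:
        raise ValueError(f"classes absent from the reference distribution: {missing}")
    n, k = len(labels), len(classes)
    return {c: n / (k * counts[c]) for c in classes}


def _base_estimator(config: ModelConfig, weights: dict | None, seed: int):
    name = config.base_learner
    if name == "random_forest":
        return RandomForestClassifier(
            n_estimators=config.n_trees, max_depth=config.max_depth,
            criterion=config.criterion, class_weight=weights,
            random_state=seed, n_jobs=1,
        )
    if name == "logistic_regression":
        return OneVsRestClassifier(
            LogisticRegression(max_iter=2000, class_weight=weights, random_state=seed)
        )
    if name == "multinomial_logistic":
        return LogisticRegression(solver="lbfgs", max_iter=2000,
                                  class_weight=weights, random_state=seed)
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=5)  # no class-weight support
    if name == "svc_linear":
        return SVC(kernel="linear", probability=True, class_weight=weights,
                   random_state=seed)
    if name == "svc_rbf":
        return SVC(kernel="rbf", probability=True, class_weight=weights,
                   random_state=seed)
    raise ValueError(name)


class FeatureMismatchError(ValueError):
    pass


def _p_label(y: pd.Series) -> np.ndarray:
    return y.isin(["P", "P+S"]).to_numpy()


def _s_label(y: pd.Series) -> np.ndarray:
    return y.isin(["S", "P+S"]).to_numpy()


class ProgressionClassifier:
    """Unified fit/predict wrapper around the four strategies.

    ``predict`` always returns a frame with columns ``class`` (one of N, P,
    S, P+S), ``p_P`` and ``p_S``.  For the duo strategy the class is the
    label-map of the two sub-models' majority votes and the probabilities
    are each sub-model's positive-class probability; other strategies derive
    p(P) = Pr(P) + Pr(P+S) and p(S) = Pr(S) + Pr(P+S).
    """

    def __init__(self, config: ModelConfig, weighted: bool = True):
        self.config = config
        self.weighted = weighted
        self.feature_names_: list[str] | None = None
        self._models: dict = {}

    # -- helpers -----------------------------------------------------------
    def _weights_for(self, labels: pd.Series, reference: pd.Series | None) -> dict | None:
        if not self.weighted or self.config.base_learner == "knn":
            return None
        source = reference if (
            self.config.class_weight_source == "full_dataset" and reference is not None
        ) else labels
        return class_weights(source)

    @staticmethod
    def _check_binary(y: np.ndarray, name: str) -> None:
        if len(np.unique(y)) < 2:
            raise ValueError(f"sub-problem {name!r} has a single class in training labels")

    # -- contract ----------------------------------------------------------
    def fit(self, X: pd.DataFrame, y, reference_labels=None) -> "ProgressionClassifier":
        y = pd.Series(np.asarray(y, dtype=object), index=X.index)
        reference = pd.Series(np.asarray(reference_labels, dtype=object)) \
            if reference_labels is not None else None
        self.feature_names_ = list(X.columns)
        cfg, seed = self.config, self.config.seed
        strategy = cfg.strategy

        if strategy == "single":
            if y.nunique() < 2:
                raise ValueError("sub-problem '4-class' has a single class in training labels")
            est = _base_estimator(cfg, self._weights_for(y, reference), seed)
            est.fit(X, y)
            self._models = {"single": est}
        elif strategy == "duo":
            for name, maker, offset in (("P", _p_label, 0), ("S", _s_label, 1)):
                yb = maker(y)
                self._check_binary(yb, name)
                weights = None
                if self.weighted and cfg.base_learner != "knn":
                    use_ref = (cfg.class_weight_source == "full_dataset"
                               and reference is not None)
                    if cfg.duo_weight_basis == "binary":
                        src = maker(reference) if use_ref else yb
                        weights = class_weights(pd.Series(src))
                    else:
                        w4 = class_weights(reference if use_ref else y)
                        positives = ("P", "P+S") if name == "P" else ("S", "P+S")
                        weights = {True: 0.0, False: 0.0}
                        for c, w in w4.items():
                            weights[c in positives] += w
                est = _base_estimator(cfg, weights, seed + offset)
                est.fit(X, yb)
                self._models[name] = est
        elif strategy == "one_vs_rest":
            for i, cls in enumerate(CLASSES):
                yb = (y == cls).to_numpy()
                self._check_binary(yb, cls)
                weights = None
                if self.weighted and cfg.base_learner != "knn":
                    weights = class_weights(pd.Series(yb))
                est = _base_estimator(cfg, weights, seed + i)
                est.fit(X, yb)
                self._models[cls] = est
        elif strategy == "multi_label":
            yp, ys = _p_label(y), _s_label(y)
            self._check_binary(yp, "P")
            self._check_binary(ys, "S")
            if cfg.base_learner != "random_forest":
                raise ValueError("multi_label strategy requires a forest base learner")
            weights = None
            if self.weighted:
                weights = [class_weights(pd.Series(yp)), class_weights(pd.Series(ys))]
            est = RandomForestClassifier(
                n_estimators=cfg.n_trees, max_depth=cfg.max_depth,
                criterion=cfg.criterion, class_weight=weights,
                random_state=seed, n_jobs=1)
            est.fit(X, np.column_stack([yp, ys]).astype(int))
            self._models = {"multi": est}
        return self

    def _check_features(self, X: pd.DataFrame) -> None:
        if self.feature_names_ is None:
            raise RuntimeError("model is not fitted")
        got, want = list(X.columns), self.feature_names_
        if got != want:
            missing = sorted(set(want) - set(got))
            extra = sorted(set(got) - set(want))
            raise FeatureMismatchError(
                f"feature names mismatch: missing={missing}, extra={extra}")

    def predict(self, X: pd.DataFrame) -> pd.DataFrame:
        self._check_features(X)
        cfg = self.config
        if cfg.strategy == "single":
            est = self._models["single"]
            proba = est.predict_proba(X)
            cols = {c: proba[:, i] for i, c in enumerate(est.classes_)}
            p_p = cols.get("P", 0.0) + cols.get("P+S", 0.0)
            p_s = cols.get("S", 0.0) + cols.get("P+S", 0.0)
            label = est.predict(X)
        elif cfg.strategy == "duo":
            votes, probs = {}, {}
            for name in ("P", "S"):
                est = self._models[name]
                votes[name] = est.predict(X).astype(bool)
                pos = list(est.classes_).index(True)
                probs[name] = est.predict_proba(X)[:, pos]
            label = np.array([assign_label(p, s).class_
                              for p, s in zip(votes["P"], votes["S"])], dtype=object)
            p_p, p_s = probs["P"], probs["S"]
        elif cfg.strategy == "one_vs_rest":
            scores = np.column_stack([
                self._models[c].predict_proba(X)[:, list(self._models[c].classes_).index(True)]
                for c in CLASSES
            ])
            label = np.asarray(CLASSES, dtype=object)[scores.argmax(axis=1)]
            total = scores.sum(axis=1)
            norm = np.divide(scores, total[:, None], out=np.full_like(scores, 0.25),
                             where=total[:, None] > 0)
            p_p = norm[:, 1] + norm[:, 3]
            p_s = norm[:, 2] + norm[:, 3]
        else:  # multi_label
            est = self._models["multi"]
            votes = est.predict(X).astype(bool)
            proba = est.predict_proba(X)
            p_p = proba[0][:, list(est.classes_[0]).index(1)]
            p_s = proba[1][:, list(est.classes_[1]).index(1)]
            label = np.array([assign_label(p, s).class_ for p, s in votes], dtype=object)
        return pd.DataFrame(
            {"class": label, "p_P": np.asarray(p_p, dtype=float),
             "p_S": np.asarray(p_s, dtype=float)},
            index=X.index,
        )

    @property
    def feature_importances_(self) -> np.ndarray:
        """Native importance of the base learner, averaged over sub-models."""
        imps = []
        for est in self._models.values():
            inner = est
            if not hasattr(inner, "feature_importances_"):
                raise AttributeError(
                    f"base learner {self.config.base_learner!r} exposes no native importance")
            imps.append(inner.feature_importances_)
        return np.mean(imps, axis=0)

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        joblib.dump({"format_version": 1, "config": self.config,
                     "feature_names": self.feature_names_,
                     "models": self._models, "weighted": self.weighted}, path)

    @classmethod
    def load(cls, path: str | Path) -> "ProgressionClassifier":
        payload = joblib.load(path)
        obj = cls(payload["config"], weighted=payload.get("weighted", True))
        obj.feature_names_ = payload["feature_names"]
        obj._models = payload["models"]
        return obj


def fit(X: pd.DataFrame, y, config: ModelConfig,
        reference_labels=None, weighted: bool = True) -> ProgressionClassifier:
    """Functional front door: fit a classifier of the configured strategy."""
    return ProgressionClassifier(config, weighted=weighted).fit(
        X, y, reference_labels=reference_labels)


def predict(model: ProgressionClassifier, X: pd.DataFrame) -> pd.DataFrame:
    return model.predict(X)


def with_seed(config: ModelConfig, seed: int) -> ModelConfig:
    return replace(config, seed=int(seed))
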
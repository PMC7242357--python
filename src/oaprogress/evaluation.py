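"""Evaluation machinery: weighted F1, repeated stratified CV with pooled
out-of-sample predictions, learning curves, the balanced-vs-imbalanced
protocol, exhaustive grid search, bootstrap bias-corrected cross-validation
(BBC-CV) and recursive feature elimination.

Scores are pooled: within one (repeat, model seed, configuration) every
instance is predicted exactly once by the model that did not see it, the
predictions are pooled and a single weighted F1 is computed.  The typical
performance of a configuration is the median over CV repeats of the median
over model seeds ("median of medians").

BBC-CV corrects the optimistic bias of selecting the best of many
configurations: each bootstrap draw of instances selects the winner on the
sampled instances (using all repeats' predictions) and scores it on the
out-of-bootstrap instances only; the estimate is the mean out-of-bootstrap
score over all draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .models import ModelConfig, ProgressionClassifier, with_seed

FoldPreprocessor = Callable[[pd.DataFrame, pd.DataFrame],
                            tuple[pd.DataFrame, pd.DataFrame]]


# ---------------------------------------------------------------------------
# weighted F1
# ---------------------------------------------------------------------------

def _f1_from_counts(cm: np.ndarray) -> float:
    """Class-frequency-weighted F1 from a confusion-count matrix.

    Uses the identity F1_c = 2*TP_c / (support_c + predicted_c); classes
    absent from the true labels carry zero weight.
    """
    tp = np.diag(cm).astype(float)
    support = cm.sum(axis=1).astype(float)
    predicted = cm.sum(axis=0).astype(float)
    denom = support + predicted
    f1 = np.divide(2.0 * tp, denom, out=np.zeros_like(tp), where=denom > 0)
    total = support.sum()
    if total == 0:
        raise ValueError("empty label vector")
    return float((f1 * support).sum() / total)


def _encode(y_true, y_pred) -> tuple[np.ndarray, np.ndarray, int]:
    labels = sorted(set(y_true) | set(y_pred), key=str)
    code = {c: i for i, c in enumerate(labels)}
    t = np.fromiter((code[v] for v in y_true), dtype=np.int64, count=len(y_true))
    p = np.fromiter((code[v] for v in y_pred), dtype=np.int64, count=len(y_pred))
    return t, p, len(labels)


def weighted_f1(y_true, y_pred) -> float:
    """Weighted average of per-class F1 over classes present in the truths."""
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise ValueError("label vectors must be non-empty and of equal length")
    t, p, k = _encode(y_true, y_pred)
    cm = np.bincount(t * k + p, minlength=k * k).reshape(k, k)
    return _f1_from_counts(cm)


# ---------------------------------------------------------------------------
# cross-validation plans and folds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVPlan:
    """Repeated stratified CV layout.

    The study-scale plan is 10 folds x 10 repeats x 25 model seeds; the
    ``desk()`` plan (3 repeats x 5 seeds) runs the full stack in minutes.
    Model seeds are constant across folds and repeats.
    """

    n_folds: int = 10
    n_repeats: int = 10
    n_seeds: int = 25
    stratified: bool = True
    master_seed: int = 0

    @classmethod
    def desk(cls, master_seed: int = 0) -> "CVPlan":
        return cls(n_folds=10, n_repeats=3, n_seeds=5, master_seed=master_seed)

    def fold_seed(self, repeat: int) -> int:
        return int(np.random.SeedSequence([self.master_seed, 1, repeat])
                   .generate_state(1)[0] % (2 ** 31))

    def model_seeds(self) -> list[int]:
        state = np.random.SeedSequence([self.master_seed, 2]).generate_state(self.n_seeds)
        return [int(s % (2 ** 31)) for s in state]


def stratified_folds(y, k: int, seed: int) -> np.ndarray:
    """Fold id per instance; per-fold class counts differ from n_c/k by <1."""
    y = np.asarray(list(y), dtype=object)
    n = len(y)
    if k > n:
        raise ValueError(f"cannot split {n} instances into {k} folds")
    if k == 1:
        return np.zeros(n, dtype=int)
    assignment = np.empty(n, dtype=int)
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(n), y)):
        assignment[test_idx] = fold
    return assignment


# ---------------------------------------------------------------------------
# repeated cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Pooled out-of-sample predictions and per-run pooled scores."""

    predictions: pd.DataFrame  # instance_id, config_id, repeat, seed, pred, p_P, p_S, true
    scores: pd.DataFrame       # config_id, repeat, seed, score
    plan: CVPlan
    skipped_folds: list = field(default_factory=list)

    def median_of_medians(self, config_id: str | None = None):
        per_repeat = (self.scores.groupby(["config_id", "repeat"])["score"]
                      .median().reset_index())
        mom = per_repeat.groupby("config_id")["score"].median()
        return float(mom[config_id]) if config_id is not None else mom

    def mad(self, config_id: str | None = None):
        def _mad(x: pd.Series) -> float:
            return float((x - x.median()).abs().median())

        mads = self.scores.groupby("config_id")["score"].apply(_mad)
        return float(mads[config_id]) if config_id is not None else mads


def _fit_predict(config: ModelConfig, seed: int, X_tr, y_tr, X_te, y_full,
                 weighted: bool) -> pd.DataFrame:
    model = ProgressionClassifier(with_seed(config, seed), weighted=weighted)
    model.fit(X_tr, y_tr, reference_labels=y_full)
    return model.predict(X_te)


def _prepare_folds(instances: pd.DataFrame, y: pd.Series, plan: CVPlan,
                   repeat: int, preprocess: FoldPreprocessor | None,
                   skipped: list):
    """Fit fold-wise preprocessing once per (repeat, fold); shared by all
    configurations and model seeds."""
    folds = stratified_folds(y, plan.n_folds, plan.fold_seed(repeat))
    prepared = []
    for k in range(plan.n_folds):
        te = folds == k
        tr = ~te
        y_tr, y_te = y[tr], y[te]
        if y_tr.nunique() < y.nunique():
            warnings.warn(f"repeat {repeat} fold {k}: class missing from the "
                          "training partition; fold skipped")
            skipped.append((repeat, k))
            continue
        X_tr, X_te = instances[tr], instances[te]
        if preprocess is not None:
            X_tr, X_te = preprocess(X_tr, X_te)
        prepared.append((X_tr, y_tr, X_te, y_te))
    return folds, prepared


def run_repeated_cv(instances: pd.DataFrame, y,
                    configs: ModelConfig | Sequence[ModelConfig],
                    plan: CVPlan,
                    preprocess: FoldPreprocessor | None = None,
                    weighted: bool = True) -> CVResult:
    """Pooled out-of-sample repeated stratified CV over one or more
    configurations.  Per-fold preprocessing is fitted on the training
    partition only, inside the loop."""
    if isinstance(configs, ModelConfig):
        configs = [configs]
    y = pd.Series(np.asarray(y, dtype=object), index=instances.index)
    model_seeds = plan.model_seeds()
    skipped: list = []
    pred_frames, score_rows = [], []
    for repeat in range(plan.n_repeats):
        _, prepared = _prepare_folds(instances, y, plan, repeat, preprocess, skipped)
        for config in configs:
            for seed in model_seeds:
                parts = []
                for X_tr, y_tr, X_te, y_te in prepared:
                    out = _fit_predict(config, seed, X_tr, y_tr, X_te, y, weighted)
                    out = out.assign(true=y_te)
                    parts.append(out)
                pooled = pd.concat(parts)
                score = weighted_f1(pooled["true"], pooled["class"])
                score_rows.append({"config_id": config.id, "repeat": repeat,
                                   "seed": seed, "score": score})
                pooled = pooled.rename(columns={"class": "pred"})
                pooled.insert(0, "instance_id", pooled.index)
                pooled = pooled.assign(config_id=config.id, repeat=repeat, seed=seed)
                pred_frames.append(pooled.reset_index(drop=True))
    return CVResult(
        predictions=pd.concat(pred_frames, ignore_index=True),
        scores=pd.DataFrame(score_rows),
        plan=plan,
        skipped_folds=skipped,
    )


# ---------------------------------------------------------------------------
# learning curves
# ---------------------------------------------------------------------------

def _stratified_subset(y: pd.Series, fraction: float, rng: np.random.Generator):
    """Positional indices of a stratified random subset; None if any class
    would fall below one instance."""
    if fraction >= 1.0:
        return np.arange(len(y))
    keep = []
    codes = y.to_numpy()
    for cls in pd.unique(codes):
        pos = np.flatnonzero(codes == cls)
        take = int(round(fraction * len(pos)))
        if take < 1:
            return None
        keep.append(rng.choice(pos, size=take, replace=False))
    return np.sort(np.concatenate(keep))


def learning_curve(instances: pd.DataFrame, y, config: ModelConfig,
                   fractions: Sequence[float], plan: CVPlan,
                   preprocess: FoldPreprocessor | None = None,
                   weighted: bool = True) -> pd.DataFrame:
    """Pooled scores at increasing training-set fractions.

    Test folds are unchanged; each training fold is subsampled (stratified)
    to the requested fraction.  Returns one row per (fraction, repeat, seed)
    plus a per-fraction summary obtainable via :func:`summarize_curve`.
    """
    y = pd.Series(np.asarray(y, dtype=object), index=instances.index)
    model_seeds = plan.model_seeds()
    rows = []
    for repeat in range(plan.n_repeats):
        folds = stratified_folds(y, plan.n_folds, plan.fold_seed(repeat))
        for fraction in fractions:
            if not 0 < fraction <= 1:
                raise ValueError("fractions must lie in (0, 1]")
            prepared = []
            skip = False
            for k in range(plan.n_folds):
                te = folds == k
                tr_idx = np.flatnonzero(~te)
                rng = np.random.default_rng(np.random.SeedSequence(
                    [plan.master_seed, 3, repeat, k, int(round(fraction * 1e6))]))
                sub = _stratified_subset(y.iloc[tr_idx], fraction, rng)
                if sub is None:
                    warnings.warn(f"fraction {fraction}: a class would vanish "
                                  f"from repeat {repeat} fold {k}; skipped")
                    skip = True
                    break
                tr_idx = tr_idx[sub]
                X_tr, X_te = instances.iloc[tr_idx], instances[te]
                if preprocess is not None:
                    X_tr, X_te = preprocess(X_tr, X_te)
                prepared.append((X_tr, y.iloc[tr_idx], X_te, y[te]))
            if skip:
                continue
            for seed in model_seeds:
                parts = []
                for X_tr, y_tr, X_te, y_te in prepared:
                    out = _fit_predict(config, seed, X_tr, y_tr, X_te, y, weighted)
                    parts.append(out.assign(true=y_te))
                pooled = pd.concat(parts)
                rows.append({"fraction": fraction, "repeat": repeat, "seed": seed,
                             "score": weighted_f1(pooled["true"], pooled["class"])})
    return pd.DataFrame(rows)


def summarize_curve(curve: pd.DataFrame) -> pd.DataFrame:
    """Per-fraction median, min/max and median absolute deviation bands."""
    def _mad(x: pd.Series) -> float:
        return float((x - x.median()).abs().median())

    grouped = curve.groupby("fraction")["score"]
    return pd.DataFrame({
        "median": grouped.median(),
        "min": grouped.min(),
        "max": grouped.max(),
        "mad": grouped.apply(_mad),
    }).reset_index()


# ---------------------------------------------------------------------------
# balanced vs cost-sensitive protocol
# ---------------------------------------------------------------------------

def balanced_subsample(labels, per_class: int, seed: int) -> np.ndarray:
    """Positional indices of a class-balanced down-sample (no replacement)."""
    y = pd.Series(np.asarray(list(labels), dtype=object))
    keep = []
    for cls in sorted(y.unique(), key=str):
        pos = np.flatnonzero((y == cls).to_numpy())
        if len(pos) < per_class:
            raise ValueError(f"class {cls!r} has only {len(pos)} instances, "
                             f"cannot draw {per_class}")
        rng = np.random.default_rng(np.random.SeedSequence([seed, len(keep)]))
        keep.append(rng.choice(pos, size=per_class, replace=False))
    return np.sort(np.concatenate(keep))


def balanced_comparison(instances: pd.DataFrame, y, config: ModelConfig,
                        plan: CVPlan, n_samplings: int = 11,
                        per_class: int | None = None,
                        preprocess: FoldPreprocessor | None = None) -> dict:
    """Paired protocol: full imbalanced training folds with class weights vs
    class-balanced down-sampled training folds, on bit-identical test folds.

    The balanced arm is repeated with ``n_samplings`` sampling seeds.
    Returns ``{"imbalanced": scores, "balanced": scores, "folds": {...}}``.
    """
    y = pd.Series(np.asarray(y, dtype=object), index=instances.index)
    imbalanced = run_repeated_cv(instances, y, config, plan,
                                 preprocess=preprocess, weighted=True)

    model_seeds = plan.model_seeds()
    rows = []
    folds_by_repeat = {}
    for repeat in range(plan.n_repeats):
        folds = stratified_folds(y, plan.n_folds, plan.fold_seed(repeat))
        folds_by_repeat[repeat] = folds
        for sampling in range(n_samplings):
            prepared = []
            for k in range(plan.n_folds):
                te = folds == k
                tr_idx = np.flatnonzero(~te)
                y_tr = y.iloc[tr_idx]
                counts = y_tr.value_counts()
                m = per_class if per_class is not None else int(counts.min())
                if m > counts.min():
                    raise ValueError(f"per_class={m} exceeds the minority count "
                                     f"{int(counts.min())} in repeat {repeat} fold {k}")
                sub_seed = int(np.random.SeedSequence(
                    [plan.master_seed, 4, repeat, k, sampling]).generate_state(1)[0]
                    % (2 ** 31))
                sub = balanced_subsample(y_tr, m, sub_seed)
                tr_idx = tr_idx[sub]
                X_tr, X_te = instances.iloc[tr_idx], instances[te]
                if preprocess is not None:
                    X_tr, X_te = preprocess(X_tr, X_te)
                prepared.append((X_tr, y.iloc[tr_idx], X_te, y[te]))
            for seed in model_seeds:
                parts = []
                for X_tr, y_tr, X_te, y_te in prepared:
                    out = _fit_predict(config, seed, X_tr, y_tr, X_te, y,
                                       weighted=False)
                    parts.append(out.assign(true=y_te))
                pooled = pd.concat(parts)
                rows.append({"config_id": config.id, "repeat": repeat,
                             "seed": seed, "sampling": sampling,
                             "score": weighted_f1(pooled["true"], pooled["class"])})
    return {"imbalanced": imbalanced.scores, "balanced": pd.DataFrame(rows),
            "folds": folds_by_repeat}


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

N_TREES_GRID = (100, 200, 400, 600, 800, 1000)
MAX_DEPTH_GRID = (4, 5, 6, 7, 8, 9, 10)
CRITERION_GRID = ("gini", "entropy")


def default_tuning_grid(strategy: str = "duo") -> list[ModelConfig]:
    """The exhaustive forest tuning grid: 6 tree counts x 7 depths x 2 split
    criteria = 84 configurations."""
    return [
        ModelConfig(strategy=strategy, n_trees=t, max_depth=d, criterion=c)
        for t in N_TREES_GRID for d in MAX_DEPTH_GRID for c in CRITERION_GRID
    ]


def desk_tuning_grid(strategy: str = "duo") -> list[ModelConfig]:
    """A small 8-configuration grid for desk-scale runs."""
    return [
        ModelConfig(strategy=strategy, n_trees=t, max_depth=d, criterion=c)
        for t in (100, 200) for d in (4, 8) for c in CRITERION_GRID
    ]


@dataclass
class GridSearchResult:
    best_config: ModelConfig
    table: pd.DataFrame
    cv_result: CVResult


def grid_search(instances: pd.DataFrame, y, grid: Sequence[ModelConfig],
                plan: CVPlan,
                preprocess: FoldPreprocessor | None = None) -> GridSearchResult:
    """Evaluate every configuration; select the highest median-of-medians.

    Ties break towards the lowest median absolute deviation of scores, then
    lower depth, then fewer trees, then gini before entropy; selection is
    deterministic.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    result = run_repeated_cv(instances, y, list(grid), plan, preprocess=preprocess)
    mom = result.median_of_medians()
    mad = result.mad()
    rows = []
    for config in grid:
        rows.append({
            "config_id": config.id, "n_trees": config.n_trees,
            "max_depth": config.max_depth, "criterion": config.criterion,
            "median_of_medians": mom[config.id], "mad": mad[config.id],
        })
    table = pd.DataFrame(rows)

    def sort_key(config: ModelConfig):
        return (-round(mom[config.id], 10), round(mad[config.id], 10),
                config.max_depth, config.n_trees,
                CRITERION_GRID.index(config.criterion))

    best = min(grid, key=sort_key)
    return GridSearchResult(best_config=best, table=table, cv_result=result)


# ---------------------------------------------------------------------------
# BBC-CV
# ---------------------------------------------------------------------------

@dataclass
class BBCResult:
    estimate: float
    ci_low: float
    ci_high: float
    B: int
    n_redraws: int

    def to_dict(self) -> dict:
        return {"estimate": self.estimate, "ci_low": self.ci_low,
                "ci_high": self.ci_high, "B": self.B}


def prediction_tensor(prediction_set: pd.DataFrame):
    """Pivot a pooled PredictionSet frame into the (config, run, instance)
    label tensor BBC-CV consumes, plus the encoded truths."""
    df = prediction_set
    instances = np.sort(df["instance_id"].unique())
    configs = sorted(df["config_id"].unique())
    runs = sorted(set(zip(df["repeat"], df["seed"])))
    labels = sorted(set(df["pred"]) | set(df["true"]), key=str)
    code = {c: i for i, c in enumerate(labels)}
    inst_pos = {v: i for i, v in enumerate(instances)}
    run_pos = {v: i for i, v in enumerate(runs)}
    cfg_pos = {v: i for i, v in enumerate(configs)}

    preds = np.full((len(configs), len(runs), len(instances)), -1, dtype=np.int64)
    true = np.full(len(instances), -1, dtype=np.int64)
    ci = df["config_id"].map(cfg_pos).to_numpy()
    ri = pd.Series(list(zip(df["repeat"], df["seed"]))).map(run_pos).to_numpy()
    ii = df["instance_id"].map(inst_pos).to_numpy()
    preds[ci, ri, ii] = df["pred"].map(code).to_numpy()
    true[ii] = df["true"].map(code).to_numpy()
    if (preds < 0).any():
        raise ValueError("prediction set is not pooled: some (config, run) "
                         "pair misses instances")
    return preds, true, configs, labels


def _score_runs(pred_block: np.ndarray, true_block: np.ndarray, k: int,
                aggregation: str) -> float:
    """Weighted F1 of an (n_runs, n) prediction block against truths."""
    r = pred_block.shape[0]
    if aggregation == "concatenate":
        codes = np.tile(true_block, r) * k + pred_block.ravel()
        cm = np.bincount(codes, minlength=k * k).reshape(k, k)
        return _f1_from_counts(cm)
    if aggregation == "mean_over_runs":
        scores = []
        for row in pred_block:
            cm = np.bincount(true_block * k + row, minlength=k * k).reshape(k, k)
            scores.append(_f1_from_counts(cm))
        return float(np.mean(scores))
    raise ValueError(f"unknown aggregation {aggregation!r}")


def bbc_cv(preds: np.ndarray, true: np.ndarray, B: int = 1000, ci: float = 0.95,
           seed: int = 0, aggregation: str = "concatenate") -> BBCResult:
    """Bootstrap bias-corrected CV estimate over a configuration ensemble.

    ``preds`` has shape (n_configs, n_runs, n_instances) of encoded labels;
    the with-repeats variant enters through n_runs > 1: all repeats'
    predictions of a sampled instance are used both for selection and for
    out-of-bootstrap scoring.  Empty out-of-bootstrap draws are redrawn.
    """
    preds = np.asarray(preds)
    if preds.ndim == 2:
        preds = preds[None, :, :]
    n_configs, _, n = preds.shape
    k = int(max(preds.max(), true.max())) + 1
    rng = np.random.default_rng(seed)
    oob_scores = np.empty(B)
    redraws = 0
    for b in range(B):
        while True:
            idx = rng.integers(0, n, n)
            oob_mask = np.ones(n, dtype=bool)
            oob_mask[idx] = False
            if oob_mask.any():
                break
            redraws += 1
        t_in = true[idx]
        best_c, best_score = 0, -np.inf
        for c in range(n_configs):
            s = _score_runs(preds[c][:, idx], t_in, k, aggregation)
            if s > best_score:
                best_score, best_c = s, c
        oob_idx = np.flatnonzero(oob_mask)
        oob_scores[b] = _score_runs(preds[best_c][:, oob_idx], true[oob_idx],
                                    k, aggregation)
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(oob_scores, [alpha, 1.0 - alpha])
    return BBCResult(estimate=float(oob_scores.mean()), ci_low=float(lo),
                     ci_high=float(hi), B=B, n_redraws=redraws)


# ---------------------------------------------------------------------------
# recursive feature elimination
# ---------------------------------------------------------------------------

def rfe_select(X: pd.DataFrame, y, config: ModelConfig, inner_k: int = 3,
               seed: int = 0) -> tuple[list[str], pd.DataFrame]:
    """Backward elimination on one outer training fold.

    An inner stratified CV scores each subset size while the least important
    feature (native learner importance averaged over inner folds) is dropped
    one by one down to a single feature.  Returns the subset maximising the
    inner score (ties towards the smaller subset) and the elimination path.
    """
    if X.shape[1] < 2:
        raise ValueError("at least 2 features are required")
    y = pd.Series(np.asarray(y, dtype=object), index=X.index)
    features = list(X.columns)
    path_rows = []
    best_features, best_score = None, -np.inf
    while features:
        splitter = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed)
        scores, importances = [], np.zeros(len(features))
        for tr, va in splitter.split(np.zeros(len(y)), y):
            model = ProgressionClassifier(config)
            model.fit(X.iloc[tr][features], y.iloc[tr], reference_labels=y)
            out = model.predict(X.iloc[va][features])
            scores.append(weighted_f1(y.iloc[va], out["class"]))
            importances += model.feature_importances_
        mean_score = float(np.mean(scores))
        path_rows.append({"n_features": len(features), "score": mean_score,
                          "features": tuple(features)})
        if mean_score >= best_score:  # path shrinks, so >= keeps the smallest tie
            best_score, best_features = mean_score, list(features)
        if len(features) == 1:
            break
        features = [f for i, f in enumerate(features)
                    if i != int(np.argmin(importances))]
    return best_features, pd.DataFrame(path_rows)


def rfe_frequency(X: pd.DataFrame, y, config: ModelConfig, plan: CVPlan,
                  inner_k: int = 3) -> tuple[pd.Series, int]:
    """Per-feature selection counts over all (repeat, outer fold) rounds."""
    y = pd.Series(np.asarray(y, dtype=object), index=X.index)
    counts = pd.Series(0, index=X.columns, dtype=int)
    rounds = 0
    for repeat in range(plan.n_repeats):
        folds = stratified_folds(y, plan.n_folds, plan.fold_seed(repeat))
        for k in range(plan.n_folds):
            tr = folds != k
            inner_seed = int(np.random.SeedSequence(
                [plan.master_seed, 5, repeat, k]).generate_state(1)[0] % (2 ** 31))
            selected, _ = rfe_select(X[tr], y[tr], config, inner_k=inner_k,
                                     seed=inner_seed)
            counts[selected] += 1
            rounds += 1
    return counts, rounds
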
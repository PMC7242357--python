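"""From longitudinal cohort to model-ready period instances.

The fixed pipeline order is: enumerate periods -> carry-forward/defaults ->
filter attributes and periods -> infer attribute kinds -> and then, inside
every cross-validation fold, impute -> one-hot encode -> (optionally) scale,
with all statistics fitted on the training partition only so that nothing
leaks from held-out rows.

Each period contributes one instance whose features are taken from its
*start* visit -- the model must predict the future, so end-of-period
covariates would leak the outcome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import labeling
from .data import AttributeMeta, CohortTable, Period, enumerate_timepoint_pairs


class EmptyDatasetError(ValueError):
    """Raised when filtering leaves no attributes or no instances."""


# ---------------------------------------------------------------------------
# period enumeration and instance construction
# ---------------------------------------------------------------------------

def enumerate_periods(cohort: CohortTable, min_years: float = 2.0,
                      policy: str = "all_pairs",
                      drop_post_replacement: bool = True) -> list[Period]:
    """All ordered visit pairs of each patient at least ``min_years`` apart.

    Periods ending at or after the patient's earliest knee replacement are
    dropped by default (their outcome measurements are invalid).
    """
    periods: list[Period] = []
    for pid in cohort.patients():
        ts = cohort.patient_timepoints(pid)
        cutoff = cohort.first_replacement(pid) if drop_post_replacement else np.inf
        for a, b in enumerate_timepoint_pairs(ts, min_years, policy):
            if b < cutoff:
                periods.append(Period(pid, a, b))
    return periods


def build_instances(cohort: CohortTable, periods: list[Period]) -> pd.DataFrame:
    """One row per period, indexed by period id, with start-visit attributes."""
    visits = cohort.indexed_visits()
    attr_cols = cohort.attribute_columns
    rows, index = [], []
    for period in periods:
        row = visits.loc[(period.patient_id, period.start), attr_cols]
        rows.append(row)
        index.append(period.id)
    instances = pd.DataFrame(rows)
    instances.index = pd.Index(index, name="instance_id")
    return instances


def carry_forward_and_defaults(cohort: CohortTable,
                               meta: dict[str, AttributeMeta] | None = None) -> CohortTable:
    """Fill flagged attributes forward in time, then apply reporting defaults.

    Carry-forward copies the latest earlier non-missing value of the same
    patient (never backwards); default values replace whatever is still
    missing for attributes with a documented reporting convention.
    """
    meta = meta if meta is not None else cohort.meta
    visits = cohort.visits.sort_values(["patient_id", "timepoint_years"]).copy()
    for name, m in meta.items():
        if name not in visits.columns:
            continue
        if m.carry_forward:
            visits[name] = visits.groupby("patient_id")[name].ffill()
        if m.default_value is not None:
            visits[name] = visits[name].fillna(m.default_value)
    visits = visits.reset_index(drop=True)
    return CohortTable(visits=visits, replacements=cohort.replacements, meta=meta)


# ---------------------------------------------------------------------------
# filtering and kind inference
# ---------------------------------------------------------------------------

def filter_table(instances: pd.DataFrame, meta: dict[str, AttributeMeta],
                 attr_missing_max: float = 0.5,
                 period_missing_max: float = 0.4) -> pd.DataFrame:
    """Drop unusable attributes and instances.

    Identifier attributes are always dropped; attributes missing in *more
    than* ``attr_missing_max`` of instances go next; then instances missing
    *over* ``period_missing_max`` of the surviving attributes; finally
    attributes with a single non-null value (no variance).  Comparisons are
    strict, so an attribute missing exactly 50% survives.
    """
    if not 0 < attr_missing_max <= 1 or not 0 < period_missing_max <= 1:
        raise ValueError("filter thresholds must lie in (0, 1]")
    out = instances.copy()
    identifiers = [c for c in out.columns
                   if c in meta and meta[c].kind == "identifier"]
    out = out.drop(columns=identifiers)

    attr_missing = out.isna().mean(axis=0)
    out = out.loc[:, attr_missing <= attr_missing_max]
    if out.shape[1] == 0:
        raise EmptyDatasetError("all attributes dropped by the missingness filter")

    period_missing = out.isna().mean(axis=1)
    out = out.loc[period_missing <= period_missing_max]
    if out.shape[0] == 0:
        raise EmptyDatasetError("all instances dropped by the missingness filter")

    nunique = out.nunique(dropna=True)
    out = out.loc[:, nunique > 1]
    if out.shape[1] == 0:
        raise EmptyDatasetError("all attributes are constant")
    return out


def infer_kinds(instances: pd.DataFrame, meta: dict[str, AttributeMeta],
                max_levels: int = 10) -> dict[str, AttributeMeta]:
    """Complete the metadata: unlabeled attributes with at most ``max_levels``
    distinct non-null values become categorical, the rest continuous.
    Explicit metadata entries are never overridden."""
    out = dict(meta)
    for col in instances.columns:
        if col in out:
            continue
        n = instances[col].nunique(dropna=True)
        if n <= max_levels:
            out[col] = AttributeMeta(name=col, kind="categorical", n_levels=int(n))
        else:
            out[col] = AttributeMeta(name=col, kind="continuous")
    return out


# ---------------------------------------------------------------------------
# fold-safe transforms
# ---------------------------------------------------------------------------

def _smallest(values) -> object:
    try:
        return min(values)
    except TypeError:
        return min(values, key=str)


@dataclass
class Imputer:
    """Mode (categorical/ordinal) or mean (continuous) imputation, fitted on
    training rows only.  Mode ties break towards the smallest value."""

    meta: dict[str, AttributeMeta]
    statistics_: dict = field(default_factory=dict, repr=False)

    def fit(self, train: pd.DataFrame) -> "Imputer":
        self.statistics_ = {}
        for col in train.columns:
            series = train[col].dropna()
            if series.empty:
                raise ValueError(f"attribute {col!r} is entirely missing in the training set")
            kind = self.meta[col].kind if col in self.meta else "continuous"
            if kind in ("categorical", "ordinal"):
                counts = series.value_counts()
                top = counts[counts == counts.max()].index
                self.statistics_[col] = _smallest(list(top))
            else:
                self.statistics_[col] = float(series.mean())
        return self

    def transform(self, rows: pd.DataFrame) -> pd.DataFrame:
        out = rows.copy()
        for col, value in self.statistics_.items():
            if col in out.columns:
                out[col] = out[col].fillna(value)
        return out


@dataclass
class OneHotEncoder:
    """One dummy per level for categoricals with >2 levels, a single 0/1
    column for binary ones, numeric rank passthrough for ordinals.  Level
    maps are fitted on training rows; unseen levels encode as all-zeros."""

    meta: dict[str, AttributeMeta]
    levels_: dict = field(default_factory=dict, repr=False)

    def fit(self, train: pd.DataFrame) -> "OneHotEncoder":
        self.levels_ = {}
        for col in train.columns:
            kind = self.meta[col].kind if col in self.meta else "continuous"
            if kind == "categorical":
                self.levels_[col] = sorted(train[col].dropna().unique(), key=str)
            elif kind == "ordinal" and not pd.api.types.is_numeric_dtype(train[col]):
                self.levels_[col] = sorted(train[col].dropna().unique(), key=str)
        return self

    def transform(self, rows: pd.DataFrame) -> pd.DataFrame:
        pieces = {}
        for col in rows.columns:
            kind = self.meta[col].kind if col in self.meta else "continuous"
            if kind == "categorical":
                levels = self.levels_.get(col, [])
                if len(levels) > 2:
                    for lvl in levels:
                        pieces[f"{col}={lvl:g}" if isinstance(lvl, float) else f"{col}={lvl}"] = (
                            (rows[col] == lvl).astype(float)
                        )
                else:
                    hot = levels[-1] if levels else None
                    pieces[col] = (rows[col] == hot).astype(float)
            elif kind == "ordinal":
                if col in self.levels_:
                    rank = {lvl: i for i, lvl in enumerate(self.levels_[col])}
                    pieces[col] = rows[col].map(rank).fillna(-1.0).astype(float)
                else:
                    pieces[col] = rows[col].astype(float)
            else:
                pieces[col] = rows[col].astype(float)
        return pd.DataFrame(pieces, index=rows.index)


@dataclass
class MinMaxScaler:
    """Per-column [0, 1] scaling from training bounds; constant columns map
    to 0; held-out values may fall outside [0, 1]."""

    bounds_: dict = field(default_factory=dict, repr=False)

    def fit(self, train: pd.DataFrame) -> "MinMaxScaler":
        self.bounds_ = {
            col: (float(train[col].min()), float(train[col].max()))
            for col in train.columns
        }
        return self

    def transform(self, rows: pd.DataFrame) -> pd.DataFrame:
        out = rows.copy()
        for col, (lo, hi) in self.bounds_.items():
            if col not in out.columns:
                continue
            span = hi - lo
            out[col] = (out[col] - lo) / span if span > 0 else 0.0
        return out


@dataclass
class PreprocessPipeline:
    """Impute -> encode -> (optionally) scale, fitted on training rows only."""

    meta: dict[str, AttributeMeta]
    scale: bool = False
    imputer_: Imputer | None = None
    encoder_: OneHotEncoder | None = None
    scaler_: MinMaxScaler | None = None

    def fit(self, train: pd.DataFrame) -> "PreprocessPipeline":
        self.imputer_ = Imputer(self.meta).fit(train)
        imputed = self.imputer_.transform(train)
        self.encoder_ = OneHotEncoder(self.meta).fit(imputed)
        encoded = self.encoder_.transform(imputed)
        self.scaler_ = MinMaxScaler().fit(encoded) if self.scale else None
        return self

    def transform(self, rows: pd.DataFrame) -> pd.DataFrame:
        if self.imputer_ is None:
            raise RuntimeError("pipeline is not fitted")
        out = self.encoder_.transform(self.imputer_.transform(rows))
        if self.scaler_ is not None:
            out = self.scaler_.transform(out)
        return out

    def fit_transform(self, train: pd.DataFrame) -> pd.DataFrame:
        return self.fit(train).transform(train)

    # -- fitted-state persistence -----------------------------------------
    def state_dict(self) -> dict:
        def _plain(v):
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v

        return {
            "imputation": {k: _plain(v) for k, v in (self.imputer_.statistics_ or {}).items()},
            "levels": {k: [_plain(x) for x in v] for k, v in (self.encoder_.levels_ or {}).items()},
            "scaling": {k: list(v) for k, v in (self.scaler_.bounds_ or {}).items()}
            if self.scaler_ is not None else None,
        }

    def save_state(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.state_dict(), indent=2))


def make_fold_preprocessor(meta: dict[str, AttributeMeta], scale: bool = False
                           ) -> Callable[[pd.DataFrame, pd.DataFrame],
                                         tuple[pd.DataFrame, pd.DataFrame]]:
    """Per-fold transform: fit a fresh pipeline on the training partition and
    apply it to both partitions (no leakage from held-out rows)."""

    def _fold(train: pd.DataFrame, test: pd.DataFrame):
        pipe = PreprocessPipeline(meta, scale=scale).fit(train)
        return pipe.transform(train), pipe.transform(test)

    return _fold


# ---------------------------------------------------------------------------
# end-to-end dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """Model-ready instances with labels and the pruned metadata."""

    instances: pd.DataFrame
    labels: pd.Series
    meta: dict[str, AttributeMeta]
    periods: list[Period]
    exclusions: pd.DataFrame


def build_dataset(cohort: CohortTable, min_years: float = 2.0,
                  policy: str = "all_pairs",
                  attr_missing_max: float = 0.5,
                  period_missing_max: float = 0.4) -> Dataset:
    """Cohort -> labeled period instances, applying the fixed pipeline order.

    Labels are computed from raw outcome columns before any filtering or
    filling of covariates touches the modelling table.
    """
    filled = carry_forward_and_defaults(cohort)
    periods = enumerate_periods(filled, min_years=min_years, policy=policy)
    labeled = labeling.label_periods(filled, periods)
    keep = labeled["class"].notna().to_numpy()
    kept_periods = [p for p, k in zip(periods, keep) if k]
    exclusions = labeled.loc[~keep, ["patient_id", "start", "end", "exclusion_reason"]]

    instances = build_instances(filled, kept_periods)
    labels = pd.Series(labeled.loc[keep, "class"].to_numpy(),
                       index=instances.index, name="class")
    filtered = filter_table(instances, filled.meta,
                            attr_missing_max=attr_missing_max,
                            period_missing_max=period_missing_max)
    labels = labels.loc[filtered.index]
    meta = infer_kinds(filtered, filled.meta)
    id_map = {p.id: p for p in kept_periods}
    final_periods = [id_map[i] for i in filtered.index]
    return Dataset(instances=filtered, labels=labels, meta=meta,
                   periods=final_periods, exclusions=exclusions.reset_index(drop=True))
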
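"""Shared domain containers for longitudinal knee-OA cohorts.

A cohort is stored as one wide table of visits (one row per patient and
timepoint) together with a table of knee-replacement events and per-attribute
metadata.  Outcome measurements -- the per-knee WOMAC pain subscale (0-100)
and the minimum joint-space width (mm) -- live in dedicated columns because
the progression labeling must only ever read raw, never imputed, values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
import yaml

#: Progression classes: non-progressor, pain, structure, combined.
CLASSES = ("N", "P", "S", "P+S")

KNEES = ("left", "right")

#: Columns holding raw outcome measurements used by the class definition.
OUTCOME_COLUMNS = (
    "womac_pain_left",
    "womac_pain_right",
    "min_jsw_left",
    "min_jsw_right",
)

#: Index columns of the visits table.
KEY_COLUMNS = ("patient_id", "timepoint_years")

ATTRIBUTE_KINDS = ("categorical", "ordinal", "continuous", "identifier")


@dataclass
class AttributeMeta:
    """Metadata for one cohort attribute.

    kind
        ``categorical`` attributes are one-hot encoded, ``ordinal`` pass
        through as numeric ranks, ``continuous`` stay as-is, ``identifier``
        attributes (barcodes, visit numbers...) are always dropped before
        modelling.
    carry_forward
        The value cannot change in the future (e.g. a past-disease flag), so
        missing values are filled from the most recent earlier visit.
    default_value
        A reporting convention exists: a missing value means this default.
    """

    name: str
    kind: str = "continuous"
    carry_forward: bool = False
    default_value: object = None
    n_levels: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ATTRIBUTE_KINDS:
            raise ValueError(f"unknown attribute kind {self.kind!r} for {self.name!r}")


class Period(NamedTuple):
    """One learning instance: a >=2-year interval of one patient."""

    patient_id: object
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def id(self) -> str:
        return f"{self.patient_id}|{self.start:g}|{self.end:g}"


def enumerate_timepoint_pairs(
    timepoints: Iterable[float], min_years: float = 2.0, policy: str = "all_pairs"
) -> list[tuple[float, float]]:
    """Ordered visit pairs at least ``min_years`` apart.

    ``all_pairs`` takes every qualifying ordered pair; ``consecutive`` takes,
    for each start visit, only the earliest qualifying end visit.
    """
    ts = sorted(float(t) for t in timepoints)
    if policy == "all_pairs":
        return [(a, b) for i, a in enumerate(ts) for b in ts[i + 1:] if b - a >= min_years]
    if policy == "consecutive":
        pairs = []
        for i, a in enumerate(ts):
            for b in ts[i + 1:]:
                if b - a >= min_years:
                    pairs.append((a, b))
                    break
        return pairs
    raise ValueError(f"unknown period policy {policy!r}")


def save_metadata(meta: dict[str, AttributeMeta], path: str | Path) -> None:
    payload = {name: {k: v for k, v in asdict(m).items() if k != "name"}
               for name, m in meta.items()}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def load_metadata(path: str | Path) -> dict[str, AttributeMeta]:
    payload = yaml.safe_load(Path(path).read_text()) or {}
    return {name: AttributeMeta(name=name, **fields) for name, fields in payload.items()}


@dataclass
class CohortTable:
    """Longitudinal cohort: visits, knee replacements and attribute metadata.

    ``visits`` has one row per (patient_id, timepoint_years); all other
    columns are attributes.  ``replacements`` has columns (patient_id, knee,
    time_years) with at most one row per patient and knee.
    """

    visits: pd.DataFrame
    replacements: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["patient_id", "knee", "time_years"])
    )
    meta: dict[str, AttributeMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in KEY_COLUMNS:
            if col not in self.visits.columns:
                raise ValueError(f"visits table lacks required column {col!r}")
        dup = self.visits.duplicated(subset=list(KEY_COLUMNS))
        if dup.any():
            raise ValueError("visits table has duplicate (patient, timepoint) rows")

    # -- basic accessors ---------------------------------------------------
    @property
    def attribute_columns(self) -> list[str]:
        return [c for c in self.visits.columns if c not in KEY_COLUMNS]

    @property
    def covariate_columns(self) -> list[str]:
        """Attribute columns that are not raw outcome measurements."""
        return [c for c in self.attribute_columns if c not in OUTCOME_COLUMNS]

    def patients(self) -> list:
        return list(pd.unique(self.visits["patient_id"]))

    def patient_timepoints(self, patient_id) -> np.ndarray:
        t = self.visits.loc[self.visits["patient_id"] == patient_id, "timepoint_years"]
        return np.sort(t.to_numpy(dtype=float))

    def indexed_visits(self) -> pd.DataFrame:
        return self.visits.set_index(list(KEY_COLUMNS)).sort_index()

    def first_replacement(self, patient_id) -> float:
        """Earliest replacement time over both knees, +inf if none."""
        rows = self.replacements.loc[self.replacements["patient_id"] == patient_id]
        if rows.empty:
            return math.inf
        return float(rows["time_years"].min())

    # -- serialisation -----------------------------------------------------
    def to_long(self) -> pd.DataFrame:
        """Tidy long format: (patient_id, timepoint, variable, value)."""
        long = self.visits.melt(
            id_vars=list(KEY_COLUMNS), var_name="variable", value_name="value"
        )
        return long.rename(columns={"timepoint_years": "timepoint"})

    @classmethod
    def from_long(
        cls,
        long: pd.DataFrame,
        replacements: pd.DataFrame | None = None,
        meta: dict[str, AttributeMeta] | None = None,
    ) -> "CohortTable":
        wide = (
            long.pivot_table(
                index=["patient_id", "timepoint"],
                columns="variable",
                values="value",
                aggfunc="first",
            )
            .reset_index()
            .rename(columns={"timepoint": "timepoint_years"})
        )
        wide.columns.name = None
        if replacements is None:
            replacements = pd.DataFrame(columns=["patient_id", "knee", "time_years"])
        return cls(visits=wide, replacements=replacements, meta=meta or {})

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_long().to_csv(out / "cohort_long.csv", index=False)
        self.visits.to_csv(out / "cohort_wide.csv", index=False)
        self.replacements.to_csv(out / "replacements.csv", index=False)
        save_metadata(self.meta, out / "metadata.yaml")

    @classmethod
    def read(cls, in_dir: str | Path) -> "CohortTable":
        src = Path(in_dir)
        visits = pd.read_csv(src / "cohort_wide.csv")
        repl_path = src / "replacements.csv"
        replacements = (
            pd.read_csv(repl_path)
            if repl_path.exists()
            else pd.DataFrame(columns=["patient_id", "knee", "time_years"])
        )
        meta_path = src / "metadata.yaml"
        meta = load_metadata(meta_path) if meta_path.exists() else {}
        return cls(visits=visits, replacements=replacements, meta=meta)


def truth_to_frame(truth: dict[Period, str]) -> pd.DataFrame:
    rows = [
        {"patient_id": p.patient_id, "start": p.start, "end": p.end, "class": c}
        for p, c in truth.items()
    ]
    return pd.DataFrame(rows, columns=["patient_id", "start", "end", "class"])


def frame_to_truth(frame: pd.DataFrame) -> dict[Period, str]:
    return {
        Period(r.patient_id, float(r.start), float(r.end)): r[3]
        for r in frame.itertuples(index=False)
    }
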
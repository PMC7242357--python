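"""Simulated trial inclusion: conventional clinical criteria vs model-based
selection.

Three scenarios are compared on the same period instances:

* **conventional** -- a conjunction of (1) ACR-style clinical criteria (knee
  pain plus one of: age over 50, under 30 minutes of morning stiffness,
  crepitus, osteophytes), (2) a Kellgren-Lawrence grade between 1 and 3
  inclusive, and (3) WOMAC pain of at least 40; a patient qualifies if one
  of the knees satisfies them.
* **ML-L** -- select every instance predicted into a progressive class.
* **ML-P** -- probability-ranked, count-matched selection: three descending
  rankings by p(P)+p(S), p(S) and p(P) each contribute a third of the target
  count (earlier groups absorb the remainder and duplicates are skipped).

Reports mirror the per-class absolute/relative/recall layout used for
enrichment comparisons, with a summary recall over all progressive classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import CLASSES, CohortTable, Period


# ---------------------------------------------------------------------------
# conventional inclusion criteria
# ---------------------------------------------------------------------------

PROFILE_COLUMNS = [
    "age", "morning_stiffness_minutes",
    "knee_pain_left", "knee_pain_right",
    "crepitus_left", "crepitus_right",
    "osteophytes_left", "osteophytes_right",
    "kl_grade_left", "kl_grade_right",
    "womac_pain_left", "womac_pain_right",
]


def conventional_profiles(cohort: CohortTable, periods: list[Period]) -> pd.DataFrame:
    """Per-period screening profile taken at the period's start visit."""
    visits = cohort.indexed_visits()
    rows, index = [], []
    for p in periods:
        row = visits.loc[(p.patient_id, p.start)]
        rows.append({c: row.get(c, np.nan) for c in PROFILE_COLUMNS})
        index.append(p.id)
    return pd.DataFrame(rows, index=pd.Index(index, name="instance_id"))


def conventional_criteria(profiles: pd.DataFrame) -> pd.Series:
    """Boolean inclusion per instance; any missing component fails its clause."""
    age = pd.to_numeric(profiles.get("age"), errors="coerce")
    stiffness = pd.to_numeric(profiles.get("morning_stiffness_minutes"), errors="coerce")
    acr_extra_shared = (age > 50) | (stiffness < 30)

    selected = pd.Series(False, index=profiles.index)
    for knee in ("left", "right"):
        def col(name: str) -> pd.Series:
            return pd.to_numeric(profiles.get(f"{name}_{knee}"), errors="coerce")

        pain_flag = col("knee_pain").fillna(0) > 0
        acr = pain_flag & (acr_extra_shared
                           | (col("crepitus").fillna(0) > 0)
                           | (col("osteophytes").fillna(0) > 0))
        kl = col("kl_grade")
        kl_ok = (kl >= 1) & (kl <= 3)
        womac_ok = col("womac_pain") >= 40
        selected |= acr & kl_ok & womac_ok
    return selected


# ---------------------------------------------------------------------------
# model-based scenarios
# ---------------------------------------------------------------------------

def select_ml_l(predictions: pd.DataFrame) -> list:
    """All instances predicted into a progressive class (anything but N)."""
    mask = predictions["class"] != "N"
    return list(predictions.index[mask])


def select_ml_p(predictions: pd.DataFrame, n_target: int,
                duplicate_policy: str = "skip") -> list:
    """Probability-ranked selection of exactly ``n_target`` instances.

    Instances are ranked descending by p(P)+p(S), by p(S) and by p(P); each
    ranking fills a third of the target (remainder to the earlier groups, in
    that order).  With the default ``skip`` policy an instance already taken
    by an earlier group is skipped and the walk continues, so exactly
    ``n_target`` distinct instances return; the alternative ``count`` policy
    lets duplicates consume quota (total may fall short).  Ranking ties break
    by instance id.
    """
    n = len(predictions)
    if n_target > n:
        raise ValueError(f"n_target={n_target} exceeds {n} instances")
    keys = {
        "total": predictions["p_P"] + predictions["p_S"],
        "p_S": predictions["p_S"],
        "p_P": predictions["p_P"],
    }
    quotas = [n_target // 3] * 3
    for i in range(n_target % 3):
        quotas[i] += 1

    chosen: list = []
    taken = set()
    for (name, key), quota in zip(keys.items(), quotas):
        ranking = sorted(predictions.index,
                         key=lambda i: (-key.loc[i], str(i)))
        filled = 0
        for inst in ranking:
            if filled >= quota:
                break
            if inst in taken:
                if duplicate_policy == "count":
                    filled += 1
                continue
            taken.add(inst)
            chosen.append(inst)
            filled += 1
    return chosen


def median_model(scores: pd.DataFrame) -> tuple[int, int]:
    """The (repeat, seed) run whose pooled score sits at the median of
    per-repeat medians; distance ties resolve to the lowest seed, then
    repeat."""
    per_repeat = scores.groupby("repeat")["score"].median()
    target = float(per_repeat.median())
    ranked = scores.assign(dist=(scores["score"] - target).abs())
    row = ranked.sort_values(["dist", "seed", "repeat"]).iloc[0]
    return int(row["repeat"]), int(row["seed"])


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass
class SelectionReport:
    """Per-class counts, shares and recalls of one selection scenario."""

    table: pd.DataFrame        # class, total, selected, share_pct, recall_pct
    not_n_recall_pct: float
    n_selected: int
    empty: bool

    def to_dict(self) -> dict:
        return {
            "n_selected": self.n_selected,
            "classes": self.table.set_index("class").to_dict("index"),
            "not_n_recall_pct": self.not_n_recall_pct,
            "empty": self.empty,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def selection_report(selected, true_labels: pd.Series) -> SelectionReport:
    selected = list(selected)
    unknown = [i for i in selected if i not in true_labels.index]
    if unknown:
        raise ValueError(f"selected instances without labels: {unknown[:5]}")
    sel = true_labels.loc[selected]
    n_sel = len(sel)
    rows = []
    for cls in CLASSES:
        total = int((true_labels == cls).sum())
        count = int((sel == cls).sum())
        share = 100.0 * count / n_sel if n_sel else 0.0
        recall = 100.0 * count / total if total else 0.0
        rows.append({"class": cls, "total": total, "selected": count,
                     "share_pct": share, "recall_pct": recall})
    table = pd.DataFrame(rows)
    prog_total = int((true_labels != "N").sum())
    prog_sel = int((sel != "N").sum())
    not_n = 100.0 * prog_sel / prog_total if prog_total else 0.0
    return SelectionReport(table=table, not_n_recall_pct=not_n,
                           n_selected=n_sel, empty=n_sel == 0)
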
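"""Synthetic longitudinal knee-OA cohorts with known progression classes.

The real cohorts this pipeline targets are controlled-access, so every
downstream stage is exercised on generated data that mimics their shape:
per-knee WOMAC pain (0-100) and minimum joint-space width (mm) at irregular
visit grids, Kellgren-Lawrence grades, knee replacements, mixed-type
covariates and heavy missingness, with a class mix skewed towards
non-progressors.

Each patient is assigned a latent progression class and outcome trajectories
are drawn *backwards* from it: slopes and intercepts are sampled from regions
of trajectory space in which **every** enumerable >=2-year window satisfies
(or violates) the pain and structure criteria as the class requires, and each
draw is verified against the labeling module (rejection sampling, capped).
Applying :func:`oaprogress.labeling.label_periods` to the complete table
therefore recovers the latent class exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import labeling
from .data import (
    AttributeMeta,
    CLASSES,
    CohortTable,
    OUTCOME_COLUMNS,
    Period,
    enumerate_timepoint_pairs,
)

#: Named visit grids (years) mimicking the two cohort layouts.
TIMEPOINT_GRIDS = {
    "check": (0.0, 2.0, 5.0, 8.0),
    "oai": (0.0, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0),
}

#: Class mix of a large observational knee-OA cohort (N, P, S, P+S).
DEFAULT_PROPORTIONS = (0.63, 0.12, 0.20, 0.05)

_MAX_DRAWS = 1000


class InvalidSpecError(ValueError):
    """Raised for degenerate cohort specifications."""


class GenerationError(RuntimeError):
    """Raised when rejection sampling exhausts its draw budget."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort."""

    n_patients: int = 200
    timepoints: tuple[float, ...] = TIMEPOINT_GRIDS["check"]
    class_proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    n_informative_features: int = 8
    n_noise_features: int = 12
    signal_strength: float = 1.0
    missingness_rate: float = 0.0
    replacement_rate: float = 0.03
    jsw_baseline_mean: float = 4.5
    jsw_baseline_sd: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise InvalidSpecError("n_patients must be at least 1")
        ts = tuple(float(t) for t in self.timepoints)
        if len(ts) < 2:
            raise InvalidSpecError("at least 2 timepoints are required")
        if ts[0] != 0.0 or any(b <= a for a, b in zip(ts, ts[1:])):
            raise InvalidSpecError("timepoints must be strictly increasing and start at 0")
        props = np.asarray(self.class_proportions, dtype=float)
        if props.shape != (4,) or (props < 0).any():
            raise InvalidSpecError("class_proportions must be 4 non-negative numbers")
        if abs(props.sum() - 1.0) > 1e-9:
            raise InvalidSpecError("class_proportions must sum to 1")
        for name in ("missingness_rate", "replacement_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate < 1.0:
                raise InvalidSpecError(f"{name} must lie in [0, 1)")
        if self.signal_strength < 0:
            raise InvalidSpecError("signal_strength must be non-negative")
        if not enumerate_timepoint_pairs(ts):
            raise InvalidSpecError("no timepoint pair is at least 2 years apart")


@dataclass
class TruthMap:
    """Latent class per enumerable period of the generated cohort."""

    classes: dict[Period, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.classes)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"patient_id": p.patient_id, "start": p.start, "end": p.end, "class": c}
            for p, c in self.classes.items()
        ]
        return pd.DataFrame(rows, columns=["patient_id", "start", "end", "class"])


def latent_truth(truth: TruthMap, period: Period) -> str:
    try:
        return truth.classes[Period(period.patient_id, float(period.start), float(period.end))]
    except KeyError:
        raise LookupError(f"period {period} was not enumerated from the generated table")


# ---------------------------------------------------------------------------
# trajectory construction
# ---------------------------------------------------------------------------

def _earliest_window_end(ts: np.ndarray, min_years: float = 2.0) -> float:
    for t in ts[1:]:
        if t - ts[0] >= min_years:
            return float(t)
    return float(ts[-1])


def _pain_trajectory(rng: np.random.Generator, ts: np.ndarray, positive: bool) -> np.ndarray:
    """Driver-knee WOMAC pain at each visit, consistent with the target class
    on every >=2-year window."""
    t_max = float(ts[-1])
    t_e = _earliest_window_end(ts)
    if positive:
        if rng.random() < 0.5:
            # sustained substantial pain: every endpoint >= 43
            p = np.empty(len(ts))
            p[0] = rng.uniform(45.0, 80.0)
            for i in range(1, len(ts)):
                p[i] = np.clip(p[i - 1] + rng.normal(0.0, 5.0), 43.0, 95.0)
            return p
        # steadily rising pain: slope >= 5.5/yr and >= 41 at every window end
        a = rng.uniform(5.5, min(9.0, (98.0 - 41.0) / t_max))
        low = max(2.0, 41.0 - a * t_e)
        high = 98.0 - a * t_max
        p0 = rng.uniform(low, max(low + 1e-6, high))
        return np.clip(p0 + a * ts, 0.0, 100.0)
    if rng.random() < 0.7:
        # persistently low pain
        return rng.uniform(0.0, 30.0, size=len(ts))
    # "improver": substantial baseline pain fading below every pain threshold
    p0 = rng.uniform(41.0, 58.0)
    b_min = (p0 - 32.0) / t_e
    b = rng.uniform(b_min, b_min + 4.0)
    return np.maximum(0.0, p0 - b * ts)


def _jsw_trajectory(rng: np.random.Generator, ts: np.ndarray, narrowing: bool,
                    mean: float, sd: float) -> np.ndarray:
    t_max = float(ts[-1])
    if narrowing:
        rate = rng.uniform(0.35, 0.5)
        jsw0 = rng.uniform(rate * t_max + 0.6, rate * t_max + 2.2)
    else:
        rate = rng.uniform(0.0, 0.1)
        jsw0 = float(np.clip(rng.normal(mean, sd), 2.8, 6.5))
    return jsw0 - rate * ts


def _verify_patient(ts: np.ndarray, pain: dict[str, np.ndarray],
                    jsw: dict[str, np.ndarray], target: str,
                    min_years: float = 2.0) -> bool:
    """Check that every enumerable window of this patient labels as target."""
    idx = {t: i for i, t in enumerate(ts)}
    for a, b in enumerate_timepoint_pairs(ts, min_years):
        knees = {
            knee: {
                "pain_s": pain[knee][idx[a]], "pain_e": pain[knee][idx[b]],
                "jsw_s": jsw[knee][idx[a]], "jsw_e": jsw[knee][idx[b]],
            }
            for knee in ("left", "right")
        }
        outcome = labeling.resolve_knees(knees["left"], knees["right"], b - a)
        if not outcome.measurable:
            return False
        got = labeling.assign_label(
            labeling.is_pain_progressive(outcome),
            labeling.is_structure_progressive(outcome),
        ).class_
        if got != target:
            return False
    return True


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(spec: CohortSpec) -> tuple[CohortTable, TruthMap]:
    """Generate a complete (pre-missingness) cohort and its latent truth.

    Pure function of ``spec.seed``: the same spec yields bit-identical
    output.  Informative covariates are drawn from class-conditional
    distributions separated by ``signal_strength``; noise covariates are
    class-independent.
    """
    spec.validate()
    ts = np.asarray([float(t) for t in spec.timepoints])
    master = np.random.SeedSequence(spec.seed)
    rng_traj, rng_feat, rng_clin, rng_repl = (
        np.random.default_rng(s) for s in master.spawn(4)
    )

    classes = rng_traj.choice(len(CLASSES), size=spec.n_patients,
                              p=np.asarray(spec.class_proportions, dtype=float))

    n_inf_cat = spec.n_informative_features // 4
    n_inf_cont = spec.n_informative_features - n_inf_cat
    n_noise_cat = spec.n_noise_features // 4
    n_noise_cont = spec.n_noise_features - n_noise_cat
    # class-conditional feature geometry, fixed for the whole cohort
    cont_offsets = rng_feat.normal(0.0, 1.0, size=(n_inf_cont, 4))
    cat_preferred = rng_feat.integers(0, 3, size=(n_inf_cat, 4))

    rows: list[dict] = []
    repl_rows: list[dict] = []
    truth = TruthMap()

    for i in range(spec.n_patients):
        pid = f"P{i:05d}"
        c = int(classes[i])
        cls = CLASSES[c]
        p_pos = cls in ("P", "P+S")
        s_pos = cls in ("S", "P+S")
        driver = "left" if rng_traj.random() < 0.5 else "right"
        other = "right" if driver == "left" else "left"

        # knee replacement: exponential waiting time snapped up to the grid
        t_repl = math.inf
        if rng_repl.random() < spec.replacement_rate:
            raw = rng_repl.exponential(scale=0.5 * float(ts[-1]))
            later = [t for t in ts[1:] if t >= raw]
            if later:
                t_repl = float(later[0])
                repl_rows.append({
                    "patient_id": pid,
                    "knee": driver if rng_repl.random() < 0.7 else other,
                    "time_years": t_repl,
                })

        # rejection sampling of trajectories (margins make rejection rare)
        for attempt in range(_MAX_DRAWS):
            pain_d = np.clip(_pain_trajectory(rng_traj, ts, p_pos), 0.0, 100.0)
            pain_o = pain_d * rng_traj.uniform(0.4, 0.9, size=len(ts))
            jsw_d = _jsw_trajectory(rng_traj, ts, s_pos,
                                    spec.jsw_baseline_mean, spec.jsw_baseline_sd)
            jsw_o = _jsw_trajectory(rng_traj, ts, False,
                                    spec.jsw_baseline_mean, spec.jsw_baseline_sd)
            pain = {driver: pain_d, other: pain_o}
            jsw = {driver: jsw_d, other: jsw_o}
            if _verify_patient(ts, pain, jsw, cls):
                break
        else:
            raise GenerationError(
                f"could not realise class {cls} for patient {pid} "
                f"within {_MAX_DRAWS} draws"
            )

        for a, b in enumerate_timepoint_pairs(ts):
            if b < t_repl:
                truth.classes[Period(pid, a, b)] = cls

        # clinical covariates feeding the conventional inclusion criteria
        age0 = float(np.clip(rng_clin.normal(57.0, 5.0), 45.0, 75.0))
        stiffness = float(np.clip(
            rng_clin.gamma(2.0, (20.0 if cls != "N" else 32.0) / 2.0), 0.0, 120.0))
        crepitus = {k: float(rng_clin.random() < (0.6 if cls != "N" else 0.35))
                    for k in ("left", "right")}
        osteo = {k: float(rng_clin.random() < (0.55 if s_pos else 0.3))
                 for k in ("left", "right")}
        kl0 = {
            driver: int(rng_clin.choice([1, 2, 3, 4], p=[0.3, 0.35, 0.25, 0.1]))
            if s_pos else int(rng_clin.choice([0, 1, 2, 3], p=[0.25, 0.35, 0.3, 0.1])),
        }
        kl0[other] = max(0, kl0[driver] - int(rng_clin.random() < 0.5))
        kl_rate = 0.25 if s_pos else 0.08

        past_disease = float(rng_clin.random() < 0.3)
        rare_disorder = 1.0 if rng_clin.random() < 0.05 else math.nan

        inf_cont_patient = cont_offsets[:, c] * spec.signal_strength \
            + rng_feat.normal(0.0, 1.0, size=n_inf_cont)
        cat_probs = np.full((n_inf_cat, 3), 1.0)
        for f in range(n_inf_cat):
            cat_probs[f, cat_preferred[f, c]] = math.exp(spec.signal_strength)
        cat_probs /= cat_probs.sum(axis=1, keepdims=True)
        inf_cat_patient = np.array([
            rng_feat.choice(3, p=cat_probs[f]) for f in range(n_inf_cat)
        ], dtype=float)
        noise_cat_patient = rng_feat.integers(0, 3, size=n_noise_cat).astype(float)

        for j, t in enumerate(ts):
            measured = t < t_repl
            row = {
                "patient_id": pid,
                "timepoint_years": float(t),
                "womac_pain_left": pain["left"][j] if measured else math.nan,
                "womac_pain_right": pain["right"][j] if measured else math.nan,
                "min_jsw_left": jsw["left"][j] if measured else math.nan,
                "min_jsw_right": jsw["right"][j] if measured else math.nan,
                "kl_grade_left": min(4, kl0["left"] + int(kl_rate * t)),
                "kl_grade_right": min(4, kl0["right"] + int(kl_rate * t)),
                "age": age0 + t,
                "morning_stiffness_minutes": stiffness,
                "crepitus_left": crepitus["left"],
                "crepitus_right": crepitus["right"],
                "osteophytes_left": osteo["left"],
                "osteophytes_right": osteo["right"],
                "knee_pain_left": float(pain["left"][j] >= 5.0) if measured else math.nan,
                "knee_pain_right": float(pain["right"][j] >= 5.0) if measured else math.nan,
                "past_disease": past_disease if j == 0 else math.nan,
                "rare_disorder": rare_disorder,
                "visit_number": float(j),
                "visit_barcode": f"BC{i:05d}{j:02d}",
            }
            for f in range(n_inf_cont):
                row[f"inf_c{f:02d}"] = inf_cont_patient[f] + rng_feat.normal(0.0, 0.2)
            for f in range(n_inf_cat):
                row[f"inf_k{f:02d}"] = inf_cat_patient[f]
            for f in range(n_noise_cont):
                row[f"noise_c{f:02d}"] = rng_feat.normal(0.0, 1.0)
            for f in range(n_noise_cat):
                row[f"noise_k{f:02d}"] = noise_cat_patient[f]
            rows.append(row)

    visits = pd.DataFrame(rows)
    replacements = pd.DataFrame(repl_rows, columns=["patient_id", "knee", "time_years"])
    meta = _build_metadata(visits.columns, n_inf_cont, n_inf_cat,
                           n_noise_cont, n_noise_cat)
    return CohortTable(visits=visits, replacements=replacements, meta=meta), truth


def _build_metadata(columns, n_inf_cont, n_inf_cat, n_noise_cont, n_noise_cat):
    meta: dict[str, AttributeMeta] = {}

    def add(name, **kw):
        if name in columns:
            meta[name] = AttributeMeta(name=name, **kw)

    for col in OUTCOME_COLUMNS:
        add(col, kind="continuous")
    for knee in ("left", "right"):
        add(f"kl_grade_{knee}", kind="ordinal", n_levels=5)
        add(f"crepitus_{knee}", kind="categorical", n_levels=2)
        add(f"osteophytes_{knee}", kind="categorical", n_levels=2)
        add(f"knee_pain_{knee}", kind="categorical", n_levels=2)
    add("age", kind="continuous")
    add("morning_stiffness_minutes", kind="continuous")
    add("past_disease", kind="categorical", n_levels=2, carry_forward=True)
    add("rare_disorder", kind="categorical", n_levels=2, default_value=0.0)
    add("visit_number", kind="identifier")
    add("visit_barcode", kind="identifier")
    for f in range(n_inf_cont):
        add(f"inf_c{f:02d}", kind="continuous")
    for f in range(n_inf_cat):
        add(f"inf_k{f:02d}", kind="categorical", n_levels=3)
    for f in range(n_noise_cont):
        add(f"noise_c{f:02d}", kind="continuous")
    for f in range(n_noise_cat):
        add(f"noise_k{f:02d}", kind="categorical", n_levels=3)
    return meta


def inject_missingness(table: CohortTable, rate: float, seed: int,
                       outcome_rate: float = 0.0) -> CohortTable:
    """Mask covariate cells missing completely at random at ``rate``.

    Outcome cells (pain/JSW) are only masked via the separate
    ``outcome_rate`` knob (default 0), so labeling stays unaffected.
    Identifier attributes are never masked.  Deterministic given ``seed``.
    """
    if not 0.0 <= rate < 1.0 or not 0.0 <= outcome_rate < 1.0:
        raise ValueError("missingness rates must lie in [0, 1)")
    visits = table.visits.copy()
    rng = np.random.default_rng(seed)
    identifier_cols = {name for name, m in table.meta.items() if m.kind == "identifier"}
    covariates = [c for c in table.covariate_columns if c not in identifier_cols]
    if rate > 0 and covariates:
        mask = rng.random((len(visits), len(covariates))) < rate
        for j, col in enumerate(covariates):
            visits.loc[mask[:, j], col] = np.nan
    if outcome_rate > 0:
        cols = list(OUTCOME_COLUMNS)
        mask = rng.random((len(visits), len(cols))) < outcome_rate
        for j, col in enumerate(cols):
            visits.loc[mask[:, j], col] = np.nan
    return replace(table, visits=visits)
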
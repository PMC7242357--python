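"""Independent oracles and toy-data builders shared by the test suite."""

import numpy as np
import pandas as pd

CLASS_NAMES = np.array(["N", "P", "S", "P+S"], dtype=object)
IMBALANCED_PROPS = (0.63, 0.12, 0.20, 0.05)


def confusion_f1(y_true, y_pred) -> float:
    """Hand-rolled weighted F1 via explicit per-class precision/recall.

    Deliberately independent of the package implementation: python loops
    over an explicit confusion dictionary.
    """
    y_true, y_pred = list(y_true), list(y_pred)
    classes = sorted(set(y_true), key=str)
    n = len(y_true)
    score = 0.0
    for c in classes:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall else 0.0)
        score += (tp + fn) / n * f1
    return score


def gaussian_dataset(n: int, seed: int, separation: float = 1.2,
                     n_features: int = 6, props=IMBALANCED_PROPS):
    """Class-conditional Gaussian features with no patient structure."""
    rng = np.random.default_rng(seed)
    y_idx = rng.choice(4, size=n, p=np.asarray(props))
    centers = rng.normal(0.0, 1.0, (4, n_features)) * separation
    X = centers[y_idx] + rng.normal(0.0, 1.0, (n, n_features))
    X = pd.DataFrame(X, columns=[f"f{i}" for i in range(n_features)])
    return X, pd.Series(CLASS_NAMES[y_idx], index=X.index)


def one_hot_dataset(n: int, seed: int):
    """Trivially separable data: features are the one-hot of the class."""
    rng = np.random.default_rng(seed)
    y_idx = rng.choice(4, size=n, p=np.asarray(IMBALANCED_PROPS))
    X = pd.DataFrame(np.eye(4)[y_idx], columns=[f"ind{i}" for i in range(4)])
    return X, pd.Series(CLASS_NAMES[y_idx], index=X.index)


def patient_level_features(cohort, truth):
    """Baseline-visit informative/noise features with one row per patient."""
    base = cohort.visits[cohort.visits.timepoint_years == 0].set_index("patient_id")
    feat_cols = [c for c in base.columns if c.startswith(("inf_", "noise_"))]
    pat_cls = {p.patient_id: c for p, c in truth.classes.items()}
    ids = [i for i in base.index if i in pat_cls]
    X = base.loc[ids, feat_cols]
    y = pd.Series([pat_cls[i] for i in ids], index=ids)
    return X, y
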
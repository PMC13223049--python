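"""Classifier evaluation: confusion matrices, per-class metrics, and the
leakage-inflation harness.

Confusion matrices follow the convention rows = truth (F, M), columns =
predicted (F, M), with raw frame counts. Undefined ratios (empty row or
column) are reported as NaN with a flag, never silently coerced to 0.

`leakage_inflation_experiment` quantifies why frame-level random splitting
is invalid for multi-frame-per-animal data: frames of one animal are
correlated, so a model scored on held-out frames of *seen* animals looks far
better than one scored on unseen animals.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import rng_for
from .partition import individual_keys

LABELS = ("F", "M")


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts; rows truth (F, M), columns predicted (F, M)."""

    f_as_f: int
    f_as_m: int
    m_as_f: int
    m_as_m: int

    def __post_init__(self):
        if min(self.f_as_f, self.f_as_m, self.m_as_f, self.m_as_m) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.f_as_f + self.f_as_m + self.m_as_f + self.m_as_m

    def as_array(self) -> np.ndarray:
        return np.array([[self.f_as_f, self.f_as_m], [self.m_as_f, self.m_as_m]])


def confusion(truth, predicted) -> ConfusionMatrix:
    """Exact integer confusion counts for labels in {F, M}."""
    t = np.asarray(truth)
    p = np.asarray(predicted)
    if t.shape != p.shape:
        raise ValueError("truth and predicted must have equal length")
    for arr, name in ((t, "truth"), (p, "predicted")):
        bad = set(np.unique(arr)) - set(LABELS)
        if bad:
            raise ValueError(f"{name} contains labels outside {LABELS}: {bad}")
    return ConfusionMatrix(
        f_as_f=int(((t == "F") & (p == "F")).sum()),
        f_as_m=int(((t == "F") & (p == "M")).sum()),
        m_as_f=int(((t == "M") & (p == "F")).sum()),
        m_as_m=int(((t == "M") & (p == "M")).sum()),
    )


@dataclass
class EvalReport:
    """Accuracy plus per-class precision/recall/F1 for one split."""

    split: str
    matrix: ConfusionMatrix
    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    undefined: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def clean(d):
            return {k: (None if math.isnan(v) else v) for k, v in d.items()}

        return {
            "split": self.split,
            "confusion": self.matrix.as_array().tolist(),
            "accuracy": self.accuracy,
            "precision": clean(self.precision),
            "recall": clean(self.recall),
            "f1": clean(self.f1),
            "undefined": self.undefined,
        }

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def metrics_from_confusion(cm: ConfusionMatrix, split: str = "") -> EvalReport:
    """Accuracy and per-class precision/recall/F1 from raw counts."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    a = cm.as_array()
    accuracy = float(np.trace(a) / cm.total)
    precision, recall, f1 = {}, {}, {}
    undefined = []

    def ratio(num, den, what):
        if den == 0:
            undefined.append(what)
            return float("nan")
        return num / den

    for i, c in enumerate(LABELS):
        precision[c] = ratio(a[i, i], a[:, i].sum(), f"precision_{c}")
        recall[c] = ratio(a[i, i], a[i, :].sum(), f"recall_{c}")
        pr, rc = precision[c], recall[c]
        if math.isnan(pr) or math.isnan(rc) or (pr + rc) == 0:
            undefined.append(f"f1_{c}")
            f1[c] = float("nan")
        else:
            f1[c] = 2 * pr * rc / (pr + rc)
    return EvalReport(split, cm, accuracy, precision, recall, f1, undefined)


def evaluate_predictions(truth, predicted, split: str = "") -> EvalReport:
    return metrics_from_confusion(confusion(truth, predicted), split)


def plot_confusion(cm: ConfusionMatrix, path: str | os.PathLike, title: str = "") -> None:
    """Annotated heatmap of the confusion counts."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a = cm.as_array()
    fig, ax = plt.subplots(figsize=(3.2, 3.0))
    row_frac = a / np.maximum(a.sum(axis=1, keepdims=True), 1)
    ax.imshow(row_frac, cmap="Blues", vmin=0, vmax=1)
    for i in range(2):
        for j in range(2):
            ax.text(j, i, str(a[i, j]), ha="center", va="center",
                    color="white" if row_frac[i, j] > 0.5 else "black")
    ax.set_xticks([0, 1], [f"pred {c}" for c in LABELS])
    ax.set_yticks([0, 1], [f"true {c}" for c in LABELS])
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# leakage-inflation harness


@dataclass
class LeakageComparison:
    """Held-out accuracy under frame-level vs individual-level splitting."""

    frame_level_accuracies: list[float]
    individual_level_accuracies: list[float]
    n_holdout_frames: list[int]
    n_holdout_individuals: list[int]

    @property
    def frame_level_mean(self) -> float:
        return float(np.mean(self.frame_level_accuracies))

    @property
    def individual_level_mean(self) -> float:
        return float(np.mean(self.individual_level_accuracies))

    @property
    def inflation_gap(self) -> float:
        return self.frame_level_mean - self.individual_level_mean


def leakage_inflation_experiment(
    images: list[np.ndarray],
    manifest: pd.DataFrame,
    model_builder,
    n_seeds: int = 5,
    holdout_frac: float = 0.2,
    seed: int = 0,
) -> LeakageComparison:
    """Train twin models per seed on (i) a frame-level random split and (ii)
    an individual-level split of matched holdout size; score each on its own
    holdout.

    ``model_builder()`` must return an estimator with ``fit(X, y)`` and
    ``predict(X)`` over flattened image rows and labels in {F, M}.
    Requires multiple frames per individual (otherwise the two strategies
    coincide and there is nothing to measure).
    """
    keys = individual_keys(manifest)
    frames_per_ind = keys.value_counts()
    if (frames_per_ind < 2).all():
        raise ValueError("need individuals with >= 2 frames for leakage to be possible")
    X = np.stack([np.asarray(i, dtype=float).ravel() for i in images])
    y = manifest["sex"].to_numpy()
    n = len(y)
    uniq = sorted(frames_per_ind.index)
    fl_acc, il_acc, nf, ni = [], [], [], []
    for s in range(n_seeds):
        rng = rng_for(seed, "leakage", s)
        # (i) frame-level random split
        n_hold = max(2, int(round(holdout_frac * n)))
        perm = rng.permutation(n)
        hold, tr = perm[:n_hold], perm[n_hold:]
        m1 = model_builder()
        m1.fit(X[tr], y[tr])
        fl_acc.append(float((m1.predict(X[hold]) == y[hold]).mean()))
        # (ii) individual-level split with matched holdout frame count
        order = rng.permutation(len(uniq))
        hold_keys, count = [], 0
        for idx in order:
            if count >= n_hold:
                break
            hold_keys.append(uniq[idx])
            count += int(frames_per_ind[uniq[idx]])
        hold_mask = keys.isin(hold_keys).to_numpy()
        m2 = model_builder()
        m2.fit(X[~hold_mask], y[~hold_mask])
        il_acc.append(float((m2.predict(X[hold_mask]) == y[hold_mask]).mean()))
        nf.append(n_hold)
        ni.append(len(hold_keys))
    return LeakageComparison(fl_acc, il_acc, nf, ni)
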
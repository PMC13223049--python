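"""Linear baseline: flattened pixels -> standardize -> PCA -> logistic regression.

Each frame is resized to 64x64 grayscale and flattened to a 4,096-dimensional
vector. Per-feature standardization statistics and the PCA basis are fitted on
the training partition only; a regularized logistic classifier with inverse
class-frequency loss weights is grid-searched over (C, penalty, solver,
n_components) and selected by balanced accuracy — the mean of per-class
recalls — on the validation partition. The test partition is never touched
during the search. Class convention: F=0, M=1 (alphabetical); the decision
threshold is 0.5 on the M probability.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from sklearn.decomposition import PCA
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

FLAT_SIZE = (64, 64)
N_FEATURES = FLAT_SIZE[0] * FLAT_SIZE[1]
CLASSES = ("F", "M")  # F=0, M=1

DEFAULT_C_VALUES = (0.001, 0.01, 0.1, 0.5, 1.0, 3.0, 5.0, 7.0, 10.0, 15.0, 20.0, 50.0, 100.0)
DEFAULT_PCA_COMPONENTS = (5, 10, 20, 30, 50, 75, 100)


@dataclass(frozen=True)
class GridSpec:
    """The hyperparameter grid for the baseline search."""

    C_values: tuple[float, ...] = DEFAULT_C_VALUES
    penalties: tuple[str, ...] = ("l1", "l2")
    solvers: tuple[str, ...] = ("liblinear", "saga")
    pca_components: tuple[int, ...] = DEFAULT_PCA_COMPONENTS

    def __post_init__(self):
        if any(c <= 0 for c in self.C_values):
            raise ValueError("C values must be positive")
        if any(k <= 0 for k in self.pca_components):
            raise ValueError("PCA component counts must be positive")

    @property
    def n_candidates(self) -> int:
        """Cartesian grid size before penalty/solver validity filtering."""
        return len(self.C_values) * len(self.penalties) * len(self.solvers) * len(self.pca_components)


def _solver_supports(solver: str, penalty: str) -> bool:
    supported = {
        "liblinear": {"l1", "l2"},
        "saga": {"l1", "l2"},
        "lbfgs": {"l2"},
        "newton-cg": {"l2"},
        "sag": {"l2"},
    }
    return penalty in supported.get(solver, set())


def flatten_features(images: list[np.ndarray]) -> np.ndarray:
    """Resize each image to 64x64 grayscale (bilinear) and flatten row-major."""
    if len(images) == 0:
        raise ValueError("empty image list")
    rows = []
    for img in images:
        pim = Image.fromarray(np.asarray(img))
        if pim.mode != "L":
            pim = pim.convert("L")
        if pim.size != (FLAT_SIZE[1], FLAT_SIZE[0]):
            pim = pim.resize((FLAT_SIZE[1], FLAT_SIZE[0]), Image.BILINEAR)
        rows.append(np.asarray(pim, dtype=float).ravel())
    return np.vstack(rows)


@dataclass
class PCAResult:
    """Fitted PCA basis plus its explained-variance bookkeeping."""

    pca: PCA
    requested_k: int

    @property
    def k(self) -> int:
        return int(self.pca.n_components_)

    @property
    def components(self) -> np.ndarray:
        return self.pca.components_

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.pca.explained_variance_ratio_

    @property
    def cumulative_variance(self) -> np.ndarray:
        return np.cumsum(self.explained_variance_ratio)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self.pca.transform(X)


def fit_pca(train_matrix: np.ndarray, k: int, seed: int = 0) -> PCAResult:
    """Fit a k-component PCA on (standardized) training features.

    If k exceeds what the data can support, the basis is reduced with a
    warning rather than failing.
    """
    n, d = train_matrix.shape
    k_eff = min(k, n, d)
    if k_eff < k:
        warnings.warn(f"reducing PCA components from {k} to {k_eff} (limited by data)", stacklevel=2)
    pca = PCA(n_components=k_eff, random_state=seed)
    pca.fit(train_matrix)
    return PCAResult(pca, requested_k=k)


def _encode(labels) -> np.ndarray:
    labels = np.asarray(labels)
    bad = set(np.unique(labels)) - set(CLASSES)
    if bad:
        raise ValueError(f"labels outside {CLASSES}: {bad}")
    return (labels == "M").astype(int)


def balanced_accuracy(truth, predicted) -> float:
    """Mean of per-class recalls over the classes present in ``truth``.

    Errors if either class F or M is absent from ``truth``.
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError("truth and predictions must have equal length")
    recalls = []
    for c in CLASSES:
        m = truth == c
        if not m.any():
            raise ValueError(f"class {c!r} absent from truth; balanced accuracy undefined")
        recalls.append(float((predicted[m] == c).mean()))
    return float(np.mean(recalls))


@dataclass
class BaselineModel:
    """A fitted baseline: train-only standardizer + PCA + logistic classifier."""

    scaler: StandardScaler
    pca: PCAResult
    classifier: LogisticRegression
    hyperparameters: dict
    val_balanced_accuracy: float
    n_evaluated: int = 0
    n_skipped: int = 0

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self.pca.transform(self.scaler.transform(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Labels in {F, M} from raw (flattened, unstandardized) features."""
        scores = self.predict_proba_m(X)
        return np.where(scores >= 0.5, "M", "F")

    def predict_proba_m(self, X: np.ndarray) -> np.ndarray:
        return self.classifier.predict_proba(self.transform(X))[:, 1]


def grid_search_baseline(
    X_train: np.ndarray,
    y_train,
    X_val: np.ndarray,
    y_val,
    grid: GridSpec | None = None,
    seed: int = 0,
) -> BaselineModel:
    """Exhaustive grid search selected by validation balanced accuracy.

    Standardizer and PCA are fitted on the training features only (one PCA
    per component count, shared across C/penalty/solver). Invalid
    penalty/solver pairs are skipped and logged. Ties break toward parsimony:
    smaller k, then smaller C, then L2 before L1.
    """
    grid = grid or GridSpec()
    if grid.n_candidates == 0:
        raise ValueError("empty grid")
    y_tr = _encode(y_train)
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training labels are single-class; nothing to fit")
    y_val = np.asarray(y_val)

    scaler = StandardScaler().fit(X_train)
    Xt = scaler.transform(X_train)
    Xv = scaler.transform(X_val)

    best = None  # (score, -tiebreak...) via ordered iteration + strict improvement
    n_eval = n_skip = 0
    for k in sorted(grid.pca_components):
        pca = fit_pca(Xt, k, seed=seed)
        Zt, Zv = pca.transform(Xt), pca.transform(Xv)
        for C in sorted(grid.C_values):
            for penalty in sorted(grid.penalties, reverse=True):  # l2 before l1
                for solver in sorted(grid.solvers):
                    if not _solver_supports(solver, penalty):
                        logger.info("skipping invalid pair solver=%s penalty=%s", solver, penalty)
                        n_skip += 1
                        continue
                    clf = LogisticRegression(
                        C=C,
                        l1_ratio=1.0 if penalty == "l1" else 0.0,
                        solver=solver,
                        class_weight="balanced",
                        max_iter=5000,
                        tol=1e-4,
                        random_state=seed,
                    )
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", ConvergenceWarning)
                        clf.fit(Zt, y_tr)
                    pred = np.where(clf.predict_proba(Zv)[:, 1] >= 0.5, "M", "F")
                    score = balanced_accuracy(y_val, pred)
                    n_eval += 1
                    if best is None or score > best[0]:
                        best = (
                            score,
                            BaselineModel(
                                scaler,
                                pca,
                                clf,
                                {"C": C, "penalty": penalty, "solver": solver, "n_components": k},
                                score,
                            ),
                        )
    model = best[1]
    model.n_evaluated = n_eval
    model.n_skipped = n_skip
    return model
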
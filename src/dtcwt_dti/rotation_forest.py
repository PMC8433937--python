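"""Rotation Forest: a tree ensemble over per-subset PCA rotations.

Each of the L ensemble members is built as follows.  The F features are
randomly permuted and split into K contiguous subsets (the first F mod K
subsets take one extra feature).  For every subset, a random non-empty
group of classes is chosen (each class kept with probability
``class_subset_prob``), a subsample of ``bootstrap_frac`` of those
classes' rows is drawn without replacement (so a fraction of 1 means
the full class sample), and PCA is run on that sample restricted to the
subset's features with *all* component loadings kept.  The loadings form
the diagonal blocks of a sparse F x F rotation matrix — orthonormal, so
the rotation changes the coordinate system but loses nothing — and one
CART decision tree is fitted on the fully rotated training matrix.
Prediction averages the member trees' class-confidence vectors on each
member's own rotation of the query rows.

The per-subset randomisation decorrelates the members while each member
still sees every feature, which is what gives the ensemble its
diversity/accuracy balance.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.tree import DecisionTreeClassifier

__all__ = ["RoFConfig", "RotationSpec", "RotationForestClassifier"]

_FORMAT_VERSION = 1


@dataclass(frozen=True)
class RoFConfig:
    """Ensemble hyper-parameters.

    ``n_subsets`` (K) and ``n_trees`` (L) default to the grid-search
    optimum K=30, L=17; ``class_subset_prob`` and ``bootstrap_frac``
    follow Rodriguez's published protocol (0.5 and 0.75).
    """

    n_subsets: int = 30
    n_trees: int = 17
    class_subset_prob: float = 0.5
    bootstrap_frac: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subsets < 1 or self.n_trees < 1:
            raise ValueError("n_subsets and n_trees must be positive")
        if not 0 < self.class_subset_prob <= 1:
            raise ValueError("class_subset_prob must be in (0, 1]")
        if not 0 < self.bootstrap_frac <= 1:
            raise ValueError("bootstrap_frac must be in (0, 1]")


@dataclass
class RotationSpec:
    """One member's feature permutation and block-diagonal rotation."""

    permutation: np.ndarray
    block_sizes: list[int]
    blocks: list[np.ndarray] = field(repr=False)

    def rotation_matrix(self) -> np.ndarray:
        """Assemble the full F x F rotation in original feature order."""
        F = self.permutation.size
        R = np.zeros((F, F))
        col = 0
        for size, block in zip(self.block_sizes, self.blocks):
            rows = self.permutation[col:col + size]
            R[rows, col:col + size] = block
            col += size
        return R

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Rotate rows of X (equals ``X @ rotation_matrix()``)."""
        pieces = []
        col = 0
        for size, block in zip(self.block_sizes, self.blocks):
            idx = self.permutation[col:col + size]
            pieces.append(X[:, idx] @ block)
            col += size
        return np.hstack(pieces)


def _subset_sizes(n_features: int, k: int) -> list[int]:
    base, extra = divmod(n_features, k)
    return [base + 1] * extra + [base] * (k - extra)


def _pca_basis(sample: np.ndarray) -> np.ndarray:
    """Full orthonormal loading matrix (columns = components by decreasing
    variance); a rank-deficient sample is completed by the remaining
    right-singular vectors, keeping the block square and orthonormal."""
    centered = sample - sample.mean(axis=0, keepdims=True)
    _, _, vt = np.linalg.svd(centered, full_matrices=True)
    d = sample.shape[1]
    if vt.shape[0] < d:  # fewer rows than features: svd still yields full V
        raise AssertionError("full_matrices SVD must return a square V")
    return vt.T


class RotationForestClassifier:
    """Binary Rotation Forest with scikit-learn-style fit/predict."""

    def __init__(self, config: RoFConfig | None = None, **kwargs):
        self.config = config or RoFConfig(**kwargs)
        self.members_: list[tuple[RotationSpec, DecisionTreeClassifier]] = []
        self.classes_: np.ndarray | None = None
        self.n_features_: int | None = None

    # -- training ----------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RotationForestClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        if X.shape[0] < 4:
            raise ValueError("need at least 4 training rows")
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training labels contain a single class")
        cfg = self.config
        F = X.shape[1]
        if cfg.n_subsets > F:
            raise ValueError(f"n_subsets K={cfg.n_subsets} exceeds feature count F={F}")
        self.classes_ = classes
        self.n_features_ = F

        seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_trees)
        self.members_ = []
        for child in seeds:
            rng = np.random.default_rng(child)
            spec = self._draw_rotation(X, y, classes, rng)
            tree_seed = int(rng.integers(0, 2 ** 31 - 1))
            tree = DecisionTreeClassifier(criterion="gini", random_state=tree_seed)
            tree.fit(spec.apply(X), y)
            self.members_.append((spec, tree))
        return self

    def _draw_rotation(self, X: np.ndarray, y: np.ndarray, classes: np.ndarray,
                       rng: np.random.Generator) -> RotationSpec:
        cfg = self.config
        F = X.shape[1]
        permutation = rng.permutation(F)
        sizes = _subset_sizes(F, cfg.n_subsets)
        blocks: list[np.ndarray] = []
        col = 0
        for size in sizes:
            feat_idx = permutation[col:col + size]
            while True:   # non-empty random class subset
                keep = rng.random(classes.size) < cfg.class_subset_prob
                if keep.any():
                    break
            row_pool = np.flatnonzero(np.isin(y, classes[keep]))
            n_draw = max(1, round(cfg.bootstrap_frac * row_pool.size))
            sample_rows = rng.choice(row_pool, size=n_draw, replace=False)
            blocks.append(_pca_basis(X[np.ix_(sample_rows, feat_idx)]))
            col += size
        return RotationSpec(permutation=permutation, block_sizes=sizes, blocks=blocks)

    # -- inference ---------------------------------------------------------

    def _check_fitted(self, X: np.ndarray) -> np.ndarray:
        if self.classes_ is None:
            raise RuntimeError("classifier is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_:
            raise ValueError(
                f"X must have {self.n_features_} features, got shape {X.shape}"
            )
        return X

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Average of member confidences on each member's rotated view."""
        X = self._check_fitted(X)
        total = np.zeros((X.shape[0], self.classes_.size))
        for spec, tree in self.members_:
            proba = tree.predict_proba(spec.apply(X))
            cols = np.searchsorted(self.classes_, tree.classes_)
            total[:, cols] += proba
        return total / len(self.members_)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Most-confident class; exact ties go to the first (negative) class."""
        proba = self.predict_proba(X)
        best = np.zeros(proba.shape[0], dtype=int)
        for j in range(1, proba.shape[1]):
            best = np.where(proba[:, j] > proba[np.arange(len(best)), best], j, best)
        return self.classes_[best]

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Confidence for the positive (last) class, for ROC analysis."""
        return self.predict_proba(X)[:, -1]

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        payload = {
            "format": "dtcwt-dti-rotation-forest",
            "format_version": _FORMAT_VERSION,
            "config": self.config,
            "classes": self.classes_,
            "n_features": self.n_features_,
            "members": self.members_,
        }
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @classmethod
    def load(cls, path: str | Path) -> "RotationForestClassifier":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("format") != "dtcwt-dti-rotation-forest":
            raise ValueError(f"{path} is not a rotation-forest archive")
        if payload.get("format_version") != _FORMAT_VERSION:
            raise ValueError(f"unsupported archive version {payload.get('format_version')}")
        model = cls(payload["config"])
        model.classes_ = payload["classes"]
        model.n_features_ = payload["n_features"]
        model.members_ = payload["members"]
        return model
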
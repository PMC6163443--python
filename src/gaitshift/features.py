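"""Per-subject standardization + PCA feature reduction of cycle matrices.

Each subject's combined baseline cycles are standardized column-wise (mean 0,
population SD 1) and decomposed by PCA; the smallest number of leading
components whose cumulative explained variance reaches the threshold
(default 95%) is retained.  Post-intervention cycles are projected with the
frozen baseline constants (mean, SD, loadings) — never re-fit — so their
scores live in the same coordinate system as the baseline scores.

The reducer follows the scikit-learn estimator contract (``fit``,
``transform``, ``get_params``; fitted attributes end in an underscore) and
composes with sklearn pipelines.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .segment import CycleMatrix


class CycleFeatureReducer(BaseEstimator, TransformerMixin):
    """Standardize cycle vectors and retain PCs explaining ≥ ``variance_threshold``.

    Parameters
    ----------
    variance_threshold : float in (0, 1]
        Minimum cumulative fraction of total variance the retained
        components must explain (minimal such count is kept).

    Attributes
    ----------
    mean_, scale_ : (n_features,) arrays
        Column means and population SDs of the fit data.  Zero-variance
        columns get scale 1 and standardized value 0, and are excluded
        from variance accounting.
    components_ : (n_components_, n_features) array
        Orthonormal PC loadings, ordered by decreasing variance, with a
        deterministic sign convention (largest-|loading| entry positive).
    explained_variance_ratio_ : (n_components_,) array
        Fraction of total variance per retained component.
    n_components_ : int
    """

    def __init__(self, variance_threshold: float = 0.95):
        self.variance_threshold = variance_threshold

    def fit(self, X, y=None):
        if not (0 < self.variance_threshold <= 1):
            raise ValueError("variance_threshold must lie in (0, 1]")
        X = self._matrix(X)
        m = X.shape[0]
        if m < 2:
            raise ValueError("need at least 2 cycles to fit the reducer")
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)  # population SD (divisor m)
        # constant columns can carry ~eps-level SD from float summation
        self.zero_variance_mask_ = sd <= 1e-10 * np.maximum(1.0, np.abs(self.mean_))
        self.scale_ = np.where(self.zero_variance_mask_, 1.0, sd)
        Z = (X - self.mean_) / self.scale_
        Z[:, self.zero_variance_mask_] = 0.0

        # SVD of the standardized matrix; rank ≤ m−1 because columns are centered
        _, s, Vt = np.linalg.svd(Z, full_matrices=False)
        var = s ** 2
        total = var.sum()
        ratios = var / total
        cum = np.cumsum(ratios)
        k = int(np.searchsorted(cum, self.variance_threshold - 1e-12) + 1)
        k = min(k, len(ratios))

        comps = Vt[:k]
        # deterministic sign: make each component's largest-|loading| entry positive
        flip = np.sign(comps[np.arange(k), np.argmax(np.abs(comps), axis=1)])
        comps = comps * flip[:, None]
        self.components_ = comps
        self.explained_variance_ratio_ = ratios[:k]
        self.singular_values_ = s[:k]
        self.n_components_ = k
        self.n_features_in_ = X.shape[1]
        self.n_samples_fit_ = m
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "components_")
        X = self._matrix(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"layout mismatch: expected {self.n_features_in_} columns, got {X.shape[1]}")
        Z = (X - self.mean_) / self.scale_
        Z[:, self.zero_variance_mask_] = 0.0
        return Z @ self.components_.T

    @staticmethod
    def _matrix(X) -> np.ndarray:
        if isinstance(X, CycleMatrix):
            return X.X
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        return X

    # -- persistence (plain-text bundle so models can be audited) -----------

    def save(self, path: str | Path) -> Path:
        check_is_fitted(self, "components_")
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savetxt(path / "mean.txt", self.mean_)
        np.savetxt(path / "scale.txt", self.scale_)
        np.savetxt(path / "components.txt", self.components_)
        meta = {
            "variance_threshold": self.variance_threshold,
            "explained_variance_ratio": self.explained_variance_ratio_.tolist(),
            "singular_values": self.singular_values_.tolist(),
            "n_components": self.n_components_,
            "n_features_in": self.n_features_in_,
            "n_samples_fit": self.n_samples_fit_,
            "zero_variance_columns": np.nonzero(self.zero_variance_mask_)[0].tolist(),
        }
        (path / "meta.json").write_text(json.dumps(meta, indent=1))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "CycleFeatureReducer":
        path = Path(path)
        meta = json.loads((path / "meta.json").read_text())
        est = cls(variance_threshold=meta["variance_threshold"])
        est.mean_ = np.loadtxt(path / "mean.txt")
        est.scale_ = np.loadtxt(path / "scale.txt")
        est.components_ = np.loadtxt(path / "components.txt", ndmin=2)
        est.explained_variance_ratio_ = np.array(meta["explained_variance_ratio"])
        est.singular_values_ = np.array(meta["singular_values"])
        est.n_components_ = meta["n_components"]
        est.n_features_in_ = meta["n_features_in"]
        est.n_samples_fit_ = meta["n_samples_fit"]
        est.zero_variance_mask_ = np.zeros(est.n_features_in_, dtype=bool)
        est.zero_variance_mask_[meta["zero_variance_columns"]] = True
        return est


@dataclass
class FeatureScores:
    """PC scores of a set of cycles under one subject's frozen reducer."""

    Z: np.ndarray
    model_id: int

    @property
    def n_cycles(self) -> int:
        return self.Z.shape[0]

    @property
    def k(self) -> int:
        return self.Z.shape[1]


def model_id_of(reducer: CycleFeatureReducer) -> int:
    """Stable identifier of a fitted reducer (hash of its constants)."""
    check_is_fitted(reducer, "components_")
    h = hash((reducer.mean_.tobytes(), reducer.scale_.tobytes(),
              reducer.components_.tobytes()))
    return h


def fit_features(baseline: CycleMatrix, variance_threshold: float = 0.95
                 ) -> CycleFeatureReducer:
    """Fit the per-subject reducer on combined baseline cycles."""
    return CycleFeatureReducer(variance_threshold=variance_threshold).fit(baseline)


def project(model: CycleFeatureReducer, cycles: CycleMatrix | np.ndarray) -> FeatureScores:
    """Project cycles with the frozen baseline constants (no re-fitting)."""
    return FeatureScores(Z=model.transform(cycles), model_id=model_id_of(model))
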
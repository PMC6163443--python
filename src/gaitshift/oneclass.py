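"""Subject-specific one-class SVM boundary on baseline PC scores.

A ν-parametrized one-class SVM (Schölkopf formulation, Gaussian kernel)
is fit on a subject's baseline gait-cycle scores.  ν is selected on a seeded
80/20 split of the baseline cycles: every ν on a grid is fit on the 80% part
and the largest ν whose held-out outlier percentage is strictly below 1% is
kept — the tightest boundary still consistent with a ≤1% false-outlier rate.
The selected ν is then refit on all baseline cycles.

Decision rule and bias.  A cycle x is an outlier iff
``f(x) = Σᵢ αᵢ K(svᵢ, x) − ρ < 0`` with Gaussian kernel
``K(x, y) = exp(−‖x−y‖²/(2·scale²))``.  Two conventions for ρ are supported:

* ``bias="calibrated"`` (default): ρ is set to the minimum training kernel
  sum, so the boundary encloses every training cycle and ν only shapes it
  (the convention of MATLAB's one-class ``fitcsvm`` with its default
  ``OutlierFraction=0``, which the held-out <1% selection rule presumes);
* ``bias="margin"``: ρ is the offset of the ν-SVM dual solution, in which
  case roughly a ν-fraction of training cycles scores negative.

The decision function is evaluated by this module's own kernel summation —
never through the fitting backend — so persisted boundaries are portable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist
from sklearn.base import BaseEstimator, OutlierMixin
from sklearn.svm import OneClassSVM
from sklearn.utils.validation import check_is_fitted

from .features import FeatureScores

DEFAULT_NU_GRID = tuple(np.round(np.arange(1, 20) * 0.05, 2))


@dataclass
class OcsvmParams:
    """Portable parameters of a trained Gaussian-kernel one-class boundary."""

    nu: float
    kernel_scale: float
    support_vectors: np.ndarray   # s × k
    alphas: np.ndarray            # s
    rho: float

    def __post_init__(self) -> None:
        if not (0 < self.nu <= 1):
            raise ValueError("nu must lie in (0, 1]")
        if self.kernel_scale <= 0:
            raise ValueError("kernel_scale must be positive")
        self.support_vectors = np.atleast_2d(np.asarray(self.support_vectors, float))
        self.alphas = np.asarray(self.alphas, float).ravel()
        if len(self.alphas) != self.support_vectors.shape[0]:
            raise ValueError("alphas must match support vector count")

    @property
    def k(self) -> int:
        return self.support_vectors.shape[1]


def kernel_sum(params: OcsvmParams, X: np.ndarray) -> np.ndarray:
    """Σᵢ αᵢ exp(−‖svᵢ−x‖²/(2·scale²)) for each row x of X (no bias)."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != params.k:
        raise ValueError(f"dimension mismatch: expected {params.k}, got {X.shape[1]}")
    d2 = cdist(X, params.support_vectors, "sqeuclidean")
    return np.exp(-d2 / (2.0 * params.kernel_scale ** 2)) @ params.alphas


def decision_function(params: OcsvmParams, x: np.ndarray) -> float | np.ndarray:
    """Decision value(s) Σ αᵢ K(svᵢ, x) − ρ; negative means outlier."""
    x = np.asarray(x, float)
    vals = kernel_sum(params, x) - params.rho
    return float(vals[0]) if x.ndim == 1 else vals


@dataclass
class OutlierResult:
    """Per-cycle decision values and the resulting outlier percentage."""

    decisions: np.ndarray
    labels: np.ndarray            # "typical" / "outlier"
    outlier_pct: float

    @classmethod
    def from_decisions(cls, decisions: np.ndarray) -> "OutlierResult":
        decisions = np.asarray(decisions, float)
        out = decisions < 0
        labels = np.where(out, "outlier", "typical")
        return cls(decisions=decisions, labels=labels,
                   outlier_pct=100.0 * out.mean())


def median_heuristic_scale(Z: np.ndarray, rng: np.random.Generator,
                           max_points: int = 200) -> float:
    """Median pairwise distance on a capped random subsample of the scores."""
    Z = np.asarray(Z, float)
    if Z.shape[0] > max_points:
        Z = Z[rng.choice(Z.shape[0], max_points, replace=False)]
    med = float(np.median(pdist(Z)))
    if med <= 0:
        raise ValueError("degenerate scores: median pairwise distance is 0")
    return med


class GaitBoundary(BaseEstimator, OutlierMixin):
    """One-class novelty detector for a single subject's gait cycles.

    Parameters
    ----------
    nu_grid : sequence of float, optional
        Candidate ν values (default 0.05 … 0.95 in steps of 0.05).
    nu_rule : {"largest", "smallest"}
        Which qualifying ν to select (largest = tightest boundary).
    kernel_scale : "median" or float
        Gaussian kernel bandwidth; "median" uses the median pairwise
        distance among baseline scores (capped seeded subsample).
    bias : {"calibrated", "margin"}
        ρ convention; see module docstring.
    cv_frac : float
        Held-out fraction of the baseline split (default 0.2).
    cv_threshold_pct : float
        Qualification criterion: held-out outlier % must be strictly below
        this (default 1.0, i.e. "<1% outliers").
    repeats : int
        Number of random splits averaged per ν (default 1: a single
        randomly selected cross-validation set).
    random_state : int
        Seed for the split(s) and the kernel-scale subsample.
    """

    def __init__(self, nu_grid: Optional[Sequence[float]] = None,
                 nu_rule: str = "largest", kernel_scale="median",
                 bias: str = "calibrated", cv_frac: float = 0.2,
                 cv_threshold_pct: float = 1.0, repeats: int = 1,
                 random_state: int = 0):
        self.nu_grid = nu_grid
        self.nu_rule = nu_rule
        self.kernel_scale = kernel_scale
        self.bias = bias
        self.cv_frac = cv_frac
        self.cv_threshold_pct = cv_threshold_pct
        self.repeats = repeats
        self.random_state = random_state

    # -- internals ----------------------------------------------------------

    def _rho(self, svm: OneClassSVM, train: np.ndarray, scale: float) -> float:
        params = OcsvmParams(nu=svm.nu, kernel_scale=scale,
                             support_vectors=svm.support_vectors_,
                             alphas=svm.dual_coef_.ravel(), rho=0.0)
        if self.bias == "calibrated":
            return float(kernel_sum(params, train).min())
        elif self.bias == "margin":
            return float(-svm.intercept_[0])
        raise ValueError("bias must be 'calibrated' or 'margin'")

    def fit(self, X, y=None):
        Z = X.Z if isinstance(X, FeatureScores) else np.asarray(X, float)
        n = Z.shape[0]
        if n < 25:
            raise ValueError(f"need ≥ 25 baseline cycles to train a boundary, got {n}")
        grid = tuple(self.nu_grid) if self.nu_grid is not None else DEFAULT_NU_GRID
        if not grid or not all(0 < v < 1 for v in grid):
            raise ValueError("nu_grid must be non-empty with values in (0, 1)")
        if self.nu_rule not in ("largest", "smallest"):
            raise ValueError("nu_rule must be 'largest' or 'smallest'")

        rng = np.random.default_rng(self.random_state)
        if self.kernel_scale == "median":
            scale = median_heuristic_scale(Z, rng)
        else:
            scale = float(self.kernel_scale)
            if scale <= 0:
                raise ValueError("kernel_scale must be positive")
        gamma = 1.0 / (2.0 * scale ** 2)

        n_cv = max(int(round(self.cv_frac * n)), 1)
        splits = []
        for _ in range(self.repeats):
            perm = rng.permutation(n)
            splits.append((perm[n_cv:], perm[:n_cv]))

        cv_rates = {}
        for nu in grid:
            rates = []
            for tr_idx, cv_idx in splits:
                svm = OneClassSVM(kernel="rbf", gamma=gamma, nu=nu).fit(Z[tr_idx])
                params = OcsvmParams(nu=nu, kernel_scale=scale,
                                     support_vectors=svm.support_vectors_,
                                     alphas=svm.dual_coef_.ravel(),
                                     rho=self._rho(svm, Z[tr_idx], scale))
                dec = decision_function(params, Z[cv_idx])
                rates.append(100.0 * np.mean(dec < 0))
            cv_rates[float(nu)] = float(np.mean(rates))

        qualifying = [nu for nu, r in cv_rates.items() if r < self.cv_threshold_pct]
        if not qualifying:
            best = min(cv_rates.values())
            raise RuntimeError(
                f"no ν on the grid achieved < {self.cv_threshold_pct}% held-out "
                f"outliers (best achieved: {best:.2f}%); widen the grid or adjust "
                "the kernel scale")
        nu_sel = max(qualifying) if self.nu_rule == "largest" else min(qualifying)

        svm = OneClassSVM(kernel="rbf", gamma=gamma, nu=nu_sel).fit(Z)
        self.params_ = OcsvmParams(nu=nu_sel, kernel_scale=scale,
                                   support_vectors=svm.support_vectors_,
                                   alphas=svm.dual_coef_.ravel(),
                                   rho=self._rho(svm, Z, scale))
        self.nu_ = float(nu_sel)
        self.kernel_scale_ = scale
        self.cv_outlier_pct_ = cv_rates[float(nu_sel)]
        self.cv_rates_ = cv_rates
        self.nu_grid_searched_ = list(map(float, grid))
        self.split_seed_ = self.random_state
        self.n_features_in_ = Z.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        Z = X.Z if isinstance(X, FeatureScores) else np.atleast_2d(np.asarray(X, float))
        return decision_function(self.params_, Z)

    def predict(self, X) -> np.ndarray:
        """+1 for typical cycles, −1 for outliers (sklearn convention)."""
        return np.where(self.decision_function(X) < 0, -1, 1)

    def score_samples(self, X) -> np.ndarray:
        return self.decision_function(X)


@dataclass
class SubjectBoundary:
    """A trained boundary bound to the feature model that produced its scores."""

    estimator: GaitBoundary
    feature_model_id: int
    cv_outlier_pct: float = field(init=False)

    def __post_init__(self) -> None:
        check_is_fitted(self.estimator, "params_")
        self.cv_outlier_pct = float(self.estimator.cv_outlier_pct_)
        if not (0 <= self.cv_outlier_pct <= 100):
            raise ValueError("cv_outlier_pct outside [0, 100]")

    @property
    def params(self) -> OcsvmParams:
        return self.estimator.params_

    @property
    def nu(self) -> float:
        return self.estimator.nu_


def train_boundary(scores: FeatureScores, **config) -> SubjectBoundary:
    """Train a subject boundary from baseline feature scores.

    Keyword arguments are forwarded to :class:`GaitBoundary`.
    """
    est = GaitBoundary(**config).fit(scores)
    return SubjectBoundary(estimator=est, feature_model_id=scores.model_id)


def score_cycles(boundary: SubjectBoundary, scores: FeatureScores) -> OutlierResult:
    """Score cycles against a subject's boundary (same feature model required)."""
    if scores.model_id != boundary.feature_model_id:
        raise ValueError(
            "feature-model mismatch: scores were not produced by this subject's "
            "baseline feature model")
    return OutlierResult.from_decisions(boundary.estimator.decision_function(scores))


# -- persistence ------------------------------------------------------------

def save_boundary(boundary: SubjectBoundary, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    p = boundary.params
    np.savetxt(path / "support_vectors.txt", p.support_vectors)
    np.savetxt(path / "alphas.txt", p.alphas)
    est = boundary.estimator
    meta = {
        "nu": p.nu, "kernel_scale": p.kernel_scale, "rho": p.rho,
        "feature_model_id": boundary.feature_model_id,
        "cv_outlier_pct": boundary.cv_outlier_pct,
        "cv_rates": est.cv_rates_, "nu_grid": est.nu_grid_searched_,
        "split_seed": est.split_seed_, "bias": est.bias,
        "n_features_in": est.n_features_in_,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    return path


def load_boundary(path: str | Path) -> SubjectBoundary:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    est = GaitBoundary(kernel_scale=meta["kernel_scale"], bias=meta["bias"],
                       random_state=meta["split_seed"])
    est.params_ = OcsvmParams(
        nu=meta["nu"], kernel_scale=meta["kernel_scale"],
        support_vectors=np.loadtxt(path / "support_vectors.txt", ndmin=2),
        alphas=np.loadtxt(path / "alphas.txt"), rho=meta["rho"])
    est.nu_ = meta["nu"]
    est.kernel_scale_ = meta["kernel_scale"]
    est.cv_outlier_pct_ = meta["cv_outlier_pct"]
    est.cv_rates_ = {float(k): v for k, v in meta["cv_rates"].items()}
    est.nu_grid_searched_ = meta["nu_grid"]
    est.split_seed_ = meta["split_seed"]
    est.n_features_in_ = meta["n_features_in"]
    return SubjectBoundary(estimator=est, feature_model_id=meta["feature_model_id"])
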
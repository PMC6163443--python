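"""Clinical improvement scores and their rank association with gait change.

Improvement is the mean post−pre change over four KOOS subscales (pain,
symptoms, activities of daily living, knee-related quality of life), clipped
at zero: subjects reporting no change or deterioration count as zero net
change, because the question asked is whether gait-pattern deviation tracks
clinical *improvement*.

The cohort association between the per-subject post-intervention outlier
percentage and the clipped improvement is Spearman's rank correlation with
mid-rank tie handling.  At the small cohort sizes this method targets
(n ≤ 9) the two-sided p-value comes from the exact permutation null (all n!
orderings); larger cohorts use the t approximation.  Correlation magnitude
is labelled negligible (<0.10), small (0.10–0.29), medium (0.30–0.49) or
large (≥0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from math import factorial

import numpy as np
from scipy import stats

from .io import KoosRecord
from .oneclass import OutlierResult


@dataclass
class ClinicalChange:
    """Per-subscale KOOS changes and the (clipped) mean improvement."""

    subject_id: str
    pain: float
    symptoms: float
    adl: float
    qol: float

    @property
    def mean_change(self) -> float:
        return float(np.mean([self.pain, self.symptoms, self.adl, self.qol]))

    @property
    def clipped_change(self) -> float:
        return max(0.0, self.mean_change)


def koos_change(pre: KoosRecord, post: KoosRecord) -> ClinicalChange:
    """Post − pre subscale changes for one subject."""
    if pre.subject_id != post.subject_id:
        raise ValueError(
            f"subject mismatch: {pre.subject_id!r} vs {post.subject_id!r}")
    if pre.timepoint != "pre" or post.timepoint != "post":
        raise ValueError("records must be the pre and post timepoints, in that order")
    d = post.subscales() - pre.subscales()
    return ClinicalChange(subject_id=pre.subject_id,
                          pain=d[0], symptoms=d[1], adl=d[2], qol=d[3])


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided p from the full n! permutation null of the rank vectors."""
    n = len(rx)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
    perms = np.array(list(permutations(range(n))))
    rhos = (ry_c[perms] @ rx_c) / denom
    # count permutations at least as extreme (small tolerance for float ties)
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman(x, y, exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman's ρ with mid-rank ties; exact permutation p for small n.

    Returns (rho, two-sided p).  Raises on constant input, where the
    correlation is undefined.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need two equal-length vectors with n ≥ 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: constant input vector")
    rx = stats.rankdata(x)  # average (mid-rank) ties
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    if n <= exact_max_n:
        p = _exact_permutation_p(rx, ry, rho)
    else:
        t = rho * np.sqrt((n - 2) / max(1.0 - rho ** 2, 1e-15))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return rho, p


def magnitude_label(rho: float) -> str:
    a = abs(rho)
    if a < 0.10:
        return "negligible"
    if a < 0.30:
        return "small"
    if a < 0.50:
        return "medium"
    return "large"


@dataclass
class CohortAssociation:
    """Cohort-level (outlier %, clipped improvement) pairs and their association."""

    subject_ids: list[str]
    outlier_pct: np.ndarray
    clipped_change: np.ndarray
    mean_change: np.ndarray
    rho: float
    p_value: float
    r: float                       # Pearson, supplementary
    label: str

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "subject_id": self.subject_ids,
            "outlier_pct": self.outlier_pct,
            "mean_change": self.mean_change,
            "clipped_change": self.clipped_change,
        })


def associate(results: list[tuple[OutlierResult, ClinicalChange]]) -> CohortAssociation:
    """Rank association between per-subject outlier % and clipped improvement."""
    if len(results) < 4:
        raise ValueError("need at least 4 subjects for the cohort association")
    ids = [c.subject_id for _, c in results]
    x = np.array([r.outlier_pct for r, _ in results])
    y = np.array([c.clipped_change for _, c in results])
    rho, p = spearman(x, y)
    r = float(stats.pearsonr(x, y)[0])
    return CohortAssociation(
        subject_ids=ids, outlier_pct=x, clipped_change=y,
        mean_change=np.array([c.mean_change for _, c in results]),
        rho=rho, p_value=p, r=r, label=magnitude_label(rho))
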
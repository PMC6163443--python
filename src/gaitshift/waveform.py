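"""Point-wise waveform comparison of baseline vs post-intervention cycles.

For every one of the 900 (sensor, axis, phase-point) columns, baseline and
post cycles are compared with a two-sample t-test (Welch by default, since
between-session variances need not match).  Family-wise error over the 900
simultaneous tests is controlled with the Holm–Bonferroni step-down
procedure, and a point is flagged only when it is both significant after
correction (adjusted p < α) and shows a large standardized effect
(|Cohen's d| > 0.8).  Cycles are treated as independent observations; stride
autocorrelation is a documented limitation, not corrected here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .segment import CycleLayout, CycleMatrix


def cohen_d(a, b) -> float:
    """Standardized mean difference (mean(b) − mean(a)) / pooled SD."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each sample needs n ≥ 2")
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                     / (na + nb - 2))
    if pooled == 0:
        raise ValueError("pooled SD is zero; effect size undefined")
    return float((b.mean() - a.mean()) / pooled)


def holm_adjust(p_raw: np.ndarray) -> np.ndarray:
    """Holm–Bonferroni step-down adjusted p-values (monotone, capped at 1)."""
    from statsmodels.stats.multitest import multipletests

    p_raw = np.asarray(p_raw, float)
    return multipletests(p_raw, method="holm")[1]


@dataclass
class WaveformComparison:
    """Per-column statistics of a baseline-vs-post comparison."""

    layout: CycleLayout
    baseline_mean: np.ndarray
    baseline_sd: np.ndarray
    post_mean: np.ndarray
    post_sd: np.ndarray
    p_raw: np.ndarray
    p_holm: np.ndarray
    d: np.ndarray
    alpha: float
    d_threshold: float
    flagged: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.flagged = (self.p_holm < self.alpha) & (np.abs(self.d) > self.d_threshold)

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.sum())

    def to_frame(self) -> pd.DataFrame:
        """Long-format table suitable for external waveform-panel plotting."""
        rows = []
        for j in range(self.layout.n_columns):
            site, axis, point, phase = self.layout.decode(j)
            rows.append((site, axis, point, phase))
        df = pd.DataFrame(rows, columns=["sensor", "axis", "point", "phase"])
        df["baseline_mean"] = self.baseline_mean
        df["baseline_sd"] = self.baseline_sd
        df["post_mean"] = self.post_mean
        df["post_sd"] = self.post_sd
        df["p_raw"] = self.p_raw
        df["p_holm"] = self.p_holm
        df["cohen_d"] = self.d
        df["flagged"] = self.flagged
        return df


def compare_waveforms(baseline: CycleMatrix, post: CycleMatrix,
                      alpha: float = 0.05, d_threshold: float = 0.8,
                      equal_var: bool = False,
                      correction_family: str = "joint") -> WaveformComparison:
    """Column-wise t-tests with Holm correction and effect-size gating.

    ``correction_family="joint"`` corrects across all 900 points together
    (conservative default); ``"per_sensor"`` corrects within each sensor's
    300 points separately.
    """
    if baseline.layout != post.layout:
        raise ValueError("baseline and post matrices must share the layout")
    A, B = baseline.X, post.X
    if A.shape[0] < 3 or B.shape[0] < 3:
        raise ValueError("need at least 3 cycles in each matrix")

    res = stats.ttest_ind(A, B, axis=0, equal_var=equal_var)
    p_raw = np.asarray(res.pvalue, float)

    na, nb = A.shape[0], B.shape[0]
    pooled = np.sqrt(((na - 1) * A.var(axis=0, ddof=1)
                      + (nb - 1) * B.var(axis=0, ddof=1)) / (na + nb - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(pooled > 0, (B.mean(axis=0) - A.mean(axis=0)) / pooled, 0.0)
    p_raw = np.where(np.isnan(p_raw), 1.0, p_raw)  # zero-variance columns: no evidence

    layout = baseline.layout
    if correction_family == "joint":
        p_holm = holm_adjust(p_raw)
    elif correction_family == "per_sensor":
        p_holm = np.empty_like(p_raw)
        per = len(layout.axes) * layout.points_per_channel
        for s in range(len(layout.sites)):
            sl = slice(s * per, (s + 1) * per)
            p_holm[sl] = holm_adjust(p_raw[sl])
    else:
        raise ValueError("correction_family must be 'joint' or 'per_sensor'")

    return WaveformComparison(
        layout=layout,
        baseline_mean=A.mean(axis=0), baseline_sd=A.std(axis=0, ddof=1),
        post_mean=B.mean(axis=0), post_sd=B.std(axis=0, ddof=1),
        p_raw=p_raw, p_holm=p_holm, d=d,
        alpha=alpha, d_threshold=d_threshold)
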
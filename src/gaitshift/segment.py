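"""Gait-cycle segmentation and time normalization.

Each complete stride (IC to next ipsilateral IC) is split at toe-off into
stance and swing, each phase is resampled to a fixed number of points
(60 stance + 40 swing = 100 per channel), and the nine acceleration channels
(back, thigh, shank × AP, ML, V) are concatenated into one 900-element
vector describing that cycle's whole-body movement pattern.  Stacking all
cycles of a trial gives an m × 900 matrix.

The column layout is fixed and documented (sensor-major, then axis, then
phase point; stance before swing) so that persisted matrices and fitted
models are portable across runs.  The grids include IC and TO in stance and
end at the next IC in swing, with no duplicated TO sample at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import GaitEvents
from .io import GaitSession

MODEL_SITES = ("back", "thigh", "shank")
AXES = ("AP", "ML", "V")


@dataclass(frozen=True)
class CycleLayout:
    """Bijective map between matrix columns and (site, axis, phase point)."""

    sites: tuple[str, ...] = MODEL_SITES
    axes: tuple[str, ...] = AXES
    n_stance: int = 60
    n_swing: int = 40

    @property
    def points_per_channel(self) -> int:
        return self.n_stance + self.n_swing

    @property
    def n_columns(self) -> int:
        return len(self.sites) * len(self.axes) * self.points_per_channel

    def encode(self, site: str, axis: str, point: int) -> int:
        """Column index of phase ``point`` (0-based) of ``axis`` at ``site``."""
        if not (0 <= point < self.points_per_channel):
            raise ValueError(f"phase point {point} out of range")
        return (self.sites.index(site) * len(self.axes) + self.axes.index(axis)) \
            * self.points_per_channel + point

    def decode(self, column: int) -> tuple[str, str, int, str]:
        """Inverse of :meth:`encode`; also returns the phase label."""
        if not (0 <= column < self.n_columns):
            raise ValueError(f"column {column} out of range")
        point = column % self.points_per_channel
        chan = column // self.points_per_channel
        site = self.sites[chan // len(self.axes)]
        axis = self.axes[chan % len(self.axes)]
        phase = "stance" if point < self.n_stance else "swing"
        return site, axis, point, phase

    def to_dict(self) -> dict:
        return {"sites": list(self.sites), "axes": list(self.axes),
                "n_stance": self.n_stance, "n_swing": self.n_swing}

    @classmethod
    def from_dict(cls, d: dict) -> "CycleLayout":
        return cls(sites=tuple(d["sites"]), axes=tuple(d["axes"]),
                   n_stance=int(d["n_stance"]), n_swing=int(d["n_swing"]))


@dataclass
class CycleMatrix:
    """m × 900 matrix of time-normalized cycles with per-row provenance.

    ``provenance`` has columns session_kind, stride, ic, to, next_ic.
    """

    X: np.ndarray
    provenance: pd.DataFrame
    layout: CycleLayout = field(default_factory=CycleLayout)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != self.layout.n_columns:
            raise ValueError(
                f"cycle matrix must have {self.layout.n_columns} columns, "
                f"got shape {self.X.shape}")
        if len(self.provenance) != self.X.shape[0]:
            raise ValueError("provenance rows must match matrix rows")

    @property
    def n_cycles(self) -> int:
        return self.X.shape[0]


def normalize_cycle(channel: np.ndarray, ic: int, to: int, next_ic: int,
                    n_stance: int = 60, n_swing: int = 40,
                    kind: str = "linear") -> np.ndarray:
    """Time-normalize one stride of one channel to n_stance + n_swing points.

    Stance spans samples [ic, to] inclusive on a grid of ``n_stance`` points;
    swing starts one normalized step after TO and ends at ``next_ic`` on a
    grid of ``n_swing`` points, so the TO sample is not duplicated.
    """
    channel = np.asarray(channel, dtype=float)
    if not (0 <= ic < to < next_ic < len(channel)):
        raise ValueError(
            f"invalid stride indices ic={ic}, to={to}, next_ic={next_ic} "
            f"for channel of length {len(channel)}")
    if to - ic < 2 or next_ic - to < 2:
        raise ValueError(
            f"stride segments too short: stance {to - ic}, swing {next_ic - to} samples "
            f"(ic={ic}, to={to}, next_ic={next_ic})")
    stance_pos = ic + (to - ic) * np.arange(n_stance) / (n_stance - 1)
    swing_pos = to + (next_ic - to) * np.arange(1, n_swing + 1) / n_swing
    pos = np.concatenate([stance_pos, swing_pos])
    idx = np.arange(len(channel), dtype=float)
    if kind == "linear":
        return np.interp(pos, idx, channel)
    elif kind == "cubic":
        from scipy.interpolate import CubicSpline
        lo = max(ic - 2, 0)
        hi = min(next_ic + 3, len(channel))
        return CubicSpline(idx[lo:hi], channel[lo:hi])(pos)
    raise ValueError("kind must be 'linear' or 'cubic'")


def build_cycle_matrix(session: GaitSession, ev: GaitEvents,
                       layout: CycleLayout | None = None,
                       interp: str = "linear") -> CycleMatrix:
    """Assemble the m × 900 cycle matrix of a preprocessed session.

    Uses linear acceleration from the back, thigh and shank sensors only
    (the foot sensor serves event detection alone).  The session must be
    attitude-corrected so axis labels are AP/ML/V.
    """
    layout = layout or CycleLayout()
    if ev.n_strides == 0:
        raise ValueError("no valid strides to segment")
    rows = []
    prov = []
    for stride_no, (ic, to, next_ic) in enumerate(ev.strides()):
        parts = []
        for site in layout.sites:
            rec = session.recordings[site]
            if tuple(rec.axis_labels) != tuple(layout.axes):
                raise ValueError(
                    f"{site}: axis labels {rec.axis_labels} do not match layout "
                    f"{layout.axes}; run attitude correction first")
            for a, axis in enumerate(layout.axes):
                parts.append(normalize_cycle(rec.accel[:, a], ic, to, next_ic,
                                             layout.n_stance, layout.n_swing, interp))
        rows.append(np.concatenate(parts))
        prov.append({"session_kind": session.session_kind, "stride": stride_no,
                     "ic": ic, "to": to, "next_ic": next_ic})
    return CycleMatrix(X=np.vstack(rows), provenance=pd.DataFrame(prov), layout=layout)


def concat_sessions(a: CycleMatrix, b: CycleMatrix) -> CycleMatrix:
    """Row-stack two cycle matrices with identical layout (provenance kept)."""
    if a.layout != b.layout:
        raise ValueError("cannot concatenate cycle matrices with different layouts")
    if a.n_cycles == 0:
        return b
    if b.n_cycles == 0:
        return a
    return CycleMatrix(
        X=np.vstack([a.X, b.X]),
        provenance=pd.concat([a.provenance, b.provenance], ignore_index=True),
        layout=a.layout,
    )
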
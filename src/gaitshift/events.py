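"""Gait event detection from foot-mounted gyroscope data.

During walking, the foot's mediolateral (ML) angular velocity traces a highly
stereotyped pattern per stride: a dominant positive lobe at mid-swing, a
positive-to-negative zero-crossing at initial contact (IC, start of stance),
and a negative trough around toe-off (TO, end of stance).  Detection anchors
on the robust mid-swing peaks and then applies the IC/TO rules between
consecutive anchors:

1. mid-swing markers = prominent positive peaks of the ML signal;
2. IC = first positive→negative zero-crossing after a mid-swing marker
   (the zero-crossing preceding stance);
3. TO = the most negative sample between that IC and the next mid-swing
   marker (the negative peak ending stance).

Strides whose IC→IC duration falls outside configurable physiological bounds
are discarded (with a logged count); of the surviving strides the longest
contiguous run is kept so that events form one interleaved IC/TO chain.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .io import SensorRecording

log = logging.getLogger(__name__)


@dataclass
class EventParams:
    """Tuning knobs for the detector (defaults cover ~1.1 m/s treadmill gait)."""

    swing_prominence_frac: float = 0.3   # × 95th percentile of the ML signal
    min_stride_s: float = 0.6            # minimum separation of mid-swing peaks
    stride_bounds_s: tuple[float, float] = (0.6, 2.0)


@dataclass
class GaitEvents:
    """Validated initial-contact / toe-off sample indices for one recording.

    Events interleave as IC_k < TO_k < IC_{k+1} for every complete stride;
    ``n_strides`` counts complete IC→IC cycles.
    """

    ic_idx: np.ndarray
    to_idx: np.ndarray
    ml_axis: int
    n_discarded: int = 0

    def __post_init__(self) -> None:
        self.ic_idx = np.asarray(self.ic_idx, dtype=int)
        self.to_idx = np.asarray(self.to_idx, dtype=int)
        if np.any(np.diff(self.ic_idx) <= 0) or np.any(np.diff(self.to_idx) <= 0):
            raise ValueError("event indices must be strictly increasing")
        if len(self.to_idx) < len(self.ic_idx) - 1:
            raise ValueError("need a toe-off for every complete stride")
        for k in range(len(self.ic_idx) - 1):
            if not (self.ic_idx[k] < self.to_idx[k] < self.ic_idx[k + 1]):
                raise ValueError(
                    f"events do not interleave at stride {k}: "
                    f"IC={self.ic_idx[k]}, TO={self.to_idx[k]}, next IC={self.ic_idx[k + 1]}")

    @property
    def n_strides(self) -> int:
        return max(len(self.ic_idx) - 1, 0)

    def strides(self):
        """Yield (ic, to, next_ic) index triples for complete strides."""
        for k in range(self.n_strides):
            yield int(self.ic_idx[k]), int(self.to_idx[k]), int(self.ic_idx[k + 1])


def _zero_crossing_after(sig: np.ndarray, start: int) -> int | None:
    """Index of the first positive→negative crossing at or after ``start``.

    Returns the sample nearest the true crossing, or None if there is none.
    """
    seg = sig[start:]
    prev_pos = seg[:-1] > 0
    next_neg = seg[1:] <= 0
    hits = np.nonzero(prev_pos & next_neg)[0]
    if hits.size == 0:
        return None
    j = int(hits[0])
    return start + j + (0 if abs(seg[j]) < abs(seg[j + 1]) else 1)


def detect_events(foot: SensorRecording, params: EventParams | None = None) -> GaitEvents:
    """Detect IC and TO events from the foot's ML angular velocity.

    The ML gyro column comes from the recording's manifest metadata
    (``ml_axis``/``ml_sign``); silent axis guessing is deliberately avoided.
    """
    params = params or EventParams()
    if foot.gyro is None:
        raise ValueError("foot recording has no gyro data")
    if foot.duration_s < 3.0:
        raise ValueError("recording too short for event detection (< 3 s)")
    if foot.ml_axis is None:
        raise ValueError("ml_axis not set on foot recording (declare it in the manifest)")
    sig = foot.ml_sign * foot.gyro[:, foot.ml_axis]

    prominence = params.swing_prominence_frac * np.percentile(sig, 95)
    if prominence <= 0:
        raise ValueError("no strides detected: ML signal has no positive excursion")
    distance = max(int(params.min_stride_s * foot.rate_hz), 1)
    swings, _ = find_peaks(sig, prominence=prominence, distance=distance)
    swings = swings[sig[swings] > 0]
    if len(swings) < 2:
        raise ValueError("no strides detected: fewer than 2 mid-swing markers")

    ics = [_zero_crossing_after(sig, int(s)) for s in swings]

    # accepted (ic, to, next_ic) triples between consecutive mid-swing markers
    triples: list[tuple[int, int, int]] = []
    n_discarded = 0
    lo = params.stride_bounds_s[0] * foot.rate_hz
    hi = params.stride_bounds_s[1] * foot.rate_hz
    for k in range(len(swings) - 1):
        ic, next_ic = ics[k], ics[k + 1]
        if ic is None or next_ic is None or next_ic <= ic:
            n_discarded += 1
            continue
        if not (lo <= next_ic - ic <= hi):
            n_discarded += 1
            continue
        window = sig[ic + 1:int(swings[k + 1])]
        if window.size == 0:
            n_discarded += 1
            continue
        to = ic + 1 + int(np.argmin(window))
        if not (ic < to < next_ic):
            n_discarded += 1
            continue
        triples.append((ic, to, next_ic))
    if not triples:
        raise ValueError("no strides detected: all candidate strides discarded")

    # keep the longest contiguous chain (next_ic of one stride == ic of the next)
    chains: list[list[tuple[int, int, int]]] = [[triples[0]]]
    for t in triples[1:]:
        if t[0] == chains[-1][-1][2]:
            chains[-1].append(t)
        else:
            chains.append([t])
    best = max(chains, key=len)
    n_discarded += len(triples) - len(best)

    ic_idx = [t[0] for t in best] + [best[-1][2]]
    to_idx = [t[1] for t in best]
    ev = GaitEvents(ic_idx=np.array(ic_idx), to_idx=np.array(to_idx),
                    ml_axis=foot.ml_axis, n_discarded=n_discarded)
    total = ev.n_strides + n_discarded
    if n_discarded > 0.2 * total:
        warnings.warn(f"{n_discarded}/{total} candidate strides discarded", stacklevel=2)
    elif n_discarded:
        log.info("discarded %d of %d candidate strides", n_discarded, total)
    return ev


def stance_fraction(ev: GaitEvents) -> np.ndarray:
    """Per-stride stance fraction (TO−IC)/(next IC−IC), each in (0, 1)."""
    return np.array([(to - ic) / (next_ic - ic) for ic, to, next_ic in ev.strides()])
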
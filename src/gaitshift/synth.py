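"""Synthetic multi-sensor treadmill gait generator with known ground truth.

The generator emulates the study design this package targets: per subject,
two baseline treadmill sessions on separate days and one post-intervention
session, each 2.5 min at 100 Hz from four body sites (lower back, lateral
thigh, lateral shank, foot dorsum), preceded by a 2 s standing-still window
for attitude correction, plus paired KOOS score records.

Signal model
------------
Each acceleration channel has a smooth periodic stride template built from a
small Fourier basis (site-specific amplitudes; vertical oscillation grows
from back to shank; vertical channels carry the +1 g gravity reaction).  The
foot mediolateral gyro template is a periodic spline with the canonical
event morphology: positive-to-negative zero-crossing at initial contact
(phase 0), negative trough at toe-off (phase = stance fraction, default
0.60) and a dominant positive mid-swing lobe (phase 0.85, ≈ +300 deg/s).

Stride-to-stride variability comes from a small set of latent factors acting
nonlinearly on the template — a multiplicative amplitude gain, smooth phase
warps and stride-time jitter — plus a low-amplitude additive smooth
perturbation and white measurement noise.  The nonlinearity matters: it
curves the cycle distribution so that many linear principal components are
needed to cover it, as in real gait data, while its intrinsic dimension
stays low.  Sessions differ by an additive day effect and a fresh mounting
tilt; the post session additionally shifts the template by
``shift_delta × shift_profile`` (a fixed smooth unit-RMS curve across
channels).  KOOS improvement is a monotone (linear) function of the shift
magnitude plus noise.  All randomness derives from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .io import G, GaitSession, KoosRecord, SensorRecording
from .segment import CycleLayout, CycleMatrix

MODEL_CHANNELS = [(site, axis) for site in ("back", "thigh", "shank")
                  for axis in ("AP", "ML", "V")]

# oscillation RMS (m/s²) per site and axis: distal sites move more
_SITE_AMP = {"back": 1.2, "thigh": 1.8, "shank": 2.6, "foot": 3.0}
_AXIS_FRAC = {"AP": 0.6, "ML": 0.4, "V": 1.0}


@dataclass
class SynthSubjectConfig:
    """Study-condition parameters of one synthetic subject."""

    seed: int = 0
    rate_hz: float = 100.0
    session_minutes: float = 2.5
    static_s: float = 2.0
    stride_time_s: float = 1.1
    stride_jitter_sd_s: float = 0.03
    stance_frac: float = 0.60
    stance_jitter_sd: float = 0.01
    # stride-to-stride latent variation (nonlinear)
    amp_gain_sd: float = 0.06
    warp_sd: float = 0.015
    asym_warp_sd: float = 0.010
    # additive perturbations, m/s² RMS per channel
    cycle_noise_sd: float = 0.05
    day_effect_sd: float = 0.008
    day_warp_sd: float = 0.004
    white_noise_sd: float = 0.02
    gyro_noise_sd: float = 2.0
    # mounting
    tilt_deg: float = 5.0
    tilt_jitter_deg: float = 2.0
    # intervention effect
    shift_delta: float = 0.0
    shift_site_weights: dict = field(default_factory=lambda: {
        "back": 0.4, "thigh": 1.0, "shank": 0.7})
    # KOOS simulation
    koos_gain_per_delta: float = 120.0
    koos_noise_sd: float = 2.0
    koos_pre_range: tuple[float, float] = (35.0, 60.0)
    n_harmonics: int = 6
    noise_harmonics: int = 4
    speed_mps: float = 1.1

    def __post_init__(self) -> None:
        if not (0 < self.stance_frac < 1):
            raise ValueError("stance_frac must lie in (0, 1)")
        for name in ("cycle_noise_sd", "day_effect_sd", "white_noise_sd",
                     "amp_gain_sd", "warp_sd", "shift_delta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")


@dataclass
class SynthGroundTruth:
    """Everything a test oracle needs about one generated subject."""

    ic_idx: dict                      # session_kind -> ground-truth IC sample indices
    to_idx: dict                      # session_kind -> ground-truth TO sample indices
    stance_fracs: dict                # session_kind -> per-stride stance fractions
    shift_delta: float
    koos_gain: float


def _tnorm(rng: np.random.Generator, size=None, clip: float = 2.5) -> np.ndarray:
    """Truncated standard normal draw (tails clipped at ±clip SD).

    Stride-to-stride gait variability is physiologically bounded; untruncated
    Gaussian latents occasionally produce single wildly atypical cycles that
    no real treadmill session contains.
    """
    return np.clip(rng.standard_normal(size), -clip, clip)


class _Fourier:
    """Small periodic Fourier series f(phi) = dc + Σ a_h cos + b_h sin."""

    __slots__ = ("dc", "a", "b", "h")

    def __init__(self, dc: float, a: np.ndarray, b: np.ndarray):
        self.dc = dc
        self.a = np.asarray(a, float)
        self.b = np.asarray(b, float)
        self.h = np.arange(1, len(self.a) + 1)

    def osc(self, phi: np.ndarray) -> np.ndarray:
        ang = 2 * np.pi * np.outer(phi, self.h)
        return np.cos(ang) @ self.a + np.sin(ang) @ self.b

    def __call__(self, phi: np.ndarray) -> np.ndarray:
        return self.dc + self.osc(phi)


def _random_fourier(rng: np.random.Generator, rms: float, n_harmonics: int,
                    dc: float = 0.0, decay: float = 1.0) -> _Fourier:
    w = 1.0 / np.arange(1, n_harmonics + 1) ** decay
    a = rng.standard_normal(n_harmonics) * w
    b = rng.standard_normal(n_harmonics) * w
    cur = np.sqrt(np.sum(a ** 2 + b ** 2) / 2)
    if cur > 0 and rms > 0:
        a *= rms / cur
        b *= rms / cur
    else:
        a[:] = 0.0
        b[:] = 0.0
    return _Fourier(dc, a, b)


def _gyro_template(rng: np.random.Generator, stance_frac: float) -> CubicSpline:
    """Periodic foot-ML angular velocity template (deg/s) vs cycle phase."""
    sf = stance_frac
    knots = np.array([0.0, 0.12 * sf, 0.35 * sf, 0.70 * sf, sf,
                      sf + 0.35 * (1 - sf), 0.85, 0.94, 1.0])
    scale = 1.0 + 0.1 * rng.standard_normal()
    vals = np.array([0.0, -50.0, -30.0, -55.0, -150.0, 0.0,
                     300.0, 150.0, 0.0]) * scale
    return CubicSpline(knots, vals, bc_type="periodic")


class _SubjectModel:
    """Frozen per-subject templates, profiles and the KOOS baseline."""

    def __init__(self, cfg: SynthSubjectConfig):
        self.cfg = cfg
        root = np.random.default_rng(np.random.SeedSequence(cfg.seed))
        self.templates: dict[tuple[str, str], _Fourier] = {}
        for site in ("back", "thigh", "shank", "foot"):
            for axis in ("AP", "ML", "V"):
                rms = _SITE_AMP[site] * _AXIS_FRAC[axis]
                dc = G if axis == "V" else 0.0
                self.templates[(site, axis)] = _random_fourier(
                    root, rms, cfg.n_harmonics, dc=dc)
        self.gyro_ml = _gyro_template(root, cfg.stance_frac)
        self.gyro_other = [_random_fourier(root, 30.0, cfg.n_harmonics)
                           for _ in range(2)]
        # fixed smooth unit-RMS shift profile over the 9 model channels
        curves = {}
        sq = 0.0
        grid = np.linspace(0, 1, 100, endpoint=False)
        for site, axis in MODEL_CHANNELS:
            w = cfg.shift_site_weights.get(site, 0.0)
            c = _random_fourier(root, w, cfg.noise_harmonics)
            curves[(site, axis)] = c
            sq += np.mean(c.osc(grid) ** 2)
        norm = np.sqrt(sq / len(MODEL_CHANNELS))
        if norm > 0:
            for c in curves.values():
                c.a /= norm
                c.b /= norm
        self.shift_curves = curves
        self.koos_pre = root.uniform(*cfg.koos_pre_range, size=4)
        self.koos_rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 9001)))

    def session_rng(self, kind: str) -> np.random.Generator:
        idx = {"baseline1": 1, "baseline2": 2, "post": 3}[kind]
        return np.random.default_rng(np.random.SeedSequence((self.cfg.seed, idx)))


def _warp(phi: np.ndarray, w1: float, w2: float) -> np.ndarray:
    """Smooth periodic phase distortion vanishing at the stride boundaries."""
    return phi + w1 * np.sin(2 * np.pi * phi) + w2 * np.sin(4 * np.pi * phi)


def _tilt_rotation(rng: np.random.Generator, tilt_deg: float,
                   jitter_deg: float) -> np.ndarray:
    """Mounting rotation about a random horizontal axis (no yaw)."""
    from scipy.spatial.transform import Rotation

    angle = np.deg2rad(tilt_deg + jitter_deg * rng.standard_normal())
    theta = rng.uniform(0, 2 * np.pi)
    axis = np.array([np.cos(theta), np.sin(theta), 0.0])
    return Rotation.from_rotvec(angle * axis).as_matrix()


def _simulate_session(model: _SubjectModel, kind: str
                      ) -> tuple[GaitSession, np.ndarray, np.ndarray, np.ndarray]:
    """Generate one session; returns (session, ic_idx, to_idx, stance_fracs)."""
    cfg = model.cfg
    rng = model.session_rng(kind)
    rate = cfg.rate_hz
    n_total = int(round((cfg.static_s + 60 * cfg.session_minutes) * rate))
    t_static_end = cfg.static_s
    shifted = kind == "post" and cfg.shift_delta > 0

    # per-session day effects: additive curve per channel + warp offset + tilt
    day_curves = {ch: _random_fourier(rng, cfg.day_effect_sd, cfg.noise_harmonics)
                  for ch in model.templates}
    day_warp = cfg.day_warp_sd * rng.standard_normal()
    tilts = {site: _tilt_rotation(rng, cfg.tilt_deg, cfg.tilt_jitter_deg)
             for site in ("back", "thigh", "shank", "foot")}

    # stride boundaries (ground truth): strides span the walking window
    ic_times = [t_static_end]
    while True:
        dur = cfg.stride_time_s + cfg.stride_jitter_sd_s * float(_tnorm(rng))
        dur = max(dur, 0.5 * cfg.stride_time_s)
        nxt = ic_times[-1] + dur
        if nxt > n_total / rate:
            break
        ic_times.append(nxt)
    ic_idx = np.round(np.array(ic_times) * rate).astype(int)
    n_strides = len(ic_times) - 1

    # per-stride latents and additive noise curves
    amps = cfg.amp_gain_sd * _tnorm(rng, n_strides + 1)
    warps = cfg.warp_sd * _tnorm(rng, n_strides + 1) + day_warp
    asyms = cfg.asym_warp_sd * _tnorm(rng, n_strides + 1)
    sfracs = np.clip(cfg.stance_frac
                     + cfg.stance_jitter_sd * _tnorm(rng, n_strides + 1),
                     0.4, 0.75)

    accel_w = {site: np.zeros((n_total, 3)) for site in tilts}
    gyro_w = np.zeros((n_total, 3))  # foot only, world frame

    # standing-still segment (world frame)
    i_static = int(t_static_end * rate)
    for site in tilts:
        accel_w[site][:i_static] = [0.0, 0.0, G]
    # per-stride synthesis, including the trailing partial stride
    bounds = ic_idx.tolist() + [n_total]
    to_times = []
    for k in range(len(bounds) - 1):
        i0, i1 = bounds[k], bounds[k + 1]
        if i1 <= i0:
            continue
        dur = (ic_times[k + 1] - ic_times[k]) if k < n_strides else cfg.stride_time_s
        phi = (np.arange(i0, i1) / rate - ic_times[k]) / dur
        phi_w = _warp(phi, warps[k], asyms[k])
        gain = 1.0 + amps[k]
        noise_rngs = rng  # one stream; draws below are ordered deterministically
        for site in ("back", "thigh", "shank", "foot"):
            for a, axis in enumerate(("AP", "ML", "V")):
                tpl = model.templates[(site, axis)]
                stride_noise = _random_fourier(noise_rngs, cfg.cycle_noise_sd,
                                               cfg.noise_harmonics)
                vals = tpl.dc + gain * tpl.osc(phi_w) \
                    + day_curves[(site, axis)].osc(phi) + stride_noise.osc(phi)
                if shifted and (site, axis) in model.shift_curves:
                    vals = vals + cfg.shift_delta * \
                        model.shift_curves[(site, axis)].osc(phi)
                accel_w[site][i0:i1, a] = vals
        gyro_w[i0:i1, 1] = gain * model.gyro_ml(phi_w % 1.0)
        gyro_w[i0:i1, 0] = model.gyro_other[0].osc(phi_w)
        gyro_w[i0:i1, 2] = model.gyro_other[1].osc(phi_w)
        if k < n_strides:
            to_times.append(ic_times[k] + sfracs[k] * dur)
    to_idx = np.round(np.array(to_times) * rate).astype(int)

    # device frame = mounting rotation applied to world signals, + sensor noise
    recordings = {}
    for site in ("back", "thigh", "shank", "foot"):
        R = tilts[site]
        acc = accel_w[site] @ R.T + cfg.white_noise_sd * rng.standard_normal((n_total, 3))
        if site == "foot":
            gy = gyro_w @ R.T + cfg.gyro_noise_sd * rng.standard_normal((n_total, 3))
        else:
            gy = None
        recordings[site] = SensorRecording(
            site=site, rate_hz=rate, accel=acc, gyro=gy,
            axis_labels=("x", "y", "z"),
            ml_axis=1 if site == "foot" else None)
    session = GaitSession(subject_id=f"S{cfg.seed:04d}", session_kind=kind,
                          speed_mps=cfg.speed_mps, recordings=recordings,
                          static_window_s=(0.1, t_static_end - 0.1))
    return session, ic_idx, to_idx, sfracs[:n_strides]


def _make_koos(model: _SubjectModel) -> tuple[KoosRecord, KoosRecord]:
    cfg = model.cfg
    gain = cfg.koos_gain_per_delta * cfg.shift_delta
    post_scores = np.clip(
        model.koos_pre + gain + cfg.koos_noise_sd * model.koos_rng.standard_normal(4),
        0.0, 100.0)
    sid = f"S{cfg.seed:04d}"
    return (KoosRecord(sid, "pre", *model.koos_pre),
            KoosRecord(sid, "post", *post_scores))


def make_koos(cfg: SynthSubjectConfig) -> tuple[KoosRecord, KoosRecord]:
    """Simulated KOOS pre/post records of one subject (shift-linked gain)."""
    return _make_koos(_SubjectModel(cfg))


def make_subject(cfg: SynthSubjectConfig
                 ) -> tuple[dict, tuple[KoosRecord, KoosRecord], SynthGroundTruth]:
    """Generate one subject: three sessions, KOOS pre/post, and ground truth."""
    model = _SubjectModel(cfg)
    sessions = {}
    ics, tos, sfr = {}, {}, {}
    for kind in ("baseline1", "baseline2", "post"):
        sessions[kind], ics[kind], tos[kind], sfr[kind] = _simulate_session(model, kind)
    koos_pre, koos_post = _make_koos(model)
    truth = SynthGroundTruth(ic_idx=ics, to_idx=tos, stance_fracs=sfr,
                             shift_delta=cfg.shift_delta,
                             koos_gain=cfg.koos_gain_per_delta * cfg.shift_delta)
    return sessions, (koos_pre, koos_post), truth


# ---------------------------------------------------------------------------
# fast path: draw normalized cycle matrices directly (no time-domain pipeline)

def make_cycle_bank(cfg: SynthSubjectConfig, kind: str, n_cycles: int,
                    layout: CycleLayout | None = None) -> CycleMatrix:
    """Sample time-normalized cycles straight from the subject model.

    Statistically mirrors what segmentation of a generated session yields
    (same templates, latents, day effects and noise), evaluated directly on
    the normalized stance/swing phase grid.  Useful for Monte-Carlo-heavy
    experiments where full signal synthesis and event detection would
    dominate runtime.
    """
    layout = layout or CycleLayout()
    model = _SubjectModel(cfg)
    rng = model.session_rng(kind)
    shifted = kind == "post" and cfg.shift_delta > 0
    sf = cfg.stance_frac
    grid = np.concatenate([
        sf * np.arange(layout.n_stance) / (layout.n_stance - 1),
        sf + (1 - sf) * np.arange(1, layout.n_swing + 1) / layout.n_swing,
    ])
    day_curves = {ch: _random_fourier(rng, cfg.day_effect_sd, cfg.noise_harmonics)
                  for ch in MODEL_CHANNELS}
    day_warp = cfg.day_warp_sd * rng.standard_normal()
    rows = np.empty((n_cycles, layout.n_columns))
    for i in range(n_cycles):
        gain = 1.0 + cfg.amp_gain_sd * float(_tnorm(rng))
        w1 = cfg.warp_sd * float(_tnorm(rng)) + day_warp
        w2 = cfg.asym_warp_sd * float(_tnorm(rng))
        phi_w = _warp(grid, w1, w2)
        parts = []
        for site, axis in MODEL_CHANNELS:
            tpl = model.templates[(site, axis)]
            noise = _random_fourier(rng, cfg.cycle_noise_sd, cfg.noise_harmonics)
            vals = tpl.dc + gain * tpl.osc(phi_w) + day_curves[(site, axis)].osc(grid) \
                + noise.osc(grid) \
                + cfg.white_noise_sd * rng.standard_normal(len(grid))
            if shifted:
                vals = vals + cfg.shift_delta * model.shift_curves[(site, axis)].osc(grid)
            parts.append(vals)
        rows[i] = np.concatenate(parts)
    prov = pd.DataFrame({"session_kind": kind, "stride": np.arange(n_cycles),
                         "ic": 0, "to": 0, "next_ic": 0})
    return CycleMatrix(X=rows, provenance=prov, layout=layout)


# ---------------------------------------------------------------------------
# cohorts

@dataclass
class SubjectBundle:
    cfg: SynthSubjectConfig
    sessions: dict
    koos_pre: KoosRecord
    koos_post: KoosRecord
    truth: SynthGroundTruth


def make_cohort(n_subjects: int = 8, deltas: Optional[np.ndarray] = None,
                seed: int = 0, **cfg_overrides) -> list[SubjectBundle]:
    """Generate an independent cohort with graded intervention effects.

    ``deltas`` default to 8 evenly spaced shift magnitudes from 0 to 0.25
    m/s² RMS (no change → strong change); per-subject seeds derive from the
    master seed.
    """
    if deltas is None:
        deltas = np.linspace(0.0, 0.25, n_subjects)
    deltas = np.asarray(deltas, float)
    if len(deltas) != n_subjects:
        raise ValueError("len(deltas) must equal n_subjects")
    seeds = np.random.SeedSequence(seed).generate_state(n_subjects) % (2 ** 31)
    out = []
    for i in range(n_subjects):
        cfg = SynthSubjectConfig(seed=int(seeds[i]), shift_delta=float(deltas[i]),
                                 **cfg_overrides)
        sessions, (pre, post), truth = make_subject(cfg)
        out.append(SubjectBundle(cfg=cfg, sessions=sessions,
                                 koos_pre=pre, koos_post=post, truth=truth))
    return out


def write_cohort(bundles: list[SubjectBundle], out_dir) -> None:
    """Write a cohort as per-subject session directories + KOOS table + truth."""
    import json
    from pathlib import Path

    from .io import write_koos_table, write_session

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    koos = []
    truth = {}
    for b in bundles:
        sid = b.koos_pre.subject_id
        for kind, session in b.sessions.items():
            write_session(session, out_dir / sid / kind)
        koos += [b.koos_pre, b.koos_post]
        truth[sid] = {
            "shift_delta": b.truth.shift_delta,
            "koos_gain": b.truth.koos_gain,
            "ic_idx": {k: v.tolist() for k, v in b.truth.ic_idx.items()},
            "to_idx": {k: v.tolist() for k, v in b.truth.to_idx.items()},
        }
    write_koos_table(koos, out_dir / "koos.csv")
    (out_dir / "ground_truth.json").write_text(json.dumps(truth))
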
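"""Static attitude correction and low-pass filtering.

Each body-worn sensor is mounted at an arbitrary (small) tilt relative to the
world frame.  A standing-still window gives the direction of the gravity
reaction in the device frame; the minimal rotation taking that direction onto
the vertical axis aligns the sensor with global vertical.  Horizontal heading
is not observable from a static accelerometer and is left as mounted: after
correction axis 3 is vertical (V, up) and axes 1–2 are the device's
horizontal projections, labelled AP and ML by the manifest's declared
mounting orientation.

All channels are then low-pass filtered.  The default is a zero-phase
forward–backward pass of a half-order Butterworth design, whose net magnitude
response equals a 4th-order Butterworth at the 10 Hz cutoff; zero phase is
preferred because phase lag would bias gait-event timing.  A ``causal`` mode
applies a single forward pass of a true 4th-order design.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal
from scipy.spatial.transform import Rotation

from .io import G, SensorRecording


@dataclass
class AttitudeCorrection:
    """Rotation aligning one sensor's device frame with gravity-defined vertical."""

    site: str
    rotation: np.ndarray          # 3×3, device frame -> gravity-aligned frame
    static_mean_accel: np.ndarray  # 3-vector, m/s², device frame

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3×3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation must be proper (det = +1)")
        self.rotation = R
        self.static_mean_accel = np.asarray(self.static_mean_accel, dtype=float)
        corrected = R @ self.static_mean_accel
        if np.any(np.abs(corrected[:2]) >= 0.05 * G):
            raise ValueError("corrected static mean is not vertical")


def _minimal_rotation_to_vertical(v: np.ndarray) -> np.ndarray:
    """Minimal (axis-angle) rotation R with R·v = (0, 0, |v|)."""
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v)
    vhat = v / norm
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.clip(vhat @ z, -1.0, 1.0))
    if c > 1.0 - 1e-14:
        return np.eye(3)
    if c < -1.0 + 1e-14:
        # antiparallel: 180° about any horizontal axis; x is as good as any
        return Rotation.from_rotvec(np.pi * np.array([1.0, 0.0, 0.0])).as_matrix()
    axis = np.cross(vhat, z)
    axis /= np.linalg.norm(axis)
    angle = np.arccos(c)
    return Rotation.from_rotvec(angle * axis).as_matrix()


def fit_attitude(rec: SensorRecording, static_window: tuple[float, float],
                 static_tolerance_g: float = 0.2) -> AttitudeCorrection:
    """Estimate the attitude correction from a standing-still window.

    Parameters
    ----------
    rec : SensorRecording
        Uncorrected recording.
    static_window : (start_s, stop_s)
        Interval during which the sensor is at rest; must span ≥ 0.5 s.
    static_tolerance_g : float
        Allowed deviation of the window-mean acceleration magnitude from 1 g.

    Raises
    ------
    ValueError
        If the window is too short or the mean magnitude indicates motion.
    """
    a, b = static_window
    i0, i1 = int(round(a * rec.rate_hz)), int(round(b * rec.rate_hz))
    if (i1 - i0) < 0.5 * rec.rate_hz:
        raise ValueError("static window too short (need ≥ 0.5 s)")
    mean = rec.accel[i0:i1].mean(axis=0)
    mag = np.linalg.norm(mean)
    lo, hi = (1 - static_tolerance_g) * G, (1 + static_tolerance_g) * G
    if not (lo <= mag <= hi):
        raise ValueError(
            f"sensor not static: mean |accel| = {mag:.2f} m/s² outside [{lo:.2f}, {hi:.2f}]")
    return AttitudeCorrection(site=rec.site,
                              rotation=_minimal_rotation_to_vertical(mean),
                              static_mean_accel=mean)


def apply_attitude(rec: SensorRecording, ac: AttitudeCorrection) -> SensorRecording:
    """Rotate all samples into the gravity-aligned frame; labels become AP/ML/V."""
    if ac.site != rec.site:
        raise ValueError(f"attitude correction fitted on {ac.site!r}, not {rec.site!r}")
    R = ac.rotation
    gyro = rec.gyro @ R.T if rec.gyro is not None else None
    return replace(rec, accel=rec.accel @ R.T, gyro=gyro,
                   axis_labels=("AP", "ML", "V"))


def lowpass(rec: SensorRecording, cutoff_hz: float = 10.0, order: int = 4,
            mode: str = "zero_phase") -> SensorRecording:
    """Low-pass Butterworth filter of every channel.

    ``zero_phase`` (default) runs a half-order design forward and backward
    (net magnitude = an ``order``-order Butterworth at ``cutoff_hz``, no phase
    distortion) with reflect padding of 3×order at each end; ``causal`` runs a
    single forward pass of the full-order design.
    """
    nyq = rec.rate_hz / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below Nyquist ({nyq} Hz)")

    if mode == "zero_phase":
        b, a = signal.butter(order // 2, cutoff_hz / nyq)

        def run(x: np.ndarray) -> np.ndarray:
            return signal.filtfilt(b, a, x, axis=0, padtype="even", padlen=3 * order)
    elif mode == "causal":
        b, a = signal.butter(order, cutoff_hz / nyq)

        def run(x: np.ndarray) -> np.ndarray:
            return signal.lfilter(b, a, x, axis=0)
    else:
        raise ValueError("mode must be 'zero_phase' or 'causal'")

    gyro = run(rec.gyro) if rec.gyro is not None else None
    return replace(rec, accel=run(rec.accel), gyro=gyro)


def preprocess_session(session, cutoff_hz: float = 10.0, order: int = 4,
                       mode: str = "zero_phase", static_tolerance_g: float = 0.2):
    """Attitude-correct and filter every recording of a session (new session)."""
    corrected = {}
    for site, rec in session.recordings.items():
        ac = fit_attitude(rec, session.static_window_s, static_tolerance_g)
        corrected[site] = lowpass(apply_attitude(rec, ac), cutoff_hz, order, mode)
    return replace(session, recordings=corrected)
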
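"""Reading and writing of sensor recordings, session manifests and score tables.

No standard interchange format exists for raw body-worn IMU gait recordings,
so this package defines a small, diff-able plain-text dialect:

* one CSV per sensor site with columns ``time_s,ax,ay,az[,gx,gy,gz]``
  (header row required);
* a YAML session manifest naming the per-site files, the input units, the
  standing-still window used for attitude correction, and subject/session
  metadata;
* KOOS score tables as CSV with columns
  ``subject_id,timepoint,pain,symptoms,adl,qol``.

Units are converted at this boundary only: internally acceleration is always
m/s² and angular velocity deg/s.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

#: standard gravity, m/s²
G = 9.80665

SITES = ("back", "thigh", "shank", "foot")
SESSION_KINDS = ("baseline1", "baseline2", "post")
KOOS_SUBSCALES = ("pain", "symptoms", "adl", "qol")
TIMEPOINTS = ("pre", "post")

_ACCEL_FACTORS = {"m/s^2": 1.0, "m/s2": 1.0, "g": G}
_GYRO_FACTORS = {"deg/s": 1.0, "rad/s": 180.0 / np.pi}


class ManifestError(ValueError):
    """Raised when a session manifest or one of its CSV files is invalid."""


@dataclass
class SensorRecording:
    """Synchronized tri-axial signals from one body-worn sensor.

    ``accel`` is T×3 in m/s²; ``gyro`` is T×3 in deg/s or ``None`` for sites
    where angular velocity is not needed.  ``ml_axis``/``ml_sign`` identify
    the mediolateral gyro column (foot sensor only) and its sign convention.
    """

    site: str
    rate_hz: float
    accel: np.ndarray
    gyro: Optional[np.ndarray] = None
    axis_labels: tuple[str, str, str] = ("x", "y", "z")
    ml_axis: Optional[int] = None
    ml_sign: int = 1

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}; expected one of {SITES}")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        self.accel = np.asarray(self.accel, dtype=float)
        if self.accel.ndim != 2 or self.accel.shape[1] != 3 or self.accel.shape[0] < 1:
            raise ValueError("accel must be a T×3 array with T ≥ 1")
        if not np.isfinite(self.accel).all():
            bad = int(np.argwhere(~np.isfinite(self.accel))[0, 0])
            raise ValueError(f"non-finite acceleration sample at row {bad} ({self.site})")
        if self.gyro is not None:
            self.gyro = np.asarray(self.gyro, dtype=float)
            if self.gyro.shape != self.accel.shape:
                raise ValueError("gyro must match accel shape (T×3)")
            if not np.isfinite(self.gyro).all():
                bad = int(np.argwhere(~np.isfinite(self.gyro))[0, 0])
                raise ValueError(f"non-finite gyro sample at row {bad} ({self.site})")
        self.axis_labels = tuple(self.axis_labels)  # type: ignore[assignment]
        if len(self.axis_labels) != 3:
            raise ValueError("axis_labels must have 3 entries")

    @property
    def n_samples(self) -> int:
        return self.accel.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz


@dataclass
class GaitSession:
    """One treadmill trial: recordings from all four sites plus metadata."""

    subject_id: str
    session_kind: str
    speed_mps: float
    recordings: dict[str, SensorRecording]
    static_window_s: tuple[float, float]

    def __post_init__(self) -> None:
        if self.session_kind not in SESSION_KINDS:
            raise ValueError(
                f"session_kind {self.session_kind!r} not in {SESSION_KINDS}"
            )
        if self.speed_mps <= 0:
            raise ValueError("speed_mps must be positive")
        for site in ("back", "thigh", "shank"):
            if site not in self.recordings:
                raise ManifestError(f"missing required site {site!r}")
        if "foot" not in self.recordings:
            raise ManifestError("missing required site 'foot'")
        if self.recordings["foot"].gyro is None:
            raise ManifestError("foot recording must include gyro channels (gx,gy,gz)")
        rates = {rec.rate_hz for rec in self.recordings.values()}
        if len(rates) > 1:
            raise ManifestError(f"inconsistent sampling rates across sites: {sorted(rates)}")
        a, b = self.static_window_s
        dur = min(rec.duration_s for rec in self.recordings.values())
        if not (0 <= a < b <= dur):
            raise ManifestError(
                f"static window {self.static_window_s} outside recording duration {dur:.2f} s"
            )
        self.static_window_s = (float(a), float(b))

    @property
    def rate_hz(self) -> float:
        return next(iter(self.recordings.values())).rate_hz


@dataclass
class KoosRecord:
    """KOOS subscale scores (0–100 each) for one subject at one timepoint."""

    subject_id: str
    timepoint: str
    pain: float
    symptoms: float
    adl: float
    qol: float

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}")
        for name in KOOS_SUBSCALES:
            v = getattr(self, name)
            if not (0 <= v <= 100):
                raise ValueError(f"KOOS subscale {name} = {v} outside [0, 100]")

    def subscales(self) -> np.ndarray:
        return np.array([self.pain, self.symptoms, self.adl, self.qol], dtype=float)


def convert_accel(values: np.ndarray, units: str) -> np.ndarray:
    """Convert acceleration from declared input units to m/s²."""
    try:
        return np.asarray(values, dtype=float) * _ACCEL_FACTORS[units]
    except KeyError:
        raise ManifestError(f"unknown acceleration units {units!r}") from None


def convert_gyro(values: np.ndarray, units: str) -> np.ndarray:
    """Convert angular velocity from declared input units to deg/s."""
    try:
        return np.asarray(values, dtype=float) * _GYRO_FACTORS[units]
    except KeyError:
        raise ManifestError(f"unknown gyro units {units!r}") from None


def _read_sensor_csv(path: Path, site: str, rate_hz: float, units: dict,
                     need_gyro: bool) -> tuple[np.ndarray, Optional[np.ndarray]]:
    df = pd.read_csv(path)
    for col in ("time_s", "ax", "ay", "az"):
        if col not in df.columns:
            raise ManifestError(f"{site}: column {col!r} missing in {path}")
    accel = convert_accel(df[["ax", "ay", "az"]].to_numpy(), units.get("accel", "m/s^2"))
    gyro = None
    if {"gx", "gy", "gz"}.issubset(df.columns):
        gyro = convert_gyro(df[["gx", "gy", "gz"]].to_numpy(), units.get("gyro", "deg/s"))
    elif need_gyro:
        raise ManifestError(f"{site}: gyro columns (gx,gy,gz) required but missing in {path}")
    # the time column is informative only; warn when spacing disagrees with rate
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) > 1:
        dt = np.diff(t)
        if np.max(np.abs(dt - 1.0 / rate_hz)) > 0.1 / rate_hz:
            warnings.warn(
                f"{site}: time column spacing deviates >10% from 1/rate_hz; "
                "samples are treated as uniformly spaced", stacklevel=3)
    return accel, gyro


def read_session(manifest_path: str | Path) -> GaitSession:
    """Read a session manifest (YAML) and its per-site CSVs into a GaitSession.

    The manifest declares per-site file paths (relative to the manifest),
    input units, the static standing window, and subject/session metadata.
    Any missing site, inconsistent rate, or non-finite sample is fatal.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        man = yaml.safe_load(fh)
    base = manifest_path.parent
    rate_hz = float(man.get("rate_hz", 100.0))
    units = man.get("units", {})
    sensors = man.get("sensors", {})
    recordings: dict[str, SensorRecording] = {}
    for site in SITES:
        if site not in sensors:
            raise ManifestError(f"manifest missing sensor entry for site {site!r}")
        entry = sensors[site]
        path = base / entry["file"]
        if not path.exists():
            raise ManifestError(f"{site}: sensor file not found: {path}")
        accel, gyro = _read_sensor_csv(path, site, rate_hz, units, need_gyro=(site == "foot"))
        ml_axis = entry.get("ml_axis")
        if isinstance(ml_axis, str):
            labels = [str(x) for x in entry.get("axis_labels", ["x", "y", "z"])]
            ml_axis = labels.index(ml_axis)
        recordings[site] = SensorRecording(
            site=site,
            rate_hz=rate_hz,
            accel=accel,
            gyro=gyro,
            axis_labels=tuple(entry.get("axis_labels", ("x", "y", "z"))),
            ml_axis=ml_axis,
            ml_sign=int(entry.get("ml_sign", 1)),
        )
    return GaitSession(
        subject_id=str(man["subject_id"]),
        session_kind=str(man["session_kind"]),
        speed_mps=float(man.get("speed_mps", 1.1)),
        recordings=recordings,
        static_window_s=tuple(man.get("static_window_s", (0.0, 2.0))),
    )


def write_session(session: GaitSession, out_dir: str | Path,
                  accel_units: str = "m/s^2", gyro_units: str = "deg/s") -> Path:
    """Write a GaitSession as manifest + per-site CSVs; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sensors = {}
    for site, rec in session.recordings.items():
        t = np.arange(rec.n_samples) / rec.rate_hz
        cols = {"time_s": t,
                "ax": rec.accel[:, 0] / _ACCEL_FACTORS[accel_units],
                "ay": rec.accel[:, 1] / _ACCEL_FACTORS[accel_units],
                "az": rec.accel[:, 2] / _ACCEL_FACTORS[accel_units]}
        if rec.gyro is not None:
            cols.update({"gx": rec.gyro[:, 0] / _GYRO_FACTORS[gyro_units],
                         "gy": rec.gyro[:, 1] / _GYRO_FACTORS[gyro_units],
                         "gz": rec.gyro[:, 2] / _GYRO_FACTORS[gyro_units]})
        fname = f"{site}.csv"
        pd.DataFrame(cols).to_csv(out_dir / fname, index=False, float_format="%.10g")
        entry: dict = {"file": fname, "axis_labels": list(rec.axis_labels)}
        if rec.ml_axis is not None:
            entry["ml_axis"] = int(rec.ml_axis)
            entry["ml_sign"] = int(rec.ml_sign)
        sensors[site] = entry
    man = {
        "subject_id": session.subject_id,
        "session_kind": session.session_kind,
        "speed_mps": session.speed_mps,
        "rate_hz": session.rate_hz,
        "static_window_s": list(session.static_window_s),
        "units": {"accel": accel_units, "gyro": gyro_units},
        "sensors": sensors,
    }
    manifest_path = out_dir / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(man, fh, sort_keys=False)
    return manifest_path


# ---------------------------------------------------------------------------
# cycle-matrix persistence (see segment.CycleMatrix)

def write_cycle_matrix(cm, path: str | Path) -> Path:
    """Persist a CycleMatrix losslessly as CSV with a JSON layout header line."""
    path = Path(path)
    prov = cm.provenance.copy()
    data = pd.DataFrame(cm.X, columns=[f"c{j:03d}" for j in range(cm.X.shape[1])])
    out = pd.concat([prov.reset_index(drop=True), data], axis=1)
    with open(path, "w") as fh:
        fh.write("# layout=" + json.dumps(cm.layout.to_dict()) + "\n")
        out.to_csv(fh, index=False, float_format="%.17g")
    return path


def read_cycle_matrix(path: str | Path):
    """Inverse of :func:`write_cycle_matrix`; fatal if not exactly 900 value columns."""
    from .segment import CycleMatrix, CycleLayout

    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# layout="):
            raise ValueError(f"{path}: missing layout header")
        layout = CycleLayout.from_dict(json.loads(header[len("# layout="):]))
        df = pd.read_csv(fh, float_precision="round_trip")
    value_cols = [c for c in df.columns if c.startswith("c")]
    if len(value_cols) != layout.n_columns:
        raise ValueError(
            f"{path}: expected {layout.n_columns} value columns, found {len(value_cols)}")
    prov_cols = [c for c in df.columns if not c.startswith("c")]
    return CycleMatrix(X=df[value_cols].to_numpy(dtype=float),
                       provenance=df[prov_cols].copy(),
                       layout=layout)


# ---------------------------------------------------------------------------
# KOOS tables

def read_koos_table(path: str | Path) -> list[KoosRecord]:
    df = pd.read_csv(path)
    required = {"subject_id", "timepoint", *KOOS_SUBSCALES}
    missing = required - set(df.columns)
    if missing:
        raise ManifestError(f"KOOS table missing columns: {sorted(missing)}")
    return [
        KoosRecord(subject_id=str(r.subject_id), timepoint=str(r.timepoint),
                   pain=float(r.pain), symptoms=float(r.symptoms),
                   adl=float(r.adl), qol=float(r.qol))
        for r in df.itertuples()
    ]


def write_koos_table(records: list[KoosRecord], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame([
        {"subject_id": r.subject_id, "timepoint": r.timepoint,
         "pain": r.pain, "symptoms": r.symptoms, "adl": r.adl, "qol": r.qol}
        for r in records
    ]).to_csv(path, index=False)
    return path
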
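"""CSV input/output for IMU, reference and result files.

The IMU dialect is a plain CSV with a commented metadata preamble::

    # f_hz=500
    # accel_units=ms2        (or g)
    # gyro_units=rads        (or dps)
    time_s,ax,ay,az,gx,gy,gz
    0.000,0.01,-0.02,9.80,0.001,0.000,-0.002
    ...

Accelerometer columns are converted to m/s^2 and gyroscope columns to
rad/s on ingest.  Reference files carry ``time_s,cord_length_m`` with
``f_ref_hz`` and ``pulley_height_m`` in the preamble.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import ImuRecording
from .orientation import STANDARD_GRAVITY
from .reference import ReferenceRecording

__all__ = [
    "read_imu_csv",
    "write_imu_csv",
    "read_reference_csv",
    "write_reference_csv",
    "write_velocity_csv",
    "write_report_json",
]


def _read_preamble(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, value = line.lstrip("# ").strip().split("=", 1)
                meta[key.strip()] = value.strip()
    return meta


def read_imu_csv(path: str | Path) -> ImuRecording:
    """Read an IMU recording, converting units per the preamble."""
    path = Path(path)
    meta = _read_preamble(path)
    f = float(meta.get("f_hz", 500.0))
    df = pd.read_csv(path, comment="#")
    required = ["time_s", "ax", "ay", "az", "gx", "gy", "gz"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"IMU CSV missing columns: {missing}")
    accel = df[["ax", "ay", "az"]].to_numpy(dtype=float)
    gyro = df[["gx", "gy", "gz"]].to_numpy(dtype=float)
    if meta.get("accel_units", "ms2") == "g":
        accel = accel * STANDARD_GRAVITY
    if meta.get("gyro_units", "rads") == "dps":
        gyro = np.deg2rad(gyro)
    return ImuRecording(t=df["time_s"].to_numpy(dtype=float), accel=accel, gyro=gyro, f=f)


def write_imu_csv(path: str | Path, recording: ImuRecording) -> None:
    path = Path(path)
    df = pd.DataFrame(
        np.column_stack([recording.t, recording.accel, recording.gyro]),
        columns=["time_s", "ax", "ay", "az", "gx", "gy", "gz"],
    )
    with open(path, "w") as fh:
        fh.write(f"# f_hz={recording.f:g}\n# accel_units=ms2\n# gyro_units=rads\n")
        df.to_csv(fh, index=False, float_format="%.8g")


def read_reference_csv(path: str | Path) -> ReferenceRecording:
    """Read a tethered-speedometer cord-length recording."""
    path = Path(path)
    meta = _read_preamble(path)
    f_ref = float(meta.get("f_ref_hz", 100.0))
    pulley = float(meta.get("pulley_height_m", 0.72))
    df = pd.read_csv(path, comment="#")
    if "cord_length_m" in df.columns:
        cord = df["cord_length_m"].to_numpy(dtype=float)
    elif "displacement_m" in df.columns:
        tare = float(meta.get("tare_m", 0.0))
        cord = df["displacement_m"].to_numpy(dtype=float) + tare
    else:
        raise ValueError("reference CSV needs a cord_length_m or displacement_m column")
    return ReferenceRecording(
        t=df["time_s"].to_numpy(dtype=float), cord_length=cord,
        f_ref=f_ref, pulley_height=pulley,
    )


def write_reference_csv(path: str | Path, ref: ReferenceRecording) -> None:
    path = Path(path)
    df = pd.DataFrame({"time_s": ref.t, "cord_length_m": ref.cord_length})
    with open(path, "w") as fh:
        fh.write(f"# f_ref_hz={ref.f_ref:g}\n# pulley_height_m={ref.pulley_height:g}\n")
        df.to_csv(fh, index=False, float_format="%.8g")


def write_velocity_csv(path: str | Path, v: np.ndarray, f: float) -> None:
    t = np.arange(len(v)) / f
    pd.DataFrame({"time_s": t, "velocity_ms": v}).to_csv(
        path, index=False, float_format="%.8g"
    )


def write_report_json(path: str | Path, report: dict) -> None:
    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        raise TypeError(f"not JSON serializable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_default)
        fh.write("\n")
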
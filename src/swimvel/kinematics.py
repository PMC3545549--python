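"""Stroke-cycle detection, forward acceleration and velocity integration.

The forward acceleration is the global-frame accelerometer signal with
gravity removed, projected onto the lane direction Y; instantaneous
velocity is its cumulative trapezoidal integral from a standing (v = 0)
start.  Stroke cycles are detected from the body-roll angular velocity:
one cycle per full roll period, bracketed by successive same-direction
zero crossings of the low-pass-filtered roll rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.integrate import cumulative_trapezoid

from . import quat
from .orientation import FORWARD, STANDARD_GRAVITY, OrientationSeries

__all__ = [
    "ImuRecording",
    "CycleSet",
    "VelocityProfile",
    "detect_cycles",
    "forward_acceleration",
    "integrate_velocity",
    "cycle_means",
]

#: Physiological bounds on a front-crawl body-roll period (seconds).
MIN_CYCLE_S = 0.4
MAX_CYCLE_S = 5.0


@dataclass
class ImuRecording:
    """Uniformly sampled 3D accelerometer + gyroscope recording.

    ``accel`` is (n, 3) in m s^-2 and ``gyro`` (n, 3) in rad s^-1, both in
    the sensor frame; ``f`` is the sampling rate in Hz (500 by default for
    the logger emulated here).
    """

    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    f: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        n = len(self.t)
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValueError("accel and gyro must be (n, 3) matching t")
        if n >= 2:
            dt = np.diff(self.t)
            if np.max(np.abs(dt - 1.0 / self.f)) > 1e-6:
                raise ValueError("non-uniform sampling or rate mismatch")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return len(self) / self.f


@dataclass
class CycleSet:
    """Ordered stroke-cycle boundary sample indices within a trial.

    Cycle ``k`` spans samples ``[boundaries[k], boundaries[k+1])``; with
    ``m`` boundaries there are ``m - 1`` cycles.
    """

    boundaries: np.ndarray
    f: float

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=int)
        if len(b) >= 2:
            lengths = np.diff(b)
            if np.any(lengths <= 0):
                raise ValueError("cycle boundaries must be strictly increasing")
            if np.any(lengths < MIN_CYCLE_S * self.f) or np.any(lengths > MAX_CYCLE_S * self.f):
                raise ValueError(
                    f"cycle lengths outside the physiological range "
                    f"[{MIN_CYCLE_S}, {MAX_CYCLE_S}] s"
                )
        self.boundaries = b

    @property
    def n_cycles(self) -> int:
        return max(len(self.boundaries) - 1, 0)

    @property
    def lengths(self) -> np.ndarray:
        """Samples per cycle."""
        return np.diff(self.boundaries)

    @property
    def frequencies(self) -> np.ndarray:
        """Per-cycle stroke frequency f / n_k (Hz)."""
        return self.f / self.lengths

    def slices(self) -> list[slice]:
        b = self.boundaries
        return [slice(int(b[k]), int(b[k + 1])) for k in range(self.n_cycles)]


@dataclass
class VelocityProfile:
    """Forward velocity series with its per-cycle means."""

    v: np.ndarray
    f: float
    cycle_means: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __len__(self) -> int:
        return len(self.v)


def detect_cycles(
    recording: ImuRecording,
    orientation: OrientationSeries,
    cutoff_hz: float = 3.0,
    refractory_s: float = 0.4,
    min_peak_frac: float = 0.7,
) -> CycleSet:
    """Detect stroke cycles from the global-frame roll angular velocity.

    The gyroscope is rotated to the global frame, its forward-axis (roll)
    component low-pass filtered at ``cutoff_hz``, and upward zero
    crossings taken as cycle boundaries, subject to a refractory period
    and an amplitude gate: the positive roll lobe following a boundary
    must reach ``min_peak_frac`` of the *median* lobe peak.  The gate
    rejects chatter and, more importantly, the partial-amplitude roll of
    the push-off transition — a stroke cycle is a full-amplitude body
    roll, and transition cycles would otherwise contaminate the
    peak-envelope drift model downstream.

    Raises ``ValueError`` when fewer than two boundaries (one full cycle)
    are found.
    """
    if len(recording) < 2 * recording.f:
        raise ValueError("need at least 2 s of data for cycle detection")
    omega_gf = quat.rotate(orientation.q, recording.gyro)
    roll = omega_gf @ FORWARD
    nyq = recording.f / 2.0
    sos = signal.butter(4, cutoff_hz / nyq, btype="low", output="sos")
    roll_f = signal.sosfiltfilt(sos, roll)

    if np.max(np.abs(roll_f)) < 1e-9:
        raise ValueError("no cycles: roll angular velocity is flat")

    up = np.nonzero((roll_f[:-1] < 0) & (roll_f[1:] >= 0))[0] + 1
    if len(up) == 0:
        raise ValueError("no cycles: roll rate never crosses zero upward")
    lobe_edges = np.append(up, len(roll_f))
    lobe_peaks = np.array(
        [np.max(roll_f[lobe_edges[i]:lobe_edges[i + 1]], initial=0.0)
         for i in range(len(up))]
    )
    gate = min_peak_frac * float(np.median(lobe_peaks))

    refractory = int(refractory_s * recording.f)
    boundaries: list[int] = []
    for idx, lobe in zip(up, lobe_peaks):
        if boundaries and idx - boundaries[-1] < refractory:
            continue
        if lobe < gate:
            continue
        boundaries.append(int(idx))

    # drop boundaries that would create cycles outside physiological bounds
    cleaned: list[int] = []
    for idx in boundaries:
        if cleaned and idx - cleaned[-1] > MAX_CYCLE_S * recording.f:
            cleaned = [idx]        # restart after an implausibly long gap
        else:
            cleaned.append(idx)
    if len(cleaned) < 2:
        raise ValueError("no cycles: fewer than 2 roll zero crossings detected")
    return CycleSet(boundaries=np.asarray(cleaned, dtype=int), f=recording.f)


def forward_acceleration(
    recording: ImuRecording,
    corrected: OrientationSeries,
    gravity: float = STANDARD_GRAVITY,
) -> np.ndarray:
    """Forward (lane-direction) acceleration in the global frame.

    Each accelerometer sample is rotated to the global frame with the
    corrected orientation; adding the gravity vector (0, 0, -g) converts
    specific force to body acceleration, which is projected onto the
    forward axis.  For a static, correctly oriented sensor the result is
    identically zero.
    """
    if len(recording) != len(corrected.q):
        raise ValueError("recording and orientation series lengths differ")
    a_gf = quat.rotate(corrected.q, recording.accel)
    g_vec = np.array([0.0, 0.0, -gravity])
    return (a_gf + g_vec) @ FORWARD


def integrate_velocity(a_forward: np.ndarray, f: float, v0: float = 0.0) -> np.ndarray:
    """Cumulative trapezoidal integration of forward acceleration."""
    if f <= 0:
        raise ValueError("sampling rate must be positive")
    a = np.asarray(a_forward, dtype=float)
    return v0 + cumulative_trapezoid(a, dx=1.0 / f, initial=0.0)


def cycle_means(v: np.ndarray, cycles: CycleSet) -> np.ndarray:
    """Arithmetic mean of the velocity over each stroke cycle."""
    v = np.asarray(v, dtype=float)
    if cycles.boundaries[-1] > len(v):
        raise ValueError("cycles extend beyond the velocity series")
    return np.array([v[s].mean() for s in cycles.slices()])
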
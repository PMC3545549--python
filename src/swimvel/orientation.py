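"""Sensor orientation tracking with the body-roll drift constraint.

The sacrum-worn IMU's orientation relative to the pool (global frame:
X lateral, Y forward along the lane, Z vertically up) is obtained by

1. an initial pose from a static accelerometer reading — at rest the
   accelerometer measures the reaction to gravity, so its reading is the
   sensor-frame image of global +Z (the start azimuth is taken as zero:
   no magnetometer is available, and the forward direction is pinned down
   by the roll constraint below);
2. strapdown integration of the gyroscope (incremental axis–angle
   quaternions applied in the body frame);
3. a per-stroke-cycle drift correction exploiting the front-crawl
   biomechanical constraint that, averaged over a full body-roll cycle,
   the sacrum rotates about the forward axis.  Within each cycle the
   dominant (first principal component) direction of the global-frame
   angular velocity is compared with the forward axis; the deviation
   angle is attributed to gyroscopic drift and removed by a corrective
   rotation ramped linearly over the cycle.  Corrections accumulate from
   cycle to cycle, so each cycle only has to remove the drift it itself
   accrued.

Sign convention (used everywhere): the corrective rotation axis is
``u = p × Y`` with a positive ramp angle, chosen so that the
end-of-cycle rotation carries the measured principal axis ``p`` exactly
onto the forward axis ``Y``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import quat

__all__ = [
    "FORWARD",
    "VERTICAL",
    "StaticPose",
    "CycleDriftCorrection",
    "OrientationSeries",
    "initial_orientation",
    "update_orientation",
    "strapdown_orientation",
    "rotate_to_global",
    "principal_roll_axis",
    "drift_correction_for_cycle",
    "corrective_quaternion",
    "correct_orientation_series",
]

logger = logging.getLogger(__name__)

#: Global-frame forward (swimming) direction.
FORWARD = np.array([0.0, 1.0, 0.0])
#: Global-frame vertical (up) direction.
VERTICAL = np.array([0.0, 0.0, 1.0])

#: Standard gravity used throughout (m s^-2); configurable via RunConfig.
STANDARD_GRAVITY = 9.81


@dataclass(frozen=True)
class StaticPose:
    """Initial sensor pose derived from a static accelerometer reading.

    Attributes
    ----------
    theta0 : float
        Initial inclination angle in radians, in [0, π].
    u0 : ndarray
        Horizontal rotation axis (unit 3-vector with zero Z component).
    q0 : ndarray
        Initial sensor-to-global quaternion.
    """

    theta0: float
    u0: np.ndarray
    q0: np.ndarray


@dataclass(frozen=True)
class CycleDriftCorrection:
    """Drift correction parameters for one stroke cycle."""

    cycle_index: int
    p_axis: np.ndarray        # principal angular-velocity axis, global frame
    delta_theta: float        # drift angle (rad)
    u_axis: np.ndarray        # corrective rotation axis (unit, ⊥ forward)
    n_samples: int


@dataclass
class OrientationSeries:
    """Per-sample sensor-to-global unit quaternions at sampling rate ``f``."""

    q: np.ndarray             # (n, 4) scalar-first unit quaternions
    f: float
    corrections: list[CycleDriftCorrection] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.q)


def initial_orientation(a0: np.ndarray, gravity: float = STANDARD_GRAVITY) -> StaticPose:
    """Initial sensor-to-global quaternion from a static accelerometer reading.

    Parameters
    ----------
    a0 : array-like, shape (3,)
        Mean accelerometer reading (m s^-2, sensor frame) over a motionless
        window.  At rest the reading is the reaction to gravity, i.e. the
        sensor-frame image of global +Z scaled by g.
    gravity : float
        Local gravity magnitude used for the plausibility check.

    Returns
    -------
    StaticPose
        ``q0`` rotates the normalized reading onto global +Z; ``theta0`` is
        the inclination from upright and ``u0`` the horizontal rotation axis.

    Raises
    ------
    ValueError
        If the reading's magnitude deviates more than 15% from gravity
        (the sensor was not static) or is zero.
    """
    a0 = np.asarray(a0, dtype=float)
    if a0.shape != (3,):
        raise ValueError("a0 must be a 3-vector")
    mag = np.linalg.norm(a0)
    if mag == 0.0:
        raise ValueError("zero accelerometer reading")
    if abs(mag - gravity) > 0.15 * gravity:
        raise ValueError(
            f"static accelerometer magnitude {mag:.3f} deviates more than 15% "
            f"from gravity {gravity:.3f}; sensor not static"
        )
    a_hat = a0 / mag
    theta0 = float(np.arccos(np.clip(a_hat @ VERTICAL, -1.0, 1.0)))
    u0 = np.cross(a_hat, VERTICAL)          # horizontal: z component is 0
    n = np.linalg.norm(u0)
    if n < 1e-12:
        # upright (theta0 = 0) or exactly inverted (theta0 = π): any
        # horizontal axis works, pick X
        u0 = np.array([1.0, 0.0, 0.0])
    else:
        u0 = u0 / n
    q0 = quat.from_axis_angle(u0, theta0)
    return StaticPose(theta0=theta0, u0=u0, q0=q0)


def update_orientation(q_prev: np.ndarray, omega: np.ndarray, f: float) -> np.ndarray:
    """One strapdown step: apply the body-frame angular increment ω/f.

    The increment quaternion (angle ‖ω‖/f about ω̂) composes on the body
    side, ``q_t = q_{t-1} ⊗ Δq``, and the result is renormalized.
    ``ω = 0`` yields an unchanged orientation.
    """
    if f <= 0:
        raise ValueError("sampling rate must be positive")
    omega = np.asarray(omega, dtype=float)
    w = np.linalg.norm(omega)
    if w == 0.0:
        return quat.normalize(q_prev)
    dq = quat.from_axis_angle(omega / w, w / f)
    return quat.normalize(quat.multiply(q_prev, dq))


def strapdown_orientation(gyro: np.ndarray, f: float, q0: np.ndarray) -> np.ndarray:
    """Integrate a gyroscope series into an orientation series.

    ``gyro`` is (n, 3) in rad s^-1 (sensor frame); sample ``t`` steps the
    orientation from ``t-1`` to ``t``; the first sample's orientation is
    ``q0``.  Returns an (n, 4) unit-quaternion array.
    """
    gyro = np.asarray(gyro, dtype=float)
    n = len(gyro)
    rates = np.linalg.norm(gyro, axis=1)
    safe = np.where(rates < 1e-15, 1.0, rates)
    axes = gyro / safe[:, None]
    half = rates / (2.0 * f)
    incs = np.concatenate([np.cos(half)[:, None], axes * np.sin(half)[:, None]], axis=1)
    incs[rates < 1e-15] = [1.0, 0.0, 0.0, 0.0]

    out = np.empty((n, 4))
    q = np.asarray(q0, dtype=float)
    out[0] = q
    for t in range(1, n):
        q = quat.multiply(q, incs[t])
        q = q / np.linalg.norm(q)
        out[t] = q
    return out


def rotate_to_global(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Express sensor-frame vector(s) in the global frame: q ⊗ v ⊗ q⁻¹."""
    return quat.rotate(q, v)


def principal_roll_axis(omega_global: np.ndarray) -> np.ndarray:
    """First principal component of a cycle's global-frame angular velocity.

    The sign is fixed so the axis has a non-negative dot product with the
    forward direction.  Raises on fewer than 3 samples or a degenerate
    (all-zero) cloud.
    """
    w = np.asarray(omega_global, dtype=float)
    if w.ndim != 2 or w.shape[1] != 3 or len(w) < 3:
        raise ValueError("need at least 3 angular-velocity samples")
    centered = w - w.mean(axis=0)
    cov = centered.T @ centered / (len(w) - 1)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] < 1e-18:
        raise ValueError("degenerate angular-velocity cloud: unusable cycle")
    p = evecs[:, -1]
    if p @ FORWARD < 0:
        p = -p
    return p


def drift_correction_for_cycle(p_axis: np.ndarray, n_samples: int, cycle_index: int = 0) -> CycleDriftCorrection:
    """Drift angle and corrective axis for one cycle.

    ``delta_theta = arccos(Y · p)``; ``u = p × Y`` normalized (so a
    positive rotation about ``u`` by ``delta_theta`` carries ``p`` onto
    the forward axis).  A principal axis already parallel to forward gives
    a zero-angle correction with a placeholder axis.
    """
    p = np.asarray(p_axis, dtype=float)
    if abs(np.linalg.norm(p) - 1.0) > 1e-6:
        raise ValueError("p_axis must be a unit vector")
    if n_samples < 2:
        raise ValueError("cycle must contain at least 2 samples")
    delta_theta = float(np.arccos(np.clip(p @ FORWARD, -1.0, 1.0)))
    u = np.cross(p, FORWARD)
    n = np.linalg.norm(u)
    if n < 1e-12:
        u = np.array([1.0, 0.0, 0.0])   # unused: delta_theta is 0 (or π)
    else:
        u = u / n
    return CycleDriftCorrection(
        cycle_index=cycle_index, p_axis=p, delta_theta=delta_theta,
        u_axis=u, n_samples=int(n_samples),
    )


def corrective_quaternion(corr: CycleDriftCorrection, t_in_cycle: int) -> np.ndarray:
    """Linearly ramped corrective rotation for the t-th sample of a cycle.

    ``t_in_cycle`` is 1-based; the rotation angle grows linearly from 0 at
    the first sample to ``delta_theta`` at the last.
    """
    n = corr.n_samples
    if n < 2:
        raise ValueError("cycle must contain at least 2 samples")
    if not 1 <= t_in_cycle <= n:
        raise ValueError("t_in_cycle out of range")
    angle = corr.delta_theta * (t_in_cycle - 1) / (n - 1)
    return quat.from_axis_angle(corr.u_axis, angle)


def _correction_pass(
    q_in: np.ndarray, gyro: np.ndarray, boundaries: np.ndarray, pass_index: int
) -> tuple[np.ndarray, list[CycleDriftCorrection]]:
    """One sweep of per-cycle measurement and ramped correction."""
    q_out = q_in.copy()
    corrections: list[CycleDriftCorrection] = []
    acc = quat.identity()   # accumulated correction, applied on the global side

    for k in range(len(boundaries) - 1):
        s, e = int(boundaries[k]), int(boundaries[k + 1])
        n = e - s
        if n < 2:
            if pass_index == 0:
                logger.warning("cycle %d has %d samples; skipped", k, n)
            continue
        q_eff = quat.multiply(acc, q_in[s:e])
        omega_gf = quat.rotate(q_eff, gyro[s:e])
        try:
            p = principal_roll_axis(omega_gf)
        except ValueError:
            if pass_index == 0:
                logger.warning("cycle %d has a degenerate angular-velocity cloud; skipped", k)
            q_out[s:e] = q_eff
            continue
        corr = drift_correction_for_cycle(p, n, cycle_index=k)
        # the first ramp starts at sample 0: drift accrued from the start
        # of integration, not from the first detected cycle boundary
        ramp_start = 0 if not corrections else s
        m = e - ramp_start
        angles = corr.delta_theta * np.arange(m) / (m - 1)
        ramp = quat.from_axis_angle(np.broadcast_to(corr.u_axis, (m, 3)), angles)
        q_out[ramp_start:e] = quat.multiply(
            quat.multiply(ramp, np.broadcast_to(acc, (m, 4))), q_in[ramp_start:e]
        )
        acc = quat.multiply(quat.from_axis_angle(corr.u_axis, corr.delta_theta), acc)
        corrections.append(corr)

    if len(boundaries) >= 2:
        last = int(boundaries[-1])
        # after the last cycle hold the final accumulated correction
        if last < len(q_in):
            q_out[last:] = quat.multiply(np.broadcast_to(acc, (len(q_in) - last, 4)), q_in[last:])
    return q_out, corrections


def correct_orientation_series(
    series: OrientationSeries,
    gyro: np.ndarray,
    boundaries: np.ndarray,
    max_passes: int = 1,
    tol_rad: float = np.deg2rad(0.1),
) -> OrientationSeries:
    """Apply the per-cycle roll-constraint drift correction.

    Parameters
    ----------
    series : OrientationSeries
        Raw strapdown orientations.
    gyro : ndarray, shape (n, 3)
        Sensor-frame angular velocity (rad s^-1) matching the series.
    boundaries : ndarray
        Ordered stroke-cycle boundary sample indices; cycle ``k`` spans
        ``[boundaries[k], boundaries[k+1])``.
    max_passes, tol_rad :
        Number of measurement-and-correction sweeps; extra sweeps stop
        early once the largest per-cycle drift angle falls below
        ``tol_rad``.  The sweep is a contraction, but the per-cycle
        principal axis carries a motion-induced deviation of order 1
        degree (pitch/yaw components of genuine body motion), so
        iterating past the first sweep chases that floor rather than
        residual drift — one pass is the default and the recommendation.

    Returns
    -------
    OrientationSeries
        Corrected quaternions with the first sweep's per-cycle
        corrections attached (the dominant ones).  Within each sweep the
        corrections accumulate: each cycle's drift is measured after
        applying earlier cycles' corrections.  Gyroscopic drift accrues
        from the start of integration, so the first cycle's corrective
        ramp spans from sample 0 (not from the first cycle boundary);
        samples after the last cycle receive the final accumulated
        correction held constant.
    """
    q_work = np.asarray(series.q, dtype=float)
    gyro = np.asarray(gyro, dtype=float)
    boundaries = np.asarray(boundaries, dtype=int)
    if len(gyro) != len(q_work):
        raise ValueError("gyro and orientation series lengths differ")
    if boundaries.size and boundaries[-1] > len(q_work):
        raise ValueError("cycle boundaries exceed series length")

    first_corrections: list[CycleDriftCorrection] = []
    for p in range(max_passes):
        q_work, corrections = _correction_pass(q_work, gyro, boundaries, p)
        if p == 0:
            first_corrections = corrections
        if not corrections or max(c.delta_theta for c in corrections) < tol_rad:
            break

    norms = np.linalg.norm(q_work, axis=1, keepdims=True)
    q_work = q_work / norms
    return OrientationSeries(q=q_work, f=series.f, corrections=first_corrections)
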
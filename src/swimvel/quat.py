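"""Unit-quaternion algebra for orientation tracking.

Conventions (used consistently across the package):

* scalar-first storage ``q = (w, x, y, z)``;
* Hamilton product: ``multiply(p, q)`` composes rotations so that the
  rotation ``q`` is applied first, then ``p``;
* a unit quaternion ``q`` representing the sensor-to-global rotation acts
  on a sensor-frame 3-vector by conjugation, ``v_global = q ⊗ v ⊗ q⁻¹``,
  implemented in :func:`rotate`.

All functions broadcast over leading axes, so a time series of quaternions
is simply an ``(n, 4)`` array.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "identity",
    "normalize",
    "multiply",
    "conjugate",
    "inverse",
    "from_axis_angle",
    "to_axis_angle",
    "rotate",
    "to_matrix",
    "angle_between",
]


def identity() -> np.ndarray:
    """Identity rotation ``(1, 0, 0, 0)``."""
    return np.array([1.0, 0.0, 0.0, 0.0])


def normalize(q: np.ndarray) -> np.ndarray:
    """Rescale to unit norm. Raises on (near-)zero quaternions."""
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(n < 1e-12):
        raise ValueError("cannot normalize a zero quaternion")
    return q / n


def multiply(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Hamilton product p ⊗ q (apply q first, then p)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    pw, px, py, pz = p[..., 0], p[..., 1], p[..., 2], p[..., 3]
    qw, qx, qy, qz = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    return np.stack(
        [
            pw * qw - px * qx - py * qy - pz * qz,
            pw * qx + px * qw + py * qz - pz * qy,
            pw * qy - px * qz + py * qw + pz * qx,
            pw * qz + px * qy - py * qx + pz * qw,
        ],
        axis=-1,
    )


def conjugate(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def inverse(q: np.ndarray) -> np.ndarray:
    """Inverse; equals the conjugate for unit quaternions."""
    q = np.asarray(q, dtype=float)
    return conjugate(q) / np.sum(q * q, axis=-1, keepdims=True)


def from_axis_angle(axis: np.ndarray, angle: np.ndarray) -> np.ndarray:
    """Rotation of ``angle`` radians about ``axis`` (need not be unit).

    A zero axis with zero angle yields the identity; a zero axis with a
    nonzero angle is rejected.
    """
    axis = np.asarray(axis, dtype=float)
    angle = np.asarray(angle, dtype=float)
    n = np.linalg.norm(axis, axis=-1)
    zero = n < 1e-15
    if np.any(zero & (np.abs(angle) > 1e-15)):
        raise ValueError("zero rotation axis with nonzero angle")
    safe_n = np.where(zero, 1.0, n)
    u = axis / safe_n[..., None]
    half = angle / 2.0
    q = np.concatenate(
        [np.cos(half)[..., None], u * np.sin(half)[..., None]], axis=-1
    )
    if np.any(zero):
        q = np.where(zero[..., None], identity(), q)
    return q


def to_axis_angle(q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`from_axis_angle`; angle in [0, π].

    For the identity the axis is arbitrarily (1, 0, 0).
    """
    q = normalize(q)
    # flip to the w >= 0 hemisphere so the angle is minimal
    q = np.where(q[..., :1] < 0, -q, q)
    w = np.clip(q[..., 0], -1.0, 1.0)
    angle = 2.0 * np.arccos(w)
    v = q[..., 1:]
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    axis = np.where(n < 1e-15, np.array([1.0, 0.0, 0.0]), v / np.where(n < 1e-15, 1.0, n))
    return axis, angle


def rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate 3-vector(s) ``v`` by unit quaternion(s) ``q``: q ⊗ v ⊗ q⁻¹."""
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    w = q[..., :1]
    u = q[..., 1:]
    # v' = v + 2 w (u × v) + 2 u × (u × v)
    uv = np.cross(u, v)
    return v + 2.0 * (w * uv + np.cross(u, uv))


def to_matrix(q: np.ndarray) -> np.ndarray:
    """3×3 rotation matrix equivalent of a unit quaternion."""
    q = np.asarray(q, dtype=float)
    w, x, y, z = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    return np.stack(
        [
            np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)], axis=-1),
            np.stack([2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)], axis=-1),
            np.stack([2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)], axis=-1),
        ],
        axis=-2,
    )


def angle_between(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Geodesic angle (radians) between two rotations, in [0, π]."""
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    dot = np.clip(np.abs(np.sum(q1 * q2, axis=-1)), 0.0, 1.0)
    return 2.0 * np.arccos(dot)
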
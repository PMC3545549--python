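"""Tethered-speedometer reference: parallax correction and resampling.

The reference device unwinds a cord from a pulley mounted on the
starting block, about 0.72 m above the water surface, so the cord is not
parallel to the swimming direction.  With cord length L and pulley
height h, the swimmer's horizontal displacement is
``x = sqrt(L² − h²)``; forward velocity is its time derivative, taken
with centered finite differences (one-sided at the endpoints) for zero
phase lag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.signal import resample_poly

__all__ = [
    "ReferenceRecording",
    "parallax_correct",
    "resample_to",
]

logger = logging.getLogger(__name__)

DEFAULT_PULLEY_HEIGHT = 0.72   # m above still water level
DEFAULT_REF_RATE = 100.0       # Hz


@dataclass
class ReferenceRecording:
    """Cord-length samples from the tethered speedometer."""

    t: np.ndarray
    cord_length: np.ndarray
    f_ref: float = DEFAULT_REF_RATE
    pulley_height: float = DEFAULT_PULLEY_HEIGHT

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.cord_length = np.asarray(self.cord_length, dtype=float)
        if len(self.t) != len(self.cord_length):
            raise ValueError("time and cord-length series lengths differ")

    def __len__(self) -> int:
        return len(self.t)


def parallax_correct(ref: ReferenceRecording) -> np.ndarray:
    """Forward velocity (m s^-1) from cord length, parallax-corrected.

    Raises on cord lengths shorter than the pulley height (geometrically
    impossible).  Samples where the swimmer sits directly beneath the
    pulley (L = h) make the geometry singular; they are logged and their
    velocity taken from the neighboring one-sided difference.
    """
    L = ref.cord_length
    h = ref.pulley_height
    if np.any(L < h - 1e-9):
        raise ValueError("cord length shorter than pulley height: corrupt data")
    sq = np.clip(L ** 2 - h ** 2, 0.0, None)
    x = np.sqrt(sq)
    singular = sq < 1e-12
    if np.any(singular) and h > 0:
        logger.warning(
            "%d sample(s) directly beneath the pulley; using one-sided differences",
            int(np.sum(singular)),
        )
    v = np.gradient(x, 1.0 / ref.f_ref)
    if np.any(singular) and h > 0:
        idx = np.nonzero(singular)[0]
        for i in idx:
            if i + 1 < len(x):
                v[i] = (x[i + 1] - x[i]) * ref.f_ref
            elif i > 0:
                v[i] = (x[i] - x[i - 1]) * ref.f_ref
    return v


def resample_to(v: np.ndarray, f_src: float, f_dst: float) -> np.ndarray:
    """Anti-aliased resampling of a velocity series from f_src to f_dst.

    Typically used to bring the 500 Hz IMU-derived velocity down to the
    reference's 100 Hz before error statistics.  The rate ratio must be
    rational; equal rates return the input unchanged.
    """
    v = np.asarray(v, dtype=float)
    if f_src <= 0 or f_dst <= 0:
        raise ValueError("sampling rates must be positive")
    if f_src < f_dst:
        raise ValueError("only downsampling (f_src >= f_dst) is supported")
    if f_src == f_dst:
        return v.copy()
    ratio = Fraction(f_dst / f_src).limit_denominator(10_000)
    out = resample_poly(v, ratio.numerator, ratio.denominator, padtype="line")
    target = int(np.floor(len(v) * f_dst / f_src))
    return out[:target]
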
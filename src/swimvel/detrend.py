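"""Velocity drift removal by segmentation and peak-envelope splines.

Trapezoidal integration of the forward acceleration leaves a slow drift
in the velocity that must be separated from genuine changes of swimming
regime.  The forward acceleration is first segmented with a geometric
moving average (GMA) change detector — a recursive exponentially
weighted variance tracker that opens a new segment whenever the tracked
variance departs from its value at the last change point by more than a
fraction (20% by default) of the whole-trial variance.  Within each
segment the swimming regime is assumed steady, so the trend of the
velocity peaks is quasi-constant: per-cycle minimum and maximum peaks
are extracted, shape-preserving (non-overshooting piecewise-cubic,
PCHIP) interpolants are fitted through each envelope, and their
pointwise average is subtracted.  Finally the velocity is anchored to
the known trial mean (pool length divided by trial duration) by an
additive constant — integration drift is additive in velocity, so no
rescaling is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import lfilter

from .kinematics import CycleSet, VelocityProfile, cycle_means

__all__ = [
    "SegmentSet",
    "TrendModel",
    "TrialInfo",
    "gma_segment",
    "fit_trend",
    "detrend_velocity",
]

logger = logging.getLogger(__name__)

#: Default GMA forgetting factor: ~1.3 s effective memory at 500 Hz, about
#: one stroke cycle — long enough that the tracked variance averages over
#: the intra-cycle acceleration oscillation (a shorter memory follows the
#: oscillation itself and chatters), short enough to flag a regime change
#: within a couple of cycles.
DEFAULT_LAMBDA = 0.9985
#: Default variance-change threshold as a fraction of the trial variance.
DEFAULT_THRESHOLD = 0.20


@dataclass
class SegmentSet:
    """Ordered, non-overlapping [start, end) intervals covering the trial."""

    segments: list[tuple[int, int]]
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        for (s0, e0), (s1, _e1) in zip(self.segments, self.segments[1:]):
            if e0 != s1:
                raise ValueError("segments must tile the trial without gaps")
        for s, e in self.segments:
            if e <= s:
                raise ValueError("empty segment")

    @property
    def n_segments(self) -> int:
        return len(self.segments)


@dataclass
class TrendModel:
    """Per-segment peak-envelope splines and the resulting velocity trend."""

    upper_knots: list[np.ndarray]   # per segment: (m, 2) [sample index, velocity]
    lower_knots: list[np.ndarray]
    trend: np.ndarray               # per-sample trend velocity (m s^-1)
    #: end sample of the leading cycle-less region (start of the first
    #: fitted segment), or None when the first segment itself is fitted.
    #: Lets the detrending step apply the standing-start constraint there.
    leadin_end: int | None = None


@dataclass
class TrialInfo:
    """Trial geometry fixing the mean velocity: pool length / duration."""

    pool_length: float = 25.0
    duration: float = 0.0
    mean_velocity: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("trial duration must be positive")
        if self.mean_velocity is None:
            self.mean_velocity = self.pool_length / self.duration
        if self.mean_velocity <= 0:
            raise ValueError("trial mean velocity must be positive")


def gma_segment(
    a_forward: np.ndarray,
    threshold_frac: float = DEFAULT_THRESHOLD,
    lam: float = DEFAULT_LAMBDA,
    min_segment: int | None = None,
) -> SegmentSet:
    """Segment the forward acceleration with GMA change detection.

    A recursive exponentially weighted mean/variance pair

    .. math:: m_t = λ m_{t-1} + (1-λ) a_t, \\quad
              s^2_t = λ s^2_{t-1} + (1-λ)(a_t - m_t)^2

    is tracked along the signal; a change point is declared (and a new
    segment opened) whenever ``|s²_t − s²_ref|`` exceeds
    ``threshold_frac × Var(a)``, where ``s²_ref`` is the tracked variance
    frozen at the last change point and ``Var(a)`` the whole-trial
    variance.  Detection is suspended for one effective-memory window
    (``1/(1-λ)`` samples) at the start and after each change point.
    Segments shorter than ``min_segment`` samples (one stroke cycle, when
    known) are merged into their left neighbor.
    """
    a = np.asarray(a_forward, dtype=float)
    if not 0.0 < lam < 1.0:
        raise ValueError("forgetting factor must be in (0, 1)")
    if threshold_frac <= 0:
        raise ValueError("threshold fraction must be positive")
    burn = int(np.ceil(1.0 / (1.0 - lam)))
    n = len(a)
    if n < 2 * burn:
        raise ValueError(f"need at least {2 * burn} samples for lambda={lam}")

    total_var = float(np.var(a))
    threshold = threshold_frac * total_var

    # exponentially weighted mean and variance via linear recursions
    m0 = float(np.mean(a[:burn]))
    m = lfilter([1.0 - lam], [1.0, -lam], a, zi=np.array([lam * m0]))[0]
    resid2 = (a - m) ** 2
    s20 = float(np.var(a[:burn]))
    s2 = lfilter([1.0 - lam], [1.0, -lam], resid2, zi=np.array([lam * s20]))[0]

    changes: list[int] = []
    s2_ref = s2[burn - 1]
    guard_until = burn
    for t in range(burn, n):
        if t < guard_until:
            continue
        if abs(s2[t] - s2_ref) > threshold:
            changes.append(t)
            s2_ref = s2[t]
            guard_until = t + burn
    bounds = [0, *changes, n]
    segments = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]

    if min_segment:
        merged: list[tuple[int, int]] = []
        for seg in segments:
            if merged and (seg[1] - seg[0]) < min_segment:
                merged[-1] = (merged[-1][0], seg[1])
            elif not merged and (seg[1] - seg[0]) < min_segment and len(segments) > 1:
                # first segment too short: fold it into the next one
                segments[1] = (seg[0], segments[1][1])
            else:
                merged.append(seg)
        segments = merged or [(0, n)]
    return SegmentSet(segments=segments, threshold=threshold_frac)


def _cycles_in_segment(cycles: CycleSet, start: int, end: int) -> list[slice]:
    """Cycles whose midpoint falls inside [start, end)."""
    out = []
    for s in cycles.slices():
        mid = (s.start + s.stop) / 2.0
        if start <= mid < end:
            out.append(s)
    return out


def fit_trend(v: np.ndarray, segments: SegmentSet, cycles: CycleSet) -> TrendModel:
    """Fit per-segment peak-envelope splines and derive the velocity trend.

    Per segment, the maximum and minimum of the velocity within each
    stroke cycle become the knots of two PCHIP interpolants (upper and
    lower envelopes); the trend is their pointwise average, held constant
    beyond the outermost knots.  A segment containing fewer than two
    cycles (e.g. the motionless lead-in) inherits the nearest fitted
    neighbor's trend edge value, keeping the trend continuous so the
    single anchoring constant is not contaminated; if no segment has
    enough cycles the trend falls back to each segment's mean velocity.
    """
    v = np.asarray(v, dtype=float)
    trend = np.full_like(v, np.nan)
    upper_knots: list[np.ndarray] = []
    lower_knots: list[np.ndarray] = []
    fitted: list[bool] = []

    for start, end in segments.segments:
        seg_cycles = _cycles_in_segment(cycles, start, end)
        if len(seg_cycles) < 2:
            logger.info(
                "segment [%d, %d) has %d cycles; trend inherited from neighbor",
                start, end, len(seg_cycles),
            )
            upper_knots.append(np.empty((0, 2)))
            lower_knots.append(np.empty((0, 2)))
            fitted.append(False)
            continue
        up = np.array([[s.start + int(np.argmax(v[s])), np.max(v[s])] for s in seg_cycles])
        lo = np.array([[s.start + int(np.argmin(v[s])), np.min(v[s])] for s in seg_cycles])
        x = np.arange(start, end, dtype=float)
        up_curve = PchipInterpolator(up[:, 0], up[:, 1])(np.clip(x, up[0, 0], up[-1, 0]))
        lo_curve = PchipInterpolator(lo[:, 0], lo[:, 1])(np.clip(x, lo[0, 0], lo[-1, 0]))
        trend[start:end] = 0.5 * (up_curve + lo_curve)
        upper_knots.append(up)
        lower_knots.append(lo)
        fitted.append(True)

    leadin_end: int | None = None
    if any(fitted):
        for i, (start, end) in enumerate(segments.segments):
            if fitted[i]:
                continue
            left = next((j for j in range(i - 1, -1, -1) if fitted[j]), None)
            right = next((j for j in range(i + 1, len(fitted)) if fitted[j]), None)
            if left is not None:
                trend[start:end] = trend[segments.segments[left][1] - 1]
            else:
                trend[start:end] = trend[segments.segments[right][0]]
        if not fitted[0]:
            first_fitted = next(i for i, ok in enumerate(fitted) if ok)
            leadin_end = segments.segments[first_fitted][0]
    else:
        for start, end in segments.segments:
            trend[start:end] = v[start:end].mean()

    return TrendModel(upper_knots=upper_knots, lower_knots=lower_knots,
                      trend=trend, leadin_end=leadin_end)


def detrend_velocity(
    v: np.ndarray,
    trend: TrendModel,
    trial: TrialInfo,
    cycles: CycleSet | None = None,
    f: float = 500.0,
) -> VelocityProfile:
    """Subtract the trend and anchor the trial mean to pool length / duration.

    The output's mean over the whole series equals ``trial.mean_velocity``
    exactly (additive anchoring).  When the trend has a leading cycle-less
    region (``trend.leadin_end``), the standing-start constraint is
    applied there: the trial begins motionless, so the detrended velocity
    at sample 0 must be zero.  Over the lead-in no peak envelope exists to
    pin the trend, and integration drift accrued there would otherwise
    leak through the anchoring constant into the whole trial; a
    one-parameter quadratic trend adjustment, zero at the lead-in's end
    (preserving continuity) and solved in closed form so that the
    anchored output starts at exactly zero, absorbs that drift.  The
    quadratic shape matches the dominant drift physics: an orientation
    error ramping up over the lead-in leaks gravity into the forward
    acceleration at a linearly growing rate, integrating to a quadratic
    velocity drift.  The adjustment is applied mean-free, so the
    trial-mean anchor still holds exactly.
    Per-cycle means are attached when a cycle set is provided.
    """
    v = np.asarray(v, dtype=float)
    if len(v) != len(trend.trend):
        raise ValueError("velocity and trend lengths differ")
    out = v - trend.trend
    out = out + (trial.mean_velocity - out.mean())
    te = trend.leadin_end
    if te is not None and 1 < te < len(out):
        delta = np.zeros(len(out))
        delta[:te] = 1.0 - (np.arange(te) / te) ** 2
        delta -= delta.mean()
        if abs(delta[0]) > 1e-12:
            out = out - (out[0] / delta[0]) * delta
    means = cycle_means(out, cycles) if cycles is not None else np.empty(0)
    return VelocityProfile(v=out, f=f, cycle_means=means)
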
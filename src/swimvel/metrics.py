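"""Agreement and variability statistics for velocity validation.

Implements the statistics used to compare an IMU-derived velocity with a
tethered reference: accuracy/precision and Bland–Altman limits of
agreement of paired cycle means (with a heteroscedasticity check),
Spearman rank correlation, the normalized pairwise variability index
(nPVI), instantaneous-error summaries, and the intra-cyclic velocity
variation (IVV).

Units follow the field's reporting habits: agreement statistics are
returned in cm s^-1 while all internal computation is in m s^-1; nPVI
and IVV are percentages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .kinematics import CycleSet

__all__ = [
    "AgreementReport",
    "IvvResult",
    "npvi",
    "ivv",
    "bland_altman",
    "instantaneous_errors",
    "spearman",
]

logger = logging.getLogger(__name__)

M_TO_CM = 100.0


@dataclass
class AgreementReport:
    """Summary of IMU-vs-reference agreement (cm s^-1 where dimensional)."""

    bias: float = np.nan
    precision: float = np.nan
    loa_low: float = np.nan
    loa_high: float = np.nan
    spearman_rho: float = np.nan
    hetero_corr: float = np.nan
    npvi: float = np.nan
    rms_instant: float = np.nan
    max_instant: float = np.nan
    max_relative: float = np.nan
    n_cycles: int = 0

    def as_dict(self) -> dict:
        return {
            "bias_cms": self.bias,
            "precision_cms": self.precision,
            "loa_low_cms": self.loa_low,
            "loa_high_cms": self.loa_high,
            "spearman_rho": self.spearman_rho,
            "hetero_corr": self.hetero_corr,
            "npvi_pct": self.npvi,
            "rms_instant_cms": self.rms_instant,
            "max_instant_cms": self.max_instant,
            "max_relative_pct": self.max_relative,
            "n_cycles": self.n_cycles,
        }


@dataclass
class IvvResult:
    """Intra-cyclic velocity variation (%) with per-cycle contributions."""

    ivv: float
    per_cycle_contributions: np.ndarray = field(default_factory=lambda: np.empty(0))


def npvi(ref_means: np.ndarray, est_means: np.ndarray) -> float:
    """Normalized pairwise variability index between paired cycle means.

    ``100 × mean_k(|r_k − e_k| / ((r_k + e_k)/2))``; symmetric in its
    arguments and invariant to a common positive scaling.
    """
    r = np.asarray(ref_means, dtype=float)
    e = np.asarray(est_means, dtype=float)
    if r.shape != e.shape or r.ndim != 1 or len(r) < 1:
        raise ValueError("need two equal-length cycle-mean sequences")
    if np.any(r <= 0) or np.any(e <= 0):
        raise ValueError("cycle-mean velocities must be positive")
    return float(100.0 * np.mean(np.abs(r - e) / ((r + e) / 2.0)))


def ivv(v: np.ndarray, cycles: CycleSet) -> IvvResult:
    """Intra-cyclic velocity variation, in percent.

    Weighted RMS of the within-cycle velocity deviations over the
    weighted mean velocity,

    .. math::
        IVV = 100 \\frac{\\sqrt{\\sum_k f_k \\sum_{t \\in C_k}
              (V_t - \\bar V_k)^2 / n}}
              {\\sum_k f_k \\sum_{t \\in C_k} V_t / n}

    with per-cycle stroke frequency ``f_k`` and total sample count ``n``
    over the analyzed cycles.  Zero iff the velocity is constant within
    every cycle.
    """
    v = np.asarray(v, dtype=float)
    if cycles.n_cycles < 1:
        raise ValueError("need at least one full cycle")
    slices = cycles.slices()
    freqs = cycles.frequencies
    n_total = int(sum(s.stop - s.start for s in slices))
    num_terms = np.empty(cycles.n_cycles)
    den_terms = np.empty(cycles.n_cycles)
    for k, (s, fk) in enumerate(zip(slices, freqs)):
        seg = v[s]
        num_terms[k] = fk * np.sum((seg - seg.mean()) ** 2) / n_total
        den_terms[k] = fk * np.sum(seg) / n_total
    den = float(np.sum(den_terms))
    if den <= 0:
        raise ValueError("mean velocity over the cycles must be positive")
    value = float(100.0 * np.sqrt(np.sum(num_terms)) / den)
    return IvvResult(ivv=value, per_cycle_contributions=num_terms)


def bland_altman(ref_means: np.ndarray, est_means: np.ndarray) -> dict:
    """Bland–Altman agreement of paired cycle means, in cm s^-1.

    Differences are estimate − reference; bias is their mean, precision
    their sample standard deviation (n−1 denominator), and the 95% limits
    of agreement bias ± 1.96 SD.  Heteroscedasticity is screened as the
    Pearson correlation between pair means and pair differences.
    """
    r = np.asarray(ref_means, dtype=float)
    e = np.asarray(est_means, dtype=float)
    if r.shape != e.shape or len(r) < 2:
        raise ValueError("need two equal-length sequences of length >= 2")
    d = (e - r) * M_TO_CM
    m = (e + r) / 2.0 * M_TO_CM
    bias = float(np.mean(d))
    precision = float(np.std(d, ddof=1))
    if np.ptp(d) == 0 or np.ptp(m) == 0:
        hetero = 0.0
    else:
        hetero = float(stats.pearsonr(m, d)[0])
    return {
        "bias": bias,
        "precision": precision,
        "loa_low": bias - 1.96 * precision,
        "loa_high": bias + 1.96 * precision,
        "hetero_corr": hetero,
    }


def instantaneous_errors(
    v_est: np.ndarray, v_ref: np.ndarray, ref_mean: float | None = None
) -> tuple[float, float, float]:
    """RMS, maximum, and relative instantaneous errors (cm s^-1, cm s^-1, %).

    Both series must share the same sampling instants (typically 100 Hz).
    The relative error is the maximum absolute difference over the
    reference velocity at the sample where that maximum occurs; if the
    reference is zero there, the trial-mean reference velocity is used
    instead (logged).
    """
    e = np.asarray(v_est, dtype=float)
    r = np.asarray(v_ref, dtype=float)
    if e.shape != r.shape or e.ndim != 1 or len(e) < 1:
        raise ValueError("need two equal-length velocity series")
    d = e - r
    rms = float(np.sqrt(np.mean(d ** 2)))
    i = int(np.argmax(np.abs(d)))
    max_abs = float(np.abs(d[i]))
    denom = r[i]
    if abs(denom) < 1e-9:
        denom = ref_mean if ref_mean is not None else float(np.mean(r))
        logger.warning("zero reference velocity at the error maximum; "
                       "relative error taken against the trial mean")
    rel = float(100.0 * max_abs / abs(denom)) if abs(denom) > 1e-12 else np.nan
    return rms * M_TO_CM, max_abs * M_TO_CM, rel


def spearman(ref: np.ndarray, est: np.ndarray) -> float:
    """Spearman rank correlation with average ranks for ties."""
    r = np.asarray(ref, dtype=float)
    e = np.asarray(est, dtype=float)
    if r.shape != e.shape or len(r) < 3:
        raise ValueError("need two equal-length sequences of length >= 3")
    if np.ptp(r) == 0 or np.ptp(e) == 0:
        raise ValueError("rank correlation undefined for constant input")
    return float(stats.spearmanr(r, e)[0])
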
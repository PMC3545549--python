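"""End-to-end orchestration: IMU recording → drift-free forward velocity.

``estimate_velocity`` chains the whole method: initial pose from the
static start window, gyroscope strapdown, stroke-cycle detection,
roll-constraint orientation correction, forward-acceleration extraction,
trapezoidal integration, GMA segmentation, peak-envelope de-trending and
trial-mean anchoring.  ``compare_runs`` validates the result against a
tethered-speedometer recording with the agreement statistics of the
metrics module.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np

from . import metrics
from .detrend import (DEFAULT_LAMBDA, DEFAULT_THRESHOLD, SegmentSet, TrendModel,
                      TrialInfo, detrend_velocity, fit_trend, gma_segment)
from .kinematics import (CycleSet, ImuRecording, VelocityProfile, cycle_means,
                         detect_cycles, forward_acceleration, integrate_velocity)
from .orientation import (OrientationSeries, correct_orientation_series,
                          initial_orientation, strapdown_orientation)
from .reference import ReferenceRecording, parallax_correct, resample_to

__all__ = ["RunConfig", "PipelineResult", "estimate_velocity", "compare_runs"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved parameters of one estimation run (all units SI)."""

    gravity: float = 9.81
    gma_threshold: float = DEFAULT_THRESHOLD
    gma_lambda: float = DEFAULT_LAMBDA
    cycle_cutoff_hz: float = 3.0
    cycle_refractory_s: float = 0.4
    static_window_s: float = 0.5
    static_sd_limit_g: float = 0.05   # accelerometer-norm SD limit over the window
    comparison_rate: float = 100.0
    max_align_lag_s: float = 2.0

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    """Everything the estimation pipeline produces for one trial."""

    profile: VelocityProfile
    cycles: CycleSet
    segments: SegmentSet
    trend: TrendModel
    orientation: OrientationSeries
    raw_orientation: OrientationSeries
    forward_accel: np.ndarray
    raw_velocity: np.ndarray
    diagnostics: dict = field(default_factory=dict)


def _static_window_accel(recording: ImuRecording, config: RunConfig) -> np.ndarray:
    """Mean accelerometer reading over the static start window, validated."""
    n = int(config.static_window_s * recording.f)
    if n < 2:
        raise ValueError("static start window shorter than 2 samples")
    window = recording.accel[:n]
    norms = np.linalg.norm(window, axis=1)
    sd_limit = config.static_sd_limit_g * config.gravity
    if np.std(norms) > sd_limit:
        raise ValueError(
            "start of recording is not static: accelerometer-norm SD "
            f"{np.std(norms):.3f} m/s^2 exceeds {sd_limit:.3f} m/s^2"
        )
    return window.mean(axis=0)


def estimate_velocity(
    recording: ImuRecording,
    trial: TrialInfo,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Estimate drift-free instantaneous forward velocity from an IMU trial.

    Raises ``ValueError`` (prefixed with the failing stage) on unusable
    input such as a non-static start or fewer than two stroke cycles.
    """
    config = config or RunConfig()
    diagnostics: dict = {"config": config.as_dict()}

    def stage(name: str):
        logger.info("pipeline stage: %s", name)
        return name

    name = stage("initial_orientation")
    try:
        a0 = _static_window_accel(recording, config)
        pose = initial_orientation(a0, gravity=config.gravity)

        name = stage("strapdown")
        q_raw = strapdown_orientation(recording.gyro, recording.f, pose.q0)
        raw_series = OrientationSeries(q=q_raw, f=recording.f)

        name = stage("detect_cycles")
        cycles = detect_cycles(
            recording, raw_series,
            cutoff_hz=config.cycle_cutoff_hz,
            refractory_s=config.cycle_refractory_s,
        )

        name = stage("correct_orientation")
        corrected = correct_orientation_series(raw_series, recording.gyro, cycles.boundaries)

        name = stage("forward_acceleration")
        a_fwd = forward_acceleration(recording, corrected, gravity=config.gravity)

        name = stage("integrate_velocity")
        v_raw = integrate_velocity(a_fwd, recording.f, v0=0.0)

        name = stage("gma_segment")
        min_seg = int(np.median(cycles.lengths)) if cycles.n_cycles else None
        segments = gma_segment(
            a_fwd, threshold_frac=config.gma_threshold,
            lam=config.gma_lambda, min_segment=min_seg,
        )

        name = stage("fit_trend")
        trend = fit_trend(v_raw, segments, cycles)

        name = stage("detrend")
        profile = detrend_velocity(v_raw, trend, trial, cycles=cycles, f=recording.f)
    except ValueError as err:
        raise ValueError(f"[{name}] {err}") from err

    diagnostics["drift_angles_rad"] = [c.delta_theta for c in corrected.corrections]
    diagnostics["segment_boundaries"] = [s for s, _ in segments.segments] + [len(recording)]
    diagnostics["n_cycles"] = cycles.n_cycles
    diagnostics["theta0_rad"] = pose.theta0
    return PipelineResult(
        profile=profile, cycles=cycles, segments=segments, trend=trend,
        orientation=corrected, raw_orientation=raw_series,
        forward_accel=a_fwd, raw_velocity=v_raw, diagnostics=diagnostics,
    )


def _align_by_xcorr(est: np.ndarray, ref: np.ndarray, max_lag: int) -> int:
    """Lag (samples) that best aligns est to ref, positive = est lags ref."""
    e = est - est.mean()
    r = ref - ref.mean()
    m = min(len(e), len(r))
    e, r = e[:m], r[:m]
    lags = np.arange(-max_lag, max_lag + 1)
    scores = np.empty(len(lags))
    for i, lag in enumerate(lags):
        if lag >= 0:
            a, b = e[lag:], r[: m - lag]
        else:
            a, b = e[: m + lag], r[-lag:]
        denom = np.linalg.norm(a) * np.linalg.norm(b)
        scores[i] = (a @ b) / denom if denom > 0 else 0.0
    best = int(np.argmax(scores))
    if scores[best] < 0.3:
        raise ValueError("alignment failure: cross-correlation peak below 0.3")
    return int(lags[best])


def compare_runs(
    result: PipelineResult,
    ref: ReferenceRecording,
    config: RunConfig | None = None,
) -> metrics.AgreementReport:
    """Validate an estimated velocity profile against the tethered reference.

    Parallax-corrects the reference, downsamples the estimate to the
    comparison rate, aligns the two by cross-correlation, and computes the
    full agreement report (cycle-mean Bland–Altman, Spearman, nPVI,
    instantaneous errors).
    """
    config = config or RunConfig()
    f_cmp = config.comparison_rate
    v_ref = parallax_correct(ref)
    if ref.f_ref != f_cmp:
        v_ref = resample_to(v_ref, ref.f_ref, f_cmp)
    v_est = resample_to(result.profile.v, result.profile.f, f_cmp)

    max_lag = int(config.max_align_lag_s * f_cmp)
    lag = _align_by_xcorr(v_est, v_ref, max_lag)
    if lag >= 0:
        v_est_a, v_ref_a = v_est[lag:], v_ref
    else:
        v_est_a, v_ref_a = v_est, v_ref[-lag:]
    m = min(len(v_est_a), len(v_ref_a))
    v_est_a, v_ref_a = v_est_a[:m], v_ref_a[:m]

    rms, max_abs, max_rel = metrics.instantaneous_errors(v_est_a, v_ref_a)

    # cycle means on the comparison grid, using the detected cycles
    ratio = f_cmp / result.profile.f
    bounds = np.round(result.cycles.boundaries * ratio).astype(int)
    bounds = bounds[bounds < m + (lag if lag > 0 else 0)]
    est_means, ref_means = [], []
    for k in range(len(bounds) - 1):
        s = slice(bounds[k], bounds[k + 1])
        if s.stop <= m:
            est_means.append(v_est_a[s].mean())
            ref_means.append(v_ref_a[s].mean())
    est_means = np.asarray(est_means)
    ref_means = np.asarray(ref_means)
    if len(est_means) < 2:
        raise ValueError("fewer than 2 comparable cycles after alignment")

    ba = metrics.bland_altman(ref_means, est_means)
    report = metrics.AgreementReport(
        bias=ba["bias"], precision=ba["precision"],
        loa_low=ba["loa_low"], loa_high=ba["loa_high"],
        hetero_corr=ba["hetero_corr"],
        spearman_rho=metrics.spearman(ref_means, est_means),
        npvi=metrics.npvi(ref_means, est_means),
        rms_instant=rms, max_instant=max_abs, max_relative=max_rel,
        n_cycles=len(est_means),
    )
    logger.info("comparison lag: %d samples at %.0f Hz", lag, f_cmp)
    return report
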
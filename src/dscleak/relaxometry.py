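"""Signal-to-relaxivity conversion, voxel QC, and reference-curve construction.

The DSC signal S(t) of each voxel is converted to a relaxivity-time curve

    dR2*(t) = -(1/TE) * ln(S(t) / S0),

with S0 the mean baseline signal before bolus arrival. The whole-brain
reference curve is the pointwise average of the relaxivity curves of
"nonenhancing" voxels: brain voxels whose tail (final time points) returns to
within one baseline SD of baseline and which show a sufficient first-pass
signal drop. Bolus entrance/exit time points are located on the averaged
curve and applied globally to all voxels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .dsc_io import DSCSeries
from .errors import NumericalError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class RelaxivityCurve:
    """A single dR2*(t) trace (1/s) sampled every ``time_step`` seconds."""

    values: np.ndarray
    time_step: float


@dataclass
class ReferenceCurve:
    """Whole-brain average relaxivity-time curve over nonenhancing voxels."""

    values: np.ndarray
    time_step: float
    n_voxels_averaged: int = 1


@dataclass
class AcquisitionWindow:
    """Baseline, bolus and tail index ranges shared by all voxels.

    ``baseline_end`` is exclusive: baseline indices are [0, baseline_end).
    ``t0``/``t1`` are the bolus entrance/exit indices (inclusive). ``tail``
    holds the final tail indices.
    """

    baseline_end: int
    t0: int
    t1: int
    n_timepoints: int
    tail: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.tail is None:
            self.tail = np.arange(max(self.n_timepoints - 10, self.t1 + 1), self.n_timepoints)
        if not (self.baseline_end <= self.t0 < self.t1 < self.n_timepoints):
            raise ValidationError(
                "window must satisfy baseline_end <= t0 < t1 < n_timepoints"
            )

    @property
    def baseline(self) -> slice:
        return slice(0, self.baseline_end)

    @property
    def bolus(self) -> slice:
        """Inclusive bolus slice [t0, t1]."""
        return slice(self.t0, self.t1 + 1)


def discard_leading_volumes(series: DSCSeries, n: int = 2) -> DSCSeries:
    """Drop the first ``n`` time frames (pre-steady-state signal)."""
    if n < 0:
        raise ValidationError("cannot discard a negative number of volumes")
    if n == 0:
        return series
    remaining = series.signal.shape[-1] - n
    if remaining < 20:
        raise ValidationError(
            f"discarding {n} volumes leaves {remaining} time points (< 20)"
        )
    return DSCSeries(
        signal=series.signal[..., n:],
        tr_seconds=series.tr_seconds,
        te_seconds=series.te_seconds,
        discarded_leading_volumes=series.discarded_leading_volumes + n,
        affine=series.affine,
    )


def estimate_baseline(
    trace: np.ndarray, window: AcquisitionWindow, min_points: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Baseline mean S0 and sample SD of a trace (or stack of traces).

    Works on any array whose last axis is time; returns arrays with that axis
    reduced (scalars for a single trace).
    """
    if window.baseline_end < min_points:
        raise ValidationError(
            f"baseline window has {window.baseline_end} points (< {min_points})"
        )
    base = np.asarray(trace, dtype=float)[..., window.baseline]
    s0 = base.mean(axis=-1)
    sd = base.std(axis=-1, ddof=1)
    return s0, sd


def signal_to_relaxivity(
    trace: np.ndarray,
    s0: float | np.ndarray,
    te_seconds: float,
    clamp_fraction: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Convert signal to dR2*(t) = -(1/TE) ln(S/S0).

    Non-positive samples are clamped to ``clamp_fraction * S0`` before the
    log (magnitude-MR noise floor) and reported in the returned boolean clamp
    mask. Positive overshoots (S > S0, negative dR2*) are preserved.
    """
    if te_seconds <= 0:
        raise ValidationError("te_seconds must be positive")
    trace = np.asarray(trace, dtype=float)
    s0 = np.asarray(s0, dtype=float)
    if np.any(s0 <= 0):
        raise ValidationError("baseline S0 must be positive to form dR2*")
    s0e = s0[..., None] if s0.ndim else s0
    clamped = trace <= 0
    safe = np.where(clamped, clamp_fraction * np.broadcast_to(s0e, trace.shape), trace)
    values = -np.log(safe / s0e) / te_seconds
    return values, clamped


def qc_sufficient_drop(
    trace: np.ndarray,
    s0: float | np.ndarray,
    baseline_sd: float | np.ndarray,
    window: AcquisitionWindow,
    drop_threshold_sd: float = 5.0,
    sd_epsilon: float = 1e-9,
) -> np.ndarray:
    """Contrast-to-noise QC: does the signal drop >= N baseline SDs?

    True iff the minimum signal over the bolus search region [t0, t1] is at
    or below ``S0 - drop_threshold_sd * SD``. When SD is exactly zero
    (noiseless data) the rule degenerates to "any drop below S0 at all",
    implemented with an absolute epsilon.
    """
    trace = np.asarray(trace, dtype=float)
    s0 = np.asarray(s0, dtype=float)
    sd = np.asarray(baseline_sd, dtype=float)
    mins = trace[..., window.bolus].min(axis=-1)
    # max(k sd, eps): degenerates to "any drop at all" on noiseless data
    return mins <= s0 - np.maximum(drop_threshold_sd * sd, sd_epsilon)


def select_nonenhancing_voxels(
    signal: np.ndarray,
    brain_mask: np.ndarray,
    window: AcquisitionWindow,
    config: RunConfig | None = None,
) -> np.ndarray:
    """Mask of brain voxels usable for the whole-brain reference curve.

    A voxel qualifies when the absolute difference between its tail mean
    (final time points) and its baseline S0 is less than one baseline SD,
    it passes the sufficient-drop QC, and its baseline is positive. With a
    zero SD (noiseless data) the tail criterion degenerates to exact
    equality within an absolute epsilon.
    """
    config = config or RunConfig()
    signal = np.asarray(signal, dtype=float)
    brain = np.asarray(brain_mask, dtype=bool)
    s0, sd = estimate_baseline(signal, window, config.baseline_min_points)
    tail_mean = signal[..., window.tail].mean(axis=-1)
    diff = np.abs(tail_mean - s0)
    tail_ok = diff < np.maximum(config.tail_threshold_sd * sd, config.sd_epsilon)
    drop_ok = qc_sufficient_drop(
        signal, s0, sd, window, config.drop_threshold_sd, config.sd_epsilon
    )
    mask = brain & tail_ok & drop_ok & (s0 > 0)
    n = int(mask.sum())
    logger.info(
        "nonenhancing selection: %d / %d brain voxels retained", n, int(brain.sum())
    )
    if n == 0:
        raise NumericalError(
            "no nonenhancing voxels selected; review tail/drop thresholds "
            "— a reference curve cannot be formed"
        )
    return mask


def build_reference_curve(
    relaxivity: np.ndarray, mask: np.ndarray, time_step: float
) -> ReferenceCurve:
    """Pointwise mean of the relaxivity curves of the masked voxels."""
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValidationError("cannot average a reference curve over an empty mask")
    values = np.asarray(relaxivity, dtype=float)[mask].mean(axis=0)
    return ReferenceCurve(values=values, time_step=time_step, n_voxels_averaged=n)


def locate_bolus_window(ref: ReferenceCurve, config: RunConfig | None = None) -> AcquisitionWindow:
    """Locate baseline, bolus entrance t0 and exit t1 on an averaged curve.

    The baseline is grown iteratively from the first ``baseline_init_points``
    samples while values stay within ``baseline_threshold_sd`` SDs of the
    running baseline mean; arrival requires two consecutive supra-threshold
    points. t0 is the last sub-threshold index before the upslope, t1 the
    first post-peak index where the curve falls below
    baseline + ``bolus_exit_fraction`` * (peak - baseline) or the
    pre-recirculation local minimum, whichever comes first.
    """
    config = config or RunConfig()
    v = np.asarray(ref.values, dtype=float)
    n = v.shape[0]
    b0 = config.baseline_init_points
    if n < b0 + 10:
        raise ValidationError("curve too short to locate a bolus window")

    b = b0
    while b < n - 1:
        mu = v[:b].mean()
        sd = v[:b].std(ddof=1)
        thr = mu + max(config.baseline_threshold_sd * sd, config.sd_epsilon)
        if v[b] > thr and v[min(b + 1, n - 1)] > thr:
            break
        b += 1
    else:
        raise NumericalError("no bolus arrival detected (flat curve)")

    mu = v[:b].mean()
    sd = v[:b].std(ddof=1)
    thr = mu + max(config.baseline_threshold_sd * sd, config.sd_epsilon)
    baseline_end = max(b - config.baseline_guard, config.baseline_min_points)

    peak = int(np.argmax(v[b:]) + b)
    if v[peak] - mu < config.peak_min_sd * sd and sd > 0:
        raise NumericalError("reference peak below detectability threshold")
    if v[peak] <= mu + config.sd_epsilon:
        raise NumericalError("no positive bolus peak on the reference curve")

    t0 = peak
    while t0 > 0 and v[t0 - 1] > thr:
        t0 -= 1
    t0 = max(t0 - 1, 0)

    exit_level = mu + config.bolus_exit_fraction * (v[peak] - mu)
    t1_frac = None
    t1_min = None
    for i in range(peak + 1, n):
        if t1_frac is None and v[i] < exit_level:
            t1_frac = i
        if t1_min is None and i < n - 1 and v[i] < v[i - 1] and v[i] <= v[i + 1]:
            t1_min = i
        if t1_frac is not None and t1_min is not None:
            break
    candidates = [c for c in (t1_frac, t1_min) if c is not None]
    t1 = min(candidates) if candidates else n - 1

    tail_start = n - config.tail_points
    if tail_start <= t1:
        logger.warning(
            "fewer than %d time points remain after bolus exit; "
            "using all %d post-bolus points as the tail",
            config.tail_points,
            n - t1 - 1,
        )
        tail_start = t1 + 1
    tail = np.arange(tail_start, n)

    window = AcquisitionWindow(
        baseline_end=baseline_end, t0=t0, t1=t1, n_timepoints=n, tail=tail
    )
    logger.info(
        "bolus window: baseline [0, %d), t0=%d, peak=%d, t1=%d, tail start=%d",
        baseline_end, t0, peak, t1, tail_start,
    )
    return window
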
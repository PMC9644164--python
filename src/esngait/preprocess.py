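"""Input construction for the network and stride segmentation.

Raw tri-axial shank acceleration is reduced to its leading principal
component, high-pass filtered, integrated twice (velocity and position), and
each of the three traces is range-normalized per trial, yielding the 3 x T
network input. The force target is z-scored per trial. Data are segmented
into strides between consecutive foot-off events, with boundary samples
flagged as transients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .signal_io import ACCEL_FS, GaitEventSeries, SampledSignal

logger = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    """Settings for building network inputs and segmenting strides."""

    hp_cutoff: float = 1.0  # Hz
    hp_order: int = 2
    target_fs: float = ACCEL_FS
    transient_samples: int = 36
    pca_sign_rule: str = "dominant-loading-positive"
    #: additionally high-pass the velocity and position traces after each
    #: integration to suppress drift (off reproduces the reference pipeline)
    detrend_integrals: bool = False

    def __post_init__(self) -> None:
        if not self.hp_cutoff > 0:
            raise ValueError("hp_cutoff must be > 0")
        if self.hp_order < 1:
            raise ValueError("hp_order must be >= 1")
        if self.transient_samples < 0:
            raise ValueError("transient_samples must be >= 0")
        if self.pca_sign_rule != "dominant-loading-positive":
            raise ValueError(f"unknown pca_sign_rule {self.pca_sign_rule!r}")


@dataclass
class NetworkInput:
    """The 3 x T input (acceleration, velocity, position rows), each row
    range-normalized to unit peak-to-peak amplitude."""

    x: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 2 or self.x.shape[0] != 3:
            raise ValueError("x must have shape (3, T)")
        ranges = self.x.max(axis=1) - self.x.min(axis=1)
        if not np.allclose(ranges, 1.0, atol=1e-9):
            raise ValueError("each input row must have unit range")

    @property
    def n_samples(self) -> int:
        return self.x.shape[1]


@dataclass
class StrideSegment:
    """One foot-off-to-foot-off slice of input/target data.

    The transient mask is ``False`` for boundary samples that should be
    excluded when assembling training targets or segment-wise metrics.
    """

    start: int
    end: int
    x: np.ndarray
    z: np.ndarray
    mask: np.ndarray
    trial_id: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")
        n = self.end - self.start
        if self.x.shape[-1] != n or self.z.shape[-1] != n or self.mask.shape[-1] != n:
            raise ValueError("segment slices must match [start, end) length")


def resample_grf(grf: SampledSignal, target_fs: float) -> SampledSignal:
    """Anti-aliased rational resampling of a force signal to ``target_fs``.

    Only downsampling (or the identity) is supported; 1 kHz to 2000/14 Hz is
    plain decimation by 7.
    """
    if target_fs > grf.fs * (1 + 1e-9):
        raise ValueError("upsampling is out of scope (target_fs > fs)")
    if np.isclose(target_fs, grf.fs):
        return grf.copy()
    ratio = Fraction(target_fs / grf.fs).limit_denominator(10_000)
    up, down = ratio.numerator, ratio.denominator
    achieved = grf.fs * up / down
    if abs(achieved - target_fs) / target_fs > 1e-6:
        logger.warning(
            "resampling to %.6f Hz instead of requested %.6f Hz", achieved, target_fs
        )
    values = sps.resample_poly(
        grf.values, up, down, axis=1, padtype="line", window=("kaiser", 12.0)
    )
    return SampledSignal(values, fs=achieved, labels=grf.labels, t0=grf.t0)


def reorient_pca(accel: SampledSignal, sign_rule: str = "dominant-loading-positive") -> SampledSignal:
    """Project mean-centered channels onto the leading principal axis.

    The retained component has variance equal to the leading eigenvalue of
    the channel covariance. The sign is fixed so the eigenvector's
    largest-magnitude loading is positive.
    """
    if accel.n_samples < 3:
        raise ValueError("need at least 3 samples for PCA re-orientation")
    centered = accel.values - accel.values.mean(axis=1, keepdims=True)
    cov = np.cov(centered)
    if not np.any(cov):
        raise ValueError("degenerate covariance")
    evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
    leading = evecs[:, -1]
    if leading[np.argmax(np.abs(leading))] < 0:
        leading = -leading
    projected = leading @ centered
    return SampledSignal(projected[None, :], fs=accel.fs, labels=("pc1",), t0=accel.t0)


def highpass_bidirectional(signal: SampledSignal, cutoff: float, order: int = 2) -> SampledSignal:
    """Zero-phase (forward-backward) Butterworth high-pass filter."""
    if cutoff >= signal.fs / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    sos = sps.butter(order, cutoff, btype="highpass", fs=signal.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, signal.values, axis=1)
    return SampledSignal(filtered, fs=signal.fs, labels=signal.labels, t0=signal.t0)


def integrate_cumulative(signal: SampledSignal) -> SampledSignal:
    """Trapezoidal cumulative time integral with initial value zero."""
    from scipy.integrate import cumulative_trapezoid

    integ = cumulative_trapezoid(signal.values, dx=1.0 / signal.fs, axis=1, initial=0.0)
    return SampledSignal(integ, fs=signal.fs, labels=signal.labels, t0=signal.t0)


def range_normalize(signal: SampledSignal) -> SampledSignal:
    """Divide each channel by its peak-to-peak range (no centering)."""
    rng = signal.values.max(axis=1) - signal.values.min(axis=1)
    if np.any(rng <= 0):
        raise ValueError("zero range")
    return SampledSignal(
        signal.values / rng[:, None], fs=signal.fs, labels=signal.labels, t0=signal.t0
    )


def zscore_signal(signal: SampledSignal) -> SampledSignal:
    """Z-score each channel (sample standard deviation, denominator T-1)."""
    sd = signal.values.std(axis=1, ddof=1)
    if np.any(sd <= 0):
        raise ValueError("cannot z-score a constant signal")
    z = (signal.values - signal.values.mean(axis=1, keepdims=True)) / sd[:, None]
    return SampledSignal(z, fs=signal.fs, labels=signal.labels, t0=signal.t0)


def build_input(accel: SampledSignal, config: PreprocessConfig | None = None) -> NetworkInput:
    """Full input pipeline: PCA -> high-pass -> integrate twice -> normalize.

    Returns the stacked, per-trial range-normalized acceleration, velocity
    and position rows. Invariant to global scaling of the raw acceleration
    and to rotations of the sensor axes (up to component sign).
    """
    config = config or PreprocessConfig()
    a_hat = reorient_pca(accel, config.pca_sign_rule)
    a_hat = highpass_bidirectional(a_hat, config.hp_cutoff, config.hp_order)
    v_hat = integrate_cumulative(a_hat)
    if config.detrend_integrals:
        v_hat = highpass_bidirectional(v_hat, config.hp_cutoff, config.hp_order)
    p_hat = integrate_cumulative(v_hat)
    if config.detrend_integrals:
        p_hat = highpass_bidirectional(p_hat, config.hp_cutoff, config.hp_order)
    rows = [range_normalize(s).values[0] for s in (a_hat, v_hat, p_hat)]
    return NetworkInput(np.vstack(rows), fs=accel.fs)


def segment_at_foot_off(
    x: np.ndarray,
    z: np.ndarray,
    events: GaitEventSeries,
    config: PreprocessConfig | None = None,
    trial_id: str = "",
) -> list[StrideSegment]:
    """Split input/target arrays into [FO_i, FO_{i+1}) stride segments.

    The first and last ``transient_samples`` of each segment are masked out.
    Fewer than two foot-off events yields an empty list (with a warning).
    """
    config = config or PreprocessConfig()
    x = np.atleast_2d(np.asarray(x, dtype=float))
    z = np.asarray(z, dtype=float).ravel()
    n = min(x.shape[1], z.shape[0])
    fos = [int(i) for i in events.foot_offs if 0 <= i <= n]
    if len(fos) < 2:
        logger.warning("fewer than two foot-off events; no segments produced")
        return []
    segments = []
    tr = config.transient_samples
    for a, b in zip(fos[:-1], fos[1:]):
        if b > n:
            break
        mask = np.ones(b - a, dtype=bool)
        if tr > 0:
            mask[:tr] = False
            mask[max(0, b - a - tr):] = False
        segments.append(
            StrideSegment(start=a, end=b, x=x[:, a:b], z=z[a:b], mask=mask, trial_id=trial_id)
        )
    return segments
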
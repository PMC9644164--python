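"""Synthetic paired shank-acceleration / vertical-force trials.

Walking strides carry a double-bump stance force (duty factor > 0.5),
running strides a single-bump stance with an early impact spike and a
flight phase (duty factor < 0.5). Force is noise-free by construction so
ground-truth events are unambiguous; realism knobs (cadence jitter, sensor
rotation, measurement noise) live on the acceleration side.

Stance templates are built from monotone piecewise-cubic segments with
linear onset/offset ramps whose slope is calibrated so that the standard
12.5%-threshold detection on the smoothed, unit-scaled force crosses the
threshold at the stance boundary. This makes the generator's stance
boundaries recoverable by the event detector to within one sample at the
accelerometer rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from .signal_io import ACCEL_FS, GRF_FS, GaitEventSeries, SampledSignal, TrialRecord

logger = logging.getLogger(__name__)

#: fraction of the scaled maximum used by the event detector
_THRESHOLD_FRAC = 0.125
#: time span of the detector's 9-sample smoothing window at 2000/14 Hz (s)
_SMOOTH_SPAN = 9.0 / ACCEL_FS


@dataclass
class GaitPatternSpec:
    """Shape parameters of one locomotion mode."""

    mode: str
    stride_duration: float  # s
    duty_factor: float  # stance fraction of stride
    peak_force: float  # multiples of body weight
    valley: float = 0.0  # walking mid-stance valley, multiples of body weight
    impact_spike: float = 0.0  # running impact amplitude, fraction of peak
    cadence_jitter_cv: float = 0.03
    accel_noise_sd: float = 0.05  # fraction of per-channel signal SD
    sensor_rotation_seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("walking", "running"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 < self.duty_factor < 1:
            raise ValueError("duty_factor must be in (0, 1)")
        if self.mode == "walking" and self.duty_factor <= 0.5:
            raise ValueError("walking requires duty_factor > 0.5")
        if self.mode == "running" and self.duty_factor >= 0.5:
            raise ValueError("running requires duty_factor < 0.5")
        if self.stride_duration <= 0:
            raise ValueError("stride_duration must be > 0")
        if self.peak_force <= 0:
            raise ValueError("peak_force must be > 0")
        if self.mode == "walking" and not 0 < self.valley < self.peak_force:
            raise ValueError("walking valley must be in (0, peak_force)")
        if self.impact_spike < 0:
            raise ValueError("impact_spike must be >= 0")


def walking_pattern(**overrides) -> GaitPatternSpec:
    spec = GaitPatternSpec(
        mode="walking", stride_duration=1.10, duty_factor=0.60, peak_force=1.1, valley=0.75
    )
    return replace(spec, **overrides) if overrides else spec


def running_pattern(**overrides) -> GaitPatternSpec:
    spec = GaitPatternSpec(
        mode="running", stride_duration=0.72, duty_factor=0.35, peak_force=2.5, impact_spike=0.3
    )
    return replace(spec, **overrides) if overrides else spec


@dataclass
class SyntheticTrialSpec:
    pattern: GaitPatternSpec
    n_strides: int = 72
    grf_fs: float = GRF_FS
    accel_fs: float = ACCEL_FS
    body_weight: float = 700.0  # N
    speed: float | None = None  # m/s, metadata only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strides < 3:
            raise ValueError("n_strides must be >= 3")
        if self.grf_fs <= 0 or self.accel_fs <= 0:
            raise ValueError("sampling rates must be > 0")
        if self.body_weight <= 0:
            raise ValueError("body_weight must be > 0")


# ---------------------------------------------------------------------------
# stance templates
# ---------------------------------------------------------------------------


def _impact_spike(t: np.ndarray, t_peak: float, amplitude: float, total: float) -> np.ndarray:
    """Alpha-function impact transient peaking at ``t_peak``, forced to zero
    at the stance end by a smooth taper."""
    u = np.clip(t / t_peak, 0.0, None)
    spike = amplitude * u * np.exp(1.0 - u)
    taper = np.clip(1.0 - (t / total) ** 8, 0.0, 1.0)
    return spike * taper


def _unit_shape(mode: str, total: float, params: GaitPatternSpec, m_up: float, m_down: float):
    """Monotone piecewise-cubic stance shape with unit peak and linear
    boundary ramps of slopes ``m_up`` / ``m_down``."""
    t1 = min(0.015, 0.06 * total)
    t2 = min(0.030, 0.12 * total)
    if mode == "walking":
        vr = params.valley / params.peak_force
        times = [0.0, t1, t2, 0.25 * total, 0.50 * total, 0.75 * total,
                 total - t2, total - t1, total]
        vals = [0.0, m_up * t1, m_up * t2, 1.0, vr, 1.0,
                m_down * t2, m_down * t1, 0.0]
    else:
        times = [0.0, t1, t2, 0.45 * total, total - t2, total - t1, total]
        vals = [0.0, m_up * t1, m_up * t2, 1.0, m_down * t2, m_down * t1, 0.0]
    return PchipInterpolator(times, vals)


def _solve_ramp_slope(
    mode: str,
    total: float,
    params: GaitPatternSpec,
    rising: bool,
) -> float:
    """Calibrate a boundary ramp slope so that the running mean of the
    stance force over the detector's smoothing window crosses
    ``threshold * peak`` exactly at the stance boundary."""
    half = _SMOOTH_SPAN / 2.0
    if total < 4.0 * half:
        # template too short for the calibration to be meaningful
        return 0.5 / min(0.030, 0.12 * total)
    theta = _THRESHOLD_FRAC  # unit-peak terms
    grid = np.linspace(0.0, half, 200)

    def boundary_mass(m: float) -> float:
        shape = _unit_shape(mode, total, params, m, m)
        f = shape(grid) if rising else shape(total - grid)
        if rising and mode == "running" and params.impact_spike > 0:
            f = f + _impact_spike(grid, 0.08 * total, params.impact_spike, total)
        return float(np.trapezoid(f, grid)) - theta * _SMOOTH_SPAN

    t2 = min(0.030, 0.12 * total)
    lo, hi = 1e-4, 0.9 / t2
    if boundary_mass(lo) >= 0:
        logger.warning("impact spike dominates the onset; ramp slope clamped low")
        return lo
    if boundary_mass(hi) <= 0:
        return hi
    return float(brentq(boundary_mass, lo, hi, xtol=1e-6))


def grf_stance_template(
    mode: str,
    stance_samples: int,
    params: GaitPatternSpec,
    fs: float = GRF_FS,
) -> np.ndarray:
    """Stance force waveform in body-weight units with peak ``peak_force``.

    Walking: double-bump (peaks at 25% and 75% of stance, valley between),
    zero at both ends. Running: single bump peaking at 45% of stance plus an
    exponentially decaying impact spike peaking at 8% of stance. The whole
    template scales linearly with ``peak_force`` (the valley and spike are
    defined relative to the peak).
    """
    if stance_samples < 8:
        raise ValueError("stance_samples must be >= 8")
    total = (stance_samples - 1) / fs  # first and last sample are exactly zero
    m_up = _solve_ramp_slope(mode, total, params, rising=True)
    m_down = _solve_ramp_slope(mode, total, params, rising=False)
    t = np.arange(stance_samples) / fs
    shape = _unit_shape(mode, total, params, m_up, m_down)(t)
    if mode == "running" and params.impact_spike > 0:
        shape = shape + _impact_spike(t, 0.08 * total, params.impact_spike, total)
    shape[0] = 0.0
    shape[-1] = 0.0
    return params.peak_force * shape


# ---------------------------------------------------------------------------
# latent shank signal
# ---------------------------------------------------------------------------


def _latent_shank(
    u: np.ndarray, stance_template: np.ndarray, duty: float, stride_duration: float, fs: float
) -> np.ndarray:
    """Deterministic shank signal as a function of the stride phase ``u``.

    Sum of the stance-force derivative (normalized), a damped 20 Hz impact
    oscillation after foot contact, and one sinusoidal burst in swing.
    """
    out = np.zeros_like(u)
    # stance: smoothed force rate of change, normalized to unit peak. The
    # smoothing keeps the boundary ramps of the force template from turning
    # into near-impulses in the acceleration channel.
    deriv = np.gradient(stance_template) * fs
    width = max(3, int(round(0.02 * fs)))
    kernel = np.exp(-0.5 * (np.arange(-3 * width, 3 * width + 1) / width) ** 2)
    kernel /= kernel.sum()
    deriv = np.convolve(deriv, kernel, mode="same")
    peak = np.max(np.abs(deriv))
    if peak > 0:
        deriv = deriv / peak
    in_stance = u < duty
    us = np.clip(u[in_stance] / duty, 0.0, 1.0)
    out[in_stance] += np.interp(us, np.linspace(0, 1, deriv.size), deriv)
    # impact transient at foot contact (u = 0)
    t_rel = u * stride_duration
    out += 0.6 * np.exp(-t_rel / 0.05) * np.sin(2 * np.pi * 20.0 * t_rel)
    # swing oscillation
    in_swing = ~in_stance
    uw = (u[in_swing] - duty) / (1.0 - duty)
    out[in_swing] += 0.2 * np.sin(2 * np.pi * uw) * np.sin(np.pi * uw) ** 2
    return out


# ---------------------------------------------------------------------------
# trial and cohort synthesis
# ---------------------------------------------------------------------------

_LEAD_PAD = 0.5  # s of zero force before the first / after the last stride

#: maximum sensor misalignment from the canonical mounting (rad). Sensors
#: are mounted on the tibia in roughly the same orientation; bounding the
#: tilt keeps the principal-component polarity consistent across trials,
#: which pooled training relies on.
_MAX_SENSOR_TILT = np.deg2rad(25.0)


def _sensor_rotation(seed: int) -> np.ndarray:
    """Random but modest sensor misalignment: rotation about a random axis
    by an angle uniform on [0, _MAX_SENSOR_TILT]."""
    rng = np.random.default_rng(seed)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, _MAX_SENSOR_TILT)
    return Rotation.from_rotvec(angle * axis).as_matrix()


def synthesize_trial(spec: SyntheticTrialSpec) -> TrialRecord:
    """Generate one trial: 3-channel accelerometer, 1-channel force,
    ground-truth events at both sampling rates. Bit-reproducible from the
    seed."""
    p = spec.pattern
    rng = np.random.default_rng(spec.seed)
    cv = p.cadence_jitter_cv
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv**2))
        mu = np.log(p.stride_duration) - 0.5 * sigma**2
        durations = np.exp(rng.normal(mu, sigma, size=spec.n_strides))
    else:
        durations = np.full(spec.n_strides, p.stride_duration)
    fc_times = _LEAD_PAD + np.concatenate([[0.0], np.cumsum(durations[:-1])])
    fo_times = fc_times + p.duty_factor * durations
    total_time = _LEAD_PAD + float(np.sum(durations)) + _LEAD_PAD

    # --- force at the force-plate rate ------------------------------------
    # Event ground truth follows the force support: FC is the last zero
    # sample before loading, FO the first zero sample after unloading,
    # mirroring the threshold detector's "last/first point below" semantics.
    n_g = int(round(total_time * spec.grf_fs))
    grf = np.zeros(n_g)
    template_cache: dict[int, np.ndarray] = {}
    fc_hi, fo_hi = [], []
    for fc_t, dur in zip(fc_times, durations):
        stance_samples = int(round(p.duty_factor * dur * spec.grf_fs))
        tpl = template_cache.get(stance_samples)
        if tpl is None:
            tpl = grf_stance_template(p.mode, stance_samples, p, fs=spec.grf_fs)
            template_cache[stance_samples] = tpl
        i0 = int(round(fc_t * spec.grf_fs))
        grf[i0 : i0 + stance_samples] = spec.body_weight * tpl[: max(0, n_g - i0)]
        fc_hi.append(i0)
        fo_hi.append(i0 + stance_samples - 1)
    fc_hi = np.asarray(fc_hi)
    fo_hi = np.asarray(fo_hi)

    # --- latent shank signal at the accelerometer rate --------------------
    n_a = int(round(total_time * spec.accel_fs))
    t_a = np.arange(n_a) / spec.accel_fs
    s = np.zeros(n_a)
    s_shift = np.zeros(n_a)
    for fc_t, dur in zip(fc_times, durations):
        sel = (t_a >= fc_t) & (t_a < fc_t + dur)
        if not sel.any():
            continue
        u = (t_a[sel] - fc_t) / dur
        stance_samples = int(round(p.duty_factor * dur * spec.grf_fs))
        tpl = template_cache[stance_samples]
        s[sel] = _latent_shank(u, tpl, p.duty_factor, dur, spec.grf_fs)
        s_shift[sel] = _latent_shank((u - 0.05) % 1.0, tpl, p.duty_factor, dur, spec.grf_fs)

    latent = np.vstack([s, 0.3 * s_shift, 0.1 * s])
    rot = _sensor_rotation(p.sensor_rotation_seed)
    accel = rot @ latent
    if p.accel_noise_sd > 0:
        sd = accel.std(axis=1, keepdims=True) * p.accel_noise_sd
        accel = accel + rng.normal(0.0, 1.0, size=accel.shape) * sd

    # --- ground-truth events at both rates --------------------------------
    ratio = spec.accel_fs / spec.grf_fs
    events_hi = GaitEventSeries(
        np.minimum(fc_hi, n_g - 1), np.minimum(fo_hi, n_g - 1), fs=spec.grf_fs
    )
    events_lo = GaitEventSeries(
        np.minimum(np.round(fc_hi * ratio).astype(int), n_a - 1),
        np.minimum(np.round(fo_hi * ratio).astype(int), n_a - 1),
        fs=spec.accel_fs,
    )

    speed = spec.speed
    if speed is None:
        speed = {"walking": 1.24, "running": 2.20}[p.mode] * (
            {"walking": 1.10, "running": 0.72}[p.mode] / p.stride_duration
        )
    return TrialRecord(
        trial_id=f"{p.mode}-{spec.seed}",
        mode=p.mode,
        speed=float(speed),
        accel=SampledSignal(accel, fs=spec.accel_fs, labels=("ax", "ay", "az")),
        grf=SampledSignal(grf[None, :], fs=spec.grf_fs, labels=("fz",)),
        events=events_lo,
        events_grf_rate=events_hi,
    )


def synthesize_cohort(
    n_trials_per_mode: int = 21,
    walking: SyntheticTrialSpec | None = None,
    running: SyntheticTrialSpec | None = None,
    master_seed: int = 0,
) -> list[TrialRecord]:
    """Generate a walking + running cohort with per-trial seeds and speeds.

    Per-trial speeds are drawn Normal(1.24, 0.12) m/s for walking and
    Normal(2.20, 0.14) m/s for running; speed scales the stride duration
    inversely around the mode default.
    """
    if n_trials_per_mode < 1:
        raise ValueError("n_trials_per_mode must be >= 1")
    walking = walking or SyntheticTrialSpec(pattern=walking_pattern())
    running = running or SyntheticTrialSpec(pattern=running_pattern())
    root = np.random.SeedSequence(master_seed)
    children = root.spawn(2 * n_trials_per_mode)
    speed_stats = {"walking": (1.24, 0.12), "running": (2.20, 0.14)}
    trials = []
    for mode_i, (mode, template) in enumerate((("walking", walking), ("running", running))):
        for i in range(n_trials_per_mode):
            child = children[mode_i * n_trials_per_mode + i]
            seeds = child.generate_state(2)
            rng = np.random.default_rng(child)
            mean_speed, sd_speed = speed_stats[mode]
            speed = float(np.clip(rng.normal(mean_speed, sd_speed), 0.3 * mean_speed, None))
            base = template.pattern
            pattern = replace(
                base,
                stride_duration=base.stride_duration * mean_speed / speed,
                sensor_rotation_seed=int(seeds[0]),
            )
            spec = replace(
                template, pattern=pattern, speed=speed, seed=int(seeds[1])
            )
            trial = synthesize_trial(spec)
            trial.trial_id = f"{mode[:4]}{i:02d}"
            trials.append(trial)
    return trials
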
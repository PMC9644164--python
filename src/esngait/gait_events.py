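"""Threshold-based foot contact / foot off detection from a force waveform.

The waveform (measured or predicted, any positive affine scaling) is mapped
to [0, 1], lightly smoothed with a first-order Savitzky-Golay filter
(+/- 30 ms, i.e. 9 samples at 2000/14 Hz), and events are read off the
crossings of a threshold at 12.5% of the smoothed maximum: foot contact is
the last point below the threshold on the ascent, foot off the first point
below it on the descent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .signal_io import GaitEventSeries, SampledSignal

logger = logging.getLogger(__name__)


@dataclass
class EventDetectionConfig:
    threshold_frac: float = 0.125
    sg_halfwidth_ms: float = 30.0
    sg_order: int = 1
    #: optional debounce: drop stance/swing phases shorter than this
    min_phase_ms: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.threshold_frac < 1:
            raise ValueError("threshold_frac must be in (0, 1)")
        if self.sg_order < 1:
            raise ValueError("sg_order must be >= 1")
        if self.sg_halfwidth_ms <= 0:
            raise ValueError("sg_halfwidth_ms must be > 0")


def scale_unit(grf: SampledSignal) -> SampledSignal:
    """Affinely map a single-channel signal onto [0, 1] exactly."""
    v = grf.values
    lo, hi = v.min(), v.max()
    if hi <= lo:
        raise ValueError("cannot scale a constant signal")
    return SampledSignal((v - lo) / (hi - lo), fs=grf.fs, labels=grf.labels, t0=grf.t0)


def savgol_window_length(fs: float, halfwidth_ms: float) -> int:
    """Odd window length spanning +/- ``halfwidth_ms`` at rate ``fs``."""
    return 2 * math.floor(halfwidth_ms / 1000.0 * fs) + 1


def smooth_savgol(signal: SampledSignal, config: EventDetectionConfig | None = None) -> SampledSignal:
    """First-order Savitzky-Golay smoothing (moving-average equivalent).

    Edges are handled by polynomial extension of the boundary windows.
    """
    config = config or EventDetectionConfig()
    window = savgol_window_length(signal.fs, config.sg_halfwidth_ms)
    if window > signal.n_samples:
        raise ValueError(
            f"smoothing window ({window}) exceeds signal length ({signal.n_samples})"
        )
    sm = savgol_filter(signal.values, window, config.sg_order, axis=1, mode="interp")
    return SampledSignal(sm, fs=signal.fs, labels=signal.labels, t0=signal.t0)


def detect_events(grf: SampledSignal, config: EventDetectionConfig | None = None) -> GaitEventSeries:
    """Detect FC/FO events from a single-channel force waveform.

    Scans the smoothed, unit-scaled signal for crossings of
    ``threshold_frac * max``: an upward crossing ``s[k] < theta <= s[k+1]``
    emits FC at ``k``; a downward crossing ``s[k-1] >= theta > s[k]`` emits
    FO at ``k``. Stance phases with fewer than two supra-threshold samples
    are discarded as spikes. By construction the result is invariant to
    positive affine transforms of the input.
    """
    config = config or EventDetectionConfig()
    if grf.n_channels != 1:
        raise ValueError("detect_events expects a single-channel signal")
    v = grf.values[0]
    if v.max() <= v.min():
        logger.warning("constant force signal; no events detected")
        return GaitEventSeries(np.empty(0, int), np.empty(0, int), fs=grf.fs)
    smoothed = smooth_savgol(scale_unit(grf), config)
    s = smoothed.values[0]
    theta = config.threshold_frac * s.max()
    above = s >= theta
    if above.all() or not above.any():
        logger.warning("force signal never crosses the detection threshold")
        return GaitEventSeries(np.empty(0, int), np.empty(0, int), fs=grf.fs)

    transitions = np.flatnonzero(np.diff(above.astype(np.int8)))
    events: list[tuple[int, str]] = []
    for k in transitions:
        if above[k + 1]:  # upward: last point below the threshold
            events.append((int(k), "FC"))
        else:  # downward: first point below the threshold
            events.append((int(k + 1), "FO"))

    events = _prune_short_phases(events, above, min_run=2)
    if config.min_phase_ms is not None:
        min_samples = int(round(config.min_phase_ms / 1000.0 * grf.fs))
        events = _debounce(events, min_samples)

    fc = np.array([i for i, t in events if t == "FC"], dtype=int)
    fo = np.array([i for i, t in events if t == "FO"], dtype=int)
    return GaitEventSeries(fc, fo, fs=grf.fs)


def _prune_short_phases(
    events: list[tuple[int, str]], above: np.ndarray, min_run: int
) -> list[tuple[int, str]]:
    """Drop event pairs bounding supra- or sub-threshold runs shorter than
    ``min_run`` samples (isolated spikes and single-sample dips).

    ``events`` is in chronological (transition) order. Removing a bounding
    pair merges the neighbouring phases, so the scan repeats until stable.
    """
    changed = True
    while changed:
        changed = False
        for i in range(len(events) - 1):
            (i0, t0), (i1, t1) = events[i], events[i + 1]
            if t0 == "FC" and t1 == "FO":
                run = i1 - i0 - 1  # samples above the threshold
            elif t0 == "FO" and t1 == "FC":
                run = i1 - i0 + 1  # samples below the threshold
            else:  # pragma: no cover - transitions alternate by construction
                continue
            if run < min_run:
                del events[i : i + 2]
                changed = True
                break
    return events


def _debounce(events: list[tuple[int, str]], min_samples: int) -> list[tuple[int, str]]:
    """Iteratively remove event pairs bounding phases shorter than
    ``min_samples`` (stances via the FC/FO pair, swings via FO/FC)."""
    changed = True
    while changed:
        changed = False
        for i in range(len(events) - 1):
            if events[i + 1][0] - events[i][0] < min_samples:
                del events[i : i + 2]
                changed = True
                break
    return events
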
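"""Prediction-quality metrics and event-timing accuracy.

Waveform quality is quantified by the range-normalized root-mean-square
error (reported as a fraction; multiply by 100 for percent) and the
coefficient of determination. Event timing is scored by greedy
nearest-neighbor matching of detected events followed by per-type mean
absolute errors in milliseconds; unmatched events are reported as counts.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np

from .gait_events import EventDetectionConfig, detect_events
from .signal_io import GaitEventSeries, SampledSignal

logger = logging.getLogger(__name__)


def nrmse(y: np.ndarray, z: np.ndarray) -> float:
    """Root-mean-square error of ``y`` vs target ``z``, normalized by the
    target's peak-to-peak range. Scale-invariant: scaling both by c > 0
    leaves the value unchanged."""
    y = np.asarray(y, dtype=float).ravel()
    z = np.asarray(z, dtype=float).ravel()
    if y.shape != z.shape:
        raise ValueError("y and z must have equal lengths")
    rng = z.max() - z.min()
    if rng <= 0:
        raise ValueError("target range is zero")
    return float(np.sqrt(np.mean((z - y) ** 2)) / rng)


def r_squared(y: np.ndarray, z: np.ndarray) -> float:
    """Coefficient of determination, 1 - SSE/SST with SST about mean(z)."""
    y = np.asarray(y, dtype=float).ravel()
    z = np.asarray(z, dtype=float).ravel()
    if y.shape != z.shape:
        raise ValueError("y and z must have equal lengths")
    sst = float(np.sum((z - z.mean()) ** 2))
    if sst <= 0:
        raise ValueError("target variance is zero")
    sse = float(np.sum((z - y) ** 2))
    return 1.0 - sse / sst


@dataclass
class MatchResult:
    """Outcome of event matching between a prediction and a target."""

    pairs_fc: list[tuple[int, int]] = field(default_factory=list)  # (target, pred)
    pairs_fo: list[tuple[int, int]] = field(default_factory=list)
    n_unmatched_target: int = 0
    n_unmatched_pred: int = 0

    @property
    def n_matched_fc(self) -> int:
        return len(self.pairs_fc)

    @property
    def n_matched_fo(self) -> int:
        return len(self.pairs_fo)


def _match_one_type(
    target: np.ndarray, pred: np.ndarray, max_lag_samples: float
) -> tuple[list[tuple[int, int]], int, int]:
    """Greedy nearest-neighbor matching on |delta|; ties break toward the
    earlier target event. Each event is used at most once."""
    candidates = []
    for ti, tv in enumerate(target):
        for pi, pv in enumerate(pred):
            d = abs(int(pv) - int(tv))
            if d <= max_lag_samples:
                candidates.append((d, tv, ti, pi))
    candidates.sort(key=lambda c: (c[0], c[1]))
    used_t: set[int] = set()
    used_p: set[int] = set()
    pairs = []
    for _, _, ti, pi in candidates:
        if ti in used_t or pi in used_p:
            continue
        used_t.add(ti)
        used_p.add(pi)
        pairs.append((int(target[ti]), int(pred[pi])))
    pairs.sort()
    return pairs, len(target) - len(used_t), len(pred) - len(used_p)


def match_events(
    pred: GaitEventSeries,
    target: GaitEventSeries,
    max_lag_ms: float | None = None,
) -> MatchResult:
    """Match predicted to target events per type, nearest neighbor first.

    Pairs further apart than ``max_lag_ms`` (default: 50% of the median
    target stride duration) are rejected.
    """
    if not np.isclose(pred.fs, target.fs):
        raise ValueError("event series must share one sampling rate")
    if target.n_events == 0:
        logger.warning("empty target event series; everything unmatched")
        return MatchResult(n_unmatched_pred=pred.n_events)
    if max_lag_ms is None:
        fcs = target.foot_contacts
        if fcs.size >= 2:
            max_lag_ms = 0.5 * float(np.median(np.diff(fcs))) * 1000.0 / target.fs
        else:
            max_lag_ms = np.inf
    max_lag_samples = max_lag_ms / 1000.0 * target.fs
    res = MatchResult()
    res.pairs_fc, ut_fc, up_fc = _match_one_type(
        target.foot_contacts, pred.foot_contacts, max_lag_samples
    )
    res.pairs_fo, ut_fo, up_fo = _match_one_type(
        target.foot_offs, pred.foot_offs, max_lag_samples
    )
    res.n_unmatched_target = ut_fc + ut_fo
    res.n_unmatched_pred = up_fc + up_fo
    return res


def event_mae_ms(match: MatchResult, fs: float) -> tuple[float, float]:
    """Mean absolute timing error (ms) of matched FC and FO pairs.

    Types without any match are reported as NaN.
    """
    def _mae(pairs: list[tuple[int, int]]) -> float:
        if not pairs:
            return float("nan")
        deltas = [abs(p - t) for t, p in pairs]
        return float(np.mean(deltas) * 1000.0 / fs)

    return _mae(match.pairs_fc), _mae(match.pairs_fo)


@dataclass
class EvaluationReport:
    """Waveform and event-timing quality of one prediction vs its target."""

    epsilon: float
    r2: float
    mae_fc_ms: float
    mae_fo_ms: float
    n_matched_fc: int
    n_matched_fo: int
    n_unmatched_target: int
    n_unmatched_pred: int

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate_trial(
    y: np.ndarray,
    z: np.ndarray,
    fs: float,
    mask: np.ndarray | None = None,
    event_config: EventDetectionConfig | None = None,
    max_lag_ms: float | None = None,
) -> EvaluationReport:
    """Full comparison of a predicted vs measured force trace.

    Waveform metrics use the (optionally mask-restricted) aligned samples;
    event detection always runs on the full traces.
    """
    y = np.asarray(y, dtype=float).ravel()
    z = np.asarray(z, dtype=float).ravel()
    if y.shape != z.shape:
        raise ValueError("y and z must have equal lengths")
    ym, zm = (y[mask], z[mask]) if mask is not None else (y, z)
    eps = nrmse(ym, zm)
    r2 = r_squared(ym, zm)
    ev_pred = detect_events(SampledSignal(y[None, :], fs=fs), event_config)
    ev_target = detect_events(SampledSignal(z[None, :], fs=fs), event_config)
    match = match_events(ev_pred, ev_target, max_lag_ms=max_lag_ms)
    mae_fc, mae_fo = event_mae_ms(match, fs)
    return EvaluationReport(
        epsilon=eps,
        r2=r2,
        mae_fc_ms=mae_fc,
        mae_fo_ms=mae_fo,
        n_matched_fc=match.n_matched_fc,
        n_matched_fo=match.n_matched_fo,
        n_unmatched_target=match.n_unmatched_target,
        n_unmatched_pred=match.n_unmatched_pred,
    )
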
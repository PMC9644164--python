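"""Training/validation schemes: segmented-train / continuous-test with a
continuation rule, repetition harness, training-size sweep, and leave-M-out
cross-validation by trial.

Per trial, one contiguous stride-aligned window holding 50% of the samples
is held out (first half validation, second half test, in temporal order);
strides outside the window are pooled across trials for training, capped at
25 strides per trial. Training is repeated with freshly drawn reservoirs
until the per-trial validation R^2 values are all positive (continuation
rule) or the attempt budget is exhausted.

Seed hierarchy: master seed -> per-repetition seed -> per-attempt network
seed, so every stochastic step replays bit-identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .evaluation import EvaluationReport, evaluate_trial, r_squared
from .gait_events import EventDetectionConfig
from .preprocess import PreprocessConfig, build_input, resample_grf, zscore_signal
from .reservoir import EchoStateNetwork, EsnConfig, fit_readout, init_network, run_states
from .signal_io import GaitEventSeries, TrialRecord

logger = logging.getLogger(__name__)


@dataclass
class ProtocolConfig:
    n_repetitions: int = 100
    max_validation_attempts: int = 100
    strides_cap_per_trial: int = 25
    train_fraction: float = 0.5
    validation_fraction: float = 0.25
    test_fraction: float = 0.25
    sweep_fractions: tuple[float, ...] = (0.04, 0.08, 0.17, 0.33, 0.5)
    lmo_m: int = 1
    lmo_repetitions: int = 42
    #: input samples preceding each training stride used to spin up the
    #: reservoir state (discarded from the fit). This replaces starting every
    #: segment from q0 = 0, which leaves segment states inconsistent with the
    #: continuous-run states used at test time.
    segment_warmup_samples: int = 50
    #: additionally drop the transient samples around foot-off from the
    #: training targets. Off by default: for running strides the trailing
    #: transient covers the entire stance phase, which would remove the
    #: force bump from the training set altogether.
    mask_training_transients: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("train_fraction", "validation_fraction", "test_fraction"):
            f = getattr(self, name)
            if not 0 < f < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.strides_cap_per_trial < 1 or self.max_validation_attempts < 0:
            raise ValueError("caps must be >= 1 and attempts >= 0")
        if self.lmo_m < 1:
            raise ValueError("lmo_m must be >= 1")

    @property
    def holdout_fraction(self) -> float:
        return self.validation_fraction + self.test_fraction


@dataclass
class PreparedTrial:
    """Network-ready view of one trial (input, z-scored target, events)."""

    trial_id: str
    mode: str
    x: np.ndarray  # (3, T)
    z: np.ndarray  # (T,)
    fs: float
    events: GaitEventSeries
    transient_samples: int = 36

    @property
    def n_samples(self) -> int:
        return self.z.shape[0]

    @property
    def strides(self) -> list[tuple[int, int]]:
        fos = [int(i) for i in self.events.foot_offs if i <= self.n_samples]
        return list(zip(fos[:-1], fos[1:]))


def prepare_trial(trial: TrialRecord, config: PreprocessConfig | None = None) -> PreparedTrial:
    """Resample + z-score the force target, build the network input, and
    align both with the trial's events at the working rate."""
    config = config or PreprocessConfig()
    xin = build_input(trial.accel, config)
    grf = resample_grf(trial.grf, config.target_fs)
    z = zscore_signal(grf).values[0]
    n = min(xin.n_samples, z.shape[0])
    if trial.events is None:
        raise ValueError(f"trial {trial.trial_id} has no events")
    if not np.isclose(trial.events.fs, trial.accel.fs, rtol=1e-6):
        raise ValueError(f"trial {trial.trial_id}: event rate differs from accel rate")
    return PreparedTrial(
        trial_id=trial.trial_id,
        mode=trial.mode,
        x=xin.x[:, :n],
        z=z[:n],
        fs=trial.accel.fs,
        events=trial.events,
        transient_samples=config.transient_samples,
    )


@dataclass
class TrialSplit:
    holdout: tuple[int, int]
    validation: tuple[int, int]
    test: tuple[int, int]
    train_strides: list[tuple[int, int]]


@dataclass
class SplitPlan:
    trials: dict[str, TrialSplit]
    seed: int | None = None

    def n_train_strides(self) -> int:
        return sum(len(t.train_strides) for t in self.trials.values())


def make_segmented_split(
    trials: list[PreparedTrial],
    config: ProtocolConfig,
    rng: np.random.Generator,
) -> SplitPlan:
    """Draw the per-trial continuous holdout window and training strides.

    The holdout window covers ``validation_fraction + test_fraction`` of the
    trial, starts at a seeded random foot-off, and is split into validation
    then test in temporal order. Training strides are a random subsample of
    the strides disjoint from the window; the subsample size tracks
    ``train_fraction`` of the trial's strides, capped per trial.
    """
    plan: dict[str, TrialSplit] = {}
    for trial in trials:
        strides = trial.strides
        if len(strides) < 4:
            raise ValueError(f"trial {trial.trial_id}: too few strides to split")
        T = trial.n_samples
        L = int(round(config.holdout_fraction * T))
        candidates = [a for a, _ in strides if a + L <= T]
        if not candidates:
            raise ValueError(f"trial {trial.trial_id}: no room for the holdout window")
        start = int(candidates[rng.integers(len(candidates))])
        mid = start + L // 2
        holdout = (start, start + L)
        available = [s for s in strides if s[1] <= start or s[0] >= start + L]
        if not available:
            raise ValueError(f"trial {trial.trial_id}: no training strides outside holdout")
        k = int(round(config.train_fraction * len(strides)))
        k = max(1, min(k, len(available), config.strides_cap_per_trial))
        chosen = rng.choice(len(available), size=k, replace=False)
        train = sorted(available[i] for i in chosen)
        plan[trial.trial_id] = TrialSplit(
            holdout=holdout, validation=(start, mid), test=(mid, start + L), train_strides=train
        )
    return SplitPlan(trials=plan)


@dataclass
class FitResult:
    network: EchoStateNetwork | None
    attempts: int
    passed: bool
    validation_r2: dict[str, float] = field(default_factory=dict)
    #: full-trial predicted waveforms of the last attempt, keyed by trial id
    predictions: dict[str, np.ndarray] = field(default_factory=dict)
    failure_reason: str | None = None


def _segment_mask(length: int, transient: int) -> np.ndarray:
    mask = np.ones(length, dtype=bool)
    if transient > 0:
        mask[:transient] = False
        mask[max(0, length - transient):] = False
    return mask


def fit_with_continuation(
    trials: list[PreparedTrial],
    train_strides: dict[str, list[tuple[int, int]]],
    validation_slices: dict[str, tuple[int, int]],
    esn_config: EsnConfig,
    max_attempts: int = 100,
    seed_seq: np.random.SeedSequence | None = None,
    warmup_samples: int = 50,
    mask_transients: bool = False,
) -> FitResult:
    """Repeatedly (re-)initialize the reservoir and fit the readout until
    every per-trial validation R^2 is positive or attempts are exhausted.

    Each training stride's states are spun up over the ``warmup_samples``
    input samples preceding the stride (warm-up columns are discarded), so
    the fitted columns are consistent with continuous operation. Failure is
    a reported state, not an exception. The last attempt's full-trial
    predictions are returned so evaluation does not need to rerun the
    reservoir.
    """
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(esn_config.seed)
    if max_attempts == 0:
        return FitResult(network=None, attempts=0, passed=False, failure_reason="no attempts allowed")
    attempt_seeds = seed_seq.spawn(max_attempts)
    by_id = {t.trial_id: t for t in trials}
    result = FitResult(network=None, attempts=0, passed=False)
    for attempt, child in enumerate(attempt_seeds, start=1):
        net_seed = int(child.generate_state(1)[0])
        net = init_network(replace(esn_config, seed=net_seed))
        noise_rng = np.random.default_rng(child)
        states, targets, masks = [], [], []
        for tid, segs in train_strides.items():
            trial = by_id[tid]
            for a, b in segs:
                a0 = max(0, a - warmup_samples)
                S = run_states(net, trial.x[:, a0:b], noise_on=True, rng=noise_rng)
                states.append(S.Q[:, a - a0:])
                targets.append(trial.z[a:b])
                if mask_transients:
                    masks.append(_segment_mask(b - a, trial.transient_samples))
                else:
                    masks.append(np.ones(b - a, dtype=bool))
        try:
            w, _ = fit_readout(states, targets, masks, ridge_lambda=esn_config.ridge_lambda)
        except ValueError as exc:
            result = FitResult(None, attempt, False, failure_reason=str(exc))
            continue
        net.W = w
        predictions, val_r2 = {}, {}
        degenerate = None
        for trial in trials:
            y = w @ run_states(net, trial.x, noise_on=False).Q
            predictions[trial.trial_id] = y
            if trial.trial_id in validation_slices:
                a, b = validation_slices[trial.trial_id]
                try:
                    val_r2[trial.trial_id] = r_squared(y[a:b], trial.z[a:b])
                except ValueError as exc:
                    degenerate = f"trial {trial.trial_id}: {exc}"
        result = FitResult(
            network=net,
            attempts=attempt,
            passed=False,
            validation_r2=val_r2,
            predictions=predictions,
            failure_reason=degenerate,
        )
        if degenerate is None and val_r2 and all(v > 0 for v in val_r2.values()):
            result.passed = True
            return result
    return result


def _evaluate_split(
    trials: list[PreparedTrial],
    plan: SplitPlan,
    fit: FitResult,
    event_config: EventDetectionConfig | None,
) -> list[dict]:
    rows = []
    for trial in trials:
        split = plan.trials[trial.trial_id]
        a, b = split.test
        report = evaluate_trial(
            fit.predictions[trial.trial_id][a:b], trial.z[a:b], trial.fs, event_config=event_config
        )
        row = {"trial_id": trial.trial_id, "mode": trial.mode}
        row.update(report.to_dict())
        rows.append(row)
    return rows


def run_repetitions(
    trials: list[PreparedTrial],
    config: ProtocolConfig,
    esn_config: EsnConfig,
    event_config: EventDetectionConfig | None = None,
    n_repetitions: int | None = None,
) -> pd.DataFrame:
    """Independent seeded draws of split + continuation fit + test evaluation.

    Returns one row per (repetition, trial); failed repetitions are recorded
    with ``passed = False`` and NaN metrics rather than raised.
    """
    n_reps = config.n_repetitions if n_repetitions is None else n_repetitions
    root = np.random.SeedSequence(config.seed)
    rep_seeds = root.spawn(n_reps)
    rows = []
    for rep, rep_seed in enumerate(rep_seeds):
        split_seq, fit_seq = rep_seed.spawn(2)
        rng = np.random.default_rng(split_seq)
        plan = make_segmented_split(trials, config, rng)
        fit = fit_with_continuation(
            trials,
            {tid: s.train_strides for tid, s in plan.trials.items()},
            {tid: s.validation for tid, s in plan.trials.items()},
            esn_config,
            max_attempts=config.max_validation_attempts,
            seed_seq=fit_seq,
            warmup_samples=config.segment_warmup_samples,
            mask_transients=config.mask_training_transients,
        )
        if not fit.passed:
            logger.warning("repetition %d: validation never passed (%s)", rep, fit.failure_reason)
            rows.append(
                {
                    "repetition": rep,
                    "trial_id": "",
                    "mode": "",
                    "attempts": fit.attempts,
                    "passed": False,
                    "n_train_strides": plan.n_train_strides(),
                }
            )
            continue
        for row in _evaluate_split(trials, plan, fit, event_config):
            row.update(
                {
                    "repetition": rep,
                    "attempts": fit.attempts,
                    "passed": True,
                    "n_train_strides": plan.n_train_strides(),
                }
            )
            rows.append(row)
    return pd.DataFrame(rows)


_METRICS = ("epsilon", "r2", "mae_fc_ms", "mae_fo_ms")


def summarize_repetitions(reports: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD across repetitions of the per-repetition trial means."""
    ok = reports[reports["passed"] == True]  # noqa: E712
    if ok.empty:
        return pd.DataFrame(columns=["metric", "mean", "sd"])
    per_rep = ok.groupby("repetition")[list(_METRICS)].mean()
    return pd.DataFrame(
        {
            "metric": _METRICS,
            "mean": [per_rep[m].mean() for m in _METRICS],
            "sd": [per_rep[m].std(ddof=1) if len(per_rep) > 1 else 0.0 for m in _METRICS],
        }
    )


def sweep_training_fraction(
    trials: list[PreparedTrial],
    fractions: tuple[float, ...],
    config: ProtocolConfig,
    esn_config: EsnConfig,
    event_config: EventDetectionConfig | None = None,
    n_repetitions: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Repeat the repetition harness for each training fraction.

    Validation and test fractions stay fixed. Returns ``(summary, per_rep)``
    where the summary has one row per fraction with metric means +/- SD and
    the mean +/- SD training stride count.
    """
    if list(fractions) != sorted(fractions):
        raise ValueError("fractions must be ascending")
    for f in fractions:
        if f >= 1.0 - config.holdout_fraction + 1e-12:
            raise ValueError(f"training fraction {f} leaves no holdout room")
    summaries, all_reports = [], []
    for frac in fractions:
        cfg = replace(config, train_fraction=frac)
        reports = run_repetitions(trials, cfg, esn_config, event_config, n_repetitions)
        reports = reports.assign(train_fraction=frac)
        all_reports.append(reports)
        ok = reports[reports["passed"] == True]  # noqa: E712
        strides = ok.groupby("repetition")["n_train_strides"].first()
        summary = {"train_fraction": frac,
                   "strides_mean": strides.mean() if len(strides) else np.nan,
                   "strides_sd": strides.std(ddof=1) if len(strides) > 1 else 0.0}
        for _, row in summarize_repetitions(reports).iterrows():
            summary[f"{row['metric']}_mean"] = row["mean"]
            summary[f"{row['metric']}_sd"] = row["sd"]
        summaries.append(summary)
    return pd.DataFrame(summaries), pd.concat(all_reports, ignore_index=True)


def make_lmo_folds(
    n_trials: int,
    m: int,
    n_repetitions: int,
    rng: np.random.Generator | None = None,
) -> list[tuple[int, ...]]:
    """Held-out index sets for leave-M-out cross-validation.

    ``m == 1`` enumerates every trial once (``n_trials`` folds); ``m > 1``
    draws ``n_repetitions`` distinct random held-out sets.
    """
    if m >= n_trials:
        raise ValueError("M must be smaller than the number of trials")
    if m == 1:
        return [(i,) for i in range(n_trials)]
    if rng is None:
        rng = np.random.default_rng(0)
    folds: list[tuple[int, ...]] = []
    seen = set()
    guard = 0
    while len(folds) < n_repetitions and guard < 100 * n_repetitions:
        fold = tuple(sorted(rng.choice(n_trials, size=m, replace=False).tolist()))
        if fold not in seen:
            seen.add(fold)
            folds.append(fold)
        guard += 1
    return folds


def leave_m_out(
    trials: list[PreparedTrial],
    config: ProtocolConfig,
    esn_config: EsnConfig,
    event_config: EventDetectionConfig | None = None,
) -> pd.DataFrame:
    """Leave-M-out by trial: train/validate on held-in trials (75/25 with
    the per-trial stride cap), test on the full continuous held-out trials."""
    root = np.random.SeedSequence(config.seed)
    fold_rng = np.random.default_rng(root.spawn(1)[0])
    folds = make_lmo_folds(len(trials), config.lmo_m, config.lmo_repetitions, fold_rng)
    fold_seeds = root.spawn(len(folds))
    rows = []
    for fold_i, (held_out, fold_seed) in enumerate(zip(folds, fold_seeds)):
        held_in = [t for i, t in enumerate(trials) if i not in held_out]
        held_out_trials = [trials[i] for i in held_out]
        split_seq, fit_seq = fold_seed.spawn(2)
        rng = np.random.default_rng(split_seq)
        train_strides: dict[str, list[tuple[int, int]]] = {}
        val_slices: dict[str, tuple[int, int]] = {}
        for trial in held_in:
            strides = trial.strides
            if len(strides) < 4:
                raise ValueError(f"trial {trial.trial_id}: too few strides")
            T = trial.n_samples
            L = int(round(0.25 * T))
            candidates = [a for a, _ in strides if a + L <= T]
            start = int(candidates[rng.integers(len(candidates))])
            val_slices[trial.trial_id] = (start, start + L)
            available = [s for s in strides if s[1] <= start or s[0] >= start + L]
            k = min(len(available), config.strides_cap_per_trial)
            chosen = rng.choice(len(available), size=k, replace=False)
            train_strides[trial.trial_id] = sorted(available[i] for i in chosen)
        fit = fit_with_continuation(
            held_in + held_out_trials,
            train_strides,
            val_slices,
            esn_config,
            max_attempts=config.max_validation_attempts,
            seed_seq=fit_seq,
            warmup_samples=config.segment_warmup_samples,
            mask_transients=config.mask_training_transients,
        )
        if not fit.passed:
            rows.append({"fold": fold_i, "trial_id": "", "mode": "", "passed": False})
            continue
        for trial in held_out_trials:
            report = evaluate_trial(
                fit.predictions[trial.trial_id], trial.z, trial.fs, event_config=event_config
            )
            row = {"fold": fold_i, "trial_id": trial.trial_id, "mode": trial.mode, "passed": True}
            row.update(report.to_dict())
            rows.append(row)
    return pd.DataFrame(rows)
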
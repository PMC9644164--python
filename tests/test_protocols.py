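import numpy as np
import pandas as pd
import pytest

from esngait.preprocess import PreprocessConfig
from esngait.protocols import (
    PreparedTrial,
    ProtocolConfig,
    fit_with_continuation,
    leave_m_out,
    make_lmo_folds,
    make_segmented_split,
    prepare_trial,
    run_repetitions,
    summarize_repetitions,
    sweep_training_fraction,
)
from esngait.reservoir import EsnConfig
from esngait.signal_io import GaitEventSeries

SMALL_ESN = EsnConfig(n_nodes=200)


class TestPrepareTrial:
    def test_shapes_aligned(self, mini_cohort):
        t = prepare_trial(mini_cohort[0], PreprocessConfig(detrend_integrals=True))
        assert t.x.shape == (3, t.n_samples)
        assert t.z.shape == (t.n_samples,)
        assert len(t.strides) >= 10

    def test_target_is_zscored(self, mini_prepared):
        # z-scored per trial before trimming to the common length, so the
        # moments are only approximately exact
        z = mini_prepared[0].z
        assert abs(z.mean()) < 1e-2
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-2)

    def test_missing_events_rejected(self, mini_cohort):
        import dataclasses

        bare = dataclasses.replace(mini_cohort[0], events=None, events_grf_rate=None)
        with pytest.raises(ValueError, match="events"):
            prepare_trial(bare)


class TestSegmentedSplit:
    def test_cap_at_25_strides(self):
        # synthetic trial with many strides
        from esngait.synthetic_gait import SyntheticTrialSpec, synthesize_trial, walking_pattern

        trial = synthesize_trial(
            SyntheticTrialSpec(pattern=walking_pattern(), n_strides=80, seed=2)
        )
        prepared = prepare_trial(trial, PreprocessConfig(detrend_integrals=True))
        plan = make_segmented_split([prepared], ProtocolConfig(), np.random.default_rng(0))
        assert len(plan.trials[prepared.trial_id].train_strides) <= 25

    def test_same_seed_identical(self, mini_prepared):
        cfg = ProtocolConfig()
        a = make_segmented_split(mini_prepared, cfg, np.random.default_rng(7))
        b = make_segmented_split(mini_prepared, cfg, np.random.default_rng(7))
        for tid in a.trials:
            assert a.trials[tid].holdout == b.trials[tid].holdout
            assert a.trials[tid].train_strides == b.trials[tid].train_strides

    def test_training_disjoint_from_holdout(self, mini_prepared):
        plan = make_segmented_split(mini_prepared, ProtocolConfig(), np.random.default_rng(3))
        for tid, split in plan.trials.items():
            h0, h1 = split.holdout
            holdout = set(range(h0, h1))
            for a, b in split.train_strides:
                assert holdout.isdisjoint(range(a, b))

    def test_validation_then_test_in_temporal_order(self, mini_prepared):
        plan = make_segmented_split(mini_prepared, ProtocolConfig(), np.random.default_rng(3))
        for split in plan.trials.values():
            assert split.validation[1] == split.test[0]
            assert split.validation[0] == split.holdout[0]
            assert split.test[1] == split.holdout[1]

    def test_holdout_fraction_covered(self, mini_prepared):
        cfg = ProtocolConfig()
        plan = make_segmented_split(mini_prepared, cfg, np.random.default_rng(3))
        for t in mini_prepared:
            h0, h1 = plan.trials[t.trial_id].holdout
            assert (h1 - h0) == pytest.approx(0.5 * t.n_samples, abs=2)

    def test_too_few_strides_named(self):
        t = PreparedTrial(
            trial_id="tiny", mode="walking",
            x=np.zeros((3, 100)), z=np.zeros(100), fs=100.0,
            events=GaitEventSeries([10, 60], [40, 90], fs=100.0),
        )
        with pytest.raises(ValueError, match="tiny"):
            make_segmented_split([t], ProtocolConfig(), np.random.default_rng(0))


class TestContinuation:
    def test_zero_attempts_fails_immediately(self, mini_prepared):
        res = fit_with_continuation(mini_prepared, {}, {}, SMALL_ESN, max_attempts=0)
        assert not res.passed and res.attempts == 0

    def test_passes_first_attempt_on_fixture(self, mini_prepared):
        plan = make_segmented_split(mini_prepared, ProtocolConfig(), np.random.default_rng(1))
        res = fit_with_continuation(
            mini_prepared,
            {tid: s.train_strides for tid, s in plan.trials.items()},
            {tid: s.validation for tid, s in plan.trials.items()},
            SMALL_ESN,
            max_attempts=5,
            seed_seq=np.random.SeedSequence(0),
        )
        assert res.passed and res.attempts == 1
        assert all(v > 0 for v in res.validation_r2.values())

    def test_degenerate_validation_reported_not_raised(self, mini_prepared):
        t = mini_prepared[0]
        flat = PreparedTrial(
            trial_id="flat", mode="walking",
            x=t.x.copy(), z=np.zeros(t.n_samples), fs=t.fs, events=t.events,
        )
        res = fit_with_continuation(
            [flat],
            {"flat": t.strides[:3]},
            {"flat": (0, 200)},
            SMALL_ESN,
            max_attempts=1,
            seed_seq=np.random.SeedSequence(0),
        )
        assert not res.passed
        assert "flat" in (res.failure_reason or "")


@pytest.fixture(scope="module")
def reports(mini_prepared):
    return run_repetitions(
        mini_prepared, ProtocolConfig(seed=21), SMALL_ESN, n_repetitions=2
    )


class TestRunRepetitions:
    def test_shape(self, reports, mini_prepared):
        ok = reports[reports["passed"] == True]  # noqa: E712
        assert set(ok["repetition"]) == {0, 1}
        assert len(ok) == 2 * len(mini_prepared)

    def test_metrics_reasonable(self, reports):
        ok = reports[reports["passed"] == True]  # noqa: E712
        assert (ok["r2"] > 0.9).all()

    def test_deterministic_rerun(self, mini_prepared, reports):
        again = run_repetitions(
            mini_prepared, ProtocolConfig(seed=21), SMALL_ESN, n_repetitions=2
        )
        pd.testing.assert_frame_equal(reports, again)

    def test_summary_shape(self, reports):
        summary = summarize_repetitions(reports)
        assert set(summary["metric"]) == {"epsilon", "r2", "mae_fc_ms", "mae_fo_ms"}
        assert (summary["sd"] >= 0).all()


class TestSweep:
    def test_single_fraction_consistent_with_repetitions(self, mini_prepared):
        cfg = ProtocolConfig(seed=4)
        summary, per_rep = sweep_training_fraction(
            mini_prepared, (0.5,), cfg, SMALL_ESN, n_repetitions=1
        )
        direct = run_repetitions(mini_prepared, cfg, SMALL_ESN, n_repetitions=1)
        merged = per_rep.drop(columns=["train_fraction"])
        pd.testing.assert_frame_equal(
            merged.reset_index(drop=True), direct.reset_index(drop=True)
        )
        assert len(summary) == 1

    def test_fraction_order_enforced(self, mini_prepared):
        with pytest.raises(ValueError, match="ascending"):
            sweep_training_fraction(
                mini_prepared, (0.5, 0.04), ProtocolConfig(), SMALL_ESN, n_repetitions=1
            )

    def test_fraction_leaves_holdout_room(self, mini_prepared):
        with pytest.raises(ValueError, match="holdout"):
            sweep_training_fraction(
                mini_prepared, (0.6,), ProtocolConfig(), SMALL_ESN, n_repetitions=1
            )


class TestLmoFolds:
    def test_42_trials_m1_gives_42_folds(self):
        assert len(make_lmo_folds(42, 1, 42)) == 42

    def test_m1_partition(self):
        folds = make_lmo_folds(10, 1, 10)
        held = sorted(i for fold in folds for i in fold)
        assert held == list(range(10))

    def test_m_too_large(self):
        with pytest.raises(ValueError, match="M"):
            make_lmo_folds(5, 5, 10)

    def test_m2_distinct(self):
        folds = make_lmo_folds(8, 2, 12, np.random.default_rng(0))
        assert len(folds) == 12
        assert len(set(folds)) == 12
        assert all(len(f) == 2 for f in folds)


class TestLeaveMOut:
    def test_each_trial_held_out_once(self, mini_prepared):
        cfg = ProtocolConfig(seed=11, lmo_m=1)
        reports = leave_m_out(mini_prepared, cfg, SMALL_ESN)
        ok = reports[reports["passed"] == True]  # noqa: E712
        assert sorted(ok["trial_id"]) == sorted(t.trial_id for t in mini_prepared)
        assert ok["fold"].nunique() == len(mini_prepared)

    def test_lmo_harder_than_pooled_split(self, mini_prepared):
        # generalization to unseen trials is no easier than within-trial testing
        cfg = ProtocolConfig(seed=31)
        pooled = run_repetitions(mini_prepared, cfg, SMALL_ESN, n_repetitions=3)
        pooled_r2 = pooled[pooled["passed"] == True]["r2"].mean()  # noqa: E712
        lmo = leave_m_out(mini_prepared, ProtocolConfig(seed=32), SMALL_ESN)
        lmo_r2 = lmo[lmo["passed"] == True]["r2"].mean()  # noqa: E712
        assert lmo_r2 <= pooled_r2 + 0.02
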
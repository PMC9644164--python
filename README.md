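# esngait

Predict continuous, z-scored vertical ground reaction force (GRF) waveforms
from tri-axial shank accelerometry with a leaky echo state network (ESN),
then detect foot-contact / foot-off gait events from the predicted waveform
by threshold crossing. The package also ships the validation protocols
(segmented-train / continuous-test with a continuation rule, repetition
harness, training-size sweep, leave-M-out cross-validation by trial) and a
synthetic walking/running gait generator so the entire pipeline is testable
without any external recordings.

## Pipeline

1. **Preprocess** (`esngait.preprocess`): re-orient the 3-channel shank
   acceleration onto its leading principal axis, zero-phase high-pass
   (Butterworth, 1 Hz, 2nd order), integrate twice (velocity, position),
   range-normalize each trace per trial, and stack them as the 3 x T network
   input. The force target is resampled to the working rate
   (2000/14 Hz ≈ 142.86 Hz) and z-scored per trial.
2. **Reservoir** (`esngait.reservoir`): sparse random connectivity rescaled
   to spectral radius 0.5, dense input weights with magnitudes in
   [0.1, 0.5], leaky (gamma = 0.5) tanh dynamics with small training-state
   noise (1e-4), and a linear readout fitted by (ridge-regularized)
   least squares over concatenated stride segments.
3. **Events** (`esngait.gait_events`): scale the (measured or predicted)
   force to [0, 1], smooth with a 1st-order Savitzky-Golay filter
   (±30 ms = 9 samples at the working rate), and read foot contact / foot
   off off the crossings of 12.5% of the maximum.
4. **Evaluate** (`esngait.evaluation`): range-normalized RMSE, R²,
   greedy nearest-neighbor event matching and per-type mean absolute
   timing errors.

## CLI

All commands accept `--config <yaml>` (nested sections `preprocess`, `esn`,
`events`, `protocol`, `synthetic`, plus `master_seed`; unknown keys are
rejected) and write a resolved-config snapshot beside their outputs.
Exit codes: 0 success, 2 usage/config error, 3 training stopped
(continuation rule never satisfied).

```sh
# synthesize a 42-trial cohort (21 walking + 21 running) with a manifest
esngait simulate --seed 1 --out cohort/

# train one network on segmented strides with the continuation rule
esngait train --manifest cohort/manifest.csv --out model/

# predict, detect events, and score
esngait predict --model model/network.npz --manifest cohort/manifest.csv --out pred/
esngait detect --input pred/walk00_pred.csv --out walk00_events.csv
esngait evaluate --pred pred/walk00_pred.csv --target resampled_grf.csv --out report.json

# validation protocols
esngait protocol repetitions --manifest cohort/manifest.csv --repetitions 5 --out reps/
esngait protocol sweep        --manifest cohort/manifest.csv --out sweep/
esngait protocol lmo          --manifest cohort/manifest.csv --out lmo/
```

File formats are plain CSV: signal tables (`time_s,<ch...>`), event tables
(`event_type,sample_index,time_s`), and a trial manifest
(`trial_id,mode,speed_mps,accel_path,grf_path,events_path`).

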
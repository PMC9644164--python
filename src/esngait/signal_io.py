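"""Containers and delimited-table I/O for sampled signals, gait events, and trials.

All tables are plain text (comma-separated by default, tab-separated variant
auto-detected), UTF-8, with a header row. Sample indices are 0-based
throughout; the time of sample ``k`` is ``t0 + k / fs``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Working sampling rate of the accelerometer pipeline (Hz).
ACCEL_FS = 2000.0 / 14.0

#: Native sampling rate of the force signal (Hz).
GRF_FS = 1000.0

#: Relative jitter of the time column (vs. the median step) that triggers a
#: warning on load; files beyond ``JITTER_ERROR`` are rejected.
JITTER_WARN = 0.01
JITTER_ERROR = 0.25


@dataclass
class SampledSignal:
    """A uniformly sampled multichannel time series.

    Parameters
    ----------
    values
        Array of shape ``(n_channels, n_samples)``. A 1-D array is promoted
        to a single channel.
    fs
        Sampling rate in Hz, strictly positive.
    labels
        Channel names; auto-generated (``ch1``, ``ch2``, ...) when omitted.
    t0
        Time of the first sample in seconds.
    """

    values: np.ndarray
    fs: float
    labels: tuple[str, ...] | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        if v.ndim != 2:
            raise ValueError("values must be a (n_channels, n_samples) array")
        if v.shape[0] == 0:
            raise ValueError("no channels")
        if v.shape[1] < 1:
            raise ValueError("need at least one sample")
        if not np.isfinite(v).all():
            raise ValueError("values contain NaN or Inf")
        if not self.fs > 0:
            raise ValueError("fs must be > 0")
        if self.labels is None:
            self.labels = tuple(f"ch{i + 1}" for i in range(v.shape[0]))
        else:
            self.labels = tuple(str(c) for c in self.labels)
            if len(self.labels) != v.shape[0]:
                raise ValueError("label count does not match channel count")
        self.values = v

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel(self, index: int = 0) -> np.ndarray:
        return self.values[index]

    def copy(self) -> "SampledSignal":
        return SampledSignal(self.values.copy(), self.fs, self.labels, self.t0)


def _check_strictly_increasing(idx: np.ndarray, what: str) -> None:
    if idx.size > 1 and not np.all(np.diff(idx) > 0):
        raise ValueError(f"{what} indices must be strictly increasing")


@dataclass
class GaitEventSeries:
    """Ordered foot-contact (FC) and foot-off (FO) sample indices.

    The merged sequence of events must strictly alternate between FC and FO
    (starting with either type).
    """

    foot_contacts: np.ndarray
    foot_offs: np.ndarray
    fs: float
    side: str = "right"

    def __post_init__(self) -> None:
        self.foot_contacts = np.asarray(self.foot_contacts, dtype=int)
        self.foot_offs = np.asarray(self.foot_offs, dtype=int)
        if not self.fs > 0:
            raise ValueError("fs must be > 0")
        if (self.foot_contacts < 0).any() or (self.foot_offs < 0).any():
            raise ValueError("event indices must be >= 0")
        _check_strictly_increasing(self.foot_contacts, "foot contact")
        _check_strictly_increasing(self.foot_offs, "foot off")
        idx, types = self.merged()
        for k in range(1, len(types)):
            if types[k] == types[k - 1]:
                raise ValueError(
                    "events must alternate FC/FO; found consecutive "
                    f"{types[k]} at samples {idx[k - 1]} and {idx[k]}"
                )

    def merged(self) -> tuple[np.ndarray, list[str]]:
        """Return all events sorted by sample index with their type labels."""
        pairs = [(int(i), "FC") for i in self.foot_contacts]
        pairs += [(int(i), "FO") for i in self.foot_offs]
        pairs.sort(key=lambda p: (p[0], p[1]))
        if not pairs:
            return np.empty(0, dtype=int), []
        idx, types = zip(*pairs)
        return np.asarray(idx, dtype=int), list(types)

    @property
    def n_events(self) -> int:
        return len(self.foot_contacts) + len(self.foot_offs)

    def times(self, which: str = "FC") -> np.ndarray:
        idx = self.foot_contacts if which == "FC" else self.foot_offs
        return idx / self.fs


@dataclass
class TrialRecord:
    """One walking or running trial with paired accelerometer and GRF data."""

    trial_id: str
    mode: str
    speed: float
    accel: SampledSignal
    grf: SampledSignal
    events: GaitEventSeries | None = None
    #: optional ground-truth events at the GRF sampling rate (synthetic data)
    events_grf_rate: GaitEventSeries | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("walking", "running"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.accel.n_channels != 3:
            raise ValueError("accel must have exactly 3 channels")
        if self.grf.n_channels != 1:
            raise ValueError("grf must have exactly 1 channel")
        if self.events is not None and np.isclose(self.events.fs, self.grf.fs):
            idx, _ = self.events.merged()
            if idx.size and idx.max() >= self.grf.n_samples:
                raise ValueError("event index beyond GRF length")


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_signal_table(path: str | Path, fs_override: float | None = None) -> SampledSignal:
    """Read a delimited signal table (first column: time in seconds).

    The sampling rate is inferred from the median time step unless
    ``fs_override`` is given. Jitter beyond 1% of the median step is logged
    as a warning; beyond 10% the file is rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected a time column plus >= 1 channel")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"{path}: non-numeric value in column {col!r} at data row {row}")
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0])
            raise ValueError(f"{path}: missing value in column {col!r} at data row {row}")
        df[col] = numeric
    t = df.iloc[:, 0].to_numpy(dtype=float)
    values = df.iloc[:, 1:].to_numpy(dtype=float).T
    if t.size > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError(f"{path}: non-monotonic time")
        med = float(np.median(dt))
        jitter = float(np.max(np.abs(dt - med)) / med)
        if jitter > JITTER_ERROR:
            raise ValueError(f"{path}: time-step jitter {jitter:.1%} exceeds {JITTER_ERROR:.0%}")
        if jitter > JITTER_WARN:
            logger.warning("%s: time-step jitter %.2f%% exceeds 1%%", path, 100 * jitter)
        fs = 1.0 / med
    else:
        if fs_override is None:
            raise ValueError(f"{path}: cannot infer fs from a single row")
        fs = fs_override
    if fs_override is not None:
        fs = float(fs_override)
    labels = tuple(df.columns[1:])
    return SampledSignal(values, fs=fs, labels=labels, t0=float(t[0]))


def write_signal_table(signal: SampledSignal, path: str | Path, sep: str = ",") -> None:
    """Write a signal as a delimited table with a reconstructed time column."""
    if signal.n_channels == 0:  # pragma: no cover - constructor forbids this
        raise ValueError("no channels")
    path = Path(path)
    df = pd.DataFrame({"time_s": signal.times})
    for label, row in zip(signal.labels, signal.values):
        df[label] = row
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_event_table(path: str | Path) -> GaitEventSeries:
    """Read an event table with columns ``event_type,sample_index,time_s``."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    required = {"event_type", "sample_index", "time_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    types = df["event_type"].astype(str).str.upper()
    unknown = sorted(set(types) - {"FC", "FO"})
    if unknown:
        raise ValueError(f"{path}: unknown event types {unknown}")
    idx = df["sample_index"].to_numpy(dtype=int)
    times = df["time_s"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = idx[idx > 0] / times[idx > 0]
    fs = float(np.median(rates)) if rates.size else ACCEL_FS
    fc = idx[types.to_numpy() == "FC"]
    fo = idx[types.to_numpy() == "FO"]
    return GaitEventSeries(np.sort(fc), np.sort(fo), fs=fs)


def write_event_table(events: GaitEventSeries, path: str | Path, sep: str = ",") -> None:
    idx, types = events.merged()
    df = pd.DataFrame(
        {
            "event_type": types,
            "sample_index": idx,
            "time_s": idx / events.fs,
        }
    )
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# trial manifests
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ("trial_id", "mode", "speed_mps", "accel_path", "grf_path", "events_path")


def write_trials(trials: Iterable[TrialRecord], directory: str | Path) -> Path:
    """Write a cohort of trials plus a ``manifest.csv`` into ``directory``.

    Returns the manifest path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for trial in trials:
        accel_path = directory / f"{trial.trial_id}_accel.csv"
        grf_path = directory / f"{trial.trial_id}_grf.csv"
        write_signal_table(trial.accel, accel_path)
        write_signal_table(trial.grf, grf_path)
        events_path = ""
        if trial.events is not None:
            events_path = f"{trial.trial_id}_events.csv"
            write_event_table(trial.events, directory / events_path)
        rows.append(
            {
                "trial_id": trial.trial_id,
                "mode": trial.mode,
                "speed_mps": trial.speed,
                "accel_path": accel_path.name,
                "grf_path": grf_path.name,
                "events_path": events_path,
            }
        )
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(manifest, index=False)
    return manifest


def read_trials(manifest: str | Path) -> list[TrialRecord]:
    """Load all trials referenced by a manifest file."""
    manifest = Path(manifest)
    base = manifest.parent
    df = pd.read_csv(manifest, dtype={"events_path": str}, keep_default_na=False)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{manifest}: missing manifest columns {sorted(missing)}")
    trials = []
    for _, row in df.iterrows():
        accel = read_signal_table(base / row["accel_path"])
        grf = read_signal_table(base / row["grf_path"])
        events = None
        if row["events_path"]:
            events = read_event_table(base / row["events_path"])
        trials.append(
            TrialRecord(
                trial_id=str(row["trial_id"]),
                mode=str(row["mode"]),
                speed=float(row["speed_mps"]),
                accel=accel,
                grf=grf,
                events=events,
            )
        )
    return trials
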
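"""Segmentation and baseline features for multichannel sensor streams.

Raw streams (time x channels, one activity label per sample, optional binary
attribute labels) are cut into fixed-length windows with fractional overlap
(64 samples, 50% overlap by default — a standard segmentation for ~30 Hz
body-worn accelerometers), standardized per channel with training-set
statistics, and summarized by per-channel means for the statistical
baseline.

Delimited-text I/O uses the column schema
``subject_id, timestamp_or_index, activity, attr_0..attr_{A-1}, ch_0..ch_{C-1}``;
within a subject, a non-consecutive ``timestamp_or_index`` starts a new
stream (gaps split streams).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SensorStream",
    "SensorWindow",
    "ChannelStats",
    "sliding_window",
    "standardize",
    "statistical_features",
    "statistical_feature_matrix",
    "concat_features",
    "flatten_windows",
    "window_labels",
    "window_subjects",
    "window_attributes",
    "read_sensor_table",
    "windows_from_table",
]

DEFAULT_WINDOW_LEN = 64
DEFAULT_OVERLAP = 0.5


@dataclass
class SensorStream:
    """A gap-free multichannel recording from one subject."""

    samples: np.ndarray  # (time, channels)
    subject_id: str
    activity: np.ndarray  # per-sample labels, length time
    attributes: np.ndarray | None = None  # (time, n_attributes) binary
    sampling_rate: float = 30.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.activity = np.asarray(self.activity)
        if self.activity.shape[0] != self.samples.shape[0]:
            raise ValueError("one activity label per sample is required")
        if self.attributes is not None:
            self.attributes = np.atleast_2d(np.asarray(self.attributes, dtype=float))
            if self.attributes.shape[0] != self.samples.shape[0]:
                raise ValueError("one attribute row per sample is required")

    def __len__(self) -> int:
        return self.samples.shape[0]


@dataclass
class SensorWindow:
    """One fixed-length segment: the classification instance."""

    samples: np.ndarray  # (window_len, channels)
    subject_id: str
    activity: object
    attributes: np.ndarray | None = None
    start: int = 0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.attributes is not None:
            self.attributes = np.asarray(self.attributes, dtype=float)


@dataclass
class ChannelStats:
    mean: np.ndarray
    sd: np.ndarray


def _majority(values: np.ndarray, first):
    """Majority vote; ties resolved by the value at the window's first sample."""
    counts = Counter(values.tolist())
    top = max(counts.values())
    winners = [v for v, c in counts.items() if c == top]
    if len(winners) == 1:
        return winners[0]
    return first


def sliding_window(
    stream: SensorStream,
    window_len: int = DEFAULT_WINDOW_LEN,
    overlap_fraction: float = DEFAULT_OVERLAP,
) -> list[SensorWindow]:
    """Cut a stream into half-open windows ``[start, start + window_len)``.

    The step is ``round(window_len * (1 - overlap_fraction))`` samples and
    starts run 0, step, 2*step, ...; a stream shorter than one window yields
    no windows.  Window labels and attribute bits are majority votes over
    the covered samples, ties going to the first sample's value.
    """
    if window_len < 2:
        raise ValueError("window_len must be >= 2")
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1)")
    step = int(round(window_len * (1.0 - overlap_fraction)))
    if step <= 0:
        raise ValueError("window step rounds to zero; reduce the overlap")
    L = len(stream)
    windows: list[SensorWindow] = []
    for start in range(0, L - window_len + 1, step):
        stop = start + window_len
        labels = stream.activity[start:stop]
        label = _majority(labels, labels[0])
        attrs = None
        if stream.attributes is not None:
            block = stream.attributes[start:stop]
            frac = block.mean(axis=0)
            attrs = np.where(frac > 0.5, 1.0, 0.0)
            ties = np.isclose(frac, 0.5)
            attrs[ties] = block[0, ties]
        windows.append(
            SensorWindow(
                stream.samples[start:stop].copy(),
                stream.subject_id,
                label,
                attrs,
                start,
            )
        )
    return windows


def standardize(
    windows: list[SensorWindow], stats: ChannelStats | None = None
) -> tuple[list[SensorWindow], ChannelStats]:
    """Per-channel z-scoring of window samples.

    When ``stats`` is None the mean and sd are computed from the given
    windows (the training set) and returned for verbatim reuse on test data.
    Constant channels get sd clamped to 1 (with a warning) so they map to 0.
    """
    if not windows:
        raise ValueError("no windows to standardize")
    if stats is None:
        stacked = np.concatenate([w.samples for w in windows], axis=0)
        mean = stacked.mean(axis=0)
        sd = stacked.std(axis=0)
        degenerate = sd < 1e-12
        if degenerate.any():
            warnings.warn("zero-variance channel(s); sd clamped to 1")
            sd = np.where(degenerate, 1.0, sd)
        stats = ChannelStats(mean, sd)
    out = [
        SensorWindow(
            (w.samples - stats.mean) / stats.sd,
            w.subject_id,
            w.activity,
            None if w.attributes is None else w.attributes.copy(),
            w.start,
        )
        for w in windows
    ]
    return out, stats


def statistical_features(window: SensorWindow, extras: bool = False) -> np.ndarray:
    """Per-channel mean of the window; optionally append sd and mean energy."""
    mean = window.samples.mean(axis=0)
    if not extras:
        return mean
    sd = window.samples.std(axis=0)
    energy = np.mean(window.samples**2, axis=0)
    return np.concatenate([mean, sd, energy])


def statistical_feature_matrix(windows: list[SensorWindow], extras: bool = False) -> np.ndarray:
    return np.stack([statistical_features(w, extras) for w in windows])


def concat_features(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise concatenation of two feature matrices, ``a`` first."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[0] != b.shape[0]:
        raise ValueError(f"row counts differ: {a.shape[0]} vs {b.shape[0]}")
    return np.hstack([a, b])


def flatten_windows(windows: list[SensorWindow]) -> np.ndarray:
    """Channel-major flattening: (n_windows, channels * window_len)."""
    return np.stack([w.samples.T.ravel() for w in windows])


def window_labels(windows: list[SensorWindow]) -> np.ndarray:
    return np.array([w.activity for w in windows])


def window_subjects(windows: list[SensorWindow]) -> np.ndarray:
    return np.array([w.subject_id for w in windows])


def window_attributes(windows: list[SensorWindow]) -> np.ndarray:
    if any(w.attributes is None for w in windows):
        raise ValueError("windows carry no attribute labels")
    return np.stack([w.attributes for w in windows])


def read_sensor_table(path: str | Path) -> list[SensorStream]:
    """Read streams from the delimited schema; index gaps split streams."""
    df = pd.read_csv(path)
    required = {"subject_id", "timestamp_or_index", "activity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns in {path}: {sorted(missing)}")
    ch_cols = sorted(
        (c for c in df.columns if c.startswith("ch_")), key=lambda c: int(c[3:])
    )
    attr_cols = sorted(
        (c for c in df.columns if c.startswith("attr_")), key=lambda c: int(c[5:])
    )
    if not ch_cols:
        raise ValueError("no channel columns (ch_*) found")
    streams: list[SensorStream] = []
    for subject, group in df.groupby("subject_id", sort=True):
        idx = group["timestamp_or_index"].to_numpy()
        breaks = np.flatnonzero(np.diff(idx) != 1) + 1
        for chunk in np.split(np.arange(len(group)), breaks):
            sub = group.iloc[chunk]
            streams.append(
                SensorStream(
                    samples=sub[ch_cols].to_numpy(dtype=float),
                    subject_id=str(subject),
                    activity=sub["activity"].to_numpy(),
                    attributes=sub[attr_cols].to_numpy(dtype=float) if attr_cols else None,
                )
            )
    return streams


def windows_from_table(
    path: str | Path,
    window_len: int = DEFAULT_WINDOW_LEN,
    overlap_fraction: float = DEFAULT_OVERLAP,
) -> list[SensorWindow]:
    """Read streams from disk and segment them in one step."""
    windows: list[SensorWindow] = []
    for stream in read_sensor_table(path):
        windows.extend(sliding_window(stream, window_len, overlap_fraction))
    return windows
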
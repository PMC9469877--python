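"""Synthetic multi-subject wearable-sensor benchmark with latent attributes.

The generator emulates the structure of a multi-subject exercise-activity
recording: several subjects each perform ~10 activities, every activity is a
binary combination of 1-3 latent semantic attributes (movement primitives),
and each attribute expresses itself as a smooth multichannel waveform
signature.  A window is the sum of its activity's attribute signatures,
scaled by per-subject channel gains (the cross-subject distribution shift)
plus white Gaussian noise:

    window[t, c] = gain[subject, c] * sum_{a active} sig_a[t, c] + eps,
    eps ~ N(0, noise_sd^2),  gain[s, c] ~ N(1, subject_gain_sd^2).

Signatures combine a per-channel DC offset with two random-phase sinusoids
at attribute-specific integer frequencies, so different attributes are
near-orthogonal: the offsets make the per-channel window means (the
statistical baseline features) partially informative, while the oscillatory
structure is only visible to methods that use the full waveform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import SensorWindow

__all__ = ["SyntheticSpec", "GroundTruth", "generate_signatures", "generate_dataset", "export"]


def _random_activity_matrix(
    n_activities: int, n_attributes: int, rng: np.random.Generator
) -> np.ndarray:
    """Binary (activities x attributes) matrix: each activity uses 1-3
    attributes, rows are unique, every attribute is used at least once."""
    for _ in range(1000):
        rows = set()
        mat = np.zeros((n_activities, n_attributes))
        ok = True
        for i in range(n_activities):
            for _ in range(200):
                k = rng.integers(1, min(3, n_attributes) + 1)
                idx = tuple(sorted(rng.choice(n_attributes, size=k, replace=False)))
                if idx not in rows:
                    rows.add(idx)
                    mat[i, list(idx)] = 1.0
                    break
            else:
                ok = False
                break
        if ok and mat.sum(axis=0).min() > 0:
            return mat
    raise RuntimeError("could not build a valid activity-attribute matrix")


@dataclass
class SyntheticSpec:
    """Generator settings (defaults sized for desk-scale full-LOSO runs)."""

    n_subjects: int = 8
    n_activities: int = 10
    n_attributes: int = 8
    activity_attribute_matrix: np.ndarray | None = None
    channels: int = 9  # three tri-axial devices
    window_len: int = 64
    windows_per_activity_per_subject: int = 20
    noise_sd: float = 1.2
    subject_gain_sd: float = 0.25
    #: Spread of the per-channel DC offsets of each attribute signature.
    dc_sd: float = 0.15
    #: Amplitude spread of the sinusoidal components.
    ac_sd: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_activities, self.n_attributes, self.channels) < 1:
            raise ValueError("counts must be positive")
        if self.window_len < 4:
            raise ValueError("window_len must be >= 4")
        if self.activity_attribute_matrix is None:
            rng = np.random.default_rng(self.seed)
            self.activity_attribute_matrix = _random_activity_matrix(
                self.n_activities, self.n_attributes, rng
            )
        self.activity_attribute_matrix = np.asarray(
            self.activity_attribute_matrix, dtype=float
        )
        mat = self.activity_attribute_matrix
        if mat.shape != (self.n_activities, self.n_attributes):
            raise ValueError("activity_attribute_matrix has the wrong shape")
        if mat.sum(axis=1).min() < 1:
            raise ValueError("every activity needs at least one attribute")
        if mat.sum(axis=0).min() < 1:
            raise ValueError("every attribute must be used by some activity")
        if len({tuple(row) for row in mat.astype(int).tolist()}) < self.n_activities:
            raise ValueError("duplicate activity rows")


@dataclass
class GroundTruth:
    """Everything the generator knows that a learner should recover."""

    attributes: np.ndarray  # (n_windows, n_attributes)
    signatures: np.ndarray  # (n_attributes, window_len, channels)
    gains: np.ndarray  # (n_subjects, channels)
    activity_attribute_matrix: np.ndarray
    activities: np.ndarray  # per-window activity label
    subjects: np.ndarray  # per-window subject id


def generate_signatures(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-attribute multichannel waveforms, shape (A, window_len, channels).

    Attribute ``a`` mixes sinusoids at the integer frequencies ``3 + a`` and
    ``3 + a + n_attributes`` (cycles per window) with random per-channel
    phases and amplitudes, on top of per-channel DC offsets.  Distinct
    integer frequencies are orthogonal over the window, so cross-attribute
    similarity comes only from the offsets; generation retries (up to 100
    times) until all pairwise normalized inner products are below 0.3.
    """
    A, L, C = spec.n_attributes, spec.window_len, spec.channels
    if 3 + 2 * A >= L // 2:
        raise ValueError("too many attributes for this window length")
    t = np.arange(L)
    for _ in range(100):
        sigs = np.zeros((A, L, C))
        for a in range(A):
            dc = rng.normal(0.0, spec.dc_sd, size=C)
            sigs[a] += dc[None, :]
            for f in (3 + a, 3 + a + A):
                amp = rng.normal(0.0, spec.ac_sd, size=C)
                phase = rng.uniform(0.0, 2 * np.pi, size=C)
                sigs[a] += amp[None, :] * np.sin(
                    2 * np.pi * f * t[:, None] / L + phase[None, :]
                )
        flat = sigs.reshape(A, -1)
        norms = np.linalg.norm(flat, axis=1)
        gram = np.abs(flat @ flat.T) / np.outer(norms, norms)
        np.fill_diagonal(gram, 0.0)
        if gram.max() < 0.3:
            return sigs
    raise RuntimeError("signature orthogonality unattainable after 100 retries")


def generate_dataset(
    spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[list[SensorWindow], GroundTruth]:
    """Draw the full benchmark: one window list plus its ground truth.

    Total windows = n_subjects * n_activities * windows_per_activity_per_subject.
    """
    signatures = generate_signatures(spec, rng)
    gains = rng.normal(1.0, spec.subject_gain_sd, size=(spec.n_subjects, spec.channels))
    mat = spec.activity_attribute_matrix
    windows: list[SensorWindow] = []
    attr_rows, act_rows, subj_rows = [], [], []
    for s in range(spec.n_subjects):
        subject = f"subj{s:02d}"
        for a in range(spec.n_activities):
            base = np.tensordot(mat[a], signatures, axes=(0, 0))  # (L, C)
            shifted = base * gains[s][None, :]
            for _ in range(spec.windows_per_activity_per_subject):
                noise = rng.normal(0.0, spec.noise_sd, size=shifted.shape)
                windows.append(
                    SensorWindow(
                        shifted + noise,
                        subject_id=subject,
                        activity=f"act{a:02d}",
                        attributes=mat[a].copy(),
                    )
                )
                attr_rows.append(mat[a])
                act_rows.append(f"act{a:02d}")
                subj_rows.append(subject)
    truth = GroundTruth(
        attributes=np.array(attr_rows),
        signatures=signatures,
        gains=gains,
        activity_attribute_matrix=mat.copy(),
        activities=np.array(act_rows),
        subjects=np.array(subj_rows),
    )
    return windows, truth


def export(windows: list[SensorWindow], ground_truth: GroundTruth, path: str | Path) -> dict:
    """Write the dataset as delimited text under ``path``.

    ``data.csv`` holds one row per sample in the standard stream schema
    (``subject_id, timestamp_or_index, activity, attr_*, ch_*``); the sample
    index restarts at 0 for every window, so the reader splits each window
    into its own stream and the set round-trips losslessly.
    ``attributes.csv`` holds the per-window ground-truth attribute vectors.
    Returns the paths written.
    """
    path = Path(path)
    try:
        path.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {path}: {exc}") from exc
    n_attr = ground_truth.attributes.shape[1]
    frames = []
    for w in windows:
        L, C = w.samples.shape
        rec = {
            "subject_id": np.repeat(w.subject_id, L),
            "timestamp_or_index": np.arange(L),
            "activity": np.repeat(w.activity, L),
        }
        for a in range(n_attr):
            rec[f"attr_{a}"] = np.repeat(
                0.0 if w.attributes is None else w.attributes[a], L
            )
        for c in range(C):
            rec[f"ch_{c}"] = w.samples[:, c]
        frames.append(pd.DataFrame(rec))
    data_path = path / "data.csv"
    pd.concat(frames, ignore_index=True).to_csv(data_path, index=False, float_format="%.10g")
    attr_df = pd.DataFrame(
        ground_truth.attributes, columns=[f"attr_{a}" for a in range(n_attr)]
    )
    attr_df.insert(0, "activity", ground_truth.activities)
    attr_df.insert(0, "subject_id", ground_truth.subjects)
    attr_path = path / "attributes.csv"
    attr_df.to_csv(attr_path, index=False)
    return {"data": data_path, "attributes": attr_path}
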
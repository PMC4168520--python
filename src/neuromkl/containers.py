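"""In-memory containers and text-based I/O for epoched EEG and features.

EEG epochs travel as a 3-D array (trials x channels x samples) with a
sampling rate, channel labels and per-trial class labels (plus optional
subject ids for grouped cross-validation).  On disk an ``EpochedEEG`` is
a single CSV of stacked trial-by-channel rows (one row per (trial,
channel), one column per sample) next to a JSON metadata sidecar holding
the shape, sampling rate, labels and channel names.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["EpochedEEG", "FeatureMatrix", "CVResult", "save_eeg", "load_eeg",
           "save_features", "load_features"]


@dataclass
class EpochedEEG:
    """Trials of multichannel EEG with sampling rate and labels."""

    data: np.ndarray  # (n_trials, n_channels, n_samples)
    fs: float
    channels: list[str]
    labels: np.ndarray
    subjects: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be 3-D (trials, channels, samples), got {self.data.shape}"
            )
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        self.channels = [str(c).upper() for c in self.channels]
        if len(self.channels) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channels)} channel labels for {self.data.shape[1]} channels"
            )
        self.labels = np.asarray(self.labels)
        if self.labels.shape[0] != self.data.shape[0]:
            raise ValueError("label count does not match trial count")
        if self.subjects is not None:
            self.subjects = np.asarray(self.subjects)
            if self.subjects.shape[0] != self.data.shape[0]:
                raise ValueError("subject-id count does not match trial count")
        if np.isnan(self.data).any():
            t, c, _ = np.argwhere(np.isnan(self.data))[0]
            raise ValueError(f"NaN in trial {t}, channel {self.channels[c]}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def channel_index(self, name: str) -> int:
        name = name.upper()
        if name not in self.channels:
            raise KeyError(f"channel {name!r} not present (have {self.channels})")
        return self.channels.index(name)


@dataclass
class FeatureMatrix:
    """n_trials x n_features table with labels and provenance."""

    values: np.ndarray
    columns: list[str]
    labels: np.ndarray
    subjects: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-D")
        if len(self.columns) != self.values.shape[1]:
            raise ValueError("column-name count does not match feature count")
        self.labels = np.asarray(self.labels)
        if self.labels.shape[0] != self.values.shape[0]:
            raise ValueError("label count does not match row count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.columns)
        df.insert(0, "label", self.labels)
        if self.subjects is not None:
            df.insert(1, "subject", self.subjects)
        return df


@dataclass
class CVResult:
    """Cross-validation outcome: per-fold accuracies and confusions."""

    fold_accuracies: list[float]
    mean_accuracy: float
    confusion: pd.DataFrame
    seed: int
    settings: dict = field(default_factory=dict)
    kernel_weights: list = field(default_factory=list)


def save_eeg(epochs: EpochedEEG, data_path: str | Path, meta_path: str | Path) -> None:
    """Write stacked-CSV data plus JSON sidecar."""
    n_t, n_c, n_s = epochs.data.shape
    flat = epochs.data.reshape(n_t * n_c, n_s)
    pd.DataFrame(flat).to_csv(data_path, index=False, header=False,
                              float_format="%.17g")
    meta = {
        "n_trials": n_t,
        "n_channels": n_c,
        "n_samples": n_s,
        "fs": epochs.fs,
        "channels": epochs.channels,
        "labels": [_js(v) for v in epochs.labels],
    }
    if epochs.subjects is not None:
        meta["subjects"] = [_js(v) for v in epochs.subjects]
    Path(meta_path).write_text(json.dumps(meta))


def _js(v):
    if isinstance(v, np.integer):
        return int(v)
    if isinstance(v, np.floating):
        return float(v)
    return str(v) if not isinstance(v, (int, float, str)) else v


def load_eeg(data_path: str | Path, meta_path: str | Path) -> EpochedEEG:
    """Load and validate a stacked-CSV + sidecar pair."""
    meta_path = Path(meta_path)
    if not Path(data_path).exists():
        raise FileNotFoundError(data_path)
    if not meta_path.exists():
        raise FileNotFoundError(meta_path)
    meta = json.loads(meta_path.read_text())
    for key in ("n_trials", "n_channels", "n_samples", "fs", "channels", "labels"):
        if key not in meta:
            raise ValueError(f"metadata missing required key {key!r}")
    flat = pd.read_csv(data_path, header=None,
                       float_precision="round_trip").to_numpy(dtype=float)
    n_t, n_c, n_s = meta["n_trials"], meta["n_channels"], meta["n_samples"]
    if flat.shape != (n_t * n_c, n_s):
        raise ValueError(
            f"data shape {flat.shape} inconsistent with declared "
            f"{n_t} trials x {n_c} channels x {n_s} samples"
        )
    if len(meta["channels"]) != n_c:
        raise ValueError(
            f"metadata declares {len(meta['channels'])} channel names for {n_c} channels"
        )
    return EpochedEEG(
        data=flat.reshape(n_t, n_c, n_s),
        fs=float(meta["fs"]),
        channels=meta["channels"],
        labels=np.asarray(meta["labels"]),
        subjects=np.asarray(meta["subjects"]) if "subjects" in meta else None,
    )


def save_features(features: FeatureMatrix, path: str | Path) -> None:
    features.to_frame().to_csv(path, index=False)


def load_features(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path)
    labels = df.pop("label").to_numpy()
    subjects = df.pop("subject").to_numpy() if "subject" in df.columns else None
    return FeatureMatrix(
        values=df.to_numpy(dtype=float),
        columns=list(df.columns),
        labels=labels,
        subjects=subjects,
    )
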
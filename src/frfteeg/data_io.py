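"""Reading, writing and segmenting EEG recordings and feature matrices.

Two plain-text formats are supported:

* the UCI EEG-database trial format ('.rd'-style): '#'-prefixed comment
  lines followed by whitespace-delimited data rows
  ``trial channel-label sample-index value`` with voltages in microvolts at
  256 Hz;
* CSV feature matrices with header ``F1,...,F34,label``.

Recordings are segmented into consecutive non-overlapping epochs (default
2048 samples = 8 s at 256 Hz) and epochs whose absolute amplitude exceeds
the movement-artifact threshold (73.3 uV) are flagged for exclusion.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, FeatureMatrix

__all__ = [
    "ClassLabel",
    "RawRecording",
    "Epoch",
    "DEFAULT_FS",
    "DEFAULT_EPOCH_LEN",
    "ARTIFACT_THRESHOLD_UV",
    "read_uci_trial",
    "write_uci_trial",
    "segment",
    "flag_artifacts",
    "clean_epochs",
    "write_feature_matrix",
    "read_feature_matrix",
]

DEFAULT_FS = 256.0
DEFAULT_EPOCH_LEN = 2048
#: Movement/blink artifact amplitude threshold in microvolts.
ARTIFACT_THRESHOLD_UV = 73.3


class ClassLabel(str, enum.Enum):
    NORMAL = "normal"
    ALCOHOLIC = "alcoholic"
    UNKNOWN = "unknown"


@dataclass
class RawRecording:
    """Multichannel voltage recording in microvolts."""

    samples: np.ndarray  # (channels, time)
    channel_labels: list[str]
    fs: float = DEFAULT_FS
    subject_class: ClassLabel = ClassLabel.UNKNOWN

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("one label per channel required")
        if np.isnan(self.samples).any():
            raise ValueError("recording contains NaN samples")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass
class Epoch:
    """A fixed-length single-channel segment with its class label."""

    samples: np.ndarray
    channel: str
    label: ClassLabel
    artifact_flag: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()

    def __len__(self) -> int:
        return len(self.samples)


def _class_from_tokens(text: str) -> ClassLabel:
    # UCI subject ids: co2a/co3a... = alcoholic, co2c/co3c... = control
    for tok in text.replace("#", " ").split():
        low = tok.lower()
        if low.startswith("co") and len(low) >= 4:
            if low[3] == "a":
                return ClassLabel.ALCOHOLIC
            if low[3] == "c":
                return ClassLabel.NORMAL
    return ClassLabel.UNKNOWN


def read_uci_trial(path) -> RawRecording:
    """Parse a UCI-style plaintext trial file into a recording.

    Data rows are ``trial channel-label sample-index value``; '#' lines are
    comments (scanned for a co*a/co*c subject id to set the class label).
    Channels appear in first-occurrence order; within a channel, samples are
    ordered by sample index.

    Raises
    ------
    ValueError
        On malformed rows (with the line number), duplicate
        (channel, index) pairs, missing indices, or a file with no data.
    """
    path = Path(path)
    per_channel: dict[str, dict[int, float]] = {}
    order: list[str] = []
    subject_class = ClassLabel.UNKNOWN

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if subject_class is ClassLabel.UNKNOWN:
                    subject_class = _class_from_tokens(line)
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(
                    f"{path.name}:{lineno}: expected 4 fields "
                    f"(trial channel index value), got {len(parts)}"
                )
            _, chan, idx_s, val_s = parts
            try:
                idx = int(idx_s)
                val = float(val_s)
            except ValueError as exc:
                raise ValueError(f"{path.name}:{lineno}: malformed row: {exc}") from exc
            if not math.isfinite(val):
                raise ValueError(f"{path.name}:{lineno}: non-finite voltage")
            bucket = per_channel.setdefault(chan, {})
            if chan not in order:
                order.append(chan)
            if idx in bucket:
                raise ValueError(
                    f"{path.name}:{lineno}: duplicate sample ({chan}, {idx})"
                )
            bucket[idx] = val

    if not per_channel:
        raise ValueError(f"{path.name}: no data rows")

    lengths = {len(v) for v in per_channel.values()}
    if len(lengths) != 1:
        raise ValueError(f"{path.name}: channels have unequal sample counts")
    n = lengths.pop()
    mat = np.empty((len(order), n))
    for row, chan in enumerate(order):
        bucket = per_channel[chan]
        if sorted(bucket) != list(range(n)):
            raise ValueError(f"{path.name}: channel {chan} has missing sample indices")
        mat[row] = [bucket[i] for i in range(n)]
    return RawRecording(samples=mat, channel_labels=order, subject_class=subject_class)


def write_uci_trial(recording: RawRecording, path, trial: int = 0) -> None:
    """Write a recording in the UCI-style plaintext trial format."""
    subject = {
        ClassLabel.ALCOHOLIC: "co2a0000000",
        ClassLabel.NORMAL: "co2c0000000",
        ClassLabel.UNKNOWN: "unknown",
    }[recording.subject_class]
    lines = [
        f"# {subject} frfteeg export, fs={recording.fs:g} Hz",
        "# trial channel sample value",
    ]
    for chan, row in zip(recording.channel_labels, recording.samples):
        for i, v in enumerate(row):
            lines.append(f"{trial} {chan} {i} {v:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def segment(recording: RawRecording, epoch_len: int = DEFAULT_EPOCH_LEN) -> list[Epoch]:
    """Cut every channel into consecutive non-overlapping epochs.

    Windows are half-open ``[i*L, (i+1)*L)``; a trailing remainder shorter
    than ``epoch_len`` is dropped. A recording shorter than one epoch yields
    an empty list.
    """
    if epoch_len < 1:
        raise ValueError("epoch_len must be >= 1")
    n_epochs = recording.n_samples // epoch_len
    label = (
        recording.subject_class
        if recording.subject_class is not ClassLabel.UNKNOWN
        else ClassLabel.UNKNOWN
    )
    out: list[Epoch] = []
    for chan, row in zip(recording.channel_labels, recording.samples):
        for i in range(n_epochs):
            out.append(
                Epoch(
                    samples=row[i * epoch_len : (i + 1) * epoch_len].copy(),
                    channel=chan,
                    label=label,
                )
            )
    return out


def flag_artifacts(
    epochs: list[Epoch], threshold: float = ARTIFACT_THRESHOLD_UV
) -> list[Epoch]:
    """Return epochs with ``artifact_flag`` set iff max |sample| > threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return [
        replace(e, artifact_flag=bool(np.max(np.abs(e.samples)) > threshold))
        for e in epochs
    ]


def clean_epochs(epochs: list[Epoch]) -> list[Epoch]:
    """Filter view excluding artifact-flagged epochs."""
    return [e for e in epochs if not e.artifact_flag]


def write_feature_matrix(matrix: FeatureMatrix, path) -> None:
    """Write a feature matrix as CSV with header ``F1,...,F34,label``."""
    n = matrix.X.shape[1]
    if n != len(FEATURE_NAMES):
        raise ValueError(f"expected {len(FEATURE_NAMES)} feature columns, got {n}")
    df = pd.DataFrame(matrix.X, columns=[f"F{i + 1}" for i in range(n)])
    df["label"] = np.asarray(matrix.y)
    df.to_csv(path, index=False, float_format="%.12g")


def read_feature_matrix(path) -> FeatureMatrix:
    """Read a ``F1..F34,label`` CSV back into a :class:`FeatureMatrix`."""
    df = pd.read_csv(path)
    expected = [f"F{i + 1}" for i in range(len(FEATURE_NAMES))] + ["label"]
    got = list(df.columns)
    if got != expected:
        extra = [c for c in got if c not in expected]
        missing = [c for c in expected if c not in got]
        detail = []
        if extra:
            detail.append(f"unexpected column(s): {', '.join(extra)}")
        if missing:
            detail.append(f"missing column(s): {', '.join(missing)}")
        raise ValueError("feature CSV header mismatch — " + "; ".join(detail)
                         if detail else "feature CSV columns out of order")
    y = df.pop("label").to_numpy()
    return FeatureMatrix(X=df.to_numpy(dtype=float), y=y)
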
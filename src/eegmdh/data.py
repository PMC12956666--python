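"""Domain types and on-disk formats for epoched EEG trials.

A trial is a time × channels matrix of (normalized) microvolt samples with a
single motor-task label.  Datasets are described by a manifest CSV with columns
``file, subject_id, label``; each referenced file is a per-trial numeric CSV
whose rows are time points and whose columns are channels (an optional header
row carries electrode names).  The transposed layout is rejected rather than
auto-detected: unambiguous parsing beats convenience.

Users of the real MILimbEEG recordings should convert their download into this
layout; see :func:`milimbeeg_adapter_stub` for the expected shape of such an
adapter.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_CHANNEL_NAMES",
    "EEGTrial",
    "TaskVocabulary",
    "TrialDataset",
    "read_trial_csv",
    "write_trial_csv",
    "read_manifest",
    "write_manifest",
    "write_feature_table",
    "read_feature_table",
]

#: 16 dry-electrode montage (10–10 placement) used as the default channel set.
DEFAULT_CHANNEL_NAMES = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4",
    "O1", "O2", "F7", "F8", "T7", "T8", "P7", "P8",
)

#: The eight motor-task classes, in their canonical 1-based code order:
#: baseline eyes open, left/right hand closing, dorsal/plantar flexion of the
#: left and right foot, and inter-task rest.
DEFAULT_TASK_LABELS = ("BEO", "CLH", "CRH", "DLF", "PLF", "DRF", "PRF", "Rest")


@dataclass(frozen=True)
class TaskVocabulary:
    """Ordered class labels with contiguous 1-based numeric codes."""

    labels: tuple[str, ...] = DEFAULT_TASK_LABELS

    def __post_init__(self) -> None:
        if len(self.labels) < 1:
            raise ValueError("vocabulary must contain at least one label")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("vocabulary labels must be unique")

    @property
    def n_classes(self) -> int:
        return len(self.labels)

    def code_of(self, label: str) -> int:
        """1-based numeric code of ``label``; raises on unknown labels."""
        try:
            return self.labels.index(label) + 1
        except ValueError:
            raise KeyError(
                f"unknown task label {label!r}; expected one of {list(self.labels)}"
            ) from None

    def label_of(self, code: int) -> str:
        if not 1 <= code <= len(self.labels):
            raise KeyError(f"class code {code} outside 1..{len(self.labels)}")
        return self.labels[code - 1]

    def encode(self, labels: Sequence[str]) -> np.ndarray:
        return np.array([self.code_of(lab) for lab in labels], dtype=np.int64)


@dataclass
class EEGTrial:
    """One epoched multichannel recording with its task label.

    ``samples`` has shape (time points, channels); ``channel_names`` fixes the
    column order.  At the study defaults there are 16 channels sampled at
    125 Hz, but any channel count >= 1 and length >= 2 is accepted so small
    fixtures stay cheap.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_names: tuple[str, ...] = DEFAULT_CHANNEL_NAMES
    label: str = "BEO"
    subject_id: str = "S00"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.channel_names = tuple(self.channel_names)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D time × channels matrix")
        if self.samples.shape[0] < 2:
            raise ValueError("a trial needs at least 2 time points")
        if self.samples.shape[1] != len(self.channel_names):
            raise ValueError(
                f"samples has {self.samples.shape[1]} columns but "
                f"{len(self.channel_names)} channel names were given"
            )
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]


@dataclass
class TrialDataset:
    """An ordered collection of trials sharing a sampling rate and montage."""

    trials: list[EEGTrial]
    vocabulary: TaskVocabulary = field(default_factory=TaskVocabulary)

    def __post_init__(self) -> None:
        if self.trials:
            fs = self.trials[0].sampling_rate
            nch = self.trials[0].n_channels
            for i, t in enumerate(self.trials):
                if t.sampling_rate != fs:
                    raise ValueError(f"trial {i} has sampling rate {t.sampling_rate}, expected {fs}")
                if t.n_channels != nch:
                    raise ValueError(f"trial {i} has {t.n_channels} channels, expected {nch}")
                # membership check doubles as label validation
                self.vocabulary.code_of(t.label)

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def labels(self) -> list[str]:
        return [t.label for t in self.trials]

    def class_supports(self) -> dict[str, int]:
        supports = {lab: 0 for lab in self.vocabulary.labels}
        for t in self.trials:
            supports[t.label] += 1
        return supports

    def encoded_labels(self) -> np.ndarray:
        return self.vocabulary.encode(self.labels)


def _parse_numeric_rows(rows: list[list[str]], path: Path) -> tuple[np.ndarray, tuple[str, ...] | None]:
    """Parse CSV rows into a float matrix, detecting an optional header."""
    if not rows:
        raise ValueError(f"{path}: empty trial file")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"{path}: ragged rows (row lengths {sorted(widths)})")

    header: tuple[str, ...] | None = None

    def _is_numeric(cell: str) -> bool:
        try:
            float(cell)
            return True
        except ValueError:
            return False

    if not all(_is_numeric(c) for c in rows[0]):
        header = tuple(c.strip() for c in rows[0])
        rows = rows[1:]

    try:
        matrix = np.array([[float(c) for c in r] for r in rows], dtype=np.float64)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell in trial body ({exc})") from None
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError(f"{path}: trial must have at least 2 time points")
    return matrix, header


def read_trial_csv(
    path: str | Path,
    sampling_rate: float,
    label: str = "BEO",
    subject_id: str = "S00",
) -> EEGTrial:
    """Read one trial from a numeric CSV (rows = time, columns = channels)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r]
    matrix, header = _parse_numeric_rows(rows, path)
    names = header if header is not None else tuple(f"ch{i}" for i in range(matrix.shape[1]))
    return EEGTrial(matrix, sampling_rate, names, label=label, subject_id=subject_id)


def write_trial_csv(trial: EEGTrial, path: str | Path) -> None:
    """Write one trial as a headered numeric CSV (inverse of read_trial_csv)."""
    df = pd.DataFrame(trial.samples, columns=list(trial.channel_names))
    df.to_csv(path, index=False)


def read_manifest(path: str | Path, sampling_rate: float = 125.0,
                  vocabulary: TaskVocabulary | None = None) -> TrialDataset:
    """Load a dataset from a manifest CSV with columns (file, subject_id, label).

    File paths are resolved relative to the manifest's directory.
    """
    path = Path(path)
    manifest = pd.read_csv(path, dtype=str)
    required = {"file", "subject_id", "label"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    if manifest["file"].duplicated().any():
        dupes = manifest.loc[manifest["file"].duplicated(), "file"].tolist()
        raise ValueError(f"duplicate file entries in manifest: {dupes}")
    vocab = vocabulary or TaskVocabulary()
    trials = []
    for row in manifest.itertuples(index=False):
        vocab.code_of(row.label)  # fail fast on unknown labels
        trials.append(
            read_trial_csv(path.parent / row.file, sampling_rate,
                           label=row.label, subject_id=row.subject_id)
        )
    return TrialDataset(trials, vocab)


def write_manifest(dataset: TrialDataset, directory: str | Path,
                   manifest_name: str = "manifest.csv") -> Path:
    """Write every trial as a CSV plus a manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records = []
    for i, trial in enumerate(dataset.trials):
        fname = f"trial_{i:04d}_{trial.subject_id}_{trial.label}.csv"
        write_trial_csv(trial, directory / fname)
        records.append({"file": fname, "subject_id": trial.subject_id, "label": trial.label})
    manifest_path = directory / manifest_name
    pd.DataFrame(records).to_csv(manifest_path, index=False)
    return manifest_path


def write_feature_table(
    features: Sequence[np.ndarray],
    labels: Sequence[str],
    path: str | Path,
    column_names: Sequence[str] | None = None,
) -> None:
    """Write one row per trial: feature columns then a final ``label`` column.

    Values are written with ``repr`` round-trip precision so read-back is
    bit-identical for any float64.
    """
    features = [np.asarray(v, dtype=np.float64) for v in features]
    if len(features) != len(labels):
        raise ValueError(f"{len(features)} feature vectors but {len(labels)} labels")
    if features and len({v.shape for v in features}) != 1:
        raise ValueError("feature vectors have inconsistent lengths")
    width = features[0].size if features else 0
    if column_names is None:
        column_names = [f"f{i}" for i in range(width)]
    if len(column_names) != width:
        raise ValueError("column_names length must match feature width")
    matrix = np.vstack(features) if features else np.empty((0, width))
    # repr is Python's shortest-round-trip float form, so write→read is
    # bit-for-bit lossless (pandas' own CSV float formatter is not)
    cells = [[repr(float(v)) for v in row] for row in matrix]
    df = pd.DataFrame(cells, columns=list(column_names), dtype=object)
    df["label"] = list(labels)
    df.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a feature table; returns (matrix, labels, feature column names)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "label" not in df.columns:
        raise ValueError("feature table must have a final 'label' column")
    labels = df["label"].astype(str).tolist()
    feat = df.drop(columns=["label"])
    return feat.to_numpy(dtype=np.float64), labels, list(feat.columns)


def milimbeeg_adapter_stub(download_dir: str | Path, out_dir: str | Path) -> None:
    """Documented stub for converting a MILimbEEG download into this layout.

    The public archive's exact directory dialect is not fixed here; a user
    adapter should walk the download, build one time × channels CSV per epoch
    via :func:`write_trial_csv`, and emit a manifest via :func:`write_manifest`
    using the task labels of :data:`DEFAULT_TASK_LABELS`.
    """
    raise NotImplementedError(
        "Point this adapter at your local MILimbEEG download and emit "
        "per-trial CSVs plus a manifest in the documented convention."
    )
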
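"""Reading and writing Bonn-style EEG recordings and CSV feature matrices.

The Bonn benchmark stores each EEG channel as a plain-text file with one
amplitude value (µV) per line; a class-set is a directory of such files
(100 channels of 4097 samples each in the original corpus).  Feature
matrices are plain CSV with one row per channel: the 11 statistical
feature columns, a ``class`` label column and a ``set`` provenance column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, ParseError, ValidationError

#: Canonical class order used everywhere (argmax tie-breaks, matrix assembly).
CLASS_ORDER = ("healthy", "seizure-free", "seizure")

#: Bonn set → class mapping: A,B healthy volunteers; C,D interictal
#: (seizure-free) intervals; E ictal (seizure) activity.
SET_CLASS = {
    "A": "healthy",
    "B": "healthy",
    "C": "seizure-free",
    "D": "seizure-free",
    "E": "seizure",
}

#: Fixed feature column order for CSV headers.
FEATURE_NAMES = (
    "X_Mean",
    "X_Me",
    "X_Mo",
    "X_SD",
    "X_Q1",
    "X_Q3",
    "X_IQR",
    "X_beta1",
    "X_beta2",
    "X_Min",
    "X_Max",
)

LABEL_COLUMN = "class"
SET_COLUMN = "set"


@dataclass
class Signal:
    """A single EEG channel: an ordered amplitude sequence in µV."""

    channel_id: str
    samples: np.ndarray
    sampling_rate: float | None = None  # samples/second, derived from duration

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValidationError(
                f"channel {self.channel_id!r}: samples must be a non-empty 1-D sequence"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError(f"channel {self.channel_id!r}: non-finite samples")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)


@dataclass
class SignalSet:
    """One class-set of EEG: equal-length channels plus recording metadata."""

    set_id: str
    class_label: str
    channels: list[Signal]
    duration_seconds: float

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValidationError(f"set {self.set_id!r}: at least one channel required")
        lengths = {ch.n_samples for ch in self.channels}
        if len(lengths) != 1:
            offenders = sorted(
                (ch.channel_id, ch.n_samples) for ch in self.channels
            )
            raise ValidationError(
                f"set {self.set_id!r}: channels have unequal lengths: {offenders}"
            )
        expected = SET_CLASS.get(self.set_id)
        if expected is not None and expected != self.class_label:
            raise ValidationError(
                f"set {self.set_id!r} maps to class {expected!r}, got {self.class_label!r}"
            )
        if self.duration_seconds <= 0:
            raise ValidationError("duration_seconds must be positive")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_samples(self) -> int:
        return self.channels[0].n_samples

    @property
    def sampling_rate(self) -> float:
        return self.n_samples / self.duration_seconds

    @property
    def channel_ids(self) -> list[str]:
        return [ch.channel_id for ch in self.channels]

    @property
    def data(self) -> np.ndarray:
        """Time points × channels matrix (rows are simultaneous samples)."""
        return np.column_stack([ch.samples for ch in self.channels])


@dataclass
class FeatureMatrix:
    """Channels × 11 statistical features with class labels and provenance.

    Backed by a :class:`pandas.DataFrame` whose columns are the 11 feature
    names followed by ``class`` and ``set``.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        expected = list(FEATURE_NAMES) + [LABEL_COLUMN, SET_COLUMN]
        if list(self.df.columns) != expected:
            raise FormatError(
                f"feature matrix columns must be {expected}, got {list(self.df.columns)}"
            )
        feat = self.df[list(FEATURE_NAMES)]
        if feat.isna().any().any() or self.df[LABEL_COLUMN].isna().any():
            raise ValidationError("feature matrix contains missing values")
        self.df = self.df.reset_index(drop=True)

    @classmethod
    def from_arrays(
        cls,
        values: np.ndarray,
        labels: Sequence[str],
        sets: Sequence[str],
    ) -> "FeatureMatrix":
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[1] != len(FEATURE_NAMES):
            raise ValidationError(
                f"feature values must be n×{len(FEATURE_NAMES)}, got shape {values.shape}"
            )
        df = pd.DataFrame(values, columns=list(FEATURE_NAMES))
        df[LABEL_COLUMN] = list(labels)
        df[SET_COLUMN] = list(sets)
        return cls(df)

    @property
    def n_rows(self) -> int:
        return len(self.df)

    @property
    def X(self) -> np.ndarray:
        return self.df[list(FEATURE_NAMES)].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        return self.df[LABEL_COLUMN].to_numpy()

    @property
    def sets(self) -> np.ndarray:
        return self.df[SET_COLUMN].to_numpy()


def read_channel_file(path: str | Path) -> Signal:
    """Parse a Bonn-style channel file (one amplitude per line) into a Signal.

    Tolerates surrounding whitespace, CRLF line endings and decimal values;
    blank lines are skipped.  A non-numeric line raises :class:`ParseError`
    naming the (1-based) line number.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise OSError(f"cannot read channel file {path}: {exc}") from exc
    values: list[float] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        try:
            values.append(float(stripped))
        except ValueError:
            raise ParseError(
                f"{path}: non-numeric value {stripped!r} at line {lineno}"
            ) from None
    if not values:
        raise ValidationError(f"{path}: channel file contains no samples")
    return Signal(channel_id=path.stem, samples=np.asarray(values))


def load_signal_set(
    directory: str | Path,
    set_id: str,
    class_label: str | None = None,
    duration_seconds: float = 23.6,
    pattern: str = "*.txt",
) -> SignalSet:
    """Assemble a SignalSet from a directory of channel files.

    Channels are ordered lexicographically by filename so loading is
    deterministic.  Unequal channel lengths raise a ValidationError that
    lists the offending files.
    """
    directory = Path(directory)
    paths = sorted(directory.glob(pattern))
    if not paths:
        raise ValidationError(f"{directory}: no channel files matching {pattern!r}")
    channels = [read_channel_file(p) for p in paths]
    if class_label is None:
        try:
            class_label = SET_CLASS[set_id]
        except KeyError:
            raise ValidationError(
                f"set_id {set_id!r} has no default class mapping; pass class_label"
            ) from None
    for ch in channels:
        ch.sampling_rate = ch.n_samples / duration_seconds
    return SignalSet(
        set_id=set_id,
        class_label=class_label,
        channels=channels,
        duration_seconds=duration_seconds,
    )


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    """Write a feature matrix as CSV (header + one row per channel).

    Floats are written with 17 significant digits so the read/write
    round trip is exact.
    """
    fm.df.to_csv(path, index=False, float_format="%.17g")


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    """Read a CSV feature matrix; the header must match the writer's exactly."""
    df = pd.read_csv(path, float_precision="round_trip")
    expected = list(FEATURE_NAMES) + [LABEL_COLUMN, SET_COLUMN]
    if list(df.columns) != expected:
        raise FormatError(
            f"{path}: expected columns {expected}, found {list(df.columns)}"
        )
    df[SET_COLUMN] = df[SET_COLUMN].astype(str)
    return FeatureMatrix(df)
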
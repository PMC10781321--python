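"""Core data containers: labeled multichannel EEG records and datasets.

A record is a 4 x S matrix of scalp potentials in microvolts from the four
10-20 electrode sites TP9, AF7, AF8, TP10 (the consumer-headset montage over
frontal and temporo-parietal cortex), optionally labeled with one of the four
motor-imagery command classes:

====  ====  =========================
code  name  activity
====  ====  =========================
0     LF    left-foot motor imagery
1     LH    left-hand motor imagery
2     RX    relaxation
3     MA    mental arithmetic
====  ====  =========================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .errors import ValidationError

#: Canonical channel order for every record in the package.
CHANNELS: tuple[str, ...] = ("TP9", "AF7", "AF8", "TP10")

#: Class names in code order (code = index).
CLASS_NAMES: tuple[str, ...] = ("LF", "LH", "RX", "MA")

CLASS_CODES: dict[str, int] = {name: i for i, name in enumerate(CLASS_NAMES)}

N_CHANNELS = len(CHANNELS)
N_CLASSES = len(CLASS_NAMES)


@dataclass
class EEGRecord:
    """One multichannel EEG trial.

    Parameters
    ----------
    data
        Array of shape ``(4, S)`` in microvolts, rows ordered as
        :data:`CHANNELS`.
    sampling_rate
        Sampling frequency in Hz.
    label
        One of ``{"LF", "LH", "RX", "MA"}`` or ``None`` for unlabeled data.
    """

    data: np.ndarray
    sampling_rate: float
    label: str | None = None
    channels: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] != N_CHANNELS:
            raise ValidationError(
                f"record data must be 4 x S, got shape {self.data.shape}"
            )
        if self.data.shape[1] < 1:
            raise ValidationError("record must contain at least one sample")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("record contains non-finite values")
        if tuple(self.channels) != CHANNELS:
            raise ValidationError(
                f"channels must be {CHANNELS} in order, got {tuple(self.channels)}"
            )
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        if self.label is not None and self.label not in CLASS_CODES:
            raise ValidationError(
                f"unknown class label {self.label!r}; expected one of {CLASS_NAMES}"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def label_code(self) -> int | None:
        return None if self.label is None else CLASS_CODES[self.label]

    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.sampling_rate

    def copy_with(self, data: np.ndarray) -> "EEGRecord":
        """New record with the same metadata but different samples."""
        return EEGRecord(data=data, sampling_rate=self.sampling_rate, label=self.label)


@dataclass
class Dataset:
    """A homogeneous collection of :class:`EEGRecord` plus its provenance.

    All records share sampling rate, duration and channel order; ``manifest``
    stores the generation (or import) parameters, including the seed, so the
    dataset is regenerable from the manifest alone.
    """

    records: list[EEGRecord]
    manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.records:
            fs = self.records[0].sampling_rate
            ns = self.records[0].n_samples
            for i, rec in enumerate(self.records):
                if rec.sampling_rate != fs or rec.n_samples != ns:
                    raise ValidationError(
                        f"record {i} differs in sampling rate or length from record 0"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[EEGRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> EEGRecord:
        return self.records[i]

    @property
    def sampling_rate(self) -> float:
        return self.records[0].sampling_rate

    @property
    def n_samples(self) -> int:
        return self.records[0].n_samples

    def labels(self) -> np.ndarray:
        """Integer class codes, shape ``(n_records,)``."""
        codes = [rec.label_code for rec in self.records]
        if any(c is None for c in codes):
            raise ValidationError("dataset contains unlabeled records")
        return np.asarray(codes, dtype=np.int64)

    def class_counts(self) -> dict[str, int]:
        counts = {name: 0 for name in CLASS_NAMES}
        for rec in self.records:
            if rec.label is not None:
                counts[rec.label] += 1
        return counts

    def stacked(self) -> np.ndarray:
        """All records as one array of shape ``(n_records, 4, S)``."""
        return np.stack([rec.data for rec in self.records])


def labels_to_codes(labels: Sequence[str]) -> np.ndarray:
    try:
        return np.asarray([CLASS_CODES[l] for l in labels], dtype=np.int64)
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValidationError(f"unknown class label {exc.args[0]!r}") from exc
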
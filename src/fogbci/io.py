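"""Delimited-text I/O for records, datasets, latent images and reports.

Records are CSV files with header ``time_s, TP9, AF7, AF8, TP10``; a
dataset is a directory of such files plus a ``manifest.json`` holding the
generation parameters, the seed and the file-to-label mapping.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .records import CHANNELS, Dataset, EEGRecord

MANIFEST_NAME = "manifest.json"
TIME_COLUMN = "time_s"
#: Tolerated relative mismatch between inferred and declared sampling rate.
RATE_TOLERANCE = 1e-3


def write_record(record: EEGRecord, path: str | Path) -> None:
    """Write one record as delimited text (columns: time_s, TP9, AF7, AF8, TP10)."""
    frame = pd.DataFrame({TIME_COLUMN: record.times()})
    for i, ch in enumerate(CHANNELS):
        frame[ch] = record.data[i]
    frame.to_csv(path, index=False, float_format="%.8g")


def read_record(
    path: str | Path,
    expected_rate: float | None = None,
    label: str | None = None,
) -> EEGRecord:
    """Parse and validate one record file.

    Channels may appear in any order in the header; they are reordered to
    the canonical TP9, AF7, AF8, TP10. The sampling rate is inferred from
    the time column and, when ``expected_rate`` is given (e.g. from a
    manifest), cross-checked to within 0.1 %.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in (TIME_COLUMN, *CHANNELS) if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    for col in (TIME_COLUMN, *CHANNELS):
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = values.index[values.isna() & frame[col].notna()]
        if frame[col].isna().any() or len(bad):
            rows = (frame[col].isna() | values.isna()).to_numpy().nonzero()[0]
            # +2: header line plus 1-based numbering
            raise ParseError(
                f"{path}: non-numeric cell(s) in column {col!r} at line(s) "
                f"{[int(r) + 2 for r in rows[:5]]}"
            )
        frame[col] = values
    times = frame[TIME_COLUMN].to_numpy()
    if len(times) < 2:
        raise ParseError(f"{path}: need at least 2 samples to infer the rate")
    dt = np.diff(times)
    if np.any(dt <= 0):
        line = int(np.argmax(dt <= 0)) + 3
        raise ParseError(f"{path}: time column not strictly increasing at line {line}")
    rate = 1.0 / float(np.median(dt))
    if expected_rate is not None:
        if abs(rate - expected_rate) / expected_rate > RATE_TOLERANCE:
            raise ParseError(
                f"{path}: inferred rate {rate:.4g} Hz differs from declared "
                f"{expected_rate:.4g} Hz by more than 0.1%"
            )
        rate = expected_rate
    data = np.stack([frame[ch].to_numpy() for ch in CHANNELS])
    return EEGRecord(data=data, sampling_rate=rate, label=label)


def save_dataset(dataset: Dataset, out_dir: str | Path) -> None:
    """Write every record plus a JSON manifest mapping files to labels."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    for i, record in enumerate(dataset.records):
        name = f"record_{i:04d}.csv"
        write_record(record, out_dir / name)
        files[name] = record.label
    manifest = dict(dataset.manifest)
    manifest["files"] = files
    manifest["sampling_rate"] = dataset.sampling_rate if len(dataset) else None
    with open(out_dir / MANIFEST_NAME, "w") as fh:
        json.dump(manifest, fh, indent=2)


def load_dataset(data_dir: str | Path) -> Dataset:
    """Read a dataset directory written by :func:`save_dataset`."""
    data_dir = Path(data_dir)
    manifest_path = data_dir / MANIFEST_NAME
    if not manifest_path.exists():
        raise ParseError(f"no {MANIFEST_NAME} in {data_dir}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    rate = manifest.get("sampling_rate")
    records = [
        read_record(data_dir / name, expected_rate=rate, label=label)
        for name, label in sorted(manifest.get("files", {}).items())
    ]
    return Dataset(records=records, manifest=manifest)


def save_latent_image(path: str | Path, image: np.ndarray) -> None:
    """Write a 16 x 21 latent image as comma-delimited text."""
    np.savetxt(path, image, delimiter=",", fmt="%.10g")


def load_latent_image(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",")
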
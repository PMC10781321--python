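"""Fog-node signal conditioning: band-pass filtering and amplitude scaling.

The filtering stage mirrors what an embedded EEG front-end does before any
feature extraction: a Butterworth band-pass covering delta through beta
(0.5-40 Hz by default), applied forward-backward for zero phase distortion,
with an optional mains notch.

Two amplitude conditionings are provided for the encoding stage:

* global scaling (default) — divide every channel by one fixed microvolt
  scale. This keeps network inputs of order one while preserving the
  per-record, per-channel amplitude differences that ERD/ERS class
  signatures consist of; band power IS the class signal, so it must survive
  conditioning.
* per-record standardization — classic per-channel zero mean, unit
  variance, with the scale factors retained for inversion. Useful for
  amplitude-agnostic analyses, but it deliberately removes per-record power
  information and is therefore not the default in the decoding pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import DegenerateChannelError, TooShortError, ValidationError
from .records import CHANNELS, Dataset, EEGRecord


@dataclass
class FilterConfig:
    """Band-pass filter parameters.

    Defaults: 0.5-40 Hz, 4th-order Butterworth, zero-phase. The band covers
    the delta (0.5-4), theta (4-8), alpha (8-13) and beta (>13 Hz) rhythms
    while rejecting drift and 50/60 Hz line noise.
    """

    low_cut: float = 0.5
    high_cut: float = 40.0
    order: int = 4
    notch_hz: float | None = None
    zero_phase: bool = True

    def validate(self, sampling_rate: float) -> None:
        nyquist = sampling_rate / 2.0
        if not (0 < self.low_cut < self.high_cut):
            raise ValidationError("need 0 < low_cut < high_cut")
        if self.high_cut >= nyquist:
            raise ValidationError(
                f"high_cut {self.high_cut} Hz must be below Nyquist ({nyquist} Hz)"
            )
        if self.order < 1:
            raise ValidationError("filter order must be >= 1")
        if self.notch_hz is not None and not (0 < self.notch_hz < nyquist):
            raise ValidationError("notch_hz must lie below Nyquist")


def bandpass_filter(record: EEGRecord, config: FilterConfig | None = None) -> EEGRecord:
    """Apply the configured band-pass (and optional notch) to every channel.

    Zero-phase mode runs the filter forward and backward (``sosfiltfilt``),
    squaring the magnitude response and cancelling group delay.
    """
    config = config or FilterConfig()
    config.validate(record.sampling_rate)
    if record.n_samples < 3 * config.order:
        raise TooShortError(
            f"record of {record.n_samples} samples is shorter than the filter "
            f"warm-up of {3 * config.order} samples"
        )
    sos = signal.butter(
        config.order,
        [config.low_cut, config.high_cut],
        btype="bandpass",
        fs=record.sampling_rate,
        output="sos",
    )
    data = record.data
    if config.zero_phase:
        padlen = min(3 * (2 * sos.shape[0] + 1), record.n_samples - 1)
        filtered = signal.sosfiltfilt(sos, data, axis=1, padlen=padlen)
    else:
        filtered = signal.sosfilt(sos, data, axis=1)
    if config.notch_hz is not None:
        b, a = signal.iirnotch(config.notch_hz, Q=30.0, fs=record.sampling_rate)
        if config.zero_phase:
            filtered = signal.filtfilt(b, a, filtered, axis=1)
        else:
            filtered = signal.lfilter(b, a, filtered, axis=1)
    return record.copy_with(filtered)


@dataclass
class ChannelScaler:
    """Per-channel affine factors recorded by :func:`standardize`."""

    mean: np.ndarray  # (4,) microvolts
    std: np.ndarray  # (4,) microvolts

    def inverse(self, record: EEGRecord) -> EEGRecord:
        """Undo the standardization, restoring microvolt units."""
        return record.copy_with(record.data * self.std[:, None] + self.mean[:, None])


def standardize(record: EEGRecord) -> tuple[EEGRecord, ChannelScaler]:
    """Zero-mean, unit-variance each channel; return the inverse factors."""
    mean = record.data.mean(axis=1)
    std = record.data.std(axis=1)
    degenerate = std < 1e-12 * np.maximum(1.0, np.abs(mean))
    if np.any(degenerate):
        bad = [CHANNELS[i] for i in np.flatnonzero(degenerate)]
        raise DegenerateChannelError(f"constant channel(s) {bad} cannot be standardized")
    scaled = (record.data - mean[:, None]) / std[:, None]
    return record.copy_with(scaled), ChannelScaler(mean=mean, std=std)


#: Default global amplitude scale: 10 uV per unit, the order of resting EEG
#: RMS amplitude, so conditioned samples are O(1) for the network.
DEFAULT_SCALE_UV = 10.0


def preprocess_record(
    record: EEGRecord,
    config: FilterConfig | None = None,
    filter_signal: bool = True,
    scaling: str = "global",
    scale_uv: float = DEFAULT_SCALE_UV,
) -> EEGRecord:
    """Standard conditioning chain: band-pass (optional), then scale.

    ``scaling="global"`` divides by the fixed ``scale_uv`` (amplitude
    preserving); ``scaling="per_record"`` applies :func:`standardize`.
    """
    if scaling not in ("global", "per_record"):
        raise ValidationError("scaling must be 'global' or 'per_record'")
    if filter_signal:
        record = bandpass_filter(record, config)
    if scaling == "per_record":
        record, _ = standardize(record)
        return record
    if scale_uv <= 0:
        raise ValidationError("scale_uv must be positive")
    return record.copy_with(record.data / scale_uv)


def preprocess_dataset(
    dataset: Dataset,
    config: FilterConfig | None = None,
    filter_signal: bool = True,
    scaling: str = "global",
    scale_uv: float = DEFAULT_SCALE_UV,
) -> Dataset:
    """Apply :func:`preprocess_record` to every record."""
    records = [
        preprocess_record(r, config, filter_signal, scaling, scale_uv)
        for r in dataset.records
    ]
    manifest = dict(dataset.manifest)
    cfg = config or FilterConfig()
    manifest["preprocessing"] = {
        "filtered": filter_signal,
        "low_cut": cfg.low_cut,
        "high_cut": cfg.high_cut,
        "order": cfg.order,
        "notch_hz": cfg.notch_hz,
        "zero_phase": cfg.zero_phase,
        "scaling": scaling,
        "scale_uv": scale_uv if scaling == "global" else None,
    }
    return Dataset(records=records, manifest=manifest)
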
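"""Synthetic motor-imagery EEG generator.

Emulates the statistical structure of a 4-channel consumer-headset
motor-imagery dataset: each labeled trial is a pink-noise (1/f) background
plus band-limited oscillations in the theta (4-8 Hz), alpha (8-13 Hz) and
beta (13-30 Hz) bands, whose amplitudes are modulated per class and channel
in the style of event-related desynchronization / synchronization (ERD/ERS).
A gain above 1 in a band mimics ERS (power increase), below 1 mimics ERD.

The four default class signatures are spectrally separable on purpose:

* ``RX`` - relaxation: alpha gain 2.0 on all channels (the classic
  eyes-closed / rest alpha rhythm).
* ``LH`` - left hand: alpha ERD (gain 0.5) with beta ERS (gain 1.5) on
  AF7/TP9.
* ``LF`` - left foot: beta ERS (gain 2.0) on AF8/TP10.
* ``MA`` - mental arithmetic: frontal theta ERS (gain 2.0) with beta ERS
  (gain 1.5) on AF7/AF8.

The ``separation`` knob scales the between-class gain contrasts: effective
gain = 1 + separation * (profile gain - 1), so separation 0 collapses every
class onto the same background process and larger values pull the class
spectra apart monotonically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .records import CHANNELS, CLASS_NAMES, Dataset, EEGRecord, N_CHANNELS

#: EEG band edges in Hz. Beta is open-ended physiologically; the generator
#: caps it at 30 Hz so oscillations stay inside the default analysis band.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

#: Baseline (gain = 1) RMS per oscillation band, relative to unit amplitude
#: scale. Alpha is the strongest resting rhythm; the values are calibrated
#: so that, with the default class profiles, each class's boosted band
#: dominates the periodogram at separation 1 (the tightest competition is
#: mental arithmetic's 2.0x theta against its own 1.5x beta).
BASELINE_BAND_RMS: dict[str, float] = {"theta": 0.35, "alpha": 0.45, "beta": 0.4}

#: RMS of the pink-noise background on the same relative scale.
BACKGROUND_NOISE_RMS = 0.7

#: Sinusoid components drawn per band per record.
N_COMPONENTS_PER_BAND = 3


def default_class_profiles() -> dict[str, dict[str, np.ndarray]]:
    """Per-class, per-band channel gain vectors (order: TP9, AF7, AF8, TP10)."""
    ones = np.ones(N_CHANNELS)

    def gains(**kw: float) -> np.ndarray:
        g = ones.copy()
        for ch, value in kw.items():
            g[CHANNELS.index(ch)] = value
        return g

    return {
        "RX": {"alpha": 2.0 * ones},
        "LH": {"alpha": gains(AF7=0.5, TP9=0.5), "beta": gains(AF7=1.5, TP9=1.5)},
        "LF": {"beta": gains(AF8=2.0, TP10=2.0)},
        "MA": {"theta": gains(AF7=2.0, AF8=2.0), "beta": gains(AF7=1.5, AF8=1.5)},
    }


@dataclass
class SyntheticSpec:
    """Full parameterization of a synthetic dataset.

    Parameters
    ----------
    n_records
        Number of trials; labels are balanced over the 4 classes with any
        remainder assigned round-robin.
    sampling_rate, duration
        256 Hz and 2 s by default (S = 512 samples), the conventional rate
        for the consumer-headset class this emulates.
    class_profiles
        Map class name -> (band name -> 4-vector of channel gains). Bands
        absent from a class's profile keep gain 1.
    noise_exponent
        Spectral slope beta of the 1/f^beta background; 1 = pink noise, the
        standard resting-EEG approximation.
    base_amplitude
        Overall scale in microvolts; records are scaled so typical samples
        sit well inside the physiological 0.5-100 uV range and hard-limited
        at ``2 * base_amplitude``.
    separation
        Scale on between-class gain contrasts (see module docstring).
    seed
        Root seed; generation is a pure function of this spec.
    """

    n_records: int = 200
    sampling_rate: float = 256.0
    duration: float = 2.0
    class_profiles: dict[str, dict[str, np.ndarray]] = field(
        default_factory=default_class_profiles
    )
    noise_exponent: float = 1.0
    base_amplitude: float = 50.0
    separation: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_records < 0:
            raise ValidationError("n_records must be >= 0")
        if self.duration <= 0:
            raise ValidationError("duration must be positive")
        if self.separation < 0:
            raise ValidationError("separation must be >= 0")
        if self.base_amplitude <= 0:
            raise ValidationError("base_amplitude must be positive")
        missing = [c for c in CLASS_NAMES if c not in self.class_profiles]
        if missing:
            raise ValidationError(f"class_profiles missing classes {missing}")
        highest = 0.0
        for cls, profile in self.class_profiles.items():
            for band, gains_ in profile.items():
                if band not in BANDS:
                    raise ValidationError(f"unknown band {band!r} in profile {cls!r}")
                g = np.asarray(gains_, dtype=float)
                if g.shape != (N_CHANNELS,):
                    raise ValidationError(
                        f"profile {cls!r}/{band!r} must give {N_CHANNELS} channel gains"
                    )
                if np.any(g < 0):
                    raise ValidationError("band gains must be >= 0")
                highest = max(highest, BANDS[band][1])
        if self.sampling_rate <= 2 * highest:
            raise ValidationError(
                f"sampling_rate must exceed twice the highest band edge ({highest} Hz)"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    def to_manifest(self) -> dict:
        """JSON-serializable description sufficient to regenerate the data."""
        return {
            "n_records": self.n_records,
            "sampling_rate": self.sampling_rate,
            "duration": self.duration,
            "noise_exponent": self.noise_exponent,
            "base_amplitude": self.base_amplitude,
            "separation": self.separation,
            "seed": self.seed,
            "class_profiles": {
                cls: {band: list(map(float, g)) for band, g in profile.items()}
                for cls, profile in self.class_profiles.items()
            },
            "baseline_band_rms": dict(BASELINE_BAND_RMS),
            "background_noise_rms": BACKGROUND_NOISE_RMS,
            "components_per_band": N_COMPONENTS_PER_BAND,
        }

    @classmethod
    def from_manifest(cls, manifest: dict) -> "SyntheticSpec":
        profiles = {
            c: {band: np.asarray(g, dtype=float) for band, g in profile.items()}
            for c, profile in manifest["class_profiles"].items()
        }
        keys = (
            "n_records sampling_rate duration noise_exponent "
            "base_amplitude separation seed"
        ).split()
        return cls(class_profiles=profiles, **{k: manifest[k] for k in keys})

    def replace(self, **kw) -> "SyntheticSpec":
        return dataclasses.replace(self, **kw)


def _pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f^exponent noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC component
    x = np.fft.irfft(spectrum * shaping, n=n)
    return x / np.std(x)


def generate_record(
    spec: SyntheticSpec, label: str, rng: np.random.Generator
) -> EEGRecord:
    """Generate one labeled synthetic trial.

    The per-channel signal is ``noise + sum_b g_cb * s_b(t)`` where ``s_b``
    is a random-phase mixture of 3 sinusoids with frequencies drawn
    uniformly in band ``b`` (frequencies shared across channels, phases
    independent) and ``g_cb = 1 + separation * (profile_cb - 1)``. The
    result is scaled to microvolts by ``base_amplitude / 5`` and clipped at
    ``+-2 * base_amplitude`` so that with the 50 uV default the samples
    respect the physiological 100 uV ceiling.
    """
    spec.validate()
    if label not in CLASS_NAMES:
        raise ValidationError(
            f"unknown class label {label!r}; expected one of {CLASS_NAMES}"
        )
    S = spec.n_samples
    if S < 1:
        raise ValidationError("duration x sampling_rate must round to >= 1 sample")
    t = np.arange(S) / spec.sampling_rate
    T = S / spec.sampling_rate
    profile = spec.class_profiles[label]

    data = np.empty((N_CHANNELS, S))
    # Draw in a label-independent order so that at separation = 0 every label
    # maps the same rng state to the same signal.
    band_components: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for band in ("theta", "alpha", "beta"):
        lo, hi = BANDS[band]
        # Frequencies drawn uniformly from the record's own Fourier grid
        # (k / T), i.e. leakage-free tones; distinct draws avoid coincident
        # components. Falls back to continuous draws when the record is too
        # short for three in-band grid frequencies.
        grid = np.arange(np.ceil(lo * T), np.floor(hi * T) + 1) / T
        grid = grid[(grid >= lo) & (grid < hi)]
        if len(grid) >= N_COMPONENTS_PER_BAND:
            freqs = rng.choice(grid, N_COMPONENTS_PER_BAND, replace=False)
        else:
            freqs = rng.uniform(lo, hi, size=N_COMPONENTS_PER_BAND)
        phases = rng.uniform(0.0, 2 * np.pi, size=(N_CHANNELS, N_COMPONENTS_PER_BAND))
        band_components[band] = (freqs, phases)

    for ch in range(N_CHANNELS):
        x = BACKGROUND_NOISE_RMS * _pink_noise(S, spec.noise_exponent, rng)
        for band, (freqs, phases) in band_components.items():
            amp = BASELINE_BAND_RMS[band] * np.sqrt(2.0 / N_COMPONENTS_PER_BAND)
            base_gain = profile.get(band, np.ones(N_CHANNELS))[ch]
            gain = 1.0 + spec.separation * (base_gain - 1.0)
            osc = np.sum(
                np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[ch][:, None]),
                axis=0,
            )
            x = x + gain * amp * osc
        data[ch] = x

    scale = spec.base_amplitude / 5.0
    data = np.clip(data * scale, -2 * spec.base_amplitude, 2 * spec.base_amplitude)
    return EEGRecord(data=data, sampling_rate=spec.sampling_rate, label=label)


def balanced_labels(n_records: int) -> list[str]:
    """Round-robin class assignment: balanced to within one record."""
    return [CLASS_NAMES[i % len(CLASS_NAMES)] for i in range(n_records)]


def generate_dataset(spec: SyntheticSpec) -> Dataset:
    """Generate a labeled dataset, fully determined by ``spec`` (incl. seed).

    Each record draws from its own child of ``SeedSequence(spec.seed)``, so
    record ``i`` is reproducible independently of the others.
    """
    spec.validate()
    labels = balanced_labels(spec.n_records)
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_records)
    records = [
        generate_record(spec, label, np.random.default_rng(child))
        for label, child in zip(labels, children)
    ]
    manifest = spec.to_manifest()
    manifest["labels"] = labels
    return Dataset(records=records, manifest=manifest)
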
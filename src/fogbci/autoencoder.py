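"""Convolutional-LSTM autoencoder mapping EEG records to 16 x 21 latent images.

Architecture
------------
The encoder treats time as the recurrence axis and the four electrodes as a
convolutional spatial axis:

* convolutional LSTM, 20 filters, kernel 2 along the electrode axis with no
  padding (recurrent kernel 'same'-padded), so the hidden state has spatial
  extent 4 - 2 + 1 = 3 with 20 filter maps;
* the final hidden state is read as a 3 x 20 single-channel image;
* a transposed convolution with a single 14 x 2 filter (stride 1, no
  padding) maps it to (3-1)+14 = 16 rows by (20-1)+2 = 21 columns — the
  latent image.

The decoder reconstructs the 4 x S signal from the latent image: flatten to
a 336-step sequence; an LSTM with 2 units; a convolution (3 filters, extent
4); two transposed convolutions (3 filters, extent 3); three convolutions
(7 filters, extents 90, 90, 11); a final convolution (4 filters, extent 10)
giving one output channel per electrode; then a fixed (non-learned) linear
time-interpolation adapter stretches the resulting 140-step sequence to S
samples. The decoder is training scaffolding only — after training, the
encoder alone is deployed.

Training minimizes the mean squared reconstruction error
``mean((X - f_dec(f_enc(X)))^2)`` by Adam. All weight initialization and
batch shuffling derive from a single seed; bit-exact reproducibility
assumes single-threaded execution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .errors import (
    ConfigurationError,
    DivergenceError,
    ShapeError,
    ValidationError,
)
from .records import Dataset, EEGRecord, N_CHANNELS

#: Rows x columns of every latent image.
LATENT_SHAPE: tuple[int, int] = (16, 21)
#: Latent image size as a flat feature count.
N_LATENT_FEATURES = LATENT_SHAPE[0] * LATENT_SHAPE[1]

#: Conv-LSTM width of the encoder.
ENCODER_FILTERS = 20
ENCODER_KERNEL = 2
#: Hidden spatial extent: 4 electrodes, kernel 2, valid padding.
ENCODER_SPATIAL = N_CHANNELS - ENCODER_KERNEL + 1
#: Transposed-convolution kernel producing the latent image.
HEAD_KERNEL = (14, 2)

#: Minimum record length the decoder stack is specified for.
MIN_DECODER_SAMPLES = 110

#: Decoder layer plan: (kind, kernel extent, output channels).
DECODER_PLAN: tuple[tuple[str, int, int], ...] = (
    ("conv", 4, 3),
    ("conv_transpose", 3, 3),
    ("conv_transpose", 3, 3),
    ("conv", 90, 7),
    ("conv", 90, 7),
    ("conv", 11, 7),
    ("conv", 10, N_CHANNELS),
)
DECODER_LSTM_UNITS = 2


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


@dataclass
class TrainConfig:
    """Optimizer settings for :func:`train_autoencoder`."""

    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 1e-3
    seed: int = 0
    validation_fraction: float = 0.0

    def validate(self, n_records: int) -> None:
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if not (0 < self.batch_size <= n_records):
            raise ValidationError(
                f"batch_size must be in [1, n_records={n_records}]"
            )
        if not (0.0 <= self.validation_fraction < 1.0):
            raise ValidationError("validation_fraction must be in [0, 1)")


class EncoderModel:
    """The deployed map f_enc: conditioned 4 x S record -> 16 x 21 image."""

    n_filters = ENCODER_FILTERS
    kernel_size = ENCODER_KERNEL

    def __init__(self, seed: int = 0, chrono_tmax: int = 512):
        """``chrono_tmax``: upper bound of the chrono bias-initialization
        timescales, in samples; normally the record length.

        Chrono initialization draws each filter's forget-gate bias as
        log U(1, T_max) (input-gate bias its negative), spreading the cell
        integration timescales log-uniformly up to the record length. Long-
        memory cells accumulate band-energy statistics over the whole
        record, which is what makes the final hidden state informative
        about slow amplitude structure rather than a snapshot of the last
        few samples.
        """
        self.seed = seed
        self.chrono_tmax = chrono_tmax
        rng = np.random.default_rng(seed)
        F = ENCODER_FILTERS
        # Gate order along the last axis: input, forget, candidate, output.
        bias = np.zeros(4 * F)
        forget_bias = np.log(rng.uniform(1.0, max(1.0, chrono_tmax), size=F))
        bias[F : 2 * F] = forget_bias
        bias[0:F] = -forget_bias
        self.params: dict[str, Tensor] = {
            "Wx": Tensor(_glorot(rng, (ENCODER_KERNEL, 4 * F), ENCODER_KERNEL, F)),
            "Wh0": Tensor(_glorot(rng, (F, 4 * F), F, F)),
            "Wh1": Tensor(_glorot(rng, (F, 4 * F), F, F)),
            "b": Tensor(bias),
            "head_w": Tensor(
                _glorot(rng, HEAD_KERNEL, HEAD_KERNEL[0] * HEAD_KERNEL[1], 1)
            ),
            "head_b": Tensor(0.0),
        }
        self.metadata: dict = {"seed": seed, "epochs_trained": 0, "final_loss": None}

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def forward_batch(self, X: np.ndarray) -> Tensor:
        """Differentiable forward pass.

        ``X``: (B, S, 4) conditioned samples -> latent Tensor (B, 16, 21).
        """
        B, S, C = X.shape
        if C != N_CHANNELS:
            raise ShapeError(f"expected {N_CHANNELS} channels, got {C}")
        p = self.params
        F = ENCODER_FILTERS
        x = Tensor(X)
        # Electrode-axis valid convolution for every timestep at once:
        # xproj[b,t,i,:] = x[b,t,i]*Wx[0] + x[b,t,i+1]*Wx[1], i = 0..2.
        x0 = x[:, :, 0 : ENCODER_SPATIAL].reshape(B, S, ENCODER_SPATIAL, 1)
        x1 = x[:, :, 1 : ENCODER_SPATIAL + 1].reshape(B, S, ENCODER_SPATIAL, 1)
        xproj = x0 * p["Wx"][0] + x1 * p["Wx"][1]  # (B, S, 3, 4F)

        h = Tensor(np.zeros((B, ENCODER_SPATIAL, F)))
        c = Tensor(np.zeros((B, ENCODER_SPATIAL, F)))
        for t in range(S):
            # Recurrent 'same' convolution, kernel 2, right-padded with zero.
            rec = h @ p["Wh0"] + ad.pad(
                h[:, 1:, :] @ p["Wh1"], ((0, 0), (0, 1), (0, 0))
            )
            gates = xproj[:, t] + rec + p["b"]
            i_g = gates[:, :, 0:F].sigmoid()
            f_g = gates[:, :, F : 2 * F].sigmoid()
            g_g = gates[:, :, 2 * F : 3 * F].tanh()
            o_g = gates[:, :, 3 * F : 4 * F].sigmoid()
            c = f_g * c + i_g * g_g
            h = o_g * c.tanh()
        # Final hidden state read as a 3 x 20 image; transposed conv to 16 x 21.
        latent = ad.conv_transpose2d(h, p["head_w"]) + p["head_b"]
        return latent

    def encode(self, record: EEGRecord) -> np.ndarray:
        """Map one preprocessed record to its 16 x 21 latent image."""
        if record.data.shape[0] != N_CHANNELS:
            raise ShapeError("record must have 4 channels")
        latent = self.forward_batch(record.data.T[None, :, :])
        return latent.data[0]

    def encode_batch(self, X: np.ndarray) -> np.ndarray:
        """Non-differentiable convenience wrapper, (B, S, 4) -> (B, 16, 21)."""
        return self.forward_batch(X).data


class DecoderModel:
    """The reconstruction map f_dec: 16 x 21 image -> 4 x S signal."""

    lstm_units = DECODER_LSTM_UNITS
    layer_plan = DECODER_PLAN

    def __init__(self, seed: int = 0, n_samples: int = 512):
        if n_samples < MIN_DECODER_SAMPLES:
            raise ConfigurationError(
                f"decoder requires S >= {MIN_DECODER_SAMPLES}, got {n_samples}"
            )
        self.seed = seed
        self.n_samples = n_samples
        rng = np.random.default_rng(seed)
        U = DECODER_LSTM_UNITS
        self.params: dict[str, Tensor] = {
            "Wx": Tensor(_glorot(rng, (1, 4 * U), 1, U)),
            "Wh": Tensor(_glorot(rng, (U, 4 * U), U, U)),
            "b": Tensor(np.zeros(4 * U)),
        }
        in_ch = U
        length = N_LATENT_FEATURES
        for li, (kind, k, out_ch) in enumerate(DECODER_PLAN):
            if kind == "conv":
                shape = (k, in_ch, out_ch)
                length = length - k + 1
            else:  # transposed convolution, stride 1, no padding
                shape = (k, out_ch, in_ch)
                length = length + k - 1
            self.params[f"w{li}"] = Tensor(
                _glorot(rng, shape, k * in_ch, out_ch)
            )
            self.params[f"b{li}"] = Tensor(np.zeros(out_ch))
            in_ch = out_ch
        #: Sequence length leaving the convolution stack (140 for 16 x 21).
        self.stack_length = length
        # Fixed linear-interpolation adapter: stack_length points -> S samples.
        self._interp = _interp_matrix(self.stack_length, n_samples)

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def forward_batch(self, latent: Tensor) -> Tensor:
        """Differentiable decode, latent (B, 16, 21) -> (B, 4, S)."""
        B = latent.shape[0]
        U = DECODER_LSTM_UNITS
        p = self.params
        seq = latent.reshape(B, N_LATENT_FEATURES, 1)
        xp = seq @ p["Wx"]  # (B, 336, 4U)
        h = Tensor(np.zeros((B, U)))
        c = Tensor(np.zeros((B, U)))
        hs = []
        for t in range(N_LATENT_FEATURES):
            gates = xp[:, t] + h @ p["Wh"] + p["b"]
            i_g = gates[:, 0:U].sigmoid()
            f_g = gates[:, U : 2 * U].sigmoid()
            g_g = gates[:, 2 * U : 3 * U].tanh()
            o_g = gates[:, 3 * U : 4 * U].sigmoid()
            c = f_g * c + i_g * g_g
            h = o_g * c.tanh()
            hs.append(h)
        y = ad.stack(hs, axis=1)  # (B, 336, 2)
        last = len(DECODER_PLAN) - 1
        for li, (kind, _k, _out_ch) in enumerate(DECODER_PLAN):
            if kind == "conv":
                y = ad.conv1d(y, p[f"w{li}"]) + p[f"b{li}"]
            else:
                y = ad.conv_transpose1d(y, p[f"w{li}"]) + p[f"b{li}"]
            if li != last:
                y = y.tanh()
        y = y.transpose((0, 2, 1))  # (B, 4, stack_length)
        return y @ Tensor(self._interp.T)  # (B, 4, S)

    def decode(self, latent_image: np.ndarray) -> np.ndarray:
        """Non-differentiable decode of one 16 x 21 image to a 4 x S array."""
        if latent_image.shape != LATENT_SHAPE:
            raise ShapeError(f"latent image must be {LATENT_SHAPE}")
        return self.forward_batch(Tensor(latent_image[None])).data[0]


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Linear-interpolation matrix M (n_out x n_in): y = M @ x."""
    M = np.zeros((n_out, n_in))
    pos = np.linspace(0.0, n_in - 1, n_out)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = pos - lo
    M[np.arange(n_out), lo] += 1.0 - frac
    M[np.arange(n_out), hi] += frac
    return M


def build_encoder(seed: int = 0) -> EncoderModel:
    """Construct an encoder with seed-deterministic initial weights."""
    return EncoderModel(seed=seed)


def build_decoder(seed: int = 0, n_samples: int = 512) -> DecoderModel:
    """Construct a decoder targeting records of ``n_samples`` samples."""
    return DecoderModel(seed=seed, n_samples=n_samples)


def encode_record(model: EncoderModel, record: EEGRecord) -> np.ndarray:
    """Functional alias for :meth:`EncoderModel.encode`."""
    return model.encode(record)


@dataclass
class TrainingHistory:
    """Per-epoch mean training (and optional validation) loss."""

    train_loss: np.ndarray
    val_loss: np.ndarray | None = None

    @property
    def first(self) -> float:
        return float(self.train_loss[0])

    @property
    def final(self) -> float:
        return float(self.train_loss[-1])


def train_autoencoder(
    dataset: Dataset,
    config: TrainConfig | None = None,
) -> tuple[EncoderModel, DecoderModel, TrainingHistory]:
    """Fit encoder and decoder by minimizing mean squared reconstruction error.

    ``dataset`` must already be conditioned (see :mod:`fogbci.preprocessing`);
    labels are ignored — training is unsupervised. Returns the fitted
    encoder, the decoder (scaffolding, discarded downstream) and the
    per-epoch loss history.
    """
    config = config or TrainConfig()
    config.validate(len(dataset))
    X = dataset.stacked().transpose(0, 2, 1)  # (N, S, 4)
    N, S, _ = X.shape

    rng = np.random.default_rng(config.seed)
    encoder = EncoderModel(seed=int(rng.integers(2**31)))
    decoder = DecoderModel(seed=int(rng.integers(2**31)), n_samples=S)
    params = encoder.parameters() + decoder.parameters()
    optimizer = ad.Adam(params, learning_rate=config.learning_rate)

    n_val = int(round(config.validation_fraction * N))
    order0 = rng.permutation(N)
    val_idx, train_idx = order0[:n_val], order0[n_val:]
    X_train, X_val = X[train_idx], X[val_idx]
    n_train = len(X_train)
    if n_train < config.batch_size:
        raise ValidationError("validation split leaves fewer records than batch_size")

    train_losses = []
    val_losses = []
    for epoch in range(config.epochs):
        perm = rng.permutation(n_train)
        epoch_loss = 0.0
        for start in range(0, n_train, config.batch_size):
            batch = X_train[perm[start : start + config.batch_size]]
            optimizer.zero_grad()
            latent = encoder.forward_batch(batch)
            recon = decoder.forward_batch(latent)
            target = Tensor(batch.transpose(0, 2, 1))
            loss = (recon - target).square().mean()
            value = float(loss.data)
            if not np.isfinite(value):
                raise DivergenceError(epoch + 1)
            loss.backward()
            optimizer.step()
            epoch_loss += value * len(batch)
        train_losses.append(epoch_loss / n_train)
        if n_val:
            latent = encoder.forward_batch(X_val)
            recon = decoder.forward_batch(latent).data
            val_losses.append(float(np.mean((recon - X_val.transpose(0, 2, 1)) ** 2)))

    history = TrainingHistory(
        train_loss=np.asarray(train_losses),
        val_loss=np.asarray(val_losses) if n_val else None,
    )
    encoder.metadata.update(
        {
            "epochs_trained": config.epochs,
            "final_loss": history.final,
            "train_seed": config.seed,
        }
    )
    return encoder, decoder, history


def encode_dataset(encoder: EncoderModel, dataset: Dataset) -> np.ndarray:
    """Latent images for every record, shape (n_records, 16, 21)."""
    X = dataset.stacked().transpose(0, 2, 1)
    images = np.empty((len(dataset), *LATENT_SHAPE))
    # Chunked to bound graph size; inference only.
    for start in range(0, len(dataset), 32):
        images[start : start + 32] = encoder.encode_batch(X[start : start + 32])
    return images


# -- serialization ---------------------------------------------------------


def save_model(
    path, encoder: EncoderModel, decoder: DecoderModel | None = None
) -> None:
    """Write a self-describing model bundle (.npz: weights + JSON manifest)."""
    arrays: dict[str, np.ndarray] = {}
    for name, tensor in encoder.params.items():
        arrays[f"enc_{name}"] = tensor.data
    meta = {
        "format": "fogbci-model-bundle-v1",
        "latent_shape": list(LATENT_SHAPE),
        "encoder": {"seed": encoder.seed, "chrono_tmax": encoder.chrono_tmax, **encoder.metadata},
    }
    if decoder is not None:
        for name, tensor in decoder.params.items():
            arrays[f"dec_{name}"] = tensor.data
        meta["decoder"] = {"seed": decoder.seed, "n_samples": decoder.n_samples}
    arrays["manifest"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    )
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_model(path) -> tuple[EncoderModel, DecoderModel | None]:
    """Load a model bundle written by :func:`save_model`."""
    with np.load(path) as bundle:
        meta = json.loads(bytes(bundle["manifest"]).decode("utf-8"))
        if meta.get("format") != "fogbci-model-bundle-v1":
            raise ConfigurationError(f"{path} is not a fogbci model bundle")
        encoder = EncoderModel(
            seed=meta["encoder"]["seed"],
            chrono_tmax=meta["encoder"].get("chrono_tmax", 512),
        )
        for name in encoder.params:
            encoder.params[name].data = np.array(bundle[f"enc_{name}"])
        encoder.metadata = {
            k: v
            for k, v in meta["encoder"].items()
            if k not in ("seed", "chrono_tmax")
        }
        decoder = None
        if "decoder" in meta:
            decoder = DecoderModel(
                seed=meta["decoder"]["seed"], n_samples=meta["decoder"]["n_samples"]
            )
            for name in decoder.params:
                decoder.params[name].data = np.array(bundle[f"dec_{name}"])
    return encoder, decoder
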
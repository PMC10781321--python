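"""Conv-LSTM autoencoder: shapes, determinism, training descent, serialization."""

import numpy as np
import pytest

from fogbci.autoencoder import (
    DECODER_PLAN,
    ENCODER_FILTERS,
    ENCODER_KERNEL,
    ENCODER_SPATIAL,
    HEAD_KERNEL,
    LATENT_SHAPE,
    DecoderModel,
    EncoderModel,
    TrainConfig,
    TrainingHistory,
    build_decoder,
    build_encoder,
    encode_dataset,
    load_model,
    save_model,
    train_autoencoder,
)
from fogbci.errors import ConfigurationError, ShapeError, ValidationError
from fogbci.preprocessing import preprocess_dataset
from fogbci.records import Dataset, EEGRecord


def random_record(rng, n_samples=160, fs=256.0, label="RX"):
    return EEGRecord(
        data=rng.standard_normal((4, n_samples)), sampling_rate=fs, label=label
    )


class TestShapeArithmetic:
    def test_printed_shape_chain(self):
        """4 electrodes, kernel 2, valid -> 3; transposed 14x2 -> 16 x 21."""
        assert ENCODER_SPATIAL == 4 - ENCODER_KERNEL + 1 == 3
        rows = (ENCODER_SPATIAL - 1) * 1 + HEAD_KERNEL[0]
        cols = (ENCODER_FILTERS - 1) * 1 + HEAD_KERNEL[1]
        assert (rows, cols) == LATENT_SHAPE == (16, 21)

    def test_encode_output_is_16_by_21(self, rng):
        encoder = build_encoder(seed=0)
        image = encoder.encode(random_record(rng))
        assert image.shape == (16, 21)
        assert np.all(np.isfinite(image))

    def test_conv_lstm_has_20_filters(self):
        encoder = build_encoder(seed=0)
        assert encoder.n_filters == 20
        # one input-kernel column per gate and filter
        assert encoder.params["Wx"].shape == (2, 4 * 20)

    def test_wrong_channel_count_rejected(self, rng):
        encoder = build_encoder(seed=0)
        with pytest.raises(ShapeError):
            encoder.forward_batch(rng.standard_normal((1, 100, 5)))


class TestEncoderBehavior:
    def test_zero_weights_give_zero_image(self, rng):
        encoder = build_encoder(seed=0)
        for p in encoder.parameters():
            p.data = np.zeros_like(p.data)
        image = encoder.encode(random_record(rng))
        np.testing.assert_array_equal(image, np.zeros((16, 21)))

    def test_same_seed_same_weights(self):
        a, b = build_encoder(seed=7), build_encoder(seed=7)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_different_seed_different_weights(self):
        a, b = build_encoder(seed=7), build_encoder(seed=8)
        assert not np.array_equal(a.params["Wx"].data, b.params["Wx"].data)

    def test_encoding_is_deterministic(self, rng):
        encoder = build_encoder(seed=3)
        rec = random_record(rng)
        np.testing.assert_array_equal(encoder.encode(rec), encoder.encode(rec))


class TestDecoder:
    def test_output_shape_matches_record(self, rng):
        decoder = build_decoder(seed=0, n_samples=300)
        out = decoder.decode(rng.standard_normal(LATENT_SHAPE))
        assert out.shape == (4, 300)

    def test_zero_weights_give_zero_reconstruction(self, rng):
        decoder = build_decoder(seed=0, n_samples=150)
        for p in decoder.parameters():
            p.data = np.zeros_like(p.data)
        out = decoder.decode(rng.standard_normal(LATENT_SHAPE))
        np.testing.assert_array_equal(out, np.zeros((4, 150)))

    def test_layer_plan_matches_declared_stack(self):
        """Layer kinds, kernel extents and filter counts in declared order."""
        kinds = [k for k, _, _ in DECODER_PLAN]
        extents = [e for _, e, _ in DECODER_PLAN]
        filters = [f for _, _, f in DECODER_PLAN]
        assert kinds == [
            "conv",
            "conv_transpose",
            "conv_transpose",
            "conv",
            "conv",
            "conv",
            "conv",
        ]
        assert extents == [4, 3, 3, 90, 90, 11, 10]
        assert filters == [3, 3, 3, 7, 7, 7, 4]
        assert DecoderModel.lstm_units == 2

    def test_too_short_target_rejected(self):
        with pytest.raises(ConfigurationError):
            build_decoder(seed=0, n_samples=100)


class TestTraining:
    def test_zero_dataset_trains_to_zero_loss(self):
        records = [
            EEGRecord(data=np.zeros((4, 128)), sampling_rate=256.0, label="RX")
            for _ in range(8)
        ]
        ds = Dataset(records=records)
        _, _, history = train_autoencoder(
            ds, TrainConfig(epochs=2, batch_size=4, seed=0)
        )
        assert history.final < 1e-6

    def test_loss_decreases_on_synthetic_data(self, small_dataset):
        processed = preprocess_dataset(small_dataset)
        _, _, history = train_autoencoder(
            processed, TrainConfig(epochs=6, batch_size=16, seed=0)
        )
        assert history.final < history.first
        assert len(history.train_loss) == 6

    def test_training_is_reproducible(self, small_dataset):
        processed = preprocess_dataset(small_dataset)
        cfg = TrainConfig(epochs=2, batch_size=16, seed=5)
        _, _, h1 = train_autoencoder(processed, cfg)
        _, _, h2 = train_autoencoder(processed, cfg)
        np.testing.assert_array_equal(h1.train_loss, h2.train_loss)

    def test_batch_size_validation(self, small_dataset):
        with pytest.raises(ValidationError):
            train_autoencoder(small_dataset, TrainConfig(batch_size=1000))

    def test_validation_split_tracked(self, small_dataset):
        processed = preprocess_dataset(small_dataset)
        _, _, history = train_autoencoder(
            processed,
            TrainConfig(epochs=2, batch_size=8, seed=1, validation_fraction=0.25),
        )
        assert history.val_loss is not None
        assert len(history.val_loss) == 2
        assert np.all(np.isfinite(history.val_loss))


class TestSerialization:
    def test_round_trip_is_bit_identical(self, tmp_path, rng, small_dataset):
        processed = preprocess_dataset(small_dataset)
        encoder, decoder, _ = train_autoencoder(
            processed, TrainConfig(epochs=1, batch_size=16, seed=2)
        )
        rec = processed.records[0]
        before = encoder.encode(rec)
        path = tmp_path / "model.npz"
        save_model(path, encoder, decoder)
        loaded_enc, loaded_dec = load_model(path)
        np.testing.assert_array_equal(loaded_enc.encode(rec), before)
        assert loaded_dec is not None
        assert loaded_dec.n_samples == decoder.n_samples

    def test_rejects_foreign_file(self, tmp_path):
        path = tmp_path / "bogus.npz"
        np.savez(path, a=np.ones(3))
        with pytest.raises(Exception):
            load_model(path)


class TestTrainedEncoder:
    """Checks against the session-scoped 30-epoch training run."""

    def test_descent_over_epochs(self, trained_autoencoder):
        _, _, history = trained_autoencoder
        assert history.final < history.first
        assert np.mean(history.train_loss[-3:]) < np.mean(history.train_loss[:3])

    def test_latents_beat_random_projections(
        self, trained_autoencoder, preprocessed_dataset
    ):
        """Latent images outperform 336 random projections of the raw signal."""
        from sklearn.ensemble import RandomForestClassifier
        from sklearn.model_selection import train_test_split

        encoder, _, _ = trained_autoencoder
        images = encode_dataset(encoder, preprocessed_dataset)
        X_latent = images.reshape(len(images), -1)
        raw = preprocessed_dataset.stacked().reshape(len(images), -1)
        y = preprocessed_dataset.labels()

        def accuracy(X, seed):
            X_tr, X_te, y_tr, y_te = train_test_split(
                X, y, test_size=0.2, stratify=y, random_state=seed
            )
            clf = RandomForestClassifier(250, random_state=seed)
            return clf.fit(X_tr, y_tr).score(X_te, y_te)

        latent_accs, projected_accs = [], []
        for seed in range(3):
            projection = np.random.default_rng(seed).standard_normal(
                (raw.shape[1], 336)
            ) / np.sqrt(raw.shape[1])
            latent_accs.append(accuracy(X_latent, seed))
            projected_accs.append(accuracy(raw @ projection, seed))
        assert np.mean(latent_accs) > np.mean(projected_accs)
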
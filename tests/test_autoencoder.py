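"""Autoencoder: formula exactness, gradients, training behaviour."""

import numpy as np
import pytest

from patchprint.autoencoder import (
    AutoencoderSpec,
    TrainHyperparams,
    bottleneck_sweep,
    encode,
    loss_and_grads,
    reconstruct,
    reconstruction_error,
    sigmoid,
    train_autoencoder,
)
from patchprint.autoencoder import _init_weights
from patchprint.errors import ConfigError


def sine_manifold(n=500, dim=200):
    """1-D manifold (phase circle) embedded in `dim` dimensions."""
    phases = np.linspace(0, 2 * np.pi, n, endpoint=False)
    t = np.arange(dim)
    return 0.5 + 0.4 * np.sin(2 * np.pi * t[None, :] / dim + phases[:, None])


class TestSigmoid:
    def test_zero_is_half(self):
        assert sigmoid(0.0) == 0.5

    def test_symmetry(self, rng):
        x = rng.normal(scale=5, size=100)
        assert sigmoid(x) + sigmoid(-x) == pytest.approx(np.ones(100))

    def test_monotone_towards_one(self):
        x = np.array([1.0, 5.0, 10.0, 30.0])
        y = sigmoid(x)
        assert np.all(np.diff(y) > 0) and y[-1] < 1.0 and y[-1] > 0.999999


class TestGradients:
    def test_backprop_matches_finite_differences_2_3_2(self, rng):
        spec = AutoencoderSpec((2, 3, 2))
        weights = _init_weights(spec.full_widths, rng)
        x = rng.uniform(0, 1, size=(5, 2))
        _, grads = loss_and_grads(weights, x)
        eps = 1e-6
        for li, (w, b) in enumerate(weights):
            for arr, grad in ((w, grads[li][0]), (b, grads[li][1])):
                it = np.nditer(arr, flags=["multi_index"])
                for _ in it:
                    idx = it.multi_index
                    orig = arr[idx]
                    arr[idx] = orig + eps
                    lp, _ = loss_and_grads(weights, x)
                    arr[idx] = orig - eps
                    lm, _ = loss_and_grads(weights, x)
                    arr[idx] = orig
                    fd = (lp - lm) / (2 * eps)
                    denom = max(abs(fd) + abs(grad[idx]), 1e-8)
                    assert abs(fd - grad[idx]) / denom < 1e-4


class TestReconstructionError:
    def test_matches_loop_oracle(self, rng):
        x = rng.uniform(0, 1, size=(40, 8))
        model = train_autoencoder(
            x, AutoencoderSpec((8, 4, 2)), TrainHyperparams(epochs=5, seed=0)
        )
        j = reconstruction_error(model, x)
        recon = reconstruct(model, x)
        oracle = sum(np.sum((recon[i] - x[i]) ** 2) for i in range(40)) / 40
        assert abs(j - oracle) < 1e-10
        assert j >= 0.0

    def test_single_sample_norm_two_gives_four(self):
        # J for one sample is the squared reconstruction norm
        x = np.zeros((1, 4))
        x_rec = np.full((1, 4), 1.0)  # ||x' - x|| = 2
        j = float(np.mean(np.sum((x_rec - x) ** 2, axis=1)))
        assert j == 4.0

    def test_permutation_invariant(self, rng):
        x = rng.uniform(0, 1, size=(30, 6))
        model = train_autoencoder(
            x, AutoencoderSpec((6, 4, 2)), TrainHyperparams(epochs=5, seed=0)
        )
        perm = rng.permutation(30)
        assert reconstruction_error(model, x) == pytest.approx(
            reconstruction_error(model, x[perm])
        )


class TestTraining:
    def test_sine_manifold_compresses_through_2d_bottleneck(self):
        # frozen from an oracle run of this configuration: final J ~ 0.18,
        # i.e. ~99% of the signal energy (J at init ~ 16-18) is captured
        x = sine_manifold()
        model = train_autoencoder(
            x,
            AutoencoderSpec((200, 100, 50, 2)),
            TrainHyperparams(epochs=600, seed=0, learning_rate=0.03),
        )
        assert reconstruction_error(model, x) < 0.25

    def test_final_loss_never_exceeds_initial(self, rng):
        x = rng.uniform(0, 1, size=(60, 10))
        model = train_autoencoder(
            x, AutoencoderSpec((10, 6, 2)), TrainHyperparams(epochs=10, seed=1)
        )
        assert model.training_log[-1] <= model.training_log[0]
        assert reconstruction_error(model, x) <= model.training_log[0] + 1e-12

    def test_same_seed_identical_training(self, rng):
        x = rng.uniform(0, 1, size=(50, 8))
        spec, hp = AutoencoderSpec((8, 4, 2)), TrainHyperparams(epochs=8, seed=3)
        a = train_autoencoder(x, spec, hp)
        b = train_autoencoder(x, spec, hp)
        assert a.training_log == b.training_log
        for (wa, ba), (wb, bb) in zip(a.weights, b.weights):
            assert np.array_equal(wa, wb) and np.array_equal(ba, bb)

    def test_unscaled_samples_rejected(self, rng):
        x = rng.normal(size=(20, 4)) * 10
        with pytest.raises(ConfigError):
            train_autoencoder(x, AutoencoderSpec((4, 2)))


class TestEncode:
    @pytest.fixture()
    def model(self, rng):
        x = rng.uniform(0, 1, size=(40, 8))
        return train_autoencoder(
            x, AutoencoderSpec((8, 4, 2)), TrainHyperparams(epochs=5, seed=0)
        ), x

    def test_encode_decode_equals_reconstruct(self, model):
        m, x = model
        latent = encode(m, x)
        # decoding the latent manually through the decoder layers
        from patchprint.autoencoder import _forward

        recon = _forward(m.weights[m.n_encoder_layers :], latent, m.spec.linear_output)[-1]
        assert np.allclose(recon, reconstruct(m, x))

    def test_coordinates_in_unit_interval(self, model):
        m, x = model
        latent = encode(m, x)
        assert latent.shape == (40, 2)
        assert np.all((latent > 0) & (latent < 1))

    def test_duplicated_rows_duplicated_latents(self, model):
        m, x = model
        latent = encode(m, np.vstack([x[:1], x[:1]]))
        assert np.array_equal(latent[0], latent[1])

    def test_dimension_mismatch_rejected(self, model):
        m, _ = model
        with pytest.raises(ConfigError):
            encode(m, np.zeros((3, 5)))


class TestBottleneckSweep:
    def test_wider_bottleneck_reconstructs_better(self, rng):
        # 2-D manifold in 16 dims: dim-1 bottleneck must lose information
        a = rng.uniform(0, 2 * np.pi, 200)
        b = rng.uniform(0, 2 * np.pi, 200)
        t = np.arange(16)
        x = 0.5 + 0.25 * np.sin(t[None, :] / 3 + a[:, None]) + 0.2 * np.cos(
            t[None, :] / 5 + b[:, None]
        )
        x = np.clip(x, 0, 1)
        sweep = bottleneck_sweep(
            x, [1, 4, 16], AutoencoderSpec((16, 12, 8, 2)),
            TrainHyperparams(epochs=150, seed=0, learning_rate=0.01),
        )
        js = dict(sweep)
        assert js[4] < js[1]
        assert js[16] < js[1]

    def test_empty_dims_rejected(self, rng):
        with pytest.raises(ConfigError):
            bottleneck_sweep(rng.uniform(0, 1, (10, 4)), [])
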
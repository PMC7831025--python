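"""Symmetric feed-forward autoencoder trained by minibatch gradient descent.

The encoder maps a w-dimensional sample through sigmoid layers down to a
narrow bottleneck (default widths 200 -> 100 -> 50 -> 2); the decoder
mirrors the encoder.  Training minimizes the mean reconstruction error

    J = (1/N) * sum_i || x'_i - x_i ||^2

with Adam updates from a Glorot-uniform initialization, fully deterministic
given the seed.  The implementation is plain numpy; the analytic gradient is
validated against finite differences in the test suite.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit as sigmoid_impl

from .errors import ConfigError, TrainingDivergedError


def sigmoid(x):
    """Logistic function 1 / (1 + exp(-x)); maps the reals into (0, 1)."""
    return sigmoid_impl(x)


@dataclass(frozen=True)
class AutoencoderSpec:
    """Encoder layer widths, input first and bottleneck last; the decoder is
    the mirror image.  ``linear_output`` swaps the final sigmoid for an
    identity (inputs are scaled to [0,1] either way)."""

    layer_widths: tuple[int, ...] = (200, 100, 50, 2)
    linear_output: bool = False

    def __post_init__(self) -> None:
        if len(self.layer_widths) < 2 or any(w <= 0 for w in self.layer_widths):
            raise ConfigError("layer_widths must be >= 2 strictly positive widths")

    @property
    def input_dim(self) -> int:
        return self.layer_widths[0]

    @property
    def bottleneck_dim(self) -> int:
        return self.layer_widths[-1]

    @property
    def full_widths(self) -> tuple[int, ...]:
        return self.layer_widths + self.layer_widths[-2::-1]

    def with_bottleneck(self, dim: int) -> "AutoencoderSpec":
        return AutoencoderSpec(self.layer_widths[:-1] + (dim,), self.linear_output)


@dataclass(frozen=True)
class TrainHyperparams:
    epochs: int = 200
    batch_size: int = 64
    learning_rate: float = 1e-3
    optimizer_name: str = "adam"
    seed: int = 0
    early_stop: tuple[int, float] | None = None  # (patience, min_delta)

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ConfigError("epochs, batch_size >= 1 and learning_rate > 0 required")
        if self.optimizer_name != "adam":
            raise ConfigError(f"unknown optimizer {self.optimizer_name!r}")


@dataclass
class TrainedAutoencoder:
    spec: AutoencoderSpec
    weights: list[tuple[np.ndarray, np.ndarray]]  # (W, b) per layer
    training_log: list[float]  # J at init then after each epoch
    fitted_on: str  # dataset fingerprint

    @property
    def n_encoder_layers(self) -> int:
        return len(self.spec.layer_widths) - 1


def _init_weights(widths, rng) -> list[tuple[np.ndarray, np.ndarray]]:
    weights = []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        w = rng.uniform(-limit, limit, size=(fan_in, fan_out))
        weights.append((w, np.zeros(fan_out)))
    return weights


def _forward(weights, x, linear_output):
    """Return the list of activations, input first, reconstruction last."""
    acts = [x]
    last = len(weights) - 1
    for i, (w, b) in enumerate(weights):
        z = acts[-1] @ w + b
        acts.append(z if (linear_output and i == last) else sigmoid_impl(z))
    return acts


def loss_and_grads(weights, x, linear_output=False):
    """Mean reconstruction error J and its gradient w.r.t. every parameter."""
    n = x.shape[0]
    acts = _forward(weights, x, linear_output)
    diff = acts[-1] - x
    loss = float(np.sum(diff**2) / n)
    delta = 2.0 * diff / n
    if not linear_output:
        delta = delta * acts[-1] * (1.0 - acts[-1])
    grads = [None] * len(weights)
    for i in range(len(weights) - 1, -1, -1):
        w, _ = weights[i]
        grads[i] = (acts[i].T @ delta, delta.sum(axis=0))
        if i > 0:
            delta = (delta @ w.T) * acts[i] * (1.0 - acts[i])
    return loss, grads


def reconstruction_error(model: TrainedAutoencoder, samples: np.ndarray) -> float:
    """J = mean over samples of the squared Euclidean reconstruction error."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.size == 0:
        raise ConfigError("no samples")
    recon = reconstruct(model, samples)
    return float(np.mean(np.sum((recon - samples) ** 2, axis=1)))


def encode(model: TrainedAutoencoder, samples: np.ndarray) -> np.ndarray:
    """Bottleneck activations per sample, order preserved."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[1] != model.spec.input_dim:
        raise ConfigError(
            f"sample dimension {samples.shape[1]} != input width {model.spec.input_dim}"
        )
    acts = _forward(
        model.weights[: model.n_encoder_layers], samples, linear_output=False
    )
    return acts[-1]


def reconstruct(model: TrainedAutoencoder, samples: np.ndarray) -> np.ndarray:
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[1] != model.spec.input_dim:
        raise ConfigError(
            f"sample dimension {samples.shape[1]} != input width {model.spec.input_dim}"
        )
    return _forward(model.weights, samples, model.spec.linear_output)[-1]


def _fingerprint(x: np.ndarray) -> str:
    h = hashlib.sha1()
    h.update(str(x.shape).encode())
    h.update(np.ascontiguousarray(x).tobytes())
    return h.hexdigest()[:16]


def train_autoencoder(
    samples: np.ndarray,
    spec: AutoencoderSpec | None = None,
    hyperparams: TrainHyperparams | None = None,
) -> TrainedAutoencoder:
    """Train on samples scaled to [0, 1]; deterministic given the seed.

    The training log records J on the full data at initialization and after
    every epoch; the returned weights are those of the best epoch, so the
    final logged J never exceeds the initial one.
    """
    spec = spec or AutoencoderSpec()
    hp = hyperparams or TrainHyperparams()
    x = np.atleast_2d(np.asarray(samples, dtype=float))
    if x.shape[1] != spec.input_dim:
        raise ConfigError(f"sample dimension {x.shape[1]} != input width {spec.input_dim}")
    if x.min() < -1e-9 or x.max() > 1 + 1e-9:
        raise ConfigError("samples must be scaled to [0, 1] before training")

    rng = np.random.default_rng(hp.seed)
    weights = _init_weights(spec.full_widths, rng)
    m = [(np.zeros_like(w), np.zeros_like(b)) for w, b in weights]
    v = [(np.zeros_like(w), np.zeros_like(b)) for w, b in weights]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    def full_loss(ws):
        return loss_and_grads(ws, x, spec.linear_output)[0]

    training_log = [full_loss(weights)]
    best_loss = training_log[0]
    best_weights = [(w.copy(), b.copy()) for w, b in weights]
    stall = 0
    n = x.shape[0]
    for _epoch in range(hp.epochs):
        perm = rng.permutation(n)
        for start in range(0, n, hp.batch_size):
            batch = x[perm[start : start + hp.batch_size]]
            loss, grads = loss_and_grads(weights, batch, spec.linear_output)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    "non-finite training loss",
                    diagnostics={"epoch": _epoch, "step": step, "loss": loss},
                )
            step += 1
            new_weights = []
            for i, ((w, b), (mw, mb), (vw, vb), (gw, gb)) in enumerate(
                zip(weights, m, v, grads)
            ):
                mw = beta1 * mw + (1 - beta1) * gw
                mb = beta1 * mb + (1 - beta1) * gb
                vw = beta2 * vw + (1 - beta2) * gw**2
                vb = beta2 * vb + (1 - beta2) * gb**2
                m[i] = (mw, mb)
                v[i] = (vw, vb)
                mw_hat = mw / (1 - beta1**step)
                mb_hat = mb / (1 - beta1**step)
                vw_hat = vw / (1 - beta2**step)
                vb_hat = vb / (1 - beta2**step)
                new_weights.append(
                    (
                        w - hp.learning_rate * mw_hat / (np.sqrt(vw_hat) + eps),
                        b - hp.learning_rate * mb_hat / (np.sqrt(vb_hat) + eps),
                    )
                )
            weights = new_weights
        epoch_loss = full_loss(weights)
        if not np.isfinite(epoch_loss):
            raise TrainingDivergedError(
                "non-finite epoch loss", diagnostics={"epoch": _epoch}
            )
        training_log.append(epoch_loss)
        if epoch_loss < best_loss - 1e-15:
            improved_by = best_loss - epoch_loss
            best_loss = epoch_loss
            best_weights = [(w.copy(), b.copy()) for w, b in weights]
            if hp.early_stop and improved_by < hp.early_stop[1]:
                stall += 1
            else:
                stall = 0
        elif hp.early_stop:
            stall += 1
        if hp.early_stop and stall >= hp.early_stop[0]:
            break

    if training_log[-1] != best_loss:
        training_log.append(best_loss)  # J of the restored (best-epoch) weights
    return TrainedAutoencoder(
        spec=spec,
        weights=best_weights,
        training_log=training_log,
        fitted_on=_fingerprint(x),
    )


def bottleneck_sweep(
    samples: np.ndarray,
    dims: list[int],
    spec: AutoencoderSpec | None = None,
    hyperparams: TrainHyperparams | None = None,
) -> list[tuple[int, float]]:
    """Final reconstruction error as a function of the bottleneck width.

    One model is trained independently per dimension with the same seed
    schedule; returns (dim, J) pairs in the order given.
    """
    if not dims:
        raise ConfigError("dims must be nonempty")
    spec = spec or AutoencoderSpec()
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    out = []
    for dim in dims:
        model = train_autoencoder(samples, spec.with_bottleneck(dim), hyperparams)
        out.append((dim, reconstruction_error(model, samples)))
    return out
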
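"""Stepwise bottleneck autoencoder for 20-dimensional column profiles.

The network is a symmetric, untied encoder/decoder pair (default
20-15-10-5-2).  Every hidden layer — the bottleneck included — is
affine -> batch normalization -> sigmoid; the 20-unit output layer is
affine -> sigmoid so reconstructions live in (0, 1) and binary
cross-entropy against the fraction vector is well-defined.  Because the
bottleneck is very narrow, training is greedy layerwise pretraining (each
encoder/decoder layer pair trained as a shallow autoencoder on the codes
of the previous depth) followed by end-to-end fine-tuning, with Adam.

Implemented directly on NumPy: explicit forward/backward passes, which
keeps training bit-reproducible for a fixed seed and data order.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1
_CLAMP = 1e-7
MODEL_FORMAT_VERSION = "evcoder-model-1"


class ModelFormatError(ValueError):
    """Raised when a model file is corrupted or of an unknown version."""


class UntrainedModelError(RuntimeError):
    """Raised when inference is requested from a model that was never trained."""


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class AutoencoderConfig:
    """Architecture and optimization settings.

    ``layer_sizes`` are the encoder sizes from the 20-dimensional input down
    to the bottleneck; the decoder mirrors them in reverse.  Defaults follow
    the reference recipe: layers 20-15-10-5-2, Adam with learning rate 1e-3,
    batch size 128.  Epoch counts are modest desk-scale defaults.  ``mode``
    records whether the model was trained on sorted (variability-pattern) or
    fixed-order (residue-identity) profiles.
    """

    layer_sizes: tuple[int, ...] = (20, 15, 10, 5, 2)
    learning_rate: float = 1e-3
    batch_size: int = 128
    pretrain_epochs: int = 20
    finetune_epochs: int = 50
    seed: int = 0
    shuffle: bool = True
    mode: str = "sorted"

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.layer_sizes)
        object.__setattr__(self, "layer_sizes", sizes)
        if len(sizes) < 2:
            raise ValueError("layer_sizes needs at least input and bottleneck")
        if sizes[0] != 20:
            raise ValueError("first layer size must be 20 (amino-acid fractions)")
        if any(a <= b for a, b in zip(sizes, sizes[1:])):
            raise ValueError("layer_sizes must be strictly decreasing")
        if sizes[-1] < 1:
            raise ValueError("bottleneck width must be >= 1")
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("learning_rate must be > 0 and batch_size >= 1")
        if self.pretrain_epochs < 1 or self.finetune_epochs < 0:
            raise ValueError("epoch counts must be positive")
        if self.mode not in ("sorted", "fixed"):
            raise ValueError("mode must be 'sorted' or 'fixed'")

    @property
    def bottleneck(self) -> int:
        return self.layer_sizes[-1]


def _sigmoid(y: np.ndarray) -> np.ndarray:
    out = np.empty_like(y)
    pos = y >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-y[pos]))
    ey = np.exp(y[~pos])
    out[~pos] = ey / (1.0 + ey)
    return out


def bce_loss(target: np.ndarray, reconstruction: np.ndarray) -> float:
    """Mean binary cross-entropy between a profile and its reconstruction.

    ``-[t ln r + (1-t) ln(1-r)]`` averaged over the 20 elements and, for
    batches, over rows.  Reconstructions are clamped 1e-7 away from {0, 1}.
    """
    t = np.asarray(target, dtype=float)
    r = np.asarray(reconstruction, dtype=float)
    if t.shape != r.shape:
        raise ValueError(f"shape mismatch: target {t.shape} vs reconstruction {r.shape}")
    r = np.clip(r, _CLAMP, 1.0 - _CLAMP)
    return float(np.mean(-(t * np.log(r) + (1.0 - t) * np.log1p(-r))))


class _Layer:
    """Affine [-> batchnorm] -> sigmoid unit with explicit backward pass."""

    def __init__(self, n_in: int, n_out: int, batchnorm: bool,
                 rng: np.random.Generator) -> None:
        limit = 1.0 / math.sqrt(n_in)
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.batchnorm = batchnorm
        if batchnorm:
            self.gamma = np.ones(n_out)
            self.beta = np.zeros(n_out)
            self.running_mean = np.zeros(n_out)
            self.running_var = np.ones(n_out)
        self._cache: dict | None = None

    @property
    def n_in(self) -> int:
        return self.W.shape[0]

    @property
    def n_out(self) -> int:
        return self.W.shape[1]

    def params(self) -> list[np.ndarray]:
        ps = [self.W, self.b]
        if self.batchnorm:
            ps += [self.gamma, self.beta]
        return ps

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        z = x @ self.W + self.b
        if self.batchnorm:
            if training:
                mu = z.mean(axis=0)
                var = z.var(axis=0)
                self.running_mean = (1 - _BN_MOMENTUM) * self.running_mean + _BN_MOMENTUM * mu
                self.running_var = (1 - _BN_MOMENTUM) * self.running_var + _BN_MOMENTUM * var
            else:
                mu = self.running_mean
                var = self.running_var
            inv_std = 1.0 / np.sqrt(var + _BN_EPS)
            xhat = (z - mu) * inv_std
            y = self.gamma * xhat + self.beta
        else:
            xhat = None
            inv_std = None
            y = z
        a = _sigmoid(y)
        if training:
            self._cache = {"x": x, "xhat": xhat, "inv_std": inv_std, "a": a}
        return a

    def backward_from_preact(self, dy: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Backprop given dL/dy at the pre-sigmoid unit; returns dL/dx, grads."""
        cache = self._cache
        if cache is None:
            raise RuntimeError("backward called before a training-mode forward")
        grads: list[np.ndarray] = []
        if self.batchnorm:
            xhat, inv_std = cache["xhat"], cache["inv_std"]
            n = dy.shape[0]
            dgamma = (dy * xhat).sum(axis=0)
            dbeta = dy.sum(axis=0)
            dz = (self.gamma * inv_std / n) * (n * dy - dbeta - xhat * dgamma)
        else:
            dz = dy
        dW = cache["x"].T @ dz
        db = dz.sum(axis=0)
        dx = dz @ self.W.T
        grads = [dW, db] + ([dgamma, dbeta] if self.batchnorm else [])
        return dx, grads

    def backward(self, da: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        a = self._cache["a"] if self._cache else None
        if a is None:
            raise RuntimeError("backward called before a training-mode forward")
        dy = da * a * (1.0 - a)
        return self.backward_from_preact(dy)

    def state(self) -> dict:
        d = {
            "n_in": self.n_in, "n_out": self.n_out, "batchnorm": self.batchnorm,
            "W": self.W.tolist(), "b": self.b.tolist(),
        }
        if self.batchnorm:
            d.update(
                gamma=self.gamma.tolist(), beta=self.beta.tolist(),
                running_mean=self.running_mean.tolist(),
                running_var=self.running_var.tolist(),
            )
        return d

    @classmethod
    def from_state(cls, d: dict) -> "_Layer":
        layer = cls.__new__(cls)
        layer.W = np.asarray(d["W"], dtype=float)
        layer.b = np.asarray(d["b"], dtype=float)
        layer.batchnorm = bool(d["batchnorm"])
        if layer.batchnorm:
            layer.gamma = np.asarray(d["gamma"], dtype=float)
            layer.beta = np.asarray(d["beta"], dtype=float)
            layer.running_mean = np.asarray(d["running_mean"], dtype=float)
            layer.running_var = np.asarray(d["running_var"], dtype=float)
        layer._cache = None
        if layer.W.shape != (d["n_in"], d["n_out"]):
            raise ModelFormatError("layer weight shape does not match header")
        return layer


class _Adam:
    """Adam with the conventional beta/epsilon defaults."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def _forward_stack(layers: Sequence[_Layer], x: np.ndarray, training: bool) -> np.ndarray:
    for layer in layers:
        x = layer.forward(x, training)
    return x


def _train_step(layers: Sequence[_Layer], opt: _Adam,
                xb: np.ndarray, tb: np.ndarray) -> float:
    r = _forward_stack(layers, xb, training=True)
    loss = bce_loss(tb, r)
    # d(mean BCE)/d(final pre-sigmoid) has the compact sigmoid-BCE form.
    dy = (r - tb) / r.size
    dx, grads = layers[-1].backward_from_preact(dy)
    all_grads = [grads]
    for layer in reversed(layers[:-1]):
        dx, grads = layer.backward(dx)
        all_grads.append(grads)
    flat = [g for grads in reversed(all_grads) for g in grads]
    opt.step(flat)
    return loss


def _run_epochs(layers: Sequence[_Layer], data: np.ndarray, target_is_input: bool,
                config: AutoencoderConfig, epochs: int,
                shuffle_rng: np.random.Generator) -> list[float]:
    params = [p for layer in layers for p in layer.params()]
    opt = _Adam(params, lr=config.learning_rate)
    n = data.shape[0]
    history: list[float] = []
    for _ in range(epochs):
        order = shuffle_rng.permutation(n) if config.shuffle else np.arange(n)
        losses = []
        for start in range(0, n, config.batch_size):
            batch = data[order[start:start + config.batch_size]]
            losses.append(_train_step(layers, opt, batch, batch))
        epoch_loss = float(np.mean(losses))
        if not math.isfinite(epoch_loss):
            raise TrainingDivergedError(f"training loss became {epoch_loss}")
        history.append(epoch_loss)
    return history


class TrainedAutoencoder:
    """Encoder/decoder stacks with frozen normalization statistics.

    ``encode`` and ``reconstruct`` run in inference mode (running batch-norm
    statistics), so they are deterministic and batch-size independent.
    """

    def __init__(self, encoder: list[_Layer], decoder: list[_Layer],
                 config: AutoencoderConfig, loss_history: dict | None = None,
                 trained: bool = False) -> None:
        if [l.n_out for l in decoder] != [l.n_in for l in encoder][::-1]:
            raise ValueError("decoder must mirror encoder layer sizes in reverse")
        self.encoder = encoder
        self.decoder = decoder
        self.config = config
        self.loss_history = loss_history or {}
        self.trained = trained

    # -- inference ---------------------------------------------------------
    def _require_trained(self, allow_untrained: bool) -> None:
        if not self.trained and not allow_untrained:
            raise UntrainedModelError(
                "model has not been trained; pass allow_untrained=True to "
                "run inference with the initial random parameters"
            )

    def encode(self, X: np.ndarray, allow_untrained: bool = False) -> np.ndarray:
        """Bottleneck activations, shape (n, bottleneck), values in (0, 1)."""
        self._require_trained(allow_untrained)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return _forward_stack(self.encoder, X, training=False)

    def reconstruct(self, X: np.ndarray, allow_untrained: bool = False) -> np.ndarray:
        """Decoder output for each input profile, values strictly in (0, 1)."""
        self._require_trained(allow_untrained)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        code = _forward_stack(self.encoder, X, training=False)
        return _forward_stack(self.decoder, code, training=False)

    def parameter_count(self) -> int:
        return sum(p.size for layer in self.encoder + self.decoder
                   for p in layer.params())

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "config": asdict(self.config),
            "trained": self.trained,
            "loss_history": self.loss_history,
            "encoder": [l.state() for l in self.encoder],
            "decoder": [l.state() for l in self.decoder],
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "TrainedAutoencoder":
        try:
            payload = json.loads(Path(path).read_text(encoding="utf-8"))
        except (json.JSONDecodeError, UnicodeDecodeError) as exc:
            raise ModelFormatError(f"{path}: not a valid model file: {exc}") from exc
        if not isinstance(payload, dict) or "format_version" not in payload:
            raise ModelFormatError(f"{path}: missing format version")
        if payload["format_version"] != MODEL_FORMAT_VERSION:
            raise ModelFormatError(
                f"{path}: unsupported model format {payload['format_version']!r}, "
                f"expected {MODEL_FORMAT_VERSION!r}"
            )
        try:
            cfg_dict = dict(payload["config"])
            cfg_dict["layer_sizes"] = tuple(cfg_dict["layer_sizes"])
            config = AutoencoderConfig(**cfg_dict)
            encoder = [_Layer.from_state(d) for d in payload["encoder"]]
            decoder = [_Layer.from_state(d) for d in payload["decoder"]]
        except (KeyError, TypeError, ValueError) as exc:
            raise ModelFormatError(f"{path}: corrupted model payload: {exc}") from exc
        return cls(encoder, decoder, config,
                   loss_history=payload.get("loss_history", {}),
                   trained=bool(payload.get("trained", False)))


def init_network(config: AutoencoderConfig) -> TrainedAutoencoder:
    """Reproducibly initialized, untrained network for ``config``.

    Weights are uniform with fan-in scaling from ``config.seed``; batch-norm
    statistics start at identity (mean 0, variance 1).
    """
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    sizes = config.layer_sizes
    encoder = [_Layer(sizes[k], sizes[k + 1], batchnorm=True, rng=rng)
               for k in range(len(sizes) - 1)]
    # Decoder hidden layers are batch-normalized; the final 20-unit output
    # layer is plain affine -> sigmoid (it is not a hidden layer).
    decoder = [_Layer(sizes[k + 1], sizes[k], batchnorm=(k > 0), rng=rng)
               for k in reversed(range(len(sizes) - 1))]
    return TrainedAutoencoder(encoder, decoder, config)


def pretrain_layerwise(
    data: np.ndarray, config: AutoencoderConfig
) -> tuple[list[tuple[_Layer, _Layer]], list[list[float]]]:
    """Greedy layerwise pretraining of every encoder/decoder layer pair.

    Stage k trains the shallow autoencoder (encoder layer k, its mirrored
    decoder layer) on the depth k-1 codes (the raw profiles for k = 1),
    minimizing BCE; the pair is then frozen and depth-k codes are computed
    in inference mode for the next stage.  Codes are sigmoid outputs, so
    BCE stays well-defined at every stage.

    Returns the layer pairs (outermost first) and per-stage loss histories.
    """
    X = np.atleast_2d(np.asarray(data, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("empty training data")
    if X.shape[1] != config.layer_sizes[0]:
        raise ValueError(f"data dimension {X.shape[1]} != input size "
                         f"{config.layer_sizes[0]}")
    ss = np.random.SeedSequence(config.seed)
    init_ss, shuffle_ss = ss.spawn(2)
    init_rng = np.random.default_rng(init_ss)
    shuffle_rng = np.random.default_rng(shuffle_ss)
    sizes = config.layer_sizes
    pairs: list[tuple[_Layer, _Layer]] = []
    histories: list[list[float]] = []
    codes = X
    for k in range(len(sizes) - 1):
        enc = _Layer(sizes[k], sizes[k + 1], batchnorm=True, rng=init_rng)
        dec = _Layer(sizes[k + 1], sizes[k], batchnorm=(k > 0), rng=init_rng)
        history = _run_epochs([enc, dec], codes, True, config,
                              config.pretrain_epochs, shuffle_rng)
        pairs.append((enc, dec))
        histories.append(history)
        codes = enc.forward(codes, training=False)
    return pairs, histories


def finetune(
    pairs: list[tuple[_Layer, _Layer]],
    data: np.ndarray,
    config: AutoencoderConfig,
    pretrain_histories: list[list[float]] | None = None,
) -> TrainedAutoencoder:
    """Joint end-to-end fine-tuning of the assembled pretrained stack."""
    X = np.atleast_2d(np.asarray(data, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("empty training data")
    encoder = [enc for enc, _ in pairs]
    decoder = [dec for _, dec in reversed(pairs)]
    model = TrainedAutoencoder(encoder, decoder, config)
    initial_loss = bce_loss(X, model.reconstruct(X, allow_untrained=True))
    ss = np.random.SeedSequence(config.seed)
    _, _, finetune_ss = ss.spawn(3)
    shuffle_rng = np.random.default_rng(finetune_ss)
    layers = encoder + decoder
    history = _run_epochs(layers, X, True, config, config.finetune_epochs,
                          shuffle_rng)
    final_loss = bce_loss(X, model.reconstruct(X, allow_untrained=True))
    model.loss_history = {
        "pretrain": pretrain_histories or [],
        "initial_finetune_loss": initial_loss,
        "finetune": history,
        "final_loss": final_loss,
    }
    model.trained = True
    return model


def train_autoencoder(data: np.ndarray,
                      config: AutoencoderConfig | None = None) -> TrainedAutoencoder:
    """Full training recipe: greedy layerwise pretraining then fine-tuning."""
    config = config or AutoencoderConfig()
    pairs, histories = pretrain_layerwise(data, config)
    return finetune(pairs, data, config, pretrain_histories=histories)
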
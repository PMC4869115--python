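"""Stacked denoising autoencoders for patient representation learning.

Each layer is a sigmoid autoencoder with tied weights: the encoder maps an
input x in [0,1]^d to a code y = sigmoid(W x + b), the decoder maps back to
a reconstruction z = sigmoid(W' y + b') with the decoder weight constrained
to the transpose of the encoder's.  During training the encoder input is a
corrupted copy of x in which a fraction nu of the coordinates, chosen
uniformly at random, is masked to zero — emulating clinical facts missing
from a record — while the reconstruction loss, the cross-entropy

    L_H(x, z) = - sum_d [ x_d log z_d + (1 - x_d) log(1 - z_d) ],

is always taken against the *clean* x, so the network is trained to fill in
the artificial blanks.  Layers are trained greedily: layer k sees the clean
(uncorrupted) codes of layer k-1, and corruption happens only inside each
layer's own training loop.  Optimization is plain mini-batch SGD.

The final representation of a patient is the top layer's code, obtained by
composing the encoders.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import scipy.sparse as sp
from scipy.special import expit
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted


@dataclass
class AutoencoderLayer:
    """One denoising autoencoder: encoder (W, b), tied decoder (W^T, b')."""

    W: np.ndarray
    b: np.ndarray
    b_prime: np.ndarray
    activation: str = "sigmoid"

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.b_prime = np.asarray(self.b_prime, dtype=float)
        if self.W.ndim != 2:
            raise ValueError("W must be 2-D (d_hidden, d_in)")
        if self.b.shape != (self.W.shape[0],):
            raise ValueError("b must have length d_hidden")
        if self.b_prime.shape != (self.W.shape[1],):
            raise ValueError("b_prime must have length d_in")
        if self.activation != "sigmoid":
            raise ValueError(f"unsupported activation {self.activation!r}")
        for name, arr in (("W", self.W), ("b", self.b), ("b_prime", self.b_prime)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {name}")

    @property
    def d_in(self) -> int:
        return self.W.shape[1]

    @property
    def d_hidden(self) -> int:
        return self.W.shape[0]


@dataclass
class SDAModel:
    """An ordered stack of autoencoder layers; transform composes encoders."""

    layers: list[AutoencoderLayer]
    input_dim: int

    def __post_init__(self) -> None:
        d = self.input_dim
        for i, layer in enumerate(self.layers):
            if layer.d_in != d:
                raise ValueError(
                    f"layer {i} expects input dim {layer.d_in}, chain gives {d}"
                )
            d = layer.d_hidden

    @property
    def output_dim(self) -> int:
        return self.layers[-1].d_hidden if self.layers else self.input_dim

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = _as_dense(X)
        if X.shape[1] != self.input_dim:
            raise ValueError(
                f"expected {self.input_dim} input columns, got {X.shape[1]}"
            )
        H = X
        for layer in self.layers:
            H = encode(layer, H)
        return H


@dataclass
class TrainConfig:
    """Hyperparameters shared by every autoencoder in the stack.

    ``hidden_units`` and ``n_layers`` set the architecture; ``corruption``
    is the masking-noise fraction nu.  ``learning_rate``, ``batch_size`` and
    ``n_epochs`` govern the mini-batch SGD loop.  ``masking="exact"`` zeroes
    exactly round(nu*d) coordinates per example without replacement;
    ``"bernoulli"`` masks each coordinate independently with probability nu.
    """

    n_layers: int = 3
    hidden_units: int = 500
    corruption: float = 0.05
    learning_rate: float = 0.1
    batch_size: int = 32
    n_epochs: int = 30
    masking: str = "exact"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers < 0:
            raise ValueError("n_layers must be >= 0")
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if not 0.0 <= self.corruption <= 1.0:
            raise ValueError("corruption must lie in [0, 1]")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1 or self.n_epochs < 1:
            raise ValueError("batch_size and n_epochs must be positive")
        if self.masking not in ("exact", "bernoulli"):
            raise ValueError("masking must be 'exact' or 'bernoulli'")


def _as_dense(X) -> np.ndarray:
    if sp.issparse(X):
        X = X.toarray()
    return np.asarray(X, dtype=float)


def mask_corrupt(
    x: np.ndarray,
    nu: float,
    rng: np.random.Generator,
    masking: str = "exact",
) -> np.ndarray:
    """Masking-noise corruption q_D: zero a random fraction nu of coordinates.

    With ``masking="exact"`` (default), exactly ``round(nu * d)`` coordinates
    per example, sampled uniformly without replacement, are set to zero;
    with ``"bernoulli"`` each coordinate is zeroed independently with
    probability nu.  Accepts a vector or a matrix (rows corrupted
    independently) and never modifies its input.
    """
    if not 0.0 <= nu <= 1.0:
        raise ValueError("corruption fraction nu must lie in [0, 1]")
    x = np.array(x, dtype=float, copy=True)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.ndim != 2:
        raise ValueError("input must be a vector or a matrix")
    n, d = X.shape
    if d < 1:
        raise ValueError("input must have at least one coordinate")
    if masking == "bernoulli":
        X[rng.random(X.shape) < nu] = 0.0
    elif masking == "exact":
        m = int(round(nu * d))
        if m > 0:
            # the m smallest of d iid uniforms per row = a uniform m-subset
            u = rng.random((n, d))
            idx = np.argpartition(u, m - 1, axis=1)[:, :m]
            np.put_along_axis(X, idx, 0.0, axis=1)
    else:
        raise ValueError("masking must be 'exact' or 'bernoulli'")
    return X[0] if single else X


def encode(layer: AutoencoderLayer, x: np.ndarray) -> np.ndarray:
    """Encoder mapping y = sigmoid(W x + b); accepts a vector or row matrix."""
    x = _as_dense(x)
    if x.shape[-1] != layer.d_in:
        raise ValueError(f"expected input dim {layer.d_in}, got {x.shape[-1]}")
    return expit(x @ layer.W.T + layer.b)


def decode(layer: AutoencoderLayer, y: np.ndarray) -> np.ndarray:
    """Tied-weight decoder mapping z = sigmoid(W^T y + b')."""
    y = _as_dense(y)
    if y.shape[-1] != layer.d_hidden:
        raise ValueError(f"expected code dim {layer.d_hidden}, got {y.shape[-1]}")
    return expit(y @ layer.W + layer.b_prime)


def cross_entropy(x: np.ndarray, z: np.ndarray) -> float | np.ndarray:
    """Reconstruction cross-entropy L_H(x, z), summed over coordinates.

    For matrices, returns one value per row.  ``z`` must lie strictly inside
    (0, 1): the decoder guarantees this, and values touching the boundary
    would make the loss infinite.
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if x.shape != z.shape:
        raise ValueError("x and z must have matching shapes")
    if np.any(z <= 0.0) or np.any(z >= 1.0):
        raise ValueError("reconstruction z must lie strictly inside (0, 1)")
    if np.any(x < 0.0) or np.any(x > 1.0):
        raise ValueError("input x must lie in [0, 1]")
    return -np.sum(x * np.log(z) + (1.0 - x) * np.log1p(-z), axis=-1)


def _loss_from_preactivation(x: np.ndarray, z_pre: np.ndarray) -> np.ndarray:
    # L_H(x, sigmoid(a)) = sum softplus(a) - x * a ; stable for saturated a
    return np.sum(np.logaddexp(0.0, z_pre) - x * z_pre, axis=-1)


class LayerGradients(NamedTuple):
    W: np.ndarray
    b: np.ndarray
    b_prime: np.ndarray
    loss: float


def layer_gradients(
    layer: AutoencoderLayer,
    x_batch: np.ndarray,
    nu: float | None = None,
    rng: np.random.Generator | None = None,
    corrupted: np.ndarray | None = None,
    masking: str = "exact",
) -> LayerGradients:
    """Gradients of the mean reconstruction cross-entropy over a batch.

    The encoder sees the corrupted batch, the loss compares the
    reconstruction to the clean batch.  The tied weight receives the sum of
    the encoder-path and decoder-path partials.  Pass ``corrupted``
    explicitly for a deterministic corruption (e.g. finite-difference
    checks); otherwise it is drawn from ``rng`` with fraction ``nu``.
    Returns the gradients and the mean batch loss.
    """
    X = _as_dense(x_batch)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("x_batch must be a non-empty 2-D array")
    if corrupted is None:
        if nu is None or rng is None:
            raise ValueError("provide either `corrupted` or both `nu` and `rng`")
        corrupted = mask_corrupt(X, nu, rng, masking)
    Xc = _as_dense(corrupted)
    if Xc.shape != X.shape:
        raise ValueError("corrupted batch shape must match the clean batch")

    n = X.shape[0]
    Y = expit(Xc @ layer.W.T + layer.b)  # (n, h)
    z_pre = Y @ layer.W + layer.b_prime  # (n, d)
    Z = expit(z_pre)
    loss = float(np.mean(_loss_from_preactivation(X, z_pre)))

    dZ = (Z - X) / n  # dL/dz_pre, mean over batch
    g_b_prime = dZ.sum(axis=0)
    gW_dec = Y.T @ dZ  # decoder-path partial for W (h, d)
    dY = dZ @ layer.W.T  # back through the tied decoder
    dY_pre = dY * Y * (1.0 - Y)
    g_b = dY_pre.sum(axis=0)
    gW_enc = dY_pre.T @ Xc  # encoder-path partial (h, d)
    return LayerGradients(gW_enc + gW_dec, g_b, g_b_prime, loss)


def _init_layer(d_in: int, d_hidden: int, rng: np.random.Generator) -> AutoencoderLayer:
    # classical sigmoid-net heuristic: U(+-4 * sqrt(6 / (fan_in + fan_out)))
    limit = 4.0 * np.sqrt(6.0 / (d_in + d_hidden))
    W = rng.uniform(-limit, limit, size=(d_hidden, d_in))
    return AutoencoderLayer(W, np.zeros(d_hidden), np.zeros(d_in))


def train_layer(
    X: np.ndarray,
    config: TrainConfig,
    rng: np.random.Generator | None = None,
    d_hidden: int | None = None,
) -> tuple[AutoencoderLayer, list[float]]:
    """Train one denoising autoencoder by mini-batch SGD.

    Rows are reshuffled every epoch; each batch is corrupted independently,
    and parameters move against the gradient of the mean batch loss.
    Returns the trained layer and the per-epoch mean training loss (the
    cross-entropy of reconstructions against the clean inputs).
    """
    X = _as_dense(X)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("training matrix must be non-empty and 2-D")
    if X.min() < 0.0 or X.max() > 1.0:
        raise ValueError("training rows must lie in [0, 1]; scale the matrix first")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if d_hidden is None:
        d_hidden = config.hidden_units

    n, d = X.shape
    layer = _init_layer(d, d_hidden, rng)
    eta = config.learning_rate
    trace: list[float] = []
    for epoch in range(config.n_epochs):
        perm = rng.permutation(n)
        total, seen = 0.0, 0
        for start in range(0, n, config.batch_size):
            batch = X[perm[start : start + config.batch_size]]
            grads = layer_gradients(
                layer, batch, nu=config.corruption, rng=rng, masking=config.masking
            )
            if not np.isfinite(grads.loss):
                raise ValueError(
                    f"non-finite loss at epoch {epoch}, batch {start // config.batch_size}"
                )
            layer.W -= eta * grads.W
            layer.b -= eta * grads.b
            layer.b_prime -= eta * grads.b_prime
            total += grads.loss * batch.shape[0]
            seen += batch.shape[0]
        trace.append(total / seen)
    return layer, trace


def fit_stack(X: np.ndarray, config: TrainConfig) -> tuple[SDAModel, list[list[float]]]:
    """Greedy layer-wise training of the full stack.

    Layer k trains (with its own corruption) on the clean codes of layer
    k-1; no corruption is applied at the interface between layers.  All
    layers share the same hyperparameters.
    """
    X = _as_dense(X)
    seeds = np.random.SeedSequence(config.seed).spawn(max(config.n_layers, 1))
    layers: list[AutoencoderLayer] = []
    traces: list[list[float]] = []
    H = X
    for k in range(config.n_layers):
        rng = np.random.default_rng(seeds[k])
        layer, trace = train_layer(H, config, rng=rng)
        layers.append(layer)
        traces.append(trace)
        H = encode(layer, H)  # clean codes feed the next layer
    return SDAModel(layers, input_dim=X.shape[1]), traces


class StackedDenoisingAutoencoder(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer wrapping the greedy SDA trainer.

    Parameters mirror :class:`TrainConfig`; ``fit`` expects a matrix scaled
    to [0, 1] and ``transform`` returns the top-layer codes (one dense
    vector per patient, entries in (0, 1)).

    Attributes
    ----------
    model_ : SDAModel
        The trained stack.
    loss_traces_ : list of list of float
        Per-layer, per-epoch mean training loss.
    """

    def __init__(
        self,
        n_layers: int = 3,
        hidden_units: int = 500,
        corruption: float = 0.05,
        learning_rate: float = 0.1,
        batch_size: int = 32,
        n_epochs: int = 30,
        masking: str = "exact",
        random_state: int = 0,
    ):
        self.n_layers = n_layers
        self.hidden_units = hidden_units
        self.corruption = corruption
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.n_epochs = n_epochs
        self.masking = masking
        self.random_state = random_state

    def _config(self) -> TrainConfig:
        return TrainConfig(
            n_layers=self.n_layers,
            hidden_units=self.hidden_units,
            corruption=self.corruption,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            n_epochs=self.n_epochs,
            masking=self.masking,
            seed=self.random_state,
        )

    def fit(self, X, y=None):
        X = check_array(X, accept_sparse="csr")
        self.model_, self.loss_traces_ = fit_stack(X, self._config())
        self.n_features_in_ = self.model_.input_dim
        return self

    def transform(self, X):
        check_is_fitted(self, "model_")
        X = check_array(X, accept_sparse="csr")
        return self.model_.transform(X)


# ---------------------------------------------------------------------------
# serialization: a directory of per-layer .npy arrays plus JSON metadata


def save_sda(model: SDAModel, directory, config: TrainConfig | None = None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "kind": "sda",
        "input_dim": model.input_dim,
        "n_layers": len(model.layers),
        "dims": [layer.d_hidden for layer in model.layers],
        "activation": "sigmoid",
        "config": None if config is None else vars(config).copy(),
    }
    for i, layer in enumerate(model.layers):
        np.save(directory / f"layer{i}_W.npy", layer.W)
        np.save(directory / f"layer{i}_b.npy", layer.b)
        np.save(directory / f"layer{i}_b_prime.npy", layer.b_prime)
    (directory / "model.json").write_text(json.dumps(meta, indent=2))


def load_sda(directory) -> SDAModel:
    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    if meta.get("kind") != "sda":
        raise ValueError(f"{directory} does not contain an SDA model")
    layers = [
        AutoencoderLayer(
            np.load(directory / f"layer{i}_W.npy"),
            np.load(directory / f"layer{i}_b.npy"),
            np.load(directory / f"layer{i}_b_prime.npy"),
        )
        for i in range(meta["n_layers"])
    ]
    return SDAModel(layers, input_dim=meta["input_dim"])
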
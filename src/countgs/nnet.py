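"""Multi-trait Poisson deep neural network (and its univariate reduction).

A fully connected feedforward network maps the predictor vector through
ReLU hidden layers to T outputs with an exponential output activation, so
every predicted value is a strictly positive Poisson rate:

    V^(1) = relu(W^(1) x + b^(1)),  ...,  y_hat_t = exp(w_t . V^(L) + b_t).

The loss is the mean (over observations) of the per-trait Poisson negative
log-likelihoods, mu - y log mu, summed over traits, plus an optional L1
penalty on the weight matrices (biases unpenalized).  With T = 1 the same
computation is the univariate Poisson deep network — the multivariate model
reduces to it exactly.

Everything here is plain numpy: forward pass, manual backpropagation, Adam,
inverted dropout and early stopping, all deterministic given a seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_NET_INPUT_CLIP = 30.0  # training-time guard on the output layer's net input


class DomainError(ValueError):
    pass


@dataclass
class NetworkSpec:
    """Topology of a Poisson deep network.

    ``units`` may be a single int (shared across hidden layers, as in the
    tuning grids) or one count per hidden layer.  Hidden activation is ReLU,
    output activation is exponential; both are fixed by the model family.
    """

    n_hidden: int
    units: int | tuple
    n_outputs: int
    dropout_rate: float = 0.0
    l1_lambda: float = 0.0

    def __post_init__(self):
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if np.isscalar(self.units):
            self.units = (int(self.units),) * self.n_hidden
        else:
            self.units = tuple(int(u) for u in self.units)
        if len(self.units) != self.n_hidden:
            raise ValueError("need one unit count per hidden layer")
        if any(u < 1 for u in self.units):
            raise ValueError("every hidden layer needs >= 1 unit")
        if self.n_outputs < 1:
            raise ValueError("n_outputs must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.l1_lambda < 0:
            raise ValueError("l1_lambda must be >= 0")

    def layer_sizes(self, d_input: int):
        return (d_input, *self.units, self.n_outputs)


@dataclass
class NetworkParams:
    """Weights and biases per layer; shapes chain input -> units -> T."""

    weights: list  # weights[l]: (fan_in, fan_out)
    biases: list  # biases[l]: (fan_out,)

    def copy(self) -> "NetworkParams":
        return NetworkParams([w.copy() for w in self.weights], [b.copy() for b in self.biases])

    def check_finite(self):
        for arr in (*self.weights, *self.biases):
            if not np.all(np.isfinite(arr)):
                raise DomainError("non-finite network parameters")

    def l1_weight_norm(self) -> float:
        return float(sum(np.abs(w).sum() for w in self.weights))

    def flat(self) -> np.ndarray:
        return np.concatenate([a.ravel() for a in (*self.weights, *self.biases)])


@dataclass
class TrainConfig:
    """Optimization settings: Adam with mini-batches and early stopping."""

    batch_size: int = 32
    learning_rate: float = 0.001
    max_epochs: int = 1000
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-7
    early_stopping_patience: int = 50
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in (0, 1)")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")


def init_params(spec: NetworkSpec, d_input: int, seed: int = 0) -> NetworkParams:
    """Glorot-uniform weights, zero biases; deterministic given the seed."""
    rng = np.random.default_rng(seed)
    sizes = spec.layer_sizes(d_input)
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return NetworkParams(weights, biases)


def _forward_hidden(spec, params, X, dropout_masks=None, clip=False):
    """Hidden activations and the output layer's net input."""
    A = np.asarray(X, dtype=float)
    hidden = []
    for l in range(spec.n_hidden):
        Z = A @ params.weights[l] + params.biases[l]
        A = np.maximum(Z, 0.0)
        if dropout_masks is not None:
            A = A * dropout_masks[l]
        hidden.append(A)
    Z_out = A @ params.weights[-1] + params.biases[-1]
    if clip:
        clipped = Z_out > _NET_INPUT_CLIP
        if clipped.any():
            warnings.warn("output net input clipped at 30 during training")
        Z_out = np.minimum(Z_out, _NET_INPUT_CLIP)
    else:
        clipped = None
    return hidden, Z_out, clipped


def forward(spec: NetworkSpec, params: NetworkParams, X) -> np.ndarray:
    """Predicted rate matrix (n x T); inference mode (no dropout)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    sizes = spec.layer_sizes(X.shape[1])
    for l, w in enumerate(params.weights):
        if w.shape != (sizes[l], sizes[l + 1]):
            raise DomainError(
                f"layer {l} weights {w.shape} incompatible with sizes {sizes}"
            )
    _, Z_out, _ = _forward_hidden(spec, params, X)
    return np.exp(Z_out)


def mpdn_loss(Y, Yhat, params: NetworkParams | None = None, l1_lambda: float = 0.0) -> float:
    """Mean summed-over-traits Poisson NLL plus L1 on the weight matrices."""
    Y = np.asarray(Y, dtype=float)
    Yhat = np.asarray(Yhat, dtype=float)
    if Y.shape != Yhat.shape:
        raise DomainError(f"shape mismatch: Y {Y.shape} vs Yhat {Yhat.shape}")
    if np.any(Yhat <= 0):
        raise DomainError("predicted rates must be strictly positive")
    with np.errstate(over="ignore", invalid="ignore"):
        nll = float(np.mean(np.sum(Yhat - Y * np.log(Yhat), axis=1)))
    if l1_lambda > 0 and params is not None:
        nll += l1_lambda * params.l1_weight_norm()
    return nll


def gradients(
    spec: NetworkSpec,
    params: NetworkParams,
    X,
    Y,
    l1_lambda: float = 0.0,
    dropout_masks=None,
    clip: bool = False,
):
    """Backpropagated gradients of :func:`mpdn_loss` for one batch.

    Returns a :class:`NetworkParams` holding d(loss)/d(parameter).  The ReLU
    subgradient at exactly 0 is 0; the L1 subgradient at 0 is 0.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n = X.shape[0]
    if n == 0:
        raise DomainError("empty batch")
    if Y.shape[0] != n or Y.shape[1] != spec.n_outputs:
        raise DomainError(f"batch Y shape {Y.shape} incompatible with n={n}, T={spec.n_outputs}")

    hidden, Z_out, clipped = _forward_hidden(spec, params, X, dropout_masks, clip=clip)
    mu = np.exp(Z_out)
    dZ = (mu - Y) / n
    if clipped is not None:
        dZ = np.where(clipped, 0.0, dZ)  # clamp is flat above the threshold

    grad_w = [None] * len(params.weights)
    grad_b = [None] * len(params.biases)
    A_prev = hidden[-1] if spec.n_hidden else X
    grad_w[-1] = A_prev.T @ dZ
    grad_b[-1] = dZ.sum(axis=0)
    dA = dZ @ params.weights[-1].T
    for l in range(spec.n_hidden - 1, -1, -1):
        if dropout_masks is not None:
            dA = dA * dropout_masks[l]
        dZ_h = dA * (hidden[l] > 0)  # post-dropout activation > 0 iff pre-ReLU > 0
        A_prev = hidden[l - 1] if l > 0 else X
        grad_w[l] = A_prev.T @ dZ_h
        grad_b[l] = dZ_h.sum(axis=0)
        if l > 0:
            dA = dZ_h @ params.weights[l].T
    if l1_lambda > 0:
        for l in range(len(grad_w)):
            grad_w[l] = grad_w[l] + l1_lambda * np.sign(params.weights[l])
    return NetworkParams(grad_w, grad_b)


@dataclass
class TrainedNetwork:
    """A trained network with its optimization history."""

    spec: NetworkSpec
    params: NetworkParams
    history: pd.DataFrame  # columns: epoch, train_loss, val_loss
    best_epoch: int
    stopped_early: bool

    def predict(self, X) -> np.ndarray:
        return forward(self.spec, self.params, X)

    def save(self, prefix) -> None:
        """JSON manifest + NPZ parameter container (bit-exact round trip)."""
        manifest = {
            "spec": {
                "n_hidden": self.spec.n_hidden,
                "units": list(self.spec.units),
                "n_outputs": self.spec.n_outputs,
                "dropout_rate": self.spec.dropout_rate,
                "l1_lambda": self.spec.l1_lambda,
            },
            "best_epoch": self.best_epoch,
            "stopped_early": self.stopped_early,
            "history": self.history.to_dict(orient="list"),
        }
        with open(f"{prefix}.json", "w") as fh:
            json.dump(manifest, fh)
        arrays = {}
        for l, (w, b) in enumerate(zip(self.params.weights, self.params.biases)):
            arrays[f"w{l}"] = w
            arrays[f"b{l}"] = b
        np.savez(f"{prefix}.npz", **arrays)

    @classmethod
    def load(cls, prefix) -> "TrainedNetwork":
        with open(f"{prefix}.json") as fh:
            manifest = json.load(fh)
        spec = NetworkSpec(**manifest["spec"])
        with np.load(f"{prefix}.npz") as data:
            n_layers = spec.n_hidden + 1
            params = NetworkParams(
                [data[f"w{l}"] for l in range(n_layers)],
                [data[f"b{l}"] for l in range(n_layers)],
            )
        return cls(
            spec=spec,
            params=params,
            history=pd.DataFrame(manifest["history"]),
            best_epoch=manifest["best_epoch"],
            stopped_early=manifest["stopped_early"],
        )


def _adam_step(params, grads, state, cfg, t):
    for group, ggroup, m, v in (
        (params.weights, grads.weights, state["mw"], state["vw"]),
        (params.biases, grads.biases, state["mb"], state["vb"]),
    ):
        for l in range(len(group)):
            m[l] = cfg.beta1 * m[l] + (1 - cfg.beta1) * ggroup[l]
            v[l] = cfg.beta2 * v[l] + (1 - cfg.beta2) * ggroup[l] ** 2
            mhat = m[l] / (1 - cfg.beta1**t)
            vhat = v[l] / (1 - cfg.beta2**t)
            group[l] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + cfg.eps)


def train(spec: NetworkSpec, X, Y, cfg: TrainConfig, init: NetworkParams | None = None) -> TrainedNetwork:
    """Train with Adam, mini-batches, inverted dropout and early stopping.

    A seeded ``validation_fraction`` of the rows monitors the loss; training
    restores the best-validation-epoch parameters.  Deterministic given
    ``cfg.seed``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[1] != spec.n_outputs:
        raise DomainError(f"Y has {Y.shape[1]} columns; spec expects {spec.n_outputs}")
    n, d = X.shape
    rng = np.random.default_rng(cfg.seed)
    params = init.copy() if init is not None else init_params(spec, d, seed=int(rng.integers(2**31)))

    perm = rng.permutation(n)
    n_val = max(1, int(round(cfg.validation_fraction * n))) if n > 1 else 0
    val_idx, trn_idx = perm[:n_val], perm[n_val:]
    if len(trn_idx) == 0:
        trn_idx, val_idx = perm, perm[:0]
    Xt, Yt = X[trn_idx], Y[trn_idx]
    Xv, Yv = X[val_idx], Y[val_idx]

    state = {
        "mw": [np.zeros_like(w) for w in params.weights],
        "vw": [np.zeros_like(w) for w in params.weights],
        "mb": [np.zeros_like(b) for b in params.biases],
        "vb": [np.zeros_like(b) for b in params.biases],
    }
    history = []
    best_val = np.inf
    best_params = params.copy()
    best_epoch = 0
    patience_left = cfg.early_stopping_patience
    stopped_early = False
    t = 0
    use_dropout = spec.dropout_rate > 0.0

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(trn_idx))
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            masks = None
            if use_dropout:
                keep = 1.0 - spec.dropout_rate
                masks = [
                    (rng.random((len(batch), u)) < keep) / keep for u in spec.units
                ]
            grads = gradients(
                spec, params, Xt[batch], Yt[batch], spec.l1_lambda, masks, clip=True
            )
            t += 1
            _adam_step(params, grads, state, cfg, t)

        train_loss = mpdn_loss(Yt, forward(spec, params, Xt), params, spec.l1_lambda)
        val_loss = (
            mpdn_loss(Yv, forward(spec, params, Xv), params, spec.l1_lambda)
            if len(val_idx)
            else train_loss
        )
        if not (np.isfinite(train_loss) and np.isfinite(val_loss)):
            raise RuntimeError(f"non-finite loss at epoch {epoch}; training aborted")
        history.append((epoch, train_loss, val_loss))

        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_params = params.copy()
            best_epoch = epoch
            patience_left = cfg.early_stopping_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                stopped_early = True
                break

    if cfg.max_epochs == 0:
        best_params = params.copy()

    return TrainedNetwork(
        spec=spec,
        params=best_params,
        history=pd.DataFrame(history, columns=["epoch", "train_loss", "val_loss"]),
        best_epoch=best_epoch,
        stopped_early=stopped_early,
    )


class PoissonDeepNet:
    """Multi-trait Poisson deep network model (statsmodels-style front end).

    Parameters
    ----------
    endog : array-like
        n x T count matrix (or length-n vector for a single trait).
    exog : array-like or DesignMatrix
        n x d predictor matrix.
    spec : NetworkSpec
        Topology; ``spec.n_outputs`` must equal T.
    """

    def __init__(self, endog, exog, spec: NetworkSpec):
        from .data import DesignMatrix

        if isinstance(exog, DesignMatrix):
            exog = exog.X
        X = np.asarray(exog, dtype=float)
        Y = np.asarray(endog, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if np.any(Y < 0) or np.any(Y != np.floor(Y)):
            raise DomainError("endog must contain non-negative integer counts")
        if Y.shape[1] != spec.n_outputs:
            raise DomainError(
                f"endog has {Y.shape[1]} traits but spec.n_outputs={spec.n_outputs}"
            )
        if X.shape[0] != Y.shape[0]:
            raise DomainError("endog and exog row counts differ")
        self.endog, self.exog, self.spec = Y, X, spec

    def fit(self, train_config: TrainConfig | None = None, init: NetworkParams | None = None):
        cfg = train_config or TrainConfig()
        net = train(self.spec, self.exog, self.endog, cfg, init=init)
        return PoissonDeepNetResults(self, net, cfg)


class UnivariatePoissonDeepNet(PoissonDeepNet):
    """Single-trait front end; the computation is the T = 1 multivariate path."""

    def __init__(self, endog, exog, spec: NetworkSpec):
        if spec.n_outputs != 1:
            raise ValueError("univariate model requires spec.n_outputs == 1")
        super().__init__(endog, exog, spec)


@dataclass
class PoissonDeepNetResults:
    """Training outcome: parameters, loss history, early-stopping state."""

    model: PoissonDeepNet
    network: TrainedNetwork
    train_config: TrainConfig

    @property
    def params(self) -> NetworkParams:
        return self.network.params

    @property
    def history(self) -> pd.DataFrame:
        return self.network.history

    def predict(self, exog=None) -> np.ndarray:
        from .data import DesignMatrix

        X = self.model.exog if exog is None else exog
        if isinstance(X, DesignMatrix):
            X = X.X
        return self.network.predict(X)

    def summary(self) -> str:
        h = self.network.history
        spec = self.model.spec
        lines = [
            "Poisson deep network",
            "=" * 44,
            f"n obs            {self.model.exog.shape[0]:>10d}",
            f"n inputs         {self.model.exog.shape[1]:>10d}",
            f"hidden layers    {spec.n_hidden:>10d}  units {spec.units}",
            f"traits (T)       {spec.n_outputs:>10d}",
            f"dropout          {spec.dropout_rate:>10.3f}",
            f"L1 lambda        {spec.l1_lambda:>10.4g}",
            f"epochs run       {len(h):>10d}",
            f"best epoch       {self.network.best_epoch:>10d}",
            f"stopped early    {str(self.network.stopped_early):>10s}",
        ]
        if len(h):
            lines.append(f"final val loss   {h['val_loss'].iloc[-1]:>10.4f}")
        return "\n".join(lines)

    def plot_history(self, ax=None):  # pragma: no cover - thin plotting helper
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        h = self.network.history
        ax.plot(h["epoch"], h["train_loss"], label="train")
        ax.plot(h["epoch"], h["val_loss"], label="validation")
        ax.axvline(self.network.best_epoch, ls="--", color="grey")
        ax.set_xlabel("epoch")
        ax.set_ylabel("Poisson NLL loss")
        ax.legend()
        return ax

    def save(self, prefix) -> None:
        self.network.save(prefix)
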
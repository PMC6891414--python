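"""Single-hidden-layer feed-forward regression network and architecture search.

The network is the classical chemometric multilayer perceptron: inputs and
targets are affinely scaled to [-1, 1] from the training set, a hidden layer
and an output layer each apply an affine map followed by one of five transfer
functions (hardlims, satlins, purelin, logsig, tansig), and predictions are
inverse-scaled back to concentration units.  Training minimizes full-batch
mean squared error on the scaled targets with an L-BFGS quasi-Newton iteration
over an analytic backpropagation gradient; everything is deterministic for a
fixed seed.  The exhaustive architecture search scans hidden sizes 2-9 crossed
with all 5x5 transfer-function pairs (200 configurations) and picks the
minimum cross-validated NRMSE, never touching the external test set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.model_selection import KFold

from .evaluate import nrmse
from .exceptions import (
    ConfigurationError,
    DataError,
    RegistryError,
    ShapeError,
)

# --------------------------------------------------------------------------
# Transfer functions
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TransferFn:
    """Forward map and (sub)gradient of a named transfer function."""

    name: str
    f: callable
    df: callable
    bounded: bool  # output confined to a fixed interval


def _satlins(x):
    return np.clip(x, -1.0, 1.0)


def _d_satlins(x):
    return ((x > -1.0) & (x < 1.0)).astype(float)


def _tansig(x):
    return np.tanh(x)


def _d_tansig(x):
    return 1.0 - np.tanh(x) ** 2


def _logsig(x):
    return expit(x)


def _d_logsig(x):
    s = expit(x)
    return s * (1.0 - s)


def _hardlims(x):
    return np.where(np.asarray(x, dtype=float) >= 0.0, 1.0, -1.0)


def _purelin(x):
    return np.asarray(x, dtype=float)


TRANSFER_FUNCTIONS = {
    "hardlims": TransferFn("hardlims", _hardlims, lambda x: np.zeros_like(np.asarray(x, float)), True),
    "satlins": TransferFn("satlins", _satlins, _d_satlins, True),
    "purelin": TransferFn("purelin", _purelin, lambda x: np.ones_like(np.asarray(x, float)), False),
    "logsig": TransferFn("logsig", _logsig, _d_logsig, True),
    "tansig": TransferFn("tansig", _tansig, _d_tansig, True),
}

TRANSFER_NAMES = tuple(TRANSFER_FUNCTIONS)


def transfer(name: str, x):
    """Apply the named transfer function elementwise."""
    if name not in TRANSFER_FUNCTIONS:
        raise RegistryError(
            f"unknown transfer function {name!r}; known: {sorted(TRANSFER_FUNCTIONS)}"
        )
    return TRANSFER_FUNCTIONS[name].f(np.asarray(x, dtype=float))


# --------------------------------------------------------------------------
# Scaling
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AffineScaler:
    """Affine map onto [-1, 1] fitted from training min/max.

    ``fit`` scales each column independently (used for the three targets);
    ``fit_global`` applies one shared map to every column, which is the right
    choice for the wavelet features: they all carry the same unit (uA), and
    stretching near-constant coefficient channels to full range would amplify
    pure measurement noise into dominant inputs.  Zero-variance columns map
    to 0 and invert to their constant value.
    """

    lo: np.ndarray
    hi: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "AffineScaler":
        X = np.asarray(X, dtype=float)
        return cls(X.min(axis=0), X.max(axis=0))

    @classmethod
    def fit_global(cls, X: np.ndarray) -> "AffineScaler":
        X = np.asarray(X, dtype=float)
        p = X.shape[-1]
        return cls(np.full(p, X.min()), np.full(p, X.max()))

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        span = self.hi - self.lo
        out = np.zeros_like(X)
        ok = span > 0
        out[..., ok] = 2.0 * (X[..., ok] - self.lo[ok]) / span[ok] - 1.0
        return out

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        Z = np.asarray(Z, dtype=float)
        span = self.hi - self.lo
        out = np.empty_like(Z)
        ok = span > 0
        out[..., ok] = (Z[..., ok] + 1.0) / 2.0 * span[ok] + self.lo[ok]
        out[..., ~ok] = self.lo[~ok]
        return out


# --------------------------------------------------------------------------
# Architecture / model
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MLPArchitecture:
    n_input: int = 144
    n_hidden: int = 5
    n_output: int = 3
    hidden_fn: str = "satlins"
    output_fn: str = "tansig"

    def __post_init__(self) -> None:
        if min(self.n_input, self.n_hidden, self.n_output) < 1:
            raise ConfigurationError("layer sizes must be positive")
        for fn in (self.hidden_fn, self.output_fn):
            if fn not in TRANSFER_FUNCTIONS:
                raise RegistryError(f"unknown transfer function {fn!r}")

    @property
    def n_params(self) -> int:
        return (self.n_input + 1) * self.n_hidden + (self.n_hidden + 1) * self.n_output


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (full-batch L-BFGS, deterministic restarts)."""

    max_iter: int = 5000
    ftol: float = 1e-12
    gtol: float = 1e-10
    n_restarts: int = 5
    init_scale: float = 0.5


@dataclass
class MLPModel:
    architecture: MLPArchitecture
    W1: np.ndarray  # (n_hidden, n_input)
    b1: np.ndarray  # (n_hidden,)
    W2: np.ndarray  # (n_output, n_hidden)
    b2: np.ndarray  # (n_output,)
    x_scaler: AffineScaler
    y_scaler: AffineScaler
    seed: int = 0
    final_loss: float = float("nan")

    def predict(self, X) -> np.ndarray:
        """Map raw features to concentrations (inverse-scaled network output)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.architecture.n_input:
            raise ShapeError(
                f"expected {self.architecture.n_input} features, got {X.shape[1]}"
            )
        arch = self.architecture
        fh = TRANSFER_FUNCTIONS[arch.hidden_fn].f
        fo = TRANSFER_FUNCTIONS[arch.output_fn].f
        Xs = self.x_scaler.transform(X)
        A1 = fh(Xs @ self.W1.T + self.b1)
        A2 = fo(A1 @ self.W2.T + self.b2)
        return self.y_scaler.inverse(A2)

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        arch = self.architecture
        payload = {
            "architecture": {
                "n_input": arch.n_input,
                "n_hidden": arch.n_hidden,
                "n_output": arch.n_output,
                "hidden_fn": arch.hidden_fn,
                "output_fn": arch.output_fn,
            },
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "W2": self.W2.tolist(),
            "b2": self.b2.tolist(),
            "x_lo": self.x_scaler.lo.tolist(),
            "x_hi": self.x_scaler.hi.tolist(),
            "y_lo": self.y_scaler.lo.tolist(),
            "y_hi": self.y_scaler.hi.tolist(),
            "seed": self.seed,
            "final_loss": self.final_loss,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MLPModel":
        d = json.loads(text)
        arch = MLPArchitecture(**d["architecture"])
        return cls(
            architecture=arch,
            W1=np.array(d["W1"], dtype=float),
            b1=np.array(d["b1"], dtype=float),
            W2=np.array(d["W2"], dtype=float),
            b2=np.array(d["b2"], dtype=float),
            x_scaler=AffineScaler(np.array(d["x_lo"]), np.array(d["x_hi"])),
            y_scaler=AffineScaler(np.array(d["y_lo"]), np.array(d["y_hi"])),
            seed=int(d["seed"]),
            final_loss=float(d["final_loss"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "MLPModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def forward(model: MLPModel, features) -> np.ndarray:
    """Functional alias for :meth:`MLPModel.predict` (1-D input -> 1-D output)."""
    feats = np.asarray(features, dtype=float)
    out = model.predict(feats)
    return out[0] if feats.ndim == 1 else out


# --------------------------------------------------------------------------
# Training
# --------------------------------------------------------------------------


def _pack(W1, b1, W2, b2):
    return np.concatenate([W1.ravel(), b1, W2.ravel(), b2])


def _unpack(theta, arch: MLPArchitecture):
    i, h, o = arch.n_input, arch.n_hidden, arch.n_output
    k = 0
    W1 = theta[k : k + h * i].reshape(h, i); k += h * i
    b1 = theta[k : k + h]; k += h
    W2 = theta[k : k + o * h].reshape(o, h); k += o * h
    b2 = theta[k : k + o]
    return W1, b1, W2, b2


def _loss_and_grad(theta, Xs, Ys, arch: MLPArchitecture):
    W1, b1, W2, b2 = _unpack(theta, arch)
    th = TRANSFER_FUNCTIONS[arch.hidden_fn]
    to = TRANSFER_FUNCTIONS[arch.output_fn]
    Z1 = Xs @ W1.T + b1
    A1 = th.f(Z1)
    Z2 = A1 @ W2.T + b2
    A2 = to.f(Z2)
    E = A2 - Ys
    n = E.size
    loss = float(np.sum(E**2) / n)
    dZ2 = (2.0 / n) * E * to.df(Z2)
    gW2 = dZ2.T @ A1
    gb2 = dZ2.sum(axis=0)
    dZ1 = (dZ2 @ W2) * th.df(Z1)
    gW1 = dZ1.T @ Xs
    gb1 = dZ1.sum(axis=0)
    return loss, _pack(gW1, gb1, gW2, gb2)


def _init_params(arch: MLPArchitecture, rng: np.random.Generator, scale: float):
    W1 = rng.uniform(-scale, scale, (arch.n_hidden, arch.n_input)) / np.sqrt(arch.n_input)
    b1 = rng.uniform(-scale, scale, arch.n_hidden) / np.sqrt(arch.n_input)
    W2 = rng.uniform(-scale, scale, (arch.n_output, arch.n_hidden)) / np.sqrt(arch.n_hidden)
    b2 = rng.uniform(-scale, scale, arch.n_output) / np.sqrt(arch.n_hidden)
    return _pack(W1, b1, W2, b2)


def train(
    X,
    Y,
    arch: MLPArchitecture = MLPArchitecture(),
    seed: int = 0,
    config: TrainConfig = TrainConfig(),
) -> MLPModel:
    """Fit the network by full-batch quasi-Newton MSE minimization.

    Deterministic for fixed (data, arch, seed, config); runs
    ``config.n_restarts`` seeded initializations and keeps the lowest final
    training loss.  The final loss never exceeds the initial loss of the
    winning restart.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or len(X) != len(Y):
        raise ShapeError("X and Y must be 2-D with equal row counts")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise DataError("training data must be finite")
    if len(X) < arch.n_hidden:
        raise DataError(
            f"need at least n_hidden={arch.n_hidden} training rows, got {len(X)}"
        )
    if X.shape[1] != arch.n_input or Y.shape[1] != arch.n_output:
        raise ShapeError("data dimensions do not match the architecture")

    x_scaler = AffineScaler.fit_global(X)
    y_scaler = AffineScaler.fit(Y)
    Xs = x_scaler.transform(X)
    Ys = y_scaler.transform(Y)

    children = np.random.SeedSequence(seed).spawn(config.n_restarts)
    best_theta, best_loss = None, np.inf
    for ss in children:
        rng = np.random.default_rng(ss)
        theta0 = _init_params(arch, rng, config.init_scale)
        loss0, _ = _loss_and_grad(theta0, Xs, Ys, arch)
        res = minimize(
            _loss_and_grad,
            theta0,
            args=(Xs, Ys, arch),
            method="L-BFGS-B",
            jac=True,
            options={
                "maxiter": config.max_iter,
                "maxfun": 4 * config.max_iter,
                "ftol": config.ftol,
                "gtol": config.gtol,
            },
        )
        theta, loss = (res.x, float(res.fun))
        if loss > loss0:  # guard: never accept an ascent
            theta, loss = theta0, loss0
        if loss < best_loss:
            best_theta, best_loss = theta, loss
    W1, b1, W2, b2 = _unpack(best_theta, arch)
    return MLPModel(arch, W1, b1, W2, b2, x_scaler, y_scaler, seed, best_loss)


# --------------------------------------------------------------------------
# Exhaustive architecture search
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SearchResult:
    """All evaluated configurations (scan order) and the winner."""

    records: tuple  # of dicts: hidden_size, hidden_fn, output_fn, cv_nrmse
    best_architecture: MLPArchitecture
    best_model: MLPModel
    grid_size: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(list(self.records))


def architecture_search(
    X,
    Y,
    hidden_sizes=range(2, 10),
    hidden_fns: tuple = TRANSFER_NAMES,
    output_fns: tuple = TRANSFER_NAMES,
    seed: int = 0,
    n_folds: int = 3,
    config: TrainConfig = TrainConfig(max_iter=300, n_restarts=1),
) -> SearchResult:
    """Scan hidden sizes x transfer-function pairs; select minimum CV NRMSE.

    Model selection uses k-fold cross-validation on the supplied (training)
    data only; ties go to the first configuration in scan order.  The winner
    is refit on the full data with the full default training budget.  The
    default per-configuration budget is deliberately lighter than
    :class:`TrainConfig`'s: ranking 200 candidates needs consistency, not a
    fully polished fit of each.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    hidden_sizes = list(hidden_sizes)
    hidden_fns = list(hidden_fns)
    output_fns = list(output_fns)
    if not hidden_sizes or not hidden_fns or not output_fns:
        raise ConfigurationError("empty architecture search grid")
    splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed % 2**31)
    folds = list(splitter.split(X))
    records = []
    best_idx, best_score = None, np.inf
    for h in hidden_sizes:
        for hf in hidden_fns:
            for of in output_fns:
                arch = MLPArchitecture(
                    n_input=X.shape[1], n_hidden=h, n_output=Y.shape[1],
                    hidden_fn=hf, output_fn=of,
                )
                pred = np.empty_like(Y)
                for tr, va in folds:
                    model = train(X[tr], Y[tr], arch, seed=seed, config=config)
                    pred[va] = model.predict(X[va])
                score = nrmse(Y, pred)
                records.append(
                    {"hidden_size": h, "hidden_fn": hf, "output_fn": of,
                     "cv_nrmse": score}
                )
                if score < best_score:
                    best_idx, best_score = len(records) - 1, score
    winner = records[best_idx]
    best_arch = MLPArchitecture(
        n_input=X.shape[1], n_hidden=winner["hidden_size"], n_output=Y.shape[1],
        hidden_fn=winner["hidden_fn"], output_fn=winner["output_fn"],
    )
    best_model = train(X, Y, best_arch, seed=seed, config=TrainConfig())
    return SearchResult(tuple(records), best_arch, best_model, len(records))
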
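"""Feed-forward back-propagation network for small-cohort regression.

The network is a classic multilayer perceptron trained to minimize the
summed-squared error

    E = 1/2 * sum_i sum_j (y_ij - O_ij)^2

over M training patterns and N output nodes, reported as
``RMSE = sqrt(2 E / (M N))``.  Two optimizers are provided:

* ``sequential_gd`` — per-pattern (online) gradient descent with a fixed
  learning rate eta in (0, 1); the pattern order is reshuffled every epoch.
* ``scg`` — Moller's scaled conjugate gradient, a full-batch Hessian-free
  conjugate method with no learning rate.

The default output unit is tanh: with an unbounded identity output, the
per-pattern update at eta = 0.4 violates the online-stability condition
eta * |h|^2 < 2 whenever the six hidden units saturate, and training can
diverge.  A bounded output keeps the error signal finite; callers range-map
regression targets into (-1, 1) and invert the map on predictions.  An
identity output remains available for linear-regression use.

Training monitors validation RMSE after every epoch and returns the weight
snapshot from the epoch with the lowest validation RMSE (earliest epoch on
ties) — early stopping against overtraining on small cohorts.

Everything is implemented directly on numpy arrays: the gradient is an exact
back-propagation of E, verified against central finite differences in the
test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetworkConfig",
    "NetworkState",
    "TrainingTrace",
    "SplitIndices",
    "TrainingDiverged",
    "init_network",
    "forward",
    "loss",
    "gradient",
    "train",
    "split_data",
]


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


_ACTIVATIONS = {
    # name -> (f, f' expressed through the activation output h)
    "tanh": (np.tanh, lambda h: 1.0 - h * h),
    "identity": (lambda x: x, lambda h: np.ones_like(h)),
    "logistic": (lambda x: 1.0 / (1.0 + np.exp(-x)), lambda h: h * (1.0 - h)),
}


@dataclass
class NetworkConfig:
    """Architecture and training hyper-parameters.

    Defaults: one hidden layer of six tanh units, identity output, sequential
    gradient descent with learning rate eta = 0.4.
    """

    n_inputs: int = 12
    hidden_layout: tuple[int, ...] = (6,)
    n_outputs: int = 1
    hidden_activation: str = "tanh"
    #: a bounded output unit keeps per-pattern updates stable at eta = 0.4;
    #: targets must then be range-mapped into (-1, 1) (see pipeline).
    #: "identity" turns the net into an unbounded regressor.
    output_activation: str = "tanh"
    eta: float = 0.4
    optimizer: str = "sequential_gd"
    max_epochs: int = 150
    patience: int = 25
    init_scale: float = 0.5
    rmse_tol: float = 1e-10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.eta < 1:
            raise ValueError("eta must lie in (0, 1)")
        if self.optimizer not in ("sequential_gd", "scg"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.hidden_activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.hidden_activation!r}")
        if self.output_activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.output_activation!r}")
        if self.n_inputs < 1 or self.n_outputs < 1:
            raise ValueError("n_inputs and n_outputs must be positive")
        if any(h < 1 for h in self.hidden_layout):
            raise ValueError("hidden layer sizes must be positive")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be at least 1")
        if self.patience < 0 or self.init_scale < 0:
            raise ValueError("patience and init_scale must be non-negative")
        self.hidden_layout = tuple(int(h) for h in self.hidden_layout)

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.n_inputs, *self.hidden_layout, self.n_outputs)


@dataclass
class NetworkState:
    """Weights ``w[l]`` of shape (fan_out, fan_in) and biases ``b[l]``."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    hidden_activation: str = "tanh"
    output_activation: str = "identity"
    epoch: int = 0

    def copy(self) -> "NetworkState":
        return NetworkState(
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
            hidden_activation=self.hidden_activation,
            output_activation=self.output_activation,
            epoch=self.epoch,
        )

    @property
    def n_layers(self) -> int:
        return len(self.weights)


@dataclass
class TrainingTrace:
    """Per-epoch RMSE history and the early-stopping outcome."""

    train_rmse: list[float] = field(default_factory=list)
    val_rmse: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stopped_reason: str = "max_epochs"

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_rmse) + 1),
                "train_rmse": self.train_rmse,
                "val_rmse": self.val_rmse,
            }
        )


@dataclass
class SplitIndices:
    """Disjoint train/validation/test index sets covering a cohort."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray

    def __post_init__(self) -> None:
        self.train = np.asarray(self.train, dtype=int)
        self.validation = np.asarray(self.validation, dtype=int)
        self.test = np.asarray(self.test, dtype=int)
        allidx = np.concatenate([self.train, self.validation, self.test])
        if len(np.unique(allidx)) != allidx.size:
            raise ValueError("splits overlap")


def init_network(config: NetworkConfig) -> NetworkState:
    """Weights uniform on [-init_scale, init_scale], biases zero; the draw is
    fully determined by ``config.seed``."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    sizes = config.layer_sizes
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        weights.append(rng.uniform(-config.init_scale, config.init_scale, (fan_out, fan_in)))
        biases.append(np.zeros(fan_out))
    return NetworkState(
        weights=weights,
        biases=biases,
        hidden_activation=config.hidden_activation,
        output_activation=config.output_activation,
    )


def _forward_cached(state: NetworkState, x: np.ndarray) -> list[np.ndarray]:
    """All layer activations, input first, output last."""
    act, _ = _ACTIVATIONS[state.hidden_activation]
    out_act, _ = _ACTIVATIONS[state.output_activation]
    a = [x]
    h = x
    last = state.n_layers - 1
    for l, (w, b) in enumerate(zip(state.weights, state.biases)):
        z = h @ w.T + b
        h = out_act(z) if l == last else act(z)
        a.append(h)
    return a


def forward(state: NetworkState, features: np.ndarray) -> np.ndarray:
    """Network output for a single feature vector or a (M, n_inputs) batch."""
    x = np.asarray(features, dtype=float)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != state.weights[0].shape[1]:
        raise ValueError(
            f"expected {state.weights[0].shape[1]} inputs, got {x.shape[1]}"
        )
    out = _forward_cached(state, x)[-1]
    return out[0] if single else out


def loss(state: NetworkState, x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Summed-squared error E = 1/2 sum (y - O)^2 and RMSE = sqrt(2E/(M N))."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 0 or x.size == 0:
        raise ValueError("empty dataset")
    y = np.asarray(y, dtype=float).reshape(x.shape[0], -1)
    out = forward(state, x)
    e = 0.5 * float(np.sum((y - out) ** 2))
    rmse = math.sqrt(2.0 * e / y.size)
    return e, rmse


def gradient(
    state: NetworkState, x: np.ndarray, y: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Exact gradient of E w.r.t. every weight and bias (back-propagation)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 0 or x.size == 0:
        raise ValueError("empty dataset")
    y = np.asarray(y, dtype=float).reshape(x.shape[0], -1)
    _, dact = _ACTIVATIONS[state.hidden_activation]
    _, dact_out = _ACTIVATIONS[state.output_activation]
    a = _forward_cached(state, x)
    delta = (a[-1] - y) * dact_out(a[-1])  # dE/dz at the output layer
    gw: list[np.ndarray] = [None] * state.n_layers  # type: ignore[list-item]
    gb: list[np.ndarray] = [None] * state.n_layers  # type: ignore[list-item]
    for l in range(state.n_layers - 1, -1, -1):
        gw[l] = delta.T @ a[l]
        gb[l] = delta.sum(axis=0)
        if l > 0:
            delta = (delta @ state.weights[l]) * dact(a[l])
    return gw, gb


def _flatten(ws: list[np.ndarray], bs: list[np.ndarray]) -> np.ndarray:
    return np.concatenate([a.ravel() for a in ws] + [a.ravel() for a in bs])


def _unflatten_into(state: NetworkState, vec: np.ndarray) -> None:
    pos = 0
    for w in state.weights:
        w[...] = vec[pos : pos + w.size].reshape(w.shape)
        pos += w.size
    for b in state.biases:
        b[...] = vec[pos : pos + b.size].reshape(b.shape)
        pos += b.size


def _grad_vec(state: NetworkState, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    gw, gb = gradient(state, x, y)
    return _flatten(gw, gb)


def _scg_epoch_stepper(state: NetworkState, x: np.ndarray, y: np.ndarray):
    """Generator performing one Moller scaled-conjugate-gradient step per
    ``next()`` call, mutating ``state`` in place.

    Follows the classic SCG recipe: a one-sided secant estimate of the
    curvature along the search direction p, a Levenberg-style scale lambda
    that grows on poor quadratic agreement and shrinks on good agreement, and
    Polak-Ribiere-type conjugate direction updates with periodic restarts.
    """
    sigma0 = 5e-5
    lam, lam_bar = 5e-7, 0.0
    w = _flatten(state.weights, state.biases)
    n_params = w.size
    r = -_grad_vec(state, x, y)
    p = r.copy()
    success = True
    delta = 0.0
    k = 0
    while True:
        k += 1
        p_norm2 = float(p @ p)
        if p_norm2 == 0:  # exact optimum reached
            _unflatten_into(state, w)
            yield
            continue
        if success:
            sigma = sigma0 / math.sqrt(p_norm2)
            _unflatten_into(state, w + sigma * p)
            s = (_grad_vec(state, x, y) - (-r)) / sigma
            delta = float(p @ s)
        delta += (lam - lam_bar) * p_norm2
        if delta <= 0:  # force positive-definite curvature estimate
            lam_bar = 2.0 * (lam - delta / p_norm2)
            delta = -delta + lam * p_norm2
            lam = lam_bar
        mu = float(p @ r)
        alpha = mu / delta
        _unflatten_into(state, w)
        e0, _ = loss(state, x, y)
        _unflatten_into(state, w + alpha * p)
        e1, _ = loss(state, x, y)
        comp = 2.0 * delta * (e0 - e1) / (mu * mu) if mu != 0 else -1.0
        if comp >= 0:  # successful step
            w = w + alpha * p
            _unflatten_into(state, w)
            r_new = -_grad_vec(state, x, y)
            lam_bar = 0.0
            success = True
            if k % n_params == 0:  # restart along the gradient
                p = r_new.copy()
            else:
                beta = (float(r_new @ r_new) - float(r_new @ r)) / mu
                p = r_new + beta * p
            r = r_new
            if comp >= 0.75:
                lam *= 0.25
        else:
            _unflatten_into(state, w)
            lam_bar = lam
            success = False
        if comp < 0.25:
            lam += delta * (1.0 - comp) / p_norm2
        lam = min(lam, 1e100)
        yield


def train(
    config: NetworkConfig,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
) -> tuple[NetworkState, TrainingTrace]:
    """Train with early stopping; returns the validation-optimal snapshot.

    Sequential mode updates after every pattern (order reshuffled each epoch
    from the config seed); SCG mode performs one full-batch scaled
    conjugate-gradient step per epoch.  After each epoch train and validation
    RMSE are recorded; the returned state is the snapshot from the epoch with
    minimal validation RMSE (earliest on ties).  Training stops when the
    validation RMSE has not improved for ``patience`` epochs, when the train
    RMSE falls below ``rmse_tol`` (reason ``converged``) or at ``max_epochs``.
    """
    x_tr = np.atleast_2d(np.asarray(train_set[0], dtype=float))
    y_tr = np.asarray(train_set[1], dtype=float).reshape(x_tr.shape[0], -1)
    x_va = np.atleast_2d(np.asarray(val_set[0], dtype=float))
    y_va = np.asarray(val_set[1], dtype=float).reshape(x_va.shape[0], -1)
    if x_tr.shape[0] == 0 or x_va.shape[0] == 0:
        raise ValueError("train and validation sets must be non-empty")

    state = init_network(config)
    order_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    trace = TrainingTrace()
    best_state = state.copy()
    best_val = math.inf
    scg_stepper = (
        _scg_epoch_stepper(state, x_tr, y_tr) if config.optimizer == "scg" else None
    )

    for epoch in range(1, config.max_epochs + 1):
        if config.optimizer == "sequential_gd":
            for i in order_rng.permutation(x_tr.shape[0]):
                gw, gb = gradient(state, x_tr[i], y_tr[i])
                for w, g in zip(state.weights, gw):
                    w -= config.eta * g
                for b, g in zip(state.biases, gb):
                    b -= config.eta * g
        else:
            next(scg_stepper)
        state.epoch = epoch

        _, tr_rmse = loss(state, x_tr, y_tr)
        _, va_rmse = loss(state, x_va, y_va)
        if not (math.isfinite(tr_rmse) and math.isfinite(va_rmse)):
            raise TrainingDiverged(f"non-finite loss at epoch {epoch}")
        trace.train_rmse.append(tr_rmse)
        trace.val_rmse.append(va_rmse)
        if va_rmse < best_val:
            best_val = va_rmse
            best_state = state.copy()
            trace.best_epoch = epoch
        if tr_rmse <= config.rmse_tol:
            trace.stopped_reason = "converged"
            break
        if epoch - trace.best_epoch > config.patience:
            trace.stopped_reason = "early_stop"
            break
    else:
        trace.stopped_reason = "max_epochs"
    return best_state, trace


def split_data(
    cohort_size: int,
    fractions: tuple[float, float, float] = (0.5, 0.25, 0.25),
    seed: int = 0,
    groups=None,
) -> SplitIndices:
    """Random train/validation/test split, optionally stratified.

    Counts follow largest-remainder rounding of ``fractions``.  When
    ``groups`` (one label per item) is given, the split is carried out within
    each group so every treatment arm contributes proportionally to every
    partition — with eight animals per arm, an unstratified split can lose a
    whole arm from training.
    """
    if cohort_size < 4:
        raise ValueError("cohort_size must be at least 4")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))

    def _split_block(indices: np.ndarray) -> list[np.ndarray]:
        perm = rng.permutation(indices)
        quotas = np.array(fractions) * perm.size
        counts = np.floor(quotas).astype(int)
        rem = perm.size - counts.sum()
        for j in np.argsort(-(quotas - counts), kind="stable")[:rem]:
            counts[j] += 1
        edges = np.concatenate([[0], np.cumsum(counts)])
        return [perm[edges[k] : edges[k + 1]] for k in range(3)]

    if groups is None:
        parts = _split_block(np.arange(cohort_size))
    else:
        groups = np.asarray(groups)
        if groups.size != cohort_size:
            raise ValueError("groups length must equal cohort_size")
        parts = [[], [], []]
        for g in pd_unique_stable(groups):
            block = _split_block(np.flatnonzero(groups == g))
            for k in range(3):
                parts[k].append(block[k])
        parts = [np.sort(np.concatenate(p)) for p in parts]
    if any(p.size == 0 for p in parts):
        raise ValueError("a split received zero items; adjust fractions or size")
    return SplitIndices(train=parts[0], validation=parts[1], test=parts[2])


def pd_unique_stable(values: np.ndarray) -> np.ndarray:
    """Unique values in order of first appearance."""
    _, idx = np.unique(values, return_index=True)
    return values[np.sort(idx)]
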
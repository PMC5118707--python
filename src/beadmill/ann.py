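"""Feed-forward neural surrogate trained by Levenberg–Marquardt (LM).

The surrogate maps the four milling factors (actual units, min–max normalized
to [−1, 1]) to COD recovery (g/L, likewise normalized).  Hidden layers use the
saturating tanh activation, the output is linear.  Training follows the
classic damped Gauss–Newton scheme: solve (JᵀJ + μI)δ = Jᵀe on the training
split, grow μ on rejected steps and shrink it on accepted ones, monitor a
validation split for early stopping, and return the parameters from the
best-validation epoch.  The 30-run design is split 20/5/5 into
train/validation/test by default.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .design import DesignTable

__all__ = [
    "Normalizer",
    "NetworkParameters",
    "TrainingConfig",
    "TrainingRecord",
    "DivergenceError",
    "fit_normalizer",
    "forward",
    "network_jacobian",
    "init_network",
    "split_data",
    "train_lm",
    "response_curve",
    "network_to_json",
    "network_from_json",
]


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


@dataclass(frozen=True)
class Normalizer:
    """Per-variable linear map sending [min, max] -> [−1, +1]."""

    lo: tuple[float, ...]
    hi: tuple[float, ...]

    def __post_init__(self) -> None:
        for lo, hi in zip(self.lo, self.hi):
            if not hi > lo:
                raise ValueError(
                    f"degenerate normalization: max ({hi}) must exceed min ({lo})"
                )

    def transform(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        lo = np.asarray(self.lo)
        hi = np.asarray(self.hi)
        return 2.0 * (x - lo) / (hi - lo) - 1.0

    def inverse(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        lo = np.asarray(self.lo)
        hi = np.asarray(self.hi)
        return lo + (z + 1.0) * (hi - lo) / 2.0


def fit_normalizer(data) -> Normalizer:
    """Column-wise min/max normalizer; raises on constant columns."""
    arr = np.atleast_2d(np.asarray(data, dtype=float))
    if arr.shape[0] == 1 and arr.shape[1] > 1 and np.asarray(data).ndim == 1:
        arr = arr.T
    lo = arr.min(axis=0)
    hi = arr.max(axis=0)
    return Normalizer(tuple(float(v) for v in lo), tuple(float(v) for v in hi))


@dataclass
class NetworkParameters:
    """Weight matrices, bias vectors and per-layer activation tags.

    ``weights[l]`` has shape (units_out, units_in); activations are ``"tanh"``
    for hidden layers and ``"linear"`` for the output layer.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    activations: list[str]

    def __post_init__(self) -> None:
        if not (len(self.weights) == len(self.biases) == len(self.activations)):
            raise ValueError("layer lists must have equal length")
        for l in range(len(self.weights) - 1):
            if self.weights[l + 1].shape[1] != self.weights[l].shape[0]:
                raise ValueError(f"layer {l}->{l+1}: shapes do not chain")
        for W, b in zip(self.weights, self.biases):
            if b.shape != (W.shape[0],):
                raise ValueError("bias shape does not match layer width")

    @property
    def n_inputs(self) -> int:
        return self.weights[0].shape[1]

    @property
    def n_params(self) -> int:
        return sum(W.size + b.size for W, b in zip(self.weights, self.biases))

    def copy(self) -> "NetworkParameters":
        return NetworkParameters(
            [W.copy() for W in self.weights],
            [b.copy() for b in self.biases],
            list(self.activations),
        )

    def flatten(self) -> np.ndarray:
        return np.concatenate(
            [W.ravel() for W in self.weights] + [b.ravel() for b in self.biases]
        )

    def set_flat(self, theta: np.ndarray) -> None:
        pos = 0
        for W in self.weights:
            W[...] = theta[pos : pos + W.size].reshape(W.shape)
            pos += W.size
        for b in self.biases:
            b[...] = theta[pos : pos + b.size]
            pos += b.size
        if pos != theta.size:
            raise ValueError("parameter vector size mismatch")


def _act(name: str, z: np.ndarray) -> np.ndarray:
    if name == "tanh":
        return np.tanh(z)
    if name == "linear":
        return z
    raise ValueError(f"unknown activation {name!r}")


def init_network(
    n_inputs: int, hidden_sizes: Sequence[int], rng: np.random.Generator
) -> NetworkParameters:
    """Seeded Nguyen–Widrow-style initialization.

    Hidden rows are random directions scaled to 0.7·h^(1/fan_in) with biases
    spread evenly across the input range, so the units' active regions tile
    [−1, 1]; the linear output layer starts with small uniform weights.
    """
    sizes = [n_inputs, *hidden_sizes, 1]
    weights, biases, acts = [], [], []
    for l in range(len(sizes) - 1):
        fan_in, h = sizes[l], sizes[l + 1]
        last = l == len(sizes) - 2
        if last:
            W = rng.uniform(-0.5, 0.5, (h, fan_in))
            b = rng.uniform(-0.5, 0.5, h)
        else:
            beta = 0.7 * h ** (1.0 / fan_in)
            W = rng.uniform(-1.0, 1.0, (h, fan_in))
            W *= beta / np.linalg.norm(W, axis=1, keepdims=True)
            b = beta * np.linspace(-1.0, 1.0, h) * np.sign(W[:, 0])
        weights.append(W)
        biases.append(np.asarray(b, dtype=float))
        acts.append("linear" if last else "tanh")
    return NetworkParameters(weights, biases, acts)


def _forward_all(net: NetworkParameters, X: np.ndarray) -> list[np.ndarray]:
    """Layer activations for a batch; element 0 is the input itself."""
    a = [np.atleast_2d(np.asarray(X, dtype=float))]
    for W, b, act in zip(net.weights, net.biases, net.activations):
        a.append(_act(act, a[-1] @ W.T + b))
    return a


def forward(net: NetworkParameters, x) -> np.ndarray | float:
    """Network output(s) on normalized input(s); scalar in, scalar out."""
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 1
    if x.shape[-1] != net.n_inputs:
        raise ValueError(
            f"input has {x.shape[-1]} features, network expects {net.n_inputs}"
        )
    out = _forward_all(net, np.atleast_2d(x))[-1][:, 0]
    return float(out[0]) if scalar else out


def network_jacobian(net: NetworkParameters, X) -> np.ndarray:
    """Jacobian of the scalar output w.r.t. all parameters, one row per sample.

    Columns follow :meth:`NetworkParameters.flatten` order (all weight
    matrices, then all bias vectors).  Computed by reverse accumulation.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    a = _forward_all(net, X)
    n = X.shape[0]
    L = len(net.weights)
    # delta[l]: d out / d z_l, shape (n, units_l)
    deltas: list[np.ndarray] = [None] * L  # type: ignore[list-item]
    deltas[L - 1] = np.ones((n, 1))  # linear output layer
    for l in range(L - 2, -1, -1):
        upstream = deltas[l + 1] @ net.weights[l + 1]
        deltas[l] = upstream * (1.0 - a[l + 1] ** 2)  # tanh'
    w_blocks = [
        np.einsum("ni,nj->nij", deltas[l], a[l]).reshape(n, -1) for l in range(L)
    ]
    b_blocks = [deltas[l] for l in range(L)]
    return np.concatenate(w_blocks + b_blocks, axis=1)


@dataclass
class TrainingConfig:
    """Controls for LM training of the surrogate."""

    hidden_sizes: tuple[int, ...] = (10,)
    split: tuple[int, int, int] = (20, 5, 5)
    seed: int = 0
    mu0: float = 1e-3
    mu_increase: float = 10.0
    mu_decrease: float = 0.1
    mu_max: float = 1e10
    max_epochs: int = 300
    patience: int = 6
    goal_mse: float = 0.0
    gradient_floor: float = 1e-7
    #: independent seeded initializations; the network with the lowest
    #: best-validation MSE is returned (the split stays fixed by ``seed``)
    restarts: int = 10

    def __post_init__(self) -> None:
        if self.mu0 <= 0:
            raise ValueError("mu0 must be > 0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class TrainingRecord:
    """Per-epoch MSE traces and the stopping diagnosis."""

    train_mse: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)
    test_mse: list[float] = field(default_factory=list)
    stop_reason: str = ""
    best_epoch: int = -1
    best_val_mse: float = math.inf

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_mse) + 1),
                "train_mse": self.train_mse,
                "val_mse": self.val_mse,
                "test_mse": self.test_mse,
            }
        )


def split_data(
    n: int, sizes: tuple[int, int, int] = (20, 5, 5), seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded disjoint train/validation/test index sets covering range(n)."""
    if sum(sizes) != n:
        raise ValueError(f"split sizes {sizes} do not sum to n={n}")
    perm = np.random.default_rng(seed).permutation(n)
    a, b, _ = sizes
    return perm[:a], perm[a : a + b], perm[a + b :]


def _mse(net: NetworkParameters, X: np.ndarray, y: np.ndarray) -> float:
    if len(y) == 0:
        return math.nan
    r = y - forward(net, X)
    return float(np.mean(r**2))


def train_lm(
    table: DesignTable, config: TrainingConfig = TrainingConfig()
) -> tuple[NetworkParameters, tuple[Normalizer, Normalizer], TrainingRecord]:
    """Train the surrogate on a design table by Levenberg–Marquardt.

    Runs ``config.restarts`` independently initialized LM trainings on the
    same 20/5/5 split and returns the network whose best-validation MSE is
    lowest, together with the input/target normalizers (fitted on the full
    table) and that restart's training record.  Within a restart, one epoch
    is one accepted LM update of the full training batch and the returned
    parameters are those of the minimum-validation-MSE epoch.
    """
    if table.response is None:
        raise ValueError("design table has no response column")
    X_act = table.actual_matrix
    y_act = np.asarray(table.response, dtype=float)
    x_norm = fit_normalizer(X_act)
    y_norm = fit_normalizer(y_act.reshape(-1, 1))
    Xn = x_norm.transform(X_act)
    yn = y_norm.transform(y_act.reshape(-1, 1))[:, 0]

    idx_tr, idx_val, idx_te = split_data(table.n_runs, config.split, config.seed)
    splits = (Xn[idx_tr], yn[idx_tr], Xn[idx_val], yn[idx_val], Xn[idx_te], yn[idx_te])

    winner: tuple[NetworkParameters, TrainingRecord] | None = None
    for restart in range(max(config.restarts, 1)):
        rng = np.random.default_rng([config.seed, restart])
        net, record = _train_once(splits, config, rng, n_inputs=Xn.shape[1])
        if winner is None or record.best_val_mse < winner[1].best_val_mse:
            winner = (net, record)
    best_net, best_record = winner
    return best_net, (x_norm, y_norm), best_record


def _train_once(
    splits, config: TrainingConfig, rng: np.random.Generator, n_inputs: int
) -> tuple[NetworkParameters, TrainingRecord]:
    Xtr, ytr, Xval, yval, Xte, yte = splits
    net = init_network(n_inputs, config.hidden_sizes, rng)
    theta = net.flatten()
    mu = config.mu0
    record = TrainingRecord()
    best = net.copy()
    fails = 0

    def sse(th: np.ndarray) -> float:
        net.set_flat(th)
        r = ytr - forward(net, Xtr)
        return float(r @ r)

    current_sse = sse(theta)
    eye = np.eye(theta.size)
    for epoch in range(1, config.max_epochs + 1):
        net.set_flat(theta)
        e = ytr - forward(net, Xtr)
        J = network_jacobian(net, Xtr)
        g = J.T @ e
        if float(np.max(np.abs(g))) < config.gradient_floor:
            record.stop_reason = "gradient_floor"
            break
        JtJ = J.T @ J
        accepted = False
        while mu <= config.mu_max:
            try:
                delta = np.linalg.solve(JtJ + mu * eye, g)
            except np.linalg.LinAlgError:
                mu *= config.mu_increase
                continue
            trial = theta + delta
            trial_sse = sse(trial)
            if not math.isfinite(trial_sse):
                raise DivergenceError(
                    f"non-finite training loss at epoch {epoch}, mu={mu:g}"
                )
            if trial_sse < current_sse:
                theta = trial
                current_sse = trial_sse
                mu = max(mu * config.mu_decrease, 1e-20)
                accepted = True
                break
            mu *= config.mu_increase
        if not accepted:
            record.stop_reason = "mu_max"
            break

        net.set_flat(theta)
        record.train_mse.append(current_sse / len(ytr))
        record.val_mse.append(_mse(net, Xval, yval))
        record.test_mse.append(_mse(net, Xte, yte))

        val = record.val_mse[-1]
        if math.isnan(val) or val < record.best_val_mse - 1e-15:
            record.best_val_mse = val if not math.isnan(val) else record.best_val_mse
            record.best_epoch = epoch
            best = net.copy()
            fails = 0
        else:
            fails += 1
            if fails >= config.patience:
                record.stop_reason = "patience"
                break
        if record.train_mse[-1] <= config.goal_mse:
            record.stop_reason = "goal"
            break
    else:
        record.stop_reason = "max_epochs"

    if record.best_epoch < 0:  # no epoch completed; return initial weights
        best = net.copy()
    return best, record


def response_curve(
    net: NetworkParameters,
    normalizers: tuple[Normalizer, Normalizer],
    factor_index: int,
    held: Sequence[float] | None = None,
    grid_points: int = 101,
) -> tuple[np.ndarray, np.ndarray]:
    """Individual-effect profile of one factor, others held fixed.

    The varied factor sweeps its normalizer range; ``held`` gives the other
    factors' actual values (default: midpoint of each range, the design
    center).  Returns (actual grid, predicted response in g/L).
    """
    x_norm, y_norm = normalizers
    lo = np.asarray(x_norm.lo)
    hi = np.asarray(x_norm.hi)
    base = (lo + hi) / 2.0 if held is None else np.asarray(held, dtype=float)
    if base.shape != lo.shape:
        raise ValueError("held values must match the number of factors")
    grid = np.linspace(lo[factor_index], hi[factor_index], grid_points)
    pts = np.tile(base, (grid_points, 1))
    pts[:, factor_index] = grid
    zn = forward(net, x_norm.transform(pts))
    y = y_norm.inverse(np.column_stack([zn]))[:, 0]
    return grid, y


# ---------------------------------------------------------------------------
# Serialization


def network_to_json(
    net: NetworkParameters,
    normalizers: tuple[Normalizer, Normalizer] | None = None,
    **kwargs,
) -> str:
    payload: dict = {
        "weights": [W.tolist() for W in net.weights],
        "biases": [b.tolist() for b in net.biases],
        "activations": list(net.activations),
    }
    if normalizers is not None:
        x_norm, y_norm = normalizers
        payload["input_range"] = {"lo": list(x_norm.lo), "hi": list(x_norm.hi)}
        payload["target_range"] = {"lo": list(y_norm.lo), "hi": list(y_norm.hi)}
    return json.dumps(payload, **kwargs)


def network_from_json(
    text: str,
) -> tuple[NetworkParameters, tuple[Normalizer, Normalizer] | None]:
    payload = json.loads(text)
    net = NetworkParameters(
        [np.asarray(W, dtype=float) for W in payload["weights"]],
        [np.asarray(b, dtype=float) for b in payload["biases"]],
        list(payload["activations"]),
    )
    norms = None
    if "input_range" in payload:
        norms = (
            Normalizer(tuple(payload["input_range"]["lo"]), tuple(payload["input_range"]["hi"])),
            Normalizer(tuple(payload["target_range"]["lo"]), tuple(payload["target_range"]["hi"])),
        )
    return net, norms
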
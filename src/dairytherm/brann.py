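"""Bayesian-regularized two-layer feedforward regression network (BR-ANN).

A single network maps the 21 normalized inputs through a tan-sigmoid hidden
layer (10 neurons by default) and a linear output layer to the 4 normalized
targets.  Training minimises the regularised objective

    F(w) = beta * E_D + alpha * E_W

where ``E_D`` is the sum of squared errors over all observations
(samples x 4 targets) and ``E_W`` the sum of squared weights, by
Levenberg-Marquardt steps

    dw = -(beta * J'J + (alpha + mu) I)^-1 (beta * J'e + alpha * w)

with the damping factor ``mu`` adapted multiplicatively.  After every
accepted step the hyperparameters are re-estimated from MacKay's evidence
framework:

    gamma = N_w - alpha * tr(H^-1),    H = beta * J'J + alpha * I
    alpha = gamma / (2 E_W),           beta  = (N_D - gamma) / (2 E_D)

``gamma`` is the effective number of well-determined parameters; it is
bounded by the total weight count and typically settles well below it,
which is what suppresses overfitting without a validation set.

The Jacobian of the stacked per-observation errors is computed by exact
per-sample backpropagation and accumulated into the (N_w x N_w) normal
matrix in row blocks, so memory stays flat in the number of samples.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .dataset import (
    FeatureMatrix,
    INPUT_COLUMNS,
    Normalizer,
    SplitIndex,
    TARGET_COLUMNS,
    split_rows,
)

__all__ = [
    "NetworkParams",
    "TrainConfig",
    "TrainState",
    "init_network",
    "forward",
    "jacobian",
    "train",
    "TrainedModel",
    "fit_model",
]


@dataclasses.dataclass
class NetworkParams:
    """Weights and biases of the two-layer network, plus the frozen
    input/target column signature of the matrix it was trained on."""

    w1: np.ndarray  # (n_hidden, n_in)
    b1: np.ndarray  # (n_hidden,)
    w2: np.ndarray  # (n_out, n_hidden)
    b2: np.ndarray  # (n_out,)
    signature: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        h, n_in = self.w1.shape
        n_out = self.w2.shape[0]
        if self.b1.shape != (h,) or self.w2.shape != (n_out, h) or self.b2.shape != (n_out,):
            raise ValueError("inconsistent layer shapes")
        for a in (self.w1, self.b1, self.w2, self.b2):
            if not np.all(np.isfinite(a)):
                raise ValueError("network parameters must be finite")

    @property
    def n_weights(self) -> int:
        return self.w1.size + self.b1.size + self.w2.size + self.b2.size

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [self.w1.ravel(), self.b1, self.w2.ravel(), self.b2]
        )

    def with_vector(self, w: np.ndarray) -> "NetworkParams":
        h, n_in = self.w1.shape
        n_out = self.w2.shape[0]
        i = 0
        w1 = w[i:i + h * n_in].reshape(h, n_in); i += h * n_in
        b1 = w[i:i + h]; i += h
        w2 = w[i:i + n_out * h].reshape(n_out, h); i += n_out * h
        b2 = w[i:i + n_out]
        return NetworkParams(w1=w1.copy(), b1=b1.copy(), w2=w2.copy(),
                             b2=b2.copy(), signature=self.signature)


@dataclasses.dataclass
class TrainConfig:
    """Optimiser settings.  Ten hidden neurons is the model-selection
    outcome adopted as default; the damping schedule is the standard
    Levenberg-Marquardt one."""

    n_hidden: int = 10
    max_epochs: int = 1000
    mu_init: float = 0.005
    mu_increase: float = 10.0
    mu_decrease: float = 0.1
    mu_max: float = 1e10
    grad_tol: float = 1e-7
    seed: int = 0
    split_fraction: float = 0.7

    def validate(self) -> None:
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        for f in ("mu_init", "mu_increase", "mu_decrease", "mu_max"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be > 0")


@dataclasses.dataclass
class TrainState:
    """Final optimiser state plus the per-epoch history.

    ``history`` rows carry epoch, mu, alpha, beta, gamma, e_d, e_w, and the
    objective before/after the accepted step evaluated at that epoch's
    (alpha, beta) — F decreases within every accepted step by construction.
    """

    epoch: int
    mu: float
    alpha: float
    beta: float
    gamma: float
    e_d: float
    e_w: float
    n_weights: int
    n_observations: int
    stop_reason: str
    history: list[dict] = dataclasses.field(default_factory=list)


def init_network(n_in: int, n_hidden: int, n_out: int, seed: int = 0) -> NetworkParams:
    """Nguyen-Widrow initialization over the [-1, 1] input cube.

    Hidden rows are random directions scaled to magnitude
    ``0.7 * n_hidden**(1/n_in)`` with biases spread uniformly across the
    active range, so the sigmoids' linear regions tile the cube; the output
    layer starts small and uniform.
    """
    if min(n_in, n_hidden, n_out) < 1:
        raise ValueError("all dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    scale = 0.7 * n_hidden ** (1.0 / n_in)
    w1 = rng.uniform(-1.0, 1.0, size=(n_hidden, n_in))
    norms = np.linalg.norm(w1, axis=1, keepdims=True)
    w1 = scale * w1 / np.where(norms == 0, 1.0, norms)
    if n_hidden > 1:
        b1 = scale * np.linspace(-1.0, 1.0, n_hidden) * np.sign(w1[:, 0])
    else:
        b1 = np.zeros(1)
    w2 = rng.uniform(-0.5, 0.5, size=(n_out, n_hidden))
    b2 = rng.uniform(-0.5, 0.5, size=n_out)
    return NetworkParams(w1=w1, b1=b1, w2=w2, b2=b2)


def forward(params: NetworkParams, x: np.ndarray, *, signature: tuple[str, ...] | None = None) -> np.ndarray:
    """Network output ``W2 tanh(W1 x + b1) + b2`` for rows of ``x``."""
    if signature is not None and params.signature and tuple(signature) != tuple(params.signature):
        raise ValueError("input column signature does not match the trained network")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != params.w1.shape[1]:
        raise ValueError(
            f"expected {params.w1.shape[1]} input columns, got {x.shape[1]}"
        )
    z = np.tanh(x @ params.w1.T + params.b1)
    return z @ params.w2.T + params.b2


def _unpack_dims(params: NetworkParams) -> tuple[int, int, int]:
    h, n_in = params.w1.shape
    return n_in, h, params.w2.shape[0]


def jacobian(params: NetworkParams, x: np.ndarray) -> np.ndarray:
    """Dense error Jacobian d y / d w, shape (n_samples * n_out, N_w).

    Rows are ordered sample-major (all outputs of sample 0, then sample 1,
    ...), columns follow the ``to_vector`` packing (W1, b1, W2, b2).  Exact
    per-sample backpropagation; intended for tests and small batches — the
    trainer accumulates J'J in blocks without materialising J.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n_in, h, n_out = _unpack_dims(params)
    m = x.shape[0]
    z = np.tanh(x @ params.w1.T + params.b1)        # (m, h)
    d = 1.0 - z * z                                  # tanh' at hidden input
    jac = np.empty((m, n_out, params.n_weights))
    # dW1[j, p] block: W2[k, j] * d[i, j] * x[i, p]
    jac[:, :, : h * n_in] = np.einsum(
        "kj,ij,ip->ikjp", params.w2, d, x
    ).reshape(m, n_out, h * n_in)
    off = h * n_in
    jac[:, :, off : off + h] = np.einsum("kj,ij->ikj", params.w2, d)
    off += h
    w2_block = np.zeros((m, n_out, n_out, h))
    idx = np.arange(n_out)
    w2_block[:, idx, idx, :] = z[:, None, :]
    jac[:, :, off : off + n_out * h] = w2_block.reshape(m, n_out, n_out * h)
    off += n_out * h
    jac[:, :, off:] = np.eye(n_out)[None, :, :]
    return jac.reshape(m * n_out, params.n_weights)


def _accumulate_normal(params: NetworkParams, x: np.ndarray, t: np.ndarray,
                       chunk: int = 2048) -> tuple[np.ndarray, np.ndarray, float]:
    """Blockwise J'J, J'e and E_D at the current weights (e = y - t)."""
    nw = params.n_weights
    jtj = np.zeros((nw, nw))
    jte = np.zeros(nw)
    e_d = 0.0
    for start in range(0, x.shape[0], chunk):
        xs = x[start : start + chunk]
        ts = t[start : start + chunk]
        jc = jacobian(params, xs)
        ec = (forward(params, xs) - ts).ravel()
        jtj += jc.T @ jc
        jte += jc.T @ ec
        e_d += float(ec @ ec)
    return jtj, jte, e_d


def _sse(params: NetworkParams, x: np.ndarray, t: np.ndarray) -> float:
    e = forward(params, x) - t
    return float(np.sum(e * e))


def train(
    x: np.ndarray,
    t: np.ndarray,
    config: TrainConfig | None = None,
    params: NetworkParams | None = None,
) -> tuple[NetworkParams, TrainState]:
    """Fit the network to normalized inputs/targets by LM under Bayesian
    regularization.

    ``x`` and ``t`` are the training rows only, already mapped to [-1, 1].
    Hyperparameters start at ``alpha = 0``, ``beta = 1`` and are updated
    from the evidence after every accepted step, using the curvature
    already accumulated at the step's starting point.  Stops on
    ``max_epochs``, the gradient tolerance, the ``mu`` cap, or zero error.

    Returns the fitted parameters and the full :class:`TrainState`.
    """
    config = config or TrainConfig()
    config.validate()
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    if x.ndim != 2 or t.ndim != 2 or x.shape[0] != t.shape[0]:
        raise ValueError("x and t must be 2-D with equal row counts")
    if x.shape[0] < config.n_hidden:
        raise ValueError("need at least n_hidden training rows")

    if params is None:
        params = init_network(x.shape[1], config.n_hidden, t.shape[1], config.seed)
    w = params.to_vector()
    nw = params.n_weights
    n_obs = t.size  # samples x targets
    eye = np.eye(nw)

    alpha, beta = 0.0, 1.0
    mu = config.mu_init
    gamma = float(nw)
    history: list[dict] = []
    stop_reason = "max_epochs"

    e_w = float(w @ w)
    e_d = _sse(params, x, t)

    epoch = 0
    for epoch in range(1, config.max_epochs + 1):
        jtj, jte, e_d = _accumulate_normal(params, x, t)
        if not np.isfinite(e_d):
            raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
        e_w = float(w @ w)
        f_current = beta * e_d + alpha * e_w

        grad = 2.0 * (beta * jte + alpha * w)
        if np.max(np.abs(grad)) < config.grad_tol:
            stop_reason = "gradient_tolerance"
            break

        accepted = False
        while mu <= config.mu_max:
            a_mat = beta * jtj + (alpha + mu) * eye
            try:
                chol = cho_factor(a_mat)
            except np.linalg.LinAlgError:
                mu *= config.mu_increase
                continue
            step = cho_solve(chol, -(beta * jte + alpha * w))
            w_new = w + step
            params_new = params.with_vector(w_new)
            e_d_new = _sse(params_new, x, t)
            e_w_new = float(w_new @ w_new)
            f_new = beta * e_d_new + alpha * e_w_new
            if np.isfinite(f_new) and f_new < f_current:
                accepted = True
                break
            mu *= config.mu_increase
        if not accepted:
            stop_reason = "mu_cap"
            break

        # Evidence update with the curvature from the step's starting point.
        # tr(H^-1) from the eigenvalues of J'J: robust to the (numerically)
        # singular gauge directions a tanh layer always carries.
        if alpha > 0.0:
            lam = np.maximum(np.linalg.eigvalsh(jtj), 0.0)
            hinv_trace = float(np.sum(1.0 / (beta * lam + alpha)))
            gamma = nw - alpha * hinv_trace
        else:
            gamma = float(nw)  # alpha = 0: every parameter is unconstrained by the prior
        gamma = float(np.clip(gamma, 0.0, nw))
        alpha = gamma / max(2.0 * e_w_new, 1e-300)
        beta = max(n_obs - gamma, 1e-12) / max(2.0 * e_d_new, 1e-300)

        params, w, e_d, e_w = params_new, w_new, e_d_new, e_w_new
        mu = max(mu * config.mu_decrease, 1e-20)
        history.append(
            {
                "epoch": epoch, "mu": mu, "alpha": alpha, "beta": beta,
                "gamma": gamma, "e_d": e_d, "e_w": e_w,
                "f_before": f_current, "f_after": f_new,
            }
        )
        if e_d == 0.0:
            stop_reason = "zero_error"
            break

    state = TrainState(
        epoch=epoch, mu=mu, alpha=alpha, beta=beta, gamma=gamma,
        e_d=e_d, e_w=e_w, n_weights=nw, n_observations=n_obs,
        stop_reason=stop_reason, history=history,
    )
    return params, state


@dataclasses.dataclass
class TrainedModel:
    """A trained network bundled with its normalizers and provenance.

    ``predict`` takes a table with the 21 frozen input columns in original
    units and returns the four targets in original units; the stored column
    signature guards against silently re-ordered matrices.
    """

    params: NetworkParams
    input_normalizer: Normalizer
    target_normalizer: Normalizer
    config: TrainConfig
    state: TrainState

    def predict_normalized(self, x_norm: np.ndarray) -> np.ndarray:
        return forward(self.params, x_norm)

    def predict(self, inputs: pd.DataFrame) -> pd.DataFrame:
        if list(inputs.columns) != INPUT_COLUMNS:
            raise ValueError("input table does not match the trained column signature")
        x_norm = self.input_normalizer.apply(inputs)
        y_norm = forward(self.params, x_norm)
        return self.target_normalizer.invert(y_norm)

    def save(self, path) -> None:
        payload = {
            "w1": self.params.w1.tolist(),
            "b1": self.params.b1.tolist(),
            "w2": self.params.w2.tolist(),
            "b2": self.params.b2.tolist(),
            "signature": list(self.params.signature),
            "input_normalizer": self.input_normalizer.to_dict(),
            "target_normalizer": self.target_normalizer.to_dict(),
            "config": dataclasses.asdict(self.config),
            "final_state": {
                "epoch": self.state.epoch, "alpha": self.state.alpha,
                "beta": self.state.beta, "gamma": self.state.gamma,
                "e_d": self.state.e_d, "e_w": self.state.e_w,
                "n_weights": self.state.n_weights,
                "n_observations": self.state.n_observations,
                "stop_reason": self.state.stop_reason,
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with open(path) as fh:
            d = json.load(fh)
        params = NetworkParams(
            w1=np.asarray(d["w1"], dtype=float),
            b1=np.asarray(d["b1"], dtype=float),
            w2=np.asarray(d["w2"], dtype=float),
            b2=np.asarray(d["b2"], dtype=float),
            signature=tuple(d["signature"]),
        )
        fs = d["final_state"]
        state = TrainState(
            epoch=fs["epoch"], mu=float("nan"), alpha=fs["alpha"],
            beta=fs["beta"], gamma=fs["gamma"], e_d=fs["e_d"], e_w=fs["e_w"],
            n_weights=fs["n_weights"], n_observations=fs["n_observations"],
            stop_reason=fs["stop_reason"], history=[],
        )
        return cls(
            params=params,
            input_normalizer=Normalizer.from_dict(d["input_normalizer"]),
            target_normalizer=Normalizer.from_dict(d["target_normalizer"]),
            config=TrainConfig(**d["config"]),
            state=state,
        )


def fit_model(
    features: FeatureMatrix,
    config: TrainConfig | None = None,
    *,
    normalize_on: str = "train",
) -> tuple[TrainedModel, SplitIndex]:
    """End-to-end fit: split rows 70/30, normalize, train.

    ``normalize_on`` selects which rows fix the [-1, 1] ranges: ``"train"``
    (default, leakage-free) or ``"all"`` (normalize the full table before
    splitting).
    """
    config = config or TrainConfig()
    if normalize_on not in ("train", "all"):
        raise ValueError("normalize_on must be 'train' or 'all'")
    split = split_rows(features.n_rows, config.split_fraction, config.seed)
    fit_rows = None if normalize_on == "all" else split.train
    norm_x = Normalizer.fit(features.inputs, rows=fit_rows)
    norm_t = Normalizer.fit(features.targets, rows=fit_rows)
    x = norm_x.apply(features.inputs)
    t = norm_t.apply(features.targets)
    params, state = train(x[split.train], t[split.train], config)
    params.signature = features.signature
    model = TrainedModel(
        params=params,
        input_normalizer=norm_x,
        target_normalizer=norm_t,
        config=config,
        state=state,
    )
    return model, split
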
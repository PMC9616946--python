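"""BiLSTM header classifier, Adam training loop, Bayesian tuning, baselines.

The network mirrors the reference architecture: a sequence input of 3-axis,
100-sample z-normalized acceleration traces feeds a bidirectional LSTM with
100 hidden units per direction; the concatenated final forward/backward
hidden states (200 values) pass through a fully connected hidden layer
(tanh, tuned width 43), a linear output map to the two classes (VH / NH)
and a softmax.  The loss is cross entropy over the softmax outputs plus an
L2 penalty on weight matrices (not biases).

The optimizer implements the Adam moving-average recurrences

    m_l = b1 * m_{l-1} + (1 - b1) * g
    v_l = b2 * v_{l-1} + (1 - b2) * g**2
    theta_{l+1} = theta_l - alpha * m_l / (sqrt(v_l) + eps)

exactly in this form, i.e. *without* the bias-correction terms of standard
Adam; a config switch restores the bias-corrected variant.  Defaults are
the tuned values of the reference configuration (alpha = 0.168, batch 119,
L2 = 0.0016, 43 hidden nodes, b1 = 0.9, b2 = 0.99, eps = 1e-8, 3 epochs).

Hyperparameter search runs Bayesian optimization: a Gaussian-process
surrogate (scikit-learn) is fit to observed validation errors over the
4-dimensional box (learning rate and L2 on log scale) and each new proposal
maximizes Expected Improvement over a random candidate pool.

The amplitude-threshold baselines classify an event as a header whenever
the peak resultant acceleration exceeds a fixed threshold (10 g or 16 g in
the reference comparison).

Everything is plain numpy; forward and backward passes are hand-written and
validated against central-difference gradients in the test suite.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .io_formats import NH, VH, LabeledEvent, SensorEventRecord

# parameter keys holding weight matrices (L2-penalized); biases are exempt
_WEIGHT_KEYS = ("Wx_f", "Wh_f", "Wx_b", "Wh_b", "W1", "W2")
_BIAS_KEYS = ("b_f", "b_b", "b1", "b2")
PARAM_KEYS = _WEIGHT_KEYS[:4] + _BIAS_KEYS[:2] + _WEIGHT_KEYS[4:] + _BIAS_KEYS[2:]


@dataclass
class NetworkConfig:
    """Architecture: D input axes, N timesteps, H LSTM units, F hidden nodes."""

    input_axes: int = 3
    seq_len: int = 100
    hidden_units: int = 100
    fc_nodes: int = 43
    classes: int = 2

    def __post_init__(self) -> None:
        for name in ("input_axes", "seq_len", "hidden_units", "fc_nodes", "classes"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if not 20 <= self.fc_nodes <= 100:
            raise ValueError("fc_nodes must lie in the search range [20, 100]")


@dataclass
class TrainingConfig:
    """Optimizer and loop settings; defaults are the tuned reference values."""

    learning_rate: float = 0.168
    batch_size: int = 119
    l2: float = 0.0016
    beta1: float = 0.9
    beta2: float = 0.99
    eps: float = 1e-8
    epochs: int = 3
    bias_correction: bool = False
    restore_best: bool = True   # return the checkpoint with lowest val loss
    val_check_steps: int = 5    # validate/checkpoint every this many updates
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ValueError("beta decay rates must lie in [0, 1)")
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.val_check_steps < 1:
            raise ValueError("val_check_steps must be >= 1")
        if self.l2 < 0:
            raise ValueError("l2 must be nonnegative")


# ---------------------------------------------------------------------------
# Model parameters
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = math.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


def init_model(cfg: NetworkConfig, seed: int | np.random.Generator = 0) -> dict:
    """Seed-deterministic Glorot-uniform initialization of all parameters.

    LSTM gate order within the stacked 4H dimension is input, forget, cell,
    output; forget-gate biases start at 1 so early gradients flow through
    the cell state.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    D, H, F, C = cfg.input_axes, cfg.hidden_units, cfg.fc_nodes, cfg.classes
    params = {}
    for suffix in ("f", "b"):
        params[f"Wx_{suffix}"] = _glorot(rng, (D, 4 * H))
        params[f"Wh_{suffix}"] = _glorot(rng, (H, 4 * H))
        bias = np.zeros(4 * H)
        bias[H:2 * H] = 1.0
        params[f"b_{suffix}"] = bias
    params["W1"] = _glorot(rng, (2 * H, F))
    params["b1"] = np.zeros(F)
    params["W2"] = _glorot(rng, (F, C))
    params["b2"] = np.zeros(C)
    return params


def parameter_count(params: dict) -> int:
    return int(sum(v.size for v in params.values()))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _lstm_forward(X: np.ndarray, Wx: np.ndarray, Wh: np.ndarray, b: np.ndarray):
    """Run one LSTM direction over X (B, N, D); return final h and cache."""
    B, N, D = X.shape
    H = Wh.shape[0]
    xp = X.reshape(B * N, D) @ Wx
    xp = xp.reshape(B, N, 4 * H) + b
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    cache = []
    for t in range(N):
        a = xp[:, t, :] + h @ Wh
        i = _sigmoid(a[:, :H])
        f = _sigmoid(a[:, H:2 * H])
        g = np.tanh(a[:, 2 * H:3 * H])
        o = _sigmoid(a[:, 3 * H:])
        c_prev, h_prev = c, h
        c = f * c_prev + i * g
        tc = np.tanh(c)
        h = o * tc
        cache.append((i, f, g, o, c_prev, h_prev, tc))
    return h, cache


def _lstm_backward(dh_last: np.ndarray, X: np.ndarray, Wx: np.ndarray,
                   Wh: np.ndarray, cache) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Backprop through one direction given the gradient at the final h."""
    B, N, D = X.shape
    H = Wh.shape[0]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H)
    dh = dh_last
    dc = np.zeros((B, H))
    for t in range(N - 1, -1, -1):
        i, f, g, o, c_prev, h_prev, tc = cache[t]
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc ** 2)
        di = dc * g
        dg = dc * i
        df = dc * c_prev
        dc = dc * f
        da = np.concatenate([
            di * i * (1.0 - i),
            df * f * (1.0 - f),
            dg * (1.0 - g ** 2),
            do * o * (1.0 - o),
        ], axis=1)
        dWx += X[:, t, :].T @ da
        dWh += h_prev.T @ da
        db += da.sum(axis=0)
        dh = da @ Wh.T
    return dWx, dWh, db


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def forward(params: dict, X: np.ndarray) -> np.ndarray:
    """Class probabilities for a batch of z-normalized traces (B, D, N)."""
    probs, _ = _forward_full(params, X)
    return probs


def _forward_full(params: dict, X: np.ndarray):
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        X = X[None]
    D = params["Wx_f"].shape[0]
    if X.ndim != 3 or X.shape[1] != D:
        raise ValueError(f"expected traces shaped (batch, {D}, N), got {X.shape}")
    Xt = X.transpose(0, 2, 1)  # (B, N, D)
    h_f, cache_f = _lstm_forward(Xt, params["Wx_f"], params["Wh_f"], params["b_f"])
    Xr = Xt[:, ::-1, :]
    h_b, cache_b = _lstm_forward(Xr, params["Wx_b"], params["Wh_b"], params["b_b"])
    hcat = np.concatenate([h_f, h_b], axis=1)
    # stacked fully connected layers with no interposed activation, as in
    # the usual sequence-classification layer stack
    a1 = hcat @ params["W1"] + params["b1"]
    logits = a1 @ params["W2"] + params["b2"]
    probs = _softmax(logits)
    return probs, (Xt, Xr, cache_f, cache_b, hcat, a1)


def loss_and_gradients(params: dict, X: np.ndarray, y: np.ndarray,
                       l2: float = 0.0):
    """Mean cross-entropy + L2 on weight matrices; returns (loss, grads, probs)."""
    y = np.asarray(y, dtype=int)
    probs, (Xt, Xr, cache_f, cache_b, hcat, a1) = _forward_full(params, X)
    B = probs.shape[0]
    eps = 1e-300
    data_loss = -float(np.mean(np.log(probs[np.arange(B), y] + eps)))
    reg_loss = l2 * sum(float((params[k] ** 2).sum()) for k in _WEIGHT_KEYS)
    grads = {}
    dlogits = probs.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits /= B
    grads["W2"] = a1.T @ dlogits + 2.0 * l2 * params["W2"]
    grads["b2"] = dlogits.sum(axis=0)
    dz1 = dlogits @ params["W2"].T
    grads["W1"] = hcat.T @ dz1 + 2.0 * l2 * params["W1"]
    grads["b1"] = dz1.sum(axis=0)
    dhcat = dz1 @ params["W1"].T
    H = params["Wh_f"].shape[0]
    dWx, dWh, db = _lstm_backward(dhcat[:, :H], Xt, params["Wx_f"],
                                  params["Wh_f"], cache_f)
    grads["Wx_f"] = dWx + 2.0 * l2 * params["Wx_f"]
    grads["Wh_f"] = dWh + 2.0 * l2 * params["Wh_f"]
    grads["b_f"] = db
    dWx, dWh, db = _lstm_backward(dhcat[:, H:], Xr, params["Wx_b"],
                                  params["Wh_b"], cache_b)
    grads["Wx_b"] = dWx + 2.0 * l2 * params["Wx_b"]
    grads["Wh_b"] = dWh + 2.0 * l2 * params["Wh_b"]
    grads["b_b"] = db
    return data_loss + reg_loss, grads, probs


# ---------------------------------------------------------------------------
# Adam, exactly as the printed recurrences
# ---------------------------------------------------------------------------

@dataclass
class OptimizerState:
    """First/second moment estimates and the iteration counter."""

    m: dict
    v: dict
    iteration: int = 0

    @classmethod
    def zeros_like(cls, params: dict) -> "OptimizerState":
        return cls(m={k: np.zeros_like(p) for k, p in params.items()},
                   v={k: np.zeros_like(p) for k, p in params.items()})


def adam_step(params: dict, grads: dict, state: OptimizerState,
              cfg: TrainingConfig) -> tuple[dict, OptimizerState]:
    """One update of the moving-average recurrences (in place, returned).

    With ``cfg.bias_correction`` the standard m-hat/v-hat correction is
    applied; the default follows the uncorrected printed form.
    """
    state.iteration += 1
    l = state.iteration
    for k, p in params.items():
        g = grads[k]
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite gradient for parameter {k!r} "
                                     f"at iteration {l}")
        state.m[k] = cfg.beta1 * state.m[k] + (1.0 - cfg.beta1) * g
        state.v[k] = cfg.beta2 * state.v[k] + (1.0 - cfg.beta2) * g ** 2
        m, v = state.m[k], state.v[k]
        if cfg.bias_correction:
            m = m / (1.0 - cfg.beta1 ** l)
            v = v / (1.0 - cfg.beta2 ** l)
        params[k] = p - cfg.learning_rate * m / (np.sqrt(v) + cfg.eps)
    return params, state


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def evaluate_loss(params: dict, X: np.ndarray, y: np.ndarray, l2: float = 0.0,
                  batch_size: int = 512) -> tuple[float, np.ndarray]:
    """Forward-only mean cross-entropy + L2; returns (loss, probabilities)."""
    y = np.asarray(y, dtype=int)
    chunks = []
    for start in range(0, len(X), batch_size):
        chunks.append(forward(params, X[start:start + batch_size]))
    probs = np.concatenate(chunks)
    data_loss = -float(np.mean(np.log(probs[np.arange(len(y)), y] + 1e-300)))
    reg = l2 * sum(float((params[k] ** 2).sum()) for k in _WEIGHT_KEYS)
    return data_loss + reg, probs


def predict(params: dict, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Hard labels (1 = header) for a batch of z-normalized traces."""
    out = []
    for start in range(0, len(X), batch_size):
        probs = forward(params, X[start:start + batch_size])
        out.append((probs[:, 1] > 0.5).astype(int))
    return np.concatenate(out) if out else np.empty(0, dtype=int)


def _sensitivity_specificity(pred: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    pos, neg = y == 1, y == 0
    sens = float((pred[pos] == 1).mean()) if pos.any() else math.nan
    spec = float((pred[neg] == 0).mean()) if neg.any() else math.nan
    return sens, spec


def train(params: dict, train_xy: tuple[np.ndarray, np.ndarray],
          val_xy: tuple[np.ndarray, np.ndarray],
          cfg: TrainingConfig) -> tuple[dict, dict]:
    """Run the mini-batch Adam loop; returns (trained params, history).

    ``train_xy`` / ``val_xy`` are (X, y) with z-normalized traces; the data
    are reshuffled each epoch with the config seed, so a fixed seed gives a
    bit-identical history.  History records per-epoch mean training loss,
    validation loss, and validation sensitivity/specificity.

    With ``cfg.restore_best`` (the default) the returned parameters are the
    checkpoint with the lowest validation loss, probed every
    ``cfg.val_check_steps`` updates and at every epoch end; the constant
    per-parameter step of the uncorrected moving-average update never
    anneals, so the last iterate is not systematically the best one and the
    validation set is what selects among checkpoints.
    """
    X, y = train_xy
    Xv, yv = val_xy
    if len(X) == 0 or len(Xv) == 0:
        raise ValueError("training and validation sets must be nonempty")
    rng = np.random.default_rng(cfg.seed)
    state = OptimizerState.zeros_like(params)
    history = {"train_loss": [], "val_loss": [], "val_sensitivity": [],
               "val_specificity": []}
    best_params, best_val = None, math.inf

    def checkpoint() -> None:
        nonlocal best_params, best_val
        vl, _ = evaluate_loss(params, Xv, yv, cfg.l2)
        if vl < best_val:
            best_val = vl
            best_params = {k: v.copy() for k, v in params.items()}

    step = 0
    for _ in range(cfg.epochs):
        order = rng.permutation(len(X))
        batch_losses = []
        for start in range(0, len(X), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            loss, grads, _ = loss_and_gradients(params, X[idx], y[idx], cfg.l2)
            params, state = adam_step(params, grads, state, cfg)
            batch_losses.append(loss)
            step += 1
            if cfg.restore_best and step % cfg.val_check_steps == 0:
                checkpoint()
        val_loss, val_probs = evaluate_loss(params, Xv, yv, cfg.l2)
        sens, spec = _sensitivity_specificity((val_probs[:, 1] > 0.5).astype(int), yv)
        history["train_loss"].append(float(np.mean(batch_losses)))
        history["val_loss"].append(float(val_loss))
        history["val_sensitivity"].append(sens)
        history["val_specificity"].append(spec)
        if cfg.restore_best:
            checkpoint()
    if cfg.restore_best and best_params is not None:
        params = best_params
    return params, history


def weight_norm(params: dict) -> float:
    """Euclidean norm over the L2-penalized weight matrices."""
    return math.sqrt(sum(float((params[k] ** 2).sum()) for k in _WEIGHT_KEYS))


# ---------------------------------------------------------------------------
# Bayesian hyperparameter optimization (GP surrogate + Expected Improvement)
# ---------------------------------------------------------------------------

@dataclass
class SearchSpace:
    """The 4-d tuning box; learning rate and L2 factor vary on log scale."""

    learning_rate: tuple[float, float] = (1e-2, 1.0)
    batch_size: tuple[int, int] = (64, 128)
    l2: tuple[float, float] = (1e-8, 1e-1)
    fc_nodes: tuple[int, int] = (20, 100)

    def to_unit(self, x: dict) -> np.ndarray:
        lr_lo, lr_hi = np.log(self.learning_rate)
        l2_lo, l2_hi = np.log(self.l2)
        return np.array([
            (math.log(x["learning_rate"]) - lr_lo) / (lr_hi - lr_lo),
            (x["batch_size"] - self.batch_size[0])
            / (self.batch_size[1] - self.batch_size[0]),
            (math.log(x["l2"]) - l2_lo) / (l2_hi - l2_lo),
            (x["fc_nodes"] - self.fc_nodes[0])
            / (self.fc_nodes[1] - self.fc_nodes[0]),
        ])

    def from_unit(self, u: np.ndarray) -> dict:
        u = np.clip(u, 0.0, 1.0)
        lr_lo, lr_hi = np.log(self.learning_rate)
        l2_lo, l2_hi = np.log(self.l2)
        return {
            "learning_rate": float(np.exp(lr_lo + u[0] * (lr_hi - lr_lo))),
            "batch_size": int(round(self.batch_size[0]
                                    + u[1] * (self.batch_size[1] - self.batch_size[0]))),
            "l2": float(np.exp(l2_lo + u[2] * (l2_hi - l2_lo))),
            "fc_nodes": int(round(self.fc_nodes[0]
                                  + u[3] * (self.fc_nodes[1] - self.fc_nodes[0]))),
        }

    def contains(self, x: dict) -> bool:
        return (self.learning_rate[0] <= x["learning_rate"] <= self.learning_rate[1]
                and self.batch_size[0] <= x["batch_size"] <= self.batch_size[1]
                and self.l2[0] <= x["l2"] <= self.l2[1]
                and self.fc_nodes[0] <= x["fc_nodes"] <= self.fc_nodes[1])


@dataclass
class HyperSearchResult:
    best: dict
    best_error: float
    observations: list  # append-only (configuration, validation error) pairs


def expected_improvement(mu: np.ndarray, sigma: np.ndarray, y_best: float,
                         xi: float = 0.01) -> np.ndarray:
    """EI for minimization under a Gaussian posterior."""
    sigma = np.maximum(sigma, 1e-12)
    z = (y_best - mu - xi) / sigma
    return (y_best - mu - xi) * stats.norm.cdf(z) + sigma * stats.norm.pdf(z)


def propose_next(space: SearchSpace, observations: Sequence[tuple[dict, float]],
                 rng: np.random.Generator, n_candidates: int = 512) -> dict:
    """Maximize EI of a GP surrogate fit to the observations so far."""
    import warnings

    from sklearn.exceptions import ConvergenceWarning
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import ConstantKernel, Matern

    U = np.stack([space.to_unit(x) for x, _ in observations])
    yv = np.array([err for _, err in observations])
    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
        length_scale=0.3, length_scale_bounds=(1e-2, 1e2), nu=2.5)
    gp = GaussianProcessRegressor(kernel=kernel, alpha=1e-4,
                                  normalize_y=True, random_state=0)
    with warnings.catch_warnings():
        # noisy objectives legitimately push the length scale to its bound
        warnings.simplefilter("ignore", ConvergenceWarning)
        gp.fit(U, yv)
    cand = rng.uniform(size=(n_candidates, U.shape[1]))
    mu, sigma = gp.predict(cand, return_std=True)
    return space.from_unit(cand[int(np.argmax(
        expected_improvement(mu, sigma, float(yv.min()))))])


def tune(train_xy, val_xy, space: SearchSpace | None = None, budget: int = 40,
         seed: int = 0, base_network: NetworkConfig | None = None,
         base_training: TrainingConfig | None = None,
         n_initial: int = 5, objective_repeats: int = 1,
         objective: Callable[[dict], float] | None = None) -> HyperSearchResult:
    """Bayesian optimization of (learning rate, batch size, L2, FC width).

    The first ``n_initial`` configurations are uniform in the (log-scaled)
    unit box; each later proposal maximizes Expected Improvement under the
    GP surrogate.  The objective is the validation error (1 - accuracy) of
    a network freshly initialized and trained with the candidate settings,
    averaged over ``objective_repeats`` independent initialization/shuffle
    seeds — on small datasets a single training run is a noisy estimate
    and favours lucky unstable configurations.
    ``objective`` can replace the train-and-score step (used in tests).
    """
    if budget < max(n_initial, 2):
        raise ValueError(f"budget must cover the initial design ({n_initial})")
    space = space or SearchSpace()
    base_network = base_network or NetworkConfig()
    base_training = base_training or TrainingConfig()
    rng = np.random.default_rng(seed)

    def default_objective(x: dict) -> float:
        net = replace(base_network, fc_nodes=x["fc_nodes"])
        errors = []
        for _ in range(objective_repeats):
            tr = replace(base_training, learning_rate=x["learning_rate"],
                         batch_size=x["batch_size"], l2=x["l2"],
                         seed=int(rng.integers(2 ** 31)))
            params = init_model(net, int(rng.integers(2 ** 31)))
            params, _ = train(params, train_xy, val_xy, tr)
            pred = predict(params, val_xy[0])
            errors.append(float((pred != val_xy[1]).mean()))
        return float(np.mean(errors))

    objective = objective or default_objective
    observations: list[tuple[dict, float]] = []
    for _ in range(n_initial):
        x = space.from_unit(rng.uniform(size=4))
        observations.append((x, objective(x)))
    while len(observations) < budget:
        x = propose_next(space, observations, rng)
        assert space.contains(x)
        observations.append((x, objective(x)))
    best_idx = int(np.argmin([err for _, err in observations]))
    best, best_error = observations[best_idx]
    return HyperSearchResult(best=best, best_error=best_error,
                             observations=observations)


# ---------------------------------------------------------------------------
# Amplitude-threshold baselines
# ---------------------------------------------------------------------------

def peak_resultant(trace: np.ndarray) -> float:
    """Maximum over samples of sqrt(x^2 + y^2 + z^2), in g."""
    trace = np.asarray(trace, dtype=float)
    return float(np.sqrt((trace ** 2).sum(axis=0)).max())


def threshold_classify(events, threshold_g: float) -> list[str]:
    """Label VH iff the raw peak resultant exceeds ``threshold_g``."""
    labels = []
    for item in events:
        if isinstance(item, LabeledEvent):
            trace = item.event.trace
        elif isinstance(item, SensorEventRecord):
            trace = item.trace
        else:
            trace = np.asarray(item)
        labels.append(VH if peak_resultant(trace) > threshold_g else NH)
    return labels


# ---------------------------------------------------------------------------
# Model serialization (shapes + flat arrays + configs, JSON)
# ---------------------------------------------------------------------------

def save_model(params: dict, net_cfg: NetworkConfig, train_cfg: TrainingConfig,
               path: str | Path) -> None:
    doc = {
        "network": net_cfg.__dict__,
        "training": {k: v for k, v in train_cfg.__dict__.items()},
        "parameters": {
            k: {"shape": list(v.shape), "data": v.reshape(-1).tolist()}
            for k, v in params.items()
        },
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path):
    doc = json.loads(Path(path).read_text())
    params = {
        k: np.asarray(v["data"], dtype=float).reshape(v["shape"])
        for k, v in doc["parameters"].items()
    }
    return params, NetworkConfig(**doc["network"]), TrainingConfig(**doc["training"])
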
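"""Six small neural-network classifiers for feature vectors.

Architectures (binary output through a sigmoid unit, cross-entropy loss,
full-batch gradient descent, seeded uniform [-0.5, 0.5] initialization):

* ``slnn`` — single hidden layer, 50 ReLU units;
* ``mlnn`` — two hidden layers of 100 tanh units;
* ``ffnn`` — single hidden layer, 200 sigmoid units;
* ``cfnn`` — cascade-forward: 100 ReLU hidden units plus direct
  input-to-output skip connections;
* ``rnn``  — Elman recurrence over the feature vector presented one feature
  per time step (50 tanh hidden units), final state read out;
* ``grnn`` — generalized regression network: no iterative training, the
  prediction is a Gaussian-kernel-weighted average of training labels.

Default hyperparameters per kind follow the reference study's parameter
table (learning rate, hidden units, activation, epochs; GRNN sigma 0.5,
radius 0.1). Features are z-scored with statistics learned from the
training set and stored on the model, so prediction never sees test-set
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CLASSIFIER_KINDS", "ClassifierConfig", "TrainedModel", "default_config", "train", "predict"]

CLASSIFIER_KINDS = ("slnn", "mlnn", "ffnn", "cfnn", "rnn", "grnn")

_DEFAULTS: dict[str, dict] = {
    "slnn": dict(learning_rate=0.01, hidden_units=50, activation="relu", epochs=100),
    "mlnn": dict(learning_rate=0.05, hidden_units=100, activation="tanh", epochs=200),
    "ffnn": dict(learning_rate=0.1, hidden_units=200, activation="sigmoid", epochs=150),
    "cfnn": dict(learning_rate=0.01, hidden_units=100, activation="relu", epochs=100),
    "rnn": dict(learning_rate=0.01, hidden_units=50, activation="tanh", epochs=200),
    "grnn": dict(learning_rate=0.0, hidden_units=0, activation="gaussian", epochs=0),
}

_INIT_RANGE = 0.5


@dataclass
class ClassifierConfig:
    kind: str
    learning_rate: float
    hidden_units: int
    activation: str
    epochs: int
    sigma: float = 0.5  # grnn kernel width
    radius: float = 0.1  # grnn confidence floor (majority fallback)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.kind != "grnn":
            if self.learning_rate <= 0:
                raise ValueError("learning_rate must be positive")
            if self.epochs < 1:
                raise ValueError("epochs must be >= 1")


def default_config(kind: str, seed: int = 0, **overrides) -> ClassifierConfig:
    """Table defaults for a classifier kind, with optional field overrides."""
    if kind not in _DEFAULTS:
        raise ValueError(f"unknown classifier kind {kind!r}")
    kwargs = dict(_DEFAULTS[kind])
    kwargs.update(overrides)
    return ClassifierConfig(kind=kind, seed=seed, **kwargs)


@dataclass
class TrainedModel:
    kind: str
    input_dim: int
    params: dict[str, np.ndarray]
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    config: ClassifierConfig
    train_history: list[float] = field(default_factory=list)


def _act(name: str, z: np.ndarray) -> np.ndarray:
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "tanh":
        return np.tanh(z)
    if name == "sigmoid":
        return _sigmoid(z)
    raise ValueError(f"unknown activation {name!r}")


def _act_grad(name: str, z: np.ndarray, a: np.ndarray) -> np.ndarray:
    if name == "relu":
        return (z > 0.0).astype(float)
    if name == "tanh":
        return 1.0 - a**2
    if name == "sigmoid":
        return a * (1.0 - a)
    raise ValueError(f"unknown activation {name!r}")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _uniform(rng: np.random.Generator, *shape: int) -> np.ndarray:
    return rng.uniform(-_INIT_RANGE, _INIT_RANGE, size=shape)


def _layer_sizes(cfg: ClassifierConfig) -> list[int]:
    if cfg.kind == "mlnn":
        return [cfg.hidden_units, cfg.hidden_units]
    return [cfg.hidden_units]


def _mlp_forward(params: dict, X: np.ndarray, cfg: ClassifierConfig):
    acts, zs = [X], []
    a = X
    for li in range(len(_layer_sizes(cfg))):
        z = a @ params[f"W{li}"] + params[f"b{li}"]
        a = _act(cfg.activation, z)
        zs.append(z)
        acts.append(a)
    o = a @ params["w_out"] + params["b_out"]
    if cfg.kind == "cfnn":
        o = o + X @ params["w_skip"]
    return _sigmoid(o), acts, zs


def _train_mlp(cfg: ClassifierConfig, X: np.ndarray, y: np.ndarray):
    rng = np.random.default_rng(cfg.seed)
    m, d = X.shape
    sizes = _layer_sizes(cfg)
    params: dict[str, np.ndarray] = {}
    prev = d
    for li, h in enumerate(sizes):
        params[f"W{li}"] = _uniform(rng, prev, h)
        params[f"b{li}"] = _uniform(rng, h)
        prev = h
    params["w_out"] = _uniform(rng, prev)
    params["b_out"] = float(rng.uniform(-_INIT_RANGE, _INIT_RANGE))
    if cfg.kind == "cfnn":
        params["w_skip"] = _uniform(rng, d)

    history = []
    for _ in range(cfg.epochs):
        p, acts, zs = _mlp_forward(params, X, cfg)
        history.append(_bce(p, y))
        delta = (p - y) / m  # (m,)
        grads = {
            "w_out": acts[-1].T @ delta,
            "b_out": float(delta.sum()),
        }
        if cfg.kind == "cfnn":
            grads["w_skip"] = X.T @ delta
        da = np.outer(delta, params["w_out"])
        for li in reversed(range(len(sizes))):
            dz = da * _act_grad(cfg.activation, zs[li], acts[li + 1])
            grads[f"W{li}"] = acts[li].T @ dz
            grads[f"b{li}"] = dz.sum(axis=0)
            if li > 0:
                da = dz @ params[f"W{li}"].T
        for k, g in grads.items():
            params[k] = params[k] - cfg.learning_rate * g
    return params, history


def _rnn_forward(params: dict, X: np.ndarray):
    m, d = X.shape
    h = np.zeros((m, params["b"].size))
    states = []
    for t in range(d):
        z = np.outer(X[:, t], params["wx"]) + h @ params["Wh"] + params["b"]
        h = np.tanh(z)
        states.append(h)
    o = h @ params["w_out"] + params["b_out"]
    return _sigmoid(o), states


def _train_rnn(cfg: ClassifierConfig, X: np.ndarray, y: np.ndarray):
    rng = np.random.default_rng(cfg.seed)
    m, d = X.shape
    hdim = cfg.hidden_units
    params = {
        "wx": _uniform(rng, hdim),
        "Wh": _uniform(rng, hdim, hdim),
        "b": _uniform(rng, hdim),
        "w_out": _uniform(rng, hdim),
        "b_out": float(rng.uniform(-_INIT_RANGE, _INIT_RANGE)),
    }
    history = []
    for _ in range(cfg.epochs):
        p, states = _rnn_forward(params, X)
        history.append(_bce(p, y))
        delta = (p - y) / m
        g = {k: np.zeros_like(v) if isinstance(v, np.ndarray) else 0.0
             for k, v in params.items()}
        g["w_out"] = states[-1].T @ delta
        g["b_out"] = float(delta.sum())
        dh = np.outer(delta, params["w_out"])
        for t in reversed(range(d)):
            dz = dh * (1.0 - states[t] ** 2)
            g["wx"] += X[:, t] @ dz
            g["b"] += dz.sum(axis=0)
            prev = states[t - 1] if t > 0 else np.zeros((m, hdim))
            g["Wh"] += prev.T @ dz
            dh = dz @ params["Wh"].T
        for k in params:
            params[k] = params[k] - cfg.learning_rate * g[k]
    return params, history


def train(config: ClassifierConfig, X: np.ndarray, y: np.ndarray) -> TrainedModel:
    """Fit a classifier; features are z-scored on the training statistics.

    ``y`` must contain exactly two classes encoded 0/1. Training is fully
    deterministic given ``config.seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (m, d) with one label per row")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if np.isnan(X).any():
        raise ValueError("features contain NaN")
    if np.unique(y).size != 2:
        raise ValueError("training labels must contain exactly two classes")

    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mean) / sd

    if config.kind == "grnn":
        params = {"X_train": Xs.copy(), "y_train": y.copy()}
        history: list[float] = []
    elif config.kind == "rnn":
        params, history = _train_rnn(config, Xs, y)
    else:
        params, history = _train_mlp(config, Xs, y)

    return TrainedModel(
        kind=config.kind,
        input_dim=X.shape[1],
        params=params,
        scaler_mean=mean,
        scaler_sd=sd,
        config=config,
        train_history=history,
    )


def _grnn_scores(model: TrainedModel, Xs: np.ndarray) -> np.ndarray:
    cfg = model.config
    Xt = model.params["X_train"]
    yt = model.params["y_train"]
    d2 = ((Xs[:, None, :] - Xt[None, :, :]) ** 2).sum(axis=2)
    w = np.exp(-d2 / (2.0 * cfg.sigma**2))
    total = w.sum(axis=1)
    floor = cfg.radius * len(yt) * np.finfo(float).eps
    majority = float(np.round(yt.mean()))
    scores = np.full(Xs.shape[0], majority)
    ok = total > floor
    scores[ok] = (w[ok] @ yt) / total[ok]
    return scores


def predict(model: TrainedModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predict 0/1 labels and sigmoid/kernel scores in [0, 1]."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.input_dim:
        raise ValueError(
            f"feature dimension mismatch: model expects {model.input_dim}, "
            f"got {X.shape[1]}"
        )
    Xs = (X - model.scaler_mean) / model.scaler_sd
    if model.kind == "grnn":
        scores = _grnn_scores(model, Xs)
    elif model.kind == "rnn":
        scores, _ = _rnn_forward(model.params, Xs)
    else:
        scores, _, _ = _mlp_forward(model.params, Xs, model.config)
    labels = (scores >= 0.5).astype(int)
    return labels, scores
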
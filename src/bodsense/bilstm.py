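"""Bidirectional LSTM regressor with explicit gate math and BPTT.

The predictor is a single recurrent layer per direction. One direction's
cell applies, at each time step with input x_t, previous hidden state
h_{t−1} and previous cell state C_{t−1}:

    f_t = σ(ω_fh h_{t−1} + ω_fx x_t + b_f)          forget gate
    i_t = σ(ω_ih h_{t−1} + ω_ix x_t + b_i)          input gate
    C̃_t = tanh(ω_ch h_{t−1} + ω_cx x_t + b_c)       candidate state
    C_t = f_t ⊙ C_{t−1} + i_t ⊙ C̃_t                 state update
    O_t = σ(ω_oh h_{t−1} + ω_ox x_t + b_o)          output gate
    h_t = O_t ⊙ tanh(C_t)

The forward layer reads the input window in time order, the backward
layer reads it reversed; both start from h_0 = C_0 = 0. A linear head
maps the concatenated final hidden states [h_L^fwd ; h_L^bwd] to the
scalar prediction. Training minimizes mean squared error with Adam;
gradients are computed analytically by backpropagation through time
(and are verified against numerical differentiation in the test suite).

Everything is plain float64 numpy: the models involved are small enough
that desk-scale retraining inside the drift-monitoring loop stays cheap,
and double precision keeps the training loop bit-reproducible under a
fixed seed on one platform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

from .dataset import ProcessDataset, Scaler, fit_scaler, fit_target_scaler

__all__ = ["BiLSTMConfig", "BiLSTMModel", "cell_step", "forward", "train",
           "fit_model", "predict_series", "save_model", "load_model"]

GATES = ("f", "i", "c", "o")
_FORMAT_TAG = "bodsense-bilstm-v1"


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class BiLSTMConfig:
    """Training hyperparameters. Loss is fixed to mean squared error."""

    lookback: int = 8        # 2 h of 15-min samples
    hidden_size: int = 32
    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int = 32
    seed: int = 0
    concurrent: bool = False  # estimate the window's last sample instead of
                              # forecasting the one after it

    def validate(self) -> None:
        if self.lookback < 1:
            raise ValueError("lookback must be >= 1")
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class BiLSTMModel:
    """Parameter container plus fitted scalers and training history.

    ``params`` holds, per direction ``"fwd"``/``"bwd"``, the gate weight
    matrices ``W_g`` (input→gate, shape V×H), ``U_g`` (hidden→gate, H×H)
    and biases ``b_g`` (H,) for g ∈ {f, i, c, o}, plus the head weights
    ``head_w`` (2H,) and bias ``head_b`` (scalar array).
    """

    params: dict
    config: BiLSTMConfig
    scaler: Scaler | None = None
    target_scaler: Scaler | None = None
    selected: list[str] = field(default_factory=list)
    loss_history: list[float] = field(default_factory=list)

    @property
    def input_dim(self) -> int:
        return self.params["fwd"]["W_f"].shape[0]


def init_params(n_inputs: int, hidden: int, rng: np.random.Generator) -> dict:
    """Uniform(−1/√H, 1/√H) initialization for every gate parameter."""
    s = 1.0 / np.sqrt(hidden)
    params: dict = {}
    for d in ("fwd", "bwd"):
        p = {}
        for g in GATES:
            p[f"W_{g}"] = rng.uniform(-s, s, size=(n_inputs, hidden))
            p[f"U_{g}"] = rng.uniform(-s, s, size=(hidden, hidden))
            p[f"b_{g}"] = np.zeros(hidden)
        params[d] = p
    params["head_w"] = rng.uniform(-s, s, size=2 * hidden)
    params["head_b"] = np.zeros(1)
    return params


def cell_step(x_t: np.ndarray, h_prev: np.ndarray, C_prev: np.ndarray,
              params_dir: dict) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM cell update; accepts (V,) vectors or (B, V) batches."""
    single = np.asarray(x_t).ndim == 1
    x_t = np.atleast_2d(np.asarray(x_t, dtype=float))
    h_prev = np.atleast_2d(np.asarray(h_prev, dtype=float))
    C_prev = np.atleast_2d(np.asarray(C_prev, dtype=float))
    if x_t.shape[1] != params_dir["W_f"].shape[0]:
        raise ValueError(
            f"input dim {x_t.shape[1]} does not match W ({params_dir['W_f'].shape[0]})"
        )
    if h_prev.shape[1] != params_dir["U_f"].shape[0]:
        raise ValueError("hidden dim mismatch")
    f = _sigmoid(x_t @ params_dir["W_f"] + h_prev @ params_dir["U_f"] + params_dir["b_f"])
    i = _sigmoid(x_t @ params_dir["W_i"] + h_prev @ params_dir["U_i"] + params_dir["b_i"])
    g = np.tanh(x_t @ params_dir["W_c"] + h_prev @ params_dir["U_c"] + params_dir["b_c"])
    o = _sigmoid(x_t @ params_dir["W_o"] + h_prev @ params_dir["U_o"] + params_dir["b_o"])
    C = f * C_prev + i * g
    h = o * np.tanh(C)
    if single:
        return h[0], C[0]
    return h, C


def _run_direction(X: np.ndarray, p: dict, cache: list | None = None) -> np.ndarray:
    """Run one direction over (B, L, V) windows; return final hidden (B, H)."""
    B, L, _ = X.shape
    H = p["U_f"].shape[0]
    h = np.zeros((B, H))
    C = np.zeros((B, H))
    for t in range(L):
        x_t = X[:, t, :]
        f = _sigmoid(x_t @ p["W_f"] + h @ p["U_f"] + p["b_f"])
        i = _sigmoid(x_t @ p["W_i"] + h @ p["U_i"] + p["b_i"])
        g = np.tanh(x_t @ p["W_c"] + h @ p["U_c"] + p["b_c"])
        o = _sigmoid(x_t @ p["W_o"] + h @ p["U_o"] + p["b_o"])
        C_new = f * C + i * g
        h_new = o * np.tanh(C_new)
        if cache is not None:
            cache.append((x_t, h, C, f, i, g, o, C_new))
        h, C = h_new, C_new
    return h


def predict_batch(params: dict, X: np.ndarray) -> np.ndarray:
    """Scalar predictions for (B, L, V) windows, in the training scale."""
    h_f = _run_direction(X, params["fwd"])
    h_b = _run_direction(X[:, ::-1, :], params["bwd"])
    return np.concatenate([h_f, h_b], axis=1) @ params["head_w"] + params["head_b"][0]


def forward(model: BiLSTMModel, window: np.ndarray) -> float:
    """Prediction for a single L×V window (inputs already scaled)."""
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[0] != model.config.lookback:
        raise ValueError(
            f"window must be {model.config.lookback}×{model.input_dim}, "
            f"got shape {window.shape}"
        )
    return float(predict_batch(model.params, window[None])[0])


def _backprop_direction(X: np.ndarray, p: dict, cache: list,
                        dh_last: np.ndarray) -> dict:
    """BPTT for one direction given the gradient at the final hidden state."""
    grads = {k: np.zeros_like(v) for k, v in p.items()}
    dh = dh_last
    dC = np.zeros_like(dh_last)
    for t in range(len(cache) - 1, -1, -1):
        x_t, h_prev, C_prev, f, i, g, o, C_new = cache[t]
        tC = np.tanh(C_new)
        do = dh * tC
        dC = dC + dh * o * (1.0 - tC**2)
        df = dC * C_prev
        di = dC * g
        dg = dC * i
        dC_prev = dC * f
        dz = {
            "f": df * f * (1.0 - f),
            "i": di * i * (1.0 - i),
            "c": dg * (1.0 - g**2),
            "o": do * o * (1.0 - o),
        }
        dh_prev = np.zeros_like(dh)
        for name, dzg in dz.items():
            grads[f"W_{name}"] += x_t.T @ dzg
            grads[f"U_{name}"] += h_prev.T @ dzg
            grads[f"b_{name}"] += dzg.sum(axis=0)
            dh_prev += dzg @ p[f"U_{name}"].T
        dh = dh_prev
        dC = dC_prev
    return grads


def loss_and_gradients(params: dict, X: np.ndarray, y: np.ndarray
                       ) -> tuple[float, dict]:
    """Mean-squared-error loss and its analytic gradient for one batch."""
    B = X.shape[0]
    H = params["fwd"]["U_f"].shape[0]
    cache_f: list = []
    cache_b: list = []
    h_f = _run_direction(X, params["fwd"], cache_f)
    h_b = _run_direction(X[:, ::-1, :], params["bwd"], cache_b)
    hh = np.concatenate([h_f, h_b], axis=1)
    pred = hh @ params["head_w"] + params["head_b"][0]
    resid = pred - y
    loss = float(np.mean(resid**2))
    dpred = 2.0 * resid / B
    grads: dict = {
        "head_w": hh.T @ dpred,
        "head_b": np.array([dpred.sum()]),
    }
    dhh = np.outer(dpred, params["head_w"])
    grads["fwd"] = _backprop_direction(X, params["fwd"], cache_f, dhh[:, :H])
    grads["bwd"] = _backprop_direction(X[:, ::-1, :], params["bwd"], cache_b,
                                       dhh[:, H:])
    return loss, grads


def _flat_items(params: dict, prefix: str = ""):
    for k in sorted(params):
        v = params[k]
        if isinstance(v, dict):
            yield from _flat_items(v, prefix + k + ".")
        else:
            yield prefix + k, v


def _copy_params(params: dict) -> dict:
    return {
        k: (_copy_params(v) if isinstance(v, dict) else v.copy())
        for k, v in params.items()
    }


def train(pairs: Iterable[tuple[np.ndarray, float]] | tuple[np.ndarray, np.ndarray],
          cfg: BiLSTMConfig, init: dict | None = None) -> BiLSTMModel:
    """Fit the network on scaled (window, target) pairs by mini-batch Adam.

    ``pairs`` may be an iterable of (L×V window, scalar) pairs or a
    pre-stacked ``(X, y)`` tuple with X of shape (N, L, V). A fixed
    ``cfg.seed`` makes initialization and batch shuffling — hence the
    whole loss history — reproducible. Passing ``init`` warm-starts from
    an existing parameter set instead of a fresh initialization.
    """
    cfg.validate()
    if isinstance(pairs, tuple) and len(pairs) == 2 and np.asarray(pairs[0]).ndim == 3:
        X = np.asarray(pairs[0], dtype=float)
        y = np.asarray(pairs[1], dtype=float)
    else:
        listed = list(pairs)
        if not listed:
            raise ValueError("empty training set")
        X = np.stack([np.asarray(w, dtype=float) for w, _ in listed])
        y = np.array([t for _, t in listed], dtype=float)
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    if X.shape[1] != cfg.lookback:
        raise ValueError(f"window length {X.shape[1]} != lookback {cfg.lookback}")
    N, _, V = X.shape

    rng = np.random.default_rng(cfg.seed)
    params = _copy_params(init) if init is not None else init_params(
        V, cfg.hidden_size, rng)
    # Adam state, keyed like the flattened parameter tree
    m = {k: np.zeros_like(v) for k, v in _flat_items(params)}
    v_ = {k: np.zeros_like(val) for k, val in _flat_items(params)}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    history: list[float] = []
    for _epoch in range(cfg.epochs):
        order = rng.permutation(N)
        epoch_loss = 0.0
        for lo in range(0, N, cfg.batch_size):
            batch = order[lo : lo + cfg.batch_size]
            loss, grads = loss_and_gradients(params, X[batch], y[batch])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {_epoch}, batch {lo // cfg.batch_size}; "
                    f"lr={cfg.learning_rate}, |y|max={np.abs(y).max():.3g}"
                )
            epoch_loss += loss * batch.size
            step += 1
            flat_g = dict(_flat_items(grads))
            for key, val in _flat_items(params):
                g = flat_g[key]
                m[key] = beta1 * m[key] + (1 - beta1) * g
                v_[key] = beta2 * v_[key] + (1 - beta2) * g**2
                mhat = m[key] / (1 - beta1**step)
                vhat = v_[key] / (1 - beta2**step)
                val -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
        history.append(epoch_loss / N)
    return BiLSTMModel(params=params, config=cfg, loss_history=history)


# ---------------------------------------------------------------------------
# dataset-level fit / predict (handles scaling and window alignment)

def _windows_scaled(ds: ProcessDataset, model_scaler: Scaler,
                    target_scaler: Scaler, cfg: BiLSTMConfig
                    ) -> tuple[np.ndarray, np.ndarray]:
    Xall = model_scaler.transform(ds.values)
    yall = (ds.target - target_scaler.mean[0]) / target_scaler.std[0]
    L = cfg.lookback
    T = Xall.shape[0]
    if T < L + 1:
        raise ValueError(f"dataset too short: T={T} needs at least L+1={L + 1} rows")
    n = T - L
    X = np.stack([Xall[j : j + L] for j in range(n)])
    # forecast mode targets the sample after the window; concurrent mode
    # estimates the window's own last sample
    y = yall[L - 1 : T - 1] if cfg.concurrent else yall[L:]
    return X, y


def fit_model(ds: ProcessDataset, cfg: BiLSTMConfig,
              init: dict | None = None) -> BiLSTMModel:
    """Fit scalers on `ds` (all of it), then train on its windows.

    `ds` should already be restricted to the selected auxiliary
    variables (see :meth:`ProcessDataset.select`).
    """
    scaler = fit_scaler(ds)
    target_scaler = fit_target_scaler(ds.target)
    X, y = _windows_scaled(ds, scaler, target_scaler, cfg)
    model = train((X, y), cfg, init=init)
    model.scaler = scaler
    model.target_scaler = target_scaler
    model.selected = list(ds.variable_names)
    return model


def predict_series(model: BiLSTMModel, ds: ProcessDataset) -> np.ndarray:
    """Predicted target series in original units (g/m³).

    Returns one prediction per admissible window — length ``T − L`` —
    aligned so that element ``j`` predicts ``ds.target[j + L]`` in
    forecast mode (``ds.target[j + L − 1]`` in concurrent mode).
    """
    if model.scaler is None or model.target_scaler is None:
        raise ValueError("model has no fitted scalers; use fit_model")
    if model.selected and list(ds.variable_names) != model.selected:
        ds = ds.select(model.selected)
    X, _ = _windows_scaled(ds, model.scaler, model.target_scaler, model.config)
    pred_scaled = predict_batch(model.params, X)
    ts = model.target_scaler
    return pred_scaled * ts.std[0] + ts.mean[0]


# ---------------------------------------------------------------------------
# serialization: a single JSON archive, versioned with a format tag

def save_model(model: BiLSTMModel, path) -> None:
    def arr(a):
        return np.asarray(a).tolist()

    payload = {
        "format": _FORMAT_TAG,
        "config": asdict(model.config),
        "selected": model.selected,
        "loss_history": model.loss_history,
        "scaler": None
        if model.scaler is None
        else {
            "mean": arr(model.scaler.mean),
            "std": arr(model.scaler.std),
            "variable_names": model.scaler.variable_names,
        },
        "target_scaler": None
        if model.target_scaler is None
        else {"mean": arr(model.target_scaler.mean), "std": arr(model.target_scaler.std)},
        "params": {
            d: {k: arr(v) for k, v in model.params[d].items()} for d in ("fwd", "bwd")
        }
        | {"head_w": arr(model.params["head_w"]), "head_b": arr(model.params["head_b"])},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> BiLSTMModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != _FORMAT_TAG:
        raise ValueError(f"unrecognized model archive format: {payload.get('format')!r}")
    params = {
        d: {k: np.array(v) for k, v in payload["params"][d].items()}
        for d in ("fwd", "bwd")
    }
    params["head_w"] = np.array(payload["params"]["head_w"])
    params["head_b"] = np.array(payload["params"]["head_b"])
    cfg = BiLSTMConfig(**payload["config"])
    sc = payload["scaler"]
    tsc = payload["target_scaler"]
    return BiLSTMModel(
        params=params,
        config=cfg,
        scaler=None
        if sc is None
        else Scaler(np.array(sc["mean"]), np.array(sc["std"]), sc["variable_names"]),
        target_scaler=None
        if tsc is None
        else Scaler(np.array(tsc["mean"]), np.array(tsc["std"])),
        selected=payload["selected"],
        loss_history=payload["loss_history"],
    )
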
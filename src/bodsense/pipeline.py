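"""Streaming orchestration: static, moving-window, and drift-triggered policies.

The soft sensor runs over a test stream in daily strides. Three
reconstruction policies are provided:

``static``
    Train once on the initial window; never retrain.
``mw`` (moving window)
    Retrain after every stride on the most recent ``window_length``
    samples, regardless of whether anything changed.
``mpdar``
    Retrain only when the drift monitor's weighted expectation change
    rate J exceeds the threshold δ — selective reconstruction instead
    of blind reconstruction.

Limit behavior ties the policies together: δ = ∞ makes ``mpdar``
predict exactly like ``static``; δ = 0 makes its retrain schedule
coincide with ``mw``.

The monitor always sees the auxiliary variables in original units; the
predictor sees z-scored values, with the scaler refit at every
reconstruction on the new window.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bilstm import BiLSTMConfig, BiLSTMModel, fit_model, predict_batch
from .dataset import ProcessDataset
from .metrics import MetricReport, evaluate
from .mi import MIProfile
from .monitor import (
    DEFAULT_DELTA,
    DriftMonitorState,
    should_reconstruct,
    weights_from_mi,
)

__all__ = ["PolicyConfig", "CycleRecord", "PolicyTrace", "run_policy",
           "compare_policies"]

logger = logging.getLogger(__name__)

POLICIES = ("static", "mw", "mpdar")


@dataclass
class PolicyConfig:
    """Reconstruction-policy settings.

    ``window_length`` defaults to 288 samples (three days at 15-min
    sampling — the size of the initial training window); ``stride``
    defaults to 96 (one day between update checks).
    """

    policy: str = "mpdar"
    window_length: int = 288
    stride: int = 96
    delta: float = DEFAULT_DELTA      # J threshold in %, mpdar only
    warm_start: bool = False
    growing_window: bool = False
    absolute_mode: bool = False
    recompute_weights: bool = False   # refresh W_i from MI at each retrain

    def validate(self, lookback: int) -> None:
        if self.policy not in POLICIES:
            raise ValueError(f"unknown policy {self.policy!r}; expected one of {POLICIES}")
        if self.window_length < lookback + 1:
            raise ValueError("window_length must be >= lookback + 1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


@dataclass
class CycleRecord:
    cycle: int
    start: int            # test-stream index range [start, stop)
    stop: int
    J: float | None
    reconstructed: bool
    retrain_seconds: float
    n_predictions: int


@dataclass
class PolicyTrace:
    policy: str
    records: list[CycleRecord] = field(default_factory=list)
    predictions: np.ndarray | None = None
    y_true: np.ndarray | None = None
    metrics: MetricReport | None = None

    @property
    def n_reconstructions(self) -> int:
        return sum(r.reconstructed for r in self.records)

    @property
    def total_retrain_seconds(self) -> float:
        return sum(r.retrain_seconds for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cycle": r.cycle,
                    "start": r.start,
                    "stop": r.stop,
                    "J": r.J,
                    "reconstructed": int(r.reconstructed),
                    "retrain_seconds": r.retrain_seconds,
                    "n_predictions": r.n_predictions,
                }
                for r in self.records
            ]
        )


def _history_dict(values: np.ndarray, names: list[str]) -> dict[str, np.ndarray]:
    return {n: values[:, j] for j, n in enumerate(names)}


def _stream_predict(model: BiLSTMModel, context: np.ndarray,
                    n_out: int) -> np.ndarray:
    """Predict `n_out` consecutive stream samples from a context matrix.

    `context` holds, in original units, the L rows preceding the first
    predicted sample followed by the stride's own rows (the latter are
    needed as inputs for the later samples of the stride — each sample
    is still predicted only from rows strictly before it in forecast
    mode).
    """
    L = model.config.lookback
    offset = 1 if model.config.concurrent else 0
    scaled = model.scaler.transform(context)
    X = np.stack([scaled[i + offset : i + offset + L] for i in range(n_out)])
    pred = predict_batch(model.params, X)
    ts = model.target_scaler
    return pred * ts.std[0] + ts.mean[0]


def run_policy(
    train: ProcessDataset,
    test: ProcessDataset,
    profile: MIProfile,
    model_cfg: BiLSTMConfig,
    pol: PolicyConfig,
) -> tuple[np.ndarray, PolicyTrace]:
    """Run one policy over the test stream.

    Returns the prediction series (one value per test index, original
    units) and the per-cycle trace. The initial model is trained on the
    last ``window_length`` rows of `train`; the stream then advances in
    strides — predict the stride with the current model, slide the
    candidate window forward, and let the policy decide whether to
    rebuild the model for the next stride.
    """
    pol.validate(model_cfg.lookback)
    if not profile.selected:
        raise ValueError("empty auxiliary-variable selection; nothing to model")
    if train.n_samples < pol.window_length:
        raise ValueError(
            f"training data has {train.n_samples} rows; window_length={pol.window_length}"
        )
    sel = profile.selected
    train_sel = train.select(sel)
    test_sel = test.select(sel)

    w0 = train_sel.n_samples - pol.window_length
    window_vals = train_sel.values[w0:].copy()
    window_tgt = train_sel.target[w0:].copy()

    def _window_ds() -> ProcessDataset:
        return ProcessDataset(values=window_vals, variable_names=list(sel),
                              target=window_tgt, target_name=train.target_name)

    model = fit_model(_window_ds(), model_cfg)

    monitor: DriftMonitorState | None = None
    mi_sel = {v: profile.mi_values[v] for v in sel}
    if pol.policy == "mpdar":
        monitor = DriftMonitorState.from_reference(
            _history_dict(window_vals, sel),
            weights_from_mi(mi_sel),
            threshold_delta=pol.delta,
            absolute_mode=pol.absolute_mode,
        )

    T = test_sel.n_samples
    L = model_cfg.lookback
    preds = np.empty(T)
    trace = PolicyTrace(policy=pol.policy)
    retrain_count = 0

    for cycle, start in enumerate(range(0, T, pol.stride)):
        stop = min(start + pol.stride, T)
        # context: last L window rows, then the stride's own rows
        context = np.vstack([window_vals[-L:], test_sel.values[start:stop]])
        preds[start:stop] = _stream_predict(model, context, stop - start)
        if not np.all(np.isfinite(preds[start:stop])):
            raise FloatingPointError(f"non-finite prediction in cycle {cycle}")

        # slide (or grow) the candidate training window
        window_vals = np.vstack([window_vals, test_sel.values[start:stop]])
        window_tgt = np.concatenate([window_tgt, test_sel.target[start:stop]])
        if not pol.growing_window:
            window_vals = window_vals[-pol.window_length:]
            window_tgt = window_tgt[-pol.window_length:]

        J: float | None = None
        reconstruct = False
        if pol.policy == "mw":
            reconstruct = True
        elif pol.policy == "mpdar":
            reconstruct, J = should_reconstruct(
                monitor, _history_dict(window_vals, sel)
            )

        retrain_seconds = 0.0
        if reconstruct:
            t0 = time.perf_counter()
            retrain_count += 1
            # fresh initialization by default ("reconstruction"); the seed
            # is derived per retrain so every rebuild is reproducible
            cfg_r = replace(model_cfg, seed=model_cfg.seed + retrain_count)
            if monitor is not None:
                monitor.commit(_history_dict(window_vals, sel))
                if pol.recompute_weights:
                    monitor.weights = weights_from_mi(mi_sel)
            if pol.warm_start:
                new_model = fit_model(_window_ds(), cfg_r, init=model.params)
            else:
                new_model = fit_model(_window_ds(), cfg_r)
            model = new_model
            retrain_seconds = time.perf_counter() - t0

        rec = CycleRecord(cycle=cycle, start=start, stop=stop, J=J,
                          reconstructed=reconstruct,
                          retrain_seconds=retrain_seconds,
                          n_predictions=stop - start)
        trace.records.append(rec)
        logger.info(
            "cycle %d [%d, %d): J=%s reconstruct=%s",
            cycle, start, stop, "n/a" if J is None else f"{J:+.2f}%", reconstruct,
        )

    trace.predictions = preds
    trace.y_true = test_sel.target.copy()
    trace.metrics = evaluate(trace.y_true, preds)
    return preds, trace


def compare_policies(
    train: ProcessDataset,
    test: ProcessDataset,
    profile: MIProfile,
    model_cfg: BiLSTMConfig,
    pol: PolicyConfig | None = None,
    policies: tuple[str, ...] = POLICIES,
) -> tuple[pd.DataFrame, dict[str, PolicyTrace]]:
    """Run several policies on identical data/seeds; one summary row each."""
    base = pol or PolicyConfig()
    rows = []
    traces: dict[str, PolicyTrace] = {}
    for name in policies:
        cfg = replace(base, policy=name)
        _, trace = run_policy(train, test, profile, model_cfg, cfg)
        traces[name] = trace
        m = trace.metrics
        rows.append(
            {
                "policy": name,
                "rmse": m.rmse,
                "mae": m.mae,
                "pcc": m.pcc,
                "n": m.n,
                "reconstructions": trace.n_reconstructions,
                "retrain_seconds": trace.total_retrain_seconds,
            }
        )
    return pd.DataFrame(rows), traces
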
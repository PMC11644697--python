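import numpy as np
import pytest

from bodsense.bilstm import (
    BiLSTMConfig,
    BiLSTMModel,
    _flat_items,
    cell_step,
    fit_model,
    forward,
    init_params,
    load_model,
    loss_and_gradients,
    predict_batch,
    predict_series,
    save_model,
    train,
)
from bodsense.dataset import ProcessDataset


def zero_gate_params(V, H):
    p = {}
    for g in "fico":
        p[f"W_{g}"] = np.zeros((V, H))
        p[f"U_{g}"] = np.zeros((H, H))
        p[f"b_{g}"] = np.zeros(H)
    return p


def reference_cell(x, h, C, p):
    """Independent scalar-formula recomputation of one cell update."""
    sig = lambda z: 1.0 / (1.0 + np.exp(-z))
    f = sig(x @ p["W_f"] + h @ p["U_f"] + p["b_f"])
    i = sig(x @ p["W_i"] + h @ p["U_i"] + p["b_i"])
    g = np.tanh(x @ p["W_c"] + h @ p["U_c"] + p["b_c"])
    o = sig(x @ p["W_o"] + h @ p["U_o"] + p["b_o"])
    C_new = f * C + i * g
    return o * np.tanh(C_new), C_new


class TestCellStep:
    def test_all_zero_parameters_give_half_gates(self):
        p = zero_gate_params(2, 3)
        C_prev = np.array([0.4, -0.2, 1.0])
        h, C = cell_step(np.ones(2), np.zeros(3), C_prev, p)
        np.testing.assert_allclose(C, 0.5 * C_prev)          # f=i=0.5, C̃=0
        np.testing.assert_allclose(h, 0.5 * np.tanh(0.5 * C_prev))

    def test_saturated_forget_open_input_closed_preserves_state(self):
        p = zero_gate_params(1, 2)
        p["b_f"] += 50.0   # f → 1
        p["b_i"] -= 50.0   # i → 0
        C_prev = np.array([0.7, -1.3])
        _, C = cell_step(np.array([2.0]), np.array([0.1, 0.2]), C_prev, p)
        np.testing.assert_allclose(C, C_prev, atol=1e-12)    # perfect memory

    def test_matches_independent_scalar_computation(self):
        rng = np.random.default_rng(0)
        p = {k: rng.normal(size=v.shape) for k, v in zero_gate_params(1, 1).items()}
        x, h0, C0 = np.array([0.3]), np.array([-0.2]), np.array([0.5])
        h, C = cell_step(x, h0, C0, p)
        h_ref, C_ref = reference_cell(x, h0, C0, p)
        np.testing.assert_allclose(h, h_ref, rtol=1e-12)
        np.testing.assert_allclose(C, C_ref, rtol=1e-12)

    def test_gate_outputs_bounded(self):
        rng = np.random.default_rng(1)
        p = {k: rng.normal(size=v.shape) * 3 for k, v in zero_gate_params(2, 4).items()}
        h, C = cell_step(rng.normal(size=2), rng.normal(size=4), rng.normal(size=4), p)
        assert np.all(np.abs(h) < 1.0)  # |h| = |O·tanh(C)| < 1

    def test_shape_mismatch_rejected(self):
        p = zero_gate_params(2, 3)
        with pytest.raises(ValueError, match="dim"):
            cell_step(np.ones(5), np.zeros(3), np.zeros(3), p)


class TestForward:
    def _model(self, V=1, H=2, L=3, seed=0):
        rng = np.random.default_rng(seed)
        return BiLSTMModel(params=init_params(V, H, rng),
                           config=BiLSTMConfig(lookback=L, hidden_size=H))

    def test_zero_head_weights_give_constant_bias(self):
        m = self._model()
        m.params["head_w"][:] = 0.0
        m.params["head_b"][:] = 2.5
        rng = np.random.default_rng(3)
        for _ in range(3):
            assert forward(m, rng.normal(size=(3, 1))) == pytest.approx(2.5)

    def test_direction_swap_symmetry(self):
        """Reversing the window while exchanging the two directions'
        parameters (and head halves) leaves the prediction unchanged."""
        m = self._model(seed=4)
        H = m.config.hidden_size
        rng = np.random.default_rng(5)
        w = rng.normal(size=(3, 1))
        base = forward(m, w)
        swapped = BiLSTMModel(
            params={
                "fwd": m.params["bwd"], "bwd": m.params["fwd"],
                "head_w": np.concatenate([m.params["head_w"][H:],
                                          m.params["head_w"][:H]]),
                "head_b": m.params["head_b"],
            },
            config=m.config,
        )
        assert forward(swapped, w[::-1]) == pytest.approx(base, rel=1e-12)

    def test_matches_hand_rolled_two_direction_loop(self):
        m = self._model(V=1, H=2, L=3, seed=6)
        rng = np.random.default_rng(7)
        w = rng.normal(size=(3, 1))
        # independent step-by-step recomputation via the scalar formulas
        finals = []
        for d, seq in (("fwd", w), ("bwd", w[::-1])):
            h, C = np.zeros(2), np.zeros(2)
            for t in range(3):
                h, C = reference_cell(seq[t], h, C, m.params[d])
            finals.append(h)
        expect = np.concatenate(finals) @ m.params["head_w"] + m.params["head_b"][0]
        assert forward(m, w) == pytest.approx(expect, rel=1e-12)

    def test_wrong_window_length_rejected(self):
        m = self._model(L=3)
        with pytest.raises(ValueError, match="window"):
            forward(m, np.zeros((4, 1)))


class TestGradients:
    def test_analytic_matches_numerical(self):
        rng = np.random.default_rng(0)
        params = init_params(2, 2, rng)       # tiny: V=2, H=2, L=3
        X = rng.normal(size=(4, 3, 2))
        y = rng.normal(size=4)
        _, grads = loss_and_gradients(params, X, y)
        flat_g = dict(_flat_items(grads))
        eps = 1e-6
        worst = 0.0
        for key, val in _flat_items(params):
            it = np.nditer(val, flags=["multi_index"])
            for _ in it:
                ix = it.multi_index
                keep = val[ix]
                val[ix] = keep + eps
                lp, _ = loss_and_gradients(params, X, y)
                val[ix] = keep - eps
                lm, _ = loss_and_gradients(params, X, y)
                val[ix] = keep
                num = (lp - lm) / (2 * eps)
                ana = flat_g[key][ix]
                worst = max(worst, abs(num - ana) / max(abs(num), abs(ana), 1e-8))
        assert worst < 1e-4


class TestTraining:
    def test_toy_linear_target_trains_below_1e3(self, toy_pairs):
        X, y = toy_pairs
        cfg = BiLSTMConfig(lookback=3, hidden_size=8, epochs=500,
                           learning_rate=1e-2, batch_size=16, seed=0)
        model = train((X, y), cfg)
        assert model.loss_history[-1] < 1e-3

    def test_zero_epochs_rejected(self, toy_pairs):
        with pytest.raises(ValueError, match="epochs"):
            train(toy_pairs, BiLSTMConfig(lookback=3, epochs=0))

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train([], BiLSTMConfig(lookback=3))

    def test_fixed_seed_reproduces_loss_history(self, toy_pairs):
        cfg = BiLSTMConfig(lookback=3, hidden_size=4, epochs=20,
                           learning_rate=1e-2, seed=9)
        a = train(toy_pairs, cfg)
        b = train(toy_pairs, cfg)
        assert a.loss_history == b.loss_history

    def test_warm_start_resumes_from_given_parameters(self, toy_pairs):
        cfg = BiLSTMConfig(lookback=3, hidden_size=4, epochs=30,
                           learning_rate=1e-2, seed=0)
        first = train(toy_pairs, cfg)
        resumed = train(toy_pairs, cfg, init=first.params)
        assert resumed.loss_history[0] < first.loss_history[0]


class TestPredictSeries:
    def _fitted(self, T=40, L=4, seed=0, **cfg_kw):
        rng = np.random.default_rng(seed)
        x = rng.normal(10, 2, size=T)
        # forecast-mode learnable: the target reflects the previous sample,
        # which is always the last row of the input window
        y = 5 + 0.5 * np.concatenate([[x[0]], x[:-1]]) + rng.normal(0, 0.01, T)
        ds = ProcessDataset(x[:, None], ["Q_in"], y)
        cfg = BiLSTMConfig(lookback=L, hidden_size=6, epochs=150,
                           learning_rate=1e-2, seed=1, **cfg_kw)
        return ds, fit_model(ds, cfg)

    def test_one_prediction_when_T_is_L_plus_1(self):
        ds, model = self._fitted()
        short = ds.slice_rows(0, 5)  # T = L+1
        assert predict_series(model, short).shape == (1,)

    def test_training_fit_quality_in_original_units(self):
        ds, model = self._fitted()
        preds = predict_series(model, ds)
        resid = preds - ds.target[model.config.lookback:]
        assert np.sqrt(np.mean(resid**2)) < 0.05

    def test_batch_partition_invariance(self):
        ds, model = self._fitted()
        X = np.stack([model.scaler.transform(ds.values[j:j + 4]) for j in range(36)])
        whole = predict_batch(model.params, X)
        parts = np.concatenate([predict_batch(model.params, X[:10]),
                                predict_batch(model.params, X[10:])])
        np.testing.assert_allclose(whole, parts, rtol=1e-12)

    def test_scale_inverse_scale_round_trip(self):
        ds, model = self._fitted()
        ts = model.target_scaler
        preds = predict_series(model, ds)
        back = (preds - ts.mean[0]) / ts.std[0] * ts.std[0] + ts.mean[0]
        np.testing.assert_allclose(back, preds, atol=1e-9)

    def test_too_short_dataset_rejected(self):
        ds, model = self._fitted()
        with pytest.raises(ValueError, match="too short"):
            predict_series(model, ds.slice_rows(0, 4))  # T == L

    def test_save_load_round_trip(self, tmp_path):
        ds, model = self._fitted()
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_array_equal(predict_series(back, ds),
                                      predict_series(model, ds))
        assert back.config == model.config

    def test_concurrent_mode_targets_window_end(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        ds = ProcessDataset(x[:, None], ["a"], np.arange(30.0))
        from bodsense.bilstm import _windows_scaled
        from bodsense.dataset import fit_scaler, fit_target_scaler
        sc, tsc = fit_scaler(ds), fit_target_scaler(ds.target)
        _, y_fore = _windows_scaled(ds, sc, tsc, BiLSTMConfig(lookback=5))
        _, y_conc = _windows_scaled(ds, sc, tsc,
                                    BiLSTMConfig(lookback=5, concurrent=True))
        # concurrent targets trail forecast targets by exactly one step
        np.testing.assert_allclose(y_conc[1:], y_fore[:-1])
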
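# bodsense

An adaptive soft sensor for **effluent biochemical oxygen demand (BOD)** in
activated-sludge wastewater treatment plants. Effluent BOD is the key
discharge-compliance variable, but measuring it directly takes days of
incubation, so plants infer it in real time from easy-to-measure process
variables (flows, component concentrations along the reactor train). The
catch: operating conditions drift — rain and storm events reshape the influent
— and a fixed data-driven model quietly degrades. Retraining on every update
cycle restores accuracy but wastes most of the compute on cycles where nothing
changed.

`bodsense` implements the full adaptive pipeline for process engineers and
soft-sensing researchers:

1. **Auxiliary-variable selection** by k-nearest-neighbor mutual information
   (the Kraskov–Stögbauer–Grassberger estimator, variant 2):

   I(X,Y) = Ψ(k) − 1/k − ⟨Ψ(n_x) + Ψ(n_y)⟩ + Ψ(S)

   with Ψ the digamma function; variables with I(X, BOD) above a threshold λ
   (in nats) become model inputs.
2. **Prediction** with a bidirectional LSTM: forward and backward recurrent
   layers built from the standard forget/input/output gate equations, a linear
   head on the concatenated final hidden states, trained by Adam on a sliding
   window (numpy implementation with analytic backpropagation through time).
3. **Drift-triggered reconstruction**: each selected variable's expectation
   E(X) = ∫x·p(x)dx is computed from a Gaussian kernel density estimate of the
   current training window, and the MI-weighted relative change rate

   J = Σᵢ Wᵢ·(Eᵢ(Xₜ) − Eᵢ(Xₜ₋₁)) / Σᵢ Wᵢ·Eᵢ(Xₜ₋₁) × 100 %,  Wᵢ = Iᵢ / Σⱼ Iⱼ

   is compared against a threshold δ. The model is rebuilt only when |J| > δ —
   selective reconstruction instead of blind per-cycle retraining.

A built-in synthetic generator produces regime-switching plant-like records
(diurnal influent signal propagating through correlated channels, rain/storm
regime shifts, pure-noise distractors, a nonlinear BOD-like target) with known
ground truth, so selection, prediction and drift detection are all testable
end to end.

## Worked example

`examples/05_compare_policies.py` trains on three dry days (288 samples at
15-minute sampling) and streams nine test days that pass from dry weather into
rain and storms, comparing three reconstruction policies on identical data:

```
policy   rmse    mae    pcc   n  reconstructions
static 0.4059 0.2868 0.9741 864                0
    mw 0.3681 0.2422 0.9783 864                9
 mpdar 0.3805 0.2522 0.9769 864                4

per-cycle drift statistic (mpdar policy):
  cycle 0: J =  -0.08%  held
  ...
  cycle 4: J =  +6.34%  retrained
  cycle 6: J = +18.03%  retrained
```

RMSE/MAE are in g/m³; PCC is the Pearson correlation between predicted and
true effluent BOD. The frozen model (`static`) is the least accurate once the
weather turns; the moving window (`mw`) retrains all 9 cycles; the
drift-triggered policy (`mpdar`) holds while J stays near zero on dry days,
fires when rain (+6%) and storms (+18%) shift the input distribution, and
reaches near-moving-window accuracy with 4 retrains instead of 9.

The other examples cover each capability in isolation: data generation
(`01`), MI selection (`02`), training and forecasting (`03`), and the drift
statistic itself (`04`). A thin CLI wraps the same library calls:

```bash
bodsense generate --config scenario.yaml --out data.csv --truth truth.csv
bodsense select   --data train.csv --target BOD_out --k 3 --lambda 1.2 --out profile.csv
bodsense train    --data train.csv --profile profile.csv --config run.yaml --out model.json
bodsense run      --train train.csv --test test.csv --profile profile.csv \
                  --config run.yaml --policy mpdar --out pred.csv --trace trace.csv
bodsense evaluate --pred pred.csv --out metrics.csv
```

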
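# Methods

## Problem setting

A wastewater treatment plant's effluent BOD cannot be measured online; a soft
sensor predicts it from auxiliary process variables sampled every 15 minutes.
The data-generating process is non-stationary: wet-weather events change the
influent distribution, and a model trained under dry conditions loses accuracy.
`bodsense` couples three components: mutual-information-based input selection,
a bidirectional LSTM regressor, and a probability-density drift monitor that
decides *when* the regressor must be rebuilt.

## Mutual-information selection (KSG variant 2)

For each candidate variable X and target Y, the estimator finds each sample's
k-th nearest neighbor in the joint space under the Chebyshev norm, takes the
per-axis distances ε_x(i)/2 and ε_y(i)/2 to those k neighbors, counts the
marginal neighbors n_x(i), n_y(i) within them (boundary included, the
variant-2 convention), and returns

    Î = Ψ(k) − 1/k − ⟨Ψ(n_x) + Ψ(n_y)⟩ + Ψ(S)   (nats).

Numerical choices:

* **k = 3** by default (useful range 2–6): lower k reduces bias, higher k
  reduces variance.
* **Tie handling**: seeded uniform jitter of amplitude 1e-10 × sd is added
  before the neighbor search, since quantized sensor readings otherwise make
  k-NN distances degenerate. The jitter is far below any physical resolution.
* **Neighbor search** uses a KD-tree; the marginal counts are exact pairwise
  comparisons. The test suite checks the counts against an O(S²) brute-force
  reference, and the estimate against the bivariate-Gaussian closed form
  −½ln(1−ρ²) and the linear-Gaussian-channel form ½ln(1+SNR).
* Estimates may be slightly negative for independent data; they are reported
  as-is and clamped to zero only when converted to drift-monitor weights.
* **Selection** keeps variables with MI strictly above λ. λ = 1.2 nats is the
  package default — the operating point appropriate for a full plant-wide
  candidate set of ~150 variables where selected inputs carry >1.2 nats. The
  synthetic study uses λ = 0.3 because its informative channels carry
  0.4–0.9 nats against 0–0.15 for distractors at these sample sizes; the
  threshold is a data-dependent operating point, not part of the estimator.

## The bidirectional LSTM

One recurrent layer per direction with the standard gates (σ forget/input/
output gates, tanh candidate, elementwise products); the forward layer reads
the L-sample window in time order, the backward layer reads it reversed, both
from zero initial states; a linear head maps the concatenated final hidden
states to the scalar prediction. Implemented in float64 numpy with analytic
backpropagation through time, verified against numerical differentiation to
relative error < 1e-4.

Defaults: lookback L = 8 (two hours), hidden size H = 32, 200 epochs of Adam
(lr 1e-3, batch 32), uniform(−1/√H, 1/√H) initialization, MSE loss. The model
**forecasts** the sample immediately after the window, so no input row ever
contains the predicted sample (a `concurrent` switch estimates the window's
last sample instead, for users whose auxiliary measurements arrive together
with the BOD estimate request). Inputs and target are z-scored on the current
training window only; predictions are returned in g/m³. Training under a
fixed seed is bit-reproducible on one platform (cross-platform float variation
up to ~1e-6 on the loss is possible).

## Drift monitoring

Each selected variable's density on the training window is smoothed with a
Gaussian KDE, p(x) = 1/(nh) Σ φ((x−x_i)/h), bandwidth h from Silverman's rule
0.9·min(sd, IQR/1.34)·n^(−1/5). The expectation E(X) = ∫x·p(x)dx is evaluated
by adaptive quadrature over [min−6h, max+6h]; for a symmetric kernel this
equals the sample mean exactly, which the tests exploit as a numerical
identity (tolerance 1e-6). The weighted change rate

    J = Σ W_i (E_i(X_t) − E_i(X_{t−1})) / Σ W_i E_i(X_{t−1}) × 100 %

uses weights W_i ∝ max(I_i, 0) frozen from the initial MI profile (a flag
recomputes them at each reconstruction). Design points:

* The decision is **|J| > δ**: J is signed and a large negative drift must
  also trigger. Opposite-sign shifts can cancel in the numerator; this is a
  property of the statistic as defined and is preserved, with an
  `absolute_mode` (Σ W_i |ΔE_i|) for users who consider it a flaw.
* δ defaults to 5 % and is the method's main attention knob; the CLI logs it
  loudly. Larger δ tolerates more drift before retraining.
* The monitor operates on **original units**. Standardized data would have
  expectation ≈ 0 and make the relative change degenerate; hence the
  architectural rule: monitor on raw values, model on scaled values.
* Near-zero weighted denominators (|Σ W_i E_i| < 1e-9 × scale) raise an error
  advising an offset or the absolute mode — BOD-relevant process variables
  are positive, so this only occurs on artificially centered data.
* `should_reconstruct` is read-only; the caller commits the candidate window
  as the new reference only when it accepts the decision, so a rejected
  candidate never silently becomes the baseline.

## Streaming policies

The test stream advances in strides of 96 samples (one day). Each cycle:
predict the stride with the current model, slide the 288-sample training
window forward (append stride, drop oldest; growing-window optional), then
apply the policy — `static` never retrains, `mw` retrains every cycle,
`mpdar` retrains iff |J| > δ, committing the monitor reference on retrain.
Retraining re-initializes from scratch with a per-retrain derived seed
(`warm_start` reuses the previous parameters as initialization). Limit
behavior is exact and tested: δ = ∞ reproduces `static` bit-for-bit, δ = 0
reproduces the `mw` schedule. Every emitted forecast uses only rows strictly
before its target index.

The daily stride and the three-day window mirror common practice of daily
model-maintenance checks against a multi-day training history; both are
configurable.

## Synthetic study conditions

The generator emulates the statistical structure the method consumes, not
activated-sludge biokinetics:

* A latent diurnal influent signal: sinusoid (period one day, amplitude 0.8)
  plus AR(1) noise (coefficient 0.8, unit unconditional sd).
* **Informative channels** = baseline (≈10 g/m³ scale) + gain (1.0–1.5) ×
  latent signal at small per-channel lags (0–3 samples, emulating transport
  through sequential tanks) + observation noise (sd 0.15).
* **Distractor channels**: independent AR(1) noise around the same baseline.
* **Regimes**: rain adds a sustained +2 latent-sd offset (≈ +20 % on a gain-1
  channel mean — the scale of wet-weather flow increases); storm adds +4
  latent-sd plus two 1-hour spikes per day at twice that amplitude
  (mimicking the abrupt mutation points that storms produce in influent
  records). The default 12-day schedule is 7 dry / 2 rain / 3 storm days,
  split as 3 training + 9 test days (288/864 samples).
* **Target**: 5 + 3·tanh(0.8 × mean of standardized informative channels) +
  Gaussian noise (sd 0.1 g/m³) — a smooth saturating response to the current
  informative values, so even short lookbacks are learnable.

Identical config and seed give bitwise-identical data; changing only the seed
changes the noise realization but never the regime schedule.

What the generator does *not* reproduce: biokinetic mass balances, settler
dynamics, control loops, inter-variable couplings beyond the shared latent
driver, heteroscedastic sensor faults, or missing data. Passing the simulation
study therefore shows that the pipeline detects and adapts to mean-shift-type
distribution changes in correlated multivariate streams — not that it matches
any particular physical plant's accuracy.

## Problem sizes in the tests and acceptance script

The multi-seed policy study uses a reduced training budget (H = 16, 60
epochs, lr 3e-3) rather than the single-model default: the study retrains the
predictor dozens of times across 10 seeds and three policies, and at this
input dimension (≤ 5 selected variables, 288-sample windows) the smaller
network already fits the windows well. MI oracle checks use S = 2000 samples
and 10 seeds; KDE identity checks 100 random windows; selection recovery 20
seeds at S = 500. These sizes are the package's reference study conditions
and are defined once in `bodsense.study`.

## Known limitations

* The KSG estimator degrades for heavily quantized variables (many exact
  ties); jitter makes it well-defined but cannot recover lost information.
* J is a first-moment statistic: drifts that change variance or shape while
  preserving all weighted means are invisible to it (and cancellation of
  opposite-sign shifts, unless `absolute_mode` is on).
* The expectation comparison assumes positive-mean process variables, which
  holds for flows and concentrations.
* One-step-ahead forecasting only; no multi-horizon output.
* Retraining cost is the price of adaptation: the pipeline reports per-retrain
  wall time in its traces but makes no timing guarantees.
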
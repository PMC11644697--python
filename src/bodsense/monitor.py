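"""Probability-density drift monitor that triggers model reconstruction.

The idea: rather than retraining the soft sensor on every update cycle,
watch the distribution of the auxiliary variables. Each variable's
density on the current training window is smoothed with a Gaussian
kernel density estimate,

    p(x) = 1/(n·h) Σ_i φ((x − x_i)/h),    φ(u) = exp(−u²/2)/√(2π),

its expectation E(X) = ∫ x·p(x) dx is computed by quadrature (for a
symmetric kernel this equals the sample mean exactly — the quadrature
is kept because it makes that identity a verifiable numerical check),
and the relative change rate between consecutive windows is

    J = (E(X_t) − E(X_{t−1})) / E(X_{t−1}) × 100%.

For m auxiliary variables the per-variable expectations are combined
with MI-derived weights W_i = I(X_i,Y)/Σ_j I(X_j,Y):

    J = Σ_i W_i (E_i(X_t) − E_i(X_{t−1})) / Σ_i W_i E_i(X_{t−1}) × 100%

which reduces to the univariate form at m = 1. The model is rebuilt
when |J| exceeds a threshold δ. Note the signed numerator lets shifts
of opposite sign cancel; ``absolute_mode`` replaces the numerator with
Σ W_i |ΔE_i| for users who consider that cancellation a flaw.

Monitoring operates on ORIGINAL units, never on z-scored data: a
standardized variable has expectation ≈ 0 and the relative change J
would be degenerate. (The predictor sees scaled data; the monitor does
not.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate

__all__ = [
    "DriftMonitorState",
    "kde_density",
    "kde_expectation",
    "silverman_bandwidth",
    "change_rate",
    "weights_from_mi",
    "multivariate_change_rate",
    "should_reconstruct",
]

DEFAULT_DELTA = 5.0  # |J| threshold in %; the method's attention knob

_SQRT2PI = np.sqrt(2.0 * np.pi)


def kde_density(samples: np.ndarray, h: float, x: float | np.ndarray):
    """Gaussian-kernel density of `samples` with bandwidth h at point(s) x."""
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size < 1:
        raise ValueError("need at least one sample")
    if h <= 0:
        raise ValueError(f"bandwidth must be > 0, got {h}")
    x = np.asarray(x, dtype=float)
    u = (x[..., None] - samples) / h
    dens = np.exp(-0.5 * u**2).sum(axis=-1) / (samples.size * h * _SQRT2PI)
    return float(dens) if dens.ndim == 0 else dens


def silverman_bandwidth(samples: np.ndarray) -> float:
    """Rule-of-thumb bandwidth 0.9·min(sd, IQR/1.34)·n^(−1/5)."""
    samples = np.asarray(samples, dtype=float).ravel()
    n = samples.size
    sd = samples.std(ddof=1) if n > 1 else 0.0
    q75, q25 = np.percentile(samples, [75, 25])
    iqr = q75 - q25
    spread = min(s for s in (sd, iqr / 1.34) if s > 0) if max(sd, iqr) > 0 else 0.0
    if spread <= 0:
        raise ValueError("degenerate sample spread; cannot pick a bandwidth")
    return 0.9 * spread * n ** (-0.2)


def kde_expectation(samples: np.ndarray, h: float,
                    quad_tol: float = 1e-9) -> float:
    """E(X) = ∫ x·p(x) dx by adaptive quadrature over [min−6h, max+6h].

    For the symmetric Gaussian kernel this equals the sample mean
    exactly; the quadrature result must agree within ~1e-6.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size < 1:
        raise ValueError("need at least one sample")
    if h <= 0:
        raise ValueError(f"bandwidth must be > 0, got {h}")
    lo = samples.min() - 6.0 * h
    hi = samples.max() + 6.0 * h
    val, _err = integrate.quad(
        lambda x: x * kde_density(samples, h, x), lo, hi,
        epsabs=quad_tol, epsrel=quad_tol, limit=200,
    )
    return float(val)


def change_rate(e_prev: float, e_curr: float) -> float:
    """Signed relative change of the expectation, in percent."""
    if e_prev == 0:
        raise ZeroDivisionError(
            "previous expectation is 0; relative change is degenerate "
            "(offset the variable or use the multivariate form)"
        )
    return (e_curr - e_prev) / e_prev * 100.0


def weights_from_mi(mi_values: dict[str, float]) -> dict[str, float]:
    """Normalize MI values into monitor weights W_i = I_i⁺ / Σ_j I_j⁺.

    Negative estimates (possible for independent data) are clamped to 0
    before normalizing; weights are ≥ 0 and sum to 1.
    """
    if not mi_values:
        raise ValueError("need at least one variable")
    clamped = {k: max(float(v), 0.0) for k, v in mi_values.items()}
    total = sum(clamped.values())
    if total <= 0:
        raise ValueError("all MI values are <= 0 after clamping; weights undefined")
    return {k: v / total for k, v in clamped.items()}


def multivariate_change_rate(
    e_prev: dict[str, float],
    e_curr: dict[str, float],
    weights: dict[str, float],
    absolute_mode: bool = False,
) -> float:
    """Weighted relative change across m variables, in percent."""
    if set(e_prev) != set(e_curr) or set(e_prev) != set(weights):
        raise ValueError("expectation and weight mappings must cover identical variables")
    num = sum(
        weights[k] * (abs(e_curr[k] - e_prev[k]) if absolute_mode
                      else e_curr[k] - e_prev[k])
        for k in weights
    )
    den = sum(weights[k] * e_prev[k] for k in weights)
    scale = max(abs(e_prev[k]) for k in e_prev)
    if abs(den) < 1e-9 * max(scale, 1e-300):
        raise ZeroDivisionError(
            "weighted previous expectation is ~0; offset the variables or "
            "use absolute_mode"
        )
    return num / den * 100.0


@dataclass
class DriftMonitorState:
    """Reference-window expectations, weights, bandwidths and threshold.

    ``previous_expectations`` are E_i over the committed reference
    window; ``should_reconstruct`` compares a candidate window against
    them without mutating anything — call :meth:`commit` once the caller
    accepts the new window as the reference.
    """

    weights: dict[str, float]
    threshold_delta: float = DEFAULT_DELTA
    absolute_mode: bool = False
    reference_window: dict[str, np.ndarray] = field(default_factory=dict)
    bandwidth_h: dict[str, float] = field(default_factory=dict)
    previous_expectations: dict[str, float] = field(default_factory=dict)
    last_J: float | None = None

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError("monitor needs at least one weighted variable")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be >= 0")
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1 (got {total!r})")

    @property
    def m(self) -> int:
        return len(self.weights)

    @classmethod
    def from_reference(
        cls,
        reference: dict[str, np.ndarray],
        weights: dict[str, float],
        threshold_delta: float = DEFAULT_DELTA,
        absolute_mode: bool = False,
    ) -> "DriftMonitorState":
        state = cls(weights=weights, threshold_delta=threshold_delta,
                    absolute_mode=absolute_mode)
        state.commit(reference)
        return state

    def expectations_of(self, window: dict[str, np.ndarray]) -> dict[str, float]:
        out = {}
        for name in self.weights:
            samples = np.asarray(window[name], dtype=float)
            h = silverman_bandwidth(samples)
            out[name] = kde_expectation(samples, h)
        return out

    def commit(self, window: dict[str, np.ndarray]) -> None:
        """Adopt `window` as the new reference (recomputes E_i and h)."""
        missing = set(self.weights) - set(window)
        if missing:
            raise ValueError(f"window missing monitored variables: {sorted(missing)}")
        self.reference_window = {k: np.asarray(window[k], dtype=float)
                                 for k in self.weights}
        self.bandwidth_h = {k: silverman_bandwidth(v)
                            for k, v in self.reference_window.items()}
        self.previous_expectations = self.expectations_of(window)


def should_reconstruct(
    state: DriftMonitorState, new_window: dict[str, np.ndarray]
) -> tuple[bool, float]:
    """Drift decision for a candidate training window.

    Computes E_i on `new_window`, the weighted change rate J against the
    committed reference, and returns ``(|J| > δ, J)``. State is NOT
    updated here; the caller commits the window when it accepts the
    decision (so a rejected candidate never silently becomes the new
    reference).
    """
    if not state.previous_expectations:
        raise ValueError("monitor has no committed reference window")
    e_curr = state.expectations_of(new_window)
    J = multivariate_change_rate(
        state.previous_expectations, e_curr, state.weights,
        absolute_mode=state.absolute_mode,
    )
    state.last_J = J
    return abs(J) > state.threshold_delta, J
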
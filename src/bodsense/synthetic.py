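"""Regime-switching synthetic process data with known ground truth.

Emulates the statistical structure of benchmark activated-sludge plant
records that the soft sensor consumes — not the biokinetics. A latent
diurnal influent signal (sinusoid + AR(1) noise) propagates through
"informative" channels via per-channel gains and small fixed lags,
mimicking sequential reaction tanks; weather regimes shift the latent
signal (rain: sustained offset; storm: larger offset plus two short
spikes per day); "distractor" channels are independent AR(1) noise; the
target is a smooth saturating function of the current informative
readings plus Gaussian noise.

Determinism contract: identical config (including seed) gives bitwise
identical output; changing only the seed changes the noise realization
but never the regime schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import ProcessDataset

__all__ = ["ScenarioConfig", "generate", "ground_truth"]

REGIMES = ("dry", "rain", "storm")


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic scenario.

    ``regime_schedule`` is an ordered list of ``(regime, n_days)`` spans
    that must tile ``[0, n_days)``. Shifts are expressed in units of the
    latent signal's nominal sd (≈1), so ``rain_shift=2.0`` moves a
    gain-1 channel's mean by about +20% of its ~10 g/m³ baseline —
    the scale of wet-weather flow increases in benchmark plant data.
    """

    n_days: int = 12
    samples_per_day: int = 96  # 15-min sampling
    n_informative: int = 5
    n_distractor: int = 10
    regime_schedule: list[tuple[str, int]] = field(
        default_factory=lambda: [("dry", 7), ("rain", 2), ("storm", 3)]
    )
    rain_shift: float = 2.0
    storm_shift: float = 4.0
    noise_sd: float = 0.1  # target observation noise (g/m³)
    channel_noise_sd: float = 0.15
    ar_coef: float = 0.8
    target_lag: int = 0
    seed: int = 0
    target_name: str = "BOD_out"

    def validate(self) -> None:
        if self.n_informative < 1:
            raise ValueError("need at least one informative channel")
        if self.n_distractor < 0:
            raise ValueError("n_distractor must be >= 0")
        if self.rain_shift < 0 or self.storm_shift < 0:
            raise ValueError("regime shifts must be >= 0")
        if not (0 <= self.ar_coef < 1):
            raise ValueError("ar_coef must be in [0, 1)")
        total = 0
        for regime, span in self.regime_schedule:
            if regime not in REGIMES:
                raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")
            if span <= 0:
                raise ValueError("regime spans must be positive")
            total += span
        if total != self.n_days:
            raise ValueError(
                f"regime schedule covers {total} days but n_days={self.n_days}"
            )

    # -- deterministic per-channel structure (independent of seed) --------
    def channel_gain(self, c: int) -> float:
        return 1.0 + 0.1 * c

    def channel_lag(self, c: int) -> int:
        return c % 4

    def channel_base(self, c: int) -> float:
        return 10.0 + float(c)

    def variable_names(self) -> list[str]:
        n = self.n_informative + self.n_distractor
        return [f"V{i + 1:02d}" for i in range(n)]


def _ar1(rng: np.random.Generator, n: int, coef: float, innov_sd: float) -> np.ndarray:
    """Stationary AR(1) path with unconditional sd = innov_sd/sqrt(1-coef²)."""
    e = rng.normal(0.0, innov_sd, size=n)
    x = np.empty(n)
    x[0] = e[0] / np.sqrt(1.0 - coef**2) if coef > 0 else e[0]
    for t in range(1, n):
        x[t] = coef * x[t - 1] + e[t]
    return x


def regime_per_sample(cfg: ScenarioConfig) -> np.ndarray:
    """Expand the per-day schedule to one label per sample."""
    labels: list[str] = []
    for regime, span in cfg.regime_schedule:
        labels.extend([regime] * (span * cfg.samples_per_day))
    return np.array(labels, dtype=object)


def latent_signal(cfg: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Diurnal latent influent driver, regime offsets included."""
    T = cfg.n_days * cfg.samples_per_day
    t = np.arange(T)
    # innovation sd scaled so the AR part has unit unconditional sd
    diurnal = 0.8 * np.sin(2.0 * np.pi * t / cfg.samples_per_day)
    ar = _ar1(rng, T, cfg.ar_coef, innov_sd=np.sqrt(1.0 - cfg.ar_coef**2))
    z = diurnal + ar
    labels = regime_per_sample(cfg)
    z = z + np.where(labels == "rain", cfg.rain_shift, 0.0)
    z = z + np.where(labels == "storm", cfg.storm_shift, 0.0)
    # two short high spikes per storm day ("mutation points")
    spike_amp = 2.0 * cfg.storm_shift
    spike_width = 4  # one hour at 15-min sampling
    storm_days = [
        d
        for d in range(cfg.n_days)
        if labels[d * cfg.samples_per_day] == "storm"
    ]
    for d in storm_days:
        day0 = d * cfg.samples_per_day
        for frac in (0.25, 0.65):
            s = day0 + int(frac * cfg.samples_per_day)
            z[s : s + spike_width] += spike_amp
    return z


def generate(cfg: ScenarioConfig) -> ProcessDataset:
    """Generate one scenario as a :class:`ProcessDataset` with regime labels."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    T = cfg.n_days * cfg.samples_per_day
    z = latent_signal(cfg, rng)
    labels = regime_per_sample(cfg)
    names = cfg.variable_names()

    cols = []
    max_lag = max(cfg.channel_lag(c) for c in range(cfg.n_informative))
    # pad the latent history backwards so lagged channels are defined at t=0
    z_pad = np.concatenate([np.full(max_lag, z[0]), z])
    informative_clean = np.empty((T, cfg.n_informative))
    for c in range(cfg.n_informative):
        lag = cfg.channel_lag(c)
        driven = z_pad[max_lag - lag : max_lag - lag + T]
        informative_clean[:, c] = cfg.channel_base(c) + cfg.channel_gain(c) * driven
        obs = informative_clean[:, c] + rng.normal(0.0, cfg.channel_noise_sd, size=T)
        cols.append(obs)
    for c in range(cfg.n_distractor):
        cols.append(10.0 + _ar1(rng, T, cfg.ar_coef, innov_sd=1.0))

    # target: saturating function of the current informative readings
    std_inf = (informative_clean - np.array(
        [cfg.channel_base(c) for c in range(cfg.n_informative)]
    )) / np.array([cfg.channel_gain(c) for c in range(cfg.n_informative)])
    drive = std_inf.mean(axis=1)
    if cfg.target_lag > 0:
        drive = np.concatenate([np.full(cfg.target_lag, drive[0]), drive])[:T]
    target = 5.0 + 3.0 * np.tanh(0.8 * drive) + rng.normal(0.0, cfg.noise_sd, size=T)

    return ProcessDataset(
        values=np.column_stack(cols),
        variable_names=names,
        target=target,
        target_name=cfg.target_name,
        regime_labels=labels,
    )


def ground_truth(cfg: ScenarioConfig) -> dict[str, str]:
    """Map every generated variable name to ``informative`` or ``distractor``."""
    names = cfg.variable_names()
    return {
        name: ("informative" if i < cfg.n_informative else "distractor")
        for i, name in enumerate(names)
    }
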
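"""k-nearest-neighbor (KSG) mutual information and threshold selection.

Auxiliary-variable selection for the soft sensor: estimate I(X; Y) in
nats between every candidate process variable X and the target Y with
the Kraskov–Stögbauer–Grassberger estimator (variant 2), then keep the
variables whose MI exceeds a threshold λ.

Estimator (KSG algorithm 2). For each sample i, locate its k-th nearest
neighbor in the joint (x, y) space under the Chebyshev (max) norm; let
ε_x(i)/2 and ε_y(i)/2 be the largest per-axis distances from i to those
k neighbors; count n_x(i) = #{j ≠ i : |x_j − x_i| ≤ ε_x(i)/2} and
analogously n_y(i). Then

    Î(X, Y) = Ψ(k) − 1/k − ⟨Ψ(n_x) + Ψ(n_y)⟩ + Ψ(S)

with Ψ the digamma function and S the sample count. The estimate can be
slightly negative for independent data; it is reported as-is (clamping
to 0 happens only where MI values become drift-monitor weights).

Boundary points exactly at ε/2 are counted (``<=``) — the variant-2
convention; with continuous data the event is measure-zero. Duplicate
sensor readings would make neighbor distances degenerate, so a seeded
uniform jitter of amplitude ``1e-10 × scale`` is added before the
neighbor search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import digamma

from .dataset import ProcessDataset

__all__ = ["MIProfile", "ksg_mi", "compute_mi_profile"]

DEFAULT_K = 3  # neighbor count; sensible values lie in 2..6
DEFAULT_LAMBDA = 1.2  # selection threshold (nats) used on full-plant data

_JITTER_AMPLITUDE = 1e-10


@dataclass
class MIProfile:
    """Per-variable MI against the target and the resulting selection."""

    mi_values: dict[str, float]
    k: int
    threshold_lambda: float
    selected: list[str]
    sample_count: int
    failed: dict[str, str] = field(default_factory=dict)

    def ranked(self) -> list[tuple[str, float]]:
        """(variable, MI) pairs sorted by descending MI."""
        return sorted(self.mi_values.items(), key=lambda kv: -kv[1])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "variable": name,
                "mi_nats": mi,
                "selected": int(name in self.selected),
                "rank": rank + 1,
            }
            for rank, (name, mi) in enumerate(self.ranked())
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, k: int = DEFAULT_K,
                   threshold_lambda: float = DEFAULT_LAMBDA,
                   sample_count: int = 0) -> "MIProfile":
        mi = dict(zip(df["variable"], df["mi_nats"].astype(float)))
        sel = df[df["selected"].astype(int) == 1].sort_values("rank")
        return cls(
            mi_values=mi,
            k=k,
            threshold_lambda=threshold_lambda,
            selected=list(sel["variable"]),
            sample_count=sample_count,
        )


def _jitter(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    scale = x.std()
    if scale == 0:
        raise ValueError("constant series: neighbor distances are degenerate")
    return x + rng.uniform(-1.0, 1.0, size=x.shape) * (_JITTER_AMPLITUDE * scale)


def _marginal_counts(v: np.ndarray, eps: np.ndarray, chunk: int = 256) -> np.ndarray:
    """n(i) = #{j != i : |v_j - v_i| <= eps_i}, by exact pairwise comparison."""
    S = v.size
    out = np.empty(S, dtype=np.int64)
    for lo in range(0, S, chunk):
        hi = min(lo + chunk, S)
        d = np.abs(v[None, :] - v[lo:hi, None])
        out[lo:hi] = (d <= eps[lo:hi, None]).sum(axis=1) - 1  # drop self
    return out


def ksg_neighbor_stats(
    x: np.ndarray, y: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample marginal neighbor counts (n_x, n_y) for the estimator.

    Neighbor search uses a KD-tree under the Chebyshev norm; the counts
    themselves are exact pairwise comparisons against the per-axis ε/2.
    """
    pts = np.column_stack([x, y])
    tree = cKDTree(pts)
    # k+1 because each point is its own nearest neighbor
    _, idx = tree.query(pts, k=k + 1, p=np.inf)
    nbrs = idx[:, 1:]
    eps_x = np.abs(x[nbrs] - x[:, None]).max(axis=1)
    eps_y = np.abs(y[nbrs] - y[:, None]).max(axis=1)
    return _marginal_counts(x, eps_x), _marginal_counts(y, eps_y)


def ksg_mi(x, y, k: int = DEFAULT_K, jitter_seed: int = 0) -> float:
    """KSG variant-2 MI estimate between two equal-length series, in nats."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    S = x.size
    if not (2 <= k <= S - 1):
        raise ValueError(f"need 2 <= k <= S-1, got k={k}, S={S}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("series contain non-finite values")
    rng = np.random.default_rng(jitter_seed)
    xj = _jitter(x, rng)
    yj = _jitter(y, rng)
    n_x, n_y = ksg_neighbor_stats(xj, yj, k)
    return float(
        digamma(k)
        - 1.0 / k
        - np.mean(digamma(n_x) + digamma(n_y))
        + digamma(S)
    )


def compute_mi_profile(
    ds: ProcessDataset,
    k: int = DEFAULT_K,
    threshold_lambda: float = DEFAULT_LAMBDA,
    jitter_seed: int = 0,
) -> MIProfile:
    """MI of every process variable against the target, plus selection.

    A variable whose estimate fails (e.g. a constant sensor) is excluded
    from the selection with a warning rather than aborting the profile.
    Selection keeps variables with MI strictly above λ, ordered by
    descending MI.
    """
    mi_values: dict[str, float] = {}
    failed: dict[str, str] = {}
    for name in ds.variable_names:
        try:
            mi_values[name] = ksg_mi(ds.column(name), ds.target, k=k,
                                     jitter_seed=jitter_seed)
        except ValueError as exc:
            failed[name] = str(exc)
            warnings.warn(f"MI estimation failed for {name!r}: {exc}", stacklevel=2)
    selected = [
        name for name, mi in sorted(mi_values.items(), key=lambda kv: -kv[1])
        if mi > threshold_lambda
    ]
    if not selected:
        warnings.warn(
            f"no variable exceeds lambda={threshold_lambda}; "
            "downstream modeling will fail without auxiliary variables",
            stacklevel=2,
        )
    return MIProfile(
        mi_values=mi_values,
        k=k,
        threshold_lambda=threshold_lambda,
        selected=selected,
        sample_count=ds.n_samples,
        failed=failed,
    )
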
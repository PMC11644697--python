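"""Process time-series container, CSV I/O, scaling, and windowing.

The central object is :class:`ProcessDataset`: a uniformly sampled
multivariate record of a treatment plant's process variables (flows in
m³/d, component concentrations in g/m³) together with the target series
(effluent BOD, g/m³) that the soft sensor predicts.

Conventions
-----------
* Row/window indices are 0-based; intervals are half-open ``[start, stop)``.
* Datasets are rejected, not repaired: missing or non-numeric cells raise.
* The on-disk format is plain CSV with one header row; an optional
  ``regime`` column carries categorical operating-condition labels
  (e.g. ``dry`` / ``rain`` / ``storm``); an optional ``t`` column carries
  timestamps in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProcessDataset",
    "Scaler",
    "read_dataset",
    "write_dataset",
    "fit_scaler",
    "window_sequences",
]

#: default sampling period in minutes
DEFAULT_PERIOD_MIN = 15.0

_RESERVED_COLUMNS = ("t", "regime")


@dataclass
class ProcessDataset:
    """Aligned multivariate process time series plus the target series.

    Parameters
    ----------
    values
        ``(T, V)`` array of process-variable readings.
    variable_names
        ``V`` unique names, e.g. ``"SS_r5"``, ``"Q_in"``; never contains
        the target's name.
    target
        Length-``T`` target series (effluent BOD, g/m³).
    target_name
        Name of the target column on disk.
    timestamps
        Length-``T`` strictly increasing, uniformly spaced sample times
        (minutes). Defaults to ``0, 15, 30, ...``.
    regime_labels
        Optional length-``T`` categorical labels (dry/rain/storm).
    """

    values: np.ndarray
    variable_names: list[str]
    target: np.ndarray
    target_name: str = "BOD_out"
    timestamps: np.ndarray | None = None
    regime_labels: np.ndarray | None = None
    period_min: float = DEFAULT_PERIOD_MIN

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.target = np.asarray(self.target, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (T, V) array")
        T, V = self.values.shape
        if T < 2 or V < 1:
            raise ValueError(f"need T >= 2 and V >= 1, got T={T}, V={V}")
        if len(self.variable_names) != V:
            raise ValueError("variable_names length does not match values")
        if len(set(self.variable_names)) != V:
            raise ValueError("variable_names must be unique")
        if self.target_name in self.variable_names:
            raise ValueError("variable_names must not include the target name")
        if self.target.shape != (T,):
            raise ValueError("target length does not match values")
        if not np.all(np.isfinite(self.values)) or not np.all(np.isfinite(self.target)):
            raise ValueError("dataset contains missing or non-finite entries")
        if self.timestamps is None:
            self.timestamps = np.arange(T, dtype=float) * self.period_min
        else:
            self.timestamps = np.asarray(self.timestamps, dtype=float)
            if self.timestamps.shape != (T,):
                raise ValueError("timestamps length does not match values")
            dt = np.diff(self.timestamps)
            if not np.all(dt > 0):
                raise ValueError("timestamps must be strictly increasing")
            if dt.size and not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-9):
                raise ValueError("timestamps must be uniformly spaced")
            self.period_min = float(dt[0]) if dt.size else self.period_min
        if self.regime_labels is not None:
            self.regime_labels = np.asarray(self.regime_labels, dtype=object)
            if self.regime_labels.shape != (T,):
                raise ValueError("regime_labels length does not match values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        """Return one variable's series by name."""
        try:
            j = self.variable_names.index(name)
        except ValueError:
            raise KeyError(f"variable {name!r} not in dataset") from None
        return self.values[:, j]

    def select(self, names: Sequence[str]) -> "ProcessDataset":
        """Restrict to a subset of variables (order of `names` kept)."""
        idx = [self.variable_names.index(n) for n in names]
        return ProcessDataset(
            values=self.values[:, idx],
            variable_names=list(names),
            target=self.target.copy(),
            target_name=self.target_name,
            timestamps=self.timestamps.copy(),
            regime_labels=None if self.regime_labels is None else self.regime_labels.copy(),
        )

    def slice_rows(self, start: int, stop: int) -> "ProcessDataset":
        """Half-open row slice ``[start, stop)`` as a new dataset."""
        if stop - start < 2:
            raise ValueError("slice must keep at least 2 rows")
        return ProcessDataset(
            values=self.values[start:stop],
            variable_names=list(self.variable_names),
            target=self.target[start:stop],
            target_name=self.target_name,
            timestamps=self.timestamps[start:stop],
            regime_labels=None
            if self.regime_labels is None
            else self.regime_labels[start:stop],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.variable_names)
        df.insert(0, "t", self.timestamps)
        df[self.target_name] = self.target
        if self.regime_labels is not None:
            df["regime"] = self.regime_labels
        return df


def read_dataset(path, target_name: str) -> ProcessDataset:
    """Read a one-header-row delimited-text dataset.

    Every column other than ``t``, ``regime`` and *target_name* becomes a
    process variable, in file order. Raises on a missing target column,
    on any non-numeric cell (naming its row and column), and on ragged
    rows.
    """
    try:
        # round_trip parsing: 17-significant-digit CSVs reload bit-exactly
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    if target_name not in df.columns:
        raise ValueError(
            f"target not found: column {target_name!r} missing from {path} "
            f"(columns: {list(df.columns)})"
        )
    var_cols = [c for c in df.columns if c != target_name and c not in _RESERVED_COLUMNS]
    if not var_cols:
        raise ValueError("dataset has no process-variable columns")
    numeric_cols = var_cols + [target_name]
    for col in numeric_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric cell at row {row}, column {col!r}: {df[col].iloc[row]!r}"
            )
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise ValueError(f"missing value at row {row}, column {col!r}")
        df[col] = coerced.astype(float)
    timestamps = df["t"].to_numpy(dtype=float) if "t" in df.columns else None
    regimes = df["regime"].to_numpy(dtype=object) if "regime" in df.columns else None
    return ProcessDataset(
        values=df[var_cols].to_numpy(dtype=float),
        variable_names=var_cols,
        target=df[target_name].to_numpy(dtype=float),
        target_name=target_name,
        timestamps=timestamps,
        regime_labels=regimes,
    )


def write_dataset(ds: ProcessDataset, path) -> None:
    """Write a dataset as CSV, preserving values to 12+ significant digits."""
    ds.to_frame().to_csv(path, index=False, float_format="%.17g")


@dataclass
class Scaler:
    """Per-variable z-score statistics fitted on a training slice.

    ``transform`` maps each retained variable to zero mean / unit sd
    under the fitted statistics; ``inverse_transform`` undoes it exactly.
    """

    mean: np.ndarray
    std: np.ndarray
    variable_names: list[str] = field(default_factory=list)

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.mean) / self.std

    def inverse_transform(self, scaled: np.ndarray) -> np.ndarray:
        return np.asarray(scaled, dtype=float) * self.std + self.mean


def fit_scaler(ds: ProcessDataset, rows: slice | tuple[int, int] | None = None) -> Scaler:
    """Fit per-variable mean/sd over a half-open row range.

    Raises for an empty range or a zero-variance variable (named in the
    message) — a constant channel cannot be standardized.
    """
    if rows is None:
        start, stop = 0, ds.n_samples
    elif isinstance(rows, slice):
        start, stop, step = rows.indices(ds.n_samples)
        if step != 1:
            raise ValueError("row range must be contiguous")
    else:
        start, stop = rows
    if stop <= start:
        raise ValueError(f"empty row range [{start}, {stop})")
    block = ds.values[start:stop]
    mean = block.mean(axis=0)
    std = block.std(axis=0)
    zero = np.flatnonzero(std <= 0)
    if zero.size:
        names = [ds.variable_names[j] for j in zero]
        raise ValueError(f"zero-variance variable(s) in fit range: {names}")
    return Scaler(mean=mean, std=std, variable_names=list(ds.variable_names))


def fit_target_scaler(target: np.ndarray) -> Scaler:
    """One-column scaler for the target series."""
    target = np.asarray(target, dtype=float)
    sd = target.std()
    if sd <= 0:
        raise ValueError("zero-variance target in fit range")
    return Scaler(mean=np.array([target.mean()]), std=np.array([sd]))


def window_sequences(
    ds: ProcessDataset, lookback: int
) -> Iterator[tuple[np.ndarray, float]]:
    """Yield (L×V window, next-step target) training pairs.

    Pair ``j`` uses rows ``j .. j+L-1`` as input and row ``j+L``'s target
    as output, so the target always lies strictly after every input row
    (no leakage). Exactly ``T - L`` pairs are produced.
    """
    L = int(lookback)
    T = ds.n_samples
    if L < 1:
        raise ValueError("lookback must be >= 1")
    if L >= T:
        raise ValueError(f"lookback {L} must be smaller than T={T}")
    for j in range(T - L):
        yield ds.values[j : j + L], float(ds.target[j + L])


def windows_as_arrays(ds: ProcessDataset, lookback: int) -> tuple[np.ndarray, np.ndarray]:
    """Stack :func:`window_sequences` into ``(N, L, V)`` and ``(N,)`` arrays."""
    pairs = list(window_sequences(ds, lookback))
    X = np.stack([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    return X, y
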
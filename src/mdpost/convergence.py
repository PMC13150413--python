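"""Uncertainty quantification for scalar observables.

Two estimators of the standard error of the mean (SEM) of a correlated time
series are provided:

* **ACF route** — the normalized autocorrelation function ACF(k) is summed
  into the statistical inefficiency ``g = 1 + 2 Σ (1 - k/N) ACF(k)``
  (triangular finite-sample correction, sum truncated at the first negative
  crossing), giving ``SEM = s √(g/N)`` with ``s`` the sample standard
  deviation, the integrated autocorrelation time ``τ_int = g dt / 2`` and the
  effective sample count ``N/g``.
* **Block averaging** — the series is cut into contiguous equal blocks and
  the SEM estimated from the scatter of block means; scanning block counts
  and locating the plateau of the resulting curve removes the block-size
  sensitivity of a single choice.

For uncorrelated data both reduce to ``s/√N``; for correlated data the block
estimate converges to the ACF estimate once blocks exceed the correlation
time. The module is unit-agnostic in the observable and only assumes a
uniform sampling interval ``dt`` (fs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSeriesError, InsufficientDataError, ParameterError


@dataclass
class TimeSeries:
    """Uniformly sampled scalar observable; dt in fs."""

    values: np.ndarray
    dt: float = 1.0
    label: str = "observable"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 2:
            raise ParameterError("time series needs at least two samples")
        if self.dt <= 0:
            raise ParameterError("dt must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("non-finite values in time series")

    def __len__(self) -> int:
        return self.values.size

    @classmethod
    def from_csv(cls, path, label: str = "observable") -> "TimeSeries":
        """Load a two-column (time_fs, value) CSV; dt from the time column."""
        import pandas as pd

        df = pd.read_csv(path, comment="#")
        t = df.iloc[:, 0].to_numpy(dtype=float)
        dt = float(np.median(np.diff(t))) if t.size > 1 else 1.0
        return cls(df.iloc[:, 1].to_numpy(dtype=float), dt=dt, label=label)


@dataclass
class ErrorEstimate:
    mean: float
    sem: float
    method: str  # {"acf", "block"}
    tau_int: float | None = None   # fs
    g: float | None = None         # statistical inefficiency
    n_eff: float | None = None
    block_size: int | None = None  # samples per block


def acf(series: TimeSeries, max_lag: int | None = None) -> np.ndarray:
    """Normalized autocorrelation function for lags 0..max_lag.

    Uses the biased (1/N) autocovariance, computed via FFT; ACF(0) == 1.
    """
    x = series.values
    n = x.size
    if max_lag is None:
        max_lag = n - 1
    if max_lag >= n:
        raise ParameterError(f"max_lag {max_lag} must be < N = {n}")
    xc = x - x.mean()
    var = float(np.dot(xc, xc)) / n
    if var == 0.0:
        raise DegenerateSeriesError("zero-variance series has no ACF")
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[: max_lag + 1] / n
    return acov / var


def sem_acf(series: TimeSeries, max_lag: int | None = None) -> ErrorEstimate:
    """ACF-based SEM with first-negative-crossing truncation.

    ``max_lag`` optionally caps the summation window; by default the sum runs
    until the ACF first dips below zero.
    """
    rho = acf(series, max_lag=max_lag)
    n = len(series)
    neg = np.nonzero(rho[1:] < 0.0)[0]
    k_stop = int(neg[0]) + 1 if neg.size else rho.size  # exclusive
    k = np.arange(1, k_stop)
    g = 1.0 + 2.0 * float(np.sum((1.0 - k / n) * rho[1:k_stop]))
    g = max(g, 1.0)  # estimator noise can push g slightly below 1
    s = float(np.std(series.values, ddof=1))
    return ErrorEstimate(
        mean=float(np.mean(series.values)),
        sem=s * np.sqrt(g / n),
        method="acf",
        tau_int=g * series.dt / 2.0,
        g=g,
        n_eff=n / g,
    )


def block_sem(series: TimeSeries, n_blocks: int) -> ErrorEstimate:
    """Block-averaging SEM with n_blocks contiguous equal blocks.

    Samples that do not fill the final block are dropped from the tail;
    the block-mean scatter uses the (n_blocks - 1) denominator.
    """
    n = len(series)
    if not 2 <= n_blocks <= n:
        raise ParameterError(f"n_blocks {n_blocks} outside [2, N] for N={n}")
    size = n // n_blocks
    trimmed = series.values[: size * n_blocks]
    means = trimmed.reshape(n_blocks, size).mean(axis=1)
    return ErrorEstimate(
        mean=float(np.mean(series.values)),
        sem=float(np.std(means, ddof=1) / np.sqrt(n_blocks)),
        method="block",
        block_size=size,
    )


def default_block_counts(n: int, n_points: int = 14) -> list[int]:
    """Logarithmically spaced block counts between 4 and N/10."""
    hi = max(4, min(n // 10, 1 << 14))
    counts = np.unique(np.round(np.logspace(np.log10(4), np.log10(hi),
                                            n_points)).astype(int))
    return [int(c) for c in counts if 2 <= c <= n // 2]


def block_scan(series: TimeSeries, block_counts=None,
               rel_tol: float = 0.10):
    """SEM as a function of block count, plus an automatic plateau estimate.

    The plateau (the "converged" SEM, insensitive to block size) is detected
    on the scan ordered by increasing block *size*: the first window of three
    consecutive SEM values that agree pairwise within ``rel_tol`` relative
    difference wins, and the median of those three is reported. If no such
    window exists, the SEM at the largest block size is returned and
    ``plateau_found`` is False.

    Returns ``(curve, plateau)`` where curve is a list of (n_blocks, sem)
    and plateau is an ErrorEstimate whose block_size marks the selection.
    """
    if block_counts is None:
        block_counts = default_block_counts(len(series))
    counts = sorted({int(c) for c in block_counts})
    if len(counts) < 3:
        raise InsufficientDataError("block_scan needs at least 3 block counts")
    estimates = {c: block_sem(series, c) for c in counts}
    curve = [(c, estimates[c].sem) for c in counts]

    by_size = sorted(counts, reverse=True)  # increasing block size
    plateau = None
    plateau_found = False
    for a, b, c in zip(by_size, by_size[1:], by_size[2:]):
        sems = np.array([estimates[a].sem, estimates[b].sem, estimates[c].sem])
        lo, hi = sems.min(), sems.max()
        if hi == 0.0 or (hi - lo) / hi < rel_tol:
            order = np.argsort(sems)
            pick = (a, b, c)[int(order[1])]
            plateau = estimates[pick]
            plateau_found = True
            break
    if plateau is None:
        plateau = estimates[by_size[-1]]
    plateau.method = "block"
    plateau.n_eff = None if plateau.sem == 0 else (
        float(np.var(series.values, ddof=1)) / plateau.sem**2)
    plateau.plateau_found = plateau_found  # type: ignore[attr-defined]
    return curve, plateau
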
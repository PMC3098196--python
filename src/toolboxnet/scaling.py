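"""Logarithmic binning and power-law exponent estimation.

Trajectories and pathway statistics are binned geometrically along the
x-axis; the exponent of ``y ~ A * x**alpha`` is estimated by least squares on
the log of the per-bin means.  Per-bin y-values are arithmetic means so that
observations equal to zero (e.g. byproduct-free pathways) contribute and bin
means may fall below 1; bins whose mean is zero carry no information on a
log scale and are dropped from the fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

from .errors import InsufficientDataError

__all__ = ["BinnedSeries", "PowerLawFit", "log_bin", "fit_power_law", "fit_ensemble"]


@dataclass
class BinnedSeries:
    """Geometrically binned (x, y) data; only non-empty bins are kept."""

    x_geo: np.ndarray  # per-bin geometric mean of x
    x_mean: np.ndarray  # per-bin arithmetic mean of x
    y_mean: np.ndarray  # per-bin arithmetic mean of y (zeros included)
    y_std: np.ndarray  # per-bin standard deviation of y
    counts: np.ndarray
    edges: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.x_geo.size

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())


@dataclass
class PowerLawFit:
    """Least-squares fit of log y vs log x on binned data."""

    alpha: float
    prefactor: float
    stderr: float
    n_bins: int
    alpha_std: float | None = None  # across-realization spread (ensemble mode)


def log_bin(x, y, bins_per_decade: int = 10) -> BinnedSeries:
    """Bin (x, y) pairs into geometric x-bins anchored at min(x).

    x must be strictly positive; y may contain zeros.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if np.any(x <= 0):
        raise ValueError("x values must be strictly positive for log binning")
    if bins_per_decade < 1:
        raise ValueError("bins_per_decade must be >= 1")
    log_ratio = 1.0 / bins_per_decade  # decades per bin
    xmin = x.min()
    # bin index of the containing geometric interval; top point folded into
    # the last bin to keep edges right-open except at the maximum
    # small nudge keeps points lying exactly on an edge in the upper bin
    idx = np.floor(np.log10(x / xmin) / log_ratio + 1e-9).astype(np.int64)
    idx = np.minimum(idx, max(int(idx.max()), 0))
    n_edges = int(idx.max()) + 2
    edges = xmin * 10.0 ** (log_ratio * np.arange(n_edges))
    nonempty = np.unique(idx)
    x_geo, x_mean, y_mean, y_std, counts = [], [], [], [], []
    for b in nonempty:
        sel = idx == b
        xs, ys = x[sel], y[sel]
        x_geo.append(np.exp(np.mean(np.log(xs))))
        x_mean.append(xs.mean())
        y_mean.append(ys.mean())
        y_std.append(ys.std())
        counts.append(xs.size)
    return BinnedSeries(
        x_geo=np.array(x_geo),
        x_mean=np.array(x_mean),
        y_mean=np.array(y_mean),
        y_std=np.array(y_std),
        counts=np.array(counts, dtype=np.int64),
        edges=edges,
    )


def fit_power_law(binned: BinnedSeries, min_count: int = 1) -> PowerLawFit:
    """Fit ``log10(y_mean) = alpha*log10(x_geo) + log10(A)`` by least squares.

    Requires at least three bins with positive mean.  ``min_count`` excludes
    bins holding fewer points; pooled-trajectory fits use this to drop the
    sparse low-x bins whose means sit on the N_L = 1 discreteness floor.
    """
    mask = (binned.y_mean > 0) & (binned.counts >= min_count)
    if int(mask.sum()) < 3:
        raise InsufficientDataError(
            f"need >= 3 bins with positive mean and >= {min_count} points, "
            f"got {int(mask.sum())}"
        )
    res = sp_stats.linregress(
        np.log10(binned.x_geo[mask]), np.log10(binned.y_mean[mask])
    )
    return PowerLawFit(
        alpha=float(res.slope),
        prefactor=float(10.0**res.intercept),
        stderr=float(res.stderr),
        n_bins=int(mask.sum()),
    )


def fit_ensemble(series, bins_per_decade: int = 10, min_count: int = 1) -> PowerLawFit:
    """Fit each realization separately; report mean alpha +- std across them.

    ``series`` is an iterable of (x, y) pairs.  The ensemble spread mirrors
    the error analysis over independent realizations of the model.
    """
    alphas, prefs, ns = [], [], []
    for x, y in series:
        fit = fit_power_law(log_bin(x, y, bins_per_decade), min_count)
        alphas.append(fit.alpha)
        prefs.append(fit.prefactor)
        ns.append(fit.n_bins)
    if not alphas:
        raise InsufficientDataError("no realizations supplied")
    alphas = np.array(alphas)
    return PowerLawFit(
        alpha=float(alphas.mean()),
        prefactor=float(np.mean(prefs)),
        stderr=float(alphas.std(ddof=1) / np.sqrt(alphas.size)) if alphas.size > 1 else 0.0,
        n_bins=int(np.mean(ns)),
        alpha_std=float(alphas.std(ddof=1)) if alphas.size > 1 else 0.0,
    )
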
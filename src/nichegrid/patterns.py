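"""Latitudinal biodiversity gradients and map validation.

The LBG of a richness map is summarized two ways: as a per-latitude median
over longitudes (requiring a minimum number of contributing longitudes),
and as a per-latitude histogram of globally min-max standardized richness
(bin width 0.05 on [0, 1]) that shows how the gradient varies across
longitudes.

Validation against an observed richness grid uses the Pearson correlation
over jointly valid cells.  Because neighbouring cells are spatially
autocorrelated, the nominal sample size overstates the information content;
alongside r we report n*, the smallest sample size at which the observed r
would remain significant in a two-sided t test at p = .05.  Small n* means
the relationship survives even a drastic effective-sample-size reduction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DegenerateInputError, InsufficientDataError


@dataclass
class LBGProfile:
    latitudes: np.ndarray
    median_richness: np.ndarray  # NaN where too few longitudes contribute
    n_longitudes: np.ndarray

    def peak_latitude(self) -> float:
        """Latitude of the maximum median richness (NaN-aware)."""
        if np.all(np.isnan(self.median_richness)):
            return np.nan
        return float(self.latitudes[np.nanargmax(self.median_richness)])


@dataclass
class LBGMatrix:
    latitudes: np.ndarray
    bin_edges: np.ndarray
    percentage: np.ndarray  # (nlat, nbins); rows with data sum to 100


@dataclass
class CorrelationReport:
    r: float
    n: int
    n_star: int | None
    p_value: float


def lbg_median(
    richness: np.ndarray,
    latitudes: np.ndarray,
    min_longitudes: int = 5,
) -> LBGProfile:
    """Per-latitude median of a richness map across longitudes.

    A latitude with fewer than ``min_longitudes`` valid cells gets NaN.
    """
    richness = np.asarray(richness, dtype=float)
    n_valid = np.isfinite(richness).sum(axis=1)
    with np.errstate(all="ignore"):
        med = np.nanmedian(
            np.where(np.isfinite(richness), richness, np.nan), axis=1
        )
    med[n_valid < min_longitudes] = np.nan
    return LBGProfile(
        latitudes=np.asarray(latitudes, dtype=float),
        median_richness=med,
        n_longitudes=n_valid,
    )


def lbg_longitude_matrix(
    richness: np.ndarray,
    latitudes: np.ndarray,
    bin_width: float = 0.05,
) -> LBGMatrix:
    """Per-latitude histogram of globally standardized richness.

    Richness is min-max standardized to [0, 1] over all valid cells once;
    each latitude row is then histogrammed into bins of ``bin_width`` and
    expressed as percentages of that row's valid longitudes.  The top bin is
    closed so the global maximum lands inside it.
    """
    richness = np.asarray(richness, dtype=float)
    finite = np.isfinite(richness)
    if not finite.any():
        raise DegenerateInputError("richness map has no valid cells")
    lo, hi = np.nanmin(richness), np.nanmax(richness)
    if hi <= lo:
        raise DegenerateInputError("constant richness map: standardization undefined")
    std = (richness - lo) / (hi - lo)
    nbins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, nbins + 1)
    nlat = richness.shape[0]
    pct = np.full((nlat, nbins), np.nan)
    for i in range(nlat):
        row = std[i][finite[i]]
        if row.size == 0:
            continue
        counts, _ = np.histogram(row, bins=edges)  # top bin closed by numpy
        pct[i] = 100.0 * counts / row.size
    return LBGMatrix(
        latitudes=np.asarray(latitudes, dtype=float), bin_edges=edges, percentage=pct
    )


def min_significant_n(r: float, alpha: float = 0.05, n_max: int = 10_000_000) -> int | None:
    """Smallest n >= 3 at which |r| is significant in a two-sided t test.

    Solves for the first n with |r| * sqrt((n-2)/(1-r^2)) exceeding the
    two-sided critical t value at n-2 degrees of freedom; None if |r| never
    reaches significance below ``n_max``.
    """
    r = abs(float(r))
    if r >= 1.0:
        return 3
    if r == 0.0:
        return None

    def significant(n: int) -> bool:
        df = n - 2
        t = r * np.sqrt(df / (1.0 - r * r))
        return t > stats.t.ppf(1.0 - alpha / 2.0, df)

    # t - t_crit is increasing in n, so the significant region is upward
    # closed: double to bracket it, then bisect for its first element.
    hi = 3
    while not significant(hi):
        hi *= 2
        if hi > n_max:
            return None
    lo = max(3, hi // 2)
    while lo < hi:
        mid = (lo + hi) // 2
        if significant(mid):
            hi = mid
        else:
            lo = mid + 1
    return int(hi)


def correlate_maps(a: np.ndarray, b: np.ndarray, alpha: float = 0.05) -> CorrelationReport:
    """Pearson correlation between two maps over jointly valid cells,
    with the minimum significant sample size n*."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise InsufficientDataError("maps must have the same shape")
    ok = np.isfinite(a) & np.isfinite(b)
    n = int(ok.sum())
    if n < 3:
        raise InsufficientDataError(f"need >= 3 jointly valid cells, found {n}")
    av, bv = a[ok], b[ok]
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        raise DegenerateInputError("zero variance: correlation undefined")
    res = stats.pearsonr(av, bv)
    r = float(res.statistic)
    return CorrelationReport(
        r=r, n=n, n_star=min_significant_n(r, alpha=alpha), p_value=float(res.pvalue)
    )
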
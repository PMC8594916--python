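"""Population-level growth diagnostics.

Two classic whole-population tests of single-cell growth behaviour:

* the *adder regression* — ordinary least squares of division length on
  birth length over all divided cells.  Slope 1 indicates a pure adder
  (cells add a fixed length), slope 0 a pure sizer (cells divide at a fixed
  length); bootstrap over cells gives the confidence interval.
* the *exponential-growth consistency test* — for exponential growth at
  rate alpha, ln(ld/lb) = alpha*T for every cell, so the per-generation-time
  bin means of ln(ld/lb) must lie on a line through the origin with slope
  alpha.  Systematic curvature of the bin means exposes non-exponential
  growth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lineage import LineageTable

__all__ = ["AdderFit", "ExpTestResult", "adder_regression", "exp_growth_test",
           "InsufficientDataError"]


class InsufficientDataError(ValueError):
    """Raised when a test has too few divided cells to be meaningful."""


@dataclass
class AdderFit:
    slope: float
    intercept: float          # µm
    ci_slope: tuple           # (2.5, 97.5) bootstrap percentiles
    n_cells: int
    n_boot: int = 0


@dataclass
class ExpTestResult:
    bin_T: np.ndarray         # mean generation time per bin (min)
    bin_mean: np.ndarray      # per-bin mean of ln(ld/lb)
    bin_sem: np.ndarray
    bin_n: np.ndarray
    alpha_hat: float          # origin-constrained slope (1/min)


def adder_regression(table: LineageTable, n_boot: int = 1000,
                     seed: int | None = None) -> AdderFit:
    """OLS of division length on birth length, with a bootstrap-over-cells
    percentile confidence interval for the slope."""
    div = table.divided_cells()
    if len(div) < 3:
        raise InsufficientDataError(
            f"adder regression needs >= 3 divided cells, got {len(div)}")
    lb = np.array([c.lb for c in div])
    ld = np.array([c.ld for c in div])
    slope, intercept = np.polyfit(lb, ld, 1)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    n = len(div)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if np.ptp(lb[idx]) == 0:
            boots[b] = np.nan
            continue
        boots[b] = np.polyfit(lb[idx], ld[idx], 1)[0]
    lo, hi = np.nanpercentile(boots, [2.5, 97.5]) if n_boot else (slope, slope)
    return AdderFit(slope=float(slope), intercept=float(intercept),
                    ci_slope=(float(lo), float(hi)), n_cells=n,
                    n_boot=n_boot)


def exp_growth_test(table: LineageTable, min_bin: int = 3) -> ExpTestResult:
    """Bin cells by generation time (one bin per frame count) and fit the
    bin means of ln(ld/lb) against T through the origin.

    Bins with fewer than ``min_bin`` cells are dropped, mirroring the usual
    at-least-three-points SEM rule.
    """
    div = [c for c in table.divided_cells() if c.T and c.T > 0]
    if not div:
        raise InsufficientDataError("no divided cells with generation times")
    dt = table.sampling_interval
    frames = np.array([int(round(c.T / dt)) for c in div])
    y = np.array([np.log(c.ld / c.lb) for c in div])
    T = np.array([c.T for c in div])

    bin_T, bin_mean, bin_sem, bin_n = [], [], [], []
    for k in np.unique(frames):
        sel = frames == k
        n = int(sel.sum())
        if n < min_bin:
            continue
        bin_T.append(T[sel].mean())
        bin_mean.append(y[sel].mean())
        bin_sem.append(y[sel].std(ddof=1) / np.sqrt(n))
        bin_n.append(n)
    if not bin_T:
        raise InsufficientDataError(
            f"no generation-time bin holds >= {min_bin} cells")
    bin_T = np.array(bin_T)
    bin_mean = np.array(bin_mean)
    alpha_hat = float(np.dot(bin_T, bin_mean) / np.dot(bin_T, bin_T))
    return ExpTestResult(bin_T=bin_T, bin_mean=bin_mean,
                         bin_sem=np.array(bin_sem),
                         bin_n=np.array(bin_n), alpha_hat=alpha_hat)
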
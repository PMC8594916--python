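"""Conditional-average ("wavefront") growth inference.

The central method of the package.  Individual single-cell length
trajectories are too noisy to classify a growth law, but the *average*
dependence of length on birth length can be extracted robustly: at every
discrete time t since birth, cell length L is regressed linearly against
birth length lb over all cells that have not yet divided.  Connecting the
fitted values across t for a fixed lb reconstructs the average elongation
trajectory L(t, lb) of cells born at that length — without ever fitting a
single noisy trajectory.  Both pure laws are exactly linear in lb
(L = lb + a*t for linear growth, L = lb*e^{alpha*t} for exponential
growth), which motivates the per-time linear fit.

Stages
------
1. per-time linear (or low-order polynomial) fits of L against lb
   (:func:`fit_wavefronts`);
2. removal of the regression-dilution bias introduced by measurement noise
   in the conditioning variable lb (:func:`correct_birth_bias`);
3. truncation at the first division event, where conditioning on survivors
   starts to bias the average (:func:`division_cutoff`);
4. assembly of the trajectory family on a birth-length grid
   (:func:`build_trajectories`);
5. smoothing and numerical differentiation into elongation-rate curves
   (:func:`elongation_rate_curves`);
6. bootstrap over cells for 2-sigma uncertainty bands
   (:func:`bootstrap_bands`).

A mirrored construction conditions on *division* length and time until
division (:func:`reverse_time_family`), valid until the shortest
generation time is exceeded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .lineage import LineageTable

__all__ = [
    "WavefrontFit",
    "TrajectoryFamily",
    "RateFamily",
    "InferenceResult",
    "DegenerateCorrectionError",
    "fit_wavefronts",
    "division_cutoff",
    "build_trajectories",
    "correct_birth_bias",
    "elongation_rate_curves",
    "bootstrap_bands",
    "reverse_time_family",
    "infer_rates",
    "default_lb_grid",
]

#: default conditioning grid: birth lengths 1.9 to 2.9 µm in 0.1 µm steps
def default_lb_grid() -> np.ndarray:
    return np.round(np.arange(1.9, 2.9 + 1e-9, 0.1), 10)


class DegenerateCorrectionError(ValueError):
    """Estimated measurement-noise variance exceeds the observed birth-length
    variance; the bias correction would be meaningless."""


@dataclass
class WavefrontFit:
    """Per-time polynomial fit of length against birth length."""

    t: float
    slope: float             # linear coefficient (dimensionless)
    intercept: float         # µm
    n: int                   # cells alive at t
    residual_sd: float       # µm
    order: int = 1
    coeffs: np.ndarray | None = None   # highest degree first (np.polyfit)
    lb_range: tuple = (np.nan, np.nan)

    def __post_init__(self) -> None:
        if self.coeffs is None:
            self.coeffs = np.array([self.slope, self.intercept])

    def predict(self, lb):
        return np.polyval(self.coeffs, lb)


@dataclass
class TrajectoryFamily:
    """Average length surface L(t, conditioning length) on a grid."""

    alignment: str                 # 'birth' or 'division'
    cond_grid: np.ndarray          # lb values (or ld for reverse alignment)
    times: np.ndarray              # min (negative offsets for 'division')
    surface: np.ndarray            # (n_t, n_cond) µm
    valid: np.ndarray              # (n_t,) bool, pre-cutoff mask
    divided_fraction: np.ndarray | None = None


@dataclass
class RateFamily:
    """Elongation-rate curves dL/dt per conditioning length, with bands."""

    alignment: str
    cond_grid: np.ndarray
    times: np.ndarray
    rates: np.ndarray              # (n_t, n_cond) µm/min, NaN off the mask
    valid: np.ndarray
    lower: np.ndarray | None = None   # point - 2*bootstrap sd
    upper: np.ndarray | None = None
    boot_counts: np.ndarray | None = None
    smoothing: int = 0


@dataclass
class InferenceResult:
    fits: list
    family: TrajectoryFamily
    rates: RateFamily
    t_cut: float
    attenuation: float = 1.0      # birth-bias factor lambda applied


# ---------------------------------------------------------------------------
# matrix representation (internal fast path, shared with the bootstrap)
# ---------------------------------------------------------------------------

def _build_matrix(table: LineageTable):
    """Cell-by-frame length matrix on the common frame grid.

    Returns (times, lb, T, L) where L[i, k] is cell i's recorded length at
    grid time k*dt (NaN where the cell has no frame there, i.e. after its
    division) and T[i] is its generation time (NaN if censored).
    """
    dt = table.sampling_interval
    n_cells = len(table.cells)
    if n_cells == 0:
        raise ValueError("empty lineage table")
    max_k = 0
    for c in table.cells:
        max_k = max(max_k, int(round(c.times[-2 if len(c.times) > 1 else -1]
                                     / dt))
                    if not _on_grid(c.times[-1], dt)
                    else int(round(c.times[-1] / dt)))
    times = np.arange(max_k + 1) * dt
    L = np.full((n_cells, max_k + 1), np.nan)
    lb = np.empty(n_cells)
    T = np.full(n_cells, np.nan)
    for i, c in enumerate(table.cells):
        lb[i] = c.lb
        if c.divided:
            T[i] = c.T
        for t, ln in zip(c.times, c.lengths):
            k = t / dt
            kr = int(round(k))
            if abs(k - kr) < 1e-6 and kr <= max_k:
                L[i, kr] = ln
    return times, lb, T, L


def _on_grid(t: float, dt: float) -> bool:
    return abs(t / dt - round(t / dt)) < 1e-6


def _moving_average(S, window: int):
    """Centered moving average along axis 0 whose half-width shrinks
    symmetrically toward the edges (no asymmetric edge bias; exact for
    linear trends everywhere)."""
    n = S.shape[0]
    if window < 2 or n < 3:
        return S
    k = (window - 1) // 2
    out = np.empty_like(S, dtype=float)
    for i in range(n):
        ki = min(k, i, n - 1 - i)
        out[i] = S[i - ki:i + ki + 1].mean(axis=0)
    return out


def _fit_columns(times, lb, L, order=1):
    """Vectorized per-time fits; returns dict of arrays over the time grid
    (NaN where fewer than 3 cells remain)."""
    n_t = len(times)
    slope = np.full(n_t, np.nan)
    intercept = np.full(n_t, np.nan)
    resid_sd = np.full(n_t, np.nan)
    n = np.zeros(n_t, dtype=int)
    coeffs = [None] * n_t
    lo = np.full(n_t, np.nan)
    hi = np.full(n_t, np.nan)
    for k in range(n_t):
        col = L[:, k]
        m = np.isfinite(col)
        nk = int(m.sum())
        n[k] = nk
        if nk < max(3, order + 2):
            continue
        x, y = lb[m], col[m]
        if np.ptp(x) == 0:
            continue
        c = np.polyfit(x, y, order)
        coeffs[k] = c
        slope[k] = c[-2]
        intercept[k] = c[-1]
        r = y - np.polyval(c, x)
        resid_sd[k] = r.std(ddof=min(order + 1, nk - 1))
        lo[k], hi[k] = x.min(), x.max()
    return dict(slope=slope, intercept=intercept, resid_sd=resid_sd, n=n,
                coeffs=coeffs, lb_lo=lo, lb_hi=hi)


# ---------------------------------------------------------------------------
# public pipeline stages
# ---------------------------------------------------------------------------

def fit_wavefronts(table: LineageTable, order: int = 1) -> list[WavefrontFit]:
    """Per-time least-squares polynomial fits of length against birth length
    over the cells still growing at each time.  Times with fewer than 3
    cells are dropped."""
    times, lb, T, L = _build_matrix(table)
    cols = _fit_columns(times, lb, L, order)
    fits = []
    for k, t in enumerate(times):
        if cols["coeffs"][k] is None:
            continue
        fits.append(WavefrontFit(
            t=float(t), slope=float(cols["slope"][k]),
            intercept=float(cols["intercept"][k]), n=int(cols["n"][k]),
            residual_sd=float(cols["resid_sd"][k]), order=order,
            coeffs=cols["coeffs"][k],
            lb_range=(float(cols["lb_lo"][k]), float(cols["lb_hi"][k])),
        ))
    return fits


def division_cutoff(table: LineageTable):
    """Earliest division event and the cumulative divided fraction.

    Returns ``(t_cut, divided_fraction)`` where ``t_cut`` is the minimum
    generation time over divided cells (average trajectories are biased by
    survivor conditioning beyond it) and ``divided_fraction(t)`` is the
    cumulative fraction of divided cells with T <= t.  With no divisions,
    ``t_cut`` falls back to the last common time and a warning is issued.
    """
    Ts = np.array([c.T for c in table.divided_cells()], dtype=float)
    if Ts.size == 0:
        warnings.warn("no divided cells; cutoff set to last common time")
        t_last = min(c.times[-1] for c in table.cells)
        return float(t_last), (lambda t: np.zeros_like(np.asarray(t, float)))
    t_cut = float(Ts.min())

    def divided_fraction(t):
        t = np.asarray(t, dtype=float)
        out = (Ts[None, ...] <= t[..., None]).mean(axis=-1)
        return float(out) if out.ndim == 0 else out

    return t_cut, divided_fraction


def correct_birth_bias(table: LineageTable, fits: list[WavefrontFit],
                       noise_sd: float | None = None):
    """Remove the regression-dilution bias caused by measurement noise in
    the conditioning birth length.

    Noise in the regressor attenuates every per-time slope by
    lambda = var(true lb) / var(observed lb); the correction divides slopes
    by lambda and shifts intercepts accordingly, after which the family
    satisfies L(0, lb) = lb exactly (the t = 0 fit is the identity by
    definition of the true relation).

    The noise variance is estimated as half the residual variance of the
    first positive-time wavefront — both axes there carry independent copies
    of the measurement noise, while biological scatter accumulated over a
    single frame is negligible — unless ``noise_sd`` is supplied.

    Returns ``(corrected_fits, lambda)``.
    """
    if any(f.order != 1 for f in fits):
        raise ValueError("birth-bias correction is defined for order-1 fits")
    lb = np.array([c.lb for c in table.cells])
    var_lb = lb.var(ddof=1)
    mu = lb.mean()

    if noise_sd is None:
        pos = [f for f in fits if f.t > 0]
        if not pos:
            raise ValueError("need a positive-time fit to estimate noise")
        sigma2 = pos[0].residual_sd ** 2 / 2.0
    else:
        sigma2 = float(noise_sd) ** 2
    lam = 1.0 - sigma2 / var_lb
    if lam <= 0:
        raise DegenerateCorrectionError(
            f"noise variance {sigma2:.4g} exceeds birth-length variance "
            f"{var_lb:.4g}")

    corrected = []
    for f in fits:
        if f.t == 0:
            corrected.append(WavefrontFit(
                t=0.0, slope=1.0, intercept=0.0, n=f.n,
                residual_sd=f.residual_sd, order=1,
                coeffs=np.array([1.0, 0.0]), lb_range=f.lb_range))
            continue
        slope = f.slope / lam
        intercept = f.intercept - f.slope * mu * (1.0 - lam) / lam
        corrected.append(WavefrontFit(
            t=f.t, slope=float(slope), intercept=float(intercept), n=f.n,
            residual_sd=f.residual_sd, order=1,
            coeffs=np.array([slope, intercept]), lb_range=f.lb_range))
    return corrected, float(lam)


def build_trajectories(fits: list[WavefrontFit], lb_grid=None,
                       t_cut: float | None = None,
                       divided_fraction=None) -> TrajectoryFamily:
    """Assemble the average length surface L(t, lb) from per-time fits.

    Grid points outside the observed birth-length range trigger an
    extrapolation warning.  Times beyond ``t_cut`` are kept but masked
    invalid (they are biased by survivor conditioning).
    """
    if not fits:
        raise ValueError("no wavefront fits supplied")
    lb_grid = default_lb_grid() if lb_grid is None else \
        np.asarray(lb_grid, dtype=float)
    times = np.array([f.t for f in fits])
    if np.any(np.diff(times) <= 0):
        raise ValueError("fits must cover a contiguous, increasing time range")
    lo = np.nanmin([f.lb_range[0] for f in fits])
    hi = np.nanmax([f.lb_range[1] for f in fits])
    for g in lb_grid:
        if g < lo - 1e-9 or g > hi + 1e-9:
            warnings.warn(
                f"conditioning length {g:.3g} µm outside observed birth "
                f"lengths [{lo:.3g}, {hi:.3g}] µm; extrapolating")
    surface = np.vstack([f.predict(lb_grid) for f in fits])
    if t_cut is None:
        valid = np.ones(len(times), dtype=bool)
    else:
        valid = times <= t_cut + 1e-9
    frac = None
    if divided_fraction is not None:
        frac = np.asarray(divided_fraction(times), dtype=float)
    return TrajectoryFamily(alignment="birth", cond_grid=lb_grid,
                            times=times, surface=surface, valid=valid,
                            divided_fraction=frac)


def elongation_rate_curves(family: TrajectoryFamily,
                           smoothing_window: int = 5) -> RateFamily:
    """Smooth each average trajectory and differentiate numerically.

    Smoothing is a centered moving average whose half-width shrinks
    symmetrically at the mask edges (so the first and last valid points
    are never biased by asymmetric averaging of a curved trajectory); the
    derivative uses central differences in the interior and second-order
    one-sided differences at the edges.  Computed on the valid mask only.
    """
    tv = family.times[family.valid]
    Sv = family.surface[family.valid]
    n_v = len(tv)
    if smoothing_window > n_v:
        raise ValueError(
            f"smoothing window {smoothing_window} exceeds the {n_v} valid "
            f"time points")
    smoothed = _moving_average(Sv, smoothing_window)
    rates_v = np.gradient(smoothed, tv, axis=0,
                          edge_order=2 if n_v >= 3 else 1)
    rates = np.full_like(family.surface, np.nan)
    rates[family.valid] = rates_v
    return RateFamily(alignment=family.alignment, cond_grid=family.cond_grid,
                      times=family.times, rates=rates, valid=family.valid,
                      smoothing=smoothing_window)


# ---------------------------------------------------------------------------
# end-to-end pipeline and bootstrap
# ---------------------------------------------------------------------------

def _pipeline_matrix(times, lb, T, L, lb_grid, order, smoothing_window,
                     correct_bias, noise_sd):
    """Fits -> bias correction -> surface -> rates, on matrix inputs.

    Returns (rates array over the full time grid, valid mask, lambda) or
    None when the data support fewer than 2 usable time points.
    """
    cols = _fit_columns(times, lb, L, order)
    ok = np.array([c is not None for c in cols["coeffs"]])
    if ok.sum() < 2:
        return None
    t_ok = times[ok]
    slope = cols["slope"][ok]
    intercept = cols["intercept"][ok]

    lam = 1.0
    if correct_bias and order == 1:
        var_lb = lb.var(ddof=1)
        mu = lb.mean()
        if noise_sd is None:
            pos = np.where(t_ok > 0)[0]
            if pos.size == 0:
                return None
            sigma2 = cols["resid_sd"][ok][pos[0]] ** 2 / 2.0
        else:
            sigma2 = float(noise_sd) ** 2
        lam = 1.0 - sigma2 / var_lb
        if lam <= 0:
            raise DegenerateCorrectionError(
                "noise variance exceeds birth-length variance")
        nz = t_ok > 0
        intercept = np.where(nz, intercept - slope * mu * (1 - lam) / lam,
                             0.0)
        slope = np.where(nz, slope / lam, 1.0)

    with np.errstate(invalid="ignore"):
        Tmin = np.nanmin(T) if np.any(np.isfinite(T)) else t_ok[-1]
    valid_ok = t_ok <= Tmin + 1e-9
    if valid_ok.sum() < 2:
        return None

    surface = intercept[:, None] + slope[:, None] * lb_grid[None, :]
    tv = t_ok[valid_ok]
    Sv = surface[valid_ok]
    Sv = _moving_average(Sv, smoothing_window)
    rates_v = np.gradient(Sv, tv, axis=0,
                          edge_order=2 if len(tv) >= 3 else 1)

    rates = np.full((len(times), len(lb_grid)), np.nan)
    idx = np.where(ok)[0][valid_ok]
    rates[idx] = rates_v
    valid = np.zeros(len(times), dtype=bool)
    valid[idx] = True
    return rates, valid, lam


def infer_rates(table: LineageTable, lb_grid=None, order: int = 1,
                smoothing_window: int = 5, noise_sd: float | None = None,
                correct_bias: bool = True) -> InferenceResult:
    """Run the full inference pipeline on a lineage table.

    Convenience wrapper chaining :func:`fit_wavefronts`,
    :func:`correct_birth_bias`, :func:`division_cutoff`,
    :func:`build_trajectories` and :func:`elongation_rate_curves`.
    """
    lb_grid = default_lb_grid() if lb_grid is None else \
        np.asarray(lb_grid, dtype=float)
    fits = fit_wavefronts(table, order=order)
    lam = 1.0
    if correct_bias and order == 1:
        fits, lam = correct_birth_bias(table, fits, noise_sd=noise_sd)
    t_cut, frac = division_cutoff(table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        family = build_trajectories(fits, lb_grid, t_cut,
                                    divided_fraction=frac)
    rates = elongation_rate_curves(family, smoothing_window)
    return InferenceResult(fits=fits, family=family, rates=rates,
                           t_cut=t_cut, attenuation=lam)


def bootstrap_bands(table: LineageTable, lb_grid=None, order: int = 1,
                    smoothing_window: int = 5, n_boot: int = 200,
                    seed: int | None = None, noise_sd: float | None = None,
                    correct_bias: bool = True) -> RateFamily:
    """Bootstrap 2-sigma uncertainty bands for the elongation-rate curves.

    Whole cells are resampled with replacement (preserving within-cell
    correlation) and the complete pipeline is rerun per replicate; bands
    are the point estimate ± 2 bootstrap standard deviations per (t, lb).
    Replicates that lose support at some time (fewer than 3 cells alive)
    contribute no value there; ``boot_counts`` records how many did.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    lb_grid = default_lb_grid() if lb_grid is None else \
        np.asarray(lb_grid, dtype=float)
    point = infer_rates(table, lb_grid, order, smoothing_window,
                        noise_sd=noise_sd, correct_bias=correct_bias)
    times, lb, T, L = _build_matrix(table)
    rng = np.random.default_rng(seed)
    n = len(lb)
    acc = np.full((n_boot, len(times), len(lb_grid)), np.nan)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            out = _pipeline_matrix(times, lb[idx], T[idx], L[idx], lb_grid,
                                   order, smoothing_window, correct_bias,
                                   noise_sd)
        except DegenerateCorrectionError:
            out = None
        if out is not None:
            acc[b] = out[0]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(acc, axis=0, ddof=1)
    counts = np.sum(np.isfinite(acc), axis=0)
    # the point estimate keeps only times with >= 3 cells: align on them
    r = point.rates
    sel = np.isin(np.round(times, 9), np.round(r.times, 9))
    sd = sd[sel]
    counts = counts[sel]
    return RateFamily(alignment=r.alignment, cond_grid=lb_grid,
                      times=r.times, rates=r.rates, valid=r.valid,
                      lower=r.rates - 2 * sd, upper=r.rates + 2 * sd,
                      boot_counts=counts, smoothing=smoothing_window)


# ---------------------------------------------------------------------------
# reverse-time (division-aligned) construction
# ---------------------------------------------------------------------------

def reverse_time_family(table: LineageTable, ld_grid=None) -> TrajectoryFamily:
    """Average length surface L(tau, ld) conditioned on division length,
    with tau = t - td <= 0 the time until division.

    Per negative offset tau, cell lengths (linearly interpolated onto the
    offset) are regressed against division length.  The construction is
    unbiased only while |tau| does not exceed the shortest generation time;
    beyond that the mask is invalid.
    """
    div = table.divided_cells()
    if len(div) < 3:
        raise ValueError("need at least 3 divided cells")
    dt = table.sampling_interval
    Ts = np.array([c.T for c in div])
    t_cut_rev = Ts.min()
    max_k = int(np.floor(Ts.max() / dt))
    taus = -np.arange(max_k + 1)[::-1] * dt   # ascending: most negative .. 0
    ld = np.array([c.ld for c in div])
    if ld_grid is None:
        ld_grid = np.round(np.arange(np.floor(ld.min() * 10) / 10,
                                     ld.max() + 1e-9, 0.1), 10)
    ld_grid = np.asarray(ld_grid, dtype=float)

    n_tau = len(taus)
    surface = np.full((n_tau, len(ld_grid)), np.nan)
    filled = np.zeros(n_tau, dtype=bool)
    for j, tau in enumerate(taus):
        xs, ys = [], []
        for c, Ti, ldi in zip(div, Ts, ld):
            t_q = Ti + tau
            if t_q < -1e-9:
                continue
            ys.append(np.interp(t_q, c.times, c.lengths))
            xs.append(ldi)
        if len(xs) < 3 or np.ptp(xs) == 0:
            continue
        c1, c0 = np.polyfit(xs, ys, 1)
        surface[j] = c0 + c1 * ld_grid
        filled[j] = True

    valid = filled & (np.abs(taus) <= t_cut_rev + 1e-9)
    keep = filled
    return TrajectoryFamily(alignment="division", cond_grid=ld_grid,
                            times=taus[keep], surface=surface[keep],
                            valid=valid[keep])
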
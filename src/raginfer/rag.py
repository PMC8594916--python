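"""Rate-limiting apical growth (RAG) kinetics.

Polarly growing rod-shaped bacteria (Corynebacteria and relatives) insert
new peptidoglycan exclusively at the cell poles.  If polar insertion is the
rate-limiting step for elongation, the elongation rate is set by the number
of active polar transglycosylase (TG) sites N(t) through Michaelis–Menten
kinetics in the Lipid-II precursor concentration C:

    dL/dt = alpha * C * N(t) / (Km + C)

With C constant (or C >> Km) the rate is simply proportional to N(t).  The
new pole is born under-saturated and recruits TG sites either at a constant
rate (first-order relaxation),

    dN/dt = beta * (Nmax - N),

or at a rate that itself grows exponentially because the recruiting polar
scaffold (DivIVA) self-recruits,

    dN/dt = beta * exp(gamma * t) * (Nmax - N).

Both variants give an elongation rate that rises from ``v_sat * s0`` at
birth toward the asymptotic rate ``v_sat``; growth is therefore
*asymptotically linear*.  The model is parameterized by the observable pair
(``v_sat``, ``s0``) so the unidentifiable prefactor alpha*C/(Km+C) never
needs to be resolved.

Closed forms
------------
gamma = 0:  v(t) = v_sat - v_sat*(1 - s0)*exp(-beta*t)
            L(t) = lb + v_sat*t - v_sat*(1 - s0)*(1 - exp(-beta*t))/beta
gamma > 0:  v(t) = v_sat - v_sat*(1 - s0)*exp(-(beta/gamma)*(exp(gamma*t)-1))
            L(t) by adaptive quadrature of v (no elementary antiderivative).

For gamma = 0 the distance to saturation is halved every ln(2)/beta minutes,
which makes the onset time of the linear regime insensitive to the initial
site count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import integrate, optimize

__all__ = [
    "RAGParams",
    "RAGFit",
    "mm_rate",
    "rag_rate",
    "rag_length",
    "fit_rag",
    "saturation_at_birth",
    "fit_scale_factor",
    "rate_vs_length",
]


@dataclass(frozen=True)
class RAGParams:
    """Kinetic parameters of the RAG model.

    v_sat : µm/min
        Asymptotic (linear-regime) elongation rate, proportional to
        alpha*Nmax*C/(Km+C).
    s0 : dimensionless, (0, 1]
        Relative saturation at birth, N(0)/Nmax = v(0)/v_sat.
    beta : 1/min
        TG-site recruitment rate constant.
    gamma : 1/min
        DivIVA self-recruitment rate; 0 selects the constant-recruitment
        variant.
    alpha_mm, Km, C
        Optional microscopic constants of the Michaelis–Menten law; kept for
        bookkeeping, never required by the closed forms.
    """

    v_sat: float
    s0: float
    beta: float
    gamma: float = 0.0
    alpha_mm: float | None = None
    Km: float | None = None
    C: float | None = None

    def __post_init__(self) -> None:
        if not self.v_sat > 0:
            raise ValueError("v_sat must be positive")
        if not 0 < self.s0 <= 1:
            raise ValueError("s0 must lie in (0, 1]")
        if not self.beta > 0:
            raise ValueError("beta must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")

    @property
    def halving_time(self) -> float:
        """Minutes in which the saturation deficit Nmax - N(t) halves
        (gamma = 0 variant)."""
        return math.log(2.0) / self.beta


def mm_rate(C: float, N: float, Km: float, alpha: float) -> float:
    """Michaelis–Menten elongation rate alpha*C*N/(Km + C) (µm/min)."""
    C = np.asarray(C, dtype=float)
    if np.any(C < 0) or np.any(np.asarray(N) < 0) or Km < 0:
        raise ValueError("concentrations and site counts must be >= 0")
    if np.any(Km + C == 0):
        raise ValueError("Km + C must be positive")
    out = alpha * C * np.asarray(N) / (Km + C)
    return float(out) if out.ndim == 0 else out


def rag_rate(t, p: RAGParams):
    """Elongation rate v(t) in µm/min; vectorized over ``t`` (minutes)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    gap = p.v_sat * (1.0 - p.s0)
    if p.gamma == 0.0:
        v = p.v_sat - gap * np.exp(-p.beta * t)
    else:
        v = p.v_sat - gap * np.exp(-(p.beta / p.gamma)
                                   * np.expm1(p.gamma * t))
    return float(v) if v.ndim == 0 else v


def rag_length(t, lb: float, p: RAGParams):
    """Length L(t) in µm for a cell born at length ``lb``.

    Closed form for gamma = 0; adaptive quadrature of :func:`rag_rate`
    (absolute tolerance 1e-9 µm) otherwise.  Vectorized over ``t``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    if p.gamma == 0.0:
        gap = p.v_sat * (1.0 - p.s0)
        L = lb + p.v_sat * t_arr - gap * (-np.expm1(-p.beta * t_arr)) / p.beta
    else:
        def integral(ti: float) -> float:
            val, err = integrate.quad(lambda u: rag_rate(u, p), 0.0, ti,
                                      epsabs=1e-9, epsrel=1e-10, limit=200)
            if not np.isfinite(val):
                raise ArithmeticError("quadrature failed for rag_length")
            return val
        L = lb + np.vectorize(integral)(t_arr)
    return float(L) if np.ndim(t) == 0 else np.asarray(L, dtype=float)


def saturation_at_birth(p: RAGParams) -> float:
    """Relative TG saturation at birth, v(0)/v_sat (= s0)."""
    return float(rag_rate(0.0, p) / p.v_sat)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class RAGFit:
    """Result of fitting the RAG model to a family of elongation-rate curves.

    ``params[i]`` carries the per-curve (v_sat, s0) together with the shared
    kinetics (beta, and gamma for the self-recruitment variant).
    """

    params: list[RAGParams]
    beta: float
    gamma: float
    variant: str
    residual: float          # sum of squared (weighted) residuals
    n_obs: int
    curve_labels: list = field(default_factory=list)

    @property
    def halving_time(self) -> float:
        return math.log(2.0) / self.beta

    @property
    def saturations(self) -> np.ndarray:
        return np.array([p.s0 for p in self.params])


def _unpack_rates(rates):
    """Accept a RateFamily-like object or a (times, rates[, weights]) tuple.

    Returns (times, rate matrix of shape (n_t, n_curves), weights or None,
    labels)."""
    if hasattr(rates, "rates"):
        times = np.asarray(rates.times, dtype=float)
        R = np.asarray(rates.rates, dtype=float)
        valid = getattr(rates, "valid", None)
        if valid is not None:
            times = times[valid]
            R = R[valid]
        w = None
        lo = getattr(rates, "lower", None)
        hi = getattr(rates, "upper", None)
        if lo is not None and hi is not None:
            width = np.asarray(hi, dtype=float) - np.asarray(lo, dtype=float)
            if valid is not None:
                width = width[valid]
            with np.errstate(divide="ignore"):
                w = np.where(width > 0, 1.0 / width, np.nan)
            med = np.nanmedian(w)
            w = np.where(np.isfinite(w), w, med if np.isfinite(med) else 1.0)
        labels = list(getattr(rates, "cond_grid", range(R.shape[1])))
        return times, R, w, labels
    times, R = rates[0], rates[1]
    w = rates[2] if len(rates) > 2 else None
    R = np.asarray(R, dtype=float)
    if R.ndim == 1:
        R = R[:, None]
    return (np.asarray(times, dtype=float), R,
            None if w is None else np.asarray(w, dtype=float),
            list(range(R.shape[1])))


def _model_matrix(times, beta, gamma, v_sat, s0):
    """Rate curves for shared (beta, gamma) and per-curve (v_sat, s0)."""
    if gamma == 0.0:
        decay = np.exp(-beta * times)[:, None]
    else:
        decay = np.exp(-(beta / gamma) * np.expm1(gamma * times))[:, None]
    return v_sat[None, :] * (1.0 - (1.0 - s0)[None, :] * decay)


def fit_rag(rates, variant: str = "constant", seed: int | None = None,
            n_starts: int = 8) -> RAGFit:
    """Fit the RAG model to elongation-rate curves by nonlinear least squares.

    The recruitment kinetics (beta, and gamma for ``variant="diviva"``) are
    shared across curves; the asymptotic rate ``v_sat`` and birth saturation
    ``s0`` are free per curve.  When bootstrap bands are attached to the
    input, residuals are weighted by the inverse band width.  A deterministic
    multi-start over log-spaced beta values guards against local minima.

    Parameters
    ----------
    rates
        A RateFamily, or a tuple ``(times, rate_matrix[, weights])`` with the
        matrix shaped (n_times, n_curves).
    variant
        ``"constant"`` for constant recruitment (gamma pinned to 0), ``"diviva"``
        for DivIVA-driven recruitment (gamma free).
    """
    if variant not in ("constant", "diviva"):
        raise ValueError("variant must be 'constant' or 'diviva'")
    times, R, W, labels = _unpack_rates(rates)
    finite = np.all(np.isfinite(R), axis=1)
    times, R = times[finite], R[finite]
    if W is not None:
        W = W[finite]
    n_t, n_curves = R.shape
    if n_curves < 1 or n_t < 5:
        raise ValueError("need at least one curve with >= 5 valid time points")

    free_gamma = variant == "diviva"

    def residuals(x):
        beta = x[0]
        gamma = x[1] if free_gamma else 0.0
        v_sat = x[1 + free_gamma:1 + free_gamma + n_curves]
        s0 = x[1 + free_gamma + n_curves:]
        res = _model_matrix(times, beta, gamma, v_sat, s0) - R
        if W is not None:
            res = res * W
        return res.ravel()

    v0 = np.maximum(np.nanmax(R, axis=0), 1e-6)
    s0_init = np.clip(R[0] / v0, 0.05, 0.99)
    beta_starts = np.logspace(-3, 0, n_starts)
    gamma_starts = [1e-4, 3e-2] if free_gamma else [0.0]

    lo = [1e-6] + ([0.0] if free_gamma else []) \
        + [1e-8] * n_curves + [1e-6] * n_curves
    hi = [10.0] + ([1.0] if free_gamma else []) \
        + [np.inf] * n_curves + [1.0] * n_curves

    best = None
    for b0 in beta_starts:
        for g0 in gamma_starts:
            x0 = np.concatenate(([b0], [g0] if free_gamma else [],
                                 v0, s0_init))
            try:
                sol = optimize.least_squares(residuals, x0,
                                             bounds=(lo, hi),
                                             xtol=1e-12, ftol=1e-12)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise RuntimeError("RAG fit failed to converge from any start")

    x = best.x
    beta = float(x[0])
    gamma = float(x[1]) if free_gamma else 0.0
    v_sat = x[1 + free_gamma:1 + free_gamma + n_curves]
    s0 = x[1 + free_gamma + n_curves:]
    params = [RAGParams(v_sat=float(v), s0=float(min(s, 1.0)), beta=beta,
                        gamma=gamma)
              for v, s in zip(v_sat, s0)]
    return RAGFit(params=params, beta=beta, gamma=gamma, variant=variant,
                  residual=float(2 * best.cost), n_obs=R.size,
                  curve_labels=labels)


def fit_scale_factor(ratesA, ratesB):
    """Least-squares scalar ``k`` minimizing ||A - k*B|| on the common valid
    grid, plus the root-mean-square shape residual.

    Used to test whether two rate families differ only by a per-site
    efficiency factor (e.g. a transglycosylase knockout).
    """
    tA, A, _, _ = _unpack_rates(ratesA)
    tB, B, _, _ = _unpack_rates(ratesB)
    common, ia, ib = np.intersect1d(np.round(tA, 9), np.round(tB, 9),
                                    return_indices=True)
    if common.size == 0:
        raise ValueError("rate families share no valid grid points")
    a = A[ia].ravel()
    b = B[ib].ravel()
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size == 0:
        raise ValueError("rate families share no valid grid points")
    k = float(np.dot(a, b) / np.dot(b, b))
    residual = float(np.sqrt(np.mean((a - k * b) ** 2)))
    return k, residual


def rate_vs_length(rates, family, window: float = 0.7,
                   lb_weights=None, n_query: int = 60):
    """Average elongation rate as a function of instantaneous cell length.

    Pools (L(t, lb), rate(t, lb)) pairs over the valid mask, optionally
    weighting each conditioning length by its density in the population, and
    applies a moving average over cells within ``window`` µm of each query
    length.

    Returns ``(L_query, mean_rate)`` arrays; query points with an empty
    window yield NaN (gaps in the curve).
    """
    t_r, R, _, _ = _unpack_rates(rates)
    Lsurf = np.asarray(family.surface, dtype=float)
    t_f = np.asarray(family.times, dtype=float)
    valid = np.asarray(family.valid, dtype=bool)
    Lsurf = Lsurf[valid]
    t_f = t_f[valid]
    common, ir, if_ = np.intersect1d(np.round(t_r, 9), np.round(t_f, 9),
                                     return_indices=True)
    R = R[ir]
    Lsurf = Lsurf[if_]
    if R.shape != Lsurf.shape:
        raise ValueError("rates and trajectory family do not share grids")

    n_lb = R.shape[1]
    w_lb = (np.ones(n_lb) if lb_weights is None
            else np.asarray(lb_weights, dtype=float))
    ok = np.isfinite(R) & np.isfinite(Lsurf)
    L_pool = Lsurf[ok]
    r_pool = R[ok]
    w_pool = np.broadcast_to(w_lb, R.shape)[ok]

    Lq = np.linspace(L_pool.min(), L_pool.max(), n_query)
    out = np.full(n_query, np.nan)
    for i, x in enumerate(Lq):
        sel = np.abs(L_pool - x) <= window
        if np.any(sel):
            out[i] = np.average(r_pool[sel], weights=w_pool[sel])
    return Lq, out
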
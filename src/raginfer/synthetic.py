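"""Synthetic microcolony generator.

Produces lineage tables that emulate time-lapse data from a microfluidic
chamber: 3-min frame interval, birth lengths around 1.9–2.9 µm, a wide
spread of generation times, asymmetric septum placement, and additive
Gaussian measurement noise on every recorded length.  Single cells grow by
a configurable law (linear, exponential, or rate-limiting apical growth)
and divide by a configurable size-control rule (adder, sizer, timer, or a
"near adder" with an arbitrary slope of division length on birth length).

True lengths drive the dynamics; measurement noise only corrupts the
recorded values, so ground truth remains available for validating the
inference pipeline.  Division occurs at the exact moment the rule is met:
records therefore contain uniformly spaced frames plus one final partial
frame at the division event.

The generator also produces per-cell 1D fluorescence profiles in which the
integrated polar signal is proportional to the pole's insertion rate — a
stand-in for nascent-peptidoglycan staining used to test the profile
analysis end to end.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .lineage import CellRecord, LineageTable
from .rag import RAGParams, rag_length, rag_rate
from .profiles import IntensityProfile

__all__ = [
    "SimConfig",
    "ProfileParams",
    "growth_length",
    "simulate_colony",
    "apply_measurement_noise",
    "simulate_profiles",
]

GROWTH_MODES = ("linear", "exponential", "rag")
DIVISION_RULES = ("adder", "sizer", "timer", "near_adder")

#: default mode-specific growth parameters: generation times of ~50 min for
#: cells doubling from ~2.3 µm, and a recruitment half-time of ~8 min with
#: 65% birth saturation for the apical-growth mode
_DEFAULT_GROWTH = {
    "linear": {"rate": 0.046},                    # µm/min
    "exponential": {"rate": math.log(2) / 50.0},  # 1/min
    "rag": RAGParams(v_sat=0.05, s0=0.65, beta=math.log(2) / 8.0),
}

_DEFAULT_DIVISION = {
    "adder": {"delta": 2.3, "noise_sd": 0.15},
    "sizer": {"target_length": 4.6, "noise_sd": 0.25},
    "timer": {"target_time": 50.0, "noise_sd": 10.0},
    "near_adder": {"slope": 0.91, "offset": None, "noise_sd": 0.15},
}


@dataclass
class SimConfig:
    """Study conditions for one simulated colony.

    All noise magnitudes are in the units of the quantity they perturb
    (µm or min).  ``asymmetry_*`` parameterize the truncated-Gaussian septum
    position fraction handed to the daughter at the new pole.
    """

    growth_mode: str = "exponential"
    growth_params: dict | RAGParams | None = None
    division_rule: str = "adder"
    division_params: dict | None = None
    asymmetry_mean: float = 0.5
    asymmetry_sd: float = 0.05
    asymmetry_bounds: tuple = (0.2, 0.8)
    growth_rate_cv: float = 0.0         # per-cell rate multiplier CV
    meas_noise_sd: float = 0.05         # µm, additive on recorded lengths
    sampling_interval: float = 3.0      # min
    n_cells: int = 500
    n_generations: int = 12
    n_founders: int = 50
    birth_mean: float = 2.3             # founders: truncated Gaussian (µm)
    birth_sd: float = 0.2
    birth_bounds: tuple = (1.9, 2.9)
    midcell_step: bool = False          # attach a mid-cell step signal
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.growth_mode not in GROWTH_MODES:
            raise ValueError(f"unknown growth mode {self.growth_mode!r}")
        if self.division_rule not in DIVISION_RULES:
            raise ValueError(f"unknown division rule {self.division_rule!r}")
        if self.growth_params is None:
            self.growth_params = _DEFAULT_GROWTH[self.growth_mode]
        dp = dict(_DEFAULT_DIVISION[self.division_rule])
        if self.division_params:
            dp.update(self.division_params)
        if self.division_rule == "near_adder" and dp.get("offset") is None:
            # offset keeping the stationary birth length at birth_mean
            dp["offset"] = 2 * self.birth_mean - dp["slope"] * self.birth_mean
        self.division_params = dp
        if not 0 < self.asymmetry_mean < 1:
            raise ValueError("asymmetry mean must lie in (0, 1)")
        lo, hi = self.asymmetry_bounds
        if not (0.2 <= lo < hi <= 0.8):
            raise ValueError("asymmetry truncation must keep f in [0.2, 0.8]")
        if self.meas_noise_sd < 0 or self.asymmetry_sd < 0:
            raise ValueError("noise sds must be non-negative")


# ---------------------------------------------------------------------------
# growth laws
# ---------------------------------------------------------------------------

def growth_length(mode: str, t, lb: float, params):
    """Noise-free length at time ``t`` (min) for a cell born at ``lb`` µm.

    ``params`` is ``{"rate": a}`` (µm/min) for linear growth,
    ``{"rate": alpha}`` (1/min) for exponential growth, or a
    :class:`~raginfer.rag.RAGParams` for rate-limiting apical growth.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if mode == "linear":
        out = lb + params["rate"] * t
    elif mode == "exponential":
        out = lb * np.exp(params["rate"] * t)
    elif mode == "rag":
        return rag_length(t, lb, params)
    else:
        raise ValueError(f"unknown growth mode {mode!r}")
    return float(out) if out.ndim == 0 else out


def growth_rate(mode: str, t, lb: float, params):
    """Instantaneous elongation rate dL/dt of the generating law (µm/min)."""
    t = np.asarray(t, dtype=float)
    if mode == "linear":
        out = np.broadcast_to(float(params["rate"]), t.shape).copy()
    elif mode == "exponential":
        out = params["rate"] * lb * np.exp(params["rate"] * t)
    elif mode == "rag":
        return rag_rate(t, params)
    else:
        raise ValueError(f"unknown growth mode {mode!r}")
    return float(out) if out.ndim == 0 else out


def _invert_growth(mode: str, lb: float, ld: float, params) -> float:
    """Exact time at which the growth law reaches length ``ld``."""
    if mode == "linear":
        return (ld - lb) / params["rate"]
    if mode == "exponential":
        return math.log(ld / lb) / params["rate"]
    # rag: monotone in t; bracket using the asymptotic and initial rates
    p = params
    hi = (ld - lb) / (p.v_sat * p.s0) + 1.0
    while rag_length(hi, lb, p) < ld:
        hi *= 2.0
    return float(optimize.brentq(lambda t: rag_length(t, lb, p) - ld,
                                 0.0, hi, xtol=1e-10))


# ---------------------------------------------------------------------------
# colony simulation
# ---------------------------------------------------------------------------

def _truncnorm(rng, mean, sd, lo, hi, size=None):
    if sd == 0:
        return np.full(size, mean) if size else mean
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def _division_target(rule: str, lb: float, dp: dict, rng) -> tuple[str, float]:
    """Sample the division target: ('length', ld) or ('time', T)."""
    sd = dp.get("noise_sd", 0.0)
    noise = rng.normal(0.0, sd) if sd > 0 else 0.0
    if rule == "adder":
        return "length", lb + dp["delta"] + noise
    if rule == "sizer":
        return "length", dp["target_length"] + noise
    if rule == "near_adder":
        return "length", dp["slope"] * lb + dp["offset"] + noise
    if rule == "timer":
        return "time", dp["target_time"] + noise
    raise ValueError(rule)


def simulate_colony(config: SimConfig, seed: int | None = None) -> LineageTable:
    """Simulate a growing colony and return its (noise-carrying) lineage table.

    Cells are processed in order of birth time until ``config.n_cells``
    records exist or the generation cap is reached; if the cap truncates a
    still-growing queue, ``metadata["truncated"]`` is set.  Fully
    reproducible for a fixed seed.
    """
    if seed is None:
        seed = config.seed if config.seed is not None else 0
    rng = np.random.default_rng(seed)
    dt = config.sampling_interval
    mode, gp = config.growth_mode, config.growth_params
    dp = config.division_params

    founders_lb = _truncnorm(rng, config.birth_mean, config.birth_sd,
                             *config.birth_bounds, size=config.n_founders)

    counter = 0
    queue: list = []  # (birth_time, counter, cell_id, parent_id, lb, gen)
    for i, lb in enumerate(np.atleast_1d(founders_lb)):
        queue.append((0.0, counter, f"c{i:05d}", None, float(lb), 0))
        counter += 1
    heapq.heapify(queue)

    cells: list[CellRecord] = []
    truncated = False
    while queue:
        if len(cells) >= config.n_cells:
            truncated = True
            break
        birth_time, _, cid, pid, lb, gen = heapq.heappop(queue)

        # per-cell growth-rate variability: scale the law's rate parameter
        gp_cell = gp
        if config.growth_rate_cv > 0:
            m = float(_truncnorm(rng, 1.0, config.growth_rate_cv, 0.3, 2.0))
            if mode == "rag":
                gp_cell = replace(gp, v_sat=gp.v_sat * m)
            else:
                gp_cell = {**gp, "rate": gp["rate"] * m}

        kind, target = _division_target(config.division_rule, lb, dp, rng)
        if kind == "length":
            for _ in range(100):
                if target > lb * 1.001:
                    break
                kind, target = _division_target(config.division_rule, lb,
                                                dp, rng)
            else:
                target = lb * 1.05
            T = _invert_growth(mode, lb, target, gp_cell)
        else:
            T = max(target, dt / 2.0)

        k = int(math.floor(T / dt - 1e-9))
        times = np.arange(k + 1) * dt
        if T > times[-1] + 1e-9:
            times = np.append(times, T)
        lengths = np.asarray(growth_length(mode, times, lb, gp_cell),
                             dtype=float)

        midcell = None
        if config.midcell_step:
            base = rng.normal(10.0, 1.0, size=len(times))
            onset = 0.75 * T
            midcell = base + np.where(times >= onset, 25.0, 0.0)

        cells.append(CellRecord(cell_id=cid, parent_id=pid, times=times,
                                lengths=lengths, birth_time=birth_time,
                                divided=True, midcell_signal=midcell))

        if gen + 1 < config.n_generations:
            ld = float(lengths[-1])
            f = float(_truncnorm(rng, config.asymmetry_mean,
                                 config.asymmetry_sd,
                                 *config.asymmetry_bounds))
            for j, frac in enumerate((f, 1.0 - f)):
                heapq.heappush(queue, (birth_time + T, counter,
                                       f"{cid}.{j}", cid, frac * ld, gen + 1))
                counter += 1

    metadata = {
        "sampling_interval": dt,
        "length_unit": "um",
        "meas_noise_sd": config.meas_noise_sd,
        "growth_mode": mode,
        "growth_params": (asdict(gp) if isinstance(gp, RAGParams)
                          else dict(gp)),
        "division_rule": config.division_rule,
        "division_params": {k: v for k, v in dp.items()},
        "seed": int(seed),
        "truncated": truncated,
        "provenance": "raginfer.synthetic.simulate_colony",
    }
    table = LineageTable(cells=cells, metadata=metadata)
    if config.meas_noise_sd > 0:
        table = apply_measurement_noise(table, config.meas_noise_sd,
                                        rng=rng)
    return table


def apply_measurement_noise(table: LineageTable, sd: float,
                            seed: int | None = None,
                            rng=None) -> LineageTable:
    """Add i.i.d. Gaussian noise (sd in µm) to every recorded length.

    Birth and division lengths are derived fields and therefore reflect the
    noisy series.  ``sd = 0`` returns an identical copy.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    new_cells = []
    for c in table.cells:
        noisy = c.lengths + (rng.normal(0.0, sd, size=c.lengths.shape)
                             if sd > 0 else 0.0)
        new_cells.append(CellRecord(
            cell_id=c.cell_id, parent_id=c.parent_id,
            times=c.times.copy(), lengths=noisy,
            birth_time=c.birth_time, divided=c.divided,
            areas=None if c.areas is None else c.areas.copy(),
            midcell_signal=(None if c.midcell_signal is None
                            else c.midcell_signal.copy()),
        ))
    meta = dict(table.metadata)
    meta["meas_noise_sd"] = float(meta.get("meas_noise_sd", 0.0) or sd)
    return LineageTable(cells=new_cells, metadata=meta)


# ---------------------------------------------------------------------------
# fluorescence profiles
# ---------------------------------------------------------------------------

@dataclass
class ProfileParams:
    """Signal model for synthetic 1D fluorescence profiles.

    The profile of each cell is a uniform cytoplasmic baseline plus one
    Gaussian-shaped insertion peak per pole whose *integrated* intensity is
    ``intensity_per_rate`` times that pole's share of the elongation rate,
    plus optional per-pixel Gaussian noise.  Positions run from the new pole
    (0) to the cell length.
    """

    pixel_size: float = 0.05        # µm
    peak_sd: float = 0.25           # µm, width of the polar insertion zone
    plasma: float = 50.0            # AU, cytoplasmic baseline
    intensity_per_rate: float = 5000.0  # AU·µm per (µm/min)
    new_pole_fraction: float = 0.6  # share of elongation at the new pole
    noise_sd: float = 0.0           # AU per pixel
    septal_peak: float = 0.0        # AU·µm mid-cell peak (dividing cells)


def simulate_profiles(table: LineageTable, params: ProfileParams | None = None,
                      seed: int | None = None):
    """One synthetic fluorescence profile per cell, sampled at a random age.

    Requires the table to carry its generating growth law in metadata (as
    written by :func:`simulate_colony`).  Returns ``(profiles, truth)``
    where ``truth`` is a DataFrame with the sampled age, true length and
    per-pole elongation rates used to build each profile.
    """
    if params is None:
        params = ProfileParams()
    rng = np.random.default_rng(seed)
    mode = table.metadata.get("growth_mode")
    gp = table.metadata.get("growth_params")
    if mode is None or gp is None:
        raise ValueError("table metadata lacks its generating growth law")
    if mode == "rag" and not isinstance(gp, RAGParams):
        gp = RAGParams(**{k: v for k, v in gp.items() if v is not None})

    profiles = []
    truth_rows = []
    for c in table.cells:
        age = float(rng.uniform(0.0, c.times[-1])) if c.times[-1] > 0 else 0.0
        L = float(growth_length(mode, age, c.lb, gp))
        rate = float(growth_rate(mode, age, c.lb, gp))
        r_new = params.new_pole_fraction * rate
        r_old = (1.0 - params.new_pole_fraction) * rate

        x = np.arange(0.0, L + 1e-12, params.pixel_size)
        intens = np.full_like(x, params.plasma)
        for center, r in ((0.0, r_new), (L, r_old)):
            amp = params.intensity_per_rate * r
            intens = intens + amp * stats.norm.pdf(x, loc=center,
                                                   scale=params.peak_sd)
        if params.septal_peak > 0:
            intens = intens + params.septal_peak * stats.norm.pdf(
                x, loc=L / 2, scale=params.peak_sd)
        if params.noise_sd > 0:
            intens = intens + rng.normal(0.0, params.noise_sd, size=x.shape)

        profiles.append(IntensityProfile(cell_id=c.cell_id, cell_length=L,
                                         positions=x, intensities=intens))
        truth_rows.append({"cell_id": c.cell_id, "age_min": age,
                           "length_um": L, "rate_um_per_min": rate,
                           "rate_new_pole": r_new, "rate_old_pole": r_old})
    return profiles, pd.DataFrame(truth_rows)
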
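# raginfer

Single-cell growth-mode inference and rate-limiting apical growth (RAG)
modelling for polarly growing bacteria.

Most rod-shaped bacteria elongate their side walls and grow exponentially at
the single-cell level.  Corynebacteria (and other Actinobacteria) instead
insert new cell wall **only at the poles**, which permits qualitatively
different growth laws — in particular *asymptotically linear* growth, where
the elongation rate dL/dt rises after birth and saturates to a constant.
Distinguishing such laws from exponential growth in time-lapse microscopy
data is hard: individual length trajectories L(t) are far too noisy.

`raginfer` is for microbiologists and biophysicists who track single cells
through a few generations (e.g. in microfluidic chambers at ~3-min frame
intervals) and want to know *how* their cells grow, not just how fast.

## What it does

**Wavefront inference.**  Instead of fitting single trajectories, the length
L of every cell alive at time-since-birth *t* is regressed linearly against
its birth length l_b, separately for every discrete *t*:

    L(t, l_b) = a_t + b_t · l_b

Connecting the fits across *t* at fixed l_b reconstructs the *average*
elongation trajectory of cells born at that length.  Both canonical laws are
linear in l_b (linear growth: L = l_b + αt, slope 1; exponential growth:
L = l_b·e^{αt}, intercept 0), so the per-time slopes and intercepts are
themselves diagnostic.  The pipeline corrects the regression-dilution bias
from measurement noise in l_b, truncates at the first division event (beyond
which survivor conditioning biases the average), smooths, differentiates to
elongation-rate curves, and bootstraps whole cells for 2σ bands.  A mirrored
construction conditions on division length and time until division.

**RAG kinetics.**  Elongation is modelled as rate-limited by polar
transglycosylase (TG) sites N(t) engaging the Lipid-II precursor (at
concentration C) with Michaelis–Menten kinetics,

    dL/dt = α · C·N(t) / (K_m + C),      dN/dt = β (N_max − N(t)),

optionally with DivIVA-driven self-recruitment, dN/dt = β e^{γt}(N_max − N).
With C constant or C ≫ K_m the observable parameters are the asymptotic rate
v_sat and the relative saturation at birth s₀ = v(0)/v_sat; the deficit
N_max − N halves every ln(2)/β minutes.  `fit_rag` shares (β, γ) across
birth-length curves and frees (v_sat, s₀) per curve.

**Population consequences.**  Generation-synchronous simulations contrast
birth-length distributions under exponential vs asymptotically linear growth
with identical division timing/placement noise (ld = l_b·e^{α(t_t+Δt)} + Δl
vs ld = L_RAG(t_t+Δt; l_b) + Δl).

**Profile analysis.**  1D fluorescence profiles of nascent-peptidoglycan
stains: mid-cell-minimum background correction, polar intensities (default
pole width 0.77 µm), moving averages over cell length, demographs, and
septum-onset detection from a mid-cell DivIVA signal.

**Synthetic data.**  A seeded colony generator (growth law × division rule ×
asymmetric septum × measurement noise) provides ground truth for every stage;
nothing here requires experimental downloads.

## Worked example

```python
import numpy as np
from raginfer import (SimConfig, simulate_colony, adder_regression,
                      infer_rates, fit_rag)

cfg = SimConfig(growth_mode="rag", n_cells=500, seed=7)   # 0.05 µm noise
table = simulate_colony(cfg, seed=7)

fit = adder_regression(table, n_boot=1000, seed=7)
res = infer_rates(table)                    # wavefronts -> rate curves
ragfit = fit_rag(res.rates, variant="constant")

print(f"adder slope {fit.slope:.3f} "
      f"(95% CI {fit.ci_slope[0]:.3f}..{fit.ci_slope[1]:.3f})")
print(f"t_cut {res.t_cut:.1f} min, attenuation lambda {res.attenuation:.3f}")
print(f"beta {ragfit.beta:.4f}/min -> halving time {ragfit.halving_time:.1f} min")
print(f"median birth saturation {np.median(ragfit.saturations):.2f}")
```

prints

```
adder slope 0.927 (95% CI 0.868..0.988)
t_cut 41.5 min, attenuation lambda 0.956
beta 0.0654/min -> halving time 10.6 min
median birth saturation 0.67
```

The colony divides adder-like (slope ≈ 1 of division on birth length).  Only
the first 41.5 min of each average trajectory are used (the earliest
division); birth lengths are de-attenuated by λ = 0.956 before conditioning.
The fitted kinetics recover the generating saturation s₀ = 0.65 and a
recruitment half-time near the generating 8 min from this 500-cell colony.

The same pipeline is scriptable from the shell:

```
raginfer simulate --config sim.yaml --seed 7 --out lineage.csv
raginfer stats    --in lineage.csv --out stats.json
raginfer infer    --in lineage.csv --lb-grid 1.9:0.1:2.9 --out family.json
raginfer fit-rag  --family family.json --variant constant --out ragfit.json
raginfer popsim   --seed 7 --out popsummary.json
raginfer profiles --in profiles.csv --out profiles.json
```

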
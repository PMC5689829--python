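# sparkfiber

Stochastic multiscale simulation of cardiac Ca²⁺ release and delayed
afterdepolarizations (DADs), from single ryanodine-receptor (RyR) openings
to a 1D fiber of coupled myocytes, with a spatial-filter + resampling
method for estimating the probability of rare, high-amplitude DADs — the
events that can trigger ectopic beats and reentrant arrhythmias.

**Who it is for.** Computational cardiac electrophysiologists studying how
molecular-scale stochasticity (RyR/L-type channel gating) propagates to
tissue-scale arrhythmia risk, and how remodeling (reduced inward-rectifier
current I_K1, reduced gap-junction coupling g_gap) modulates that risk.

## The model and the method

A myocyte is a 3D lattice of Ca²⁺ release sites (full scale 25×20×50),
each with 48 stochastic RyRs and 8 L-type channels. RyRs open at rate

    r_o = φ(ca_JSR) · k⁺ · ca_SS^η ,   φ = 0.8025 + (ca_JSR / 1.5 mM)⁴

(k⁺ = 1.107×10⁻⁴ ms⁻¹µM⁻η, η = 2.1, mean open time 2 ms). Local release
diffuses through submembrane (SM) compartments to neighbouring sites —
Ca²⁺-induced Ca²⁺ release lets sparks become propagating waves above a
threshold SR load. The Na/Ca exchanger (half of it sensing the SM) turns
spontaneous release into a depolarizing current: a DAD. Cells couple into
a fiber via gap junctions, I_gap = g_gap (V_i − V_{i+1}), solved by
Crank–Nicolson with 50 µs steps.

The rare-event method estimates the upper tail of V_peak (the largest
per-cell diastolic V_max along a fiber) without millions of biophysical
simulations:

1. filter the whole-cell release flux J_RyR(x, t) with a uniform spatial
   window of odd width W:  J^f(x,t) = (1/W) Σ_k J(x+k, t);
2. take per-cell maxima J^f_max(x) = max_t J^f(x,t);
3. choose W to maximize r²(V_max, J^f_max) and predict
   V^f_max = μ_V + (σ_V/σ_J)(J^f_max − μ_J);
4. shuffle interior cell positions of J_RyR (release is independent across
   cells) to generate arbitrarily many surrogate fibers, and read the
   exceedance probabilities P(V_peak − μ_V > θ) off the resampled ensemble.

The summary S_V = (σ_V/σ_J)/W scales with the SD of the predicted V_max:
less I_K1 (larger σ_V) and less coupling (smaller W) both fatten the tail.

## Worked example

```python
import numpy as np
from sparkfiber import (SyntheticProfileParams, generate_profiles,
                        analytic_vmax_surrogate, fit_filter_model,
                        estimate_tail, s_v, expected_waiting_time)

# a 120-cell fiber of independent release profiles (24 quiescent buffer
# cells per end), plus ground-truth V_max affine in the W=7 filtered flux
flux = generate_profiles(SyntheticProfileParams(n_cells=120, seed=1))
v_max = analytic_vmax_surrogate(flux, true_w=7, gain=40.0, offset=-77.0,
                                noise_sd=0.05, rng=np.random.default_rng(1))
model = fit_filter_model(flux, np.nan_to_num(v_max, nan=-77.0))
print(f"W={model.w}  r2={model.r2:.3f}  sigma_V={model.sigma_v:.2f} mV  "
      f"S_V={s_v(model):.2f}")

tail = estimate_tail(flux, model, n_realizations=10_000,
                     thresholds=[8.0, 10.0, 12.0], seed=2)
for th, p in zip(tail.thresholds, tail.probabilities):
    print(f"P(V_peak - mu_V > {th:.0f} mV) = {p:.4f}")
print(f"waiting time at p=1e-6, 1 Hz: "
      f"{expected_waiting_time(1e-6, 1.0):.1f} days")
```

Output:

```
W=7  r2=1.000  sigma_V=3.95 mV  S_V=5.72
P(V_peak - mu_V > 8 mV) = 0.6804
P(V_peak - mu_V > 10 mV) = 0.3802
P(V_peak - mu_V > 12 mV) = 0.1558
waiting time at p=1e-6, 1 Hz: 11.6 days
```

The fit recovers the construction's window width with unit r² (the
surrogate is affine in the W = 7 filtered flux by design); the tail
probabilities of the fiber-wide peak fall steeply with threshold; a
once-per-10⁶-beats event at 1 Hz is expected roughly every 11.6 days.

Biophysical simulations run through the same API (`run_cell`, `run_fiber`,
`ecc_gain_protocol`, `leak_load_protocol`, `dad_ensemble`,
`calibrate_ggap`) or the CLI:

```
sparkfiber simulate-fiber --seed 1 --n-cells 60 --out fiber.h5
sparkfiber fit-filter --flux fiber.h5 --vmax fiber.h5 --out model.json
sparkfiber estimate-tail --model model.json --pool fiber.h5 \
    --n 1e5 --thresholds 0:8:0.25 --seed 2 --out tail.csv
```

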
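# dsbkinetics

Quantitative live-cell kinetics of DNA-repair proteins at damage sites:
FRAP and FCS model fitting, laser micro-irradiation image quantification,
and a Brownian-dynamics binding simulator that provides ground truth for
every analysis stage.

## The problem

When a focused laser inflicts DNA damage in a living nucleus, tagged repair
factors (the motivating system is GFP-Ku70, the DNA-end-binding subunit of
the non-homologous end-joining machinery) accumulate at the lesion within
seconds. Three live-cell assays quantify how they exchange there:

- **FRAP** — bleach a 1–4 µm² spot inside the damaged region and watch the
  fluorescence return. The reaction-limited recovery

  `frap(t) = 1 − (k′_on/(k′_on + k_off))·exp(−k_off·t)`

  yields the pseudo-first-order association rate `k′_on = k_on·[BS]`
  (intrinsic on-rate × local break-site concentration) and the dissociation
  rate `k_off` (inverse bound residence time). A diffusion-limited
  alternative, `frap(t) = e^(−τ_D/2t)·[I₀(τ_D/2t) + I₁(τ_D/2t)]`, covers the
  unbound regime.
- **FCS** — autocorrelate a 30 s photon-count trace from a confocal spot;
  fit `G(t) = (1/2^{3/2}N)·(1+t/τ)⁻¹·(1+t/(ω²τ))^{−1/2}` (structural
  parameter ω fixed at 6) or its two-population mixture to resolve a fast,
  freely diffusing pool from a slow, chromatin-engaged one.
- **Imaging** — segment the damaged region from a photoactivated histone
  marker, score accumulation `A_d = (I_d−I_bg)/(I_n−I_bg)` normalized to
  pre-damage, laser-track enrichment, photoactivated-line thickness
  (chromatin relaxation), and tethering-spot (lacO) enrichment.

Since no raw microscopy accompanies the motivating study, the
`simulate` module generates all of these measurements from a particle-level
model with first-order binding (`Free + BS ⇌ Bound`) at known rates, so
every estimator in the package is tested against ground truth. See
`docs/methods.md` for the full model description and statistical choices.

## Worked example

```python
from dsbkinetics import simulate, frap

cfg = simulate.frap_study_config(seed=1, bleach_area=1.0)   # k'_on=0.3/s, k_off=0.1/s
record, truth = simulate.simulate_frap_record(cfg)
curve = frap.normalize_frap(record)
fit = frap.fit_frap(curve, "reaction")                      # window starts 3 s post bleach
print(f"k'_on = {fit.params.k_on_prime:.3f}/s  (truth {truth.k_on_prime})")
print(f"k_off = {fit.params.k_off:.3f}/s  (truth {truth.k_off})")
print(f"half-recovery = {frap.half_recovery_time(curve):.1f} s")
```

Output:

```
k'_on = 0.099/s  (truth 0.3)
k_off = 0.077/s  (truth 0.1)
half-recovery = 2.8 s
```

(The half-recovery time sits well below `ln2/k_off ≈ 6.9 s` because the
measured curve also contains the fast diffusive refill of the unbound pool;
the 3 s fit window excludes that phase from the kinetic fit.)

A single simulated cell is noisy — bound-molecule occupancy fluctuates with
a correlation time of `1/k_off`, so per-record `k_off` estimates scatter by
20–30% (as they do in real single-cell FRAP) and shallow recoveries leave
`k'_on` weakly identified. Pooling replicates, as the experiments this
mirrors do across ~15 cells, stabilizes the estimate:

```python
import numpy as np
curves = []
for seed in range(12):
    cfg = simulate.frap_study_config(seed=20 + seed, bleach_area=4.0, n_particles=8000)
    rec, truth = simulate.simulate_frap_record(cfg)
    curves.append(frap.normalize_frap(rec).value)
mean_curve = frap.NormalizedFrapCurve(frap.normalize_frap(rec).time_post_bleach,
                                      np.mean(curves, axis=0))
print(f"pooled k_off = {frap.fit_frap(mean_curve, 'reaction').params.k_off:.3f}/s")
```

```
pooled k_off = 0.108/s
```

The same pattern runs from the shell:

```sh
dsbkinetics simulate-frap --seed 1 --bleach-area 1.0 --out run/
dsbkinetics fit-frap run/frap_record.csv --model reaction --out run/
dsbkinetics report run/manifest.json run/frap_fit.json --out run/
```

Other subcommands: `simulate-fcs`, `fit-fcs`, `simulate-track`,
`quantify-track`, `quantify-relaxation`.

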
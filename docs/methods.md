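# Methods

## Scope and model

`dsbkinetics` quantifies the exchange kinetics of fluorescently tagged
DNA-repair proteins (the motivating system is GFP-Ku70 and its regulator at
laser-induced DNA damage) from three complementary live-cell measurements:

1. **FRAP at damage sites.** A small region inside a micro-irradiated area
   is photobleached and the fluorescence return is recorded. Two limiting
   closed-form models are fitted:
   - *diffusion-limited*: `frap(t) = exp(-x)(I0(x) + I1(x))` with
     `x = tau_D / (2 t)`, `I0, I1` modified Bessel functions of the first
     kind and `tau_D` the characteristic diffusion time across the bleached
     area. The argument convention is exactly this one; `tau_D` is defined
     operationally by the formula and is not rescaled to other Soumpasis
     parameterizations in the literature.
   - *reaction-limited*: first-order exchange `Free + BS <-> Bound` with
     pseudo-first-order association rate `k'_on = k_on [BS]` gives
     `frap(t) = 1 - (k'_on / (k'_on + k_off)) exp(-k_off t)`. The model has
     no free amplitude: the implied bleach depth is the equilibrium bound
     fraction. The default fit window starts 3 s after the bleach, which
     suppresses the fast diffusive component and isolates the bound pool.
2. **FCS.** 30-s photon-count traces from a confocal spot are
   autocorrelated and fitted with one- or two-population models whose
   zero-lag amplitude is `1/(2^{3/2} N)` and whose structural parameter
   `omega` is fixed at 6 (never fitted). The amplitude prefactor is
   implemented exactly as written even though it differs from the common
   3D-Gaussian convention; `N` is therefore defined by the model.
3. **Imaging.** Damage-site accumulation
   `A_d = (I_d - I_bg) / (I_n - I_bg)`, normalized to its pre-damage mean;
   laser-track relative enrichment
   `(I_damage - I_bg)/(I_nucleoplasm - I_bg) - 1`; photoactivated-line
   thickness (Gaussian FWHM) as a chromatin-relaxation readout; and
   tethering-spot (lacO-array) enrichment.

## Synthetic ground truth

No imaging data accompany the motivating study, so every analysis stage is
validated against a Brownian-dynamics simulator with known parameters.

*Geometry and dynamics.* Particles diffuse in the 2D nuclear mid-plane
(reflecting disk, default radius 7 µm — large, flat U2OS-like nuclei).
Inside a damage region (default a 6 × 2 µm stripe, matching the
micro-irradiated area of the FRAP protocol) free particles bind immobile,
unsaturable sites with per-step probability `1 - exp(-k'_on dt)` and release
with `1 - exp(-k_off dt)` (exact for the per-step two-state chain; a plain
`r dt` would bias rates at coarse steps). Update order is fixed: move →
bind/unbind → detect. Default rates `k'_on = 0.3 /s`, `k_off = 0.1 /s` give
an equilibrium bound fraction of 0.75 in the damage region; default
`D = 15 µm²/s` puts FRAP deep in the reaction-dominant regime (diffusional
refill of a 1 µm² spot takes ~20 ms versus a 10 s bound residence time).

*FRAP records.* The bleach instantaneously darkens every fluorophore inside
the ROI (1–4 µm², inside the damage stripe). Traces are region-mean
intensities: the ROI, the unbleached remainder of the damage region (the
damage-site protocol's reference), and an extracellular background; read
noise is Gaussian, and molecular shot noise arises naturally from the finite
particle number. Initial states are drawn from the analytic binding steady
state (free particles uniform in the nucleus, bound particles uniform in
the damage region at density `c_f k'_on / k_off`), so no burn-in is needed.

*FCS traces.* Particles (optionally two species with different D) diffuse
in a periodic box — laterally area-matched to a region around the spot,
axially a few focal depths tall — and the detector weights each molecule by
a 3D Gaussian `exp(-2(x²+y²)/w² - 2z²/(omega w)²)`. The axial dimension is
deliberate: the fitted models contain the axial factor
`(1 + t/(omega² tau))^{-1/2}`, and a purely lateral simulation produces
curves that are measurably *not* of that family — at realistic
signal-to-noise, model selection then correctly (and unhelpfully) rejects
the one-population model even for a single species. With the axial
coordinate the printed model is the exact correlation function of the
simulated process and `omega` acquires its usual geometric meaning
(axial/lateral ratio). The lateral residence time remains `w²/(4D)`.
Binned expected counts (brightness × summed weights + background) are
Poisson sampled.

*Imaging stacks.* Rendered directly (no particles): a uniform nucleus whose
damage region rises to the configured enrichment factor at the damage frame
while the nucleoplasm is depleted to conserve the nuclear total (protein
redistributes rather than being created), a marker channel showing the
activated stripe, Poisson shot noise plus Gaussian read noise. Default
nuclear intensity 400 counts gives pixel SNR ≈ 20.

Everything is reproducible from `(config, seed)`; `GroundTruth` carries the
values fits are scored against.

### What the generator does not emulate

Chromatin-polymer mechanics, PSF optics beyond a Gaussian profile, detector
afterpulsing, triplet blinking, cell movement, and binding-site saturation
or depletion. Passing tests therefore demonstrate correctness of the
estimators under the stated model, not robustness to every artifact of real
microscopy. One consequence observed during development is physical rather
than artifactual: at finite diffusion speed, locally released dark
molecules can rebind near the bleach spot before diluting, so fitted
`k_off` from particle-level FRAP sits a few percent below the configured
rate — exactly the diffusion contamination the reaction-dominant regime
minimizes and the spot-size-invariance check is designed to expose.

## Statistical choices

- **FRAP fitting**: bounded least squares (via lmfit) with deterministic
  multi-start initialization (`k_off` from the half-recovery time, `k'_on`
  from the initial depth, plus a coarse grid); uniform weights by default
  since the detector noise model is unspecified.
- **Single-population adequacy**: Wald–Wolfowitz runs test on residual
  signs (p < 0.01 flags structured residuals) and reduced chi-square > 2
  when a noise scale is supplied; both thresholds configurable. A minimum
  recovery span guards against "adequate" fits to pure noise.
- **Spot-size invariance of `k_off`**: ordinary least-squares slope of
  `k_off` against bleach area with a 95% t-interval; pass when the interval
  covers zero. Five fits per area are used in the packaged checks, matching
  the ~15-cells-per-condition scale of the motivating experiments.
- **Multi-tau correlator**: m = 16 lags per octave, pairwise binning; the
  first 2m lags coincide exactly with the direct O(N²) estimator, which
  serves as the oracle. Per-lag standard errors come from the scatter of
  the correlation over 8 disjoint sub-traces, smoothed by a moving median
  over one octave (the raw scatter of 8 values is itself too noisy to use
  as weights); lags longer than a sub-trace resolves inherit the last
  resolved error scaled linearly with lag.
- **Finite-acquisition bias**: estimating ⟨F⟩ from the same 30-s record
  depresses the measured correlation by ≈ `(2/T)∫(1-s/T)G(s)ds` at every
  lag, which biases slow residence times and fractions low. `fit_fcs`
  optionally (and the pipeline does) subtracts this offset evaluated on the
  model itself — no extra free parameter.
- **Model comparison (1 vs 2 populations)**: corrected AIC difference ≥ 10
  *and* nested-model F-test p < 0.01, a conservative double gate; ties go
  to the simpler model. Two refinements keep the gate calibrated on real
  estimator noise: (i) both statistics are evaluated on every fourth
  weighted residual — neighboring multi-tau lags share data, and feeding
  strongly correlated points to information criteria overstates the
  evidence for spurious slow components (the fits themselves always use
  the full grid); (ii) a second population whose fitted fraction is below
  0.1 is not considered resolved — few-percent "components" almost always
  absorb correlated noise bumps rather than kinetics.
- **Residence-time comparisons across conditions**: Welch two-tailed
  t-tests on the slow residence time.

## Numerical choices

- `exp(-x)(I0(x)+I1(x))` is evaluated with scipy's exponentially scaled
  `i0e`/`i1e` at all arguments — no overflow for any `t > 0`; `t = 0`
  returns the limit 0 exactly.
- Two-population parameters are canonically ordered (`tau1 ≤ tau2`, `f1`
  relabeled) on construction, removing label-switching ambiguity.
- Degenerate inputs raise typed errors naming the offending frame or
  column (degenerate denominators, empty masks, unreachable half-recovery).
- Simulation timesteps must satisfy `dt ≤ 0.1/max(k'_on, k_off)`
  (rate resolution); the constructor enforces it.

## Problem sizes in the packaged checks

The test suite and acceptance script use simulation sizes chosen to keep a
full run on a single CPU comfortable while leaving the statistical
conclusions stable: 6 000–20 000 particles for FRAP records; 700 particles,
30 000 one-millisecond bins, a 0.25 µm waist and D = 4 µm²/s for FCS traces
(the statistical power of two-population detection scales with the number
of slow-pool focal transits per 30 s acquisition, ≈ `T·4D_slow/w²`, so the
waist and diffusion coefficient sit at the fast end of their realistic
ranges); 50-run batches for selection-rate estimates; 10-run batches for
invariance checks. These sizes are stated here as the package's reference
conditions; all of them are plain config parameters.

## Known limitations

- Fitted `k'_on` from single noisy FRAP records is weakly identified when
  recovery is shallow (the model's amplitude and rate trade off); the
  multi-start initializer mitigates but cannot remove this.
- Single-record `k_off` estimates at realistic molecular abundance carry
  20–30% scatter because bound-occupancy fluctuations are correlated over
  `1/k_off`; condition-level conclusions should pool replicates, as the
  packaged checks do.
- The detrending window (default 2 s) trades drift removal against
  distortion of correlations slower than the window; it is configurable
  and should exceed the slowest kinetic time of interest by an order of
  magnitude.
- The imaging renderer draws enrichment as a step (optionally normalized
  against pre-damage frames); it does not model recruitment kinetics, which
  FRAP/FCS cover.
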
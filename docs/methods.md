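# Methods

## The per-cell reporter model

Each cell carries `c` plasmid copies (lognormal across cells, ln-mean 3.0,
ln-sd 0.35, i.e. a ~20-copy plasmid with broad spread). Five species are
tracked in arbitrary units: immature and mature POI–RFP, an aggregated
("dark") POI pool, and immature and mature GFP. All fluxes are first order:

```
poi_immature' = k_syn·c·I(t) − (k_matR + k_deg(t) + k_agg + μ(t))·poi_immature
poi_mature'   = k_matR·poi_immature − (k_deg(t) + k_agg + μ(t))·poi_mature
poi_dark'     = k_agg·(poi_immature + poi_mature) − μ(t)·poi_dark
gfp_immature' = A(t) − (k_matG + μ(t))·gfp_immature
gfp_mature'   = k_matG·gfp_immature − μ(t)·gfp_mature
```

with maturation rates `k_mat = ln2/t50` (t50 = 42 min red, 14 min green, so
half of a pulse is matured after exactly one half-time), induction
`I(t) = leak_fraction` before t = 0 and 1 afterwards, and dilution `μ(t)`
taken from the variant's logistic growth model. Cells are independent;
division is not simulated — dilution enters as a continuous per-capita rate.

**Folding.** The client protein folds in a fast two-state equilibrium, so
the unfolded pool is never a separate state:
`U(t) = f_u · (poi_immature + poi_mature)` with
`f_u = 1/(1 + exp(s·(Tm − T)/(R·T_K)))`, `R = 1.987e-3 kcal mol⁻¹ K⁻¹`.
The chromophore state of the RFP fusion is independent of the folding state
of the client domain, which is why both immature and mature POI contribute
to `U`. The slope `s` (default 0.10 kcal mol⁻¹ °C⁻¹) is an *effective
in-vivo* stability slope: it is deliberately shallow so that the unfolded
fraction is graded across the whole panel (f_u ≈ 0.98 at Tm = 8 °C down to
≈ 0.003 at 61 °C at 37 °C growth) rather than saturated at both ends —
crowding, the fusion partner and non-specific interactions compress
in-vitro stability differences in the cell.

**Promoter activity.**

```
A(t) = basal·c + α·k_syn·c·I(t) + β·ramp(t; τ_stress)·U(t)
```

The three terms are: constitutive (σ32-independent) promoter activity,
coupling to instantaneous translation (co-translational chaperone
engagement of nascent chains), and coupling to the equilibrium
misfolded pool. The stability arm switches on first order
(`ramp = 1 − e^(−t/τ)`, τ_stress = 120 min): the pre-existing DnaK pool
buffers the first wave of misfolded protein, and only as client
accumulates is σ32 released in proportion to `U`. Likewise the
stability-dependent degradation `k_deg(t) = k_deg_basal +
k_deg_unfolded·f_u·ramp(t; τ_pqc)` (τ_pqc = 120 min) builds up as the
protease arm of the response is induced — degradation is minimal right
after induction and dominant later. These two activation ramps are what
produce the model's signature behaviour: early rates report translation,
late rates and accumulated abundance report stability. With both τ set to
0 the system has constant coefficients and an exact matrix-exponential
solution, which the test suite uses as an independent oracle (agreement to
1e-6 relative).

**Aggregation** is a single variant-independent first-order loss
(k_agg = 0.004 min⁻¹) to a tracked but never-fluorescing dark pool.
**GFP is not degraded**, only diluted. An optional **toxicity switch**
(off by default) permanently shuts off synthesis once a cell's total POI
exceeds a threshold; because the threshold is crossed at a
copy-number-dependent time, it produces the late low-abundance
subpopulations used to exercise the mixture-model reporting.

## The measurement layer

At every schedule time (0, 2, then every 5 min to 30, every 10 min to 120,
every 30 min to 240 — 21 timepoints) a fresh set of ~3000 cells is drawn,
as a cytometer samples from a large culture. Channels are
`red = gain·c·poi_mature + background` (green analogous), each multiplied
by unit-mean lognormal noise (CV 0.25); backgrounds (300/600 a.u.) keep
all channels positive so log transforms are always defined. Forward and
side scatter are stationary lognormals carried only for gating. Replicates
differ through day-to-day induction strength (lognormal CV 0.15 on k_syn)
and growth-rate jitter (CV 0.05); variants additionally differ in
translation rate (lognormal CV 0.4 on k_syn, Tm-independent) — point
mutations change expression level, and without genuine translation spread
the early-rate correlations of the study could not arise. Growth is
logistic with N0 = 0.5 (induction at mid-exponential), K = 1.5, and r
interpolated in Tm over a narrow band (0.018–0.020 min⁻¹): more stable
variants burden the cell less, but the band is kept narrow because the
dilution impact on fluorescence rates is small in this regime.

With toxicity off the ODE system is linear in `c`, so one unit-copy
trajectory per variant/replicate is integrated (LSODA, rtol 1e-9) and
scaled per cell; with toxicity on, a fixed cohort is integrated per cell.
All randomness derives from one master seed through `SeedSequence` spawn
keys per variant and replicate, so any panel subset reproduces exactly and
two identical runs are byte-identical.

### What the generator does not emulate

Cell division and lineage correlations; spectral spillover between
channels; mechanistic forward/side-scatter morphology; explicit σ32/FtsH
dynamics or promoter saturation at high unfolded load; death phase (the
late OD drop of stable variants); inclusion-body biology beyond the
uniform dark-state loss. Passing tests therefore demonstrate that the
statistical chain recovers the kinetic structure the model encodes — not
that real cytometry data are this well behaved (real data add spillover,
autofluorescence structure, debris and doublet populations that the
rectangular percentile gate only crudely removes).

## The statistical chain

* **Gating**: rectangular FSC/SSC gate; default bounds at the pooled
  1st–99th percentiles (no numeric gate is standard; this is permissive
  and idempotent).
* **Summaries**: arithmetic per-event means per sample. The GFP/RFP ratio
  defaults to the mean of per-event ratios — both reporters sit on the
  same plasmid, so per-event ratios cancel copy number; ratio-of-means is
  a config switch.
* **Rates**: OLS slope of a summary series inside a closed time window,
  divided by the in-window mean ("relative rate", min⁻¹). Closed windows
  mean a boundary point belongs to both adjacent windows (the 30–60 and
  60–90 min windows share the 60-min point). Relative rates are invariant
  to channel gain and, once signal dominates background, to synthesis
  scale — which is why late-window rates isolate stability.
* **Correlations**: Spearman's ρ as the Pearson correlation of mid-ranks
  (ties get average ranks), computed across all variant × replicate points
  (24 by default) at each time or window. Zero rank variance raises an
  error at the single-correlation level and is surfaced as an explicit
  `undefined` status inside tracks. Signed values only; an exact
  permutation p-value is available for n ≤ 10.
* **Mixtures**: variational Bayesian Gaussian mixture in
  (log10 red, log10 green) — raw fluorescence is heavy-tailed, log space
  is where diagonal Gaussians are adequate. Dirichlet weight prior with
  concentration 1e-6 over up to 7 components, independent Normal–Gamma
  priors per dimension (prior mean = data mean, prior precision mean =
  1/data variance, β0 = 1, a0 = 1). Coordinate ascent with k-means++
  seeding, 5 restarts keeping the best ELBO, convergence at a per-point
  ELBO gain below 1e-5, 500 iterations max; the ELBO is exact for this
  conjugate family and nondecreasing by construction (asserted in tests to
  float tolerance). "Effective components" = weight ≥ 0.01; the
  subpopulation report flags surviving components whose mean falls below
  the 5 % quantile of the heaviest component's marginal.
* **Growth**: logistic fits by bounded nonlinear least squares
  (initialised from the early log-slope); uncertainty by seeded residual
  bootstrap (default, 500 resamples) or an emcee ensemble with uniform
  priors over the fitting bounds. The maximum growth rate is the maximum
  *specific* rate r·(1 − N/K) over the observed window, evaluated
  numerically per posterior draw (absolute dN/dt via a switch); posterior
  mean ± sd are reported. Dilution bias over a window is the log-OD
  difference divided by the window length; its spread across variants uses
  the sample (n−1) standard deviation and can be expressed as a
  percentage of a reference relative rate.

## Problem sizes

Defaults reflect the emulated study: 8 variants × 3 replicates × 21
timepoints × 3000 events. The distributional tests run 20 independent
panel realisations at full size; the mixture-recovery tests use n = 2000
two-component datasets; the byte-determinism check runs the full pipeline
twice at 300 events per sample with 50 bootstrap resamples per growth
curve — determinism does not depend on sample size, and this keeps the
suite fast.

## Known limitations

The promoter model is linear in `U`; saturation of chaperone capacity at
high unfolded load is not modelled, so extreme-overload regimes
extrapolate poorly. The activation time constants (120 min) are effective
lumped parameters, not measured induction kinetics. The abundance–Tm rank
correlation at 120 min is strong on average (median ρ ≈ 0.75 across
realisations) but varies between realisations because the between-variant
translation spread is Tm-independent noise on abundance. The dilution
spread across variants is larger early than late under the default growth
band (curves saturate together); diverging growth curves reverse this, as
the tests show with constructed curves.
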
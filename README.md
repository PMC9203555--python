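# dnakflow

Simulation and analysis of dual-reporter chaperone-response flow-cytometry
time series.

## The problem

When *E. coli* overexpresses a recombinant protein, the Hsp70 chaperone DnaK
senses the load of misfolded protein and, through the transcription factor
σ32, upregulates the quality-control network. A two-reporter plasmid makes
this observable in single cells: a red fluorescent protein (slow-maturing,
t50 ≈ 42 min) fused to the protein of interest reports its abundance, and a
green fluorescent protein (fast-maturing, t50 ≈ 14 min) expressed from the
DnaK promoter reports chaperone induction. Sampling a panel of point mutants
with different melting temperatures (Tm) over a 240-minute induction time
course asks a sharp question: is the DnaK response driven by *how much* is
being translated, or by *how unstable* the product is?

`dnakflow` packages both halves of that study:

* **a generative kinetic model** of the experiment — per-cell ODEs for
  immature/mature/aggregated reporter pools with two-state folding
  (fraction unfolded `f_u = 1/(1 + exp(s·(Tm − T)/RT))`), promoter activity
  `A(t) = basal + α·synthesis + β(t)·f_u·POI(t)`, stability-dependent
  degradation, growth dilution `μ(t) = r(1 − N/K)` from logistic growth,
  plasmid copy-number spread and measurement noise — so the entire analysis
  chain is testable without any experimental download;
* **the statistical chain** — scatter gating, per-timepoint channel means
  and GFP/RFP ratios, windowed relative rates (OLS slope / window mean),
  Spearman rank-correlation tracks against variant Tm (mid-rank tie
  handling, implemented from first principles), per-event log-log slope
  fits, a sparsity-pruned variational Bayesian Gaussian mixture
  (Dirichlet weight prior 1e-6, diagonal covariances, coordinate-ascent
  inference with a monotone ELBO) for subpopulation detection, and logistic
  growth fits with bootstrap/MCMC uncertainty plus the dilution bias
  `⟨μ⟩ = [ln N(t₁) − ln N(t₀)]/(t₁ − t₀)` they imply for relative rates.

## Worked example

```python
from dnakflow.pipeline import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(seed=1, out_dir="demo_run",
                                     n_cells=500, growth_n_samples=100))
for key in ("early_green_vs_red_rate_rho", "late_green_rate_vs_tm_rho",
            "ratio_vs_tm_rho_at_120min"):
    print(key, round(report.metrics[key], 3))
```

prints

```
early_green_vs_red_rate_rho 0.948
late_green_rate_vs_tm_rho -0.573
ratio_vs_tm_rho_at_120min -0.899
```

Read: in the first 30 minutes the relative rate of the DnaK reporter tracks
the relative rate of protein production almost perfectly (ρ ≈ 0.95 across
8 variants × 3 replicates) — the early response is set by translation. By
150–180 minutes the green rate correlates negatively with melting
temperature (ρ ≈ −0.57): once protein has accumulated, unstable variants
drive a stronger chaperone response. The copy-number-normalised response
(GFP/RFP at 120 min) separates the panel most cleanly (ρ ≈ −0.9). The
report also carries per-variant maximum specific growth rates and the
effective mixture-component counts over time for the least stable and
wild-type variants.

The same stages are available as a CLI:

```bash
dnakflow run-all --seed 1 --out demo_run
dnakflow generate --variants wt,L57G --out small_run
```

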
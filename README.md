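# extvortex

Analysis pipeline for **extinction-vortex dynamics** in vertebrate
populations that were monitored all the way to local extinction
(extirpation), with a focus on how **adult body size** modulates the
final decline. It is aimed at population ecologists and conservation
modellers working with Living-Planet-Database-style annual abundance
series, a species body-mass table, and a species-level phylogeny.

Small, declining populations can enter a self-reinforcing downward
spiral — the extinction vortex — in which the rate of decline steepens
and year-to-year variability in growth explodes as extinction nears.
The pipeline tests three signatures of that spiral, and whether each is
stronger in smaller-bodied species.

## What the pipeline does

1. **Selection of extirpation series.** From wide-format abundance
   tables, it keeps only series that genuinely document an extirpation:
   terminal zero run of length ≥ 2, no interior zero followed by a
   recovery, ≥ 5 nonzero observations before the extinction year, last
   nonzero observation adjacent to the first zero, span ≥ 10 years from
   first observation to first zero, and no country-wide aggregates.
   Calendar time is re-indexed as *years to extinction* (YTE), counting
   backward from the first zero year.

2. **State-space correction.** Within-series scaled abundance
   (N_t / max N) is modelled on the natural-log scale with the
   exponential-growth state-space (EGSS) model

   ```
   x_t = x_{t-1} + μ + ε_t,   ε_t ~ N(0, σ²)      (process noise)
   y_t = x_t + F_t,           F_t ~ N(0, τ²)      (observation error)
   ```

   fit by maximum likelihood (Kalman prediction-error decomposition,
   multi-start quasi-Newton, missing years propagated without update).
   Fixed-interval (RTS) smoothing yields the corrected abundance path
   P_t and the annual growth rates γ_t = ln P_t − ln P_{t−1}.

3. **Phylogenetic correlation.** The species tree gets Grafen node
   heights (height ∝ number of descendant tips − 1, normalized so the
   root is at 1), making it ultrametric without divergence-time data;
   polytomies are resolved with zero-length inserted edges so the
   resulting unit-diagonal correlation matrix **A** is independent of
   the arbitrary resolution.

4. **Three Bayesian hierarchical analyses.** All share the skeleton

   ```
   η_i = β₀ + β' z_i + b[species_i],   b ~ N(0, σ_phylo² A + σ_species² I)
   ```

   with standardized covariates z, slope priors N(0, 1), intercept
   N(0, 2.5), and Exponential(1) priors on every scale:

   * **Years to extinction** (negative binomial, log link):
     YTE ~ Y_t (or log₁₀ Y_t) × log₁₀ body mass, where Y_t is the
     smoothed corrected abundance; the two abundance transforms are
     compared by PSIS-LOO expected log predictive density (ELPD).
   * **Growth rate** (Gaussian): γ_t ~ YTE × log₁₀ body mass. A
     positive YTE coefficient means growth deteriorates toward
     extinction.
   * **Residual variability** (Gaussian, two stages): raw geometric
     growth rates r = ln(N_t / N_{t−1}) are regressed on YTE; the
     squared conditional residuals are then regressed on
     YTE × log₁₀ body mass. A negative YTE coefficient means growth
     variability inflates toward extinction.

   Fixed effects are classified by the widest credible interval that
   excludes zero: 95% → strong, 90% → moderate, 80% → weak evidence.
   Posteriors are sampled with an adaptive Hamiltonian Monte Carlo
   sampler (analytic gradients, 4 chains, split-R̂ and ESS reported per
   parameter); phylogenetic signal is the posterior of σ_phylo.

5. **Synthetic studies.** A seeded generator produces phylogenies,
   Brownian body masses, and extirpation series from a mechanistic
   vortex model (drift deterioration and variance inflation below a
   small-population threshold, both stronger for small-bodied species),
   with full ground truth recorded — so every stage of the pipeline is
   testable without any data download.

## Worked example

Run the whole pipeline on a generated default-condition study
(35 populations, 32 species):

```bash
extvortex run --config config.yaml --seed 1
```

with `config.yaml`:

```yaml
out_dir: results/demo
simulate: {}                 # generate a default synthetic study
models: {iterations: 1500, warmup: 500, force: true}
```

The run writes per-stage CSVs, a manifest, and a report. For seed 1 the
growth-rate rows of `results/demo/posterior_summaries.csv` read:

```
     parameter  median  ci95_lo  ci95_hi   rhat evidence
     intercept -0.2210  -0.2782  -0.1674 1.0072   strong
           yte  0.0920   0.0528   0.1301 1.0032   strong
    log10_mass -0.0157  -0.0585   0.0272 1.0011     none
yte:log10_mass -0.0147  -0.0504   0.0204 1.0000     none
```

Read: mean annual growth is −0.22 per year overall, and the positive
`yte` coefficient (0.092, strong evidence) says growth was *less*
negative farther from extinction — i.e. decline accelerates as
extinction approaches, the first vortex signature. The model comparison

```
               model     elpd    se  elpd_diff  se_diff
yte_logged_abundance -1637.17 25.38       0.00     0.00
   yte_raw_abundance -1864.13 19.47    -226.96    19.06
```

prefers the log-abundance years-to-extinction model by far more than
the standard error of the difference: time to extinction scales with
the *logarithm* of population size, the nonlinear-collapse signature.

## Layout

| Module | Role |
| --- | --- |
| `extvortex.lpd` | wide-CSV parsing, the seven selection criteria, YTE, scaling |
| `extvortex.egss` | EGSS likelihood, ML fitting, Kalman/RTS smoothing, γ_t |
| `extvortex.phylo` | Newick I/O, polytomy resolution, Grafen lengths, correlation matrix |
| `extvortex.bayes` | the three hierarchical analyses, intervals, evidence classes, R̂ |
| `extvortex.sampler` | HMC backend for the Gaussian and negative-binomial mixed models |
| `extvortex.loo` | pointwise log-likelihoods, PSIS-LOO, ELPD comparison |
| `extvortex.simulate` | vortex study generator + model-structured recovery datasets |
| `extvortex.pipeline` / `extvortex.cli` | orchestration, manifests, reports, `extvortex` CLI |

See `docs/methods.md` for modelling assumptions, parameter defaults,
and known limitations.
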
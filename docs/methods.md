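# Methods

## Model

Cells of two distinguishable types are loaded into N partitions (droplets,
wells, or well combinations). The single modelling assumption is that the
number of cells of type *i* in a partition is Poisson(μᵢ), independently
across partitions and between types. Then, with c the total cell count of a
partition and μ = μ₁ + μ₂:

- Pr(c ≥ 1) = 1 − e^(−μ)
- Pr(c ≥ 2) = 1 − e^(−μ) − μ e^(−μ)
- multiplet frequency M = Pr(c ≥ 2 | c ≥ 1) = 1 − μ e^(−μ) / (1 − e^(−μ))

M depends on the rates only through their sum, is strictly increasing in it,
and M → μ/2 as μ → 0.

The observables are N₁, N₂ (partitions with ≥1 cell of each type, *inclusive*
of mixed partitions) and N₁,₂ (partitions with ≥1 cell of both). Moment
matching gives Nᵢ = N(1 − e^(−μᵢ)), and independence of the two loading
processes gives N₁,₂/N = (N₁/N)(N₂/N), hence

    N = N₁N₂/N₁,₂,    μᵢ = −ln((N − Nᵢ)/N).

This is a method-of-moments inversion: three observables, three parameters,
closed form. N is generally fractional and is deliberately never rounded
before the logarithms — rounding perturbs the rates in the fourth decimal.
The implementation uses `log1p`/`expm1` so small loads lose no precision.

### Degenerate inputs

Two boundary cases are distinct, named errors rather than silent numbers:

- **unidentifiable-total** (N₁,₂ = 0): N = N₁N₂/N₁,₂ is unbounded and M is
  formally unconstrained; returning 0 would hide an underpowered experiment.
  The message points to the doublet approximation's lower bound of 0.
- **inconsistent-counts** (N₁,₂ = N₁ or N₂): the inferred N equals an observed
  per-type count, implying an infinite rate (log of zero). The error names the
  saturated observable.

Counts may be non-negative reals (upstream pipelines sometimes report
estimated, fractional partition counts); a non-integer input is accepted with
a log notice. All other invariant violations are validation errors raised at
construction.

### The equal-mix shortcut

`doublet_approximation` = 2·N₁,₂/(N₁+N₂−N₁,₂) is reported alongside every
estimate. For equal mixes at low loading it agrees with M to within a couple
of percent; at high loading it overestimates M because it ignores multiplets
of more than two cells, and for unequal mixes it is simply the wrong quantity.

### Uncertainty

The closed form is a point estimate. Two extensions are provided:

- `estimator_standard_error`: first-order delta method. Per partition, the
  indicator triple (≥1 type 1, ≥1 type 2, both) has an exact covariance under
  the model; the gradient of the estimator map at the expected counts is taken
  by central differences (step 10⁻⁶ relative). This is the sampling standard
  error of one experiment of N partitions and is what the recovery tests use
  as the Monte-Carlo tolerance.
- `bootstrap_interval`: parametric bootstrap — replicate triples are drawn
  from the fitted load and re-estimated; the equal-tailed percentile interval
  is returned. Parametric rather than nonparametric because only the three
  summary counts exist, not per-partition data. Replicates landing on a
  degenerate triple are redrawn (cap 1,000 across the run, then an error);
  the redraw count is reported. Default 1,000 replicates, 95% level.
  Replicate draws use a four-category multinomial over partition classes
  (empty / type-1-only / type-2-only / mixed), which has exactly the law
  induced by per-partition Poisson loading.

## Simulator

`simulate` draws per-partition cell counts, tallies (N₁, N₂, N₁,₂) under the
inclusive convention by construction, computes the *realized* multiplet
frequency (the fraction of non-empty partitions with ≥2 cells — well defined
whatever the loading law), and re-estimates M from the tallied counts. One
seed determines everything; recovery grids spawn per-replicate child streams
from a root `SeedSequence`, so tables are reproducible regardless of
execution order.

Three loading laws:

- `poisson` — the model's own assumption; used for recovery validation.
- `overdispersed` — a gamma factor with mean 1 and variance `clump_param`
  scales both types' rates in each partition (means preserved). This emulates
  clumping or capture variability that is equally likely across cell types;
  it inflates cross-type co-occurrence, so the inferred N is too small, the
  inferred rates too large, and the estimator biased **upward** relative to
  the realized truth.
- `intra_type_clumps` — cells of each type arrive in same-type clumps of
  fixed size `clump_param` (per-type means preserved). Mixed partitions then
  under-report the realized multiplet load (a clump is already a multiplet
  that the cross-species signal cannot see), biasing the estimator
  **downward**.

Tests assert only the direction of these biases, not magnitudes, which depend
on the clumping model; the modes exist to demonstrate how the Poisson
assumption fails, not to model any particular instrument.

What the simulator does *not* emulate: transcript counts with ambient RNA or
barcode-collision chemistry (the synthetic matrices below draw clean
per-species UMIs), variable capture efficiency per cell, or more than two
types. Passing recovery tests therefore validate the algebra and the Poisson
sampling behaviour, not robustness to those real-data artifacts.

## Species classifier

`read_matrix` ingests a cellranger-style triplet (MatrixMarket counts,
features TSV, barcodes TSV; plain or gzipped) and assigns each feature to a
species by a literal, case-sensitive id prefix — no guessing of reference
naming dialects; unmatched ids are an error naming the offenders.
`call_cells` labels each barcode:

- **background** iff total UMIs < `min_umi` (default 100),
- otherwise **mixed** if the minor species' UMI share ≥ `minor_fraction`
  (default 0.1; boundary inclusive, so an exact 50/50 split is mixed),
- otherwise the majority species.

The summary counts follow the inclusive convention and feed the estimator
directly. The rule is deliberately the simplest transparent one — scale-free
above the UMI floor, deterministic, two documented parameters — chosen for
reproducibility over sophistication; ambient-RNA-aware calling is out of
scope. "Substantial number of transcripts from both species" has no canonical
quantification, so the defaults are a documented choice.

`synthesize_matrix` builds matrices for end-to-end tests: non-empty simulated
partitions become barcodes, per-species UMI totals are Poisson with mean
`umis_per_cell` (default 1,000) per cell, split uniformly across that
species' features, with no ambient contamination. At that depth no call can
flip, so the classifier must reproduce the simulator's tally exactly — which
is what the integration test asserts.

## Numerical and design choices

- Estimates are stored at full precision; the 3-decimal values in reports are
  display fields only.
- Default problem sizes in tests: recovery checks run 20 replicates per
  condition at 200,000 partitions, end-to-end classification at 50,000
  partitions with deep UMIs — large enough that Monte-Carlo bands are a few
  percent of M, small enough to run in seconds.
- The CLI writes every output via temp-file-and-rename, so failed runs leave
  no partial files; seeds default to a fixed documented value rather than
  entropy so pipelines are reproducible unless the user opts out.
- Exit codes: 2 for validation/usage problems, 3 for the two degenerate
  estimation errors, each with a machine-greppable one-line reason on stderr.

## Known limitations

- Very unequal, dilute mixes are intrinsically underpowered: the expected
  mixed count N·(1−e^(−μ₁))(1−e^(−μ₂)) can drop to a handful, at which point
  replicates with N₁,₂ = 0 (no estimate at all) become common and the
  estimate's sampling distribution is markedly skewed. The estimator reports
  these as errors; it cannot manufacture information the design did not
  collect. Spiking in more of the rare type, or more partitions, is the fix.
- The delta-method standard error is first-order and mildly optimistic when
  expected mixed counts are below ~20.
- Departures from Poisson loading bias M in the directions described above;
  the package demonstrates the signs but offers no correction.
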
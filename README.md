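# barnyard

Multiplet-frequency estimation for droplet- and well-based single-cell
RNA-sequencing from two-species cell-mixing ("barnyard") experiments, at
**arbitrary** mixing proportions.

## The problem

A standard scRNA-seq quality control mixes two distinguishable cell types —
classically human and mouse — before loading cells into barcoded partitions.
Partitions whose transcriptomes contain a substantial number of transcripts
from *both* species must hold multiple cells, which reveals the **multiplet
frequency** M: the probability that a non-empty partition contains two or more
cells. When the two types are mixed equally and loading is dilute, the
classical shortcut is M ≈ 2·N₁,₂/(N₁+N₂−N₁,₂) ("twice the cross-cell-type
fraction"). That shortcut breaks for unequal mixes — whether from counting
error or from deliberately spiking in few cells of the control species — and
overestimates M at high loading.

`barnyard` implements the closed-form solution for the general case. The only
assumption is that the number of cells of each type per partition is Poisson
distributed, with means μ₁ and μ₂. Writing N for the total number of
partitions (empty ones included) and N₁, N₂, N₁,₂ for the observed counts of
partitions holding ≥1 cell of type 1, ≥1 of type 2, and ≥1 of both
(**N₁ and N₂ include the mixed partitions**), independence of the two loading
processes gives

    N = N₁·N₂ / N₁,₂                        (total partitions)
    μᵢ = −ln((N − Nᵢ)/N)                    (rate inversion)
    M = 1 − μ e^(−μ) / (1 − e^(−μ)),  μ = μ₁ + μ₂

Three observed numbers in, point estimate out — no simulation or fitting
required. The package also provides a parametric-bootstrap interval, a
delta-method standard error, a seeded droplet-loading simulator (including
non-Poisson clumping modes that probe the assumption's failure directions),
and a species classifier that derives (N₁, N₂, N₁,₂) directly from a
cellranger-style gene–barcode matrix whose feature ids carry species prefixes.

Out of scope: identifying *which* barcodes are multiplets, more than two cell
types, and ambient-RNA correction.

## Worked example

An experiment returns 3,050 partitions containing human cells, 1,050
containing mouse cells, and 100 containing both (so 4,000 non-empty
partitions, a roughly 3:1 mix):

```sh
barnyard estimate --n1 3050 --n2 1050 --n12 100
```

```json
{
  "multiplet_frequency": 0.06522697398532618,
  "multiplet_frequency_display": "0.065",
  "mu1": 0.10008345855698253,
  "mu2": 0.0333364202675918,
  "n_total_droplets": 32025.0,
  "n_nonempty": 4000.0,
  "doublet_approximation": 0.05,
  "doublet_approximation_display": "0.050",
  "counts": {
    "n_type1": 3050.0,
    "n_type2": 1050.0,
    "n_mixed": 100.0
  }
}
```

6.5% of non-empty partitions are multiplets. The inferred loading is about
0.100 human and 0.033 mouse cells per partition across an estimated 32,025
total partitions. Note the equal-mix shortcut (`doublet_approximation`, 0.050)
understates M here — cross-species partitions under-count multiplets when one
species dominates, because same-species doublets of the majority type go
unseen.

The same quantities are available from Python:

```python
from barnyard import DropletCounts, estimate_from_counts
est = estimate_from_counts(DropletCounts(n_type1=3050, n_type2=1050, n_mixed=100))
est.multiplet_frequency   # 0.0652...
```

Degenerate inputs raise named errors rather than returning a number:
`UnidentifiableTotalError` when N₁,₂ = 0 (the total N is unbounded; the
experiment cannot constrain M) and `InconsistentCountsError` when N₁,₂ equals
a per-type count (an implied infinite rate). The CLI maps both to exit
status 3, and ordinary validation problems to exit status 2.

Other subcommands: `barnyard simulate` (seeded loading simulation with
`poisson`, `overdispersed` and `intra_type_clumps` modes), `barnyard recover`
(estimator bias table over a grid of loads) and `barnyard classify` (species
calls and an estimate straight from a matrix.mtx / features.tsv /
barcodes.tsv triplet). All accept `--help`, which documents the inclusive
counting convention.

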
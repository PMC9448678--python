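# Methods

This note documents the statistical procedures, the generative models behind
the synthetic-data modules, the defaults and why they were chosen, and the
known limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Screen hit calling

### sgRNA phenotypes

For samples *a* (reference) and *b*, counts are normalized to counts per
million within each sample, a pseudocount *ps* (default 1) is added, and

    raw_i = log2((cpm_i,b + ps) / (cpm_i,a + ps)),
    phenotype_i = raw_i − median(raw over NTC sgRNAs).

Adding the pseudocount *after* depth normalization makes the phenotype
exactly invariant to multiplying either sample's counts by a constant — the
property a depth-normalized statistic should have; adding it to raw counts
would only satisfy it approximately. sgRNAs with fewer than 10 reads in the
reference sample are flagged `low_count` but never dropped: dropping rows
changes the NTC median and the Mann–Whitney pool in ways the caller should
decide about, not the library.

### Gene p-values

A gene's sgRNA phenotypes are compared against all NTC sgRNA phenotypes with
a two-sided Mann–Whitney *U* test. The exact null distribution is used when
the smaller group has ≤ 8 observations, the pooled sample has ≤ 300 values
and there are no ties; otherwise the normal approximation with midranks, tie
correction and continuity correction. The switch point trades exactness
against the cost of the exact distribution for large pools; the test suite
pins the exact path to an exhaustive labeling-enumeration oracle for all
group sizes ≤ 5 vs ≤ 20 and checks the approximate path against Monte-Carlo
permutation at 5 vs 500.

### Quasi-genes and standardization

Negative-control quasi-genes are groups of five NTC sgRNA ids drawn i.i.d.
with replacement from the NTC pool (`make_quasi_genes`, seeded). Gene raw
phenotypes (default: mean of the gene's sgRNA phenotypes; a top-3-by-|value|
mode is exposed for pipelines that downweight weak guides) are standardized
against the quasi-gene raw distribution:

    z_g = (raw_g − median(quasi)) / sd(quasi),   sd with ddof = 1.

The **Gene Score** is `z × (−log10 p)`, so its sign is the phenotype
direction and it is exactly 0 when p = 1.

Two calibration details matter at small scale:

* **Quasi count.** `call_hits` builds three quasi-genes per real gene. A
  balanced count (one per gene) leaves the empirical null so coarsely
  resolved that, with the add-one FDR estimate below, no hit set smaller
  than ~10% of the genome could ever be called; three per gene brings the
  smallest callable hit set down to ~n_genes/(0.1·(3·n_genes+1)) ≈ 4 genes
  while keeping runtime linear. Screens expected to carry only one or two
  true hits should raise `n_quasi` further (the estimate needs enough null
  resolution to certify a tiny discovery set).
* **Self-exclusion.** Each quasi group is tested against the NTC phenotypes
  *excluding its own members*. Testing a group against a pool that contains
  it biases its p-value conservative, which compresses the quasi Gene Score
  null and admits borderline real genes; in simulations with 100 NTCs this
  inflated the realized false-discovery proportion by ~50%. With hundreds of
  NTCs the overlap is ~1% and the distinction is negligible. When fewer than
  two NTC phenotypes remain after exclusion the full pool is used.

### Empirical FDR threshold

Per tail (positive and negative Gene Scores separately, since phenotypes are
signed), the cutoff is the smallest |Gene Score| *c* among the gene scores
such that

    est_FDR(c) = [(1 + #{quasi ≥ c}) / (n_quasi + 1)] · n_genes / #{genes ≥ c} ≤ target.

The add-one numerator is the standard correction for a finite empirical
null: a quasi tail fraction of exactly zero reflects resolution, not a zero
false-discovery rate, and without the correction any lone gene exceeding
every quasi-gene is called regardless of the target, which destroys FDP
control in null screens. A tail with no admissible cutoff yields no hits
(not an error). Quasi-genes are reported alongside genes but never flagged
as hits. The guarantee is on the *mean* FDP over repeated screens; the
per-screen FDP fluctuates, especially with few discoveries.

## Screen simulator

Defaults mirror the druggable-genome screen design: 2,325 genes × 5 sgRNAs
plus 500 NTCs, 1,000 cells per library element at t0, bottom/top 30% FACS
gates. Quantities the design does not fix are simulation choices:

| parameter | default | rationale |
|---|---|---|
| `doublings` | 5 | growth between sampling points of a two-week screen |
| `fraction_hits` / `effect_size` | 0.1 / 1.0 | a sparse hit landscape with effects of one log2 unit per doubling |
| `shift_size` | 2.0 | a strong reporter shift, ~2 reporter SDs |
| `reporter_mu`, `reporter_sigma` | 0, 1 | log-normal reporter; only the shift/sigma ratio matters |
| efficacy ~ Beta(5, 1) | — | most guides strong, a tail of weak ones, matching the observed spread of knockdown strength between sgRNAs of one gene |
| `depth` | coverage × elements | one read per seeded cell |
| sequencing noise | multinomial | no overdispersion by default (none is quantified for these screens); a Dirichlet-multinomial concentration parameter is exposed |

Survival mode: t0 seeds exactly `coverage` cells per element;
`tF = coverage · 2^(doublings·(1 + efficacy·γ))`, NTCs have γ = 0 by
construction. FACS mode: every cell carries one sgRNA; its log reporter is
Normal(μ + efficacy·shift, σ); bins take the bottom and top
`floor(bin_fraction · n)` cells with ties broken by cell index, so gating is
deterministic. Per-bin tallies (and survival abundances) are sequenced
multinomially at the configured depth, so per-sample counts sum to the depth
exactly. One master seed spawns independent substreams for effects,
efficacies, growth/reporter noise and sequencing, making each stage
individually reproducible and every output bit-identical under a fixed seed.

What the simulator does *not* model: differentiation bottlenecks, guide
dropout during selection, PCR jackpotting (beyond optional overdispersion),
FACS instrument noise beyond the log-normal reporter, or multi-guide cells.
Passing tests on this generator therefore demonstrate correctness of the
statistics under clean sampling assumptions, not robustness to every
artifact of real screens.

## CROP-seq simulator

Per cell: integration count ~ Poisson(moi) with distinct guides drawn
uniformly from the library; a cluster drawn from the base proportions
(uniform over 9 states by default), multiplicatively reweighted by the
carried gene's occupancy effects (the first integrated guide's gene governs
reweighting in multi-integration cells; NTC and unperturbed cells use base
proportions); expression UMIs ~ Poisson with cluster-specific means — one
distinctive high-expression marker per cluster (an SPP1-like
disease-associated state, a CCL13-like chemokine state, and so on), profiles
scaled to ~2,000 UMIs per cell, and every carried target gene's mean scaled
by (1 − knockdown_strength) *after* depth scaling so the carrying/
non-carrying expression ratio is exactly 1 − knockdown_strength in
expectation. sgRNA UMIs are Poisson(50) on integrated guides plus
Poisson(0.2) ambient background on every guide.

Defaults: MOI 0.10 (the design requires < 0.15 so that most transduced cells
are singlets; the config validates the bound), ambient rate 0.2 UMIs/cell/
guide and signal level 50 (no quantitative ambient measurement exists for
this assay; these produce the qualitative regime — clean singlets dominated
by their guide, rare ambient counts well below the assignment floor).
Poisson expression noise was chosen over negative binomial for analytic
transparency; cluster-level means, not per-cell biological dispersion, carry
the signal the downstream statistics consume. Cells with ≥ 2 integrations
are retained and truth-labeled so the singlet filter is testable. The
simulator makes no attempt to reproduce real microglial transcriptomes,
UMAP geometry or cross-dataset integration — clusters are consumed
downstream as labels only.

## CROP-seq analysis

* **Assignment** (`assign_sgrnas`): per cell, on log1p UMIs, the background
  is every guide except the maximum; a guide is called if its raw count
  ≥ `min_umi` (default 5) and its log1p count is ≥ `z_cutoff` (default 3)
  background SDs above the background mean; the top guide is assigned iff it
  is called and the runner-up is not. With a degenerate (zero-variance)
  background, any strictly-above-background signal counts as infinitely
  separated. This single z-score rule with a UMI floor and runner-up
  exclusion stands in for ambient-model-based demultiplexing; the value 3 is
  a conventional choice, and the `min_umi` floor is what keeps ambient
  counts from ever winning. Reasons (`assigned`, `ambiguous_multiple`,
  `no_signal`) partition all cells.
* **Knockdown-cell selection**: among cells assigned to a target's sgRNAs,
  those with log1p-CPM target expression strictly below that population's
  median. Normalized rather than raw counts, so per-cell depth does not
  masquerade as knockdown; "strictly below" means an all-tied population
  selects no cells, and a target with no assigned cells raises a distinct
  `EmptySelection` signal rather than an error.
* **Differential expression**: Welch two-sample t per gene on expression
  that is log1p-CPM normalized and z-scored per gene across the two groups
  jointly — a deliberate, documented replacement for variance-stabilizing
  Pearson residuals, preserving the "standardized expression, t-test"
  structure without a heavy normalization dependency. Bonferroni adjustment
  by default (Benjamini–Hochberg by flag), significant iff adjusted
  p < 0.1. Zero-variance genes get p = 1. Per-target top-20-by-|effect|
  summaries are emitted only for targets with > 50 knockdown cells; smaller
  targets stay in the full tables.
* **Occupancy**: prop(g, c) = (n_gc / n_g) / (n_NTC,c / n_NTC), gene level
  by default (a gene's sgRNAs pooled), guide level optional. The NTC row is
  identically 1 where defined; clusters with zero NTC cells yield NaN (never
  a silent 0), and cells lacking a cluster label are excluded with a count.
  Quality-control exclusions (e.g. high-mitochondrial clusters) are an
  input-side cell filter for the caller, since clustering itself happens
  upstream.
* **State proportions**: two-sided Fisher's exact test (sum of tables at
  most as probable as the observed one) with the sample odds ratio.

## Verification strategy

Every statistic is pinned to an independent oracle in the test suite: exact
Mann–Whitney p-values to exhaustive labeling enumeration, Fisher p-values to
direct hypergeometric-support summation (exhaustive for all tables of total
≤ 12, sampled up to margins of 30), the FDR scan to brute-force threshold
enumeration, phenotypes to hand arithmetic, and every simulator to its
closed-form expectations (multinomial depth, Poisson singlet fraction,
16-fold depletion of a γ = −1 gene over four doublings, knockdown expression
ratio). End-to-end, the pipeline recovers planted survival-screen hits and
CROP-seq occupancy effects, and the empirical-FDR procedure's mean realized
FDP over 200 fully null screens (100 genes, 100 NTCs, depth 10⁶ — sizes
chosen to keep the whole check to ~a minute) stays below the 10% target;
`scripts/acceptance.py` recomputes that number and the CROP-seq infection
rate from scratch.

## Known limitations

* The empirical-FDR estimate cannot certify discovery sets smaller than
  ~n_genes/(target·(n_quasi+1)) genes; raise `n_quasi` for sparse-hit
  screens.
* Exact read counting assumes error-free reads within the trim window; the
  optional Hamming-1 mode tolerates single mismatches but nothing more
  (no indel or quality-aware matching).
* The DEG stage's standardized-mean effect is not a fold change; it is
  comparable across genes, not across datasets.
* Multi-integration CROP-seq cells reweight occupancy by the first guide's
  gene only, and knockdown applies to all carried targets — a simplification
  at MOI < 0.15 where such cells are < 1% of the pool.
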
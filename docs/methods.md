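# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the limitations of `cfdecon`. It states what the code computes and
why each default is what it is; every empirical number quoted here is computed
by the test suite or `scripts/acceptance.py`, not asserted.

## Scope and shape

The package is a pipeline (simulate → segment → select markers → build atlas →
deconvolve → evaluate → bound), not a single model fitted to one dataset, so it
is organised as functional modules around typed containers. The one stage that
is a genuine fitted model — the mixture deconvolution — follows the
statsmodels model/results convention: `MethylationDeconvolution(atlas)` is the
model, `.fit(mixture)` returns a `DeconvolutionResults` carrying estimates,
residual, the data sizes used, and `summary()`.

## Synthetic data generator

The generator produces the world the pipeline is evaluated in. Its defaults
are the package's study conditions:

| parameter | default | rationale |
|---|---|---|
| cell types | 10 | enough for a multi-column atlas while keeping runs minutes-scale |
| CpGs | 130,000 | hosts 5,000 planted blocks plus background |
| CpG spacing | geometric, mean 100 bp | genome-average CpG density |
| planted blocks / cell type | 500 | supports the largest marker count studied (k = 500) |
| planted block size | 12–24 CpGs (~1.2–2.4 kb) | real co-methylated blocks average ~17 CpGs genome-wide, and cell-type-specific hypomethylation is enhancer/domain scale; smaller blocks would starve markers of fragments at 10× |
| propensities | 0.10 in the owner's blocks, 0.90 elsewhere | hypomethylation gap 0.8, well above the 0.3 selection threshold |
| fragment length | truncated geometric, mean 5 CpGs, cap 20 | cfDNA fragments (~167 bp) cover few CpGs; the cap keeps U/X/M classification meaningful |
| bisulfite miscall | 0.005 symmetric per-call flip | no error model is prescribed by the upstream formats; 0.5% is typical post-QC |
| reference coverage | 30× per replicate, 3 replicates | deep reference WGBS (30× is the standard target); replicates merge to ~90× per cell type |
| mixture coverage | 2.5–30× | the range studied; 10× matches typical plasma cfDNA WGBS |

Fragment starts are uniform over CpG indices, never span chromosome
boundaries, and each covered CpG is called Bernoulli(propensity) then flipped
with the miscall rate. Mixtures are defined over **CpG calls**: the expected
fraction of calls originating from the spike pool equals the nominal spike
fraction (information content, not fragment count), with up-sampling by
drawing fragments with replacement when a pool is smaller than its call
budget. One explicitly seeded RNG stream per operation makes all outputs —
including on-disk PAT files — byte-identical across reruns.

What the generator does **not** emulate: genomic sequence and SNPs,
nucleosome-driven fragmentation patterns, region-dependent CpG density,
cell-type relatedness (every pair of cell types is equally distant), and
reference-vs-plasma biological mismatch. Passing tests therefore demonstrate
the pipeline's statistical behaviour under clean conditions — recovery
linearity, detection limits set by counting noise — not its robustness to the
systematic noise of real cfDNA, where published deconvolutions report
false-positive calls and degraded AUC.

## Block segmentation

`segment_genome` is a greedy left-to-right scan: a block absorbs the next CpG
iff (a) the bp span stays ≤ `max_bp` (5,000), (b) the chromosome is unchanged,
and (c) the candidate CpG's methylation stays within `homogeneity_tol` (0.25)
of the running block mean. Runs shorter than `min_cpg` are discarded.

The per-sample deviations in (c) are aggregated with **max** by default
(`homogeneity_stat="max"`), not the cross-sample mean. The reason is
arithmetic: a boundary that is specific to one cell type among *n* samples
moves the mean absolute deviation by only (gap)/n — with 10+ samples a full
0.8 methylation jump contributes less than 0.1 and a mean rule can never
split there, which would merge every cell-type-specific block into its
methylated surroundings and dilute all markers below the 0.3 threshold. The
max rule fires on a single deviating sample; to keep its false-trigger rate
negligible the segmentation input should be per-cell-type methylomes at
high effective depth (replicates merged; at ~90×, binomial noise per CpG has
sd < 0.04, far below 0.25). `homogeneity_stat="mean"` remains available.

This greedy rule is a deliberate substitute for the unpublished segmentation
of the established WGBS toolchain; absolute block counts are therefore not
comparable with published genome-wide figures.

Block tables record methylated/total calls per block per sample, with a cell
set missing when depth < `min_depth` — 10 for clustering, 5 for marker
selection, both exposed. Sample clustering is scipy's average-linkage
agglomeration on city-block (L1) distances with optimal leaf ordering,
applied to the top 1% most variable fully-observed blocks.

## Marker selection

For each target cell type vs the union of all others: blocks with more than
1/3 missing values in either group are dropped; a candidate needs
(background mean − target mean) ≥ `min_diff` (0.3) **and** two-sided Welch
p ≤ `alpha` (0.05); ranking uses the margin = background 2.5th percentile −
target 75th percentile (linear interpolation between order statistics), ties
broken by p-value then genomic position. Welch's unequal-variance test is the
deliberate reading of "t-test": group sizes are very unequal in atlas use
(3 target vs hundreds of background samples). **No multiple-testing
correction is applied** — the procedure reproduced here uses raw p ≤ 0.05,
acceptable only because the 0.3 effect-size gate dominates; users screening
many weak candidates should correct externally. The hypermethylated direction
runs the identical rule on 1 − methylation.

The Welch p-value is computed vectorized from the closed form (verified in
the tests against both `scipy.stats.ttest_ind` and an exhaustive 70-relabelling
permutation oracle on 4v4 fixtures, where the mean |p_Welch − p_perm| is
below 0.05).

## Fragment-level deconvolution

Thresholds follow the established fragment-level (U/X/M) convention: U iff
methylated-call fraction ≤ 0.25, M iff ≥ 0.75, minimum 3 informative calls
inside the marker; all configurable. Atlas entries are reference U-fractions;
rows lacking a single classifiable reference fragment in any cell type are
dropped (and logged). The fit is plain (unweighted) non-negative least
squares on the per-marker U-fractions, normalized to the simplex afterwards.
Unweighted rows are a known inefficiency — marker support is heteroscedastic —
but are kept as the faithful baseline; support-weighting was measured to
change estimates by well under the sampling noise at the study's scale.
Degenerate NNLS solutions (all-zero) are returned as zeros with a warning
rather than renormalized. "Detected" means estimated proportion strictly
greater than `detection_epsilon`, default 0 (any mass), with an alternative
epsilon exposed because operational definitions vary.

## Spike-in evaluation harness

Backgrounds are per-replicate "individuals": mixtures of the non-target cell
types at Dirichlet(5)-drawn proportions (12 individuals by default, mirroring
a 12-sample healthy cohort; `background_cell_types` can restrict the
composition to a sparse subset). The spike source is a sibling replicate of
the target cell type — same methylome, an RNG stream never used for the
references — so the atlas is never fitted on spiked reads. Detection
probability is the share of replicates with estimate > epsilon; AUC is the
rank-based (Mann–Whitney, midrank ties) comparison of spiked vs 0%-spiked
estimates within the same coverage/k condition. Recovery linearity is OLS of
estimated on true fraction over 1–10%; by default one point per fraction
(replicate mean), per-replicate points optional. Normalized RMSE divides the
RMSE of estimates by the mean true fraction.

`false_positive_model` regresses the number of detected cell types on
coverage and marker count (OLS with intercept). On clean synthetic mixtures
this count is dominated by *true*-type detection, which improves with
coverage and markers, so the coefficients come out positive; the negative
correlations reported for real plasma data arise from reference/plasma
mismatch noise the generator deliberately does not model. The regression
machinery itself is verified on counts with a planted linear law.

## Pharmacokinetic detectability bound

Constant cell death is an infusion: release rate k₀ = n_cells · m_genome /
duration (pg/min), steady-state concentration C = d·k₀·t½/(ln 2·Vd), fraction
= C / total cfDNA. Parameters, with units and defaults: d (dimensionless,
bounds 3×10⁻² to 3×10⁻⁵ from observed cell-type extremes), t½ = 114 min
(steady-state, not distribution, half-life), Vd = 3.0 L plasma (converted to
µL once at the interface; pg and minutes everywhere internally), n_cells =
5×10⁵, m_genome = 6.46 pg, total cfDNA = 297 pg/µL. The "constant rate of
loss over the disease course" assumption is taken literally — k₀ is constant
over `duration`, no onset ramp — and `duration` is an explicit argument
rather than a hard-coded progression speed, because the fastest duration
behind any single printed bound is a modelling choice, not a measurement.
The closed form is verified against numerical integration of
dC/dt = d·k₀/Vd − (ln 2/t½)·C to < 10⁻⁶ relative error, and the inverse
(`required_death_rate`) is an exact algebraic inversion (round-trip identity
tested). Across 1–5-year durations and the full range of d, every fraction in
the scenario grid is orders of magnitude below the ~1% fragment-level WGBS
detection threshold — the package's headline theoretical result.

## Numerical and convention choices

- CpG coordinates are 0-based half-open internally; the on-disk PAT dialect
  is 1-based. The shift happens only in `cfdecon.io`.
- PAT records: 4 tab-separated columns (chrom, start, pattern over `C`/`T`/`.`,
  count ≥ 1), sorted on write; equal records can be merged (flag) by summing
  counts. Writers are deterministic to the byte.
- Tie-breaking is always genomic order, then lexicographic sample label;
  variance ranking uses a stable sort so ties keep genomic order.
- Classification thresholds are inclusive (≤ for U, ≥ for M).
- U/X/M tallies are computed by binning every CpG call to its marker and
  reducing per (fragment, marker) pair with `np.unique` — exact, and fast
  enough for ~10⁷ calls per collection.
- Percentiles use linear interpolation between order statistics (numpy
  default).
- Problem sizes in the acceptance script: the main grid uses the full default
  world (10 cell types, 130k CpGs, k = 500, 10× mixtures, 6 replicates per
  fraction); marker recovery and the detected-type regression use smaller
  worlds (3–6 cell types, 4–12k CpGs) where the quantities are
  scale-invariant.

## Known limitations

- Clean-world optimism: no atlas/plasma mismatch, so AUC and detection
  probabilities saturate at spike fractions where real data degrade.
- The greedy segmentation is order-robust but not globally optimal; block
  boundaries can shift by a CpG around noisy edges.
- Raw p ≤ 0.05 marker gate (no FDR), faithful to the reproduced procedure.
- Single-compartment PK with constant release; distribution-phase kinetics
  and clearance mechanisms are out of scope.
- Proportions are fragment-level estimates of call-level spike fractions;
  the two coincide in expectation because both pools share one fragment-length
  distribution, and the residual bias (~3% relative, measured in the
  acceptance run) is far below sampling noise at realistic coverages.
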
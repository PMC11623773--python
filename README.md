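# cfdecon

Fragment-level cell-free DNA (cfDNA) methylation deconvolution, cell-type-specific
hypomethylated marker selection, spike-in detection-limit evaluation, and a
closed-form pharmacokinetic bound on the detectability of rare cell types.

## The problem

cfDNA in plasma is released by dying cells, and its methylation pattern betrays the
tissue of origin. A disease that selectively kills one rare cell type — lower motor
neurons (MN) in ALS are the motivating case — could in principle be monitored by
finding that cell type's DNA in a blood draw: find genomic blocks that are
unmethylated *only* in the target cell type, classify each sequenced fragment over
those blocks, and estimate the cell type's share of the mixture. `cfdecon`
implements that entire chain on fragment-level whole-genome bisulfite sequencing
(WGBS) data, together with the simulation machinery needed to measure its
detection limits and a pharmacokinetic argument for what those limits mean.

The package is aimed at people designing methylation-based liquid-biopsy assays
for rare cell types: it answers "how many markers, what coverage, and what spike-in
fraction does fragment-level deconvolution need?" and, independently, "how much of
the target cell type's DNA can plasma physically contain?"

## What it computes

**Blocks and markers.** The CpG universe is segmented into blocks of co-methylated
CpGs (greedy scan; a block absorbs the next CpG while the span stays ≤ `max_bp`
and no sample's methylation jumps by more than a homogeneity tolerance). For each
cell type, blocks are kept as candidate markers when the background-minus-target
mean methylation difference is ≥ 0.3 and a two-sided Welch t-test gives p ≤ 0.05;
candidates are ranked by the separation margin (background 2.5th percentile −
target 75th percentile) and the top *k* kept.

**U/X/M deconvolution.** Each fragment with ≥ 3 CpG calls inside a marker is
classified **U** (methylated-call fraction ≤ 0.25), **M** (≥ 0.75) or **X**
(between). The reference atlas **A** stores, per marker × cell type, the
U-fraction of that cell type's fragments; a mixture contributes the vector **b**
of its per-marker U-fractions. Proportions solve

```
min ‖A·x − b‖₂   subject to  x ≥ 0,     x ← x / Σx
```

**Spike-in evaluation.** Synthetic mixtures spike a target cell type's fragments
into background cfDNA at known fractions (0–10%) and coverages (2.5–30×); the
harness reports detection probability, rank-based AUC against unspiked mixtures,
recovery linearity (OLS of estimated on true fraction), normalized RMSE, and a
linear model of detected-cell-type counts on coverage and marker count.

**Detectability bound.** Treating constant cell death as a drug infusion, the
steady-state plasma concentration of the cell type's DNA is

```
C = d · k₀ · t½ / (ln 2 · Vd),        k₀ = n_cells · m_genome / duration
```

with `d` the fraction of released DNA reaching plasma (3×10⁻² … 3×10⁻⁵ across
cell types), `t½ = 114 min` the steady-state cfDNA half-life, `Vd = 3.0 L`
plasma, 6.46 pg per diploid genome and ~500,000 lower MN. Dividing by the total
cfDNA concentration (297 pg/µL) gives the fraction a deconvolution would need to
detect, and the inverse form gives the death rate required for any target
fraction.

## Worked example

```python
import cfdecon as cf

sim = cf.SimulationConfig(n_cell_types=4, n_cpgs=8000, blocks_per_cell_type=25, seed=7)
grid = cf.SpikeGridConfig(replicates=1, base_seed=7)
assets = cf.prepare_assets(sim, grid)

atlas = cf.build_reference_atlas(assets, grid, min_cpg=4, k=25)
print(f"atlas: {atlas.n_markers} markers x {len(atlas.cell_types)} cell types")

mixture = cf.mix_fragments(
    assets.background_pools[0], assets.spike_pool,
    spike_fraction=0.05, target_coverage=10.0, cmap=assets.cmap, seed=1,
)
model = cf.MethylationDeconvolution(atlas)
print(model.fit(mixture).summary())

res = cf.steady_state_concentration(cf.PKParams(d=0.03, duration_min=1440.0))
print(f"\nPK bound: fraction of plasma cfDNA = {res.percent:.3g} %")
```

prints

```
atlas: 100 markers x 4 cell types
Fragment-level methylation deconvolution (NNLS on U-fractions)
markers used: 100    fragments used: 2498    residual ||Ax-b||: 0.8947
----------------------------------------------------------
cell type                 proportion
cell02                        0.4228
cell04                        0.2813
cell03                        0.2413
cell01                        0.0547

PK bound: fraction of plasma cfDNA = 0.00124 %
```

The mixture was built by spiking 5% of `cell01` fragments (by CpG calls) into a
background of the other three cell types at 10× coverage; the model attributes
5.5% to `cell01` and splits the rest across the true background types. The last
line is the detectability bound: even if every one of 500,000 motor neurons died
within 24 hours, at the most favourable plasma availability (d = 3%) their DNA
would make up ~0.0012% of plasma cfDNA — three orders of magnitude below the ~1%
fraction-level WGBS detection limit the spike-in experiments measure.

A CLI mirrors the library (`cfdecon simulate-refs | segment | markers | atlas |
deconvolve | spike-eval | pk | run-all`); `cfdecon run-all --config cfg.yaml
--seed 5 --outdir out/` runs the whole pipeline and writes every intermediate
artifact as TSV/PAT next to a resolved copy of the configuration.

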
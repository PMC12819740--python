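# tescope

Cell-type-resolved analysis of transposable-element (TE) dysregulation in
case/control single-nucleus RNA-seq, with chromatin-accessibility-weighted
scoring of candidate TE–gene regulatory pairs.

Repetitive mobile DNA — SINEs (Alu, MIR), LINEs (L1, L2), LTR/ERV elements
and DNA transposons — contributes a substantial share of the transcripts
captured in droplet single-nucleus assays of human brain (roughly 10–15%
of UMIs per nucleus). In neurodegeneration, loss of epigenetic silencing
can reactivate individual TE loci in specific cell populations. `tescope`
provides a desk-scale, fully testable implementation of the analysis that
detects such events from a locus-level gene+TE count matrix:

1. **Pseudobulk differential expression.** Within each cell type, counts
   are summed per biological sample, and each feature is tested with a
   negative-binomial log-linear model
   `log μ_s = β₀ + β₁·1[s ∈ case] + log N_s` (offset `N_s` = sample
   library size) via a likelihood-ratio test of `β₁ = 0` against
   χ²₁; `log₂FC = β₁/ln 2`. Dispersions are per-feature Cox–Reid
   profile-ML estimates shrunk toward the common dispersion;
   Benjamini–Hochberg FDR is applied within each cell type.
2. **Balanced-downsampling robustness.** With unbalanced designs
   (e.g. 11 case vs 7 control samples) the larger group is repeatedly
   subsampled to parity (K = 10 distinct subsets); a TE is *highly
   robust* only if significant in the full data **and** in all K
   iterations, with `FDR < 0.05` and `|log₂FC| ≥ 2` as the final filter.
3. **Annotation and enrichment.** Robust TEs are summarized by
   direction, class, family and evolutionary age (L1HS/L1PA2–8 young,
   AluY young, AluS old, AluJ/MIR ancient, …); family composition is
   tested against the genomic baseline (45% Alu, 17% L1, 8% L2, 5% MIR,
   8% ERV, 3% DNA, 14% other) with a χ² goodness-of-fit test and
   per-family exact binomial tests; chromosome-level enrichment is
   normalized for chromosome size; cluster-size bias diagnostics report
   per-1,000-cell rates and size/effect correlations.
4. **TE–gene proximity.** Genes are paired with TEs at 50 kb, 250 kb,
   500 kb and 1 Mb windows (interval-gap distance); each window is
   scored on isolation %, median genes/TE and gene-set enrichment
   strength, and a normalized selection matrix picks the operating
   window. AD-risk-gene tiers, TE-derived-gene content (Fisher test vs
   the ~3% genome-wide rate) and genomic-feature assignment
   (promoter > enhancer > exon > intron > intergenic) follow.
5. **ATAC integration.** Accessibility profiles (peak overlap, mean
   signal, variance, cell-type specificity τ) feed a weighted composite
   score per TE–gene pair,
   `0.3·s_dist + 0.3·s_acc + 0.2·s_eff + 0.2·s_corr ∈ [0, 1]`,
   tiered Very High / High / Medium / Low around peak support and the
   median composite.

A first-class synthetic-data module generates every input the pipeline
consumes (counts, metadata, BED tracks, ATAC matrix, gene lists) with
planted, recoverable TE effects, so the whole analysis runs and is
validated without any external download.

## Worked example

```python
import warnings
from tescope import SimulationConfig, generate_dataset, plant_ad_scenario
from tescope import filter_low_expression, aggregate_pseudobulk
from tescope.robustness import run_robustness, select_robust_tes
from tescope.annotation import summarize_direction

cfg = plant_ad_scenario(SimulationConfig(seed=1, n_genes=250, n_te_loci=150), 24)
bundle = generate_dataset(cfg)            # 11 AD vs 7 control samples
m = filter_low_expression(bundle.matrix, min_cells=10)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    pb = aggregate_pseudobulk(m, bundle.cell_meta, "EX").subset_features(m.kind == "TE")
    full, iters, rec = run_robustness(pb, k=10, seed=1)
robust = select_robust_tes(full, rec)
print(len(robust), "robust DE TEs in EX")
print(summarize_direction(robust)[["n", "up", "down", "up_pct"]].to_string(index=False))
```

prints

```
14 robust DE TEs in EX
 n  up  down  up_pct
14  14     0   100.0
```

— 14 of the planted excitatory-neuron effects survive the full
robustness procedure (significant in the full design and in all 10
balanced 7-vs-7 subsamples with `|log₂FC| ≥ 2`), and all of them are
upregulated, matching the planted direction structure.

The same analysis runs end-to-end from the command line:

```bash
tescope run --seed 1 --outdir run1       # simulate → DE → … → ATAC scores
tescope simulate --seed 1 --outdir bundle --n-effects 0   # null bundle only
```

Outputs are plain TSV/JSON tables plus a run manifest; re-running with
the same config and seed reproduces every table byte-for-byte.

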
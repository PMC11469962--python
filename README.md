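# gastrukit

Computational staging and comparison of stem-cell-derived embryo models
(gastruloids) from single-cell RNA-seq, for developmental biologists who want
to ask: *how far along is my embryo model, and how consistent is it?*

Embryo models such as human RA-gastruloids are routinely profiled by
scRNA-seq, but placing them on an in-vivo developmental timeline — and
comparing their cell types and variability across species and protocols — is
usually done ad hoc. `gastrukit` packages a systematic framework:

* **Computational staging.** Pseudobulk profiles of a staged reference cohort
  are depth-normalized, log1p- and z-transformed, and decomposed by PCA.
  Among the top PCs the one whose embedding best rank-correlates (Spearman)
  with known stages is chosen as the developmental-time axis — in practice
  the leading PC often captures assay technology instead, so selection is by
  correlation, not variance. Query datasets (other species via an ortholog
  map, other embryo models) are projected through the reference loadings and
  assigned a stage by piecewise-linear interpolation against per-stage
  medians of the reference axis, for whole samples or per cell type.
* **Reciprocal-NNLS cell-type correspondence.** Each cell type `a` of dataset
  A is predicted from all cell-type profiles of dataset B by non-negative
  least squares over marker genes (union of the 200 most expressed and 200
  most specific genes in the target), and vice versa; the directional
  coefficients combine as `β = 2(β_ab + 0.001)(β_ba + 0.001)`, are z-scaled
  within each target, and the argmax calls the best match.
* **Composition-variance testing.** 100 cells are drawn without replacement
  from each individual, ten times, to form pseudo-replicates; per cell type
  the s.d. of its frequency across individuals is compared between groups by
  one-way ANOVA with Tukey's HSD post hoc.
* **Pseudotime dynamics conservation.** Genes are tested for
  pseudotime-dependent expression (negative-binomial GLM with a natural
  cubic spline basis, likelihood-ratio test, BH q < 0.05), their dynamics
  clustered into up/down groups (Ward), and cross-dataset DEGs classified
  into up–up, down–down, up–down, down–up, up–unexpressed, down–unexpressed.
* **Morphometric rules.** Length-to-width summaries (widths at 10/50/90%
  positions), the paired-somite rule (left/right area ratio within 70–130%,
  gastruloid "paired" if ≥ 2 of 3 sampled pairs are), and rostrocaudal
  boundary detection from anti-phase marker intensity tracks (LOWESS
  smoothing, mean normalization, peak calling on the difference signal).
* **Synthetic data.** A first-class generator plants the structure the
  analyses assume — a shared latent time program across two "species", a
  stronger technology/batch axis, cell-type programs, noisy many-to-many
  ortholog maps, Dirichlet-multinomial compositions, monotone trajectory
  genes and periodic intensity profiles — so the whole pipeline is testable
  without any external download.

## Worked example

```sh
gastrukit demo --seed 7 --out demo_out
```

runs the full synthetic pipeline (simulate → pseudobulk → HVG → stage →
map cell types → composition variance → dynamics → morphometrics) and writes
TSV outputs plus `report.md`. With seed 7 the summary reads:

```
staging:      axis PC2, Spearman vs truth 0.88 (reference), 0.98 (query)
self-mapping: 1.00 of cell types map to themselves on a random 50/50 split
composition:  ANOVA p ~ 1e-13..1e-17 for all three cell types
dynamics:     72 DEGs along pseudotime, conserved fraction 0.90
morpho:       4/6 gastruloids paired, 4 boundary peaks detected
```

Read it as: the staging model put the developmental-time signal on PC2 (PC1
absorbed the planted technology axis) and ordered held-out cross-species
samples almost perfectly; the NNLS mapping recovered every cell type; the
deliberately variable cohort was detected as significantly more variable
than the consistent one; 90% of trajectory DEGs kept their planted direction
across "species"; and the somite rules matched their hand-computable labels.

The same stages are available as granular subcommands (`simulate`,
`preprocess`, `hvg`, `convert`, `stage fit/project/assign/celltypes`,
`map-celltypes`, `composition-variance`, `dynamics`,
`morpho pair/summarize/boundaries`) and, more flexibly, as library functions
(`gastrukit.staging`, `gastrukit.nnls_map`, …).

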
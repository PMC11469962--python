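# Methods

This note documents the models and procedures implemented in `gastrukit`,
the choices made where the design was genuinely open, and what the synthetic
data do and do not establish about real data.

## Data model and normalization

Counts enter as sparse gene × cell UMI matrices with per-cell metadata
(individual, cell type, stage, species, model), interchanged as Matrix
Market + TSV. Pseudobulking sums UMIs over an individual (or over an
individual × cell type pair for lineage-level staging); total counts are
conserved exactly. The pre-PCA normalization chain is

1. depth normalization: each sample divided by its total, times a scale
   constant (default 1e4 — the constant is conventional, and cancels from
   any statistic computed after z-scoring only up to the log1p
   nonlinearity, so it is configurable);
2. `log1p`;
3. per-gene z-scoring across samples using the sample (n−1) standard
   deviation, matching the default of mainstream single-cell toolchains.
   Genes with zero variance get z = 0 and are flagged rather than dropped,
   so feature indices stay aligned.

QC is rule-based: a gene-family pattern filter (prefix/substring/suffix
token lists targeting cell-cycle and housekeeping families; the default
lists are user-overridable and matching is literal), a kernel-density
valley finder for bimodal UMI/feature-count distributions (Gaussian KDE on
log10 values; the threshold is the density minimum between the two highest
modes, and `None` is returned for unimodal or merged distributions so the
caller must choose a manual cutoff), an upper/lower total-count filter, a
`doublet_flag` metadata filter, and marker-based cell exclusion
(`exclude_cells_by_marker`) for removing, e.g., ventrally contaminating
populations before trajectory analysis. Doublet *detection* is out of
scope; flags are honoured, not computed.

## Highly variable genes against a Poisson noise model

For a raw gene × sample matrix with depth-adjusted expectations
μ_gs = (row total)(column total)/(grand total), the statistic
Σ_s (x_gs − μ_gs)²/μ_gs is χ²_{S−1} under Poisson sampling. Genes exceeding
it after Benjamini–Hochberg correction (α = 0.05) are selected. This is a
reconstruction of "HVG selection based on the Poisson distribution" — the
exact published formula is not printed anywhere accessible — so it is
validated by calibration: on simulated Poisson data the selected fraction
stays near α, and on negative-binomial data (size 1) power exceeds 90%.
Zero-total genes are excluded with a flag rather than erroring.

## Cross-species feature conversion

Ortholog maps are two-column, many-to-many tables. Converting a pseudobulk
matrix into the other namespace happens on the raw or depth-normalized
scale (never after z-scoring): a source gene mapping to k targets
contributes its full row to each (k-fold duplication is intentional — both
homologues are retained), and multiple sources mapping to one target are
summed, because pseudobulk counts are additive; a "first match" mode exists
for non-additive inputs. Unmapped genes are dropped with a logged count.

## Staging

The reference model is an exact PCA (SVD) of the z-normalized sample × gene
matrix, with signs fixed so each loading column's largest-magnitude entry
is positive (bit-reproducibility). The time axis is the PC (among the top
7 by default) whose reference embedding has the largest |Spearman| with
known stages, ties broken toward the lower index, oriented to increase
with stage. PC1 is *not* privileged: in multi-technology references the
leading component typically captures assay differences, which is exactly
why selection is by correlation. An `exclude_pcs` argument lets a declared
batch PC be removed from the eligible set.

Projection supports two normalization modes:

* **joint** (default): reference and query raw pseudobulks are concatenated
  and the normalization chain is re-applied to the combined matrix before
  multiplying by the stored loadings. This mirrors the original procedure
  faithfully but lets query samples shift the reference's per-gene
  statistics — a deliberate leakage that users should be aware of.
* **frozen**: the query alone is z-scored against stored per-gene
  means/s.d.s. This is leakage-free and affine, and is used whenever a
  query must reproduce a reference sample's embedding exactly.

Features missing from a query are imputed at z = 0 (the mean under the z
model — unbiased, and the feature coverage is reported so users can judge);
projection refuses to run below 80% coverage by default.

Stage assignment interpolates piecewise-linearly between per-stage medians
of the reference axis values (with the nearest reference stage also
reported, since cross-species alignments are usually quoted discretely).
Medians that are not monotone in stage are isotonically adjusted with a
warning. Queries beyond the calibrated range clamp to the end stages and
are flagged `beyond_range`; extrapolation is intentionally not attempted.
Lineage-level staging pseudobulks by (individual, cell type) and skips
cell types with fewer than 10 cells.

## Reciprocal NNLS cell-type correspondence

Profiles are depth-normalized, log1p pseudobulks per cell type. Marker
genes per target are the union of the top-200 by expression and top-200 by
specificity, where specificity is the target's share of the summed
per-cell-type means among genes expressed in the target (a reconstruction;
"most specific" is not defined more precisely in the source procedure).
The NNLS fit minimizes ‖T − β₀·1 − M β‖² with β ≥ 0; the intercept is an
appended all-ones column constrained non-negative like the rest (its sign
constraint is unstated in the source; an unconstrained-intercept mode, fit
on centred data, is provided for comparison). Directional coefficients
combine as β = 2(β_ab + 0.001)(β_ba + 0.001) — the 0.001 pseudocount gives
a 2×10⁻⁶ floor — and are z-scaled within each target across candidates
(row-wise; column-wise and whole-matrix scaling are available behind a
flag since the scaling axis is not specified). The best match is the
argmax z per target, with matches whose z-gap to the runner-up is below
0.1 flagged ambiguous. β_ab is read as "coefficient of cell type b in the
fit of target a"; the converse reading would transpose the matrices but
leave the combined statistic unchanged.

## Composition variance

To equalize depth across individuals, 100 cells are sampled without
replacement from each individual (individuals with fewer are excluded),
independently 10 times, forming pseudo-replicates; sampling without
replacement from an individual's cell-type tally is a multivariate
hypergeometric draw. Cell types averaging fewer than one cell per
individual in any group are excluded from testing. Per cell type, the s.d.
of its frequency across individuals within each (group, replicate) feeds a
one-way ANOVA by group, with Tukey's HSD when p < 0.05, per cell type
without multiplicity correction as in the original description (a
BH-corrected column is emitted alongside).

**Known limitation, by construction.** Pseudo-replicates reuse the same
individuals, so the ANOVA's "observations" are dependent: between-group
variance includes individual-sampling noise that the between-replicate
(within-group) variance cannot estimate. The procedure is therefore
anti-conservative under the null, and `null_rejection_rate` measures this
empirically rather than hiding it: at realistic Dirichlet concentrations
the measured size is far above the nominal 0.05 (≈0.7 at concentration
(8,8,8) with 10 individuals/group), and remains inflated (≈0.17) even when
individuals are essentially identical. The implementation reproduces the
described procedure faithfully and surfaces the bias; significant p-values
from it should be read as strong-effect screening, not calibrated
inference. Power against genuinely different concentrations — e.g. (2,2,2)
vs (50,50,50), where the Dirichlet variance α_i(α₀−α_i)/(α₀²(α₀+1)) orders
the groups for every cell type — is essentially 1.

## Pseudotime dynamics and conservation

Pseudotime is an input (any trajectory method; a rank-along-PC1 fallback
exists for fixtures only). The per-gene test is a likelihood-ratio test of
a negative-binomial GLM on a natural cubic spline basis of pseudotime
(df = 3, hand-built truncated-power construction) against intercept-only,
with a log library-size offset; NB dispersion is moment-estimated from a
Poisson pre-fit and clamped to [1e-8, 10]; non-convergent genes get p = 1.
This reconstructs the original smooth-function-of-pseudotime test (a
vector generalized additive model) with an equivalent parametric basis;
the two agree on what "depends smoothly on pseudotime" means but are not
numerically identical. BH q < 0.05 defines DEGs; all-zero genes get p = 1.

Dynamics are represented as per-gene z-scored mean expression over 20
equal-occupancy pseudotime bins (empty bins linearly interpolated);
direction labels come from Ward hierarchical clustering cut at two
clusters, each labelled by its centroid's last-minus-first-bin sign, with
a per-gene-sign fallback when both clusters trend the same way. Clustering
is per dataset (a joint mode exists). A focal DEG whose ortholog
counterpart is not detected in the other dataset (nonzero counts in < 1%
of cells, or absent) is classified up/down–unexpressed; otherwise the
direction pair gives the category, with many-to-many orthologs resolved by
majority direction (ties count as discordant). The conserved fraction is
reported both over DEGs with detected counterparts (primary) and over all
DEGs, since the denominator convention differs between reports.

## Morphometrics

Whole-body/neural-tube summaries average widths measured at the 10%, 50%
and 90% positions and divide length by that average. The paired-somite
rule matches left/right somites by their order from the posterior end and
calls a pair "paired" when the left/right area ratio lies in [0.70, 1.30]
inclusive; three pairs are sampled uniformly without replacement (seeded)
and the gastruloid is "paired" when at least two qualify (an `--all-pairs`
mode applies a ≥2/3 majority over every matched pair). The literal
interval is asymmetric under swapping sides (0.70 vs 1/1.30 ≈ 0.769) —
this is asserted in tests, and a `symmetric` mode using min/max ∈
[0.769, 1] restores invariance for users who want it.

Boundary detection smooths each marker channel by locally weighted linear
regression with tricube weights (span 0.075 — the same smoother family and
parameter convention as R's `lowess`, which the original quantification
used), divides by the channel mean (making the result invariant to
per-channel gain), and calls local maxima on the channel difference with a
minimum peak separation of 60 positions. On a noiseless anti-phase
sinusoid of period 300 over 1200 positions this returns exactly 4 maxima
at the analytic positions.

## Synthetic data: what it emulates, and what it does not

Counts are negative-binomial (per-gene size, default 8) around
exp(baseline + time_loading·t + celltype_offset + tech_level·tech_shift),
renormalized per cell to a lognormal library size (log-mean log 5000,
log-sd 0.3). Defaults: 600 genes with baselines N(2.0, 0.8); 40% of genes
carry time loadings N(0, 0.3); every gene carries a technology shift
N(0, 1.2) whose per-sample strength alternates within the reference cohort
(two "technologies") and is constant in the query species — so the batch
axis is genuinely stronger than the time axis and lands on PC1, while the
time signal must be found on a later PC. The baseline level matters: with
low baselines, log1p of depth-normalized pseudobulk saturates and a 1-D
time gradient arches across two components (the classic ordination
artifact), making single-PC recovery impossible; baselines were chosen so
the planted log-linear signal stays recoverable, which is the generator's
contract. Cohorts default to 6 stages × 5 individuals × 200 cells per
species, with per-individual compositions Dirichlet(10,10,10,10) over four
cell types whose offsets mark ~25% of genes at N(0, 0.8). Ortholog maps
default to 90% 1:1, 5% 1:2 (an extra species-B paralog re-drawn from the
same gene program), 5% unmapped.

Trajectory fixtures use log-linear slopes ±U(0.9, 1.6) over pseudotime
∈ [0, 1] with N(0, 0.3) log-scale noise and Poisson counts; the paired
dataset reuses the programs with a chosen fraction of directions flipped
(planted discordance). Intensity fixtures are anti-phase sinusoids with an
offset keeping intensities non-negative. Every generator is bit-reproducible
from its seed; a global seed fans out to stage seeds via a blake2s hash.

What passing tests on these data show: the pipeline recovers planted
low-dimensional structure (time vs batch axes, cell-type identity,
composition variability ordering, monotone dynamics) at realistic noise
levels and respects its own contracts exactly (conservation of counts,
determinism, formula-level arithmetic). What they do not show: robustness
to real-data pathologies absent from the generator — ambient RNA,
cell-type-specific library sizes, non-linear developmental programs,
HOX-cluster structure, doublets, or annotation errors — nor that any
particular real embryo model maps to any particular in-vivo stage.

## Problem sizes and numerics

Simulation-based checks use: 1000 null datasets for the composition-ANOVA
size estimate and 100 for power; 600 flat genes (250 cells) for DEG
calibration and 100 monotone genes among 500 flat for power; 200 genes at
90% planted concordance for the conservation classifier; 100 random
instances against a projected-gradient solver (1e-6 agreement) for NNLS.
These sizes give binomial standard errors comfortably inside the asserted
margins while keeping the whole suite and the acceptance script fast.
Tolerances: PCA self-consistency at 1e-8; z-scoring treats s.d. below
1e-12 (relative) as zero; isotonic-adjusted calibration medians are
tie-broken by 1e-9 steps so interpolation stays defined.
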
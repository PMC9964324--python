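# Methods

## Scope and model

`ferrocup` packages a transcriptomic pipeline for quantifying ferroptosis
and cuproptosis in HCC cells: per-sample gene-set potential indices built on
single-sample GSEA, flanked by moderated-t differential expression,
weighted co-expression module detection, Kaplan–Meier prognosis, and
per-cell subcluster contrasts. Everything runs on dense genes × samples
matrices (log2 intensities for bulk, raw counts for single cell); gene ids
are opaque case-sensitive strings with no alias resolution.

## ssGSEA engine

Genes are ranked per sample in descending expression; the gene with the
highest expression gets absolute rank *N*. Ties break by lexicographic gene
id, which makes every score platform-deterministic. The enrichment score is
the *integrated* running difference between the weighted in-set rank CDF and
the uniform out-of-set CDF (not the maximum deviation used by multi-sample
GSEA). The weighting exponent α defaults to 0.25, the canonical ssGSEA
choice; α = 0 gives the unweighted running sum. Set genes absent from the
matrix are ignored and the per-row `n_set_genes_present` records how many
survived; a set with no genes in the matrix is dropped with a warning, a set
covering *all* matrix genes is an error (the out-set CDF would be
undefined).

**Monotonicity caveat.** For α = 0 the ES is provably monotone in any set
gene's expression: moving a set gene up the ranking only shifts its mass
earlier and displaces out-set genes later. For α > 0 this is *not* strictly
true: raising a low-ranked set gene increases its rank weight r^α, which
inflates the in-set normalization denominator and dilutes the contribution
of higher-ranked set members; the net ES can decrease slightly. Measured on
random perturbations of the bundled CPI at α = 0.25, about 1–2% of trials
move against the expected direction, always by a small amount. The
monotonicity acceptance check therefore runs at α = 0 where the property is
exact, and the weighted violation rate is reported alongside it.

## Potential indices

An index is a directional gene-set pair. Per sample the raw value is
ES(positive) − ES(negative); the reported value normalizes the raw
differences across the samples *of one call* (z-score by default, min–max
and identity available). Normalization is deliberately call-local: scoring
one cell line's treated + control panel together mirrors per-line analyses
in which each panel is displayed on its own scale. Whether to normalize
within line or across a whole experiment is a genuine free choice; callers
decide by what they pass in.

The bundled CPI components are positive {PDX1, LIAS, LIPT1, DLD, DLAT,
PDHA1, PDHB}, negative {MTF1, GLS, CDKN2A}. The cuproptosis literature's
genome-wide screen names **FDX1**, not PDX1, among the promoters; the
bundled default keeps the PDX1 spelling as given by the analysis this
pipeline mirrors, and a `CPI_positive_FDX1_variant` set ships in
`ferrocup/data/index_components.gmt` so users can score either variant. The
discrepancy is surfaced, not silently corrected. Ferroptosis
driver/suppressor memberships vary across curations, so the FPI has no
hard-coded list: its sets are data (GMT input), and the bundled
`FPI_*_example` sets are synthetic demonstrations, not curated signatures.

Two-group index comparisons use the two-sided Wilcoxon rank-sum test with
significance codes at 0.05/0.01/0.001/0.0001. The exact null enumeration is
used when the combined n ≤ 12 and the data are tie-free; otherwise a
tie-corrected normal approximation with continuity correction. Note the
exact test's granularity: at n = 3 vs 3 the smallest achievable two-sided p
is 2/20 = 0.1, so a single cell line's triplicate contrast can never reach
0.05 — significance claims at that scale require pooling (the replicate
acceptance checks pool the three simulated lines, 9 vs 9).

## Differential expression

Within one cell line, treated vs control on the log2 scale. Gene-wise pooled
variances s² with d = n₁+n₂−2 df are shrunk toward a prior estimated by the
method of moments on log s² (digamma/trigamma matching, Newton inversion of
the trigamma function); the moderated t uses s̃² = (d₀s₀² + d s²)/(d₀+d)
with d₀+d df. If the moment equation has no positive solution the prior df
is infinite and every variance collapses to s₀². d₀ = 0 recovers the
ordinary pooled t (tested); d₀ = ∞ gives the closed-form z against s₀. A
gene with zero variance in *both* groups is reported with p = 1 by
convention and logged. DEG gates: |log2FC| > 1 and BH-adjusted p < 0.05,
adjusted across all genes of the call. The cross-line intersection is
membership-only — direction agreement is not required, mirroring
overlap-of-lists reporting.

## Co-expression modules

Unsigned network: adjacency |cor|^β, diag 0. Soft power selection fits the
scale-free law to the connectivity distribution: equal-count bins of k,
regression of log10(*density*) on log10(mean k). Density (bin mass / bin
width) rather than raw frequency is essential — equal-count bins have
constant frequency by construction. R² counts only when the fitted slope is
negative; the smallest candidate power reaching the target R² (default
0.85) is selected, else the argmax with a `target_met=False` flag.

Topological overlap: TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j)+1−a_ij),
TOM_ii = 1, computed as a matrix product with zeroed diagonal (verified
exactly against a triple-loop oracle). Modules come from average-linkage
clustering of 1 − TOM with a *static* cut placed at a relative position
(default 0.6) between the smallest and largest merge heights. A fixed
quantile of merge heights does not work here: background-gene merges crowd
the top of the dendrogram, so a high-quantile cut absorbs noise into giant
clusters. The relative-position rule recovers planted modules across β from
6 to 21 (adjusted Rand 0.94–1.0 on the test fixture). Dynamic tree cutting
is intentionally not reimplemented; the static cut plus the minimum-size
filter (unassigned genes → "grey") plus eigengene merging (merge while any
pair of module eigengenes correlates ≥ 1 − mergeCutHeight, default 0.75)
is the testable contract, and module counts on real data are data-dependent
under any cutter.

A module eigengene is the unit-norm first right-singular vector of the
gene-standardized module submatrix, sign-fixed to correlate positively with
the module's mean expression profile. Module–trait correlation is Pearson r
with a two-sided t test on n−2 df; two-level categorical traits are coded
0/1 in sorted level order; constant traits yield r = 0, p = 1 with a
degenerate flag.

## Survival

Kaplan–Meier estimation and the unweighted log-rank test are delegated to
lifelines and adapted to the pipeline's record containers; tied events and
censorings at the same time count the events first. Cohorts are
dichotomized at the covariate median — strictly above goes "high", ties go
"low" — with an optional quantile cut. The gene-by-gene prognostic screen
reports *raw* per-gene log-rank p-values and flags genes at p < 0.05; no
multiplicity adjustment is applied, and the output carries an explicit note
to that effect (callers can feed the p column to `bh_adjust`).

## Single-cell scoring

Counts are CPM-scaled and log2(1+x)-transformed per cell — minimal and
rank-preserving within a cell, so per-cell ES values are invariant to
sequencing depth. Zero-count cells are dropped with a warning. Indices are
computed per cell with joint normalization across all cells of the call,
then summarized per subcluster (median, IQR). Scoring is per cell rather
than pseudobulk because per-cell values are what admit the displayed
significance tests; clustering itself is out of scope — subcluster labels
are required input. The omnibus test is tie-corrected Kruskal–Wallis;
pairwise BH-adjusted rank-sum tests are computed only when the omnibus
rejects at 0.05, with BH spanning all pairs jointly. Subclusters under 3
cells are excluded with a warning.

## Synthetic data

The bulk generator emulates a three-cell-line (PLC/KMCH/Huh7), two-arm
(control/curcumin), three-replicate microarray design: per-gene baselines
Normal(7,1) on the log2 scale (array-like log intensities), additive
treatment effects on a planted DE gene set (magnitudes uniform in [2,3]
log2 units by default — at least 4-fold — with random sign so up/down
counts balance), co-expression blocks via shared latent factors (loading
chosen so the within-block correlation equals the requested strength), and
additive index-component shifts per (cell line, arm) in units of the noise
SD (default 0.5). One common DE gene set applies across all lines, so the
cross-line intersection has a planted truth. The single-cell generator
draws negative-binomial counts (shared dispersion, default 0.5) with
log-normal library sizes and per-subcluster multiplicative shifts on the
index-component means, 16 subclusters by default. The survival generator
draws exponential event times with hazard h₀·exp(β·x) for x ~ N(0,1) and
independent exponential censoring whose rate is solved numerically to hit
the target censoring fraction.

What these generators do *not* emulate: real marginal intensity
distributions, batch effects, probe-level artifacts, gene-specific
dispersions, doublets or ambient RNA. Passing recovery tests therefore
demonstrates the pipeline's statistical correctness under its stated model,
not fidelity to any particular public dataset.

## Numerical choices and problem sizes

- Ranking ties break by gene id; all stages are deterministic under a fixed
  seed, and the pipeline re-run on the same config is byte-identical.
- p-values are clamped into (0, tiny..1]; degenerate inputs (constant
  vectors, all-tied groups) return flagged p = 1 results rather than
  errors where a rectangular output matters.
- The exact rank-sum path caps at combined n = 12 — beyond that the
  enumeration grows combinatorially while the tie-corrected normal
  approximation is already within 0.02 of exact (tested).
- Duplicate gene rows collapse to the highest-mean row at load, the common
  microarray convention; loaders reject missing values by default with an
  opt-in drop.
- Test and acceptance runs use deliberately modest sizes — hundreds to a
  few thousand genes, tens of samples, a few hundred cells, 50–200
  replicate loops — chosen so the whole suite completes in seconds while
  keeping the Monte-Carlo bands (e.g. null rejection 2–8% at 200 reps)
  informative.

## Known limitations

- Unsigned networks only; no signed adjacency, no blockwise processing for
  very large gene universes.
- No array preprocessing/normalization, GEO/SRA retrieval, probe
  annotation, clustering/UMAP, or GO/pathway annotation — inputs are
  assumed preprocessed and labelled.
- The weighted-ES monotonicity caveat above.
- The prognostic screen's raw-p convention matches per-gene screening
  practice but inflates family-wise error by design; downstream users
  should adjust when making gene-level claims.
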
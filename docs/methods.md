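# Methods

## Scope and data model

The package screens a *cohort* — an aligned pair of a genes × samples
expression matrix and a clinical table with overall-survival time
(months, > 0) and event indicator — through a cascade of filters, and
augments the survivors with copy-number, methylation, mutation and
single-cell evidence.  All inputs are plain-text: TSV matrices (genes
as rows), GCT v1.2 as an alternative for expression, MatrixMarket plus
barcode/feature/label TSVs for single-cell counts.  Duplicate gene rows
are collapsed by keeping the highest-mean row (a deterministic stand-in
for the many collapse conventions in circulation); missing expression
values are allowed and all downstream statistics use pairwise-complete
observations.  Readers validate rather than coerce: out-of-range
copy-number states, β values outside [0,1], non-positive survival times
and unlabeled barcodes are errors, not warnings.

## Immune scoring

The immune score is single-sample GSEA: within sample *j*, genes are
ranked by descending expression (average ranks for ties; missing values
rank last), and a running sum walks the ranking accumulating
`P_hit − P_miss`, where `P_hit` grows by `|rank|^α` (normalized over the
signature) at signature genes and `P_miss` by a uniform step elsewhere;
the score is the sum of the running sum over all positions.  The score
therefore depends on expression only through within-sample ranks, which
the tests exploit as an invariance (any strictly monotone per-sample
transform leaves scores unchanged).  Ties in the walking order are
broken by gene id so the score is invariant to input gene order.
α defaults to 0.25, the common ssGSEA weighting.  Signature gene lists
are user-supplied (GMT or plain list); no fixed signature is bundled,
because published signature lists are licensed data while the scoring
computation is not.  Stratification: "high" means strictly above the
cutoff; the cutoff is the median (or, in quantile mode, the (1−q)
quantile, so q is the fraction targeted for the high group); samples
exactly at the cutoff go to "low".  A sample with constant expression
carries no rank information and scores 0 with a warning.

## Survival statistics

`km_estimate` is the Kaplan–Meier product-limit estimator over distinct
event times; censored observations at an event time remain at risk at
that time (the standard convention).  `logrank_test` is the two-group
Mantel–Cox test: at each event time the expected events per group are
`d_t·n_g/n_t` with the hypergeometric variance, χ² = (O−E)²/Var on 1 df.
Zero events (or zero variance) short-circuits to χ² = 0, p = 1,
direction "none".  The direction call is `high_worse` when the
designated high group observes more events than expected — a
deterministic rule that needs no hazards model.  The per-gene screen
splits each gene at its median (configurable quantile), excludes
missing-expression samples, records constant or degenerate genes as
*skipped* rather than failing, and gates on raw p < 0.05 by default;
Benjamini–Hochberg q-values are available by flag.  The unadjusted
default reflects how this class of genome-wide prognostic screens is
typically gated; the type-I cost is quantified by the null-calibration
test rather than hidden.  BH-FDR delegates to statsmodels; Pearson
correlation (r plus two-sided t-distribution p on n−2 df) delegates to
scipy; both sit behind the module surface so the screening code treats
them as primitives, and the tests check them against brute-force
definitions.

## Differential expression

The immune-high vs immune-low test is an empirical-Bayes moderated t.
Per gene, the pooled two-group variance s²_g has d_g = n_h + n_l − 2 df.
Because log s²_g of normal data follows a shifted log-χ² with known
digamma/trigamma moments, matching the observed mean and variance of
e_g = log s²_g − ψ(d_g/2) + log(d_g/2) across genes yields the prior
(d₀, s₀²); the trigamma inversion uses Newton iterations (tolerance
1e-8, ≤ 50 iterations).  When the excess variance is non-positive the
prior df is infinite (complete shrinkage to s₀²); when estimation is
impossible (fewer than two genes with positive variance) the model
falls back to d₀ = 0 — the ordinary pooled t — with a warning.  The
moderated variance s̃²_g always lies between s²_g and s₀², and the
statistic interpolates between the pooled t (d₀ = 0) and a z-like
common-variance statistic (d₀ → ∞); both limits are property-tested and
the full quantity set is cross-checked against Bioconductor limma.
Genes with zero variance in both groups get p = 1 when the fold change
is zero and are flagged otherwise.  DEG selection keeps both tails:
|log2FC| > log2(1.5) and p < 0.05.

For bulk RNA-seq quantification the package computes
FPKM = fragments / (mapped reads in millions × exon length in kb).
One upstream description prints this formula with the length factor in
the numerator; that literal reading contradicts the quantity FPKM is
universally defined to be, so the standard definition is implemented.
The bulk DEG gate uses fold change on linear FPKM group means with a
1e-6 pseudocount (FC > 2 or FC < 0.5) and a pooled two-sample t on
log2(FPKM + 1) — for two groups this is exactly the F test between
nested linear models (F = t²).

## Multi-omic evidence gates

"Duplication" is thresholded copy-number state > 0 (gain or
amplification), since GISTIC-style calls do not expose the underlying
cutoff.  CNV–expression concordance is Pearson r over shared samples
with BH-FDR across the tested gene set; the flag requires q < 0.05 and
r > 0.  Methylation evidence is per-probe Pearson r between β and
expression; the gene-level flag requires at least one probe with r < 0
at q < 0.05, with the FDR pool defaulting to *all* probes tested in the
analysis (configurable to per-gene).  Probe-level survival splits β at
the median and reports low- vs high-methylation-worse.  Mutation
presence is binary per (sample, gene) — any variant class counts —
giving a mutated-sample fraction and a mutated-vs-unmutated log-rank.
Every per-gene precondition failure (constant layer, too few samples in
a group) is a recorded skip, not an error, so one degenerate gene never
aborts a screen.

## Cascade and nomination

Stages run in order: score → stratify → moderated-t DEG → survival
screen restricted to the DEG set → direction classification
(IBG/IHG) → k-of-n cross-cohort validation with direction consistency
(defaults k = 1, consistency on; both configurable because replication
rules of this kind are rarely pinned down precisely) → omics gates and
single-cell specificity on the credible harmful set (cIHG by default; a
flag screens the beneficial side symmetrically).  Candidates are ranked
by the unweighted count of five boolean evidence flags — CNV
concordance, duplication-worse survival, negative methylation probe,
low-methylation-worse probe survival, specificity ≥ 0.5 — with ties
broken by CNV–expression r then gene id.  Equal weighting is
deliberate: the evidence layers are qualitatively different and any
learned weighting would be unidentifiable at these scales.  Set
inclusions (DEG ⊇ IPG ⊇ IBG∪IHG ⊇ cIPG ⊇ candidates) are asserted on
every run, and the JSON report is byte-deterministic given inputs,
config and seed.

## Single-cell stage

QC metrics are total UMI, detected genes (strictly positive entries)
and mitochondrial fraction (0 for an empty cell).  Removal uses strict
inequalities — below 2000 UMI, below 500 genes, above 10% mitochondrial
counts, or (above 40,000 UMI AND above 5000 genes) for doublets — so
cells sitting exactly on a threshold are kept; most toolkits default to
≤/≥, which is why the boundary semantics are spelled out and tested.
Normalization scales each cell to 10,000 counts and applies natural
log1p (the target sum and natural log are the common library-size
conventions; the choice only shifts scores monotonically).  The
mitochondrial set defaults to the "MT-" prefix rule.  Cell-type labels
are inputs: clustering and annotation are out of scope.  Specificity of
a gene is max per-label mean / sum of per-label means (ε = 1e-9), in
[1/k, 1] for k labels; ties go to the lexicographically first label and
are flagged.

## Synthetic cohorts

The generator is the package's test bed and defines its study
conditions.  Per sample a latent immune factor u ~ N(0,1); expression
x_g = a_g·u + N(0,1) + 8 on a log2-like scale, with a_g = 1.2 for the
40 signature genes, a_g = 0.6 for planted prognostic genes (so they
pass the DEG gate) and 0 otherwise.  Survival is exponential with
log-hazard β₀ + Σ β_g·z_g + Σ log(HR)·carrier over planted genes
(z standardized expression), baseline median 50 months; censoring is
independent Uniform(0, c) with c calibrated by bisection to the target
fraction (default 60%, typical of lung-adenocarcinoma overall
survival).  Because planted genes share the immune factor, the factor
carries the *sum* of their coefficients; the default truth therefore
balances 6 beneficial (β = −log 2.2) against 6 harmful genes
(β = log 2), with the fully-planted checkpoint at β = log 3 —
otherwise every gene's marginal direction would be dominated by the
shared factor rather than its own sign.  Discovery n = 400 with four
validation cohorts of 133/133/132/132 (530 cases in total).

Copy-number states come from a Gaussian copula: a latent variable
correlated with standardized expression is thresholded at fixed normal
quantiles; the latent correlation is inflated by the numerically
computed discretization attenuation so the realized Pearson correlation
lands near the target ρ (recorded per gene; targets |ρ| > 0.95 are
rejected as unreachable).  Methylation probes are
β = logistic(b₀ − c·z + 0.8·ε) with c set from the target negative
correlation; 2–4 promoter probes per planted gene plus one null probe
for each of 50 background genes.  Mutation carriers for planted
prognostic genes are drawn at cohort generation (fraction 0.3, hazard
ratio 2) so their hazard effect is consistent with the survival data;
background genes mutate at 2%.  The single-cell generator gives each
cell type a gamma-weighted profile over the gene universe padded with
1500 filler genes (so detected-gene counts sit realistically above the
QC floor), fixes mitochondrial mass at 3%, expresses each planted
specific gene at ~5% of reads in its mapped type and ~1000× less
elsewhere, and injects labeled low-UMI, high-mitochondrial and
doublet-like cells with the injection truth returned for QC tests.
All generators are pure functions of (parameters, seed); child seeds
derive from the master via `SeedSequence`.

### What the generator does not emulate

Real cohorts have batch effects, non-proportional hazards, correlated
gene blocks beyond one immune factor, platform-specific noise, CNV
segments spanning many genes, and cell-type compositions far richer
than four balanced populations.  Passing tests therefore demonstrate
that the *machinery* is correct and calibrated under the stated model,
not that any particular gene list from real tumors is right.  Headline
counts from real multi-cohort analyses additionally depend on
preprocessing choices that are not part of this package's contract.

## Problem sizes and numerical choices

Test and acceptance workloads are sized for a single desk run: null
calibration at 200 samples × 1000 genes, power at 400 samples × 50
planted genes × 10 seeds, CNV recovery at 300 samples × 1000 genes, and
the full cascade at the default bundle (400 + 530 samples, 500 genes,
~625 cells).  Tolerances: exact identities are asserted to 1e-10–1e-12;
Monte-Carlo comparisons use binomial confidence bounds; the log-rank
permutation check allows 4 MC standard deviations plus 0.03 for the
χ²-approximation error at n = 10.  Fold-change pseudocount 1e-6;
specificity ε = 1e-9; trigamma-inversion tolerance 1e-8.

## Known limitations

No Cox regression or covariate adjustment; no optimal-cutpoint
scanning (median splits only); no probe-level methylation
preprocessing; no mutation-class filtering (silent variants count
unless removed upstream); no doublet simulation beyond the UMI/gene
rule; validation treats cohorts as exchangeable and ignores platform
differences.  The k-of-1 validation default is permissive by design —
its false-pass rate under null validation cohorts is itself measured in
the test suite.
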
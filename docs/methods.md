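# Methods

This note documents the models implemented in `methatlas`, the defaults
and why they were chosen, the numerical decisions, and what the
synthetic benchmarks do and do not demonstrate.

## Promoter summarization

Bulk Illumina-style beta matrices are summarized from probes to gene
promoters as the mean beta over the probes annotated to the gene's
TSS200 region (200 bp upstream of the transcription start site); genes
without any TSS200 probe carrying data fall back to their first-exon
probes, and the region class actually used is recorded per gene.
Missing probe values are excluded from the mean, never imputed as zero.
The fallback order is strict: when a probe maps to the same gene under
both region classes, the TSS200 assignment wins. Illumina-style
manifests with semicolon-separated multi-gene annotations are exploded
so that a probe shared by several genes contributes to each gene's
promoter mean; the alternative (exclusive assignment) would silently
drop information and there is no principled tie-break between genes.

## Expression reference

Marker genes per cell type are found with one-vs-rest Wilcoxon rank-sum
tests (one-sided, greater in the target type; normal approximation with
tie correction, since single-cell zero inflation makes exact tests
infeasible), BH-FDR per cell type across genes (default threshold
0.05). The marker specificity score (MSS) of a gene for a target type
is the number of *other* types whose median expression is zero; a
perfect marker attains MSS = K − 1. Selection starts at MSS = K − 1 and,
when fewer than 100 markers qualify (fewer markers make the downstream
regression noticeably noisier), relaxes the threshold one step at a
time down to ceil((K − 1)/2) — a schedule chosen so relaxation can never
admit genes expressed in most cell types. Each marker's target type is
the type with maximal median expression, ties broken by smaller
Wilcoxon p then lexicographic type name, so outputs are deterministic.
The reference entry is the median expression over the cells of a type.

Validation of a reference in an independent labeled dataset assigns
each cell the arg-max of its estimated fraction vector (unweighted
robust regression of the cell's marker expression on the reference
columns) and reports overall and per-type accuracy with the full
confusion matrix. Arg-max assignment accuracy is our
operationalization of "validation accuracy"; a cell of a type missing
from the reference still receives an arg-max and can only be recognized
by its low maximal fraction.

## Imputation of the DNAm reference

Only *imputable* markers are retained: genes whose promoter beta and
expression have Pearson r ≤ −0.3 in **both** of two independent matched
compendia. The −0.3 / both-datasets rule is a conservative
operationalization of "strongly anticorrelated" and is exposed as a
flag (`rho_max`). Where a marker is expressed in a cell type, its
promoter beta is imputed as exactly 0 (high expression implies an
unmethylated promoter). Where it is silent, the imputed value is the
mean of the high-methylation component of a two-state gamma mixture
fitted to the gene's pooled cross-sample compendium betas: across the
compendium, samples expressing the gene populate a low-methylation
state and silent samples a high-methylation state, and the mixture
separates the two. Fitting on the full distribution (rather than on a
low-expression subset) is deliberate: restricting first makes the input
unimodal, and a two-state fit on unimodal data splits the single mode
and biases the high-component mean upward.

Mixture EM details: components ordered by increasing mean (the
high-methylation state is by convention the larger-mean component);
zeros shifted by ε = 1e−4 because the gamma support is (0, ∞); M-step
solves the weighted gamma likelihood exactly (shape from the digamma
equation by bracketed root finding), so the log-likelihood is
non-decreasing by construction; initialization splits the data at the
median (extra seeded restarts split at random quantiles); at least 20
observations are required, and degenerate all-identical input is an
error.

Marker weights: weight(g) = mean imputed beta over the cell types where
g is *not* expressed, clipped to [0, 1]. A marker whose silent-state
promoters are convincingly methylated (weight near 1) discriminates
well; one whose silent-state betas are low is uninformative and is
downweighted. Markers expressed in every type carry weight 1 by
convention (there is no silent state to judge them by). This
mean-over-unexpressed-types rule is our reading of "weighted according
to the imputed DNAm value"; the exact formula used elsewhere is not
published in a closed form.

## Weighted robust deconvolution

Per bulk sample, the marker-beta vector is regressed on the K reference
columns without an intercept (the columns span the mean structure and
the coefficients are fraction-like), with the marker weights entering
as observation weights — multiplying all weights by a constant leaves
the solution unchanged. The default loss is Huber's M-estimator with
tuning constant k = 1.345 (the standard 95%-efficiency choice; the
estimator is solved by iteratively reweighted least squares, scale
re-estimated each iteration by the normalized median absolute
deviation, at most 50 iterations, coefficient tolerance 1e−8, with an
early exit on a perfect fit). Squared loss is available via
`robust=False`; on noise-free data the two coincide. Estimated
coefficients are projected to fractions by zeroing negatives and
rescaling the rest to sum to one; if every coefficient is non-positive
the sample gets a documented all-zero row and a warning. Markers
missing in a sample are dropped for that sample only. A rank-deficient
reference (e.g. two identical cell-type columns) is rejected with the
collinear types named — note that per-sample missingness patterns that
remove *all* markers of one type make that type unidentifiable even
when the full reference has full rank.

## Single-nucleus reference derivation

Single-nucleus methylomes arrive as Bernoulli calls (0/1) per CpG and
nucleus. CpGs with reads in fewer than 5 nuclei are dropped; per gene
and nucleus, the promoter beta is the mean of the covered calls over
the gene's TSS200 CpGs (missing where nothing is covered). Markers per
cell type are genes with at least 10 non-missing target-type values,
Wilcoxon FDR < 0.05 (alternative: lower methylation in the target
type), ranked by AUC descending, top 20 kept. The AUC comes from the
Mann–Whitney U with tie correction, oriented so that AUC near 1 means
lower methylation in the target type. Reference entries are mean betas
over the non-missing nuclei of a type, with unit weights; the rare
(gene, type) cell with no covered nucleus at all is filled with the
uninformative value 0.5. Upstream sequencing QC (e.g. excluding
mitochondrial cytosines by total-read filters) is treated as the data
producer's responsibility.

Two references are compared over their shared (gene, type) entries by
median absolute deviation and Pearson correlation. The permutation
null shuffles gene rows of the second reference — not individual
entries — preserving each cell type's marginal distribution; p-values
use the add-one rule p = (1 + #null ≥ obs)/(1 + n_mc) so p is never
zero, with exhaustive enumeration available for tiny marker sets. The
per-marker hypomethylation check is a one-tailed Welch t-test of a
marker's promoter betas in its own type versus all others, BH-adjusted
across markers.

## Cell-type-specific differential methylation

Per site, ordinary least squares of the beta vector on the K fraction
terms, the K fraction × phenotype interactions, and covariates
(categoricals one-hot encoded dropping one level). There is no global
intercept: fractions sum to one, so an intercept would be perfectly
collinear and the μ_ck terms absorb it — which is also why adding a
constant to a site's betas changes only the μ_ck estimates, never the
interactions. Interaction t-tests use the residual variance per site;
BH-FDR is computed per cell type across sites (DMCT counts are reported
per cell type, so pooling would mix different null scales); a site is a
DMCT for type k when FDR < 0.05, with direction from the sign of the
interaction coefficient (positive = hypermethylated in cases). A cell
type with near-zero fraction variance is reported with a collinearity
warning rather than dropped. Locus enrichment is a one-tailed Fisher
exact test of the 2×2 hit × in-locus table over a declared background;
pairwise overlap tests are provided, multi-set intersection p-values
are not.

## Derived scores

Tumor purity is 1 − Σ stromal fractions, clipped to [0, 1] (clipping is
our decision for the rounding case where stromal sums slightly exceed
1); the total immune score is Σ immune fractions. Which cell types
count as stroma or immune is user-supplied configuration, since the
choice is tissue-specific. The two-phenotype proxy panel keeps
differential markers (Wilcoxon FDR < 0.05, median > 0 in one phenotype
and 0 in the other) whose promoter beta exceeds 0.6 in at least 3 of
the other cell types' profiles — hypermethylation there guards the
proxy against contamination by those types — and scores a bulk sample
as the mean TSS200 beta over the panel. The sign convention is recorded
in the panel: higher panel methylation means a *lower* fraction of the
phenotype the markers belong to.

## Synthetic data

The generators are pure functions of a config and a mandatory seed, and
default to a brain-like regime: K = 6 cell types, 100 markers per type
(600 total, above the 100-marker guideline), 400 background genes, 100
cells per type, 200 bulk mixtures with Dirichlet(1) fractions,
truncated-Gaussian beta noise of sd 0.05, planted marker betas 0.1
(own type) / 0.9 (others), a compendium silent-state beta of 0.8, a
nucleus call coverage of 0.1 (90% missingness), and an EWAS of 200
samples × 1,000 sites with a planted interaction effect of 0.2 and
residual sd 0.05. Scales not fixed by the study design (background
gene count, cells per type, compendium size of 120 samples, 3 CpGs per
gene, 300 nuclei per type, the age-confounder slope of 5e−4 beta/year)
were chosen once as realistic desk-scale values and are config fields.

What the generators emulate: block-structured marker specificity,
paired expression/methylation anticorrelation with a gamma-distributed
silent state, simplex-distributed mixing, Bernoulli promoter calls with
uniform random missingness, and the interaction-model EWAS with an
i.i.d. Gaussian error term. What they do not emulate: array probe
artifacts and type-2 bias, correlated or coverage-biased missingness,
batch structure, cell-type-correlated confounders, overdispersed or
spatially correlated noise, and closely related cell types with shared
markers. Passing benchmarks therefore demonstrates correctness of the
estimators under the stated generative assumptions, not performance on
real cohorts. Beta noise is truncated Gaussian rather than
logit-normal for simplicity; at sd ≤ 0.05 the clipping mass is
negligible.

## Benchmark problem sizes

The bundled benchmarks run at the defaults above: fraction recovery on
200 mixtures (noiseless per-type RMSE < 0.02, noisy < 0.05); the
corruption-tolerance experiment on an 11-point grid q ∈ {0, …, 0.5}
with 10 replicates per point (22,000 sample regressions total);
CellDMC operating characteristics on 2,000 null sites and on 1,000
sites with 50 planted effects at n = 200; and marker recovery on the
600-marker expression simulation and the 120-marker nucleus simulation.
Oracle checks (pair-enumerated U/AUC, normal-equation OLS,
hypergeometric Fisher tails, exhaustively enumerated permutation
p-values) run on toys small enough to enumerate.

## Known limitations

Imputation is promoter-centric; enhancer methylation is out of scope.
The imputable-gene screen typically retains only 10–30% of markers, so
closely related cell types can end up under-marked. Estimated
fractions are best interpreted as relative quantities comparable across
samples. The single-nucleus pathway assumes nucleus annotations are
given; clustering and annotation are upstream concerns.
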
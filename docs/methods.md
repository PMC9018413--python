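# Methods

This note records the models behind each stage, the tunables that
matter, what the synthetic generators do and do not emulate, and the
design choices made where the design was genuinely open.

## Bulk cell-signal deconvolution

Each bulk count vector *b* over *G* genes is modeled as
*b_g ~ Poisson(N·λ_g)* with *λ = P f + f₀ u*, where *P* is the
genes × types matrix of reference frequency profiles (columns sum to 1),
*u* is a **flat intercept profile** (1/G on every gene), *N = Σ b*, and
*f, f₀ ≥ 0*. The fit maximizes the weighted log-likelihood
Σ_g w_g (b_g log λ_g − λ_g) by multiplicative (fixed-basis KL-NMF)
updates, which are monotone — the implementation asserts a
non-decreasing objective every iteration. Initialization spreads the
total equally over components (deterministic, no randomness);
convergence is a relative log-likelihood change < 10⁻⁸ with a 10⁴
iteration cap (non-convergence is flagged, not fatal). Reported
fractions are normalized so reference weights plus intercept sum to 1.

Choices made here: the intercept profile is uniform (any transcript
mass the reference cannot explain is absorbed without favoring specific
genes); per-gene weights default to 1 and an optional weights TSV is
accepted as an opaque input; gene universes are aligned by id
intersection with a ≥ 500 shared-gene floor (configurable — the
synthetic demos use smaller universes). Profiles are built from **raw**
counts (summed per type, normalized to frequency) because the
likelihood is on counts; log-normalization is used only by the matcher.

The ELP ratio is (f_ELP + ε)/(Σ later-B + ε) with later-B =
{pre-pro-B, pro-B, pre-B, naive-B} and ε = 10⁻⁶ purely to keep the
ratio finite when later-B signals vanish.

## Per-cell logistic matching

One-vs-rest elastic-net logistic scorers (mixing α = 0.99, i.e.
lasso-dominant) are trained per reference type on log-normalized
expression (counts scaled to 10,000 per cell, log1p). One-vs-rest
rather than a grouped multinomial fit is deliberate: per-type sigmoid
scores justify independent > 0.8 / < 0.2 similarity bands and allow a
cell to match nothing. The penalty strength is selected by
cross-validated deviance over a logarithmic grid spanning two decades
below the all-zero-coefficient edge (the glmnet-style path; the default
grid has 20 values and 10 folds, the tests and demos use smaller grids),
picking the minimum without a one-standard-error rule. Class imbalance
is handled by inverse-frequency observation weights **for the
coefficients only**: the fitted intercept is then shifted by
logit(prevalence) (standard case-control prior correction) so that a
cell expressing none of a type's discriminative genes scores its true
base rate (≈ 1/K, well inside the dissimilar band) rather than 0.5.
Query genes are aligned by id; model genes missing from a query are
imputed as zero and logged.

Cancer/noncancer cluster assignment from immunophenotype panels is a
share rule: a cluster is cancer iff ≥ 50% of positive-panel genes have
cluster-mean normalized expression above the threshold and no normal
lineage panel reaches that share; both the share and the expression
threshold are configurable.

## Somatic phylogeny of the remission/ALL/AML trio

**Germline filter.** One-sided exact binomial test of alt count against
heterozygous expectation (p₀ = 0.5 diploid autosomes; 0.95 on X/Y in XY
cases), lower tail — somatic variants present as sub-heterozygous in a
normal-containing sample. P-values are BH-adjusted across variants;
q ≥ 10⁻⁵ flags germline. Two pooling modes exist: `normal` (default)
tests the remission sample only; `all` pools the trio. The default is
`normal` because in a three-sample trio at ~40× a variant clonal in
both tumors but absent from remission has pooled VAF ≈ ⅓, which the
pooled test cannot separate from heterozygosity at q < 10⁻⁵ — the
normal-only test keeps full power for exactly those
leukemia-common variants while mosaic embryonic variants (remission VAF
well below 0.5) still pass. Sites with zero normal coverage cannot
reject germline and are flagged conservatively.

**Depth filter.** Mean depth across samples within [20, 60] for
autosomes and [10, 30] for X/Y (closed ranges); outside is flagged.

**Site error model.** Per site, counts across the trio are fit by a
beta-binomial with mean fixed at the pooled VAF and overdispersion ρ
maximized on a 101-point logarithmic grid over [10⁻⁶, 0.89]
(parameterization a = μ(1−ρ)/ρ, b = (1−μ)(1−ρ)/ρ). Recurrent
low-level noise affects every sample at a shared small rate and is
nearly binomial (small ρ); genuine somatic variants present in a subset
of samples force large ρ. The artifact call is ρ < 0.1 **and** pooled
VAF ≤ 0.1: the second clause encodes that site-specific error
processes are low-level by definition, and protects variants carried by
all samples at substantial VAF (e.g. embryonic mosaics that are clonal
in both tumors) whose across-sample dispersion alone can sit near the ρ
threshold with only three observations. Sites with no alt reads
anywhere are "absent" without a fit.

**Branch assignment.** Presence in a sample = alt ≥ 3 reads (the
presence threshold is configurable) at a site retained by every filter.
Patterns map: all three samples → embryonic; both tumors only →
leukemia-common; one tumor → that tumor's private branch; any pattern
containing remission but not both tumors → inconsistent (flagged, not
counted). Copy number: diploid and single-copy (XY sex chromosome)
cases are handled; the clonal target VAF generalizes as
purity·m/(purity·CN + 2(1−purity)) and is exposed, but copy-number
calling itself is an upstream input.

**Clonality.** Binomial mixture over variant alt/total counts fitted by
EM for K = 1..5 with five seeded initializations (VAF quantiles plus
jitter), best-likelihood run kept per K, and K chosen by
BIC = −2·loglik + (2K−1)·ln n. EM monotonicity is asserted; a decrease
is treated as an internal error. A component is clonal when its
probability is within ±0.05 of the purity-adjusted heterozygous VAF,
subclonal when below that band (a component above the band is labeled
"superclonal" and left for the analyst).

**Timing.** A branch with n substitutions at a minimum rate of 0.9
substitutions per cell division corresponds to at most n/0.9 divisions.

## Mutational signature refitting

96-channel spectra are fit by multinomial maximum likelihood
(equivalently, minimal KL divergence) using the same multiplicative
update machinery as the deconvolution — a deliberate choice over least
squares, since mutation counts are multinomial draws. Stage 1 fits the
whole catalog; signatures below the 2% retention fraction are dropped
and the retained set refit. When the spectrum's total count is below
100, blocklisted signatures (defaults: ultraviolet SBS7a,
mismatch-repair SBS6 — biologically implausible C>T explanations of
sparse spectra) are removed and the fit re-run. A 10⁻⁹ probability
floor keeps restricted catalogs full-support. Degenerate case: if no
signature reaches the retention fraction, the single largest
contributor is kept rather than returning an empty model.

## Core transcriptome

**Differential expression** runs on pseudobulk replicates (raw counts
summed per group): median-of-ratios size factors (library-size fallback
when fewer than 10 genes are expressed everywhere); per-gene
method-of-moments NB dispersion shrunk 60% on the log scale toward a
fitted a₁ + a₀/μ mean-dispersion trend; a per-gene NB GLM with a group
indicator and log size-factor offset; and a Wald test on the log2 fold
change referred to a t distribution with residual degrees of freedom (a
small-sample correction for the estimated dispersions — with the
asymptotic normal reference the null is visibly anticonservative at
five replicates). Significance is padj < 0.05 and |log2FC| > 1
(absolute value; the threshold is two-sided). All-zero genes are
reported NA. Under a simulated global null (2,000 genes, 5 vs 5, NB
θ = 10) the p-value distribution is uniform to a KS statistic ≤ 0.05;
with 100 planted 4-fold changes the test recovers ≥ 70% at empirical
FDR ≤ 0.15 — both checked in the suite.

**Enrichment** draws the core-set size from the universe without
replacement (hypergeometric sampling) and reports three p-values: the
empirical tail (1 + #{null ≥ obs})/(reps + 1), which saturates at
1/(reps+1); a t-statistic comparison of the observed overlap with the
null sample; and the exact hypergeometric tail as the analytic
cross-check. The three agree on moderate effects; for extreme effects
only the hypergeometric tail is informative.

**Lineage specificity**: a gene is tagged to a lineage iff expressed
(normalized value > 0) in ≥ 25% of cells of some type in that lineage
and ≤ 5% of cells of every outside type; genes on in several lineages
are "shared". The on/off fractions are explicit, configurable choices —
dot-plot-style published figures do not pin them down.

**Marker pairs**: the full cross of myeloid-tagged × lymphoid-tagged
surface markers; per cluster, the coexpression level is the mean over
cells of the product of the two genes' normalized log values and the
coexpressing fraction is the share of cells with both > 0.

## Synthetic data: what it emulates, what it does not

The atlas generator draws negative-binomial counts (variance
μ + μ²/θ, scalar θ = 10 by default — realistic over-dispersion) from
per-type programs over a shared gene universe, with uniform library
sizes in [2,000, 8,000] and ~5% mitochondrial mass; the demo atlas
arranges a B-lineage gradient (HSC → LMPP → ELP → pre-pro-B → pro-B →
pre-B → naive-B) with half-block overlap between adjacent stages plus
myeloid and T types. Bulk samples are Poisson draws from known mixtures
at a chosen depth; the "unexplained" component uses an independent
sparse gamma-shaped program never shown to the fitter, mirroring an
out-of-reference cell state. Not emulated: doublets, ambient RNA, batch
effects, gene-length or GC bias, or read-level data — so passing tests
demonstrate correctness of the estimators under the stated generative
models, not robustness to those real-data artifacts.

The variant-table generator plants branch structure (defaults 2
embryonic, 6 leukemia-common, 30/40 private substitutions, purity
0.95), germline sites at VAF 0.5 (0.95 on X/Y for XY cases), and
recurrent artifact sites at a shared 0.002 error rate, drawing
binomial reads at per-site Poisson depths. Two coverage/VAF choices
were made by power analysis of the downstream thresholds (q < 10⁻⁵,
alt ≥ 3, depth ∈ [20, 60]) and are deliberate study conditions, not
free dials: the remission sample is simulated at 1.8× and each tumor
at 0.75× of `depth_mean` (trio mean ≈ the nominal depth), and the
embryonic mosaic VAF in remission defaults to 0.125. At 40× flat
coverage no mosaic VAF lets an embryonic variant simultaneously clear
the presence threshold (alt ≥ 3) and stay separably below heterozygous
expectation — deeper normal coverage is exactly what a sequencing
design aimed at early-embryonic mosaics would specify. Even so, exact
branch recovery is a tail event away: across seeds roughly 96% of
simulated trios reproduce the planted counts exactly; the residual
misses are single binomial-tail events at the presence or germline
boundary, not estimator errors.

Signature spectra are multinomial draws from mixtures of a synthetic
catalog (sparse Dirichlet columns, clearly separated); the catalog is a
labeled synthetic stand-in with COSMIC-style layout, and any real
catalog CSV in that layout loads directly.

## Numerical details and degenerate inputs

Multiplicative updates floor rates at 10⁻¹²; EM clips binomial
probabilities to [10⁻⁶, 1−10⁻⁶] and renormalizes weights; beta-binomial
fits clip μ identically. Zero-total cells must be removed by QC before
normalization (error); zero-count spectra and empty queries are
rejected; an empty QC result warns rather than errors. All generators
and fits are deterministic given their seeds; the only intentional
nondeterminism anywhere is the seed itself.

## Known limitations

The deconvolution objective is Poisson (no extra-Poisson bulk noise
term); the matcher's probabilities are not calibrated across types
beyond the prior-corrected intercept; the site-error model sees only
three samples, so its ρ estimate is coarse (hence the pooled-VAF
clause); the DE test is a documented stand-in for heavier
empirical-Bayes machinery and does not moderate log-fold-changes; and
the clonality EM assumes a shared purity and diploid copy number per
run.
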
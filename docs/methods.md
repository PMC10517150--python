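# Methods

## The phenotype and its models

The trait is a self-reported, 4-level ordinal balding pattern recorded at
up to four visits.  Because androgenetic hair loss is progressive, the
reconciliation step treats any later visit reporting a strictly lower
pattern than an earlier one as an implausible improvement.  When that
happens the rules are purely count-based: with exactly two visits and a
one-step gap the higher pattern is used; with three visits a pattern
recorded exactly twice; with four visits a pattern recorded exactly three
times; otherwise the sample is excluded.  Two readings of the source rules
were genuinely open and are resolved here as follows: "improvement" means
*any* later-lower pair, not only adjacent visits; and the improvement
check runs before the count rules, so a four-visit sequence whose most
recent value is its maximum but which dipped in between still goes through
the count rules.  The selected pattern is always one actually recorded.
Case age is the lowest age at which the selected pattern was recorded;
control ages are the highest age at pattern 1 (all/continuous/extreme
models) or pattern ≤ 2 (two-as-control), matching the asymmetry between a
progressive case onset and a still-unaffected control.

The four models trade power against misclassification: continuous (1–4 as
a linear response), all (1 vs 2–4), two-as-control (1–2 vs 3–4, robust to
the subjective 1/2 boundary), and extreme (pattern 4 under age 60 vs
pattern 1 at 60 or older; no age covariate because the design separates on
age).  Kinship pruning removes one member of each pair with coefficient
≥ 0.0442 (third degree), iteratively deleting the sample with most
remaining relatives; ties break toward the lexicographically smallest
sample id purely for determinism.  Pruning runs separately per model
roster.

## Variant QC

Filters run in a fixed order — sample missingness, variant missingness
(recomputed after sample removal), exact Hardy–Weinberg, subset MAF,
consequence mask — with the strict inequalities kept (< 5% missing keeps;
HWE p > 10⁻⁶ keeps; 0 < MAF < 1% keeps).  The HWE test is the exact
conditional test given allele counts, computed by the numerically stable
two-sided recurrence over heterozygote counts; the two-sided p sums all
outcomes no more probable than the observed one.  Hemizygous male-X
columns bypass the test: with a {0,2} dosage coding there are no
heterozygotes and the diploid sampling model does not apply.  MAF is
computed within each phenotype model's samples, so a variant can be rare
for one model and not another.  The consequence vocabulary distinguishes a
moderate tier (missense, in-frame indels, regulatory-region ablation), a
high tier (frameshift, splice acceptor/donor, start/stop-altering,
transcript ablation/amplification) and a no-impact class; the
nonsynonymous mask is moderate + high, and the high-impact mask is the
strict subset.

## Association tests

Single-variant tests are GLM Wald tests (OLS for the continuous response,
ML logistic otherwise) with continuous covariates standardized to mean 0,
population variance 1, categoricals one-hot with the reference dropped,
and missing dosages mean-imputed to 2×MAF.  Conditioning appends
(mean-imputed) same-chromosome lead-SNP dosages to the covariates,
dropping exactly collinear columns with a warning.  A vectorized
Frisch–Waugh scan provides the same linear results at panel scale
(agreement with per-variant fits is tested to 1e-10).

LD uses the standard D, D′ = |D|/D_max and r² on haplotypes; male X
genotypes are haplotypes directly, and unphased autosomal pairs go through
two-locus EM (at most 100 iterations, tolerance 1e-10), where the
unambiguous genotype pairs contribute g₁g₂/2 haplotypes and the double
heterozygotes split by the current odds of coupling vs repulsion phase.

The genomic inflation factor is λ = median(χ²₁)/0.4549 on a
common-variant panel.  The PC count k* is the smallest k whose λ is within
0.05 of the minimum over the candidate range: λ is a median over
correlated tests and fluctuates by roughly that much between adjacent k
even without structure, so an exact argmin would pick arbitrary large k;
the tolerance makes "flat in k" resolve to the smallest model while leaving
genuine inflation (which is an order of magnitude larger) detectable.

## Gene-collapsing tests

Gene scores follow the CADD-weighted burden construction
Sᵢ = Σᵥ w(MAFᵥ)·CADDᵥ·gᵢᵥ with w the Beta(1,25) density, w = 25(1−MAF)²⁴,
so rarer and more deleterious variants dominate.  The score column is
standardized before fitting.  For binary models the reported p-value is an
unpenalized score test of the standardized gene score against the
covariate-only logistic null; an L1-penalized logistic fit of
[score, covariates] is run alongside purely as a selection/stability
diagnostic and recorded in the result.  This choice is deliberate: a
penalized coefficient has no standard Wald inference, while the score test
needs only the null fit and is exact under the same asymptotics as the
variance-component tests.

SKAT-type tests use the score statistic
Q_ρ = (1−ρ)Σᵥ(wᵥgᵥᵀr)² + ρ(Σᵥwᵥgᵥᵀr)² on null-model residuals r, with
ρ = 0 the variance-component (SKAT) kernel, ρ = 1 the weighted burden
test.  Under the null the score vector is asymptotically N(0, Z₁ᵀZ₁) with
Z₁ the covariate-projected (and, for binary traits, variance-weighted)
weighted genotype matrix, so Q_ρ is a mixture of 1-df chi-squares with
weights the eigenvalues of R_ρ^{1/2} Z₁ᵀZ₁ R_ρ^{1/2}.  Mixture survival
probabilities are computed by moment matching (four-moment, chi-square
target) by default, or by numerical inversion of the characteristic
function as the high-precision option: Imhof's oscillatory integral is
split into smooth factors against sin/cos weights and evaluated with
Fourier quadrature, which stays accurate however many oscillations the
statistic induces.

SKAT-O takes the minimum p over the ρ grid
{0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1} and corrects for the grid
search.  The default mode uses the standard one-dimensional integration
over the burden-direction chi-square with per-ρ quantiles from the
moment-matched mixtures (ρ capped at 0.999 inside this machinery).  The
high-precision mode instead evaluates the null distribution of the min-p
statistic directly by seeded Monte Carlo from N(0, Z₁ᵀZ₁) (200,000 draws),
which removes the approximation error of the one-dimensional correction at
the cost of ~0.1 s per gene; it is deterministic for a fixed build.  A
one-variant gene reduces exactly to that variant's score test for every ρ.
For binary traits with fewer than 200 cases the asymptotics are replaced
by residual-permutation resampling; the exact small-sample machinery of
specialized binary SKAT implementations is out of scope.

Conditional gene tests rerun SKAT-O after removing named variants from the
gene; removal (rather than covariate adjustment) is the operation
implemented, and emptying the gene is flagged instead of tested.  The
gene-level significance threshold is Bonferroni alpha/n_genes, reported
also at two significant figures.

## Downstream analyses

Enrichment uses one-tailed (greater) Fisher tests over the tested-gene
background; "near locus" means any base of the gene span inside the closed
±1 Mb window of a lead SNP (1-based coordinates).  The trichosis list
shipped under `mphl_exwas/data/` is a synthetic stand-in of 65 plausible
inherited-hair-disorder symbols, not a curated clinical resource.  The
dependence analysis refits each common variant in a lead ± 500 kb window
with and without the local gene score as an extra covariate and classifies
|Δ(−log₁₀p)| < 1 as minimally impacted; a zero-variance score contributes
Δ = 0 exactly rather than a degenerate fit.

The PRS is clumping + thresholding: greedy best-p-first clumping removes
neighbors with r² > 0.1 within 250 kb (LD from the target panel), then
each threshold on a fixed grid scores Σ beta·dosage, and the best-fit
threshold maximizes the score's partial R² on a tuning split kept apart
from risk-model training to avoid leakage.  Risk models split the cohort
25–50–25: the first block estimates per-gene weights (univariate OLS
effects of the continuous response on each standardized gene score) and
collapses the gene-score matrix to one scalar; the second trains
L2-logistic models with 10-fold cross-validated regularization for each
feature set (PRS, collapsed gene score, both, each plus covariates when
supplied); the third yields AUC (Mann–Whitney rank form, identical to
trapezoidal ROC integration) and trapezoidal average precision for the
severe (4 vs 1), moderate (3–4 vs 1) and slight (2–4 vs 1) contrasts,
pattern 1 always the control class.

## The synthetic cohort

The generator emulates the features the analysis depends on, not the
biology: a log-uniform rare MAF spectrum on (0, 0.01); consequence
categories drawn from a fixed mixture with impact-tier-dependent gamma
deleteriousness scores (means ≈ 3/12/30 for none/moderate/high, so tier
ordering holds stochastically); autosomal genotypes as two Bernoulli
draws (Hardy–Weinberg by construction) and male-X genotypes as one draw
coded {0,2}; an optional per-variant flag that plants a heterozygote
deficit (inbreeding-style, F = 0.6) for QC testing; liability =
polygenic N(0, h²) + Σ effect × standardized deleterious-allele burden +
N(0, 1−h²), with pattern(age) = 1 + #{thresholds below liability +
slope·(age − age_min)}, nondecreasing in age; visits at sorted uniform
ages misreported with a fixed probability to a uniformly different
pattern; kinship pairs at ≈0.25/0.125/0.0625 plus sub-threshold noise
pairs; and batch plus PC-like covariates with an optional confounding
loading on liability.  Defaults (h² = 0.3, thresholds (0.30, 0.95, 1.70),
age slope 0.04/yr over ages 39–82, 5% misreports, visit-count
probabilities (0.60, 0.25, 0.10, 0.05)) give roughly 31/22/25/22% pattern
prevalences at mid-cohort age and a strongly age-shifted pattern-4 group,
the qualitative shape of the real phenotype distribution.

What the generator does **not** emulate: realistic LD structure (variants
are independent given their frequencies), site-frequency spectra from
demography, genotype-calling error profiles, or any calibrated resemblance
to the real cohort's age-by-pattern densities.  Passing tests therefore
demonstrate the statistical machinery — calibration, invariances, recovery
under a known truth — not agreement with any real-data estimate.

## Numerical choices and problem sizes

Bit-identical reproducibility comes from per-operation child streams of a
single seed.  Calibration tests use 2,000 null units at n = 2,000 and
check the 99% binomial band at alpha = 0.05; recovery runs 20 replicates
of 300 genes at n = 5,000 with 0.5 liability-SD burden effects; the
risk-model check uses n = 20,000 with a 30%/2% PRS/burden architecture.
These sizes were chosen as the smallest at which the asymptotics the tests
rely on are comfortably valid.  SKAT-O p-values are clipped to
[1e-15, 1]; monomorphic columns are carried with zero weight but an
all-monomorphic gene is an error; eigenvalues below 1e-10 of the largest
are treated as null space.  The SKAT-O-vs-permutation comparison allows
4 Monte-Carlo standard errors plus 1/n: the permutation null and the
asymptotic Gaussian score null genuinely differ at O(1/n), visible already
in single-ρ p-values at n = 60.

## Known limitations

Binary-trait SKAT below 200 cases relies on residual permutation, which
ignores covariate-residual dependence under strong confounding.  The
L1-logistic inference is a design decision (see above), not a replication
of any particular tool's internals.  The EM phasing assumes random mating
within the sample.  PRS clumping is O(kept × candidates) and meant for
panels of hundreds to thousands of SNPs, not biobank-scale arrays.
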
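# Methods

This note documents the models, numerical choices and study conditions
behind `snpwrap`, and what the synthetic-data experiments do and do not
demonstrate about real cohorts.

## Synthetic cohorts

**Genotypes.** Each SNP's minor-allele frequency is drawn uniformly on
`[maf_low, maf_high]`; two haplotypes per sample are generated as
thresholded latent Gaussians, so every marginal is at exact
Hardy–Weinberg equilibrium. Linkage disequilibrium, when requested, is
induced by an AR(1) Gaussian copula within blocks of `ld_block_size`
SNPs (parameter `ld_rho`): adjacent SNPs in a block share latent
correlation while marginals stay at HWE. This produces controllable
pairwise r² but not realistic human LD maps — recombination hotspots,
allele-frequency-dependent LD decay and long-range structure are out of
scope, as are X-chromosome dosage and admixture.

**Phenotypes.** Binary traits follow an explicit logistic model per
trait:

    logit P(y=1) = b0 + b_sex·sex + Σ_j β_j g_j + Σ_{jk} γ_jk g_j g_k
                   + w/(1-w) · u

with genotype dosages g ∈ {0,1,2}, an independent Bernoulli(0.5) sex
covariate unless supplied, and a per-sample standard-normal liability
`u` shared across traits. The shared-liability weight w ∈ [0,1) has no
natural scale in the log-odds metric; we map it through w/(1−w) so that
w = 0 gives exact independence and the coupling grows without bound as
w → 1. Target prevalences are hit by tuning the intercept with Brent
root-finding on the sampled linear predictor (expected-prevalence
matching), not by rejection sampling; designed cohorts with exact
case/control counts (e.g. 80/16) use `resample_to_counts`.

**Visit records.** Each patient draws each diagnosis code independently
at its prevalence, except planted pairs (D, C), for which
P(C|D) = lift·P(C) and P(C|¬D) is adjusted so C's marginal is
preserved. Feasibility requires lift·P(D) ≤ 1 as well as
lift·P(C) ≤ 1; configurations violating either are rejected at
validation. Because visit tables contain only patients with at least
one code, the rule miner accepts the screened-cohort size `n_total`
explicitly; omitting it biases lift downward whenever diagnosis-free
patients exist.

## Quality control

Filters run in a fixed order (sample call rate ≥ 0.95 → SNP call rate
≥ 0.95 → MAF ≥ 0.05 → HWE exact p ≥ 10⁻⁶ in controls → per-sample
heterozygosity within 3 SD → pairwise relatedness < 0.1875), all
configurable. Because removing samples shifts per-SNP statistics and
vice versa, the six-step pass repeats until a sweep removes nothing;
the report accumulates per-step counts, and re-running QC on its own
output is exactly a no-op. Relatedness uses the standardized
allele-sharing (GRM) estimate rather than IBD segment inference —
adequate at desk scale, but noisy when fewer than a few hundred SNPs
survive, in which case the 0.1875 cutoff should be relaxed or the
filter disabled. The HWE exact test uses the mid-support recurrence for
numerical stability; the test suite checks it against a log-factorial
enumeration oracle over every table with ≤ 60 alleles. Sex-concordance
checking is a documented no-op on autosomal-only data.

## Association scan

Per-SNP logistic regression with additive minor-allele coding and Wald
inference, fitted by Newton iterations vectorized across SNPs
(per-SNP missing genotypes enter as zero weights, equivalent to
dropping those samples for that SNP). Convergence is declared at a
max-step of 10⁻¹⁰ within 30 iterations; steps are clipped at ±5 to
stabilize separated fits. Monomorphic SNPs, fits with |β| > 15 or
SE > 100 (complete or quasi-separation — common at n ≈ 100), and
non-converged fits are flagged and excluded from λ_GC and candidate
sets rather than reported as numbers. The solver is validated against
`statsmodels.Logit` coefficient-by-coefficient in the tests.
λ_GC is the median 1-df chi-square quantile of the p-values divided by
0.4549364 (the chi-square median); QQ coordinates use the (i−½)/m
uniform order-statistic convention. PCA covariates mean-impute missing
genotypes, standardize columns, and fix component signs by making the
largest-magnitude loading positive.

## Wrapper selection

Best-first forward search from the empty set (scored as the majority
baseline): an open priority queue ordered by LOOCV accuracy, expansion
of the best open node by all single-feature additions, termination
after `stale_limit` (default 5, the convention of standard wrapper
implementations) consecutive expansions without a strict improvement of
the global best. Ties break toward higher score, then smaller subset,
then lexicographic feature order — results are platform-deterministic.
With an unbounded stale budget the search provably visits the whole
lattice, which the tests exploit by checking equality with exhaustive
search on 7-feature problems.

The scored metric is accuracy only; AUC is recorded downstream but not
optimized. LOOCV has closed-form fast paths: the majority baseline
(counting argument), and k-NN (one distance matrix per subset; holding
out sample i is nearest-neighbour search excluding self). The default
wrapper classifier is 5-NN: 1-NN's LOOCV score is high-variance and
noticeably less stable at retaining truly causal SNPs during the
search; any registry classifier or scikit-learn estimator can be
substituted, at the cost of n refits per subset. The candidate pool
defaults to the lenient GWAS set (p < 10⁻²) and is configurable up to
the full post-QC panel; on noise-dominated panels an unfunneled search
selects large, badly overfit subsets — that behaviour is demonstrated,
not hidden, by the leakage experiments.

Two protocols: `fixed_subset_workflow` (one search on the full
discovery cohort; the subset is frozen for all later evaluation; its
score is optimistic because held-out samples steered the search) and
`embedded_selection_cv` (search and the optional GWAS screen re-run
inside every leave-one-out training fold; the held-out predictions give
an honest accuracy). On pure-noise cohorts (n = 96, 2,000 SNPs,
balanced classes) the fix-once score exceeds the honest estimate by
roughly 30 accuracy points on average — the quantitative signature of
selection leakage at this sample size.

## Evaluation

Internal: repeated stratified k-fold (default 10×10) via scikit-learn's
splitter; fold AUC is rank-based (Mann–Whitney with half credit for
ties, checked against an O(n²) pairwise oracle). External: the fitted
model predicts the external cohort once; B = 1,000 bootstrap replicates
resample indices with replacement within each class, so replicate class
counts equal the originals exactly, and accuracy/AUC are summarized as
mean ± SD with a percentile (2.5/97.5) CI — no bias correction, since a
plain percentile interval is the contract. Classifier probabilities
feed AUC where available, decision values otherwise; for margin-only
learners the scores are rank-meaningful only.

The registry's lwl, ripper, part and logistic_model_tree entries are
nearest-equivalent substitutes (distance-weighted k-NN, pruned CART,
pruned CART, penalized logistic regression respectively), marked as
such in `SUBSTITUTE_NAMES`; exact replication of every benchmark
learner is not a goal of the package.

## Acceptance study conditions

The quantities recomputed by `scripts/acceptance.py` use these fixed
conditions, chosen once as representative of the small-cohort regime:

* **Baselines** — majority-class LOOCV at case/control splits 46/50,
  34/62 and 42/54 (n = 96): forced arithmetic, no tolerance needed.
* **Null calibration** — n = 500 samples × 10,000 null SNPs, sex-only
  model; λ_GC and the KS uniformity p of the Wald p-values.
* **Leakage gap** — 20 pure-noise cohorts of 96 × 2,000 SNPs;
  per-fold GWAS screen at p < 0.01 inside the embedded protocol.
* **Planted recovery / pipeline contrast** — 10 replicates of a
  three-trait design: per trait, three causal SNPs with additive
  per-allele OR 4.5 at MAF ≈ 0.3 among 500 SNPs at n = 96. The effect
  size follows a power analysis: for the search to see a causal SNP it
  must enter the lenient pool, and per-SNP power ≈ 0.85 at α = 0.01
  under liability attenuation requires an OR near 4.5 at this n. The
  GWAS-only comparator is a random forest on the stringent (p < 10⁻⁴)
  union across the three traits — the direct analog of building one
  model from all trait-level GWAS hits — evaluated by external
  stratified bootstrap on an independent cohort of 200; the marker
  pipeline refines each trait's lenient pool by wrapper selection.
* **Rule mining** — planted lift 8.0 with P(D) = 0.1, P(C) = 0.05 at
  n = 10,000 patients (lift·P(D) < 1 keeps the marginal-preserving
  construction feasible).

Problem sizes were set so the whole script runs in minutes on one core;
they are stated here because every tolerance in the tests is a function
of them (binomial standard errors, KS critical values, Monte-Carlo
replicate counts).

## What passing does and does not show

The generator draws independent or block-AR(1) SNPs with clean logistic
effects; real cohorts add LD with causal variants untyped, batch and
population structure, phenotype misclassification and ascertainment.
Passing the planted-recovery and pipeline-contrast experiments shows
the machinery is correct and the protocol sound at these effect sizes —
not that wrapper selection will recover real loci at OR ≈ 1.2, where no
method at n = 96 has meaningful power. The leakage experiment, by
contrast, transfers directly: it is a property of the protocol, not of
the genetic architecture.

## Known limitations

Rule mining is co-occurrence only (no temporal ordering of diagnoses);
strand flipping is not attempted for retained low-MAF palindromic SNPs
(they pass through flagged); binary BED reading is not implemented
(text PED/MAP is the interchange format); the relatedness filter is not
an IBD estimator; λ_GC comparisons across covariate models are exposed
but no claim is made about how added PCs shift inflation in any
particular cohort.
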
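# Methods

## Statistical model

`pathperm` tests whether a predefined set of genes is associated with a
binary disease outcome in a stratified case-control panel, using a max-SNP
gene-set statistic with permutation-based significance.

**Per-SNP model.** For sample *i* with minor-allele count *g* ∈ {0, 1, 2}
at one SNP, case status follows an additive logistic model

    logit P(case) = β₀ + β g + Σₖ γₖ 1[cluster = k] + δᵀx,

where the cluster indicators absorb between-centre differences in both
disease frequency and allele frequency, and *x* holds any user-supplied
numeric covariates (e.g. ancestry principal components computed upstream —
the package does not compute PCs itself). The per-SNP evidence is the Wald
statistic z = β̂ / se(β̂); a likelihood-ratio alternative was deliberately
not used because the gene score is defined through the coefficient scaled
by its standard error.

**Gene scores.** Gene intervals are extended by `flank_bp` (default
100 000 bp; 1-based inclusive coordinates) on both sides, floored at
position 1. Flanked intervals on one chromosome that overlap *or abut* are
merged transitively — a shared boundary base is treated as one locus
neighbourhood; merging is order-independent and merged regions are
disjoint, so each SNP maps to at most one region. Region score
zᵢ = max |z| over the region's SNPs (mode `second_best`: the
second-largest, guarding against single spuriously strong SNPs; a
single-SNP region falls back to its only |z|). Ties break toward the
earlier SNP in panel order and affect only the reported best-SNP id.

**Set statistics.** For the k scored regions of a set,
SUMSTAT = Σ|zᵢ| and SUMSQ = Σzᵢ². Both satisfy SUMSQ ≤ SUMSTAT² and
SUMSTAT² ≤ k·SUMSQ (Cauchy–Schwarz); these are asserted at construction.
Subgroup sets reuse the same region scores; nothing is refit.

**Permutation null.** Case-control labels are permuted independently
within each cluster, conserving every cluster's case count exactly, so the
null distribution respects the study's geographic structure. Each permuted
dataset is pushed through the *identical* scan → score → set-statistic
pipeline (genotypes and covariates untouched), and all sets and both
statistics are evaluated on the same stream of permuted datasets. The
empirical p-value is the strict-exceedance fraction
p_emp = #{permuted > observed}/N, which admits p_emp = 0; an opt-in
`unbiased=True` switches to (r+1)/(N+1). For N = 200 permutations the exact
null level of the event p_emp ≤ 0.05 is therefore 11/201 ≈ 0.0547, which is
what the calibration tests check against.

**Mean-p set test.** The alternative summary selects the set's SNPs with
association p ≤ `p_threshold` (default 0.05), orders them by ascending p,
and greedily discards any later SNP with genotypic r² > `r2_threshold`
(default 0.5) against an already retained SNP; the statistic is the mean p
of the retained SNPs, recomputed per permutation. Because the statistic is
small when association is strong, significance counts permuted values
*below* the observed (this orientation is a documented package convention).
If no SNP is selected on the observed data the statistic is undefined and
the result is reported non-significant (p_emp = 1) with a warning; permuted
scans selecting no SNP never count as exceedances. r² is the squared
Pearson correlation of minor-allele counts over jointly non-missing
samples; an undefined r² (constant genotype on the joint subset) is treated
as "not in LD".

## Quality control

Per-SNP verdicts are assigned with a fixed precedence so counts partition
the panel: call rate (< 0.97 excluded; exactly 0.97 passes), then pooled
MAF (< `maf_min` excluded; default 0.01, set 0 to disable — no universal
convention exists, so the threshold is exposed and reported as a separate
verdict), then the conjunction rule: exact-HWE p < 10⁻⁵ **and**
cross-cluster heterogeneity p > 0.001. The conjunction retains HWE-deviant
SNPs whose allele frequencies differ between clusters, because pooling
differentiated strata depresses heterozygosity (Wahlund effect) without
implying a genotyping artefact.

The exact HWE test conditions on allele counts: the probability of every
possible heterozygote count is computed by the standard multiplicative
recurrence (rescaled to avoid overflow; distribution cached per allele
total), and the two-sided p sums all outcomes with conditional probability
≤ that observed (ties included with a 1+10⁻¹² slack). By default HWE is
computed on cases and controls pooled; `hwe_scope="controls_only"` is
available. The heterogeneity test is a Pearson χ² on the 2×K minor/major
allele count table with df = K−1 after dropping zero-total clusters (six
strata give the 5-d.f. test).

X-chromosome genotypes are treated as autosomal 0/1/2 counts; no
hemizygosity recoding is applied. This is a documented simplification —
male X dosages enter as whatever the pedigree encodes.

## Numerical implementation

The permutation engine refits every SNP for every permuted label vector,
so the logistic scan is a Newton/IRLS iteration batched across SNPs: the
covariate block is shared, only the genotype column differs, and the
per-SNP (p×p) systems are solved as one stacked `numpy.linalg.solve` call.
Convergence requires gradient max-norm < 10⁻⁸ within 100 iterations;
missing genotypes drop a sample for that SNP only (zero IRLS weight);
linear predictors are clipped at ±35 to avoid overflow. |β̂| > 30, a
singular information matrix, a constant genotype, or a one-class outcome
mark the fit non-converged; such SNPs are *excluded* from gene scoring
(assigning z = 0 would deflate SUMSTAT unpredictably), and a region losing
all its SNPs drops out of k for that permutation, mirroring how genes
without genotyped SNPs shrink random sets. The batched fits agree with
statsmodels' Logit to ~10⁻¹² on test panels and with the closed-form 2×2
log cross-product ratio and Woolf standard error to 10⁻⁶.

Clopper–Pearson binomial intervals use beta quantiles; the analytic
probability that a random set of s genes contains ≥ 1 of m associated genes
among G is 1 − (1 − m/G)ˢ, with an exact hypergeometric variant.

All randomness flows from one top-level seed; the pipeline derives
per-stage seeds via `numpy.random.SeedSequence`, so a rerun is
byte-identical and any stage is independently reproducible.

## Synthetic data: what it emulates, and what it does not

The generator produces quota-based case-control panels: per cluster,
genotype vectors are drawn SNP-wise from the genotype distribution implied
by the cluster's minor-allele frequency and an inbreeding-style coefficient
F (heterozygote probability scaled by 1 − F — a single monotone knob for
HWE violation), case status is drawn from the additive logistic model, and
rejection sampling continues until the cluster's exact case and control
quotas are met (capped at 10⁶ draws, after which generation fails loudly).
Missing genotypes are masked per SNP at a configurable rate. Cluster
stratification is emulated by jittering per-cluster allele frequencies.

SNPs are independent by default; the only linkage structure available is a
pairwise "tag SNP" feature (one SNP copying another with a target r²),
provided so LD pruning is exercisable. Consequently, passing tests
demonstrate correct behaviour under cluster confounding, missingness, and
additive effects — they do **not** certify performance under realistic LD
blocks, haplotype structure, rare-variant spectra, or genotyping batch
artefacts.

Default study conditions used by the test suite: the QC fixture mirrors a
1178-SNP candidate panel with 60 low-call-rate SNPs and 5 homogeneous HWE
violators across 6 clusters of 100 samples; calibration uses 200 null
datasets (2 clusters × 100 samples, 6 genes × 2 SNPs, MAF 0.15–0.45 with
±0.05 cluster jitter) at 200 permutations each; power uses n = 1000 with a
single causal SNP at OR ∈ {1.0, 1.3, 2.0}. These problem sizes are the
package's chosen test scale: large enough for stable calibration bands,
small enough for routine continuous testing.

## Design choices on genuinely open points

- **Exclusion precedence** (call rate → MAF → HWE) makes each SNP count
  once, so exclusion tallies are additive.
- **Minor-allele orientation** is determined empirically from pooled
  counts; at exactly 0.5 the lexicographically smaller allele is minor, a
  deterministic tie-break that keeps recoding behaviour testable.
- **Cluster labels travel in the pedigree family-ID column**, making a
  panel a self-contained ped/map pair.
- **Strict ">" exceedance** for p_emp (rather than ≥ or add-one) is the
  primary estimator; its bias is visible and documented rather than hidden.
- **Random-set sampling routes through region building**, so genes without
  SNPs shrink k exactly as in the main analysis.

## Known limitations

- No sample-level QC (relatedness, sex checks, ancestry outliers) — the
  package assumes an upstream-cleaned panel.
- Bi-allelic autosomal-style treatment only; no dominant/recessive models,
  no score/LRT statistics, no meta-analysis across study phases.
- The bundled 43-gene table carries approximate build-36 coordinates,
  adequate for the ±100 kb flank scale but not base-precise.
- Empirical p-values are bounded below by 1/N (or exactly 0 under the
  default estimator); multiplicity across many pathways is not addressed.
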
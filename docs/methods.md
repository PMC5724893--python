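# Methods

`rarecollapse` implements a case-control gene-based collapsing analysis
for rare, putatively deleterious variation, together with the QC and
diagnostic machinery such an analysis needs to be trustworthy: hard
variant filters, kinship- and PCA-based sample pruning, case/control
coverage harmonization, Fisher and Firth-penalized association tests,
permutation-calibrated QQ expectations, and known-gene rank enrichment.
Because individual-level exome data of this kind are protected, the
package ships a synthetic cohort generator that reproduces the
statistical structure the analysis assumes, and every stage is validated
against planted truth on generated cohorts.

## The collapsing model

For each gene *g* and sample *i*, an indicator
X<sub>ig</sub> ∈ {0, 1} records whether the sample carries at least one
*qualifying variant* in the gene — a dominant model. A variant qualifies
when it is

1. absent from the external population databases (EVS and ExAC r0.3),
2. ultra-rare in the cohort itself: at most 4 alternate-allele copies
   across all retained cases and controls (het = 1, hom-alt = 2), counted
   after genotype-level QC, and
3. predicted impactful: one of the six loss-of-function classes
   (stop_gained, frame_shift, splice_site_acceptor, splice_site_donor,
   start_lost, exon_deleted) or missense rated probably-damaging by
   PolyPhen-2 HumDiv.

Carrier proportions are compared between n₁ cases and n₀ controls per
gene with a two-tailed Fisher's exact test on
[[a, n₁−a], [c, n₀−c]], using the standard "sum of small p" two-sided
rule (scipy's convention; the tie comparison carries a ~1e-7 relative
tolerance). Genes with no carriers are reported with p = 1.

### Covariate-adjusted Firth regression

Rare-variant burdens differ systematically between sequencing batches and
ancestries; the per-sample count of *ultra-rare synonymous* variants
(same rarity rules, no impact filter) proxies that background load and is
included as a covariate in a logistic regression of case status on the
gene indicator. With single-digit carrier counts the ordinary ML
estimate separates frequently, so the model is fit by Firth's penalized
likelihood, ℓ*(β) = ℓ(β) + ½ log |I(β)| (a Jeffreys prior), which keeps
estimates finite under complete separation.

Newton iterations use the hat-value-adjusted score
U*(β) = Xᵀ(y − π + h(½ − π)) — the exact gradient of ℓ* — with
step-halving; when the Newton step oscillates near the optimum (the
unpenalized information is not the Hessian of ℓ*), a BFGS polish on the
exact objective finishes the fit (convergence: max |U*| < 1e−6 and
max |Δβ| < 1e−6, at most 100 Newton iterations).

The per-gene test is the **penalized profile likelihood ratio**:
2(ℓ*(β̂) − ℓ*₀) referred to χ²(1), where ℓ*₀ maximizes the *same*
full-design penalized likelihood under the constraint β_gene = 0. Keeping
the penalty's dimension fixed is essential: comparing a 3-parameter
penalized likelihood to a separately-fit 2-parameter one shifts the
statistic by the ½ log |I| dimension mismatch and destroys calibration
(empirically: size ≈ 1 instead of 0.05). A constant covariate column is
dropped (collinear with the intercept), which also makes the degenerate
case reduce exactly to the covariate-free fit.

Genome-wide significance uses Bonferroni: α = 0.05 / n_genes_targeted
(0.05/18,668 = 2.68×10⁻⁶ at the CCDS gene count the original design
targeted). The reporting layer flags significance under each test and
jointly; the ranking used for enrichment is by the Firth p-value, ties
broken by Fisher p then gene name.

## Sample QC

**Kinship.** Pairwise kinship uses the within-pair robust estimator
φ = (N_het,het − 2·N_AA,aa) / (N_het(i) + N_het(j)) over sites jointly
typed in both samples of a common-SNP panel: 0.5 for duplicates, ≈0.25
for first-degree pairs, 0 in expectation for unrelated pairs under HWE
regardless of allele frequencies (hence robust to stratification). Pairs
with no jointly-typed het site are undefined (NaN, treated unrelated with
a warning). Its null sampling noise has sd ≈ 0.7/√L for an L-SNP panel,
so the 0.1 cutoff needs L in the thousands to avoid false edges over
millions of pairs; the synthetic panel defaults to L = 5,000.

**Relatedness pruning** (cutoff φ > 0.1) deletes greedily: the sample
with the most remaining relatedness edges first, preferring to delete
controls over cases, then lower mean CCDS coverage, then the
lexicographically larger sample ID. The retained set is guaranteed free
of above-cutoff pairs; the estimator formula and the greedy policy are
design choices (the cutoff, case preference and coverage tie-break are
the analysis's stated policy).

**PCA outlier removal.** On an LD-pruned panel (sliding-window r² > 0.1,
earlier SNP kept), genotypes are standardized per SNP by
(g − 2p̂)/√(2p̂(1−p̂)), the sample covariance is eigendecomposed, and any
sample deviating more than 6 sd from the mean on any of the top 10 PCs is
removed; this repeats for up to 5 iterations, recomputing frequencies,
PCs and the outlier statistics on the survivors each round. Per-PC
z-scores (not Mahalanobis distance) follow the EIGENSTRAT convention.
Eigenvector signs are fixed by making the largest-magnitude loading
positive, so results are reproducible.

A practical detectability note: a *single* outlier from a population at
divergence F appears as a covariance spike of size ≈ 1 + F against a
Marchenko-Pastur bulk edge of (1 + √(n/L))², so mild divergence
(F ≈ 0.2) is frequently invisible at desk-scale panels. The generator
plants outliers at F = 0.3, which simulation shows is detected in every
seed at the default panel size; real analyses with 10⁴–10⁵ exome SNPs
detect correspondingly milder outliers.

## Coverage harmonization

For every candidate site the fractions of cases and of controls with
≥10× coverage are computed (exact rational arithmetic) and the site is
excluded when the fractions differ by more than 11.97 percentage points
(strict inequality; a gap of exactly 11.97% is retained). The threshold
is taken as a given constant, configurable. A pruned site contributes to
neither qualifying-variant carriage nor the synonymous covariate —
uniform treatment, since both counts should come from territory where the
groups are comparable.

## Permutation QQ and λ

Expected p-value distributions come from label permutation rather than a
uniformity assumption. For the Fisher test, case/control labels are
reshuffled uniformly with the case count fixed; for the covariate-
adjusted Firth test, uniform reshuffling would destroy the confounding
the covariate exists to absorb, so permuted case sets are drawn from the
**multivariate Fisher noncentral hypergeometric** distribution with
per-sample odds wᵢ = exp(α̂ + γ̂ zᵢ) from a logistic fit of phenotype on
the covariate (Firth fallback if that fit separates; weights rescaled to
geometric mean 1). Sampling is exact: the target law is independent
Bernoulli draws with those odds conditioned on the case count, so the
sampler tilts the Bernoulli probabilities to match the expected count and
accept-rejects on the exact count.

For each of n_perm (default 1,000) permutations the gene-wise p-values
are recomputed and sorted; per-rank means give the expected order
statistics, per-rank 2.5/97.5 percentiles a 95% band. The genomic
inflation factor is the median-based 1-df definition
λ = median(χ²-quantile(1 − p)) / 0.4549. With genuinely rare carriers the
p-value distribution is heavily discrete (many p = 1) and λ loses
meaning; calibration experiments therefore use common indicators (carrier
rate 0.2), where λ's Monte-Carlo sd is small.

## Rank enrichment

Whether K known disease genes cluster at the top of the genome-wide
ranking is quantified at each known gene's rank r (its j-th member):
P(X ≥ j), X ~ Hypergeometric(N, K, r), evaluated in log space; ties share
the best rank among tied genes (an optimistic convention, flagged in the
output). N is the number of genes actually tested in the run. A coarser
Fisher test compares the nominally significant fraction inside the known
set against the genome-wide fraction.

## Synthetic cohorts

The generator reproduces the structure the analysis assumes, at
carrier level — the collapsing statistic's sufficient statistic:

* **Sample sizes** default to the post-QC analysis cohort (488 cases,
  12,151 controls); testing and calibration use scaled-down cohorts
  (typically 500/2,000 and 2,000 genes) so full runs complete in minutes
  on one CPU.
* **Qualifying carriers**: each sample carries ≥1 qualifying variant in a
  gene with probability p (background default 0.002, risk genes higher in
  cases); carriers are grouped into variants of 1–4 heterozygous carriers
  so planted variants respect the ≤4-copy rule. Non-qualifying decoys
  (ExAC-present, benign missense, artifact-flagged) exercise the filters.
* **Synonymous covariate**: per-sample counts are negative binomial
  (default mean 8, dispersion 8 — overdispersed, the realistic stressor
  for the adjustment), realized exactly as singleton/shared synonymous
  variants. In the confounded-null regime the qualifying-carrier rate
  scales multiplicatively with the sample's synonymous count, so cases
  (shifted mean) carry more of everything — the scenario the covariate
  adjustment and the weighted-urn permutation are for.
* **Coverage**: a configurable fraction of sites (default 10%) gets a
  capture-kit-style case/control coverage gap (default 0.2, above the
  pruning threshold); other sites are fully covered.
* **Relatives and structure**: duplicate and parent-offspring pairs are
  planted by copying/gamete-transmitting panel genotypes among controls;
  two subpopulations (Balding-Nichols, Fst 0.05) and ancestry outliers
  (Fst 0.3) shape the common-SNP panel only — rare qualifying variants
  carry no structure, mirroring the use of common SNPs for PCA.

All randomness flows from one seeded generator; identical configs give
byte-identical cohorts. What the generator does **not** model: site
frequency spectra, LD/haplotype structure on the panel (SNPs are
independent given the subpopulation), sequencing error, genotype-level
coverage dropout (the planted coverage gap marks sites for harmonization
but does not erase genotypes), or trio/de-novo structure. Passing tests
therefore demonstrate the pipeline's statistical behaviour under the
assumed model, not robustness to artifacts outside it.

## Numerical and design notes

* Fisher p-values under permutation are memoized on (case carriers,
  total carriers) — the margins are fixed — which makes 200–1,000
  permutations of a few thousand genes cheap.
* The type-I-error acceptance experiment uses carrier rate 0.2 at
  500/2,000 samples: the exact attained size of the two-sided Fisher test
  there is 0.0465 (computed by hypergeometric enumeration), close enough
  to nominal for a [0.04, 0.06] band; at genuinely rare carrier counts
  the exact test is far more conservative and no band around 0.05 is
  attainable.
* Coverage fractions compare as exact `Fraction`s, so threshold-boundary
  behaviour is not at the mercy of binary rounding.
* Multiallelic sites are decomposed per alt allele; genotypes not
  involving that alt count as hom-ref for carrier logic. Missing
  genotypes are non-carriers; coverage-based exclusion is handled by the
  coverage table, not the GT field.
* Hemizygous male X genotypes are not modeled separately; a het call
  counts one copy.
* The end-to-end family-wise error check relies on Bonferroni plus the
  joint two-test significance requirement, which is conservative by
  construction; null runs are expected to produce zero genome-wide hits.
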
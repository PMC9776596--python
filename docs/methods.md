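# Methods

`gutmwas` implements a metagenome-wide association analysis for a binary
clinical outcome (acute graft-versus-host disease, aGvHD, vs none) measured
on pre-transplant stool metagenomes. All inputs can be simulated with known
ground truth, so every statistical procedure in the package is tested
against planted effects and against brute-force oracles.

## Data model

- **Reference catalog** — one row per bacterial species: a stable
  `species_id` (GCF-style assembly id or UMGS-style metagenomic id), a
  display name, taxonomic rank and genome length in bp. Genome length is
  load-bearing: it enters the normalisation below.
- **Cohort table** — one row per stool sample: `sample_id`, `patient_id`,
  `sampling_day` (days relative to transplant, always ≤ 0), the binary
  `outcome` (1 = aGvHD grades II–IV), and ten clinical covariates.
- **TaxProfile** — per-classifier raw species read counts
  (samples × species).
- **AbundanceMatrix** — relative abundances; row closure to 1 is validated
  at construction.

## Synthetic generator

The patient-level data behind the motivating study is access-restricted,
so the package ships a generator that reproduces its shape: ~2505-species
catalog, 172 patients contributing 181 samples (9 patients with two
samples), 39/172 cases, and three classifiers ("DeepMicrobes", "Kaiju",
"Kraken2") with classified-read rates near 21%, 57% and 74%.

Latent compositions are log-normal: species base abundances
log-normal(0, 2) (heavy-tailed rank-abundance curve), per-sample noise
log-normal(0, 1), closed to the simplex. Ground truth is a `PlantedTruth`:
enriched/depleted species with fixed |log2 fold-change| (planted at
mid-range base abundance so they are prevalent), plus an optional shrinkage
of case compositions toward the case centroid, which lowers within-group
beta diversity in cases. Reads are drawn multinomially with species weights
proportional to composition × genome length × a per-classifier log-normal
detection bias, so genome-length normalisation and ensemble averaging are
both measurably consequential downstream.

**Scope and limits.** The generator emulates marginal shapes
(rank-abundance, prevalence, imbalance, classifier bias), not real
taxon–taxon correlation structure, batch effects, or longitudinal dynamics.
Recovery results on it bound what the pipeline can do under a favourable,
well-specified model.

## Ensemble profiling

All 7 non-empty subsets of the 3 classifiers, crossed with
{complete, reduced} species sets, give 14 configurations. A subset's
profile is the unweighted arithmetic mean of its classifiers' counts.
Counts are normalised by genome length and depth:
`a_ij = (c_ij / L_j) / Σ_k (c_ik / L_k)`. Samples with fewer than 1,000,000
reads are dropped (strict less-than). Duplicate samples are collapsed to
one profile per patient: the sample closest to day 0 wins; same-day pairs
are merged by element-wise mean and re-closed.

## Permutation species filter (PERFect-style)

The filtering loss of a species set J is
`FL(J) = 1 − ‖X₋Jᵀ X₋J‖²_F / ‖Xᵀ X‖²_F`. Species are ordered by individual
filtering loss; the sequential losses along that order are compared, per
position, to losses from random removal orders (default 99 permutations);
species from the first position with p ≤ 0.10 onward are retained. The
retained set is a suffix of the order, so the filter is monotone.

## Diversity

Seven alpha indices (Berger–Parker, Simpson, Heip's evenness, inverse
Simpson, richness, Shannon, Strong's dominance) plus a reference-free
k-mer richness (distinct k-mer count, F0). Ten beta indices (Canberra,
Chebyshev, Clark, correlation, Euclidean, geodesic, Hellinger,
Horn–Morisita, Jaccard nestedness — the Baselga nestedness-resultant
component, Manhattan). All are checked against naive-loop oracles to 1e-10.

"Beta diversity of a group" is the distribution of within-group pairwise
distances; groups are compared per index by the Wilcoxon rank-sum
statistic, BH-adjusted across indices. **Numerical-inference choice:**
pairwise distances sharing a sample are dependent, so the classical
rank-sum null is badly anti-conservative here (empirical type-I error
≈ 0.42 at nominal 0.05 in simulation). The statistic is therefore referred
to its exact sample-label permutation null by default (vectorised via the
Mann–Whitney U identity with midrank ties; the permutation keeps pair
counts fixed). The asymptotic p is still reported as `p_asymptotic`.
Because groups are unequal, a group-equalised variant repeats the test on
random same-size subsets of the larger group and reports the significant
fraction.

## Dissimilarity inference

Distances: robust Aitchison (rclr — centred log-ratio over positive
entries, zeros kept at 0 — then Euclidean) and Bray–Curtis. Tests:

- **PERMANOVA** with sequential (Type-I) sums of squares over ordered
  design terms (`a:b` interaction syntax), Gower double-centering, QR-based
  hat matrices, trace identities for permuted pseudo-F, free row
  permutation. On 1-D Euclidean distances the single-factor pseudo-F equals
  the classical ANOVA F (checked to 1e-8).
- **ANOSIM** on ranked distances, one-sided permutation p.
- **Dispersion homogeneity** (betadisper-style): principal-coordinate
  embedding keeping negative eigenvalues on imaginary axes, per-group
  distance to centroid, one-way F with permutation p.
- **MWMOTE** majority-weighted minority oversampling (k1 = 5, k2 = 3,
  k3 = |minority|/2, cf_th = 5, cmax = 2, c_p = 3) for a balanced
  re-analysis; synthetic rows are convex combinations of minority samples.

All permutation p-values use `(1 + exceedances) / (1 + n_perm)`, so p is
never 0 and tests are exact-level valid.

## Per-species screens

All screens share one tidy schema (`species_id`, `statistic`,
`effect_size`, `direction`, `p`, `p_adj`, `adjust_method`):

- **Wilcoxon screen** (Mann–Whitney, BH) with log2 fold-change using a
  half-minimum-positive pseudo-count;
- **IndVal.g** — group-equalised indicator value (specificity A ×
  prevalence B), permutation p, with prevalence filters min_B = 0.2 and
  min_A = 0.5 (inclusive);
- **point-biserial r.g** — group-equalised correlation (weights 0.5/n_g),
  invariant to replicating the majority group;
- **sign-association** — |mean difference| two-sided exact permutation
  test with Šidák adjustment `1 − (1 − p)^m`;
- **conditional mutual information** — equal-frequency binning with
  ⌊N^⅓⌋ bins, bits, reported alongside the MI between species and the
  confounder; small confounder levels are merged (or raise);
- **Spearman** association with an optional covariate correlation column.

Clinical covariates are modelled by logistic regression (statsmodels) on
10 dichotomised predictors (age ≥ 60, Karnofsky ≥ 90 with
outcome-stratified median imputation), with VIF diagnostics and
McFadden/Cragg–Uhler pseudo-R².

## Feature ranking

13 rankers: 7 Relief variants (Relief, ReliefF with equal-K /
exponential-rank / best-K weighting, myopic ReliefF, merit- and
distance-weighted ReliefF) and 6 impurity measures (gain ratio, MDL, DKM,
uniform-prior information gain, equal-prior Hellinger, Euclidean
distance-based impurity). **Numerical choice:** `rank_features` log10-
transforms abundances by default (pseudo-count = half the minimum positive
value) because min-max scaling of heavy-tailed abundances collapses the
contrast Relief neighbourhoods rely on; impurity measures are invariant to
the monotone transform. Ranks per ranker are exact permutations 1..S (ties
broken lexicographically); the consensus is the median rank.

## Prediction benchmark

Repeated stratified k-fold (default 2 × 5) elastic-net logistic regression
(saga solver) with per-fold standardisation, optional inner 3-fold grid
selection over (C, l1_ratio), vertically averaged ROC, median weights and
a sign-robustness score per species. The benchmark grid evaluates all 14
ensemble configurations and flags the single best mean AUROC. A
label-shuffle control yields mean AUROC ≈ 0.5 (accepted range [0.4, 0.6]).

## Consensus call

A species is a consensus aGvHD-associated species when (1) any indicator
statistic (IndVal.g, r.g, sign-association) has raw p < α, (2) the
Wilcoxon screen has raw p < α, and (3) its median rank is within the top
`top_n` (defaults α = 0.05, top_n = 20). The criterion is conjunctive, so
tightening either threshold can only remove species.

## Problem sizes and runtime

Designed for n ≈ 200 samples and up to a few thousand species. On a
laptop-class core: full synthetic study simulation (172 patients, 500
species) in seconds; screens with 499 permutations in a few seconds; the 500-replicate null
calibration ≈ 1 minute; the 14-cell benchmark a few minutes. PERMANOVA is O(n²) per permutation; the permutation filter is
O(S) sequential losses × permutations.

## Limitations

- The rank-sum permutation null fixes the anti-conservativeness of the
  within-group distance comparison but tests the sharp null of label
  exchangeability, which mixes location and dispersion alternatives.
- MWMOTE-balanced re-analyses reuse minority information; their p-values
  are descriptive, not confirmatory.
- The synthetic generator omits taxon correlation structure; recovery
  rates on real data will be lower.
- `kmer_f0` is exact distinct-k-mer counting, intended for validation-scale
  read sets, not production-scale FASTQ.
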
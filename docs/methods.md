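# Methods

## The permutation posterior

PICS is a non-parametric Bayesian fine-mapper. It never fits a model
relating genotype to trait; instead it asks a counterfactual question per
variant: *if variant j were the causal one, how often would the observed
lead SNP still emerge as the lead?* The answer is estimated by permuting
the rows of the genotype matrix under the constraint that variant j's
empirical relationship with the phenotype is untouched.

**Constrained permutation family.** We permute rows only within strata of
equal focal dosage. This family is exactly characterized by three
invariances: (i) the focal column is unchanged *as a vector*, so its
association with any fixed phenotype is numerically identical, (ii) rows
move as whole units, so every pairwise column correlation (the LD
structure) is preserved, and (iii) the row multiset is preserved. It is
the largest row-permutation group with property (i), and it forms a group
(a direct product of symmetric groups on the strata), which matters for
implementation: permuting the phenotype by a uniformly drawn within-stratum
shuffle samples the same null as permuting the genotype rows, because the
group is closed under inversion. The implementation exploits this to
compute all R permutation correlations with one matrix product per focal
variant. `enumerate_constrained_permutations` provides the exhaustive
(product-of-factorials) enumeration used as the test oracle on small
strata.

**Association statistic and ties.** Marginal association is the squared
Pearson correlation r²; for a simple regression this is a monotone
transform of the F statistic and of the two-sided p-value, so the lead
variant is the same under any of these conventions. Monomorphic variants
get statistic 0. All argmax operations (lead SNP, per-permutation lead,
per-set selection) break exact ties by smallest genomic position, then
lexicographic variant ID — a pure determinism device; exact ties are rare
in float arithmetic but common in tiny enumerable fixtures.

**Lead re-emergence is judged within the neighborhood.** During
permutation the lead is recomputed among the LD neighborhood 𝒩ℓ only, not
the whole locus, mirroring the restriction of the procedure to variants
with |r| > 0.5 to the lead. The alternative (recomputing over all
remaining locus variants) is conceivable; we chose the neighborhood
reading because the posterior is defined, normalized and reported over 𝒩ℓ.

**Degenerate corner.** If no permutation keeps the lead for any focal
variant (possible only at extreme R·|𝒩ℓ| ≪ 1 scales), the posterior falls
back to a point mass on the lead rather than 0/0.

**Defaults.** |r| threshold 0.5, C = 3 potential sets, R = 500
permutations, uniform prior. The prior is normalized internally, making
posterior orderings invariant to its scale. One seeded generator per
fine-mapping run drives all permutations in iteration order, so results
are bit-reproducible given the seed.

## Selection strategies

*Plain* takes the pooled-posterior argmax. *Top* residualizes the
phenotype on the top `n_pcs` = 5 genotype principal components (computed
by SVD of the column-centered, unscaled dosage matrix; five follows the
usual elbow choice for this cohort structure, and an automated
largest-eigenvalue-drop elbow utility is provided but not used by
default). Because the centered dosage columns are orthogonal to the
intercept, the PC regression reduces to projecting the centered phenotype
off the left singular vectors; rank-deficient PC sets drop collinear
components with a warning. Residualization is idempotent, and with
`n_pcs=0` it reduces to centering, which leaves every correlation-based
statistic unchanged — hence top ≡ plain at `n_pcs=0`, a relation the tests
exploit.

*Stable* runs the backend on the pooled unresidualized data and on each
population slice with at least `min_slice_size` = 3 samples (correlations
are degenerate below that; smaller slices are skipped with a warning, and
a slice that yields fewer than c potential sets simply contributes no
vector for set c). For potential set c, the candidates are the variants
with positive probability in the pooled vector; each candidate's support
count is the number of available probability vectors (pooled + slices) in
which it is positive; the stable set S_c keeps the maximal-count
candidates and the pooled-posterior argmax among them is reported,
together with its support count and whether it was supported in the Yoruba
slice. Slice runs recompute their own leads — each slice run is an
independent invocation of the full algorithm, not a re-scoring of pooled
leads. *Combined* is the stable rule on the residualized phenotype.

**Backend contract.** The wrapper drives any object exposing
`fine_map(genotypes, phenotype) -> [probability vectors]` and a
`positive_support` predicate. For PICS, positive means probability > 0;
for PIP-style backends, PIP ≥ 1/(number of variants included in the run),
because such methods assign small nonzero probabilities everywhere. The
bundled `SingleEffectFineMapper` is a deliberately minimal iterative
Bayesian single-effect regression (fixed prior effect variance, fixed
residual variance) intended for exercising the wrapper and the PIP support
rule; it is not a numerical-parity reimplementation of the reference
sum-of-single-effects software, and its per-effect vectors — unlike PICS
potential sets — may overlap in support. For PIP backends the pooled PIP
plays the role of the pooled posterior in the final argmax.

## Simulator

Given a locus (optionally restricted to a ±1 Mb cis window around a TSS,
boundary inclusive), the homogeneous model draws causal indices uniformly
among variants with MAF ≥ 0.01 (the floor avoids monomorphic picks that
would make the variance target unattainable; it is a package choice, not
part of the model), effects b_j ~ N(0, 0.6²), and sets
σ² = var(Xb)·(1−φ)/φ with the empirical N−1 variance — "proportion of
variance explained" is an empirical statement about the realized genetic
values, and this choice makes SNR = var(Xb)/σ² = φ/(1−φ) hold exactly.

Heterogeneity scenarios modify only the exogenous noise, with the
population order fixed as (TSI, GBR, FIN, CEU, YRI). Variance scenarios
use per-population variances σ²(t) = 5σ²·α(t) where α(t) are the
population sizes (taken from the data's labels) raised to the power t and
normalized; α is computed in log space so t = 256 cannot overflow, and the
product is grouped as σ²·(5α) so that t = 0 reproduces the homogeneous
noise bit-exactly. Mean scenarios shift the noise mean by the smooth
(2σ, 0, σ, σ, 2σ) or spiked (0, 2σ, 0, 0, 0) vector, with σ the square
root of the homogeneous σ². All noise draws are independent across
individuals.

Grid enumeration derives one seed per (gene, n_causal, φ, replicate,
scenario) cell by SHA-256 hashing of the cell key with the master seed
(kept below 2³¹), so any cell can be regenerated in isolation; effects are
drawn fresh per replicate.

**Synthetic genotypes.** Haplotypes come from a latent-Gaussian copula:
within each LD block the latent variables follow an AR(1) process with
parameter `ld_rho`, thresholded at the normal quantile of the
population-specific ALT frequency, so marginal frequencies are exact and
LD is controllable; dosages are sums of two independent haplotypes
(Hardy–Weinberg within population). Population frequencies drift from a
shared ancestral draw by a Balding–Nichols Beta perturbation with
differentiation parameter `fst_like_drift`. This emulates the two features
the method cares about — block LD and between-population frequency
divergence — but *not* realistic recombination maps, frequency spectra,
admixture, or LD differences in structure (only in realized frequencies)
between populations. Passing tests on these genotypes therefore
demonstrate correctness of the algorithms and directional behavior of the
comparisons, not the numerical recovery rates one would obtain on real
reference-panel genotypes.

## Evaluation and annotation statistics

"Recovered" is computed in both reported senses and kept apart in column
names: the selected variant is causal (`selected_causal`), and the
potential set's support contains a causal variant (`set_contains_causal`).
Recovery intervals are Wald: freq ± 1.96·√(freq(1−freq)/n), truncated to
[0, 1]. McNemar is the exact binomial test on discordant pairs (discordant
counts are small at package scale, where the χ² approximation is poor);
zero discordant pairs yield p = 1 with a warning. Matching enrichment
contrasts the causal frequency of selections on which two strategies agree
against each strategy's selections where they disagree, with fold ratios
reported as NA when a group is empty.

Wilcoxon comparisons use the rank-sum (unpaired, matching vs non-matching)
or signed-rank (paired top-vs-stable) tests from scipy, one-sided in the
requested direction, with all-tied inputs mapped to p = 1 with a warning;
scipy's method selection uses the exact distribution for small untied
samples and the tie-corrected normal approximation otherwise.
Benjamini–Hochberg is applied jointly across annotations × potential sets
within one comparison family, and per moderator for trend tests. The
Jonckheere–Terpstra trend test is implemented by permutation (default
5000 relabelings, add-one corrected) since no installed library provides
it. F_ST is Hudson's two-population estimator
((p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1)) / (p₁(1−p₂) + p₂(1−p₁)),
chosen for its robustness to unequal sample sizes; being unbiased it can
be slightly negative near F_ST = 0. Allele frequencies are ALT-allele
dosage means / 2 — the maximized absolute pairwise difference is
indifferent to the minor/ALT convention in all non-pathological cases.
Moderator statistics that need ≥ 2 supporting subpopulations (diversity,
differentiation) are NA below that.

## Data handling

Coordinates are 1-based inclusive throughout (VCF convention); the cis
window test is |pos − TSS| ≤ window. Missing genotypes are mean-imputed
and rounded (NA propagation through row permutations would corrupt the
strata; the imputed count is logged). Multiallelic VCF records keep the
first ALT with a warning; dosages are ALT counts with no strand or allele
flipping. Result TSVs write probabilities at 17 significant digits so
read/write round trips are lossless at double precision, with run
parameters in a JSON sidecar.

## Problem sizes

The package's standard demo locus is 80 variants in LD blocks of 10 at
ρ = 0.85 over the five-population cohort (N = 445). The bundled
reduced-scale experiment uses 20 such loci × φ ∈ {0.05, 0.4} ×
{1, 3} causal variants with R = 100 permutations — large enough for the
directional conclusions (recovery increasing in φ; matching selections
enriched for causal variants) to be stable across seeds, and small enough
to run on a laptop in minutes. Full-scale grids (hundreds of loci,
R = 500) are a matter of the same API with larger parameters.

## Known limitations

- The constrained-permutation family is our reconstruction from its
  required invariances; other characterizations could in principle differ
  on inputs with repeated dosage patterns.
- PICS probabilities are not posterior inclusion probabilities of any
  linear model; credible-set coverage metrics are deliberately out of
  scope.
- The PIP backend is a testing aid, not a production fine-mapper; plug in
  a full implementation through the backend contract for real analyses.
- Synthetic genotypes do not emulate population-specific LD *patterns*,
  admixture, or realistic allele-frequency spectra.
- Trans-eQTL loci, phasing, imputation-quality modeling and
  summary-statistic-only fine-mapping are out of scope.
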
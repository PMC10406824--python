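# Methods

## Data model and fixtures

Four per-population summary tables (metadata/sizes, environmental
means + HD, genetic indices, trait means + iFD_CV) are packaged as TSV at
their printed precision and never re-derived. The raw survey records
(individual genotypes, quadrat records, individual traits) are not
redistributed; individual- and record-level operations are validated on
synthetic data with known ground truth instead. Genotypes use the GenAlEx
codominant layout (two integer allele columns per locus, 0 = missing,
configurable); individuals scored at fewer than four loci are dropped by
default, mirroring the survey's retention rule. Traits that were not
measured at the alpine site (chlorophyll-fluorescence F_v/F_m and PI) stay
missing and are excluded from averages, never imputed.

## Population size

Counts below 500 are rounded to the nearest 10; larger stands are
extrapolated as mean quadrat abundance × habitat area, rounded to the
nearest 100. Rounding is half-away-from-zero — the worked examples are
insensitive to the half rule, but fixing it keeps outputs bit-stable. The
small/large split is taken at the median with ties assigned to "small";
that tie rule is the only one that reproduces the survey's 7/6 partition
(the median population, 1100 plants, is labelled small). One printed size
(Bottendorf, 2300) is not recoverable from the printed area × abundance
because the published abundance is rounded to two decimals; the pipeline
reports its own estimate (2400) alongside the printed value.

## Environment metrics

The "+" Schmidt cover class maps to 0.5% by default (configurable; it only
feeds the community metrics, not HD). Community-weighted Ellenberg values
are abundance-weighted *means* — a raw sum would leave the 1–9 indicator
scale, which the published per-population values do not. Species flagged
indifferent ("x") are excluded from numerator and denominator.
Per-population Ellenberg summaries take the median across records. Heip
evenness is defined as 1 for a single species. All CVs use the sample
(n − 1) standard deviation, consistently between HD and iFD_CV. Slope
exposure enters its CV as plain compass degrees to mirror the original
analysis; a circular treatment would be defensible but would change HD for
north-facing sites, so it is not the default.

## Genetic indices

H_e is the plain 1 − Σp² estimator, not the small-sample-corrected one:
the published F_IS column equals (H_e − H_o)/H_e under the plain form to
within 5 × 10⁻⁴ for all 13 populations, which pins the convention. Locus
means are unweighted; N_A is the *sum* of distinct alleles over loci (the
published range 49–71 across nine loci is incompatible with a per-locus
mean); P_Ap is normalized by the population's own N_A (3/52 = 5.77%
matches the published value). The per-population G_ST estimator behind the
published column is ambiguous in its source; both a pairwise-mean Nei
G_ST (default) and a focal-vs-pooled-rest variant are implemented, and no
published-value check recomputes G_ST from genotypes. Identical multilocus
genotypes are reported, not removed — clones were screened upstream in the
survey.

## Regression and ordination

Only explanatory variables are standardized; population size and habitat
area are natural-logged before standardization. Backward selection drops
exactly one term per step (largest p; ties toward the later column) while
p > 0.1, logging AIC and the nested-model F-test. AIC is monitored, not
enforced: dropping a term with p just above the threshold raises AIC
whenever t² exceeds ≈ 2 (p ≲ 0.17 at n = 100), and the tests assert
exactly that boundary rather than a blanket "AIC always falls".
Contribution shares use absolute standardized coefficients, since the
survey reports positive percentages for effects of both signs. Permutation
p-values are two-sided with the add-one correction (never zero); for n ≤ 8
an exact enumeration over all n! shuffles is available and is what the
calibration tests compare against. PCA is the correlation PCA
(z-score, then SVD) with a deterministic sign convention
(largest-magnitude loading positive); the survey's "+5 range shift"
provably cannot change it, and a regression test asserts score equality
with and without the shift. The environmental PCA takes the 22 numeric
variables (ordinal slope exposure excluded, alpine site excluded); its
variable set is configurable because the published 45% two-component
figure does not pin it down.

## Piecewise SEM

The basis set follows the union convention: one claim per non-adjacent
pair with at least one endogenous member, conditioned on the parents of
both, oriented toward the downstream variable; exogenous–exogenous pairs
are excluded and declared correlated-error pairs are exempt. Claims are
tested as the two-sided t-test of the partial coefficient in an OLS of the
downstream variable. Fisher's C floors claim p-values at 10⁻¹² (floored
claims are logged). The packaged full-study DAG (eight habitat-factor CVs
plus HD → ln size; ln area → HD; ln size → six genetic indices; HD → H_e;
HD and H_e → iFD_CV; nine published correlated-error pairs, one of which
duplicates an edge and is ignored with a warning) yields 99 claims; the
survey reports 84, a count that cannot be reconstructed unambiguously from
the published description, so the size is reported, never asserted. On the
packaged summary tables only the reduced model (without the record-level
CV terms) can be refit, and it is labelled as such in the provenance.

## Synthetic data

The generator mirrors the survey design: 13 populations, 20 plants, 9
loci (8 alleles each), 5 records, H_e targets spanning 0.57–0.69, 10%
missing genotype scores, inbreeding f = 0.05, factor CVs in 0.05–0.35 with
means typical of central-European semi-dry grassland soils. Allele
frequencies come from a symmetric Dirichlet whose concentration solves
E[1 − Σp²] = H_e target; genotypes follow the inbreeding mixture
P(hom i) = p² + f·p(1 − p). Environmental factors are truncated normals
with sd = CV × mean; truncation slightly shrinks realized CVs, which the
calibration tolerances (± 0.03–0.05) absorb. `simulate_study` wires the
causal structure in by construction — factor CVs drive ln size, H_e
targets rise with ln size, trait dispersion rises with HD and H_e — and
records every generating coefficient in a truth ledger.

What passing synthetic tests do *not* show: the generator draws
independent Gaussian factors and Dirichlet frequencies, so it cannot
expose spatial autocorrelation, locus-specific mutation behavior, or
non-Gaussian trait distributions of real surveys. One deliberate
realism: genetic indices estimated from the *same* genotypes are
residually correlated (H_o with H_e, I with N_A, …) beyond what the DAG
declares, so the global d-separation test rejects on full synthetic
surveys — the same phenomenon the original analysis absorbed by declaring
correlated errors. SEM calibration (global p > 0.05 in ≥ 90% of
replicates, coefficient coverage) is therefore tested on data generated
exactly under the DAG via `simulate_psem_dataset`.

## Problem sizes and numerical choices

Fixture-level computations are 13-row problems and effectively instant.
Simulation-based tests use 200–500 individuals/records per population for
estimator recovery, 20–25 replicates at n = 200 for SEM calibration, and
60–200 replicates for type-I-rate checks — sizes at which binomial and
Monte-Carlo error are small relative to the asserted tolerances. All
generators are pure functions of (config, seed); reruns are byte-identical.

## Known limitations

* The published 68% two-component trait-PCA figure is not reproducible
  from the printed (rounded) trait means, which give 65.2%; perturbing the
  means within their rounding intervals spans only 64.8–65.6%, so the
  original value was evidently computed from unrounded data. The pipeline
  reports the honest recomputed value.
* Quantities that need the raw field records (the CV → size multiple
  regression R²_adj = .96, Fisher's C = 146.50, HD and iFD_CV column
  recomputation, the total allele count) are covered by parameter-recovery
  and oracle-equivalence properties on synthetic data, not by value checks.
* The G_ST published column cannot be validated against genotypes without
  the raw data; both candidate estimators are exposed.
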
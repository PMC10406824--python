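# tmontanum

Population size, habitat heterogeneity, microsatellite diversity and
intraspecific trait variation (ITV) in *Trifolium montanum* (mountain
clover), rebuilt as a tested, reproducible analysis pipeline.

## The scientific problem

Small plant populations are expected to lose genetic diversity, accumulate
inbreeding, and ultimately show reduced phenotypic variability and
performance. This package implements the complete chain of analyses for a
13-population semi-dry grassland survey that links those layers:

* **Population size** — direct counts (< 500 plants, rounded to 10) or
  extrapolation from quadrat abundance × occupied area (rounded to 100),
  classified small/large at the median.
* **Habitat heterogeneity** — per-factor coefficients of variation
  (CV = s/x̄) over 4 m² vegetation records for ten non-collinear abiotic
  factors; their mean is the heterogeneity index **HD**. Community metrics:
  species richness S, Heip evenness E = (e^H′ − 1)/(S − 1), and
  community-weighted Ellenberg indicator values Σaᵢvᵢ/Σaᵢ.
* **Population genetics** (9 microsatellite loci, ≤ 20 diploid plants per
  population): allelic richness N_A, private-allele percentage P_Ap,
  observed heterozygosity H_o, Nei's expected heterozygosity
  H_e = 1 − Σp², Shannon's I = −Σp ln p, inbreeding coefficient
  F_IS = (H_e − H_o)/H_e, and per-population differentiation G_ST.
* **Traits** — nine functional traits; intraspecific trait variation
  **iFD_CV** is the mean CV over traits across individuals.
* **Statistics** — standardized OLS with backward selection (drop the
  least significant term while p > .1, AIC-monitored), contribution
  shares |β|/Σ|β|, correlation PCA with permutation-tested axis
  correlations, and a piecewise structural-equation model whose
  d-separation basis set is aggregated by Fisher's
  C = −2Σ ln p ~ χ²(2k).

The per-population summary tables of the survey are packaged as fixtures;
a synthetic-data generator with a recorded truth ledger stands in for the
raw field records, so every record-level stage is testable end to end.

## Worked example

```python
from tmontanum import run_study

results = run_study()          # packaged summary tables
row = results.regressions.query("response == 'H_o'").iloc[0]
print(f"H_o ~ ln N: R2 = {row.r2:.2f}, p = {row.p:.4f}")
fit = results.psem_fit
print(f"reduced path model: C = {fit.fishers_c:.2f}, p = {fit.global_p:.2f}")
print(f"iFD_CV component R2 = {fit.r2()['iFD_CV']:.2f}")
```

prints

```
H_o ~ ln N: R2 = 0.67, p = 0.0006
reduced path model: C = 73.93, p = 0.11
iFD_CV component R2 = 0.81
```

i.e. observed heterozygosity rises strongly with log population size, the
summary-level path model is consistent with the data, and habitat
heterogeneity plus expected heterozygosity explain 81% of the variance in
trait variation.

The numbered scripts under `analysis/` walk through the study stage by
stage (sizes, environment, genetics, traits, path model, synthetic
recovery) and write their tables under `results/`. A thin CLI mirrors the
two entry points: `tmontanum run` and `tmontanum simulate --seed 1`.

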
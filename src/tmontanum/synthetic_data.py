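"""Synthetic field studies with known ground truth.

The generator emulates the design of the real survey — 13 grassland
populations, up to 20 plants genotyped at 9 microsatellite loci, five 4 m^2
vegetation records per site with ten abiotic factors, nine functional
traits — but with every generating parameter recorded, so parameter
recovery of the whole pipeline (allele-frequency-based indices, CV-based
habitat heterogeneity, the CV -> population size link, the trait-dispersion
links) can be tested without the field data.

Genotypes: per population and locus, allele frequencies are drawn from a
symmetric Dirichlet whose concentration is solved so the expected
heterozygosity matches the target; diploid genotypes then follow the
inbreeding mixture P(homozygote i) = p_i^2 + f p_i (1 - p_i), which is what
the F_IS estimator should recover.  Environmental factors are truncated
normals with sd = CV x mean (truncation slightly shrinks realized CVs; the
calibration tests carry that tolerance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from tmontanum.data_io import GenotypeTable, VegetationTable
from tmontanum.env_metrics import HD_FACTORS

#: Realistic central-German semi-dry grassland factor means (units as measured).
DEFAULT_FACTOR_MEANS = {
    "altitude": 400.0,      # m a.s.l.
    "slope_exposure": 200.0,  # compass degrees
    "slope": 10.0,          # degrees
    "LAI": 3.0,             # unitless
    "soil_depth": 15.0,     # cm
    "CEC_pot": 16.0,        # cmol/kg
    "pH": 7.0,
    "N": 0.5,               # percent
    "P": 1.4,               # mg/100 g
    "K": 15.0,              # mg/100 g
}

#: Sign pattern of the CV -> ln population size link found in the study:
#: more variable soil depth / altitude / N / exposure shrink populations,
#: more variable LAI / K / pH / P / slope go with larger ones.
DEFAULT_SIZE_COEFS = {
    "CV_LAI": 0.9, "CV_soil_depth": -0.85, "CV_K": 0.8, "CV_N": -0.5,
    "CV_pH": 0.5, "CV_altitude": -0.45, "CV_P": 0.3, "CV_slope_exposure": -0.3,
    "CV_slope": 0.2,
}

#: Trait means on the scale of the study's trait table.
DEFAULT_TRAIT_MEANS = {
    "RH": 35.0, "AGB": 1.0, "LA": 700.0, "SLA": 16.0, "LDMC": 270.0,
    "FvFm": 0.84, "PI": 9.0, "SPS": 255.0, "SPI": 2.9,
}


@dataclass
class SimConfig:
    """Study-level generating parameters (defaults mirror the field design)."""

    n_populations: int = 13
    n_individuals: int = 20
    n_loci: int = 9
    n_alleles: int = 8
    he_target: float | tuple[float, float] = (0.57, 0.69)  # range across pops
    inbreeding_f: float = 0.05
    missing_rate: float = 0.10          # the survey scored ~90% of loci
    factor_means: dict = field(default_factory=lambda: dict(DEFAULT_FACTOR_MEANS))
    cv_range: tuple[float, float] = (0.05, 0.35)  # per-pop factor CV targets
    n_records: int = 5
    richness: int = 25
    size_coefs: dict = field(default_factory=lambda: dict(DEFAULT_SIZE_COEFS))
    size_intercept: float = 7.0          # ln scale, e^7 ~ 1100 plants
    size_sigma: float = 0.15             # residual sd of ln size
    he_size_slope: float = 0.02          # He gain per unit ln size
    trait_means: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_MEANS))
    trait_base_cv: float = 0.10
    trait_cv_hd_slope: float = 0.5       # dispersion gain per unit HD
    trait_cv_he_slope: float = 0.8       # dispersion gain per unit He

    def validate(self) -> None:
        if not 0 <= self.inbreeding_f < 1:
            raise ValueError("inbreeding f must lie in [0, 1)")
        if min(self.cv_range) < 0:
            raise ValueError("CV targets must be non-negative")
        for n in (self.n_populations, self.n_individuals, self.n_loci,
                  self.n_alleles, self.n_records, self.richness):
            if n <= 0:
                raise ValueError("all counts must be positive")

    def he_targets(self) -> np.ndarray:
        if np.isscalar(self.he_target):
            return np.full(self.n_populations, float(self.he_target))
        lo, hi = self.he_target
        return np.linspace(lo, hi, self.n_populations)


@dataclass
class SimulatedStudy:
    genotypes: GenotypeTable
    vegetation: VegetationTable
    traits: pd.DataFrame
    meta: pd.DataFrame
    truth: dict


def _dirichlet_alpha(he: float, k: int) -> float:
    """Concentration of a symmetric Dirichlet(k) with E[1 - sum p^2] = he."""
    he_max = 1.0 - 1.0 / k
    if he >= he_max:
        raise ValueError(f"He target {he} infeasible with {k} alleles (max {he_max})")
    if he <= 0:
        raise ValueError("He target must be positive")
    return he / (k - 1 - k * he)


def _pop_names(n: int) -> list[str]:
    return [f"P{i + 1:02d}" for i in range(n)]


def simulate_genotypes(
    config: SimConfig,
    seed: int,
    he_targets=None,
    f=None,
) -> GenotypeTable:
    """Diploid genotypes under the Dirichlet/inbreeding-mixture model."""
    config.validate()
    rng = np.random.default_rng(seed)
    pops = _pop_names(config.n_populations)
    he = np.asarray(he_targets if he_targets is not None else config.he_targets())
    fs = np.full(config.n_populations, config.inbreeding_f if f is None else f,
                 dtype=float)
    loci = [f"L{j + 1}" for j in range(config.n_loci)]
    lengths = 100 + 2 * np.arange(config.n_alleles)  # fragment lengths
    rows = []
    for pi, pop in enumerate(pops):
        for locus in loci:
            if config.n_alleles == 1:
                freq = np.array([1.0])
            else:
                alpha = _dirichlet_alpha(he[pi], config.n_alleles)
                freq = rng.dirichlet(np.full(config.n_alleles, alpha))
            for ind in range(config.n_individuals):
                name = f"{pop}_i{ind + 1:03d}"
                if rng.random() < fs[pi]:
                    a = b = rng.choice(config.n_alleles, p=freq)
                else:
                    a, b = rng.choice(config.n_alleles, size=2, p=freq)
                rows.append((pop, name, locus, lengths[a], lengths[b]))
    df = pd.DataFrame(rows, columns=["population", "individual", "locus",
                                     "allele_a", "allele_b"])
    if config.missing_rate > 0:
        # never blank an individual's first locus, so everyone keeps >= 1 locus
        mask = (rng.random(len(df)) < config.missing_rate) & (df["locus"] != loci[0])
        df.loc[mask, ["allele_a", "allele_b"]] = 0
    return GenotypeTable(df)


def _truncated_normal(rng, mean, sd, lower, upper, size):
    if sd == 0:
        return np.full(size, mean)
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


_FACTOR_BOUNDS = {
    "slope_exposure": (0.0, 360.0),
    "pH": (2.0, 12.0),
}


def simulate_environment(
    config: SimConfig,
    seed: int,
    cv_targets: pd.DataFrame | None = None,
) -> VegetationTable:
    """Vegetation records with controlled per-factor CVs and fixed richness.

    ``cv_targets`` (populations x factors) overrides the uniform draw from
    ``config.cv_range``.  Every species occurs in every record, so pooled
    richness equals the configured value by construction.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    pops = _pop_names(config.n_populations)
    factors = list(config.factor_means)
    if cv_targets is None:
        lo, hi = config.cv_range
        cv_targets = pd.DataFrame(
            rng.uniform(lo, hi, size=(len(pops), len(factors))),
            index=pops, columns=factors)
    abiotic_rows, species_rows = [], []
    schmidt_numeric = [1, 3, 5, 8, 10, 15, 20, 25, 30, 40]
    for pop in pops:
        for r in range(config.n_records):
            row = {"population": pop, "record": f"{pop}_r{r + 1}"}
            for fac in factors:
                mean = config.factor_means[fac]
                lower, upper = _FACTOR_BOUNDS.get(fac, (1e-6, np.inf))
                row[fac] = _truncated_normal(
                    rng, mean, cv_targets.loc[pop, fac] * mean, lower, upper, 1)[0]
            abiotic_rows.append(row)
            for s in range(config.richness):
                species_rows.append({
                    "population": pop,
                    "record": row["record"],
                    "species": f"sp{s + 1:03d}",
                    "schmidt": int(rng.choice(schmidt_numeric)),
                })
    return VegetationTable(
        species=pd.DataFrame(species_rows),
        abiotic=pd.DataFrame(abiotic_rows),
    )


def simulate_traits(
    config: SimConfig,
    seed: int,
    hd: pd.Series,
    he: pd.Series,
) -> pd.DataFrame:
    """Individual trait values whose dispersion grows with HD and He."""
    rng = np.random.default_rng(seed)
    rows = []
    for pop in hd.index:
        cv = (config.trait_base_cv
              + config.trait_cv_hd_slope * hd[pop]
              + config.trait_cv_he_slope * max(he[pop] - 0.5, 0.0))
        for ind in range(config.n_individuals):
            row = {"population": pop, "individual": f"{pop}_i{ind + 1:03d}"}
            for trait, mean in config.trait_means.items():
                row[trait] = max(rng.normal(mean, cv * mean), 1e-6 * mean)
            rows.append(row)
    return pd.DataFrame(rows)


def simulate_psem_dataset(
    spec,
    n: int,
    seed: int,
    coef_range: tuple[float, float] = (0.5, 1.0),
    noise_sd: float = 1.0,
) -> tuple[pd.DataFrame, dict[tuple[str, str], float]]:
    """Linear-Gaussian data generated exactly under a path-model DAG.

    Every variable is a linear function of its parents plus N(0, noise_sd)
    noise, with edge coefficients drawn uniformly from ``coef_range`` (sign
    randomized).  Columns named in ``spec.log_vars`` are exponentiated so
    that refitting the model (which logs them again) sees the generating
    scale.  Returns the data and the generating edge coefficients.
    """
    import networkx as nx

    rng = np.random.default_rng(seed)
    g = spec.graph()
    order = list(nx.topological_sort(g))
    lo, hi = coef_range
    coefs = {
        (a, b): float(rng.uniform(lo, hi) * rng.choice([-1.0, 1.0]))
        for a, b in g.edges
    }
    data = pd.DataFrame(index=range(n))
    for v in order:
        x = rng.normal(0.0, noise_sd, n)
        for parent in g.predecessors(v):
            x = x + coefs[(parent, v)] * data[parent].values
        data[v] = x
    for v in spec.log_vars:
        if v in data.columns:
            data[v] = np.exp((data[v] - data[v].mean()) / max(data[v].std(), 1e-9))
    return data, coefs


def simulate_study(config: SimConfig, seed: int) -> SimulatedStudy:
    """A full synthetic survey with the causal structure of the field study.

    Per-population factor CVs drive ln population size through the
    configured linear link (so the CV -> size path is true by
    construction); expected-heterozygosity targets rise with ln size;
    trait dispersion rises with heterogeneity and heterozygosity.  The
    truth ledger records every generating coefficient.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    pops = _pop_names(config.n_populations)
    factors = list(config.factor_means)
    lo, hi = config.cv_range
    cv_targets = pd.DataFrame(
        rng.uniform(lo, hi, size=(len(pops), len(factors))),
        index=pops, columns=factors)
    # ln size from standardized CVs
    z = (cv_targets - cv_targets.mean()) / cv_targets.std(ddof=1)
    ln_size = pd.Series(config.size_intercept, index=pops, dtype=float)
    for term, coef in config.size_coefs.items():
        fac = term.removeprefix("CV_")
        if fac in z.columns:
            ln_size += coef * z[fac]
    ln_size += rng.normal(0.0, config.size_sigma, len(pops))
    sizes = np.exp(ln_size)
    # genetic diversity targets rise with ln size
    he_max = 1.0 - 1.0 / config.n_alleles
    he = np.clip(
        0.60 + config.he_size_slope * (ln_size - ln_size.mean()),
        0.30, he_max - 0.05)
    he = pd.Series(he, index=pops)
    genotypes = simulate_genotypes(
        config, int(rng.integers(2**31)), he_targets=he.values)
    vegetation = simulate_environment(
        config, int(rng.integers(2**31)), cv_targets=cv_targets)
    hd = cv_targets.loc[:, [f for f in HD_FACTORS if f in cv_targets.columns]].mean(axis=1)
    traits = simulate_traits(config, int(rng.integers(2**31)), hd=hd, he=he)
    abundance = rng.uniform(1.0, 10.0, len(pops))
    meta = pd.DataFrame({
        "habitat_area_m2": sizes / abundance,
        "abundance_per_m2": abundance,
        "direct_count": [int(round(s)) if s < 500 else np.nan for s in sizes],
    }, index=pd.Index(pops, name="population"))
    truth = {
        "cv_targets": cv_targets,
        "ln_size": ln_size,
        "he_targets": he,
        "hd_targets": hd,
        "inbreeding_f": config.inbreeding_f,
        "size_coefs": dict(config.size_coefs),
        "size_intercept": config.size_intercept,
        "trait_base_cv": config.trait_base_cv,
        "trait_cv_hd_slope": config.trait_cv_hd_slope,
        "trait_cv_he_slope": config.trait_cv_he_slope,
    }
    return SimulatedStudy(genotypes=genotypes, vegetation=vegetation,
                          traits=traits, meta=meta, truth=truth)
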
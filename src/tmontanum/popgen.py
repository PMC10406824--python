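"""Microsatellite diversity, inbreeding and differentiation indices.

Per locus and population: observed heterozygosity Ho (fraction of typed
individuals carrying two different alleles), Nei's expected heterozygosity
He = 1 - sum(p_i^2), Shannon's I = -sum(p_i ln p_i).  Population values are
unweighted means over scored loci; allelic richness N_A is the total count
of distinct alleles over loci.  F_IS = (He - Ho) / He from the population
means; G_ST contrasts a focal population against the others (pairwise mean
of Nei's two-population G_ST by default).  He is the plain (biased)
estimator, the form under which the study's printed F_IS column is exactly
(He - Ho)/He.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from tmontanum.data_io import GenotypeTable

logger = logging.getLogger(__name__)


@dataclass
class AlleleFrequencies:
    population: str
    locus: str
    freq: pd.Series  # allele -> relative frequency
    n_typed: int


def allele_frequencies(
    genotypes: GenotypeTable, population: str, locus: str
) -> AlleleFrequencies | None:
    """Allele frequencies at one locus in one population.

    Each typed individual contributes both alleles.  Returns ``None`` (with
    a warning) when the locus is entirely missing in that population.
    """
    sub = genotypes.scored()
    sub = sub[(sub["population"] == population) & (sub["locus"] == locus)]
    if sub.empty:
        logger.warning("locus %s entirely missing in population %s", locus, population)
        return None
    alleles = pd.concat([sub["allele_a"], sub["allele_b"]])
    freq = alleles.value_counts(normalize=True).sort_index()
    return AlleleFrequencies(population, locus, freq, n_typed=len(sub))


def _he(freq: pd.Series) -> float:
    return float(1.0 - (freq**2).sum())


def _shannon(freq: pd.Series) -> float:
    p = freq[freq > 0]
    return float(-(p * np.log(p)).sum())


def diversity_indices(
    genotypes: GenotypeTable, population: str
) -> tuple[float, float, float, int]:
    """(Ho, He, I, N_A) for one population, means over scored loci."""
    ho, he, shannon, n_a = [], [], [], 0
    for locus in genotypes.loci:
        af = allele_frequencies(genotypes, population, locus)
        if af is None:
            continue
        sub = genotypes.scored()
        sub = sub[(sub["population"] == population) & (sub["locus"] == locus)]
        ho.append(float((sub["allele_a"] != sub["allele_b"]).mean()))
        he.append(_he(af.freq))
        shannon.append(_shannon(af.freq))
        n_a += len(af.freq)
    if not ho:
        raise ValueError(f"population {population} has no typed loci")
    return (float(np.mean(ho)), float(np.mean(he)), float(np.mean(shannon)), n_a)


def inbreeding_coefficient(h_o: float, h_e: float) -> float | None:
    """F_IS = (He - Ho)/He from population-mean heterozygosities.

    Positive values mean homozygote excess (inbreeding).  Undefined (None)
    for He = 0.
    """
    if h_e == 0:
        return None
    return (h_e - h_o) / h_e


def private_allele_pct(genotypes: GenotypeTable) -> pd.Series:
    """Percentage of each population's alleles found in no other population.

    Normalized by the population's own allelic richness N_A, i.e. a
    population with 52 alleles of which 3 are unique scores 3/52 = 5.77%.
    """
    pops = genotypes.populations
    if len(pops) < 2:
        logger.warning("single population: every allele is trivially private")
    # allele identity is (locus, length)
    seen: dict[str, set[tuple[str, int]]] = {}
    scored = genotypes.scored()
    for pop in pops:
        sub = scored[scored["population"] == pop]
        alleles = set(zip(sub["locus"], sub["allele_a"])) | set(
            zip(sub["locus"], sub["allele_b"]))
        seen[pop] = alleles
    out = {}
    for pop in pops:
        others = set().union(*(seen[q] for q in pops if q != pop)) if len(pops) > 1 else set()
        private = seen[pop] - others
        out[pop] = 100.0 * len(private) / len(seen[pop])
    return pd.Series(out, name="P_Ap")


def _pairwise_gst(fa: pd.Series, fb: pd.Series) -> float | None:
    """Nei's G_ST between two allele-frequency vectors at one locus."""
    alleles = fa.index.union(fb.index)
    pa = fa.reindex(alleles, fill_value=0.0)
    pb = fb.reindex(alleles, fill_value=0.0)
    hs = (_he(pa) + _he(pb)) / 2.0
    ht = _he((pa + pb) / 2.0)
    if ht == 0:
        return None
    return (ht - hs) / ht


def gst_per_population(
    genotypes: GenotypeTable, focal: str, mode: str = "pairwise_mean"
) -> float:
    """Differentiation of one population relative to all the others.

    mode "pairwise_mean": mean over other populations of the locus-averaged
    two-population Nei G_ST.  mode "focal_vs_rest": G_ST between the focal
    population and the pooled remainder (populations weighted equally).
    """
    pops = genotypes.populations
    if len(pops) < 2:
        raise ValueError("G_ST needs at least two populations")
    freqs: dict[str, dict[str, pd.Series]] = {}
    for pop in pops:
        freqs[pop] = {}
        for locus in genotypes.loci:
            af = allele_frequencies(genotypes, pop, locus)
            if af is not None:
                freqs[pop][locus] = af.freq
    others = [p for p in pops if p != focal]
    if mode == "pairwise_mean":
        pair_means = []
        for other in others:
            per_locus = []
            for locus in genotypes.loci:
                if locus in freqs[focal] and locus in freqs[other]:
                    g = _pairwise_gst(freqs[focal][locus], freqs[other][locus])
                    if g is not None:
                        per_locus.append(g)
            if per_locus:
                pair_means.append(float(np.mean(per_locus)))
        if not pair_means:
            raise ValueError("G_ST undefined: no polymorphic shared loci")
        return float(np.mean(pair_means))
    if mode == "focal_vs_rest":
        per_locus = []
        for locus in genotypes.loci:
            if locus not in freqs[focal]:
                continue
            rest = [freqs[p][locus] for p in others if locus in freqs[p]]
            if not rest:
                continue
            alleles = freqs[focal][locus].index
            for f in rest:
                alleles = alleles.union(f.index)
            pooled = sum(f.reindex(alleles, fill_value=0.0) for f in rest) / len(rest)
            g = _pairwise_gst(freqs[focal][locus], pooled)
            if g is not None:
                per_locus.append(g)
        if not per_locus:
            raise ValueError("G_ST undefined: no polymorphic loci")
        return float(np.mean(per_locus))
    raise ValueError(f"unknown G_ST mode {mode!r}")


def find_identical_genotypes(genotypes: GenotypeTable) -> list[tuple[str, list[str]]]:
    """Report (not remove) identical multilocus genotypes within populations.

    Suspected clones were screened out upstream in the field study; this
    check only flags candidates.
    """
    out = []
    for pop in genotypes.populations:
        sub = genotypes.data[genotypes.data["population"] == pop]
        keys = {}
        for ind, g in sub.groupby("individual"):
            key = tuple(sorted(
                (r.locus, min(r.allele_a, r.allele_b), max(r.allele_a, r.allele_b))
                for r in g.itertuples()))
            keys.setdefault(key, []).append(ind)
        for inds in keys.values():
            if len(inds) > 1:
                out.append((pop, sorted(inds)))
    return out


def summarize(
    genotypes: GenotypeTable, gst_mode: str = "pairwise_mean"
) -> pd.DataFrame:
    """Per-population table of N_A, P_Ap, Ho, He, I, F_IS and G_ST."""
    pap = private_allele_pct(genotypes)
    rows = {}
    for pop in genotypes.populations:
        ho, he, shannon, n_a = diversity_indices(genotypes, pop)
        rows[pop] = {
            "n": genotypes.n_individuals(pop),
            "N_A": n_a,
            "P_Ap": pap[pop],
            "H_o": ho,
            "H_e": he,
            "I": shannon,
            "F_IS": inbreeding_coefficient(ho, he),
            "G_ST": gst_per_population(genotypes, pop, mode=gst_mode),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "population"
    return out
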
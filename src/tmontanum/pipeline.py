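"""End-to-end orchestration: data -> summaries -> models -> results bundle.

Two entry points share the statistical stages.  On the packaged summary
tables the pipeline reruns everything the printed numbers support: size
estimation and the small/large split, internal consistency of the
inbreeding coefficient, the size ~ genetics regressions (with the named
sensitivity refit of G_ST excluding the study's largest-G_ST outlier
population), the genetic-index correlation matrix, both PCAs, and the
reduced path model.  On a synthetic study (or user-supplied raw tables) it
additionally computes the record-level stages - allele-frequency indices,
per-factor CVs and HD, individual-level iFD_CV - and fits the full path
model including the CV -> size stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from tmontanum import env_metrics, ordination, popgen, population_size, psem
from tmontanum import regression as reg
from tmontanum import trait_metrics
from tmontanum.data_io import FixtureBundle, load_fixtures
from tmontanum.synthetic_data import SimulatedStudy

GENETIC_INDICES = ("N_A", "P_Ap", "H_o", "H_e", "I", "F_IS", "G_ST")

TRAIT_PCA_VARS = ("RH", "AGB", "LA", "SLA", "LDMC", "FvFm", "PI", "SPS", "SPI")

#: Numeric environmental variables for the environmental PCA; the ordinal
#: slope exposure stays out, matching the study's ordination.
ENV_PCA_VARS = (
    "altitude", "T_a", "P_a", "slope", "LAI", "crop_height", "soil_depth",
    "CEC_pot", "pH", "N", "P", "K", "wL", "wK", "wF", "wT", "wR", "wN",
    "S", "E", "cover_herb", "bare_ground",
)


@dataclass
class StudyResults:
    summary: pd.DataFrame                 # per-population merged table
    regressions: pd.DataFrame             # size ~ index fits
    correlations: pd.DataFrame            # genetic-index correlation matrix
    pca_traits: ordination.PcaResult | None
    pca_env: ordination.PcaResult | None
    psem_fit: psem.PsemFit | None
    provenance: dict = field(default_factory=dict)

    def to_bundle(self, outdir: str | Path) -> None:
        """Write the TSV + JSON results bundle."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(out / "summary.tsv", sep="\t")
        self.regressions.to_csv(out / "regressions.tsv", sep="\t", index=False)
        self.correlations.to_csv(out / "index_correlations.tsv", sep="\t")
        report: dict = {"provenance": self.provenance}
        for name, p in (("traits", self.pca_traits), ("environment", self.pca_env)):
            if p is not None:
                report[f"pca_{name}"] = {
                    "variance_fraction": [round(v, 6) for v in p.variance_fraction],
                    "variables": p.variables,
                }
        if self.psem_fit is not None:
            report["psem"] = {
                "fishers_c": round(self.psem_fit.fishers_c, 4),
                "df": self.psem_fit.df,
                "global_p": round(self.psem_fit.global_p, 4),
                "n_claims": len(self.psem_fit.claims),
                "component_r2": {k: round(v, 4)
                                 for k, v in self.psem_fit.r2().items()},
            }
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)


def _size_regressions(
    table3: pd.DataFrame, sizes: pd.Series, gst_exclude: tuple[str, ...]
) -> pd.DataFrame:
    """Each genetic index regressed on ln population size."""
    rows = []
    lnN = np.log(sizes.astype(float)).rename("lnN")
    for index in GENETIC_INDICES:
        if index not in table3.columns:
            continue
        fit = reg.fit_ols(table3[index], lnN.to_frame(), standardize=True,
                          response=index)
        rows.append({"response": index, "predictor": "lnN", "subset": "all",
                     "slope_std": fit.coef["lnN"], "r2": fit.r2,
                     "p": fit.pvalues["lnN"], "n": fit.n})
    if gst_exclude and "G_ST" in table3.columns:
        keep = [p for p in table3.index if p not in gst_exclude]
        fit = reg.fit_ols(table3.loc[keep, "G_ST"], lnN.loc[keep].to_frame(),
                          standardize=True, response="G_ST")
        rows.append({"response": "G_ST", "predictor": "lnN",
                     "subset": f"excl. {','.join(gst_exclude)}",
                     "slope_std": fit.coef["lnN"], "r2": fit.r2,
                     "p": fit.pvalues["lnN"], "n": fit.n})
    return pd.DataFrame(rows)


def run_fixture_study(
    fixtures: FixtureBundle | None = None,
    gst_exclude: tuple[str, ...] = ("St",),
    pca_exclude: tuple[str, ...] = ("KW",),
) -> StudyResults:
    """Re-run the printed-table analyses.

    ``gst_exclude`` names the populations for the G_ST sensitivity refit;
    ``pca_exclude`` the populations dropped from both PCAs (the alpine site
    in the study: different climate, missing fluorescence traits).
    """
    fx = fixtures or load_fixtures()
    # stands below the direct-count limit were censused; their printed size is
    # the (rounded) count itself
    direct = [
        s if s < population_size.DIRECT_COUNT_LIMIT else np.nan
        for s in fx.table1["population_size"]
    ]
    sizes = population_size.estimate_sizes(fx.table1.assign(direct_count=direct))
    summary = pd.concat(
        [fx.table1[["habitat_area_m2", "abundance_per_m2", "population_size",
                    "size_class"]],
         sizes.add_prefix("est_"),
         fx.table2[["HD"]],
         fx.table3[list(GENETIC_INDICES)],
         fx.table4[["iFD_CV"]]],
        axis=1)
    summary["F_IS_recomputed"] = [
        popgen.inbreeding_coefficient(r.H_o, r.H_e) for r in summary.itertuples()]
    regressions = _size_regressions(
        fx.table3, fx.table1["population_size"], gst_exclude)
    # HD ~ ln area and size ~ HD, the two environment-level fits
    lnA = np.log(fx.table1["habitat_area_m2"]).rename("ln_area")
    fit_hd = reg.fit_ols(fx.table2["HD"], lnA.to_frame(), response="HD")
    fit_sz = reg.fit_ols(np.log(fx.table1["population_size"]).rename("lnN"),
                         fx.table2[["HD"]], response="lnN")
    regressions = pd.concat([regressions, pd.DataFrame([
        {"response": "HD", "predictor": "ln_area", "subset": "all",
         "slope_std": fit_hd.coef["ln_area"], "r2": fit_hd.r2,
         "p": fit_hd.pvalues["ln_area"], "n": fit_hd.n},
        {"response": "lnN", "predictor": "HD", "subset": "all",
         "slope_std": fit_sz.coef["HD"], "r2": fit_sz.r2,
         "p": fit_sz.pvalues["HD"], "n": fit_sz.n},
    ])], ignore_index=True)
    correlations = fx.table3[list(GENETIC_INDICES)].corr(method="pearson")
    keep = [p for p in fx.table4.index if p not in pca_exclude]
    pca_traits = ordination.pca(fx.table4.loc[keep, list(TRAIT_PCA_VARS)])
    env_vars = [v for v in ENV_PCA_VARS if v in fx.table2.columns]
    pca_env = ordination.pca(fx.table2.loc[keep, env_vars])
    # reduced path model: the record-level CV terms are not in the summary
    # tables, so the CV -> size stage cannot be refit here
    data = pd.concat([
        fx.table1[["population_size", "habitat_area_m2"]].rename(
            columns={"population_size": "size", "habitat_area_m2": "habitat_area"}),
        fx.table2[["HD"]], fx.table3[list(GENETIC_INDICES)],
        fx.table4[["iFD_CV"]]], axis=1)
    fit = psem.fit_psem(psem.reduced_model_spec(), data)
    return StudyResults(
        summary=summary,
        regressions=regressions,
        correlations=correlations,
        pca_traits=pca_traits,
        pca_env=pca_env,
        psem_fit=fit,
        provenance={"inputs": "packaged summary tables",
                    "psem": "reduced model (summary-level data)",
                    "gst_exclude": list(gst_exclude),
                    "pca_exclude": list(pca_exclude)},
    )


def run_synthetic_study(
    sim: SimulatedStudy, min_loci: int = 4, seed: int | None = None
) -> StudyResults:
    """Full record-level pipeline on a simulated survey, incl. the full SEM."""
    genotypes = sim.genotypes.drop_undertyped(min_loci)
    gen_summary = popgen.summarize(genotypes)
    hd_rows = {}
    for pop in sim.meta.index:
        hs = env_metrics.habitat_heterogeneity(
            sim.vegetation.records(pop), population=pop)
        hd_rows[pop] = dict(hs.cv.add_prefix("CV_"))
        hd_rows[pop]["HD"] = hs.HD
    habitat = pd.DataFrame.from_dict(hd_rows, orient="index")
    traits = trait_metrics.summarize_traits(sim.traits)
    sizes = population_size.estimate_sizes(sim.meta)
    summary = pd.concat([sizes, habitat, gen_summary, traits[["iFD_CV"]]], axis=1)
    regressions = _size_regressions(gen_summary, sizes["size"], gst_exclude=())
    correlations = gen_summary[[c for c in GENETIC_INDICES
                                if c in gen_summary.columns]].corr()
    data = summary.rename(columns={"habitat_area_m2": "habitat_area"}).join(
        sim.meta[["habitat_area_m2"]].rename(
            columns={"habitat_area_m2": "habitat_area"}))
    fit = psem.fit_psem(psem.study_model_spec(), data)
    trait_cols = [c for c in traits.columns if c != "iFD_CV"]
    pca_traits = ordination.pca(traits[trait_cols])
    return StudyResults(
        summary=summary,
        regressions=regressions,
        correlations=correlations,
        pca_traits=pca_traits,
        pca_env=None,
        psem_fit=fit,
        provenance={"inputs": "synthetic study", "seed": seed,
                    "min_loci": min_loci, "psem": "full model"},
    )


def run_study(data: SimulatedStudy | None = None, **kwargs) -> StudyResults:
    """Dispatch: packaged tables when no data bundle is given."""
    if data is None:
        return run_fixture_study(**kwargs)
    return run_synthetic_study(data, **kwargs)
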
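"""Functional-trait summaries and intraspecific trait variation.

iFD_CV is the unweighted mean, over the traits measured in a population, of
the coefficient of variation across individuals.  Traits absent for a
population (chlorophyll-fluorescence measures were not taken at the alpine
site) are excluded from the mean, never zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from tmontanum.env_metrics import UndefinedMetricError, coefficient_of_variation

#: The nine traits of the study, in table order.
TRAITS = ("RH", "AGB", "LA", "SLA", "LDMC", "FvFm", "PI", "SPS", "SPI")


@dataclass
class TraitSummary:
    population: str
    means: pd.Series
    cv: pd.Series
    iFD_CV: float


def trait_summary(
    traits: pd.DataFrame,
    population: str,
    trait_cols: tuple[str, ...] = TRAITS,
) -> TraitSummary:
    """Per-trait means and CVs for one population, plus their mean iFD_CV.

    ``traits`` is individual-level with a ``population`` column; a trait
    needs at least two measured individuals to contribute.
    """
    sub = traits[traits["population"] == population]
    if sub.empty:
        raise UndefinedMetricError(f"no individuals for population {population}")
    means, cvs = {}, {}
    for t in trait_cols:
        if t not in sub.columns:
            continue
        vals = pd.to_numeric(sub[t], errors="coerce").dropna()
        if len(vals) < 2:
            continue
        means[t] = float(vals.mean())
        cvs[t] = coefficient_of_variation(vals)
    if not cvs:
        raise UndefinedMetricError(f"no measurable traits for population {population}")
    cv = pd.Series(cvs, name="cv")
    return TraitSummary(
        population=population,
        means=pd.Series(means, name="mean"),
        cv=cv,
        iFD_CV=float(np.mean(list(cvs.values()))),
    )


def summarize_traits(
    traits: pd.DataFrame, trait_cols: tuple[str, ...] = TRAITS
) -> pd.DataFrame:
    """Per-population trait means + iFD_CV over all populations present."""
    rows = {}
    for pop in sorted(traits["population"].unique()):
        s = trait_summary(traits, pop, trait_cols)
        row = dict(s.means)
        row["iFD_CV"] = s.iFD_CV
        rows[pop] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "population"
    return out
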
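"""Community metrics and within-habitat heterogeneity.

Per vegetation record: community-weighted Ellenberg indicator values
(abundance-weighted means over the species that carry a score).  Per
population: species richness S over pooled records, Heip evenness E,
per-factor coefficients of variation and their mean, the habitat
heterogeneity index HD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from tmontanum.data_io import SCHMIDT_CLASSES, VegetationTable

#: Cover percentage assigned to the "+" (present, <1%) Schmidt class.
PLUS_COVER = 0.5

#: The ten non-collinear abiotic factors entering HD.
HD_FACTORS = (
    "altitude", "slope_exposure", "slope", "LAI", "soil_depth",
    "CEC_pot", "pH", "N", "P", "K",
)

#: Ellenberg indicator dimensions (light, continentality, moisture,
#: temperature, reaction, nutrients).
ELLENBERG_DIMS = ("L", "K", "F", "T", "R", "N")


class UndefinedMetricError(ValueError):
    """A metric has no defined value for the given input."""


@dataclass
class HabitatSummary:
    population: str
    cv: pd.Series  # indexed by factor
    HD: float


def schmidt_to_cover(cls, plus_cover: float = PLUS_COVER) -> float:
    """Map a Schmidt cover-abundance class to a percentage.

    Numeric classes are percentages already; "+" (present at under 1%)
    becomes ``plus_cover``.
    """
    if isinstance(cls, str) and cls.strip() == "+":
        return plus_cover
    try:
        val = float(cls)
    except (TypeError, ValueError):
        raise UndefinedMetricError(f"unknown Schmidt class {cls!r}") from None
    if val not in {float(c) for c in SCHMIDT_CLASSES if c != "+"}:
        raise UndefinedMetricError(f"unknown Schmidt class {cls!r}")
    return val


def community_weighted_value(
    abundances: dict[str, float] | pd.Series,
    indicators: pd.DataFrame,
    which: str,
) -> float:
    """Abundance-weighted mean indicator value over the scored species.

    ``indicators`` is indexed by species with one column per Ellenberg
    dimension; indifferent species ("x" or NaN) are excluded from both
    numerator and denominator.
    """
    abund = pd.Series(abundances, dtype=float)
    if which not in indicators.columns:
        raise UndefinedMetricError(f"indicator table has no {which!r} column")
    iv = indicators.reindex(abund.index)[which]
    iv = pd.to_numeric(iv, errors="coerce")  # "x" (indifferent) -> NaN
    scored = iv.notna()
    if not scored.any():
        raise UndefinedMetricError(f"no species with an indicator value for {which}")
    w = abund[scored]
    if w.sum() <= 0:
        raise UndefinedMetricError("total abundance of scored species is zero")
    return float((w * iv[scored]).sum() / w.sum())


def richness_evenness(abundances: pd.Series | dict[str, float]) -> tuple[int, float]:
    """Species richness S and Heip evenness E over pooled abundances.

    E = (exp(H') - 1) / (S - 1) with Shannon H' over relative abundances;
    by convention E = 1 for a single species.  E is 0 when one species
    completely dominates and 1 when all are equally abundant.
    """
    a = pd.Series(abundances, dtype=float)
    a = a[a > 0]
    if a.empty:
        raise UndefinedMetricError("no species with positive abundance")
    s = len(a)
    if s == 1:
        return 1, 1.0
    q = a / a.sum()
    h = float(-(q * np.log(q)).sum())
    return s, float((np.exp(h) - 1.0) / (s - 1))


def coefficient_of_variation(values) -> float:
    """Sample CV: sd (n-1 denominator) over mean.  Requires n >= 2, mean != 0."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        raise UndefinedMetricError("CV needs at least two values")
    mean = x.mean()
    if mean == 0:
        raise UndefinedMetricError("CV undefined for zero mean")
    return float(x.std(ddof=1) / mean)


def habitat_heterogeneity(
    records: pd.DataFrame,
    population: str | None = None,
    factors: tuple[str, ...] = HD_FACTORS,
    skip_undefined: bool = False,
) -> HabitatSummary:
    """Per-factor CVs over a population's records and their mean, HD.

    ``records`` holds one row per vegetation record with one column per
    factor; slope exposure enters as compass degrees.  A factor with an
    undefined CV raises unless ``skip_undefined`` is set, in which case it is
    left out of the mean.
    """
    if len(records) < 2:
        raise UndefinedMetricError("HD needs at least two records")
    cvs = {}
    for f in factors:
        try:
            cvs[f] = coefficient_of_variation(records[f])
        except UndefinedMetricError:
            if not skip_undefined:
                raise
    cv = pd.Series(cvs, name="cv")
    return HabitatSummary(
        population=population or "", cv=cv, HD=float(cv.mean()))


def vegetation_summary(
    veg: VegetationTable,
    indicators: pd.DataFrame,
    plus_cover: float = PLUS_COVER,
) -> pd.DataFrame:
    """Per-population community summary from pooled vegetation records.

    Returns S, Heip evenness E and the median over records of each
    community-weighted Ellenberg value (wL, wK, wF, wT, wR, wN), matching
    how ordinal quantities are summarized per population in the study.
    """
    rows = {}
    species = veg.species.assign(
        cover=veg.species["schmidt"].map(lambda c: schmidt_to_cover(c, plus_cover))
    )
    for pop, pooled in species.groupby("population"):
        total = pooled.groupby("species")["cover"].sum()
        s, e = richness_evenness(total)
        row = {"S": s, "E": e}
        for dim in ELLENBERG_DIMS:
            per_record = []
            for _, rec in pooled.groupby("record"):
                try:
                    per_record.append(community_weighted_value(
                        rec.set_index("species")["cover"], indicators, dim))
                except UndefinedMetricError:
                    continue
            row[f"w{dim}"] = float(np.median(per_record)) if per_record else np.nan
        rows[pop] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "population"
    return out
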
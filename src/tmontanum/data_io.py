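"""Readers, writers and the shared data model.

Genotypes follow the GenAlEx codominant layout: one row per individual,
two integer allele columns per microsatellite locus, 0 marking a missing
score.  Vegetation records are split into a long species table (one row per
species per record, Schmidt cover-abundance class) and a wide abiotic block
(one row per record).  The four in-study summary tables are packaged as TSV
fixtures at their printed precision and exposed through :func:`load_fixtures`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: GenAlEx convention for an unscored allele.
MISSING_ALLELE = 0

#: Populations of the study, in Table 1 order.
POPULATIONS = (
    "KW", "Bo", "Ha", "Wo", "Ba", "St", "Sa", "If", "Ni", "Di", "Er", "Gr", "Eh",
)

#: Ordinal cover-abundance ladder used in the vegetation records.
SCHMIDT_CLASSES = ("+", 1, 3, 5, 8, 10, 15, 20, 25, 30, 40, 50, 60, 70, 80, 90, 100)


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


@dataclass
class GenotypeTable:
    """Diploid codominant genotypes in long form.

    ``data`` has columns ``population``, ``individual``, ``locus``,
    ``allele_a``, ``allele_b``; alleles are integer fragment lengths with
    ``missing`` as sentinel.  A locus is either scored with both alleles or
    fully missing for an individual.
    """

    data: pd.DataFrame
    missing: int = MISSING_ALLELE

    def __post_init__(self) -> None:
        required = {"population", "individual", "locus", "allele_a", "allele_b"}
        if not required.issubset(self.data.columns):
            raise FormatError(f"genotype table needs columns {sorted(required)}")
        half = ((self.data["allele_a"] == self.missing)
                ^ (self.data["allele_b"] == self.missing))
        if half.any():
            bad = self.data.loc[half, ["individual", "locus"]].iloc[0]
            raise FormatError(
                f"half-missing genotype for {bad['individual']} at {bad['locus']}"
            )

    @property
    def populations(self) -> list[str]:
        return sorted(self.data["population"].unique())

    @property
    def loci(self) -> list[str]:
        return sorted(self.data["locus"].unique())

    def scored(self) -> pd.DataFrame:
        """Rows with a non-missing genotype."""
        return self.data[self.data["allele_a"] != self.missing]

    def n_individuals(self, population: str | None = None) -> int:
        df = self.data if population is None else (
            self.data[self.data["population"] == population])
        return df["individual"].nunique()

    def drop_undertyped(self, min_loci: int) -> "GenotypeTable":
        """Drop individuals scored at fewer than ``min_loci`` loci."""
        counts = self.scored().groupby("individual")["locus"].nunique()
        keep = counts[counts >= min_loci].index
        dropped = self.data["individual"].nunique() - len(keep)
        if dropped:
            logger.info("dropped %d individuals typed at < %d loci", dropped, min_loci)
        return GenotypeTable(
            self.data[self.data["individual"].isin(keep)].reset_index(drop=True),
            missing=self.missing,
        )


@dataclass
class VegetationTable:
    """Pooled vegetation records for one or more populations.

    ``species`` is long (population, record, species, schmidt) and
    ``abiotic`` wide (population, record, one column per measured factor).
    """

    species: pd.DataFrame
    abiotic: pd.DataFrame

    def records(self, population: str) -> pd.DataFrame:
        return self.abiotic[self.abiotic["population"] == population]


@dataclass
class FixtureBundle:
    """The four packaged per-population summary tables, indexed by population."""

    table1: pd.DataFrame  # metadata: coordinates, area, abundance, size, class
    table2: pd.DataFrame  # environmental means/medians + HD
    table3: pd.DataFrame  # population-genetic indices
    table4: pd.DataFrame  # trait means + iFD_CV

    def __post_init__(self) -> None:
        ids = set(POPULATIONS)
        for name in ("table1", "table2", "table3", "table4"):
            tab = getattr(self, name)
            if set(tab.index) != ids:
                raise FormatError(f"{name} must cover exactly the 13 study populations")


def _apply_config(df: pd.DataFrame, config: str | Path | dict | None) -> pd.DataFrame:
    """Rename columns according to a YAML config with a ``column_map`` entry."""
    if config is None:
        return df
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    return df.rename(columns=config.get("column_map", {}))


def read_genotypes(
    path: str | Path,
    min_loci: int = 4,
    missing: int = MISSING_ALLELE,
) -> GenotypeTable:
    """Read a GenAlEx-style codominant TSV.

    Layout: columns ``individual``, ``population``, then two allele columns
    per locus; each pair is named after its locus (the second column name is
    ignored).  Individuals scored at fewer than ``min_loci`` loci are
    dropped, mirroring the study's retention rule.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 4:
        raise FormatError("genotype file needs individual, population and loci columns")
    allele_cols = df.columns[2:]
    if len(allele_cols) % 2:
        raise FormatError(f"odd number of allele columns ({len(allele_cols)})")
    rows = []
    for i in range(0, len(allele_cols), 2):
        locus = allele_cols[i]
        sub = df[[df.columns[0], df.columns[1], allele_cols[i], allele_cols[i + 1]]]
        sub.columns = ["individual", "population", "allele_a", "allele_b"]
        sub = sub.assign(locus=locus)
        rows.append(sub)
    long = pd.concat(rows, ignore_index=True)
    for col in ("allele_a", "allele_b"):
        if not pd.api.types.is_integer_dtype(long[col]):
            try:
                long[col] = long[col].astype(int)
            except (ValueError, TypeError) as exc:
                raise FormatError(f"non-integer allele call in column {col}") from exc
        if (long[col] < 0).any():
            raise FormatError("negative allele length")
    table = GenotypeTable(
        long[["population", "individual", "locus", "allele_a", "allele_b"]],
        missing=missing,
    )
    return table.drop_undertyped(min_loci)


def write_genotypes(table: GenotypeTable, path: str | Path) -> None:
    """Write a :class:`GenotypeTable` back to the GenAlEx-style wide TSV."""
    loci = table.loci
    wide = None
    for locus in loci:
        sub = table.data[table.data["locus"] == locus]
        sub = sub.set_index(["individual", "population"])[["allele_a", "allele_b"]]
        sub.columns = [locus, f"{locus}.b"]
        wide = sub if wide is None else wide.join(sub)
    wide = wide.reset_index()
    wide.to_csv(path, sep="\t", index=False)


def read_vegetation(
    species_path: str | Path,
    records_path: str | Path,
    config: str | Path | dict | None = None,
) -> VegetationTable:
    """Read the long species table and the wide per-record abiotic block."""
    species = _apply_config(pd.read_csv(species_path, sep="\t"), config)
    abiotic = _apply_config(pd.read_csv(records_path, sep="\t"), config)
    for need, df, name in (
        ({"population", "record", "species", "schmidt"}, species, "species"),
        ({"population", "record"}, abiotic, "records"),
    ):
        if not need.issubset(df.columns):
            raise FormatError(f"vegetation {name} table needs columns {sorted(need)}")
    valid = {str(c) for c in SCHMIDT_CLASSES}
    bad = ~species["schmidt"].astype(str).isin(valid)
    if bad.any():
        raise FormatError(
            f"unknown Schmidt class {species.loc[bad, 'schmidt'].iloc[0]!r}")
    return VegetationTable(species=species, abiotic=abiotic)


def write_vegetation(
    table: VegetationTable, species_path: str | Path, records_path: str | Path
) -> None:
    table.species.to_csv(species_path, sep="\t", index=False)
    table.abiotic.to_csv(records_path, sep="\t", index=False)


def read_traits(path: str | Path, config=None) -> pd.DataFrame:
    """Individual-level trait table: population, individual, one column per trait."""
    df = _apply_config(pd.read_csv(path, sep="\t"), config)
    if not {"population", "individual"}.issubset(df.columns):
        raise FormatError("trait table needs population and individual columns")
    return df


def read_meta(path: str | Path, config=None) -> pd.DataFrame:
    """Per-population metadata (habitat area, coordinates, counts/abundance)."""
    df = _apply_config(pd.read_csv(path, sep="\t"), config)
    if "population" not in df.columns:
        raise FormatError("metadata table needs a population column")
    if (df.get("habitat_area_m2", pd.Series(dtype=float)) <= 0).any():
        raise FormatError("habitat_area_m2 must be positive")
    return df.set_index("population")


def _fixture(name: str) -> pd.DataFrame:
    ref = resources.files("tmontanum.data") / name
    with resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t", na_values=["NA"]).set_index("population")


def load_fixtures() -> FixtureBundle:
    """Load the four packaged per-population tables at printed precision.

    Optional traits that were not measured in KW (FvFm, PI) and the crop
    height there are NaN, never imputed.
    """
    return FixtureBundle(
        table1=_fixture("table1_populations.tsv"),
        table2=_fixture("table2_environment.tsv"),
        table3=_fixture("table3_popgen.tsv"),
        table4=_fixture("table4_traits.tsv"),
    )
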
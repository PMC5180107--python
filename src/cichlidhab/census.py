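"""Census data model, species metadata and habitat summaries.

An annual quadrat census records, per year and 1 x 1 m cell, how many
individuals of each species were seen in each body-size class (small /
medium / large, i.e. juvenile / sub-adult / adult).  Analyses use adults
only.  Species metadata (tribe, feeding ecomorph, territoriality) for the
Lake Tanganyika herbivorous cichlid community ships with the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

TRIBES = ("Ectodini", "Eretmodini", "Lamprologini", "Tropheini")
ECOMORPHS = ("grazer", "browser", "scraper", "scooper")
TERRITORIALITY = ("territorial", "partial", "none")
SIZE_CLASSES = ("small", "medium", "large")

CENSUS_COLUMNS = ["year", "species", "row", "col", "size_class", "count"]


@dataclass(frozen=True)
class SpeciesProfile:
    name: str
    abbreviation: str
    tribe: str
    ecomorph: str
    territoriality: str

    def __post_init__(self):
        if self.tribe not in TRIBES:
            raise ValueError(f"unknown tribe {self.tribe!r} for {self.abbreviation}")
        if self.ecomorph not in ECOMORPHS:
            raise ValueError(f"unknown ecomorph {self.ecomorph!r} for {self.abbreviation}")
        if self.territoriality not in TERRITORIALITY:
            raise ValueError(
                f"unknown territoriality {self.territoriality!r} for {self.abbreviation}"
            )


def load_species_metadata(path=None) -> pd.DataFrame:
    """Load the species metadata table (packaged roster by default)."""
    if path is None:
        src = resources.files("cichlidhab.data").joinpath("species_tanganyika.tsv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    required = {"name", "abbreviation", "tribe", "ecomorph", "territoriality"}
    if not required.issubset(df.columns):
        raise ValueError(f"species metadata must have columns {sorted(required)}")
    if df["abbreviation"].duplicated().any():
        dup = df.loc[df["abbreviation"].duplicated(), "abbreviation"].tolist()
        raise ValueError(f"duplicate species abbreviations: {dup}")
    # validate vocabularies via the dataclass
    for rec in df.itertuples(index=False):
        SpeciesProfile(rec.name, rec.abbreviation, rec.tribe, rec.ecomorph, rec.territoriality)
    return df


def ecomorph_counts(metadata: pd.DataFrame) -> dict[str, int]:
    """Number of species per feeding ecomorph."""
    counts = metadata["ecomorph"].value_counts().to_dict()
    return {e: int(counts.get(e, 0)) for e in ECOMORPHS}


@dataclass
class CensusTable:
    """Long-format adult/juvenile census counts.

    ``records`` has columns year, species, row, col, size_class, count;
    one row per (year, species, cell, size_class) after aggregation.
    """

    records: pd.DataFrame

    def __post_init__(self):
        df = self.records
        missing = set(CENSUS_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"census table missing columns {sorted(missing)}")
        self.records = df[CENSUS_COLUMNS].reset_index(drop=True)

    @property
    def years(self) -> list[int]:
        return sorted(self.records["year"].unique().tolist())

    @property
    def species_set(self) -> set[str]:
        return set(self.records["species"].unique())

    @property
    def total_count(self) -> int:
        return int(self.records["count"].sum())

    def __len__(self) -> int:
        return len(self.records)


def _validate_census_frame(df: pd.DataFrame, metadata: pd.DataFrame | None,
                           grid_shape: tuple[int, int] | None) -> pd.DataFrame:
    problems = []
    for line_no, rec in enumerate(df.itertuples(index=False), start=2):
        if rec.size_class not in SIZE_CLASSES:
            problems.append(f"line {line_no}: unknown size_class {rec.size_class!r}")
        if rec.count < 0 or int(rec.count) != rec.count:
            problems.append(f"line {line_no}: count must be a non-negative integer")
    if metadata is not None:
        known = set(metadata["abbreviation"])
        unknown = sorted(set(df["species"]) - known)
        if unknown:
            problems.append(f"unknown species abbreviations: {unknown}")
    if grid_shape is not None:
        nr, nc = grid_shape
        bad = df[(df["row"] < 0) | (df["row"] >= nr) | (df["col"] < 0) | (df["col"] >= nc)]
        if len(bad):
            cells = bad[["row", "col"]].drop_duplicates().values.tolist()
            problems.append(f"cells outside the {nr}x{nc} grid: {cells[:10]}")
    if problems:
        raise ValueError("invalid census data:\n  " + "\n  ".join(problems))
    return df


def make_census_table(df: pd.DataFrame, metadata: pd.DataFrame | None = None,
                      grid_shape: tuple[int, int] | None = None) -> CensusTable:
    """Validate and aggregate raw census records into a CensusTable.

    Duplicate (year, species, cell, size_class) keys are summed with a
    logged notice — field sheets may legitimately repeat cells.
    """
    df = df.copy()
    df["count"] = pd.to_numeric(df["count"])
    _validate_census_frame(df, metadata, grid_shape)
    keys = ["year", "species", "row", "col", "size_class"]
    if df.duplicated(keys).any():
        n_dup = int(df.duplicated(keys).sum())
        log.info("census input: summing %d duplicate record keys", n_dup)
    agg = df.groupby(keys, as_index=False)["count"].sum()
    agg["count"] = agg["count"].astype(int)
    return CensusTable(records=agg)


def read_census(path, metadata: pd.DataFrame | None = None,
                grid_shape: tuple[int, int] | None = None) -> CensusTable:
    """Read a census TSV (year, species, row, col, size_class, count)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(CENSUS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"census TSV {path} missing columns {sorted(missing)}")
    return make_census_table(df, metadata=metadata, grid_shape=grid_shape)


def write_census(table: CensusTable, path) -> None:
    table.records.to_csv(path, sep="\t", index=False)


def filter_adults(table: CensusTable) -> CensusTable:
    """Keep only adult (large size class) records."""
    adults = table.records[table.records["size_class"] == "large"]
    if adults.empty:
        log.warning("filter_adults: no adult records present")
    return CensusTable(records=adults.reset_index(drop=True))


def density_matrix(table: CensusTable, species: str) -> pd.DataFrame:
    """Cells x years matrix of counts for one species.

    Rows are indexed by (row, col) cell tuples, columns by census year.
    """
    years = table.years
    sub = table.records[table.records["species"] == species]
    if sub.empty:
        log.warning("density_matrix: species %r absent from table", species)
    cells = sorted(set(zip(table.records["row"], table.records["col"])))
    mat = pd.DataFrame(0, index=pd.MultiIndex.from_tuples(cells, names=["row", "col"]),
                       columns=years)
    for rec in sub.itertuples(index=False):
        mat.loc[(rec.row, rec.col), rec.year] += rec.count
    return mat


@dataclass
class HabitatSummary:
    species: str
    total_count: int
    mean_depth: float | None
    depth_quartiles: tuple[float, float, float] | None  # Q1, median, Q3
    mean_inclination: float | None
    counts_by_substratum: dict[str, int]

    @property
    def empty(self) -> bool:
        return self.total_count == 0


def _weighted_quantiles(values: np.ndarray, counts: np.ndarray, qs) -> list[float]:
    expanded = np.repeat(values, counts)
    return [float(np.quantile(expanded, q)) for q in qs]


def habitat_summary(table: CensusTable, cell_attrs: pd.DataFrame, species: str) -> HabitatSummary:
    """Count-weighted depth/inclination/substratum summary for one species.

    Uses the cell's mean depth and inclination as the habitat value of
    every individual counted in that cell, pooled over all years.
    """
    sub = table.records[table.records["species"] == species]
    attrs = cell_attrs.set_index(["row", "col"])
    merged = sub.merge(cell_attrs, on=["row", "col"], how="left")
    if merged["mean_depth_m"].isna().any():
        missing = merged[merged["mean_depth_m"].isna()][["row", "col"]].values.tolist()
        raise ValueError(f"cell attributes missing for occupied cells {missing[:5]}")
    total = int(merged["count"].sum())
    if total == 0:
        return HabitatSummary(species, 0, None, None, None, {})
    w = merged["count"].to_numpy(float)
    depths = merged["mean_depth_m"].to_numpy(float)
    mean_depth = float(np.average(depths, weights=w))
    q1, med, q3 = _weighted_quantiles(depths, merged["count"].to_numpy(int), (0.25, 0.5, 0.75))
    mean_incl = float(np.average(merged["inclination_deg"].to_numpy(float), weights=w))
    by_sub: dict[str, int] = {}
    if "substratum" in merged.columns:
        by_sub = merged.groupby("substratum")["count"].sum().astype(int).to_dict()
    return HabitatSummary(species, total, mean_depth, (q1, med, q3), mean_incl, by_sub)


def habitat_summary_table(table: CensusTable, cell_attrs: pd.DataFrame,
                          species_list=None) -> pd.DataFrame:
    """One habitat-summary row per species (TSV-ready)."""
    if species_list is None:
        species_list = sorted(table.species_set)
    rows = []
    for sp in species_list:
        s = habitat_summary(table, cell_attrs, sp)
        rows.append(
            {
                "species": sp,
                "total_count": s.total_count,
                "mean_depth_m": s.mean_depth,
                "depth_q1_m": s.depth_quartiles[0] if s.depth_quartiles else None,
                "depth_median_m": s.depth_quartiles[1] if s.depth_quartiles else None,
                "depth_q3_m": s.depth_quartiles[2] if s.depth_quartiles else None,
                "mean_inclination_deg": s.mean_inclination,
            }
        )
    return pd.DataFrame(rows)


def expand_observations(table: CensusTable, cell_attrs: pd.DataFrame,
                        value: str = "mean_depth_m") -> pd.DataFrame:
    """One row per individual with its cell's habitat value.

    This is the observation unit for the within-ecomorph ANOVA: each adult
    contributes its cell's mean depth (or inclination), pooled over years.
    """
    merged = table.records.merge(cell_attrs, on=["row", "col"], how="left")
    if merged[value].isna().any():
        raise ValueError("cell attributes do not cover all occupied cells")
    reps = merged.loc[merged.index.repeat(merged["count"])]
    return reps[["species", value]].reset_index(drop=True)
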
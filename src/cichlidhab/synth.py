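"""Seeded synthetic data with the statistical structure of the survey.

Emulates the study design end to end: a sloped 10 x 40 m quadrat surface
spanning roughly 2-14 m depth with smooth roughness, depth-sorted
substratum classes, a 15-species herbivore pool with Gaussian depth
niches and substratum affinities, 14 annual censuses with a shared
log-normal year effect, and a unit-height Yule tree whose tips can carry
Brownian-evolved depth optima (coupling habitat depth to phylogeny).

Every generator is a pure function of (config, master seed); sub-seeds
are namespaced per generator so adding one stream never shifts another.
"""

from __future__ import annotations

import dataclasses
import json
import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
import yaml

from .census import CensusTable, load_species_metadata, make_census_table
from .geometry import SUBSTRATUM_CLASSES, NodeGrid

# fixed per-generator namespaces for seed derivation
_SEED_SURFACE = 101
_SEED_SUBSTRATUM = 102
_SEED_TREE = 103
_SEED_CENSUS = 104


def _rng(master_seed: int, namespace: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(namespace,)))


@dataclass(frozen=True)
class SpeciesNiche:
    """Generating parameters for one species.

    mu is the depth optimum (m), sigma the niche breadth (m; sharper for
    territorial species), beta0 the baseline log abundance per cell-year
    at the optimum, affinity a per-substratum log-rate offset.
    """

    abbreviation: str
    ecomorph: str
    territoriality: str
    mu: float
    sigma: float
    beta0: float
    affinity: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not (self.sigma > 0):
            raise ValueError(f"{self.abbreviation}: niche breadth sigma must be > 0")
        bad = set(self.affinity) - set(SUBSTRATUM_CLASSES)
        if bad:
            raise ValueError(f"{self.abbreviation}: unknown substrata {sorted(bad)}")


# niche breadth defaults by territoriality: defended feeding territories
# concentrate a species in a narrower depth band
_SIGMA_BY_TERRITORIALITY = {"territorial": 1.0, "partial": 1.4, "none": 1.8}

# (mu, beta0, affinity) defaults per species, depth ordering taken from the
# observed shallow-to-deep sequence within each ecomorph
_DEFAULT_NICHE = {
    "Pfas": (2.8, 0.0, {"stone": 0.8}),
    "Ppol": (3.2, 0.0, {}),
    "Pfam": (4.0, -0.3, {}),
    "Ptre": (6.0, -0.7, {}),
    "Iloo": (8.0, -0.5, {}),
    "Phor": (11.0, -4.0, {}),
    "Pcur": (2.6, -0.2, {}),
    "Vmoo": (3.0, 0.3, {}),
    "Sdia": (3.6, -0.4, {}),
    "Tmoo": (5.0, 0.2, {}),
    "Ttem": (6.5, -0.3, {"gravel": 0.8}),
    "Ldar": (8.5, -0.8, {}),
    "Tvit": (10.0, -0.8, {}),
    "Ecya": (2.6, -0.2, {"sand": -1.5}),
    "Xpap": (11.0, -1.5, {"sand": 1.0}),
}


def default_species_niches() -> list[SpeciesNiche]:
    meta = load_species_metadata()
    niches = []
    for rec in meta.itertuples(index=False):
        mu, beta0, aff = _DEFAULT_NICHE[rec.abbreviation]
        niches.append(
            SpeciesNiche(
                abbreviation=rec.abbreviation,
                ecomorph=rec.ecomorph,
                territoriality=rec.territoriality,
                mu=mu,
                sigma=_SIGMA_BY_TERRITORIALITY[rec.territoriality],
                beta0=beta0,
                affinity=aff,
            )
        )
    return niches


@dataclass
class ScenarioConfig:
    """All generation parameters for one synthetic study."""

    n_rows: int = 40            # cells along the slope
    n_cols: int = 10            # cells along the shore
    edge_length: float = 1.0    # string spacing, metres (3D chord)
    shallow_depth: float = 2.1  # depth at the shallow node row, metres
    slope_per_row: float = 0.2875   # mean depth gain per node row, metres
    roughness_amplitude: float = 0.12   # metres
    roughness_wavelength: float = 8.0   # metres
    sorting_strength: float = 2.5   # depth sorting of gravel/sand classes
    n_years: int = 14
    start_year: int = 1995
    sigma_year: float = 0.2     # SD of the shared year random effect
    brownian_rate: float = 0.0  # >0 couples tip depth optima to the tree
    master_seed: int = 0
    species: list[SpeciesNiche] = field(default_factory=default_species_niches)

    def __post_init__(self):
        if self.sigma_year < 0 or self.roughness_amplitude < 0:
            raise ValueError("variance-like parameters must be >= 0")
        if self.brownian_rate < 0:
            raise ValueError("brownian_rate must be >= 0")
        max_step = abs(self.slope_per_row) + 4 * self.roughness_amplitude * (
            2 * np.pi / self.roughness_wavelength
        )
        if max_step >= self.edge_length:
            raise ValueError(
                "infeasible scenario: worst-case depth step per node "
                f"({max_step:.3f} m) reaches the string spacing {self.edge_length} m"
            )

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        species = [SpeciesNiche(**s) for s in d.pop("species", [])]
        if not species:
            return cls(**d)
        return cls(species=species, **d)


def generate_surface(config: ScenarioConfig) -> tuple[NodeGrid, dict]:
    """Sloped quadrat surface: mean down-slope gradient + smooth roughness."""
    rng = _rng(config.master_seed, _SEED_SURFACE)
    nr, nc = config.n_rows + 1, config.n_cols + 1
    i = np.arange(nr)[:, None] * config.edge_length   # down-slope coordinate
    j = np.arange(nc)[None, :] * config.edge_length   # along-shore coordinate
    base = config.shallow_depth + config.slope_per_row * np.arange(nr)[:, None]
    lam = config.roughness_wavelength
    a = config.roughness_amplitude
    ph = rng.uniform(0, 2 * np.pi, size=4)
    rough = (
        a * np.sin(2 * np.pi * i / lam + ph[0]) * np.cos(2 * np.pi * j / (1.7 * lam) + ph[1])
        + 0.5 * a * np.sin(2 * np.pi * j / (0.9 * lam) + ph[2])
        + 0.5 * a * np.sin(2 * np.pi * i / (1.3 * lam) + ph[3])
    )
    depth = base + rough
    grid = NodeGrid(depth=depth, edge_length=config.edge_length)
    # generated surfaces must always be embeddable
    steps = max(np.abs(np.diff(depth, axis=0)).max(), np.abs(np.diff(depth, axis=1)).max())
    if steps >= config.edge_length:
        raise ValueError("generated surface infeasible: node depth step >= string spacing")
    truth = {"node_depths": depth.tolist(), "roughness_phases": ph.tolist()}
    return grid, truth


def cell_mean_depths(grid: NodeGrid) -> np.ndarray:
    d = grid.depth
    return 0.25 * (d[:-1, :-1] + d[:-1, 1:] + d[1:, :-1] + d[1:, 1:])


def generate_substratum(grid: NodeGrid, sorting_strength: float,
                        master_seed: int) -> pd.DataFrame:
    """Depth-sorted categorical substratum per cell.

    Gravel probability decays with depth and sand grows with it (shore
    sorting by grain weight); rock/stone/rubble are spread broadly.  At
    sorting_strength 0 all five classes are equiprobable everywhere.
    """
    rng = _rng(master_seed, _SEED_SUBSTRATUM)
    depths = cell_mean_depths(grid)
    t = (depths - depths.min()) / max(depths.max() - depths.min(), 1e-9)
    rows = []
    for r in range(depths.shape[0]):
        for c in range(depths.shape[1]):
            w = {
                "rock": 1.0,
                "stone": 1.0,
                "rubble": 1.0,
                "gravel": float(np.exp(-sorting_strength * t[r, c])),
                "sand": float(np.exp(-sorting_strength * (1 - t[r, c]))),
            }
            total = sum(w.values())
            probs = [w[k] / total for k in SUBSTRATUM_CLASSES]
            cls = rng.choice(SUBSTRATUM_CLASSES, p=probs)
            rows.append({"row": r, "col": c, "substratum": cls})
    return pd.DataFrame(rows)


def generate_tree(species: list[str], brownian_rate: float, master_seed: int,
                  mu_by_species: dict[str, float] | None = None):
    """Unit-height Yule tree over the species, with optional trait signal.

    Returns (newick string, tip depth optima).  With ``brownian_rate > 0``
    the optima are a Brownian realisation on the tree, affinely mapped to
    the configured optimum range, so closely related tips get similar
    depths.  With rate 0 the optima are the configured values, independent
    of the tree topology.
    """
    if len(species) < 3:
        raise ValueError("need at least 3 species for a tree")
    rng = _rng(master_seed, _SEED_TREE)
    pyrng = random.Random(int(rng.integers(0, 2**31 - 1)))
    from dendropy.simulate import treesim

    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=len(species),
        rng=pyrng,
    )
    # scale to unit height (ultrametric by construction: pure birth in time)
    height = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / height

    # attach species names to tips in a seeded random order
    order = list(species)
    pyrng.shuffle(order)
    for leaf, name in zip(tree.leaf_node_iter(), order):
        leaf.taxon.label = name

    if mu_by_species is None:
        mu_by_species = {s: float(i) for i, s in enumerate(species)}

    if brownian_rate > 0:
        values: dict[int, float] = {id(tree.seed_node): 0.0}
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            parent_val = values[id(node.parent_node)]
            step = rng.normal(0.0, np.sqrt(brownian_rate * (node.edge.length or 0.0)))
            values[id(node)] = parent_val + step
        raw = {leaf.taxon.label: values[id(leaf)] for leaf in tree.leaf_node_iter()}
        lo, hi = min(raw.values()), max(raw.values())
        mu_lo, mu_hi = min(mu_by_species.values()), max(mu_by_species.values())
        if hi - lo < 1e-12:
            optima = {s: 0.5 * (mu_lo + mu_hi) for s in raw}
        else:
            optima = {s: mu_lo + (v - lo) / (hi - lo) * (mu_hi - mu_lo) for s, v in raw.items()}
    else:
        optima = {s: mu_by_species[s] for s in species}

    newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
    return newick, optima


# fixed fractions of adult counts written as juvenile / sub-adult records,
# present only so adult filtering has something to remove
_SMALL_FRACTION_DIV = 2
_MEDIUM_FRACTION_DIV = 3


def generate_census(
    grid: NodeGrid,
    substratum: pd.DataFrame,
    species: list[SpeciesNiche],
    n_years: int,
    sigma_year: float,
    master_seed: int,
    start_year: int = 1995,
    optima: dict[str, float] | None = None,
) -> tuple[CensusTable, dict]:
    """Poisson censuses from Gaussian depth niches + substratum affinities.

    count(cell, year, sp) ~ Poisson(exp(beta0 - (d - mu)^2 / (2 sigma^2)
    + affinity[substratum] + b_year)), with one shared b_year ~ N(0,
    sigma_year^2) per census.  Small/medium records are fixed fractions of
    the adult counts.  Returns the table and the generating truth.
    """
    rng = _rng(master_seed, _SEED_CENSUS)
    depths = cell_mean_depths(grid)
    nrc, ncc = depths.shape
    sub_map = substratum.set_index(["row", "col"])["substratum"]
    year_effects = rng.normal(0.0, sigma_year, size=n_years)

    cell_sub = np.empty((nrc, ncc), dtype=object)
    for (r, c), s in sub_map.items():
        cell_sub[r, c] = s

    records = []
    for yi in range(n_years):
        year = start_year + yi
        b = year_effects[yi]
        for sp in species:
            mu = optima[sp.abbreviation] if optima else sp.mu
            log_rate = (
                sp.beta0
                - (depths - mu) ** 2 / (2 * sp.sigma**2)
                + b
            )
            for cls, off in sp.affinity.items():
                log_rate = log_rate + off * (cell_sub == cls)
            rate = np.exp(log_rate)
            if rate.max() > 1e6:
                raise ValueError(
                    f"Poisson rate overflow for {sp.abbreviation}: max {rate.max():.3g}"
                )
            counts = rng.poisson(rate)
            rr, cc = np.nonzero(counts)
            for r, c in zip(rr, cc):
                n_adult = int(counts[r, c])
                records.append((year, sp.abbreviation, int(r), int(c), "large", n_adult))
                n_small = n_adult // _SMALL_FRACTION_DIV
                n_medium = n_adult // _MEDIUM_FRACTION_DIV
                if n_small:
                    records.append((year, sp.abbreviation, int(r), int(c), "small", n_small))
                if n_medium:
                    records.append((year, sp.abbreviation, int(r), int(c), "medium", n_medium))

    df = pd.DataFrame(records, columns=["year", "species", "row", "col", "size_class", "count"])
    table = make_census_table(df, grid_shape=depths.shape)
    truth = {
        "year_effects": year_effects.tolist(),
        "species": {
            sp.abbreviation: {
                "mu": optima[sp.abbreviation] if optima else sp.mu,
                "sigma": sp.sigma,
                "beta0": sp.beta0,
                "affinity": sp.affinity,
                "ecomorph": sp.ecomorph,
            }
            for sp in species
        },
        "sigma_year": sigma_year,
    }
    return table, truth


def generate_scenario(config: ScenarioConfig) -> dict:
    """All synthetic inputs for one study: surface, substrata, tree, census."""
    grid, surface_truth = generate_surface(config)
    substratum = generate_substratum(grid, config.sorting_strength, config.master_seed)
    mu_by_species = {sp.abbreviation: sp.mu for sp in config.species}
    newick, optima = generate_tree(
        [sp.abbreviation for sp in config.species],
        config.brownian_rate,
        config.master_seed,
        mu_by_species=mu_by_species,
    )
    census, census_truth = generate_census(
        grid,
        substratum,
        config.species,
        config.n_years,
        config.sigma_year,
        config.master_seed,
        start_year=config.start_year,
        optima=optima,
    )
    truth = {
        "surface": surface_truth,
        "census": census_truth,
        "tree_newick": newick,
        "tip_optima": optima,
        "brownian_rate": config.brownian_rate,
        "master_seed": config.master_seed,
    }
    return {
        "grid": grid,
        "substratum": substratum,
        "census": census,
        "newick": newick,
        "optima": optima,
        "truth": truth,
    }
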
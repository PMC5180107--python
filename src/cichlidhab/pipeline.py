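"""End-to-end orchestration: simulate a dataset, analyse a dataset.

``run_simulate`` writes one dataset directory (node depths, substratum
map, census, tree, generating truth).  ``run_analyze`` runs the full
statistical battery on such a directory — grid embedding, cell
attributes, habitat summaries, within-ecomorph ANOVA/Tukey/letters,
per-ecomorph Poisson GLMMs, depth GLMs, and Mantel tests — and writes a
results directory plus a Markdown report.  Stage failures are logged and
downstream stages that depend on them are skipped.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import census as cc
from . import geometry as geo
from . import phylo
from . import stats as hs
from .glmm import build_ecomorph_design, fit_poisson_glmm
from .synth import ScenarioConfig, generate_scenario

log = logging.getLogger(__name__)

DATASET_FILES = ("node_depths.tsv", "substratum.tsv", "census.tsv", "tree.nwk", "truth.json")

EXIT_CONFIG_ERROR = 2
EXIT_INPUT_ERROR = 3
EXIT_NUMERICAL_ERROR = 4


def run_simulate(config: ScenarioConfig, outdir) -> Path:
    """Generate a complete synthetic dataset directory.

    Everything is generated in memory first, so an infeasible configuration
    fails cleanly without partial output.
    """
    data = generate_scenario(config)  # raises before any file is written
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    geo.write_node_depths(data["grid"], out / "node_depths.tsv")
    data["substratum"].to_csv(out / "substratum.tsv", sep="\t", index=False)
    cc.write_census(data["census"], out / "census.tsv")
    (out / "tree.nwk").write_text(data["newick"] + "\n")
    with open(out / "truth.json", "w") as fh:
        json.dump(data["truth"], fh, indent=1)
    config.to_yaml(out / "scenario.yaml")
    log.info("simulated dataset written to %s", out)
    return out


def _config_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def run_analyze(
    dataset_dir,
    outdir,
    seed: int = 0,
    alpha: float = 0.05,
    n_perm: int = 9999,
    do_glmm: bool = True,
    min_occurrence: int = 30,
) -> dict:
    """Full analysis of a dataset directory; returns a results summary dict."""
    ds = Path(dataset_dir)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for required in ("node_depths.tsv", "substratum.tsv", "census.tsv"):
        if not (ds / required).exists():
            raise FileNotFoundError(f"dataset is missing required input file: {required}")

    summary: dict = {"skipped": [], "failures": []}
    metadata = cc.load_species_metadata()

    # --- geometry -----------------------------------------------------------
    grid = geo.read_node_depths(ds / "node_depths.tsv")
    embedded = geo.embed_grid(grid)
    geo.write_embedded_grid(embedded, out / "embedded_grid.tsv")
    substratum = pd.read_csv(ds / "substratum.tsv", sep="\t")
    attrs = geo.cell_attributes(embedded, substratum)
    attrs.to_csv(out / "cell_attributes.tsv", sep="\t", index=False, float_format="%.6f")
    summary["depth_summary"] = geo.depth_summary(grid)
    summary["max_edge_residual_m"] = embedded.max_residual

    # --- census and habitat summaries --------------------------------------
    table = cc.read_census(ds / "census.tsv", metadata=metadata,
                           grid_shape=(grid.n_rows, grid.n_cols))
    adults = cc.filter_adults(table)
    habitat = cc.habitat_summary_table(adults, attrs)
    habitat.to_csv(out / "habitat_summary.tsv", sep="\t", index=False, float_format="%.4f")
    summary["n_adults"] = adults.total_count
    summary["habitat_summary"] = habitat

    # --- within-ecomorph ANOVA / Tukey / letters ----------------------------
    summary["letters"] = {}
    for ecomorph in ("grazer", "browser"):
        spp = set(metadata.loc[metadata["ecomorph"] == ecomorph, "abbreviation"])
        eco_table = cc.CensusTable(
            records=adults.records[adults.records["species"].isin(spp)].reset_index(drop=True)
        )
        for value, tag in (("mean_depth_m", "depth"), ("inclination_deg", "inclination")):
            try:
                obs = cc.expand_observations(eco_table, attrs, value=value)
                res = hs.species_letter_analysis(obs, alpha=alpha)
            except ValueError as exc:
                log.warning("%s %s analysis skipped: %s", ecomorph, tag, exc)
                summary["skipped"].append(f"{ecomorph}_{tag}")
                continue
            hs.pairwise_to_frame(res["pairwise"]).to_csv(
                out / f"tukey_{ecomorph}_{tag}.tsv", sep="\t", index=False
            )
            pd.DataFrame(
                {
                    "species": list(res["letters"]),
                    "mean": [res["means"][s] for s in res["letters"]],
                    "letters": list(res["letters"].values()),
                }
            ).to_csv(out / f"letters_{ecomorph}_{tag}.tsv", sep="\t", index=False)
            summary["letters"][f"{ecomorph}_{tag}"] = res

    # --- depth ~ substratum / inclination GLMs ------------------------------
    try:
        glms = hs.fit_depth_glms(attrs, alpha=alpha)
        rows = []
        for contrast in glms.get("substratum", {}).get("contrasts", []):
            rows.append(
                {
                    "term": f"depth[{contrast.pair[0]}-{contrast.pair[1]}]",
                    "estimate": contrast.mean_difference,
                    "p": contrast.p_adjusted,
                }
            )
        rows.append(
            {
                "term": "depth~inclination slope",
                "estimate": glms["inclination"]["slope"],
                "p": glms["inclination"]["p"],
            }
        )
        pd.DataFrame(rows).to_csv(out / "depth_glm.tsv", sep="\t", index=False)
        summary["depth_glms"] = glms
    except ValueError as exc:
        log.warning("depth GLMs failed: %s", exc)
        summary["failures"].append("depth_glms")

    # --- per-ecomorph Poisson GLMM ------------------------------------------
    summary["glmm"] = {}
    if do_glmm:
        for ecomorph in ("grazer", "browser"):
            try:
                fit, excluded = fit_ecomorph_glmm(
                    adults, attrs, metadata, ecomorph, min_occurrence=min_occurrence
                )
            except ValueError as exc:
                log.warning("GLMM for %s failed: %s", ecomorph, exc)
                summary["failures"].append(f"glmm_{ecomorph}")
                continue
            frame = fit.summary_frame()
            frame.to_csv(out / f"glmm_{ecomorph}.tsv", sep="\t", index=False,
                         float_format="%.5f")
            summary["glmm"][ecomorph] = {
                "fit": fit,
                "excluded_species": excluded,
            }

    # --- Mantel: phylogeny vs habitat depth ---------------------------------
    summary["mantel"] = {}
    tree_path = ds / "tree.nwk"
    if not tree_path.exists():
        log.info("no tree.nwk in dataset: Mantel stage skipped")
        summary["skipped"].append("mantel")
    else:
        tree = phylo.read_newick(tree_path)
        coph = phylo.cophenetic_matrix(tree)
        depths = dict(zip(habitat["species"], habitat["mean_depth_m"]))
        mantel_all = {}
        for name, spp in _mantel_groups(metadata).items():
            usable = [s for s in spp if s in depths and depths[s] is not None
                      and np.isfinite(depths[s]) and s in coph.labels]
            if len(usable) < 3:
                log.warning("Mantel %s skipped: fewer than 3 usable species", name)
                continue
            hd = phylo.habitat_depth_distance({s: depths[s] for s in usable})
            res = phylo.mantel_test(
                coph.subset(hd.labels), hd, n_perm=n_perm, seed=seed, tail="greater"
            )
            mantel_all[name] = res.to_dict()
        with open(out / "mantel.json", "w") as fh:
            json.dump(mantel_all, fh, indent=1)
        summary["mantel"] = mantel_all

    _write_report(out, summary, metadata, alpha=alpha)
    return summary


def fit_ecomorph_glmm(adults: cc.CensusTable, attrs: pd.DataFrame,
                      metadata: pd.DataFrame, ecomorph: str,
                      min_occurrence: int = 30):
    """Assemble the per-(cell, year, species) counts and fit the GLMM.

    Zero-count cell-years are included for each species so absences inform
    the fit; species rarer than ``min_occurrence`` adults are excluded.
    """
    spp = sorted(metadata.loc[metadata["ecomorph"] == ecomorph, "abbreviation"])
    recs = adults.records[adults.records["species"].isin(spp)]
    if recs.empty:
        raise ValueError(f"no adult records for ecomorph {ecomorph!r}")
    years = sorted(adults.records["year"].unique())
    cells = attrs[["row", "col", "mean_depth_m", "inclination_deg", "substratum"]]
    full = (
        pd.MultiIndex.from_product([years, spp, cells.index], names=["year", "species", "ci"])
        .to_frame(index=False)
        .merge(cells.reset_index(names="ci"), on="ci")
        .drop(columns="ci")
    )
    counts = recs.groupby(["year", "species", "row", "col"], as_index=False)["count"].sum()
    full = full.merge(counts, on=["year", "species", "row", "col"], how="left")
    full["count"] = full["count"].fillna(0).astype(int)
    full = full.rename(columns={"mean_depth_m": "depth", "inclination_deg": "inclination"})
    y, X, groups, names, excluded = build_ecomorph_design(full, min_occurrence=min_occurrence)
    fit = fit_poisson_glmm(y, X, groups, param_names=names)
    return fit, excluded


def _mantel_groups(metadata: pd.DataFrame) -> dict[str, list[str]]:
    """Species sets compared in the Mantel stage."""
    gr = metadata[metadata["ecomorph"] == "grazer"]
    br = metadata[metadata["ecomorph"] == "browser"]
    return {
        "grazers": sorted(gr["abbreviation"]),
        "browsers": sorted(br["abbreviation"]),
        "browsers_tropheini": sorted(br.loc[br["tribe"] == "Tropheini", "abbreviation"]),
    }


def _write_report(out: Path, summary: dict, metadata: pd.DataFrame, alpha: float) -> None:
    lines = ["# Quadrat habitat-segregation analysis", ""]
    ds = summary.get("depth_summary", {})
    if ds:
        lines += [
            "## Quadrat",
            "",
            f"- depth range: {ds['min']:.1f}-{ds['max']:.1f} m "
            f"(extent {ds['range']:.1f} m, mean {ds['mean']:.1f} m)",
            f"- max grid-edge embedding residual: {summary['max_edge_residual_m']:.2e} m",
            "",
        ]
    eco = cc.ecomorph_counts(metadata)
    lines += [
        "## Species pool",
        "",
        f"- {sum(eco.values())} species: "
        + ", ".join(f"{v} {k}s" for k, v in eco.items()),
        f"- adult individuals censused: {summary.get('n_adults', 'n/a')}",
        "",
    ]
    for key, res in summary.get("letters", {}).items():
        ecomorph, tag = key.split("_", 1)
        a = res["anova"]
        lines += [
            f"## {ecomorph.capitalize()} {tag} preference (ANOVA + Tukey, alpha={alpha})",
            "",
            f"ANOVA: F({a['df_between']}, {a['df_within']}) = {a['F']:.1f}, p = {a['p']:.3g}",
            "",
            "| species | mean | letters |",
            "|---|---|---|",
        ]
        for sp, letters in res["letters"].items():
            lines.append(f"| {sp} | {res['means'][sp]:.2f} | {letters} |")
        lines.append("")
    for ecomorph, g in summary.get("glmm", {}).items():
        fit = g["fit"]
        lines += [
            f"## Poisson GLMM: {ecomorph} density",
            "",
            f"converged: {fit.converged}; year random-effect SD = {fit.sigma_year:.3f}; "
            f"excluded rare species: {g['excluded_species'] or 'none'}",
            "",
            "| term | estimate | SE | z | p |",
            "|---|---|---|---|---|",
        ]
        for rec in fit.summary_frame().itertuples(index=False):
            lines.append(
                f"| {rec.term} | {rec.estimate:.3f} | {rec.std_error:.3f} "
                f"| {rec.z:.2f} | {rec.p:.3g} |"
            )
        lines.append("")
    if summary.get("mantel"):
        lines += ["## Mantel tests (phylogenetic distance vs habitat-depth difference)", ""]
        for name, m in summary["mantel"].items():
            lines.append(
                f"- {name}: r = {m['r']:.3f}, p = {m['p']:.4f} "
                f"({m['n_perm']} permutations, tail={m['tail']})"
            )
        lines.append("")
    if summary.get("skipped"):
        lines.append(f"Skipped stages: {', '.join(summary['skipped'])}")
    (out / "report.md").write_text("\n".join(lines) + "\n")
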
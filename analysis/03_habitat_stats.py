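"""Habitat-preference statistics within each ecomorph.

Adult-only habitat summaries per species, one-way ANOVA + Tukey + compact
letter displays for depth and inclination among grazers and among
browsers, depth GLMs, and the Poisson GLMM of per-cell density with the
census year as a random intercept.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

from cichlidhab import census as cc
from cichlidhab import stats as hs
from cichlidhab.pipeline import EXIT_INPUT_ERROR, fit_ecomorph_glmm


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dataset", type=Path, default=Path("results/dataset"))
    ap.add_argument("--outdir", type=Path, default=Path("results/analysis"))
    ap.add_argument("--alpha", type=float, default=0.05)
    ap.add_argument("--min-occurrence", type=int, default=30,
                    help="minimum adult count for a species to enter the GLMM")
    args = ap.parse_args()

    try:
        attrs = pd.read_csv(args.outdir / "cell_attributes.tsv", sep="\t")
    except OSError:
        print("run 02_embed_quadrat.py first (cell_attributes.tsv missing)",
              file=sys.stderr)
        return EXIT_INPUT_ERROR
    metadata = cc.load_species_metadata()
    table = cc.read_census(args.dataset / "census.tsv", metadata=metadata)
    adults = cc.filter_adults(table)
    print(f"{adults.total_count} adults across {len(adults.years)} years")

    habitat = cc.habitat_summary_table(adults, attrs)
    args.outdir.mkdir(parents=True, exist_ok=True)
    habitat.to_csv(args.outdir / "habitat_summary.tsv", sep="\t", index=False,
                   float_format="%.4f")

    for ecomorph in ("grazer", "browser"):
        spp = set(metadata.loc[metadata["ecomorph"] == ecomorph, "abbreviation"])
        eco = cc.CensusTable(
            records=adults.records[adults.records["species"].isin(spp)]
            .reset_index(drop=True)
        )
        for value, tag in (("mean_depth_m", "depth"), ("inclination_deg", "inclination")):
            obs = cc.expand_observations(eco, attrs, value=value)
            res = hs.species_letter_analysis(obs, alpha=args.alpha)
            hs.pairwise_to_frame(res["pairwise"]).to_csv(
                args.outdir / f"tukey_{ecomorph}_{tag}.tsv", sep="\t", index=False)
            letters = ", ".join(f"{s}:{l}" for s, l in res["letters"].items())
            print(f"{ecomorph} {tag}: F={res['anova']['F']:.1f} "
                  f"p={res['anova']['p']:.2g} | letters {letters}")

        fit, excluded = fit_ecomorph_glmm(adults, attrs, metadata, ecomorph,
                                          min_occurrence=args.min_occurrence)
        fit.summary_frame().to_csv(args.outdir / f"glmm_{ecomorph}.tsv", sep="\t",
                                   index=False, float_format="%.5f")
        frame = fit.summary_frame().set_index("term")
        print(f"{ecomorph} GLMM: depth coef {frame.loc['depth', 'estimate']:+.3f} "
              f"(p={frame.loc['depth', 'p']:.2g}), year SD {fit.sigma_year:.3f}, "
              f"excluded {excluded or 'none'}")

    glms = hs.fit_depth_glms(attrs, alpha=args.alpha)
    slope = glms["inclination"]
    print(f"depth~inclination slope {slope['slope']:+.4f} (p={slope['p']:.2g})")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
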
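"""Phylogenetic distance versus habitat-depth differentiation.

Cophenetic distances from the ultrametric tree are compared with pairwise
habitat-depth differences (count-weighted species mean depths) by Mantel
permutation tests within grazers, all browsers, and Tropheini browsers.
"""

import argparse
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from cichlidhab.census import load_species_metadata
from cichlidhab.phylo import (
    cophenetic_matrix,
    habitat_depth_distance,
    mantel_test,
    read_newick,
)
from cichlidhab.pipeline import EXIT_INPUT_ERROR, _mantel_groups


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dataset", type=Path, default=Path("results/dataset"))
    ap.add_argument("--outdir", type=Path, default=Path("results/analysis"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-perm", type=int, default=9999)
    args = ap.parse_args()

    tree_path = args.dataset / "tree.nwk"
    summary_path = args.outdir / "habitat_summary.tsv"
    if not tree_path.exists():
        print("no tree.nwk in the dataset: nothing to do", file=sys.stderr)
        return EXIT_INPUT_ERROR
    if not summary_path.exists():
        print("run 03_habitat_stats.py first (habitat_summary.tsv missing)",
              file=sys.stderr)
        return EXIT_INPUT_ERROR

    tree = read_newick(tree_path)
    coph = cophenetic_matrix(tree)
    habitat = pd.read_csv(summary_path, sep="\t")
    depths = dict(zip(habitat["species"], habitat["mean_depth_m"]))
    metadata = load_species_metadata()

    results = {}
    for name, spp in _mantel_groups(metadata).items():
        usable = [s for s in spp if s in depths and np.isfinite(depths[s])
                  and s in coph.labels]
        if len(usable) < 3:
            print(f"{name}: fewer than 3 usable species, skipped")
            continue
        hd = habitat_depth_distance({s: depths[s] for s in usable})
        res = mantel_test(coph.subset(hd.labels), hd, n_perm=args.n_perm,
                          seed=args.seed, tail="greater")
        results[name] = res.to_dict()
        verdict = "significant" if res.p <= 0.05 else "not significant"
        print(f"{name} (n={len(usable)}): r = {res.r:+.3f}, p = {res.p:.4f} "
              f"({verdict}; {args.n_perm} permutations)")

    args.outdir.mkdir(parents=True, exist_ok=True)
    with open(args.outdir / "mantel.json", "w") as fh:
        json.dump(results, fh, indent=1)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
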
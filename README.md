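# cichlidhab

Quadrat-census analysis of depth and substratum niche segregation among
coexisting herbivorous cichlids on a rocky littoral slope.

Up to 15 herbivorous cichlid species from four feeding ecomorphs (grazers,
browsers, a scraper, a scooper) coexist on Lake Tanganyika's rocky shores.
This package implements the analysis chain used to ask *how* apparently
equivalent species of the same ecomorph partition space: a permanent
10 × 40 m quadrat subdivided by string into 1 × 1 m cells is censused
annually, and each species' use of water depth, substratum type and
substratum inclination is quantified and compared.

It is organised as an analysis project: every computation lives in the
library under `src/cichlidhab/`, and the numbered drivers under
`analysis/` run the study end to end on synthetic data that emulates the
survey design.

## What it computes

**Quadrat geometry.** Divers record the depth *z* at every string node;
the taut 1 m string spacing is the 3D chord between adjacent nodes.
Node (x, y) positions are recovered by two-anchor trilateration: the node
lies on the intersection of spheres of radius 1 m centred on its west and
north neighbours, cut by the plane of its known depth. Each cell then gets
a mean depth, a substratum class from its dominant grain size — rock
(> 50 cm), stone (20–50), rubble (3–20), gravel (0.5–3), sand (< 0.5) —
and an inclination: the mean angle between the vertical and the normals
of the four triangles formed by its corner nodes,

&nbsp;&nbsp;&nbsp;&nbsp;θ = ¼ Σₜ arccos |n⁽ᵗ⁾·ẑ| .

**Habitat statistics.** Adults (large size class) are the observation
unit; each contributes its cell's mean depth / inclination. Within each
ecomorph, species are compared by one-way ANOVA and Tukey's HSD, condensed
into compact letter displays (species sharing a letter do not differ at
α = 0.05). Per-cell, per-year counts are modelled by a Poisson GLMM

&nbsp;&nbsp;&nbsp;&nbsp;y ~ Poisson(μ), log μ = β₀ + β_species + β_d·depth +
β_substratum + β_i·inclination + b_year, b_year ~ N(0, σ²),

fitted by maximum marginal likelihood with adaptive Gauss–Hermite
quadrature over the year random intercept. Gaussian GLMs relate cell depth
to substratum class and inclination.

**Phylogeny vs depth.** From an ultrametric Newick tree, cophenetic
distances (tip-to-tip path lengths) are compared to pairwise differences
in species' count-weighted mean habitat depth with a Mantel permutation
test (Pearson r of the off-diagonal vectors; 9999 joint row/column
permutations; exact enumeration available for n ≤ 8 as a reference).

**Synthetic data.** A seeded generator reproduces the design: a sloped
surface spanning ~2.1–13.6 m depth, depth-sorted substrata, Gaussian depth
niches (sharper for territorial species), substratum affinities, Poisson
counts with a shared year effect over 14 annual censuses, and a
unit-height Yule tree whose tip depth optima can evolve by Brownian
motion to couple phylogeny and habitat depth.

## Worked example

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_embed_quadrat.py
python analysis/03_habitat_stats.py
python analysis/04_phylo_mantel.py
python analysis/05_report.py
```

prints (abridged):

```
embedded 40x10 cells; depth 2.0-13.7 m (extent 11.7 m); max edge residual 5.77e-15 m; ...
14368 adults across 14 years
grazer depth: F=2261.5 p=0 | letters Ppol:a, Pfas:b, Pfam:c, Ptre:d, Iloo:e, Phor:f
grazer inclination: F=1.7 p=0.14 | letters Phor:a, Pfam:a, Ptre:a, Iloo:a, Pfas:a, Ppol:a
grazer GLMM: depth coef -0.338 (p=0), year SD 0.265, excluded ['Phor']
...
grazers (n=6): r = -0.259, p = 0.7809 (not significant; 9999 permutations)
```

Reading this: the node lattice re-embeds with numerically zero edge error;
the six grazer species occupy significantly different depth zones (every
species gets its own letter) while none separates by inclination (all
share "a"); grazer density declines with depth once species identity and
substratum are controlled (β_depth = −0.34), with a year-to-year SD of
0.27 on the log scale; the rarest grazer is excluded from the GLMM by the
minimum-occurrence rule; and with tree–trait coupling off (the default),
the Mantel test finds no association between phylogenetic distance and
depth differentiation, as expected. Full tables land in
`results/analysis/`, including a consolidated `report.md`.

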
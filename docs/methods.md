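# Methods

## Quadrat embedding

The survey quadrat is a lattice of (n_rows+1) × (n_cols+1) string nodes
with measured depths (z, metres, positive down) and a nominal 1 m string
spacing. We treat the spacing as the **3D chord** between adjacent nodes
(a taut string), not as horizontal distance: that is the only reading
under which the (x, y) of a node must be *solved* from its depth and its
distances to two neighbours rather than read off the lattice index.

Reconstruction is sequential and deterministic. Node (0,0) sits at the
origin; the first node row extends along +x with y = 0, each step
covering the horizontal chord √(L² − Δz²). The first node of each later
row advances +y below its north neighbour. Every interior node is
trilaterated from its west and north neighbours: intersect the two
spheres of radius L with the plane of the node's depth, giving two planar
circle intersections; the solution preserving the lattice handedness
(columns +x, rows +y) is kept, which prevents the sheet folding onto
itself. Degenerate cases — |Δz| > L on any edge, coincident anchors,
disjoint circles — raise a geometry error naming the node. For exact
(noiseless) inputs every reconstructed edge matches L to ~1e-15 m; an
optional global least-squares polish (`embed_grid(refine=True)`) is
provided for inconsistent field measurements, with the gauge re-pinned to
node (0,0) and the first row afterwards.

Cell inclination is the arithmetic mean, over the four triangles obtained
by dropping each corner of the cell in turn, of the angle between the
triangle normal and the vertical, folded into [0°, 90°] via |n_z| so the
result is independent of normal orientation. For a planar cell all four
angles coincide and equal arcsin(Δz/L) on a uniform slope. Averaging
angles (not normals) keeps the statistic insensitive to triangle area.

Substratum classes partition grain size (cm) as sand [0, 0.5), gravel
[0.5, 3), rubble [3, 20), stone [20, 50], rock (50, ∞). The stated class
limits are ambiguous at the boundaries; we use lower-closed intervals
except that 50 cm falls to stone, since stone is described as 20–50 and
rock as strictly > 50. Cell mean depth is the mean of the four corner
depths (the simplest unbiased choice; the statistic is not otherwise
pinned down). A water-level offset operation shifts all node depths by a
constant — a pure translation that provably leaves inclinations and the
depth extent unchanged — for exploring inter-annual lake-level change; the
default pipeline does not apply it.

## Census model and habitat summaries

Censuses are long-format records (year, species, cell, size class,
count). Only the large size class — sexually mature adults — enters any
analysis. Duplicate record keys are summed with a logged notice.
A species' habitat summary pools all years: mean depth is the
count-weighted mean of occupied-cell depths, quartiles are computed on
the count-expanded per-individual vector (standard boxplot semantics),
and the same expansion defines the observation unit for the ANOVA below.
The count-weighted pooled mean is also the single-number depth statistic
used for the Mantel habitat matrix. Pooling per-individual observations
across years is an assumption (the alternative — annual species means —
is not distinguishable from the study description); it matches the
granularity of per-individual boxplots.

## Within-ecomorph comparisons

For each ecomorph with several species (grazers, browsers), per-adult
depth and inclination values are compared across species by one-way
ANOVA and Tukey's HSD (α = 0.05, no additional correction across
ecomorphs). Pairwise outcomes are condensed by the insert-and-absorb
compact-letter algorithm: start with one column holding all species; for
each significant pair, split every column containing both; absorb subset
columns; assign letters to columns ordered by group mean. The resulting
display satisfies, exactly: two species share a letter iff their
comparison is non-significant (verified exhaustively for all significance
patterns on up to four groups).

## Poisson GLMM

Per-cell, per-year adult counts for one ecomorph are modelled as
y_ij ~ Poisson(exp(x_ij'β + b_j)) with a Gaussian random intercept b_j
per census year. Fixed effects: species (treatment-coded), depth (m),
substratum class (treatment contrasts, reference rock — the modal class
on a rocky shore), inclination (degrees). Zero counts are included: a
species' absence from a cell-year is information. Species with fewer
than 30 adults total are excluded with a notice (too rare to estimate;
this reproduces the rare-grazer exclusion in the motivating survey). The
error family (Poisson, log link) is the natural choice for counts; the
family and the zero-inclusion rule are both configurable.

The marginal likelihood factorises over years; each year's 1-D integral
is computed by adaptive Gauss–Hermite quadrature (21 nodes) centred at
the conditional mode with curvature scaling. Because the data enter each
group only through S_j = Σy and T_j(β) = Σexp(x'β), one likelihood
evaluation costs a single pass over the data, which makes replicate
simulations cheap. Optimisation is L-BFGS-B over (β, log σ) with
log σ bounded below at log(1e-4) so a zero variance component is
representable; standard errors come from the numerical Hessian at the
optimum; non-convergence or a non-PD Hessian sets a flag rather than
raising. Estimates, SEs and σ̂ agree with lme4::glmer (nAGQ = 21) to
~1e-4 on test fixtures, and the log-likelihood agrees with brute-force
numerical integration.

Overdispersion, zero inflation and spatial autocorrelation between
adjacent cells are deliberately not modelled.

## Mantel test

Phylogenetic distance is the cophenetic (tip-to-tip path-length) distance
on a user-supplied ultrametric tree; tree inference itself is upstream
and out of scope. Habitat distance is |mean depth difference|. The Mantel
statistic is the Pearson correlation of the strictly-upper-triangle
vectors; the null distribution jointly permutes rows and columns of the
second matrix (9999 permutations by default), and
p = (#{r* ≥ r} + 1)/(n_perm + 1) for the default tail "greater" — the
convention of the standard community-ecology implementations, so a
*negative* observed r is reported as non-significant under this tail, as
in the motivating study. The tail and permutation count are configurable;
a seeded generator makes every p reproducible. For n ≤ 8 an exact variant
enumerates all n! permutations and is used as the calibration reference:
the Monte Carlo p stays within binomial error of the exact p, and the
type-I error at α = 0.05 sits in [0.03, 0.07] over 500 null replicates.

## Synthetic scenario

The generator provides the study's statistical structure with known
truth. Defaults reproduce the survey scale: 40 × 10 cells of 1 m, shallow
edge 2.1 m, mean slope 0.2875 m per row (depth extent ≈ 11.5 m), smooth
random-phase sinusoidal roughness (amplitude 0.12 m, wavelength 8 m —
small enough that every edge stays embeddable, which is checked before
generation), 14 censuses, and the packaged 15-species roster (6 grazers,
7 browsers, 1 scraper, 1 scooper; 10 Tropheini).

Species k has log rate per cell-year
β₀k − (d − μ_k)²/(2σ_k²) + affinity_k[substratum] + b_year, a standard
Gaussian niche on the log scale — the simplest model producing unimodal
species depth distributions. Depth optima μ_k follow the observed
shallow-to-deep ordering within each ecomorph; niche breadths σ_k encode
territoriality (territorial 1.0 m, partially territorial 1.4 m,
non-territorial 1.8 m), reflecting that territory holders occupy sharper
depth bands; baseline abundances β₀k give totals of order 10³ adults per
common species over 14 years, and the rare deep grazer is set rare enough
(~20 adults) to trigger the GLMM exclusion rule. A few signature
substratum affinities (stone-preferring shallow grazer, gravel-preferring
mid-depth browser, sand-avoiding scraper, sand-dwelling scooper) exercise
the substratum terms. The year effect is one shared N(0, 0.2²) intercept
per census, mirroring the GLMM's random factor. Substratum classes are
drawn from a depth-dependent categorical model in which gravel decays and
sand grows with depth (shoreline grain sorting) while rock/stone/rubble
are spread broadly; sorting strength 0 degenerates to uniform classes.
Juvenile and sub-adult records are deterministic fractions (½, ⅓) of
adult counts and exist only to exercise adult filtering.

The tree is a unit-height Yule (pure-birth) tree over the species pool.
With Brownian rate 0 (default), tip depth optima are the configured μ_k,
independent of topology. With rate > 0, a Brownian realisation on the
tree is affinely mapped onto the configured optimum range, so close
relatives receive similar depths and the Mantel test has true signal; the
strong-coupling settings used in tests and the acceptance script use
rate 5 on the unit-height tree.

Determinism: every generator draws from a stream derived from the master
seed with a fixed per-generator namespace key (SeedSequence spawn keys),
so enabling one generator never shifts another's stream and identical
configurations yield byte-identical outputs.

What the generator does **not** emulate: behavioural exclusion dynamics
between territory holders, spatially autocorrelated counts beyond what
the smooth depth field induces, inter-annual lake-level trends, observer
error, and real niche shapes (which are unknown). Passing recovery tests
therefore demonstrates the statistical machinery is correct and
calibrated under the assumed model, not that the model captures every
feature of field data.

## Problem sizes and numerical choices

Replicate batteries are sized to give informative Monte Carlo precision
while keeping a full run cheap: Mantel calibration uses 20 exact-vs-MC
cases and 500 null replicates of 999 permutations (the headline test
itself defaults to 9999); GLMM recovery uses 200 replicates of the
400-cell × 14-year design at the generating values β_depth = −0.3,
σ_year = 0.2 (observed: ~95% CI coverage, < 1% bias); end-to-end rank
recovery uses 50 replicate scenarios (mean Spearman ρ ≈ 0.96). Tolerances:
embedding residuals < 1e-6 m on noiseless input (achieved ~1e-15),
planar inclination recovery < 1e-6°, trilateration solutions satisfy both
sphere equations to 1e-9 m. Ties in the Mantel tail count use a 1e-12
slack so permutations equal to the observed statistic count as extreme
(conservative). The exact Mantel enumeration is capped at n = 8 (40 320
permutations).

## Known limitations

- The GLMM supports a single random intercept (year); crossed or nested
  random effects are out of scope.
- The sequential embedding propagates measurement error row by row; for
  noisy field data use the least-squares refinement flag.
- Compact letters are not guaranteed minimal in letter count for every
  pathological significance relation, only correct (sharing ⇔
  non-significance), which is the property the display promises.
- The per-individual ANOVA treats individuals as independent; flocking or
  territory clustering would understate within-species variance.
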
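# Methods

This note documents the models, conventions, parameter choices and known
limitations of petalspectrum, in the order the pipeline runs them.

## Outlines and conventions

An outline is an ordered, implicitly closed polyline in arbitrary planar
units.  Internally every outline is counter-clockwise with positive signed
area; raster input (origin top-left, y down) has its y axis flipped on
ingestion so one convention holds everywhere.  The canonical start vertex is
the one nearest the view's anchor landmark (front: top; side: tube base),
which makes elliptical Fourier coefficients invariant to how the source file
happened to order its points.

Raster tracing uses connected-component labelling plus marching squares at
level 0.5 on the largest component.  A 1-pixel Gaussian smoothing is applied
first: marching squares on hard binary data produces a staircase contour
whose length overestimates the true boundary by several percent, while the
smoothed contour recovers a 20-px disk's perimeter to within 0.5% (the cost
is slight corner rounding, negligible for flower silhouettes).  Resampling
places vertices at equal arc-length spacing (default 300 points — more than
8× the default harmonic ceiling, so lobed corollas are never aliased), with
landmarks re-snapped to the nearest new vertex (ties to the lower index).

## Alignment and elliptical Fourier analysis

Landmark configurations (4 front / 3 side) are superimposed by full
generalised Procrustes analysis: centre, scale to unit centroid size, rotate
by the 2D orthogonal Procrustes solution against an evolving consensus, with
per-specimen optimal scaling, iterated until the consensus moves by less than
1e-10.  The similarity transform fitted on landmarks is applied to the whole
outline; harmonic-based normalisations are deliberately not used, since they
would fight the landmark alignment.  After convergence the whole set is
rotated rigidly so the consensus bilateral axis (front: top→bottom landmark;
side: tube base → lip midpoint) lies along +x.

Coefficients follow the classical chord-length parameterisation; offsets
(A0, C0) are arc-length means.  With the bilateral axis on +x, mirroring a
shape maps (a, b, c, d) → (a, −b, −c, d) and C0 → −C0 exactly, so the (b, c)
subspace *is* the left–right asymmetric component.  Removing within-specimen
asymmetry zeroes b, c and C0 — identical to averaging the shape with its own
mirror image in coefficient space; this is applied to the front view only
(the side view's upper/lower asymmetry is a real trait, not noise).  The
complementary mode (zeroing a, d, A0 to *keep* the asymmetric residual) is
available via `component="symmetric"`.  Asymmetry is removed per specimen
before taxon means are taken.

Harmonic-count calibration finds the smallest N whose mean cumulative power
fraction across outlines reaches the threshold (default 0.99, ceiling 64).
Fractions are measured against the full available spectrum (the Nyquist
harmonic of the coarsest outline, capped at 256), not against the N_max
truncation — otherwise the fraction at N_max would be 1 by construction and
an unreachable threshold could never be reported.  Whether the original
workflow applied its threshold per outline or on average is not recorded
anywhere; the arithmetic mean across outlines is used here.

## Morphospace and clustering

PCA is run on centred, unscaled per-taxon coefficient vectors (covariance
PCA: after Procrustes scaling all coefficients share units).  Loading signs
follow a deterministic convention (largest-magnitude entry positive).  Clade
occupancy is the convex-hull area of each clade's scores on a chosen axis
pair; clades with fewer than three non-collinear taxa are flagged degenerate
with area zero.

Cluster-number selection runs seeded k-means (Lloyd, k-means++, best of 10
restarts) for each K in [2, 20] and lets a battery of ten internal validity
indices vote, each with its standard optimum rule: maximise
Calinski–Harabasz, silhouette, Dunn and Krzanowski–Lai; minimise
Davies–Bouldin, C-index and Xu; gap statistic by the Tibshirani one-SE rule
with 50 seeded uniform reference sets; Hartigan's smallest K with H ≤ 10;
Ball–Hall by largest successive drop.  The modal vote wins, ties broken
toward smaller K.  The majority mechanism is the point; the battery is
configurable and intentionally smaller than the 30-index battery of the R
ecosystem — each member here has a standard published formula.  Note that
with few points a K range running close to n lets near-singleton clusterings
degenerate several indices (Calinski–Harabasz grows without bound as K → n),
so K_max should stay well below the taxon count; the bundled demo uses
K_max = 8 for its 24 taxa.

## Ornstein–Uhlenbeck shift detection

Traits (by default the first three PCs per view) follow a stationary-root OU
process with piecewise-constant optimum.  A shift acts from the start of its
edge — the same convention the trait simulator uses, so simulation and
inference agree by construction.  Tip expectations are linear in the shifts
via the design X_ie = 1 − e^{−α(T_i − s_e)} on ancestral edges, and the tip
covariance is (σ²/2α) e^{−α d_ij} with d_ij the patristic gap above the MRCA.

Fitting profiles everything but α in closed form (GLS for θ0 and β, variance
MLE per trait, floored at 1e-12 for degenerate data) and maximises over α by
a 16-point log grid spanning phylogenetic half-lives of 0.05–10 tree heights,
refined by golden section.  α is shared across traits by default (the traits
are PCs of one structure); per-trait α sits behind `shared_alpha=False`.
Measurement error is not modelled.

Candidate shift sets come from a whitened group-lasso path (FISTA, edges as
groups across traits, intercept projected out) at each grid α, harvesting
every support along the path together with its norm-ordered nested prefixes.
Two repairs make the search robust: supports containing all root-child edges
(jointly collinear with the intercept on an ultrametric tree) also contribute
variants dropping one; and when the total number of edge subsets up to s_max
is small (≤ 300) the candidate list is completed by exhaustive enumeration,
making the procedure an exact best-subset search on small trees.  Every
candidate is refitted exactly and scored by
pBIC = −2 logL + p log n + 2 s log m (p counts σ², θ0 and β per trait plus
the shared α; the 2 s log m term charges for placing s of the m edges).  The
ten best candidates are then polished by alternating backward elimination and
a forward pass restricted to lasso-screened edges, to a fixpoint.  The search
is fully deterministic.

Calibration, measured by the bundled experiments: on 6-tip trees the search
attains the exhaustive-enumeration optimum; on 100-tip null simulations
(q = 3) the empty configuration is selected in ≥ 95% of replicates; three
planted shifts of 4 stationary SDs per trait on disjoint mid-sized clades of
a 128-tip tree are typically recovered exactly (≥ 2 of 3, ≤ 1 false edge
across seeds, counting the adjacent parent/child edge as a hit — adjacent
placements are likelihood-equivalent to numerical precision when the
connecting edge is short).

## D-statistics

Pattern sums are frequency-weighted per site: ABBA = (1−p1)p2p3(1−pO) and
analogously for BABA and BBAA, so fixed sites reduce to integer pattern
counts and polymorphic outgroup sites are down-weighted by 1−pO.  Sites
missing any trio population are skipped.  Arrangement modes: **BBAA** places
the pair sharing derived alleles most often as P1/P2 (three-way ties flagged
and broken lexicographically) and orients P2 so D ≥ 0, matching all-positive
heatmaps; **min** reports the smallest |D| over the three pairings;
**tree** fixes the sister pair from a supplied species tree (lexicographic
P1/P2 order, sign kept).  Significance is by delete-one contiguous-block
jackknife (default 20 equal blocks; the block count is configuration), with
Z = D/SE and a two-sided normal p; zero jackknife variance with D ≠ 0 is
flagged degenerate with p = 0.  BH correction is applied jointly across all
trios of one run before heatmaps are built; heatmap cell (P2, P3) carries the
D of the maximal-|Z| trio over P1 choices, with empty cells left missing.

## Synthetic generators

The corolla family is an engineering construction spanning the qualitative
phenotypes of interest, not a claim about floral development.  Front view:
r(θ) = R[1 + L(θ) cos k(θ−π/2)] with L(θ) = L0(1 + g sin θ), phased so a
petal sits at the top and the shape is exactly mirror-symmetric when noise is
off; an angular warp θ + b cos θ widens upper vs lower inter-lobe angles
while preserving that symmetry; lateral doubling adds Gaussian bumps at the
inter-petal trough pair nearest the horizontal axis (7 radial maxima for
k = 5).  Left–right noise is radial and anti-symmetric (vertex j pairs with
n−j under the mirror; fixed points stay unperturbed), so its entire effect
lands in the (b, c) coefficient subspace.  Side view: a constant-width tube
(aperture width 1) with constant-curvature centreline, upper/lower lips of
fixed 0.8-rad flare whose lengths differ by the upper-lobe excess, deflected
further by the reflex angle; tubes that would self-intersect are rejected.

Trees are pure-birth (unit rate), stopped at n tips plus one further waiting
time, rescaled to height 1 — the simplest model supporting OU
identifiability; real chronograms are supplied by the user.  OU traits use
the exact pre-order Gaussian transition, so no discretisation error enters.
The genotype generator is pattern-based, not coalescent: per site a class is
drawn from {BBAA, ABBA, BABA, invariant} with probabilities
{p_b, p_d + f_e, p_d, remainder}, which is the minimal sufficient generator
for D-statistics (they depend only on site-pattern frequencies) and gives
the closed form E[D] = f_e/(2 p_d + f_e).  None of the generators emulate
linkage, sequencing error, missing data or within-population frequency
variation; passing tests therefore validate the estimators under clean
inputs, not robustness to those artefacts.

A note on a tempting but wrong check: the cross-tip sample variance of one
OU simulation is *not* the stationary variance σ²/2α — shared ancestry
correlates tips and biases it down by roughly the mean off-diagonal
correlation (≈ 14% at α = 1 on a unit-height pure-birth tree).  The variance
check is therefore run at α = 2.5, where the bias is negligible, and the
rigorous validation is the replicated-simulation covariance test against
(σ²/2α) e^{−α d_ij} on a fixed 4-tip tree.

## Pipeline and reproducibility

A single global seed fans out to stage seeds by a fixed affine scheme
(seed × 100003 + stage index, mod 2³¹−1), so stages rerun in isolation
reproduce their in-pipeline behaviour.  All floating-point CSV output is
written at 12 significant digits; two runs with identical config and seed
produce byte-identical result files.  The manifest records package version,
seed, config echo and SHA-256 hashes of all inputs and outputs; per-stage
wall times go to `run.log`, deliberately outside the manifest so the manifest
itself is reproducible.

## Problem sizes of the bundled experiments

Chosen to exercise each claim well inside a single-CPU desk budget: EFA
analytic checks on 512-point circles and 300-point flowers at 64 harmonics;
clustering on 3 × 50 blob points with K ∈ [2, 20]; OU brute-force equivalence
on three 6-tip datasets (s_max = 2); null conservativeness over 50 replicates
of 100 tips × 3 traits; 3-shift recovery on 128 tips; D-statistic null
calibration over 200 replicates of 10⁵ sites (20 blocks) and admixture
recovery at f_e = p_d = 0.1; demo reproducibility on 16 taxa × 2 specimens ×
2 views with 8000 sites.  The full suite runs in a few minutes.

## Known limitations

- One tip per taxon is required for shift detection; collapsing multiple
  conspecific samples is left to the user.
- No semilandmark sliding, no Fourier normalisation variants, no
  phylogenetically corrected or between-group PCA, no 3D shapes.
- Shift regimes are independent; convergent regimes on distinct edges are
  not merged.
- The pBIC placement penalty 2 s log m approximates the original criterion's
  determinant and configuration-count terms; it is validated here by
  conservativeness and recovery experiments, not by numeric equality with
  any particular reference implementation.
- No f4-ratio/f-branch statistics, windowed scans or network inference; the
  D-statistic machinery assumes biallelic sites and a fixed-ancestral
  outgroup designation.
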
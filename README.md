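# petalspectrum

Quantitative analysis of flower-symmetry variation and its evolution, built
for clades — such as the tropical *Rhododendron* radiations — where corolla
symmetry is a continuum rather than a clean radial/bilateral dichotomy.  The
package is aimed at plant evolutionary biologists who have corolla outlines
(front and side views), a dated phylogeny and genome-wide biallelic SNPs, and
who want to go from raw outlines to morphospaces, symmetry phenotypes,
evolutionary-regime shifts and introgression scans in one reproducible run.

## What it computes

**Outline morphometrics.** Each corolla outline (traced from a binary mask or
read from a coordinate table) is closed, counter-clockwise and landmarked
(front: left-mid/right-mid/top/bottom; side: tube base and the two lip tips).
After a full generalised Procrustes alignment on the landmarks, elliptical
Fourier analysis decomposes the outline into per-harmonic quadruples
(a_n, b_n, c_n, d_n):

    x(t) = A0 + Σ_n a_n cos(2πnt/T) + b_n sin(2πnt/T)
    y(t) = C0 + Σ_n c_n cos(2πnt/T) + d_n sin(2πnt/T)

with t the cumulative arc length and T the perimeter.  The harmonic count is
calibrated so the mean cumulative harmonic power Σ(a²+b²+c²+d²)/2 exceeds a
threshold (default 99%).  With the bilateral axis mapped to +x, the (b, c)
subspace is exactly the left–right asymmetric part of shape, so
within-specimen asymmetry is removed by zeroing it — the coefficient-space
average of a flower with its own mirror image.

**Morphospace and phenotypes.** Per-taxon mean coefficients enter an ordinary
(covariance) PCA; clade occupancy is measured by convex-hull areas, and
symmetry phenotypes are found by k-means with the cluster number chosen by
majority vote of a ten-index validity battery (Calinski–Harabasz, silhouette,
Davies–Bouldin, Dunn, C-index, gap statistic, Hartigan, Krzanowski–Lai,
Ball–Hall, Xu).

**Shifts in floral evolution.** The leading PC scores evolve under a
multivariate Ornstein–Uhlenbeck model whose optimum θ may jump on selected
edges of the phylogeny.  Tip expectations are linear in the shifts,
E[y_i] = θ0 + Σ_e β_e (1 − e^{−α(T_i − s_e)}), with stationary-root covariance
(σ²/2α) e^{−α d_ij}.  Candidate shift placements come from a whitened
group-lasso path over an α grid; each candidate is refitted by profiled
maximum likelihood and scored with a phylogenetic BIC,
pBIC = −2 logL + p log n + 2 s log m, whose placement term keeps the search
conservative.

**Introgression.** Trio D-statistics D = (ABBA − BABA)/(ABBA + BABA) from
per-population derived-allele frequencies, in three arrangement modes (BBAA,
D_min, species-tree), with delete-one block-jackknife Z-scores,
Benjamini–Hochberg correction across trios and P2×P3 heatmap matrices.

**Synthetic generators** provide ground truth for every stage: a parametric
corolla family (petal count, lobing depth, dorsoventral gradients, lateral
doubling, tube length/curvature, left–right noise), unit-height pure-birth
trees, exact OU trait simulation with planted shifts, and a site-pattern
genotype generator with a known admixture excess (expected
D = f_e/(2 p_d + f_e)).

## Worked example

Detect optimum shifts on a simulated 64-tip tree with one planted shift of
two stationary standard deviations on the edge above 20 tips:

```python
from petalspectrum import gen_tree, sim_ou_traits, OUShiftModel
from petalspectrum.simulate import OUSimSpec

tree = gen_tree(64, seed=7)
traits = sim_ou_traits(tree, OUSimSpec(q=3, alpha=2.0, sigma2=1.0,
                                       shifts=[(65, 2.0)], seed=8))
print(OUShiftModel(tree, traits).fit(s_max=6).summary())
```

```
Ornstein-Uhlenbeck shift detection
============================================
tips: 64   edges: 126   traits: 3
alpha (shared): 2.337
sigma2: [0.8207 1.5005 1.2274]
theta0: [-0.3661 -0.0037 -0.0792]
log-likelihood: -88.3037
pBIC: 227.8688
shifts (1):
  mrca(t1,t54): [2.5249 1.6599 1.9654]
```

The search recovers exactly the planted edge (the clade spanning t1..t54,
edge 65) with per-trait optimum deltas near the simulated value of 2, a
selection strength α near the simulated 2.0, and no spurious shifts.

The full pipeline runs from a config file or as a bundled synthetic demo:

```bash
petalspectrum demo --out demo --seed 0      # generate + analyse, ~30 s
petalspectrum run demo/inputs/config.yaml   # same thing from the config
```

The demo prints a summary like
`{"front_chosen_k": 3, "front_n_shifts": 4, "dstat_BBAA_significant": 1, ...}`
and writes coefficient tables, PC scores, hulls, cluster votes, shift models,
D-statistic tables and a manifest of input/output hashes under `demo/results/`.
Re-running with the same seed reproduces every result file byte for byte.

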
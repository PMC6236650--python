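# Methods

## The inference model

The package assumes the sampled population descends from a radial range
expansion without admixture from pre-existing populations: as small founder
groups colonise new territory along the wavefront, variation is sequentially
subsampled, so expected heterozygosity declines monotonically with distance
from the origin. Inference never fits that process explicitly; it only
exploits the monotone-decline signature through rank-free machinery:

- **Kernel rule.** A grid node is an *accepted kernel* when at least
  `min_samples` (default 5) samples lie within `radius_km` (default 500 km,
  boundary-inclusive) of it, by great-circle distance on a sphere of mean
  radius 6371.0088 km. Ellipsoidal corrections are below 0.5% and immaterial
  at this scale, so no geodesy library is used. Grids are node-registered
  lattices, inclusive of the lower bound. Co-located samples all count;
  coordinates are never jittered or deduplicated.
- **Diversity.** Per locus, Nei's unbiased gene diversity
  h = n/(n−1)(1 − Σpᵢ²) over the kernel members' non-missing allele copies;
  h is undefined for n < 2 and such loci are excluded from the across-locus
  mean rather than imputed (this keeps the estimator unbiased and
  well-defined under arbitrary missingness). With one scored allele copy per
  sample — the default, appropriate for a strongly selfing crop — n is the
  number of members with a call at the locus.
- **Candidate scoring.** Pearson's r between distance-to-kernels and kernel
  mean diversity. Zero-variance inputs give an undefined (NaN) r, never 0;
  a variance at floating-point rounding scale (≤ 10⁻¹⁰ relative) counts as
  zero. Surfaces report r at every node; the argmin (first node in
  lat-major order on exact ties) is the best-supported origin. Interpolation
  of surfaces is bilinear, for display only.
- **Permutation comparison.** The unit of permutation is the whole genotype
  vector (all loci plus GBSSI jointly), reassigned across the fixed sample
  coordinates; this preserves the marginal allele pool and within-sample
  linkage exactly, and means kernel memberships never change within a
  comparison (asserted by test against full per-permutation recomputation).
  p = (1 + #{|Δr*| ≥ |Δr_obs|})/(n_perm + 1), ties counting as exceedances;
  the +1 correction keeps p in (0, 1]. Sample-level (not site-grouped)
  shuffling is used; with several samples per location the site-grouped
  alternative would permute blocks instead, which this package does not
  implement.

Neighbouring grid nodes frequently contain exactly the same member set.
Kernel sets record this grouping and the permutation loop computes one
diversity value per distinct member set, fanning values back out to nodes.
Every node keeps its own centre and distance, so grouping is purely a
speed-up: grouped and ungrouped computations are exactly equal (tested).

## The synthetic expansion generator

Demes on a regular lat/lon lattice (default 1° step over a 20°×10° domain)
are colonised breadth-first from the origin deme, wave by wave. A deme holds
`deme_capacity` (100) individuals; an individual is one allele copy per
locus (selfing collapses within-individual heterozygosity, so copies are
tracked, not diploid genotypes). Each new deme is founded by
`founder_copies` (8) individuals drawn without replacement from the pooled
copies of all its already-colonised rook neighbours, regrown to capacity by
resampling, then run for `generations_per_step` (1) Wright–Fisher
generations with stepwise mutation (±1 repeat, rate 5·10⁻⁴ per copy per
generation, reflecting at the ancestral repeat bounds, default 8–40).
Sampling draws 200 individuals at deme centres (uniform over demes by
default; a Dirichlet-weighted "clustered" mode and coordinate jitter are
available) with 2% missing calls.

Two modelling choices deserve emphasis:

- **Wavefront gene flow.** Founding from the pooled neighbours, rather than
  a single parent deme, is what keeps adjacent lineages from drifting apart.
  Without it, pooled kernel diversity stops declining with distance (local
  between-deme divergence compensates for within-deme loss) and the
  distance–diversity signal collapses — an instructive failure mode of
  purely tree-like expansion simulators. There is no migration after
  founding: demes are frozen once their children exist, so the expected
  within-deme decline along any colonisation path is exactly geometric with
  per-step factor (1 − 1/founder_copies)(1 − 1/deme_capacity)^generations
  (defaults: 0.866 per step), which the drift test verifies by Monte Carlo
  against the closed form.
- **What is and is not emulated.** The generator produces the monotone
  diversity decline, multi-allelic loci with missing calls, spatially
  clustered sampling and (optionally) painted GBSSI genotypes. It does not
  model post-expansion migration, admixture, selection, timescale
  calibration (generations are abstract), or anisotropic geography; lattice
  colonisation is rook-wise while distances downstream are great-circle, a
  mild anisotropy that the recovery tests absorb. Passing tests therefore
  demonstrate that the inference machinery recovers the idealised signal it
  assumes — not that real data satisfy those assumptions.

Default problem sizes (200 samples, 16 loci, 0.5° candidate grids, 20
recovery replicates, 200 calibration runs at 199 permutations) keep the
full test suite and the acceptance script at a couple of minutes on one
CPU while leaving Monte-Carlo error well inside the asserted margins.

## Secondary analyses

- **PCA.** Samples are encoded as allele copy fractions per (locus, allele)
  column; rows of complete loci sum to 1 per locus. Missing loci take the
  column mean; columns are centred (not scaled — scaling is exposed as a
  choice for the caller by pre-transforming the matrix) and zero-variance
  columns dropped. Variance fractions are eigenvalues over the total
  variance, computed via scikit-learn's full SVD and cross-checked in tests
  against a dense eigendecomposition.
- **ΔK.** From a delimited log of per-run clustering log-probabilities
  (columns K, run, lnP; replicates paired by run index), ΔK at interior K is
  mean over runs of |L(K+1) − 2L(K) + L(K−1)| divided by the across-run
  standard deviation of L(K). ΔK is undefined (NaN, not infinite) at
  boundary K and wherever the standard deviation is zero. Note ΔK is
  invariant both to adding a constant to all lnP and to scaling them: the
  numerator and denominator scale together. Running the Bayesian clustering
  itself is out of scope; a fixture generator produces logs with a
  controlled elbow for testing.
- **GBSSI.** Allele frequencies for S0/S−15 and LC/LY/Lf with missing
  genotypes excluded from denominators. Phenotype classing: any S0 copy ⇒
  wild type (S0 is dominant); S−15 homozygotes are waxy, graded fully waxy
  when no LC copy is present. The LC-rescue grading is an interpretive rule
  and can be disabled (`lc_rescues_waxy=False`).
- **Maps.** Plain matplotlib on equirectangular lat/lon axes: interpolated
  correlation surfaces (red = negative r = plausible origin), sample points,
  starred candidate sites, per-sample ancestry pies, genotype-coloured
  points. Projections would only affect display, not statistics, and are
  deliberately omitted.

## Named candidate sites

Published work compares archaeological candidate sites (Dadiwan,
Xinglonggou, Sokol'tsy); their coordinates are not part of the genotype
data, so `originscan.sites` ships approximate literature-derived defaults
(35.01°N 105.60°E; 42.33°N 119.25°E; 48.70°N 29.90°E) that callers should
override when better coordinates are available. At 500-km kernel scale the
comparison is insensitive to errors of a few tens of km.

## Degenerate inputs and numerical choices

- Fewer than two accepted kernels, or fewer than two with defined
  diversity: surfaces and comparisons raise; single-kernel inputs are an
  error path, not a silent zero.
- An undefined correlation at a compared site raises naming the site.
- Unparseable coordinates are retained as missing (the row survives);
  numerically out-of-range coordinates are validation errors naming the
  row. Coordinate strings are parsed with correctly-rounded `float()` so
  write→read→write is byte-stable.
- Permutation streams derive from a single named seed
  (`numpy.random.default_rng`); swapping the two compared sites negates
  Δr and reproduces the identical p under the same seed.

## Known limitations

- The kernel-correlation scan treats kernels as independent observations;
  overlapping 500-km discs make neighbouring kernels highly dependent, so r
  magnitudes are descriptive and only the permutation p is inferential.
- With few effective independent kernel patches (small domains), the null
  spread of Δr is wide and power to separate nearby candidate sites is low
  — mirroring the inconclusive site comparisons typical of this design on
  real data.
- Sample-level permutation assumes exchangeability of genotype vectors
  across locations under the null; strong within-site duplication (clonal
  resampling of accessions) would violate it.
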
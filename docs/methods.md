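# Methods

This note documents the models, algorithms and defaults implemented in
`pbsnet`, the choices made where the design was genuinely open, and what
the synthetic cohorts do and do not establish about real data.

## Voxel graph and density-weighted distance

A gray-matter mask is a boolean 3D volume; masks that are not 26-connected
are restricted to their largest component with a logged warning, since
seed placement and growth are undefined across components. Voxels are
enumerated by ascending linear index `x + sx·(y + sy·z)` over 0-based
(x, y, z) grid coordinates; all deterministic tie-breaks below refer to
this order. Edges join 26-neighbors with weights 1, √2, √3 by whether the
pair shares a face, an edge, or only a vertex. Distances are in lattice
units (one face step = 1); anisotropic voxel dimensions are carried as
metadata only, since the weight table is unitless.

Geodesic distances are Dijkstra shortest paths on this sparse graph
(`scipy.sparse.csgraph`). The local density `L(i)` sums the `M` smallest
nonzero geodesic distances from voxel *i*, with `M = floor(V/N)` the
expected parcel size. The computation is exact: sources are processed in
chunks with a distance cutoff that doubles until every source has at
least `M` finite neighbors. Because `L(i)` is a sum of the `M` smallest
*values*, distance ties cannot change it, so no tie rule is needed there.
The density-weighted distance is `D(i,j) = 2·G(i,j)/(L(i)+L(j))`: doubling
all densities halves all distances, and `D` inherits symmetry and
positivity from `G` on connected masks.

## Random parcellation

One PBS sample is generated as:

1. **First seed** uniform over mask voxels, from the sample's RNG seed.
   This is the only random draw; everything after is deterministic, so
   one integer indexes one ensemble member.
2. **Remaining seeds** by farthest-point sampling under `D`: each new
   seed maximizes the minimum `D` to all placed seeds (argmax ties go to
   the lowest linear index). This spreads seeds evenly over the sheet,
   with the density weighting pulling them slightly toward sparse,
   hard-to-grow regions.
3. **Growth** (default `method='balanced'`): iterative region growing in
   which the currently smallest parcel claims the cheapest unassigned
   voxel on its frontier; the cost of a frontier voxel is the
   density-weighted geodesic from the parcel's seed accumulated through
   the parcel's own territory. Scheduling ties break by lower label,
   frontier ties by lower linear index. Because every claim extends an
   existing region through an adjacency edge, parcels are 26-connected by
   construction, and sizes stay within one voxel of each other until a
   front is walled in by its neighbors — trapping is the only source of
   size variation during growth.
4. **Size balancing.** Trapped fronts leave a tail of small parcels, so a
   deterministic post-pass migrates boundary voxels from larger parcels
   to adjacent parcels at least two voxels smaller. A voxel may move only
   if it is not its parcel's seed and its remaining same-parcel neighbors
   stay 26-connected inside its 3×3×3 neighborhood (a simple-point
   criterion, sufficient to preserve global contiguity). Voxels are
   visited in linear-index order and each transfer strictly decreases the
   sum of squared sizes, so the pass terminates (bounded at 20 sweeps; it
   converges in a handful). On a 30k-voxel shell this brings SD/mean from
   ~7% to 1–4% and IQR/median to 0.02–0.07 across N = 250–1000.

A single-pass nearest-seed assignment (`method='voronoi'`, the exact
argmin over seeds of `D(s, v)`, with a deterministic repair step for the
rare fragments that arise because `L` varies along a path) is provided
for comparison. It is substantially less size-homogeneous — on a 30k
shell it measures SD/mean around 15–17% against 6–8% for the balanced
grower — which is why balanced growth is the default: the entire point of
the algorithm is that ensemble members be size-comparable.

No Lloyd-style re-seeding is performed: a single growth pass already
reaches the target homogeneity, and re-seeding would decouple the sample
from its RNG seed history.

Parcel-size statistics use linear-interpolation (type-7) quantiles; this
matters for the IQR/median ratio at small parcel sizes, where sizes are
coarsely quantized. NMV, the normalized maximum variation, is
`(max − min)/min` of the size multiset.

## Connectivity matrices

**Structural.** A streamline connects the parcel pair of its two terminal
points (nearest-voxel lookup; interior points are ignored — the simplest
reading of endpoint connectivity). Streamlines with an off-mask endpoint
are discarded and counted. Edge weights are
`w_ij = 2/(n_i+n_j) · Σ_m 1/L_ij^m` with `L_ij^m` the polyline arc length
of the *m*-th connecting fiber and `n_i` the parcel voxel counts; pairs
with fewer than 10 fibers (default) are set to zero to suppress spurious
tracts. An alternative normalization — raw count divided by mean node
volume and mean fiber length — is available as
`normalization='mean'`; the two readings differ and the displayed-formula
variant is the default.

**Functional.** Voxel series are residualized on an intercept plus the
confound columns (ordinary least squares; rank-deficient confound sets
are rejected with the collinear columns named), then averaged within
parcels and correlated (Pearson). The diagonal is stored as zero so that
ensemble summaries (mean FC, strengths) exclude self-correlation.
Negative correlations are kept unthresholded, and no Fisher z-transform
is applied before averaging. Regression happens at the voxel level,
before parcel averaging; with parcel-mean aggregation the two orders are
nearly equivalent, and voxel-level is the conservative choice.

## Global metrics

Six per-network scalars, computed on the positive part of the weights for
the path- and community-based quantities (relevant for signed FC
matrices), with strength keeping signed sums:

- **average degree** — mean count of nonzero neighbors;
- **mean strength** — mean row sum;
- **clustering** — Onnela geometric-mean weighted clustering, weights
  normalized by the network maximum;
- **global efficiency** — mean of `1/d_ij` with path lengths on `1/w`
  edge costs; unreachable pairs contribute zero;
- **modularity** — best Q over 20 Louvain restarts with consecutive
  seeds (ties keep the earlier restart, so Q is non-decreasing in the
  number of restarts);
- **diversity** — mean Rubinov–Sporns diversity coefficient: per-node
  Shannon entropy of strength across the Louvain modules, normalized by
  log of the module count.

The specific clustering/diversity formulations are toolkit conventions;
different conventions shift absolute values, which is why cross-study
magnitude comparisons of these two metrics should be made with care.

## Ensemble statistics

For a cohort array (subjects × scans × parcellations, per metric):

- `sigma_parcellation`: SD across the ensemble at scan 1, averaged over
  subjects;
- `sigma_between_scan`: RMS difference of the two scans' subject-level
  ensemble means, `sqrt(mean_i (Ḡ1_i − Ḡ2_i)²)`;
- `sigma_subject`: SD across subjects of scan-1 ensemble means.

These are descriptive statistics, not unbiased estimators of generative
variance components: under an additive subject/scan/parcellation model
with SDs (σa, σb, σe) and P parcellations, their expectations are
approximately σe, `sqrt(2σb² + 2σe²/P)` and `sqrt(σa² + σb² + σe²/P)`.
The recovery tests therefore compare against these analytic expectations,
averaged over replicate cohorts because a single SD estimate at 20
subjects carries ~16% sampling error of its own.

ICC is the one-way random-effects ICC(1,1),
`(MS_between − MS_within)/(MS_between + (k−1)·MS_within)`, which can be
negative; degenerate (zero-variance) tables are rejected. The comparison
report computes the ICC of the subject-level ensemble means and the mean
of per-parcellation ICCs, with a one-tailed one-sample t-test of the
per-parcellation ICC sample against the ICC of the mean. Averaging first
removes independent parcellation noise from the within-subject variance,
so the ICC of the mean is systematically the larger — the ensemble's main
reliability payoff.

## Fingerprinting

The mFCV of a subject/session is the vector of mean off-diagonal FC
values, one per ensemble parcellation, in a parcellation order shared by
all subjects. Similarity between mFCVs is the plain Pearson correlation
(a scalar; the vectors are unordered samples, so lagged cross-correlation
would be meaningless), and identification is the row/column argmax of the
cross-session similarity matrix, ties broken by lowest subject index with
a warning. The accuracy-vs-samples curve subsamples parcellation indices
without replacement, the same subset in both sessions. A matrix baseline
(correlating vectorized upper-triangle FC from a single parcellation) is
included for comparison.

## Synthetic cohorts

The generators produce the smallest data that exercise each estimator
with known ground truth:

- **Mask**: a hollow ellipsoid shell (axis ratio 1 : 0.85 : 0.72,
  thickness 2.5 voxels by default), voxelized to within 5% of a target
  count, optionally folded by a sinusoidal radial perturbation. It mimics
  the sheet-like topology of cortex — the regime where Euclidean seed
  spreading fails and geodesic spreading matters — but not gyral
  geometry, partial-volume edges, or segmentation noise.
- **Streamline cohorts**: a shared backbone assigns latent mean fiber
  counts to a random 35% of parcel pairs (gamma-distributed around 30
  fibers); subjects multiply edges by log-normal effects (SD 0.5),
  scans by log-normal noise (SD 0.15), both mean-one; observed counts are
  Poisson draws, and each fiber is a straight 2-point streamline with
  endpoints uniform in its two parcels. This tests the counting,
  weighting and variance estimators, not tractography realism: real
  fibers curve, have length-dependent seeding biases, and correlated
  errors.
- **BOLD cohorts**: voxel series are `factors @ loadings.T` plus white
  noise and confound leakage. Loadings mix a population pattern with a
  subject-specific one (weight `identity_signal`, default 1.0, i.e. half
  the factor variance is subject-specific) and persist across sessions;
  temporal factors are redrawn per session. Defaults: 5 factors, 300
  timepoints, noise SD 1.0, 8 confounds. The identity information is
  purely spatial-covariance structure stable across days — the premise
  fingerprinting relies on; hemodynamics, motion and scanner drift are
  out of scope. Passing fingerprint tests therefore show the estimator
  chain is correct, not that real cohorts reach any particular accuracy.
- **Metric cohorts**: direct draws from the additive
  subject/scan/parcellation model, for estimator tests at scale without
  running the imaging pipeline.

All draws come from one `numpy.random.Generator` per cohort, so every
dataset is reproducible from (spec, seed).

## Problem sizes and numerical choices

The shipped verification runs use reduced problem sizes chosen as the
package's own desk-scale conditions: a ~30,000-voxel shell for the
parcel-homogeneity studies (20 ensembles at N=500 and N=1000, 100 at
N=250), and a ~3,000-voxel shell with 60-node parcellations, 400 PBS
samples and 50 subjects for the end-to-end fingerprinting study. Exact
oracle checks (Floyd–Warshall distances, ANOVA ICC, hand-computed edge
weights) run at toy sizes where brute force is feasible.

Other numerics: distance comparisons use strict `<` with
first-come-wins ties so chunked and unchunked growth agree; the
connectivity repair loop is bounded at 100 sweeps (in practice 0–2);
Lilliefors normality p-values are only computed for non-constant samples
of at least 20; zero-variance node series, empty masks, and degenerate
ICC tables raise rather than propagate NaNs.

## Known limitations

- Parcel labels are not comparable across parcellations — by design; the
  package offers no node-level cross-subject statistics.
- The balanced grower equalizes sizes at a small cost in boundary
  smoothness; parcels can be mildly irregular at their meeting fronts.
- Structural weights depend on the endpoint rule; streamlines passing
  through a parcel without terminating there contribute nothing.
- FC metrics on signed matrices follow the positive-weights convention
  noted above; alternatives (absolute values, signed variants) are not
  implemented.
- Geodesic distances ignore anisotropic voxel sizes; strongly anisotropic
  acquisitions should be resampled before parcellation.
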
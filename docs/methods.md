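# Methods

This note records the models, conventions and parameter choices behind
`swallownet`, including the places where the design was genuinely open and
the package had to fix a convention.

## Atlas and region order

The node set is the 90 cerebral regions of the AAL parcellation (45
structures × 2 hemispheres; cerebellum and vermis excluded).  The packaged
CSV fixes the matrix row order: structures in canonical atlas order, left
hemisphere immediately before right, so structure *s* occupies rows 2*s*
(left) and 2*s*+1 (right).  This interleaving is a package convention —
published connectivity maps group regions in other orders — chosen so that
homologous pairs are adjacent and trivially indexable.  Output labels use
the `ABBR.L` / `ABBR.R` style (e.g. `PHG.L`, `SMA.R`).

The swallowing-ROI set contains 42 regions: 19 bilateral structures plus
four unilateral entries (postcentral gyrus left, precentral gyrus right,
fusiform gyrus left, putamen left), exactly as identified by prior
swallowing-activation studies.

## Synthetic cohort generator

The generator emulates the statistical structure of task-fMRI regional
series that the downstream analysis relies on, not the physiology:

- **Spatial structure.** A planted region-level correlation matrix is
  assembled as identity → local blocks → homologous pairs → diagonal
  loading.  Local blocks group `local_block_size = 5` consecutive
  same-hemisphere structures at correlation `local_rho = 0.35`
  (short-range intra-hemispheric connectivity); each left/right homologue
  pair is set to `homolog_rho = 0.6` (strong bilaterally symmetric
  inter-hemispheric connectivity).  If the assembled matrix is not positive
  definite it is ridge-loaded and renormalized to unit diagonal until it
  is; with the defaults no loading is needed.
- **Temporal structure.** Each subject is an independent stationary
  Gaussian AR(1) process with `ar1_phi = 0.3` and marginal covariance equal
  to the planted matrix.  AR(1) is the simplest stationary model with
  fMRI-like temporal smoothness; no hemodynamic response, drift, or scanner
  artifact is modeled.
- **Dimensions** default to 22 subjects × 350 volumes × 90 regions at
  TR 2.2 s, the acquisition shape of the emulated study.
- **Motion** traces are Gaussian random walks (step SD 0.04 mm / 0.03°,
  chosen so ordinary subjects stay well below the exclusion limit);
  `n_high_motion` subjects receive one 6 mm jump so the QC rule is
  exercised deterministically.
- The correlation strengths above are package choices — the emulated study
  reports no effect sizes for connectivity beyond qualitative "strong"
  homologous connections — fixed once and used everywhere, including the
  acceptance run.

Because the planted covariance is known, the analytic partial-correlation
matrix (from its inverse) is an exact recovery target: the sample estimator
converges to it at the usual 1/√T rate, which the tests check by quadrupling
T and watching the error halve.

What passing these tests shows is that the *pipeline* is correct on data
with the assumed structure; it says nothing about hemodynamic confounds,
motion–signal coupling, or non-Gaussian noise in real recordings.

## Preprocessing scope

Inputs are already-parcellated regional series; image-space preprocessing
(realignment, coregistration, normalization, smoothing) belongs to standard
neuroimaging toolchains and is out of scope.  Three computations are kept:

- **Volume discarding:** drop the first 10 volumes (magnetic equilibration).
- **Motion summary:** mean frame-to-frame Euclidean displacement, computed
  separately for the translation channels (mm) and rotation channels
  (degrees).
- **Exclusion rule:** a subject is excluded when *any* frame-to-frame
  displacement magnitude (translation or rotation) strictly exceeds
  4.0 mm.  Whether such rules apply frame-wise or cumulatively is often
  unstated in the literature; frame-wise maximum is the package decision
  (the limit is configurable).

## Partial correlation

Series are mean-centered and variance-scaled per region, so the estimator
is correlation-based and invariant to per-region affine rescaling.  The
full matrix comes from the precision matrix in one inversion,
`−P_ij / √(P_ii P_jj)` — mathematically identical to correlating the
residuals of i and j after regressing out the other 88 regions (the test
suite verifies this equivalence to 1e−8), but O(N³) instead of O(N⁵).
With T = 340 > N = 90 the plain estimator is well defined; an optional
ridge term (scaled by the mean diagonal of the correlation matrix) is
available for shorter series or collinear regions, and the error message
for a singular matrix points to it.  The diagonal is stored as 0: networks
have no self-loops.

## Thresholding conventions

- **Degree-targeted:** keep exactly E = K·n/2 edges with the largest
  |connectivity|, default K = 48 (2160 edges on 90 nodes) with presets
  36/48/60.  Ranking by absolute magnitude keeps strong negative partial
  correlations — the sign policy is not standardized in the field, and
  magnitude ranking is the common convention.  Ties are broken by
  lexicographic (i, j) order so the edge count is exact and deterministic,
  and edge sets are nested across K.
- **Sweep:** binarize at |C_ij| > r for r = 0 … 1 in steps of 0.05 (21
  thresholds), strict inequality.  A flag switches to signed comparison.
- **Weights:** retained magnitudes divided by the largest retained
  magnitude, the minimal map onto (0, 1].

## Graph measures

- Binary clustering is the triangle fraction 2tᵢ/(kᵢ(kᵢ−1)); weighted
  clustering is the geometric-mean (cube-root product) triangle intensity
  with weights renormalized by the network maximum, which bounds C ≤ 1.
  The denominator uses the neighbor count, so the weighted and binary
  variants coincide on 0/1 weights.  Nodes with fewer than two neighbors
  get C = 0 (kept in the mean, matching common toolbox behavior; an
  exclusion variant would change Cp only through the averaging set).
- Weighted distances use edge length 1/w; with w ≤ 1 every edge length is
  ≥ 1, so weighted efficiencies are ≤ 1 like binary ones.  Note this
  convention cannot produce network path lengths below 1; sub-unit
  published Lp values imply some other internal normalization and are not
  reproducible from these definitions.
- Characteristic path length is reported in two recorded variants:
  arithmetic (infinities propagate, the textbook definition) and harmonic
  (reciprocal of the mean reciprocal distance, finite on disconnected
  networks).  The harmonic form is the package primary — it is the form
  that makes disconnected null-ensemble members quantifiable — and is what
  enters λ and σ.
- Local efficiency of node i is the global efficiency of the subgraph
  induced on i's neighbors, distances computed within that subgraph only;
  k < 2 nodes score 0.
- The hierarchy exponent β is the negative slope of log C against log k
  over nodes with ≥ 2 neighbors and C > 0, by ordinary least squares; the
  fit reports β, intercept and R², and raises on degenerate inputs (fewer
  than three eligible nodes, or a single degree value, e.g. complete
  graphs).  A polynomial C(k) curve of configurable order is available as a
  purely descriptive diagnostic; β is always the power-law slope.
- Shortest paths are computed with `scipy.sparse.csgraph` (BFS for binary,
  Dijkstra for weighted); everything else is implemented in the package and
  verified against exhaustive enumeration oracles (all simple paths, all
  triangles) on hundreds of small random graphs in both modes.

## Null models and small-worldness

Degree-matched random networks are generated by Markov-chain double-edge
swaps on the binary network: pick edges (a,b), (c,d), replace with (a,d),
(c,b) when no self-loop or duplicate results.  Each ensemble member
performs 10 accepted swaps per edge (a standard mixing heuristic; the
tests check that 50 swaps per edge changes the null means by less than
Monte-Carlo noise).  If a graph admits no legal swap (e.g. a triangle plus
isolated nodes) the original is returned with a warning.  Connectivity is
not enforced during rewiring; the harmonic path length handles
disconnected members.  Ensembles default to 1000 members in the library
API, matching standard practice; the end-to-end pipeline and acceptance
script use 100 per subject and the test suite 50 or fewer, with seeds, as
documented problem sizes.

γ = Cp/C_rand, λ = Lp/L_rand, σ = γ/λ; a network is classified small-world
when γ > 1 and σ > 1.  Nulls are computed on binary networks; weighted
small-worldness is future work.

## ROI vs whole-brain comparison

The swallowing-ROI submatrix is extracted from each subject's full
connectivity matrix *before* thresholding, then thresholded on its own
entries — this keeps both scopes on the same r scale (the alternative,
inducing the subgraph after whole-brain thresholding, is available behind a
flag).  Per threshold and metric, the per-subject scalar samples of the two
scopes are compared with the two-sided Mann–Whitney rank-sum test: exact
enumeration when n₁·n₂ ≤ 400 and the pooled sample is tie-free, otherwise
the normal approximation with midranks, tie-corrected variance and
continuity correction.  Significance is flagged at α = 0.05 without
multiplicity correction, matching how per-threshold significance intervals
are conventionally reported in this literature; a 21-threshold × 6-metric
run yields 126 tests, so ~6 false positives are expected under the null.

## Pipeline and reproducibility

Every stage writes plain text (TSV/CSV/JSON); matrices round-trip at 15
significant digits.  All randomness flows through named seeds recorded in
the run manifest: the cohort seed drives data generation, and per-subject
null-ensemble seeds are spawned deterministically from the null seed.  The
same configuration reproduces every output bit-for-bit.  Stages are
re-enterable from their serialized outputs through the CLI subcommands
(`connectivity`, `threshold`, `metrics`, `nulls`, `compare`).

## Known limitations

- The generator is Gaussian and stationary; real BOLD data are neither.
- At the conservative K = 48 density (54% of possible edges) networks are
  near diameter-2, so λ ≈ 1 and σ barely exceeds 1 on the default synthetic
  cohort; small-world contrast grows at sparser thresholds.
- Weighted networks reuse the binary null ensemble; no weighted rewiring.
- β on dense thresholded networks is small and noisy — the degree range
  after thresholding to a fixed mean degree is narrow, which limits the
  leverage of the log–log fit.
- No statistical edge-significance thresholding, no frequency filtering,
  global-signal regression or task-regressor modeling.
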
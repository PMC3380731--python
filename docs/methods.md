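# Methods

This note records the models, numerical choices and limitations behind
surfcart, in the order the pipeline runs them.

## Surfaces and sectioning

Surfaces are triangle meshes in Å. Protein surfaces come from MSMS
(`.vert`/`.face`); synthetic surfaces are generated analytically. The
icosphere uses the canonical icosahedron with vertices at the cyclic
permutations of (±1, ±φ, 0) (φ the golden ratio), subdivided 1-to-4
with shared edge midpoints deduplicated and every vertex projected to
the unit sphere: `10·4^L + 2` vertices and `20·4^L` faces at level L.
The reference hemisphere is the level-2 icosphere cut at the z ≥ 0
half-space through the center (89 vertices, 152 faces with this
orientation). Orientation matters because the cut plane slices the
vertex lattice differently for different icosahedron embeddings; the
score tolerances used in the tests absorb this.

Half-space cuts keep a face only when all three vertices satisfy the
half-space test; straddling faces are dropped rather than clipped (no
new vertices are invented), and vertices exactly on the plane belong
to both half-spaces, so opposing sections may share an equator ring.
Sectioning cuts at the three axis planes through the vertex centroid
by default (translation-invariant); cutting at the raw coordinate
origin is available for reproducing analyses done in the PDB frame.

The cylinder sector (`make_cylinder_patch`) is the developable-surface
oracle: it unrolls exactly to the plane (u = Rθ, v = z), so a perfect
flattening method must recover that development. Two caveats
discovered in testing and worth recording:

- a *uniform* grid has constant triangle areas, which makes the area
  score (a Pearson correlation) degenerate — the `graded=True` option
  spaces the grid as t^1.5 so areas vary smoothly while the patch
  stays developable;
- discrete edges are chords of the smooth surface, so "exact" isometry
  claims hold only to chord-vs-arc accuracy (~0.1% at 20×20 over π).

## Geodesic distances

Two regimes, both Dijkstra over a weighted graph
(`scipy.sparse.csgraph`):

- **edge graph** (`edge_subdivisions=0`): vertices connected by mesh
  edges weighted by 3-D length. This is the graph the neighbor-score
  evaluation uses. Its metric is anisotropic (paths must zigzag along
  lattice directions, overestimating by up to ~8% on grid-like
  meshes), but it is parameter-free and exactly reproducible.
- **Steiner-refined** (`edge_subdivisions=m > 0`): m points are
  inserted along every edge and each triangle becomes a clique of
  straight segments (a segment between two edge points of one triangle
  lies inside it, so its 3-D length is an exact surface distance).
  Paths may then cross triangle interiors, and the graph metric
  converges to the true polyhedral geodesic metric as m grows. The
  embedding routines default to m = 3, where the mean relative error
  on the cylinder oracle is ~1% at a few-fold cost over the raw graph.

The split is deliberate: Isomap's quality depends on how well the
distance matrix approximates the surface metric, so the embeddings use
the refined distances; the evaluation compares 3-D and 2-D adjacency
structure and uses the mesh's own graph, which is also what makes it
independent of the embedding parameters. k-NN graphs over Euclidean
distance were rejected for both: on non-convex surfaces they create
shortcut edges through the solvent and badly distort the metric
(verified on the graded cylinder, where they halve the area score).

## Embeddings

All embeddings preserve vertex order and count and record their
method, parameters and seed.

- **PCA**: SVD of centered vertices, top-2 axes, deterministic sign
  convention (largest-magnitude coordinate per axis made positive).
  Rank < 2 input is an error.
- **MDS**: classical Torgerson scaling — double-center the squared
  Euclidean distance matrix, embed on the top-2 eigenvectors scaled by
  √eigenvalue. Mathematically equivalent to PCA up to an orthogonal
  transform; the equivalence is asserted in the tests (Procrustes
  residual < 1e−8). Note the 2-D *subspace* is only well-defined when
  the second and third covariance eigenvalues are distinct; on an
  exact sphere the equivalence holds per run but the subspace is
  arbitrary.
- **Sammon**: diagonal-Newton iteration (Sammon's classic update,
  step factor 0.3) with step halving so accepted stress never
  increases; initialized at the PCA solution (deterministic, and
  standard practice). Stops on relative stress change < 1e−7 (default)
  or 500 iterations. Duplicate vertices are an error (infinite
  weights).
- **Isomap**: classical scaling of the refined geodesic matrix.
- **Landmark Isomap**: seeded uniform-random landmark subset
  (default 50), classical scaling of the landmark-landmark geodesics,
  remaining vertices placed by the standard distance-based
  triangulation formula against the landmark eigenbasis; reproduces
  the landmark positions exactly and equals full Isomap when all
  vertices are landmarks.
- **SNE**: original (asymmetric) formulation. 3-D conditional
  probabilities use per-point Gaussian bandwidths solved by bisection
  to match perplexity 15 (default); 2-D probabilities use unit
  Gaussians. Cost is the sum of per-point KL divergences. Descent
  starts from seeded 1e−4 Gaussian noise and uses momentum
  (0.5 → 0.8) with backtracking step halving, because plain gradient
  steps at a useful learning rate diverge on small meshes; the
  backtracking guarantees the final cost is no worse than the
  initialization, and `learning_rate` (default 10) caps the step. The
  final KL cost is reported in `params["kl_cost"]`.
- **Sinusoidal projection**: spherical coordinates about the vertex
  centroid; x = R̄ (λ − λ̄) cos φ, y = R̄ φ, with R̄ the mean radius and
  λ̄ the circular-mean longitude (longitude differences wrapped to
  (−π, π]). A vertex at the centroid is an error.

## Evaluation

- **Area score**: Pearson r between per-face areas of the 3-D mesh
  and the same faces re-measured under the map. Faces come from the
  mesh's own triangulation (the natural correspondence); a fresh
  Delaunay triangulation of the map points would be an alternative
  but breaks the face-to-face pairing. Zero variance in either area
  vector is an error, not a NaN.
- **Neighbor score**: each vertex marks its k = 3 nearest others —
  geodesically (edge graph) in 3-D, Euclidean in 2-D — and the two
  directed connectivity matrices, linearized as bit vectors with the
  diagonal dropped, are compared with the Tanimoto coefficient
  T = X·Y / (‖X‖² + ‖Y‖² − X·Y), which equals the Jaccard similarity
  of the marked-pair sets (cross-checked in the tests against an
  independent set computation). The matrices are deliberately *not*
  symmetrized: k-nearest-neighborhood is a directed relation, and the
  directed form is what the score's reference values reflect; a
  union-symmetrized variant remains available via `symmetrize=True`.
  Both-empty bit vectors define T = 1.
- **Ties**: distances are quantized to 12 relative digits before
  ranking and ties break by ascending vertex index. Regular meshes
  have many exactly equidistant neighbors; without quantization the
  tie outcomes flip with the floating-point noise of whatever
  coordinate frame the embedding happens to be in, and scores of
  mathematically identical embeddings (PCA vs MDS) differ in the
  second decimal.

## Feature channels

- **Hydrophobicity**: the Kyte–Doolittle hydropathy index of the
  residue owning each vertex's nearest atom (the MSMS per-vertex atom
  index when present, else a KD-tree search with a 5 Å cutoff; a
  vertex with no atom in range is an error). The 20-residue scale is
  embedded as constants (−4.5 Arg … +4.5 Ile); display clip range
  [−4.5, 4.5]. Nearest-atom transfer (not distance-weighted
  smoothing) keeps residue boundaries sharp on the map.
- **Electrostatic potential**: screened Coulomb sum
  φ(v) = Σ qᵢ / (ε(dᵢ) dᵢ) with distance-dependent dielectric
  ε(d) = 4d, i.e. φ = q/(4d²), d floored at 1.0 Å (surface vertices
  normally sit ≥ probe radius from atoms; the floor guards malformed
  input). Default charges are formal: Asp/Glu −1 and Lys/Arg +1 on a
  representative side-chain atom, His +0.1, chain termini ±1; a
  user charge set can be passed instead. This is a deliberate
  lightweight model — for publication-grade electrostatics compute
  the potential externally (Poisson–Boltzmann) and import the OpenDX
  grid, which is sampled trilinearly at the vertices (outside
  vertices clamp to the boundary with one warning). Display range is
  symmetric at the 95th percentile of |φ|.
- **Mean curvature**: cotangent Laplace–Beltrami,
  H(v) = ±‖Δv‖ / (2 A_v) with Meyer mixed-Voronoi vertex areas
  (Voronoi split for non-obtuse triangles, half/quarter split
  otherwise); sign positive where the Laplacian opposes the outward
  normal (convex), negative in concavities. Barycentric areas were
  tried first and overshoot by ~14% at the 12 valence-5 vertices of
  an icosphere; the mixed-Voronoi areas are exact to ≪1% there.
  Boundary vertices (where the operator is unreliable) take the mean
  of their interior one-ring neighbors. Inconsistent face orientation
  is an error.
- **Annotation mask**: 1 for vertices whose owning atom belongs to a
  listed (chain, residue) pair, 0 otherwise; residues missing from
  the structure warn and are skipped.

All channels are invariant to rigid motion of the (structure, mesh)
pair.

## Imaging

Rasterization fits the map bounding box into the raster with a 5%
margin and preserved aspect (longest side = `resolution` pixels), then
splats each vertex as a disc of `splat_radius` pixels; overlapping
discs resolve to the nearest vertex. Channel values are normalized to
0–255 over each field's clip range, so assigned colors do not depend
on raster size. Default channel order for enriched maps is potential,
hydrophobicity, curvature (R, G, B); single-channel export is
available through the CLI by listing one channel.

Registration does an exhaustive rotation scan (default 2° steps,
optional reflection). Each rotation's best integer translation comes
from FFT template matching; the pose is then *scored* by NCC over the
pixels where both coverage masks overlap (template matching alone
dilutes the score with empty padding, capping it near 0.78 for a 40°
rotation of identical images). Sub-degree and sub-pixel refinement is
out of scope; with step 2° the residual misalignment costs a few NCC
points on sharp images. Superposition warps B into A's frame
(nearest-neighbor), blends 50/50 over the overlap and reports the
overlap fraction over the union of the coverage masks.

Texture mapping samples the containing pixel of each map point and is
exactly invertible against `rasterize` when the raster is fine enough
that every vertex owns its own pixel (≥ 4√n pixels per side in
practice on the hemisphere); the colored mesh is exported as ASCII PLY
with per-vertex RGB, triangle interpolation being delegated to the
viewer.

## Synthetic data and what the tests do (and do not) show

The synthetic surfaces cover the three regimes a flattening method
meets: positive curvature (sphere/hemisphere — not developable,
bounded distortion), zero curvature (cylinder sector — exactly
developable, distortion should vanish), and closed topology (full
sphere — must collapse, used as the negative control). They are
clean, near-uniform meshes; real MSMS surfaces add sharp pockets,
tunnels, non-uniform vertex density and occasional slivers. Passing
the synthetic suite therefore validates the *machinery* (metrics,
embeddings, geodesics, imaging round trips), not protein-scale mapping
quality; protein benchmarks additionally depend on MSMS
density/probe settings, which is why protein runs are a supported
demonstration rather than a test dependency. Problem sizes used by
the test suite — 89–400 vertex meshes, 64–128 px rasters, 2°
rotation grids — were chosen so the whole suite runs in well under a
minute while every score lands in a stable regime.

## Known limitations

- Geodesics are graph approximations; exact polyhedral geodesics
  (MMP-style window propagation) are not implemented.
- The Coulomb potential ignores solvent screening beyond ε(d) = 4d
  and ionic strength; import a solved grid for quantitative work.
- Registration is rigid (rotation + integer translation + optional
  reflection) and NCC-only; mutual information, SSD and deformable
  alignment are out of scope.
- Landmark Isomap's landmark choice is uniform random; no max-min or
  curvature-aware placement.
- Sections are the six axis-plane half-surfaces; overlapping-chart
  atlases and curvature-guided seams are not provided.
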
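# surfcart

Molecular cartography for protein surfaces: flatten a triangulated 3-D
molecular surface into a 2-D map, quantify how faithful the map is,
paint it with biochemical and geometric feature channels, compare maps
of different proteins by rigid image registration, and texture images
back onto the 3-D surface.

## Who this is for

Structural bioinformaticians who want to compare proteins by their
*surfaces* rather than by sequence or backbone. Proteins interact
through their solvent-excluded surfaces, and convergent evolution can
produce similar surface patches (binding sites, catalytic sites) on
proteins with unrelated folds. Working with 2-D surface maps makes
such patches easy to visualize, annotate and compare with cheap image
operations.

## The method

A surface is a triangulated mesh `S = (V, F)` — typically MSMS output
(`.vert`/`.face`, probe radius 1.4 Å) or one of the built-in analytic
surfaces (icosphere, hemisphere, cylinder sector). An enclosed surface
cannot be flattened without collapse, so it is first **bisected by the
three coordinate planes into six half-sections**.

Each open section is embedded in the plane with one of:

- **PCA** — projection on the top two principal axes;
- **MDS** — classical (Torgerson) scaling of Euclidean distances
  (equivalent to PCA up to an orthogonal transform);
- **Sammon mapping** — iterative minimization of Sammon's stress
  `E = (Σ d_ij)⁻¹ Σ (d_ij − δ_ij)² / d_ij` from a PCA start;
- **Isomap** / **landmark Isomap** — classical scaling of surface
  geodesic distances (shortest paths over the mesh, refined with
  Steiner points so paths may cross triangle interiors);
- **SNE** — stochastic neighbor embedding of the vertex cloud,
  minimizing `Σᵢ KL(Pᵢ‖Qᵢ)` with per-point Gaussian bandwidths
  matched to a target perplexity;
- **sinusoidal projection** — the cartographic equal-area baseline
  `x = R̄ (λ − λ̄) cos φ`, `y = R̄ φ`.

Two scores measure mapping fidelity:

- **area score** ∈ [−1, 1]: Pearson correlation between each
  triangle's area in 3-D and its area re-measured in the map;
- **neighbor score** ∈ [0, 1]: Tanimoto coefficient
  `T(X,Y) = X·Y / (‖X‖² + ‖Y‖² − X·Y)` between k-nearest-neighbor
  connectivity bit vectors, with 3-D neighborhoods taken geodesically
  along the surface and 2-D neighborhoods by map distance (k = 3).

Maps are enriched per vertex with **Kyte–Doolittle hydrophobicity**,
**electrostatic potential** (screened Coulomb with distance-dependent
dielectric ε(d) = 4d, or an imported OpenDX grid from an external
Poisson–Boltzmann solver), **mean curvature** (cotangent
Laplace–Beltrami), and 0/1 **annotation masks** (e.g. active-site
residue lists). Enriched maps are rasterized into multi-channel PNGs,
registered rigidly by exhaustive rotation search maximizing normalized
cross-correlation over the overlap, and arbitrary images can be
textured back onto the 3-D mesh through the map (exported as colored
PLY).

## Worked example

Score a panel of methods on the built-in reference hemisphere (a
level-2 icosphere, 162 vertices / 320 faces, cut at a center plane):

```sh
$ surfcart benchmark --methods pca,sammon,isomap,sinusoidal --out bench.json
pca              seed=None area=0.232 neighbor=0.402 (0.00s)
sammon           seed=None area=0.691 neighbor=0.534 (0.02s)
isomap           seed=None area=0.860 neighbor=0.571 (0.04s)
sinusoidal       seed=None area=0.056 neighbor=0.463 (0.00s)
```

Reading the numbers: linear projection (PCA) squashes the curved
hemisphere, so triangle areas near the rim shrink and its area score
is low (0.23); the cartographic projection preserves areas even worse
here (0.06) because the section is not a full sphere. The nonlinear
methods that work with surface distances — Sammon (0.69) and
especially Isomap (0.86) — preserve both areas and neighborhoods far
better, which is why they are the recommended methods for protein
maps. The same ordering holds for real protein sections.

The same panel is available in Python:

```python
import surfcart as sc

hemi = sc.reference_hemisphere()          # icosphere(2) cut at z >= 0
emb = sc.embed_isomap(hemi)
print(sc.area_score(hemi, emb))           # 0.860
print(sc.neighbor_score(hemi, emb, k=3))  # 0.571
```

A protein run (given MSMS output and the PDB file) chains the stages:

```sh
surfcart pipeline --mesh protein.vert --face protein.face \
    --pdb protein.pdb --method sammon --channels pot,hyd,curv \
    --out results/
```

which writes the six half-sections, the 2-D map (`map.tsv`), the
score report (`scores.json`), and the enriched raster
(`enriched.png`). `surfcart register` aligns two such rasters and
reports the rotation, translation and overlap NCC; `surfcart texture`
paints an arbitrary PNG back onto the 3-D surface as a colored PLY.

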
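# Methods

## Model and assumptions

The normalization assumes that the functional topography of the gridded
region is proportional to its shape: a hotspot at, say, two thirds of the
dorsoventral extent of the sensorimotor band sits at two thirds in every
subject and hemisphere, even when the band's absolute shape and size differ.
Under this assumption, mapping every band onto the same N × M tile lattice
aligns homologous locations, and the quality of the alignment can be read
off the similarity of activation patterns across hemispheres and subjects.

The construction requires a *flattened* surface (distances in arbitrary
units, ~1 a.u. per mm) with the central sulcus running vertically (dorsal
up). `validate_flatmap` checks this by the principal axis of the
central-sulcus boundary vertices and reports, rather than raises, so callers
can decide how to escalate.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| N (rows) | 28 | dorsoventral segments per curve |
| M (columns) | 84 | anteroposterior columns (must be even; column M/2 is the central sulcus) |
| polynomial order | 10 | flexibility of the border fits; enough to follow sulcal curvature while still extrapolating stably over [y_min, y_max] |
| densify step | 0.1 a.u. | node spacing for arc-length estimation before equal-arc resampling |
| smoothing FWHM | caller's choice (6 a.u. typical) | iterated neighborhood averaging on the mesh graph |

N and M are configurable everywhere; 28 × 84 (2352 tiles per hemisphere) is
the published default for the sensorimotor band.

## Numerical choices

* **Fit conditioning.** Order-10 fits on raw coordinates are
  ill-conditioned, so y is affinely mapped to [−1, 1] before building the
  Vandermonde system. Coefficient interpolation across the three fits is
  only meaningful in a shared basis, so `build_cgrid` fits all three borders
  over the common [y_min, y_max] window. Rank-deficient or underdetermined
  systems raise named errors.
* **Column order and orientation.** The three fits are ordered along the
  flat map's x axis, and the builder records which side is precentral.
  `orient_grid` flips columns so the precentral gyrus is always the left
  half (and flips rows so dorsal is row 0); for maps lacking that record it
  falls back to the hemisphere tag plus a flattening-convention flag
  (`caret`: the right hemisphere is column-flipped). Grid rows in the
  *definition* run ventral → dorsal (the truncation keeps the ventral cut
  first); display-convention maps are row-flipped copies.
* **Extrapolation guard.** The unit-step lattice extrapolates each
  polynomial beyond its border's own y range; if any curve leaves 3× the
  mesh's x extent the build aborts rather than produce wild tiles.
* **Truncation before densification.** Curves are truncated on the
  unit-step lattice (nearest node to any cap-border vertex, both cut nodes
  inclusive), then densified to 0.1 a.u. for arc length. Coincident cut
  nodes raise a degenerate-curve error.
* **Tile assignment.** Tiles are quadrilaterals from adjacent curve nodes;
  point-in-polygon queries run through an STR-tree with boundary counting as
  inside. A vertex on a shared edge goes to the first tile in row-major
  order — deterministic, and exercised in practice only by vertices exactly
  on the grid's outer boundary. Bow-tie quadrilaterals (possible only for
  crossing curves) are repaired by zero-buffering before the query.
* **Tile means and masking.** A tile's value is the unweighted mean over
  the finite values of all enclosed vertices; the tile is valid only if at
  least one contributor carries a gyrus label. NaN inputs are dropped;
  count-weighted group averaging is available but off by default.
* **Correlation clamp.** r is clamped to ±(1 − 1e−7) before arctanh;
  synthetic data routinely produce |r| = 1 and the clamp keeps z finite
  while preserving order. Correlations need ≥ 3 jointly valid tiles and
  nonzero variance on both sides, else named errors.
* **Leave-one-out mean.** A tile enters the mean of the remaining subjects
  only if valid in *every* contributor; the correlation then additionally
  intersects with the held-out subject's own mask.
* **Smoothing calibration.** One smoothing step replaces each value by the
  mean over the closed 1-ring. The per-step variance gain is measured from
  the mesh itself (mean squared neighbor displacement), and the step count
  is the rounded ratio of the target Gaussian variance (FWHM²/(8 ln 2)) to
  that gain. The kernel is approximately Gaussian by the central limit
  theorem; the impulse-response FWHM is verified within 15% in tests.
  Missing values are handled by diffusing a normalization field alongside.

## The synthetic generator

`synthetic.make_subject` triangulates a parametric band (s anteroposterior
∈ [0,1], t dorsoventral ∈ [0,1]; physical size 50 × 100 a.u., target edge
0.7 a.u.), labels it precentral/postcentral about s = 0.5 with the eight
neighbor regions in their anatomical margin positions, and warps it with a
seeded random displacement field. The warp is harmonic along the band's long
axis and linear across its width, RMS amplitude 2.5 a.u. by default: gyral
shape variability is dominated by dorsoventral bending and shifting of the
whole band, and across a band only a few centimetres wide the displacement
gradient is approximately constant. Warps that fold the band are rejected.
The right hemisphere is a mirrored, independently warped copy sharing the
subject's parametric hotspot layout.

Activation fields are sums of parametric-space Gaussians (width 0.1) at the
canonical somatotopic centers — feet (0.5, 0.90), hand (0.5, 0.67), tongue
(0.5, 0.15) — plus white noise; hand tasks are predominantly contralateral
(ipsilateral factor 0.25). Cohorts jitter the hotspot centers per subject
(sd 0.02 parametric by default) and draw an independent warp per hemisphere.
The generator exposes every vertex's true (s, t) for oracle use
(`parametric_lookup`); the normalization pipeline never reads it.

What the generator does *not* emulate: realistic fMRI noise spectra and
hemodynamics, multi-focal or subject-specific activation shapes, label
noise in the parcellation, metric distortion from the flattening itself,
and within-band nonlinear warp components (which linear coefficient
interpolation between the border fits cannot represent anyway). Passing
tests therefore demonstrate correctness of the construction and its behavior
under smooth band-scale shape variation, not performance on real data.

## Problem sizes

The test suite and the reproduction script use full-size grids (28 × 84) on
meshes of ~16k vertices; hotspot recovery is summarized over 20 warped
subjects × 3 body parts and the cohort analysis uses 10 subjects × 2
hemispheres × 4 tasks with 6 a.u. smoothing — about 80 grid builds in total,
a couple of minutes end to end. All of it is seeded and deterministic.

## Known limitations

* Borders with disconnected label islands are reduced to their largest
  connected component (with a warning); the rule is a repair heuristic for
  messy parcellations, not part of the construction proper.
* The one-sided border definition places the central sulcus border on
  precentral vertices only, so column M/2 sits half an edge length anterior
  of the true label boundary.
* Empty-tile fractions on synthetic subjects (5–15%, concentrated at the
  truncated edges) are higher than on real data, where the surface mesh is
  denser relative to the tile size; empty tiles are masked and excluded from
  all correlations either way.
* Smoothing operates on the flat map in a.u.; equivalence to mm-FWHM
  smoothing on the folded surface is approximate by the same token as the
  flat map itself.
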
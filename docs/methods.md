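# Methods

## Problem setting

A vessel cross section is observed twice: unloaded, as a stained histological
section segmented into tissue regions (A1 intact elastin without thrombus,
A2 intact elastin with thrombus attachment, A3 fragmented elastin, A4
intramural thrombus with red blood cells, A5 thrombus without red blood
cells), and loaded, as an in vivo image in which only the lumen and the outer
wall are identifiable. The analysis maps the interior region boundaries from
the unloaded to the loaded configuration so that in vivo strain values can be
grouped by tissue type.

## Strain estimation (DDE)

Deformation between two volumetric frames is estimated directly by fitting
the affine warp

    W(x; p) = [[1+p1, p4,   p7,   p10],
               [p2,   1+p5, p8,   p11],
               [p3,   p6,   1+p9, p12]] [x, 1]ᵀ

to voxel intensities: minimize Σ (T(W(x;p)) − R(x))² over a window, where R
is the reference frame and T the deformed frame, sampled with trilinear
interpolation. The deformation gradient is F = I + [p1..p9] (column-wise), so
no displacement field is differentiated. The first principal Green-Lagrange
strain is the largest eigenvalue of E = (FᵀF − I)/2; it is frame-indifferent
(pure rotations give E1 = 0) and bounded below by −0.5.

Numerics: Gauss–Newton with analytic Jacobian (image gradient sampled at the
warped coordinates), step halving on residual increase, stop at relative
residual change below 1e-8 or 200 iterations. Windows default to 16³ voxels
tiled with 50 % overlap; windows with intensity variance below 1e-8 are
rejected as texture-free, and failed windows are masked in the output field.
The warp origin is the window centre, so p10–p12 are window-local
translations in voxels.

## Contour resampling

Segmentation contours are densified with the biharmonic spline in the
arc-length parameter. In one dimension the Green's function of the biharmonic
operator, |t|³, generates exactly the cubic spline, so the interpolant is a
periodic cubic spline through all input points; resampling is evaluation at
equally spaced parameters. Self-intersecting resampled contours are rejected
as an input pathology.

## Non-rigid CPD registration

The unloaded contour (source, default 200–1,000 points) is registered onto
the loaded contour resampled to high density (default 20,000 points). The
motion model is T = Y + G W with Gaussian kernel
G_ij = exp(−|y_i−y_j|²/2β²); the EM iterations of standard non-rigid CPD
update soft correspondences and the kernel weights, with the outlier weight
fixed at 0 (closed contours contain no gross outliers). Source and target
centroids are superimposed before iteration; data are normalized by the
target's RMS radius, and β = interaction_sigma / scale.

Two numerical choices matter. First, the Gaussian kernel matrix is
near-singular; a 1e-6 diagonal nugget keeps the M-step solvable when the
annealed variance σ² (and with it the Tikhonov term smoothing_weight·σ²)
becomes tiny. Second, on a densely resampled curve target σ² does not anneal
to zero: it reaches a genuine fixed point at the tangential quantization
scale (≈ source spacing²/12), because target points between two source
points remain at that distance from their soft assignment. Iteration
therefore stops at σ² stationarity (relative change < 1e-5) or point motion
below 1e-12. The residual RMSE floor against the dense target is the
curvature sagitta of the source spacing — about 0.09 µm for a 200-point
source on a 1 mm lumen, well under the 0.2 µm lumen gate.

Registration acceptance mirrors the protocol: nearest-point RMSE < 0.2 µm
(lumen) / 0.75 µm (outer wall), unchanged angular ordering of the points
about the centroid, and a spacing-uniformity score (1 − CV of arc-length
gaps; larger is more uniform) above 0.5. Contours with alternating
concave/convex lobes are registered in two or three steps through auxiliary
contours generated as linear blends between source and target at fractions
1/3 and 2/3 — a reproducible substitute for manually drawn auxiliaries.

A note on correspondence: point-to-curve registration cannot identify the
tangential component of a ground-truth motion, and even spacing of the
registered points is an explicit goal, so fidelity is assessed as distance to
the warped target curve, not to per-index warped points.

## Meshing

The wall annulus is triangulated region by region with linear triangles. The
mesher requires sector-structured region sets (each region spans an angular
interval between the lumen and outer contours, recorded in
`sector_intervals`) — the geometry of segmented aneurysm cross sections and
of all phantoms. Radial node columns are built at region interfaces (shared
between neighbours, using the finer spacing, so the mesh conforms exactly)
and at interior angles; neighbouring columns are stitched into triangle
strips. Boundary radii are interpolated along the contour polylines
(chordally), so boundary nodes lie exactly on the input polygons and a
zero-displacement solve reproduces the input region set to machine precision.
Per-region target edge lengths are divided by (2+√2)/3 ≈ 1.14 (the mean edge
of a right-triangle strip) so realized mean edge lengths land on target; the
histology protocol default is 4.0 µm in (fragmented) elastin and 8.6 µm
elsewhere.

## Displacement – zero traction finite elements

The registered boundary displacements are prescribed on every lumen and
outer node; no tractions act. The body is compressible Neo-Hookean in plane
stress with strain energy W = μ/2(tr(FᵀF)−2) − μ ln J + λ'/2 (ln J)², where
the plane-stress condition is imposed analytically by the condensed Lamé
parameter λ' = 2λμ/(λ+2μ); μ = 2·C10 and the Poisson-like ratio defaults to
0.45 (near-incompressible without volumetric locking of linear triangles).
The default stiffness is uniform (C10 = 1 GPa nominally); in this
displacement-controlled problem any uniform scaling of the stiffness leaves
the solution unchanged, which is verified to machine precision.

The boundary motion is applied in 10 equal increments; each increment is
solved by Newton's method with sparse factorization, backtracking on residual
increase, and automatic increment halving on divergence or element inversion
(down to 1/64 of the base increment). Convergence requires the free-node
residual below 1e-8 times the reaction-force norm, or below the assembly
roundoff floor (estimated from the pre-cancellation magnitude of the stress
terms) for stress-free motions such as rigid translations. Only the deformed
nodal positions are kept; the stresses and strains of this solve are
artefacts of the arbitrary constitutive choice and are discarded. Region
contours are traced along the once-used edges of each region's element set
and returned as closed counterclockwise contours.

## Strain grouping

A strain voxel joins region r iff its centre lies inside r's mapped contour
(even-odd rule); voxels claimed by several contours go to the smallest region
label, `outer_excluded` and out-of-contour voxels are dropped. No sub-voxel
area weighting is applied: at imaging resolution (tens of µm) edge effects
are small against the region sizes.

## Strain distribution indices and tests

For a sample of local E1 values: mean; maximum; coefficient of variation
(sample SD / mean — the heterogeneity index; undefined and reported as NaN
for zero-mean samples); adjusted Fisher–Pearson sample skewness (0 by
convention for constant samples; positive = right-skewed). Group comparisons
screen both groups with Shapiro–Wilk at 0.05 and use a pooled two-sample
t-test if both pass, otherwise a Mann–Whitney rank-sum test; groups too small
to screen (n < 3) default to the t branch, and constant (zero-variance)
groups trivially fail normality and take the rank branch. Pairwise region
comparisons use Mann–Whitney U at the 5 % level with Bonferroni correction;
the divisor is the number of pairs actually tested (regions absent from a
section are skipped with a flag), and the default pair list is the six
comparisons of interest: A1–A2, A1–A3, A4–A5, A1–A4, A2–A5, A3–A5. The
relation between cross-sectional mean strain and a tissue proportion is an
ordinary least-squares fit reporting R² and the two-sided slope p-value.

## Sensitivity analyses

**Material insensitivity.** Each phantom is mapped twice: uniform stiffness,
and a tissue-specific ladder proportional to tangent moduli from tensile
tests on the tissue types — thrombus with RBCs 65 kPa (softest), 2.5× for
thrombus without RBCs, 10× for intact elastin, 15× for fragmented elastin.
Per region the report gives the Dice similarity of the two mapped areas
(pixel-counted at 1 µm), the absolute difference of the median grouped
strains in percentage points of E1, and the relative error of the medians.
The relative-error denominator is the uniform-stiffness run's median. The
multi-phantom study (`run_material_sensitivity_study`, also behind
`scripts/acceptance.py`) uses five phantoms and a mesh scaled uniformly from
the histology protocol (8 µm elastin / 16 µm elsewhere) — the package's
working problem size, at which the mapped contours are mesh-converged far
below the 1 µm raster (halving edge lengths moves them by < 0.5 µm).

**Segmentation perturbation.** One region's sector is inflated to change its
area by a target fraction (its neighbours shrink; sector area is linear in
angular width, and the realized change is verified on the polygon areas), the
mapping and grouping are re-run with uniform material, and the maximum
per-region median-strain difference and relative error against the
unperturbed run are reported per perturbation level.

## The phantom generator

The phantom emulates the study conditions: a circular lumen of diameter
1,000 µm, wall thickness 150 µm, partitioned into the five regions as
perturbed angular sectors (area proportions configurable; default
A1 0.25, A2 0.15, A3 0.15, A4 0.20, A5 0.25; sector breaks jittered by
±0.02 rad). The unloaded→loaded boundary deformation is a low-order Fourier
series in the angular coordinate (default amplitude 5 % of the radius,
modes ≤ 2, with the outer-wall series largely shared with the lumen series);
the ground-truth interior displacement blends the two boundary motions
linearly across the wall thickness. Across a thin wall this blend is close to
the elastostatic field, which keeps the FE recovery test well-posed (the
solver reproduces it with a median error below 2 % of the boundary
amplitude); it is not itself an equilibrium field, so agreement is expected
only at that level, not to solver precision.

Strain fields are region-coded: per-voxel values are the region's mean level
plus Gaussian noise (SD 0.02), clipped at 0, on a 10 µm grid; voxels outside
all regions are masked. Default region levels follow the qualitative ordering
of the study (highest in intact elastin without thrombus, comparable in
thrombus with RBCs, lowest in thrombus without RBCs): A1 0.12, A4 0.10,
A2 0.05, A3 0.04, A5 0.02. The magnitudes are free phantom parameters within
the 0–20 % display range of the strain maps, not measured values.

Volume pairs are Gaussian-filtered white-noise textures (σ = 1.5 voxels);
the reference is the target sampled through the known warp with the same
trilinear interpolation the estimator uses, so exact recovery is well-posed,
plus optional intensity noise.

The two-group generator draws per-specimen strain samples from a shifted
log-normal family (aneurysmal-like: right-skewed, median 0.035 + 0.005
shift, σ = 0.5·skew_magnitude) or a reflected log-normal family
(non-aneurysmal-like: left-skewed, ceiling 0.20 − median 0.055,
σ = 0.45·skew_magnitude), with ±8 % log-normal jitter of the median per
specimen. Both groups share a near-ceiling "peak strain" component (1.5 % of
samples at min(0.26, 0.248 + 0.005·LogNormal(0, 0.45))), reflecting that
maximum local strains were similar in all animals: specimen maxima are then
group-independent and often saturate at the ceiling, so the maximum index
does not separate the groups while mean, heterogeneity and skewness do. With
5 vs 3 specimens of 2,000 samples, the full qualitative pattern (mean lower,
CV higher, skewness higher in the aneurysmal group; maximum not significant)
reproduces in ≈ 96–98 % of 200-replicate batches.

What the phantoms do **not** emulate: ultrasound speckle and attenuation,
segmentation-observer variability, non-sector region topologies (islands,
branching), out-of-plane motion, and any quantitative link between tissue
stiffness and the synthetic strain levels. Passing tests therefore validate
the pipeline's mechanics and statistics, not the biological magnitudes.

## Known limitations

- The mesher requires star-shaped, sector-structured cross sections; generic
  multi-region polygon meshing is out of scope.
- Registration quality metrics assume closed, roughly convex-to-lobed
  contours; open or self-intersecting contours are rejected rather than
  repaired.
- The FE model is 2D plane stress with linear triangles; residual stress,
  through-thickness variation and 3D shell effects are not modelled.
- CPD recovers the target curve, not per-point material correspondence;
  downstream stages only use the displaced boundary positions, which is all
  the zero-traction problem needs.
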
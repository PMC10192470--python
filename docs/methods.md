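# Methods

`myelosurf` implements a surface-based pipeline for comparing cortical
myeloarchitecture across primate species: per-vertex T1w/T2w myelin maps,
gradient-ridge areal parcellation, per-parcel areal metrics in native
space, and a two-way interspecies ANOVA.  Because the absolute
measurements of any real comparative study depend on scanned animals, the
package ships a synthetic cortical phantom generator with known ground
truth; every stage is validated against that truth or against closed-form
geometric oracles.

## Surface model and geometric primitives

The cortical sheet is a pair of triangle meshes — white-matter and pial
boundaries — with identical face lists and a 1:1 vertex correspondence.
All measurements are taken in world millimetres.

- **Mid-thickness surface**: the vertexwise average of white and pial;
  the locus for myelin sampling weights, surface areas, and gradients.
- **Vertex areas** use the barycentric one-third rule: each triangle
  contributes A/3 to each corner.  Unlike Voronoi-type weights this is
  exactly conservative (the map sums to the mesh area identically), which
  is the property the per-parcel area sums rely on.
- **Wedge volumes**: the prism between corresponding white and pial
  triangles is cut into three tetrahedra.  The cut diagonals are keyed to
  global vertex indices (on the side quad over edge (i, j), i < j, the
  diagonal always runs pial(i)→white(j)), so the two prisms sharing a quad
  triangulate it identically and the side walls cancel: for closed
  surface pairs the summed signed wedge volumes equal the enclosed-volume
  difference of the two surfaces to machine precision.  Prisms with
  negative signed volume (locally inverted ribbon) are counted, reported
  via a warning, and accumulated signed rather than clamped.
- **Thickness** is the Euclidean white→pial correspondence distance.
  FreeSurfer's internal thickness definition is not reproduced; phantom
  surfaces are built with near-normal correspondence, where the two
  definitions coincide.
- **On-surface smoothing** approximates a geodesic Gaussian by iterated
  symmetric diffusion with cotangent (discrete Laplace–Beltrami) edge
  weights, clamped non-negative.  The step size λ and iteration count n
  are set so the accumulated kernel variance per tangent coordinate
  matches σ²: n·λ·S_w = 2σ², where S_w is the mean over vertices of
  Σ_j w_ij d_ij².  The one-step operator is symmetric, row-stochastic and
  non-negative (λ ≤ 1/(2·max weighted degree)), hence doubly stochastic:
  constants are preserved bitwise, the plain vertex mean is preserved,
  and the variance never increases.  On a planar grid the kernel matches
  the continuous Gaussian within a few percent RMS for σ ≥ 2 edge
  lengths; near open-mesh borders the kernel is asymmetric (anatomical
  surfaces are closed, so this only affects flat test sheets).

## Myelin mapping

1. **Ratio volume**: voxelwise T1w / max(T2w, ε), with ε defaulting to
   10⁻⁶ of the T2w robust max; low-signal voxels are masked non-finite.
   The ratio is computed first and then sampled (one interpolation pass),
   rather than sampling T1w and T2w separately.
2. **Volume→surface sampling**: per vertex, the ratio volume is
   trilinearly sampled at n = 7 evenly spaced points on the straight
   white→pial segment and combined with Gaussian weights centred on the
   segment midpoint, σ = FWHM/(2√(2 ln 2)).  The default FWHM is the
   species parameter (1.8 mm for the night-monkey conditions, scaled with
   species thickness otherwise).  Weights are renormalized over finite
   samples; vertices with no finite sample are masked and counted.  The
   straight-segment model is the main simplification versus
   ribbon-partial-volume mapping; on phantoms with near-normal
   correspondence the two coincide.
3. **Bias correction**: corrected = individual − smooth(individual −
   template, σ = 5 mm), the subtractive low-frequency formulation.  The
   template is the symmetrized group average of the individual maps; on
   phantoms the left/right correspondence is the identity (the right
   hemisphere is an exact mirror), so symmetrization needs no
   registration.  Smoothing preserves constants, so uniform offsets are
   removed exactly; a sinusoidal bias of wavelength λ is suppressed by
   factor 1 − exp(−2π²σ²/λ²), which is > 90% for derivative scale
   λ/2π ≥ 15 mm.  The smoothing is geodesic on-surface (whether the
   original procedure smoothed on the surface or in the volume is not
   specified; on-surface is assumed).

## Gradient-ridge parcellation

- **Gradient operator**: after pre-smoothing (σ = 0.5 mm), the 1-ring
  neighbours of each vertex are projected into the vertex tangent plane
  (normal = area-weighted face-normal average) and a linear field is
  least-squares fitted to the centre and neighbour values; the gradient
  magnitude is the fitted slope norm.  Linear fields on planar meshes are
  recovered to machine precision; vertices with fewer than three usable
  neighbours are masked.
- **Ridges**: vertices with gradient ≥ 0.5 × the 98th percentile of the
  gradient map (a robust max), connected components under 10 vertices
  discarded.  Both defaults are explicit knobs, not inferences of any
  expert's intent.
- **Parcels**: breadth-first flood fill from an explicit seed vertex,
  never entering ridge vertices — the reproducible surrogate for manual
  border drawing.  A fill reaching > 90% of the mesh raises a
  "leaky boundary" warning.  Afterwards, unassigned ridge-band vertices
  are folded into adjacent parcels by intensity: a ridge vertex joins a
  neighbouring parcel iff its myelin value is closer to that parcel's
  interior mean than to the background mean (lowest adjacent label wins
  ties; a few deterministic passes until stable).  This is the package's
  operationalization of boundary placement "using both the intensity and
  the gradient", and it handles high-myelin islands (MT+-like,
  auditory-like) and enclosed low-myelin islands (BA7-like)
  symmetrically.  Overlaps are resolved first-come in seed order with a
  conflict report.
- **Label resampling** between meshes is nearest-vertex (Euclidean) with
  lowest-index tie-breaking.

## Synthetic phantoms

The generator supplies everything downstream of (out-of-scope) image
registration and surface reconstruction:

- **Geometry**: a radially perturbed icosphere (default subdivision 5,
  ~10k vertices; tests use 4) with 3 sinusoidal "sulcal" indentations of
  amplitude 6% of the radius; real gyrification is not modelled — the
  folds exist to exercise curvature handling.  The pial surface is the
  white surface displaced along vertex normals by the thickness field, so
  the correspondence separation equals the thickness exactly.  The right
  hemisphere is the exact mirror (x → −x) of the left with shared vertex
  ids; this stands in for cross-subject and cross-hemisphere surface
  registration and makes total L/R areas identical by construction.
- **Parcels** are geodesic patches grown (by graph-Dijkstra distance)
  from fixed, well-separated anchor directions until their mid-thickness
  area fraction matches the species target; an unreachable target at the
  mesh resolution is an explicit error naming the parcel.  The myelin
  field is a background of 1.0 ratio-units plus a per-parcel contrast
  with a hard step at the border.
- **Study conditions**: the three-species defaults place parcel area
  fractions at the reported worked-example values (MT+ 2.4/0.9/1.2%,
  auditory 2.5/0.6/1.5%, BA7 2.3/3.2/2.0%, V1 18.8/11.7/20.4% for night
  monkey/macaque/marmoset), hemisphere sizes near the reported total
  areas (2030/9894/1053 mm²), thicknesses near 2.0/2.2/1.8 mm, and
  subject counts 9/32/20 at full design (4 per species at desk scale).
  Myelin contrasts (+0.8 MT+-like, +0.65 auditory-like, −0.6 BA7-like,
  +0.7 V1-like) are not reported quantities; they are chosen of
  comparable magnitude so every areal border produces a ridge of similar
  strength — the generator is set for testability, not radiometric
  realism.  Across-subject variability: total-area jitter sd 6%,
  thickness jitter sd 2% (within the range of the reported group sds).
- **Volumes**: T1w = B·S√m and T2w = S/(B·√m) (S = 100 arbitrary units),
  so the noiseless unbiased ratio equals the myelin field m exactly and
  the multiplicative bias B enters the ratio as B².  The contrast
  functions are monotone (increasing/decreasing) and invertible, and
  configurable.  Voxels take the myelin value of the nearest
  correspondence segment (nearest-sample-wins splatting with segments
  through vertices, face centroids and edge midpoints, extended 0.6 voxel
  past each surface; interior gaps closed morphologically), keeping step
  borders voxel-sharp.  Outside the ribbon, background intensities give
  ratio 0.125, well separated from cortex.  The default voxel size is
  0.25 × mean thickness (0.5 mm for 2 mm cortex), inside the
  two-voxels-across-the-ribbon criterion.  Bias B = 1 + a·Σ₃ cosines with
  wavelengths 100–180 mm (derivative scale ≥ 15 mm — near-linear ramps,
  like B1-transmit profiles), so it is separable from areal steps by the
  5 mm correction.  Noise is additive Gaussian per channel with sd
  noise_sd·S/√2, making the ratio noise ≈ noise_sd near baseline — a
  simplification of Rician noise valid away from the low-SNR regime.
  All randomness flows from named seeds; no global RNG state is touched.

## Areal metrics and statistics

Per parcel and hemisphere: area = Σ vertex areas over labelled vertices
on the mid-thickness surface; volume = Σ wedge volumes; thickness = plain
unweighted vertex mean (an area-weighted variant sits behind a flag);
totals run over all vertices.  Relative area/volume divide by the
hemisphere totals; printed percentages round half-up to one decimal.

The interspecies test is a fixed-effects two-way ANOVA (species, parcel,
interaction) with Type III sums of squares under sum-to-zero contrasts —
the appropriate choice for the unbalanced species design; residual
df = N − a·b.  Hemispheres are treated as independent observations,
matching the hemisphere-count accounting (64/18/40 hemispheres, 4
parcels → interaction df (6, 476)); the within-subject L/R correlation
this ignores is a known limitation, not modelled.  The implementation is
direct linear algebra (model-comparison sums of squares via least
squares) and is cross-checked in the test suite against
`statsmodels.stats.anova.anova_lm(typ=3)` on the same design.  A
single-level parcel factor degrades gracefully to the one-way model, in
which the species F on two balanced groups equals the squared pooled t
exactly.  Post hoc comparisons are per-parcel pairwise Welch
(unequal-variance) t tests with Bonferroni correction over
m = (species pairs) × (parcels) comparisons (m = 12 for the 3 × 4
design); the plain "t test" of the source procedure is not further
specified, and Welch is the conservative default.  Zero residual
variance is flagged rather than reported as an F statistic.

## Pipeline, determinism, problem sizes

`run_pipeline` sequences simulate → map-myelin → parcellate → metrics →
stats.  Parcels are delineated once per species on the group-average
corrected map and group-average mid-thickness mesh (left hemispheres;
the mirror correspondence makes right hemispheres redundant for this
step) and projected to every hemisphere through the shared vertex ids;
metrics are then computed in each hemisphere's native space.  A
provenance manifest records the config hash and product checksums;
identical configs give identical checksums, and a rerun against a
matching manifest resumes from the stored metrics table.  Stage failures
raise an error naming the stage and retain completed products.

Problem sizes: the desk profile uses subdivision-4 meshes (2562
vertices; subdivision 5 for the macaque so the mesh edge stays below the
voxel size) and 3–4 subjects per species, which keeps a full three-species
replicate around ten seconds; the full-design runs in the acceptance
script use the reported subject counts (9/32/20) at the same mesh
scale.  Dice recovery, area-fraction bias, the 20-replicate population
recovery, and the 10 000-simulation ANOVA null calibration are all
computed at these sizes.

## What the phantoms do and do not show

Passing tests demonstrate that the measurement chain — rasterization,
sampling, bias removal, ridge delineation, areal accounting, statistics —
recovers known ground truth under controlled noise and bias, and that the
reported relative-area arithmetic and design degrees of freedom are
reproduced exactly.  They do not validate surface reconstruction,
registration, B0/readout distortion handling, dura/vessel exclusion, or
any claim about real tissue: phantom folds are mild, correspondence is
exact by construction, noise is Gaussian, and the myelin field is
piecewise constant.  Real-data boundary contrast is weaker and the
semi-manual delineation it requires is out of scope.
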
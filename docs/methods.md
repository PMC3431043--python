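# Methods

This note documents the models and procedures implemented in `mothatlas`,
the parameter defaults and why they were chosen, what the synthetic
benchmark does and does not emulate, and the numerical choices that matter
for reproducibility.

## Coordinate conventions

All physical coordinates are micrometres. Image stacks are stored
`(z, y, x)` with spacing `(dz, dy, dx)` and an origin, so the physical
position of voxel `(k, j, i)` is `origin + (k·dz, j·dy, i·dx)`; points
(SWC nodes, landmarks) are `(x, y, z)`. The default stack geometry is 2 µm
optical sections with 1 µm in-plane pixels. Voxel spacing is an explicit
parameter or a JSON sidecar, never read from TIFF tags: microscope exports
are unreliable, and registration routinely mixes stacks of different
magnification. The brain coordinate origin is anchored at the center of the
esophageal foramen in the middle slice (the slice with the largest brain
outline), because that point is unambiguous in every sample.

## Landmark transforms

Landmarks are matched between files by name (case-insensitive), never by
row order, mirroring the name-landmarks-and-register workflow.

* **Rigid** (≥ 3 non-collinear pairs): least-squares orthogonal Procrustes
  with reflections excluded — the recovered rotation always has
  determinant +1. Mirroring is a separate, explicit operation
  (`mirror`), because a silent flip would corrupt hemisphere identity.
  No scaling: the atlas-building alignment changes position and
  orientation only, preserving each brain's size and shape so the average
  reflects true inter-individual variability.
* **Affine** (≥ 4 non-coplanar pairs): 12-parameter least squares.
* **Thin-plate spline** (≥ 4 non-coplanar pairs): the 3D biharmonic kernel
  `U(r) = r` is used — the correct Green's function of the biharmonic
  operator in three dimensions (`r² log r` is the 2D kernel). The standard
  block system (kernel block + affine polynomial block) is solved per
  coordinate; regularization λ (default 0) is added to the kernel diagonal.
  With λ = 0 the spline interpolates every landmark to machine precision;
  the default treats landmarks as exact anchors, which is how the
  registration-error evaluation protocol is defined. The warp coefficients
  satisfy the side conditions (zero sum, orthogonality to source
  coordinates), so the spline is exactly affine for affine-consistent data.
* **Image resampling** uses inverse mapping with trilinear interpolation,
  slab-by-slab to bound memory. Rigid/affine transforms invert
  analytically; the TPS has no closed-form inverse, so the inverse is
  fitted by exchanging the roles of source and destination landmarks —
  standard practice, and consistent with one landmark file driving both
  directions. The TPS is fitted and applied fully in 3D (not slicewise);
  a slicewise variant could differ slightly near strong out-of-plane
  warps.
* **SWC registration** maps node coordinates only by default
  (`radius_policy="fixed"`). An opt-in `local_scale` policy multiplies each
  radius by `|det J|^(1/3)` of the local Jacobian (central differences,
  h = 0.5 µm) for workflows that want diameters to follow volume change.

## Atlas construction

Left-hemisphere stacks are mirrored about the sagittal (x) midplane and
their left/right landmark labels swapped, doubling the sample count under a
bilateral-symmetry assumption. All stacks are rigidly resampled into the
geometry of a designated reference stack (a config key, matching the
practice of selecting one base brain image), averaged voxelwise in floating
point, and binarized. Binarization is Otsu's global threshold by default
(a fixed threshold is available); the largest 26-connected component is
kept and interior holes are filled so the outline is a single solid region,
and the surface is a marching-cubes isosurface at level 0.5 in physical
coordinates (the volume is padded by one background voxel first so masks
touching the boundary still close). Watertightness is checked and warned
about, not enforced. No per-stack intensity normalization is applied by
default; whether to normalize before averaging is genuinely open, and the
default keeps the average a plain arithmetic mean of the inputs.

## Phantom benchmark

The tracing benchmark uses synthetic neurons with exact ground truth: a
random binary tree of tapering cylinders (frusta, matching SWC semantics)
rendered into an 8-bit stack. Defaults, chosen to produce the four
qualitative image regimes at desk scale and exposed in `PhantomSpec`:
256 × 256 × 128 voxels at (1, 1, 2) µm; foreground 200 on background 20; a
trunk plus 2–4 binary branching generations (≥ 3 bifurcations); segment
lengths 20–60 µm; branch angles 20–70°; root radius 2 µm tapering ×0.8 per
generation; noise σ = 30 (below half the foreground–background gap, so
signal is never drowned); bias amplitude 100; distractor cylinder radius
8 µm. Every phantom is bit-reproducible from its integer seed. The full
suite is 4 conditions × 3 phantoms = 12 stacks.

The phantoms emulate tubular fluorescent structures, background offsets,
detector noise and occluding objects. They do **not** emulate real confocal
optics — depth-dependent attenuation, anisotropic PSF, uneven staining,
multi-neuron clutter — so benchmark scores bound what the pipeline can do
on clean-to-moderately-corrupted data, not on every real stack.

## Tracer

The automatic tracer is a deterministic embodiment of region-growing
centerline extraction (the original's exact growing criterion is not
published, so a reproducible standard formulation was chosen):

1. optional rolling-ball-style background subtraction (grey opening with a
   15 µm box — larger than any neurite diameter — follows large smooth
   bright objects and is subtracted), Gaussian denoising (σ = 0.7 µm), and
   a global threshold;
2. flood fill from the seed (default: brightest foreground voxel; ties
   break on lexicographic voxel order) keeps the seed's connected
   component, with a coverage warning for unreachable components;
3. a shortest-path tree over the component's voxel graph (26-connectivity
   by default), edge costs weighted by `1/(1 + EDT)` so paths hug the
   medial axis; branches are added farthest-first until the component is
   covered by centerline balls;
4. spurs shorter than 3 µm are pruned (branches continuing through a
   mid-neurite seed are exempt — a degree-2 root is a path-through point,
   not a junction), centerlines are resampled at 1 µm, nodes are nudged to
   the local mask centroid, and radii come from the EDT (floor 0.25 µm).

Thresholding note: plain Otsu fails on these volumes because foreground is
a tiny fraction of the voxels (it splits the background distribution).
The tracer therefore re-applies Otsu to above-threshold voxels while the
foreground fraction exceeds 5 %, then lifts the cut to the midpoint
between a robust background level (median below threshold) and a robust
foreground level (90th percentile above), which places the cut near the
half-intensity surface of thin blurred structures instead of in their
smoothing skirt.

Terminal branches are trimmed because the geodesically farthest voxel lies
on the surface of the end cap, not on the centerline; the trim length is
the mean of the local radius and the tip's depth deficit, which centres the
recovered endpoint for both flat and rounded caps.

The **semiautomatic** mode replays the human correction loop
deterministically against a reference morphology: false branches are cut at
their first node farther than the tolerance (2 µm) from true cable, and
missed true cable is re-drawn as node chains (the reference is densified to
1 µm spacing first, so detection granularity is finer than the tolerance).
Because deletions remove only unmatched cable and additions are exact true
cable, the corrected consistency is never below the automatic one — the
monotonicity the benchmark relies on. The **manual** mode is the same edit
machinery applied to an empty trace; the interactive GUI of the original
tool is out of scope.

## Consistency metric

Both trees are resampled to ≤ 0.5 µm arc-length point chains with per-point
length weights. `c_miss` is the weighted fraction of ground-truth points
with an extracted point within τ; `c_false` is the symmetric quantity; the
score is their mean, so it weights cable **length**, not node or branch
count (the alternative branch-count weighting is not used). τ defaults to
2 µm, about one optical-section step. Diameter discrepancy is the
length-weighted mean of `|d_test − d_gt| / d_gt` over matched ground-truth
points. An empty extraction scores 0, not 0.5: a null answer must not get
half credit for "detecting nothing falsely". Statistical comparisons
(ANOVA-style testing across methods) are out of scope; the reports expose
per-sample tables for any stats package.

## Passive cable model

The passive validation asks whether an extraction is *electrically*
faithful. Each SWC edge becomes a frustum compartment; potentials are
solved at the nodes, each node carrying half the membrane area of its
incident frusta. The frustum axial resistance `R = Ra·L/(π r₀ r₁)` and the
slant lateral area are both exactly invariant under splitting an edge into
collinear halves, so mesh refinement converges cleanly (halving the node
spacing changes tip voltages by < 0.5 %). Defaults are generic passive
conventions, not measured values: Rm = 10 000 Ω·cm², Ra = 100 Ω·cm,
Cm = 1 µF/cm², E_rest = −65 mV. The headline comparison is steady state —
constant current (0.1 nA default) at the root, tip voltages compared after
nearest-Euclidean tip pairing, error = mean relative deflection difference,
with the input-resistance relative error alongside. Steady state was chosen
because it is a single reproducible linear solve; under a purely passive
membrane, transients add only the membrane time constant, and a
backward-Euler step-response mode (`step_response`, dt 25 µs) is available
for time-domain checks. The error functional is deliberately swappable: any
scalar comparison of the two voltage profiles plugs in at the same place.

## Overlap volume

Both arbors are rasterized as frusta onto one isotropic grid covering their
joint bounding box (default 1 µm; halving the grid changes smooth fixtures
by < 5 %). Overlap is the intersection voxel volume; Jaccard is reported
for scale-free comparison. An optional isotropic dilation (added to every
local radius) turns strict intersection into a proximity criterion —
about 2 µm is a sensible putative-contact scale. The toolkit reports
geometry only: how overlap maps to synaptic weight is deliberately left to
the user's model.

## Verification strategy and problem sizes

The test suite checks each stage against independent oracles: generating
transforms for rigid/affine recovery, the TPS interpolation property, the
closed-form sealed cable `V(L)/V(0) = 1/cosh(L/λ)`, analytic
cylinder/sphere volumes, a Monte-Carlo sphere-lens integrator, and the
Maxwell-distribution mean for landmark jitter. The benchmark suite used in
tests and in `scripts/acceptance.py` is the full 12-phantom set at the
default phantom geometry; atlas-pipeline tests use a 48 × 64 × 64 synthetic
brain blob with 12 jittered hemisphere samples. End-to-end runtime of the
whole suite is a few minutes on a single CPU.

## Known limitations

* The tracer assumes a single connected neuron per stack; disconnected
  fragments are reported, not traced (use `connect` edits or per-component
  seeds).
* Otsu-based thresholds assume bimodal-ish histograms; densely packed
  neuropil or strong depth attenuation would need intensity-adaptive
  growing criteria, which are intentionally not guessed at here.
* The TPS inverse (for image resampling) is a fitted approximation; for
  violent warps forward(inverse(x)) ≠ x far from the landmarks.
* Radii from the distance transform are biased upward by about half a
  voxel on thin, anisotropically sampled neurites; the diameter
  discrepancy of automatic traces (~0.1 on clean phantoms) reflects this.
* No intensity-based (landmark-free) or diffeomorphic registration.
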
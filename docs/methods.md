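# Methods

`uroscope` turns a delayed-phase CT volume of a kidney into simulated
endoscopic views of its collecting system, and provides the measurement
tools to evaluate each stage.  This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic
phantoms do and do not establish about real data.

## Preprocessing (`volumes`)

CT volumes are resampled to a fixed voxel-count grid (canonically 256³)
with trilinear interpolation (nearest-neighbour for label maps), preserving
the physical extent per axis: the output spacing is `extent / target_shape`
with voxel centres at `(i + 0.5) * spacing`.  Grids are corner-aligned;
coordinates outside the input are clamped to the nearest voxel
(no extrapolated intensities).  Intensities are then clipped to a fixed
Hounsfield window, default [−256, 512] HU — wide enough to span soft tissue
and pooled urographic contrast while suppressing metal and air extremes —
and rescaled to [0, 1].  Arrays are indexed `(z, y, x)` throughout, with
`spacing` in the same order.

## Collecting-system extraction (`extraction`)

Delayed-phase contrast pools in the renal pelvis, making the cavity the
brightest tissue inside the kidney.  Extraction therefore starts from a
whole-kidney mask (from any segmentation backend behind the `Predictor`
interface), dilates it with a 5×9×9 voxel box — 5 along the slice axis
because thick-slice CT (≈5 mm slices vs sub-millimetre in-plane) makes that
element roughly isotropic in millimetres — masks the CT with the dilated
region, and splits the masked intensities into three classes with
multi-level Otsu thresholding (256 uniform bins over the observed masked
range, `skimage.filters.threshold_multiotsu`).  The brightest class is the
collecting system; voxels outside the dilated mask are always background.
Otsu is computed over masked voxels only: masking first is the point of the
dilation, since the rest of the scan would otherwise dominate the
histogram.  No connected-component filtering is applied by default; a
`largest_cc` flag exists for noisy inputs.

Equal-variance threshold ties are real: well-separated modes leave empty
histogram gaps in which every threshold attains the same between-class
variance, so tests compare the attained objective rather than the raw
threshold values.

Sliding-window inference tiles the volume with patches (default 128³) at
50% overlap, snaps the final window inside the volume (no padded
intensities), and fuses overlapping predictions with an unweighted mean.
Training-time augmentations draw uniformly from fixed ranges: intensity
shifts ±0.026, per-axis rotations ±30° with ±10% anisotropic scaling,
Gaussian smoothing with σ ∈ [0.5, 1.5] voxels, and 16-crop sampling with
alternating foreground/background centre voxels.

## Meshing (`meshing`)

The binary cavity mask is smoothed with a Gaussian of σ = 0.8 voxels
(reflective boundaries, so a full mask stays 1.0 to the volume edge) and
the 0.5 iso-surface of the smoothed field is triangulated with marching
cubes (scikit-image's Lewiner variant, which yields closed 2-manifolds for
interior-solid fields).  Vertices are emitted in physical millimetres so
skeleton distances and camera poses are metric.  A `step_size` parameter
coarsens the marching grid when a lighter mesh is wanted (the pipeline
default is 2).

## Wave-propagation skeletonization (`skeleton`)

A wave is launched from a seed vertex across the mesh edge graph; the step
at which each vertex is reached is its breadth-first hop count.  Vertices
with equal quantized step `floor(step / step_size)` that are edge-connected
*within that band* form a ring; each ring contracts to its centroid, and
rings sharing a mesh edge are linked.  The band-connectivity requirement is
what separates two branches lying at equal wave distance into distinct
nodes.  An edge-length-weighted (geodesic) metric is available as an
option; hop counts are the default.

Breadth-first step counts are not smooth on irregular triangulations: a
vertex can be reached one step after its entire neighbourhood, stranding a
one- or two-vertex ring at a quantization boundary.  Rings smaller than
`min_ring_size` (default 3) are therefore absorbed into the adjacent ring
they share the most edges with before contraction.  This removes wavefront
noise, not genuine branches — legitimate calyx tip rings at the default
mesh resolution have ≥ 5 vertices.  Occasional spurious short branches can
still appear for unlucky geometry (a trailing wavefront lobe pinching off
inside a wide chamber); this is inherent to surface-wave skeletonization
and is visible in the method's own qualitative behaviour at small step
sizes.

`step_size` (default 5) trades skeleton density against sparsity: larger
steps collapse more rings per node, and the node count is monotonically
non-increasing in it.  `wave_count` (default 2) launches additional waves
from farthest-point seeds (first seed: vertex of maximal hop distance from
vertex 0; second: the vertex farthest from the first — deterministic, no
randomness actually consumed by the default strategy).  The first wave
fixes the topology; each later wave is contracted independently and its
nodes are matched to the reference by normalized arc position (flipped for
the opposite-seed wave), tie-broken by spatial proximity within a radius of
3× the median skeleton edge length.  Matched positions are averaged;
unmatched nodes are kept unaveraged.  Averaging recentres nodes that a
single wave places off-axis; on an analytic cylinder every ring centroid is
exactly on the axis by symmetry, and a second wave does not move it.

**Coverage statistic.**  Skeleton quality is summarized by the mean
distance from `n_samples` (default 5000) points sampled uniformly by area
on the mesh to the nearest point on any skeleton *segment*.  Distances are
measured to segments rather than nodes because a node-only metric would
penalize sparse skeletons for ring quantization alone.  Isolated nodes
count as degenerate segments.

## Camera paths and rendering (`render`)

Poses are placed at fixed arc-length intervals along a depth-first
traversal of the skeleton edges rooted at a degree-1 node (the tube entry
when one exists), endpoints included.  The view direction is the local
tangent; the up vector is parallel-transported along each chain, which
avoids roll flips at branch turns.  The vertical field of view defaults to
60° and is configurable — style-transfer realism depends on it, and real
ureteroscope intrinsics are not modelled.

The renderer casts one primary ray per pixel from a pinhole camera,
intersects it with the mesh (Möller–Trumbore; with a shared ray origin the
per-triangle factors reduce to three precomputed cross products, so each
ray chunk is three dense matmuls), and shades the first hit with the Phong
model `I = ambient·C + diffuse·C·max(0, n·l) + specular·max(0, r·v)^m`,
normals flipped toward the camera so tube interiors are lit.  Rays that
miss the mesh get a black background (the endoscopic surround).  The base
colour is a single light-gray RGB constant — the rendered domain is
deliberately solid and textureless.  Three presets:

| preset          | ambient | diffuse | specular | light               | edges |
|-----------------|---------|---------|----------|---------------------|-------|
| `baseline`      | 0       | 1.0     | 0        | global directional  | on    |
| `customsurface` | 1.0     | 0.3     | 0        | global directional  | on    |
| `customlight`   | 0       | 0.5     | 0.1      | headlight           | off   |

The headlight sits 1 mm behind the camera along the view axis — the
smallest faithful reading of a light source "behind the camera"; the offset
is configurable.  Inverse-square distance falloff is available but off by
default, matching fixed-intensity scene lights; with it off, brightness
depends on incidence angle only, which is what the Lambert-law checks
exercise.  Wireframe overlay colours pixels whose minimum barycentric
coordinate falls below 0.06, cycling a five-colour palette by triangle
index.

## Distribution distances and style transfer (`metrics`, `style_transfer`)

FID fits a Gaussian to each feature set (covariances with 1/(n−1)) and
evaluates `‖μa−μb‖² + Tr(Σa + Σb − 2(ΣaΣb)^½)`; the matrix square root is
taken on the symmetric form `(Σa^½ Σb Σa^½)^½` by eigen-decomposition,
clamping eigenvalues above −1e−8 and failing loudly if strongly negative
eigenvalues (> 1e−4 of the spectral norm) indicate ill-conditioning.  KID
is the unbiased squared MMD under the cubic polynomial kernel
`(x·y/d + 1)³`, averaged over seeded subsets (default 100 × 10; scaled to
the set size at fixture scale and always reported alongside the estimate).

The feature extractor is pluggable.  The canonical identifier is
`inception-v3-pool3` (2048-d) for parity with the literature, but all
tests and the acceptance run use a deterministic random-projection
extractor (16×16 block-average → fixed Gaussian projection → ReLU →
projection, 192-d), so no pretrained weights are required.  Numerical
parity with published FID/KID values is therefore not claimed anywhere;
only orderings and closed-form identities are asserted.

The style-transfer component is a *contract*, not a trainer: full
contrastive unpaired translation is far outside desk scale.  The smoke
harness realizes the same objective shape — a GAN loss plus a patchwise
InfoNCE loss tying output patches to input patches at the same location —
with a 12-parameter per-pixel colour-transform generator (central finite
differences), a logistic discriminator on image colour statistics
(analytic gradients), and a frozen random-projection patch encoder
(5×5 patches, 24-d, unit-norm).  InfoNCE uses temperature τ = 0.07 and
λ_NCE = 1, the conventional defaults.  The synthetic style domain maps
render luminance to a tissue palette (R > G ≥ B) with low-frequency
mottling, a radial vignette and specular blobs; the palette is anchored to
the source luminance because endoscopic cavities are dark — a bright fixed
offset would let global brightness, not illumination structure, dominate
the distribution distances.

## Synthetic phantoms (`phantom`)

A phantom emulates one delayed-phase kidney: a pelvis ellipsoid (semi-axes
10×12×9 mm) tapering through a funnel into a ureter-direction entry tube
(the real pelvis is funnel-shaped; a thin tube T-joined to a wide chamber
would leave a pocket where a surface wave terminates, which is geometry
noise, not anatomy), plus `n_calyces` capsule branches (default 6, radii
2.5–4 mm, lengths 12–24 mm) fanned over the upper pelvis at evenly spaced
azimuths with seeded jitter and polar angles staggered between ~33° and
~49° cones.  The stagger keeps neighbouring branches disjoint in 3D angle —
a validity requirement: if two branches merge, the ground-truth branch
count no longer describes the cavity's actual topology.  The parenchyma
shell is everything within 4 mm of the cavity (Euclidean distance
transform), and intensities default to −100 / 80 / 300 HU for background /
parenchyma / contrast with Gaussian noise of sd 20 HU — plausible
delayed-phase magnitudes chosen for three well-separated modes, not values
fitted to any dataset.  Everything is deterministic under `rng_seed`, and
the generator verifies that every centerline point carries the
collecting-system label.

What the phantoms do not emulate: partial-volume mixing at cavity walls,
CT noise physics (streaks, beam hardening), anatomical variation beyond
branch count/angles, stones or tumours in the lumen, and deformation.
Extraction Dice ≈ 1.0 on phantoms therefore shows the post-processing
logic is correct under the stated contrast model, not that any segmentation
network reaches clinical accuracy; the clinical step lives behind the
`Predictor` interface and is out of scope here.

## Pipeline and reproducibility (`pipeline`, `cli`)

`run_pipeline` executes phantom (or user inputs) → preprocess → extract →
mesh → skeletonize → trajectory → render → metrics, writing the resolved
config next to the outputs and a manifest listing every artifact with its
SHA-256.  Stage timings go to stderr only, so identical seeds produce
byte-identical manifests; volume outputs default to uncompressed `.nii`
because gzip members embed a modification time that would break
byte-identical reruns.  Stages are resumable: existing outputs are not
recomputed, and regenerating a deleted output reproduces it exactly.

Default problem sizes (128³ phantom, marching-cubes step 2, six 64²
frames, 5000 coverage samples) keep a full run around a few seconds on one
CPU while exercising every stage; all of them scale up through the config.

## Known limitations

- Hop-count wavefronts on irregular triangulations occasionally produce a
  spurious short branch despite small-ring absorption; the geodesic metric
  trades this for a metric-dependent step unit.
- Ring contraction guarantees centredness only for roughly tubular
  geometry; no medial-axis property is claimed for blobs.
- The renderer models neither fisheye distortion nor the rolling
  illumination of real ureteroscopes.
- The smoke-scale style transfer can only adjust global colour; mottling,
  vignette and specular structure of the target domain are beyond its
  generator class, which is why its loss plateaus well above zero.
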
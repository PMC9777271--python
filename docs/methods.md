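# Methods

This note records the models, parameter choices and numerical decisions
behind the toolkit, and what the synthetic validation does and does not
demonstrate.

## Coordinate conventions

Volumes are `(z, y, x)` arrays of axial slices; `spacing`/`origin` are
`(x, y, z)` millimetres, and voxel `(k, j, i)` sits at world point
`origin + (i·sx, j·sy, k·sz)`. Direction cosines beyond the identity are
not modelled: oriented volumes are reoriented to the nearest axis-aligned
frame on read, with a warning. The patient is assumed supine with the
anterior surface at low row indices (configurable flip). Rigid
transforms are proper rotations plus translations; scale is never
estimated anywhere, because the virtual (CT) and real (scan) surfaces
belong to the same patient.

## Denoising

Anisotropic diffusion runs independently per axial slice (the in-plane
pixel pitch is far finer than the slice pitch, so 2D diffusion avoids
mixing across slices). One iteration adds `λ · Σ_d g(|∇_d I|) · ∇_d I`
over the four in-plane neighbour differences. The conduction function is
Perona–Malik exponential `g(d) = exp(-(d/κ)²)` by default (rational form
selectable). Defaults λ = 0.2, κ = 30 intensity units, 5 iterations:
λ is within the explicit stability bound 0 ≤ λ ≤ 0.25 of the
4-neighbour scheme; κ = 30 sits well above the phantom's noise scale
(σ = 8) and well below its skin/air contrast (100), so noise diffuses
while the skin edge conducts almost nothing. Zero-flux (replicated-edge)
boundaries make the scheme conservative: per-slice total intensity is
preserved to round-off and no new extrema can appear — both asserted by
tests.

## Skin segmentation

Per slice: (1) Otsu's threshold on a 256-bin histogram after min–max
scaling, ties broken toward the smaller threshold; foreground is
`value > T`. (2) SRG with zero tolerance on the binary result, seeded at
the foreground pixel nearest the slice centre — a deterministic stand-in
for "a point near the image centre", chosen for reproducibility. This
keeps the body and drops disconnected bright structures (scanner pads).
(3) SRG from a background seed at top-centre (bottom-centre fallback)
finds the exterior; background pixels unreachable from the border are
interior cavities and are filled. (4) One opening with a 3×3 square —
the smallest element that removes speckle without eroding the skin
outline; a closing pass is available but off by default. Slices with no
foreground return an empty mask with a warning (CT stacks may start or
end off-body).

SRG is implemented as connected-component labelling of the band
`|I − c| ≤ tol` restricted to components containing a seed, with the
criterion `c` being the seed mean (or a caller-frozen value). This is
exactly the fixed-criterion growing recipe, computed in one vectorized
pass.

## Nipple detection

On each slice in a central z-band (default: middle 60%, excluding
shoulder/abdomen contours) the anterior profile is the minimum-row
foreground pixel per column. Slope angles between consecutive points are
smoothed with a 5-point moving average; each maximal section where the
angle passes from positive through zero to negative yields a candidate
whose apex is the most anterior point (plateau middles are used, since
rasterization flattens tips) and whose prominence is the apex height
above the mean endpoint height.

Candidates are pooled per body side and clustered by apex column
(tolerance 6 px). Each cluster is represented by its most anterior
member; its slice index is the median of the member slices whose apex
comes within 3 px of that extreme — the slices where the nipple itself,
not just the breast mound, is present. The final pair is the
left×right cluster pairing with the best symmetry score: the mean
absolute difference between the left gradient profile and the mirrored
right profile (resampled to the tallest candidate's section length),
plus penalties for apex asymmetry about the body centre and for apex
height disagreement. The height term matters: a mound shoulder can
mimic the profile of a true tip but sits visibly lower. The published
description of this score ("sum of gradient differences … based on the
region with the largest height") is under-determined; the formula here
is one consistent reading, isolated in a single function
(`nipples._pair_score`) and exercised by an exhaustive-enumeration test,
not asserted as the only possible interpretation. A side with no
candidate is populated by mirror ("virtual") candidates so a pair always
exists.

## Meshing and ROI

The binary mask is cast to a float occupancy field, smoothed with a 2 mm
Gaussian (suppressing slice-thickness staircase aliasing without slice
interpolation, which would multiply memory and compute), and polygonized
with marching cubes at iso-level 0.5 — the half-occupancy surface of the
smoothed field. The volume is zero-padded by one voxel first so the
surface is always closed.

Decimation is a batched greedy variant of quadric edge collapse: each
pass computes every edge's collapse cost from accumulated vertex plane
quadrics, places the merged vertex at the quadric minimizer (midpoint
fallback for ill-conditioned quadrics, with a guard that rejects
solutions flying further than 10 mean edge lengths), and greedily
collapses the cheapest non-interacting edges until the face budget is
met. There is no randomness and ties break by edge order, so results are
bit-reproducible. The default budget of 192,000 faces matches a
full-resolution clinical setting; phantom studies use 8,000 (the phantom
surface carries far less detail, and the study must run quickly).

The registration ROI is the vertex set within a 100 mm ball around the
nipple midpoint (left/right selectable for a specific surgical site),
intersected by default with the anterior-facing half (outward normal
with a positive anterior component). The anterior filter reflects what a
hand-held depth sensor can see: posterior and far-lateral skin has no
counterpart in a scan, and leaving it in the source cloud biases even a
trimmed ICP. Ball radius and filter are configuration, since the
geometry of the exposed field is site-specific.

## Registration

Centre-of-mass translation first, then point-to-point ICP with the ROI
vertices as the moving source and the scan as the fixed target, so the
resulting transform maps CT-space data into the real frame. Each
iteration: KD-tree nearest-neighbour correspondences; optional rejection
beyond a distance gate (default ∞) and trimming of the worst 10% —
partial scan coverage leaves some ROI vertices without true
counterparts; closed-form SVD rigid fit with reflection correction.
Convergence when the trimmed RMS changes by < 1e-4 mm, or at 100
iterations. The RMS recorded at each correspondence stage is provably
non-increasing for a fixed trim fraction, and the last value is the
reported FRE. Degenerate geometry (correspondence covariance of rank
< 2) raises rather than returning an arbitrary rotation.

## 2.5D lesion segmentation

The seed slice is segmented by SRG around the seed voxel with tolerance
`3 × σ̂`, where `σ̂` is the slice's robust noise scale (1.4826 × MAD of
the residual against a 3×3 median filter — the median filter removes
anatomy so only pixel noise remains). The factor 3 admits ~99.7% of
in-region pixels under Gaussian noise while staying far below any
usable lesion/tissue contrast; smaller factors (e.g. 1.5) leave so many
in-lesion pixels out that the subsequent opening collapses the region.
An absolute tolerance override is available. After growing: one 3×3
opening, hole filling, and retention of components overlapping the grown
region (the grown region rather than the bare seeds, since opening may
erode a thin seed). The region criterion is then re-centred on the mean
of this first result and **frozen** for the whole propagation;
re-estimating it per slice lets the reference drift into surrounding
tissue and flood the volume. Propagation runs independently in +z and
−z: the distance-map core (strictly deeper than 2 mm — equivalent to
morphological erosion by a 2 mm disc) of each slice's result seeds the
next slice, and stops when a slice yields nothing or the stack boundary
is reached, which guarantees termination and a z-contiguous result.

## Phantom generator

The phantom emulates the study conditions end to end: an 80×128×160
volume at 1 mm isotropic spacing holding a supine chest section built as
an anterior height field — an elliptical torso cross-section (70 mm
half-width, 55 mm depth, flat posterior, mild recession toward the stack
ends), two Gaussian breast protrusions (amplitude 22 mm, σ ≈ 15 mm)
topped by a sharper 3 mm cosine nipple apex, ellipsoidal lesions
(radii 7–10 mm) in the parenchyma, an optional bright pad crescent
separated from the body and touching the posterior border, and additive
Gaussian noise (σ = 8 on a body intensity of 100, lesion 160 — a
CT-like contrast regime). The height-field construction gives a single
gradient sign change per breast and exact analytic ground truth (skin
mask, apex coordinates, lesion mask) before noise is added.

Scans sample the analytic surface where the outward normal lies within
a 120° coverage cone of the anterior axis (2,000 points, 1 mm isotropic
noise), then apply a true rigid transform of 15° rotation and 30 mm
translation — magnitudes held fixed across study cases while the axis
and direction are randomized, emulating scans "from different angles".
The Monte-Carlo study additionally jitters breast positions (±6 mm),
bump amplitude (±4 mm) and lesion geometry per case.

What the phantom does **not** model: HU calibration, beam hardening or
metal artifacts, breathing motion, tissue deformation between CT and
scan, realistic breast ptosis, or depth-sensor-specific error patterns
(quantization, edge flaring). Passing phantom studies therefore
demonstrates correctness of the algorithms under the stated geometric
and noise assumptions, not clinical-grade accuracy; the clinical numbers
this pipeline family reports (skin Dice ≈ 98%, nipple error ≈ 2.8 mm,
FRE ≈ 3–5 mm) require patient data that no synthetic stand-in
reproduces.

## Problem sizes and determinism

The study default is 20 cases of the 80×128×160 phantom with
8,000-face meshes — small enough that the whole suite and the
acceptance study each run in a couple of minutes, large enough that all
structures are resolved at the stated accuracies. Every random draw
flows from an explicit seed through `numpy.random.default_rng`; the
pipeline itself contains no randomness, so identical inputs give
byte-identical masks and transforms (asserted by test).

## Known limitations

* Rigid registration only; deformation between imaging and surgery is
  out of scope.
* The symmetry score for nipple pairing is one reading of an
  under-specified published description (see above).
* Skin segmentation assumes the body is the bright connected component
  nearest the slice centre; unusual fields of view (arms-up partial
  coverage, very off-centre patients) would need the seed rules adjusted.
* The decimator prioritizes determinism and robustness over the last
  factor of speed; extremely large meshes (millions of faces) would
  benefit from a heap-based implementation.
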
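# Methods

## The inference problem

High-speed AFM records, per pixel, the height at which a vibrating probe
tip first touches the specimen.  The image is therefore a dilation of
the true surface by the (unknown) tip shape: a blunt tip widens every
feature and fills every groove.  Recovering a molecule's placement from
an image without knowing the tip — or the tip without knowing the
placement — is ill-posed; this package infers both at once by exhaustive
search: for every candidate combination of molecular orientation,
translation, vertical offset and parametric tip shape, a pseudo-AFM
image is simulated and scored against the reference, and the lowest-cost
combination wins.

## Probe model and image simulation

The tip is a hemisphere of radius `r` capped onto a circular cone
frustum whose flank makes the half-apex angle `theta` with the vertical.
The frustum is treated as extending upward indefinitely: specimens are
tens of nm tall at most, far below any realistic frustum top.  Atoms are
hard spheres; by default per-element van der Waals radii
(C 0.170, N 0.155, O 0.152, S 0.180, H 0.120, P 0.180 nm), with a
uniform override.  All internal lengths are nm; the PDB boundary
converts from Angstrom.

For a pixel whose centre passes at lateral distance `d` from an atom at
height `z_a` with radius `r_a`, the apex height at first contact has two
regimes, continuous at `d = (r + r_a) cos(theta)`:

    sphere:  z_tip = z_a + sqrt((r + r_a)^2 - d^2) - r
    cone:    z_tip = z_a + (r + r_a - d cos(theta)) / sin(theta) - r

The pixel height is the maximum over atoms, floored at the stage
(z = 0).  These closed forms are verified in the test suite against a
purely geometric oracle that descends a densely sampled tip surface to
first contact (bisection to 1e-4 nm); agreement is required to 1e-3 nm
across the probe grid.

Pixel (i, j) has its centre at `origin + ((j+0.5), (i+0.5)) *
pixel_size`, row 0 at the lowest Y; auto-chosen frames snap the origin
to whole pixels so that whole-pixel translations of the molecule shift
the image exactly.  Synthetic reference images add spatially independent
Gaussian noise (default sd 0.3 nm, the level typical of high-speed AFM
background regions); noise is not clipped at zero because experimental
backgrounds are symmetric about the stage plane.

## Similarity scores and trimming

Scores are evaluated on both images cut to the minimum bounding
rectangle of the *pseudo* image's non-zero pixels, so a noisy reference
background cannot attract the molecule; only the simulation decides
which pixels count.  Generated images are exactly zero on the stage, so
"non-zero" needs no epsilon.  Four costs are provided:

* cosine: `1 - <sim, ref> / (|sim| |ref|)` — scale-invariant, sees
  absolute heights; range [0, 1].
* correlation: `1 - Pearson(sim, ref)` — scale- and shift-invariant;
  range [0, 2].
* pixel-RMSD: root-mean-square pixel difference (nm) — sensitive to
  scale and shift.
* penalty: per pixel `+k_penalty` where the simulation pokes above the
  reference, `-k_reward` within a band of `thickness` below it, 0
  further down (defaults 10.0 / 1.0 / 1.2 nm).  The penalty branch wins
  where the two conditions overlap, so the reward band is
  `ref - thickness < sim <= ref`.

Normalizing both windows to unit Euclidean norm ties the first and third
scores together: `rmsd(normalized)^2 = (2/N) * cosine_cost`, asserted to
1e-12 in a property test.  Windows on which a score is undefined (zero
norm or zero variance) cost `+inf`, so the search never selects them.

## Search grids

Orientations combine near-uniform sphere directions with spins about the
new Z axis, both at an angular step that divides 360 into a multiple of
4 (default 10 degrees; the scaled-down validation uses 30).  Latitude
rings sit at multiples of the step; ring `n` carries `4n` azimuths, so
the equator is divided at exactly the step (e.g. 614 directions x 36
spins at 10 degrees; 24 rotations — the octahedral group — at 90).  The
source description of the ring population ("n components") is also
available (`ring_multiplier=1`), but `4n` is the default because only it
keeps the point spacing near-uniform.  Spins are applied uniformly,
poles included (redundant but simple).

After each candidate rotation the model is re-grounded
(`min(z - radius) = 0`) before rendering; without this most orientations
would float above or clip through the stage.  Translations step by one
pixel over every placement that keeps the trimmed window inside the
reference.  Vertical offsets (step 0.064 nm, finer than instrument
Z resolution) are scanned only when the reference contains a pixel
taller than every pseudo-image pixel, and act by lifting the non-zero
pseudo-image pixels rather than re-rendering.  Probe grids default to
radii {0.5, 1, 2, 3, 4, 5} nm and half-apex angles {5 ... 30} degrees,
the range of real tips.

Window sums over all translations are computed directly with stride
tricks (no FFT — the method is deliberately a plain exhaustive scan),
and all requested scores share one pass over the renders.  Ties are
broken deterministically in enumeration order: orientation index, then
row-major offset, then Z index, then probe index.  A tiny-instance test
checks the whole search against a scalar quadruple loop.

## Grounding and structure-RMSD

Molecules are initially laid on the stage on the largest face of their
PCA-based oriented bounding box (axis 1 = first principal component,
axis 2 = second component re-orthogonalized, axis 3 = their cross
product), mimicking weak physisorption.  On ties the earlier principal
axis stays horizontal.  Placement error is reported as structure-RMSD
without re-superposition, so orientation and translation errors count;
with a 10-degree grid the best reachable RMSD is of the order of the
half step sizes.  For filaments fitted as sub-structures, the RMSD is
the minimum over all consecutive monomer windows of the longer truth
filament.

## Twin experiments

A twin experiment plants a ground truth (grounded placement + probe
shape), renders the reference, adds `n` independent noise realizations
(per-replicate seeds `seed + 1 + i`), scrambles the template by random
rotations about X, Y and Z (once per experiment, so replicates differ
only in noise), and runs the search on each replicate.  Recovery means
the global cost minimum lands exactly on the truth probe's grid cell.
With zero noise and the truth on-grid, cosine, correlation and
pixel-RMSD must recover everything exactly; the penalty score is exempt
because it systematically favours smaller probes (nothing in it rewards
reproducing tip dilation, and smaller tips generate fewer forbidden
pixels) — the validation asserts this artifact rather than hiding it.

## Synthetic generators

`make_blob` emulates a large multi-domain protein: atoms are grouped
into Gaussian clumps (default 10 clumps, sd 1.2 nm) whose centres fill
an anisotropic ellipsoid, rescaled so the cloud spans the requested
extents exactly.  The clumps matter: a smooth uniform ellipsoid is
nearly centrosymmetric, its image barely constrains orientation, and
probe-shape inference on it is ambiguous in a way no real corrugated
protein target is.  `make_filament` repeats a monomer helically
(default rise 2.75 nm per unit, actin-like in scale only).  What these
stand-ins do not emulate: real side-chain texture, conformational
flexibility (the rigid-body assumption is exact here but not for real
molecules), tip contamination, or scan-line artifacts — so passing twin
tests demonstrate the inference machinery, not performance on
experimental data.

The scaled-down validation run uses a 150-sphere blob spanning
12 x 8 x 5 nm (sphere radius 0.5 nm), truth probe 3 nm / 20 degrees,
1 nm pixels, noise sd 0.3 nm, 10 replicates, a 30-degree orientation
grid and a 12-point probe grid — sizes chosen so a complete
twin experiment runs in a few minutes on one core while keeping the
molecule/noise/probe regime of a realistic large-target experiment.

## Stage correction and rescaling

Experimental frames are flattened by least-squares fitting a tilted
plane `z = ax + by + c` over background pixels (manual rectangles, or a
low-height-quantile fallback — note the quantile mask conditions on the
noisy heights and slightly biases the residual sd low) and subtracting
it; heights are not clipped afterwards.  The background noise level is
the residual sd about the fitted plane.  `affine_rescale` finds the
least-squares uniform scale/shift of one image onto another (optionally
shift-only, scale-only, or with the shift constrained non-positive),
used for post-hoc comparison of best-fit images.

## Blind tip reconstruction

For comparison with the parametric inference, the classic morphological
blind tip estimate is included.  Writing `P(d) <= 0` for the reflected
tip relative to its apex, every pixel `y` hides a contact point `u`
(within the tip window, with `i(u) >= i(y) - P(y - u)`) whose surface
height is at least `i(y)`; combining with the dilation inequality gives,
for every `y` and offset `d`,

    P(d) <= max_{u in U(y)} i(u + d) - i(y) + tau

where `U(y)` is the feasible contact set under the current estimate and
`tau` a noise threshold.  Iterating from a flat tip to the fixed point
yields a monotonically sharpening estimate that never becomes sharper
than the true tip.  The estimate is stored as depth below the apex
(>= 0, apex 0).  The threshold trades sharpness for noise robustness;
the tests assert the outer-bound property on clean spike images, exact
recovery there, and monotone blunting with the threshold — the
ambiguity that motivates fitting a parametric tip instead.

## Numerical choices and limitations

* Costs are accumulated with vectorized sums; the naive-loop equality
  test allows 1e-10 for float reassociation while requiring the discrete
  argmin to match exactly.
* Grounding uses SVD-based PCA with deterministic axis-sign conventions
  so repeated grounding is idempotent to 1e-9 nm.
* Degenerate inputs raise typed errors (empty models, collinear point
  sets, undefined scores, oversized windows) rather than propagating
  NaNs.
* The search cost grows as orientations x probes x pixels; tens of
  minutes at the default 10-degree grid for protein-sized inputs, which
  is the method's intended operating point.  No stochastic or
  FFT-accelerated shortcut is provided by design.
* Flexible molecules violate the rigid-body assumption; the fitted probe
  then absorbs conformational spread and the inferred tip can be
  distorted.  Multi-molecule frames are out of scope.
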
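# Methods

This note records the models, numerical choices and limitations behind
`myogape`, in the order the pipeline runs them.

## Coordinate conventions

All coordinates are millimetres in a right-handed frame. No axis convention
is assumed by the restoration operators: the sagittal plane is whatever
`fit_symmetry_plane` returns. The synthetic generator uses x rostral,
y left-lateral, z dorsal, with the symmetry plane at y = 0.

## Symmetry plane

The plane minimises Σᵢ ‖reflect(lᵢ) − rᵢ‖² over bilateral landmark pairs;
midline landmarks contribute squared point-to-plane distances. The solver
seeds the normal with the dominant (sign-aligned) direction of the pair
difference vectors (SVD) and the offset with the mean pair midpoint, then
refines normal spherical angles + offset with Nelder–Mead (xatol 1e-12).
The closed-form seed is returned if refinement fails to improve it, so
perfectly symmetric inputs recover their plane to machine precision. Fewer
than three non-midline pairs, or pairs that all coincide, are rejected.

## Retrodeformation (symmetrising warp)

A 3D thin-plate-spline interpolant (biharmonic kernel U(r) = r with affine
part) maps each landmark to its symmetrised target: for a pair (l, r) the
target of l is the midpoint of l and reflect(r), and the target of r is its
mirror image; midline landmarks project onto the plane. Both sides therefore
move toward the symmetric mean shape — a deliberate choice where the
alternative (warping one side onto the other) would privilege whichever side
is arbitrarily labelled "preserved". With the default zero ridge term the
warp interpolates controls exactly (≤ 1e-6 mm); an optional smoothing
parameter trades exactness for lower bending energy on noisy landmarks.
Because the TPS reproduces affine maps exactly, a purely affine (shear)
deformation is removed completely, which is what the recovery tests measure.
At least four non-coplanar controls are required; coplanar sets are rejected
as underdetermined.

## Rearticulation

Rigid fits use the Kabsch/Umeyama SVD solution with the determinant
correction, so a reflection is never returned even for mirrored targets
(those keep a nonzero residual by design). Assembly order is left to the
user/config: the package automates only the fit, since deciding which
articulation facets to trust is expert judgement.

## Fiber seeding

Up to 10 fibers per muscle. Endpoints are chosen on each attachment patch by
farthest-point sampling seeded at the point nearest the patch centroid, and
paired by rank of projection onto each patch's first principal axis, with the
two axes sign-aligned. Rank pairing (rather than nearest-neighbour) keeps
fibers from crossing on curved or offset patches. The procedure is fully
deterministic; the seed argument exists only for interface uniformity.

## Radius growth

One shared radius per muscle, grown in synchronous steps Δr (default 1% of
mandible anteroposterior length; all growth parameters overridable). A group
stops — keeping the radius of the triggering step — at the first of:

- **merge**: its capsule overlap graph becomes connected (requires ≥ 2
  fibers); merging halts growth rather than continuing as one body,
- **other muscle**: any capsule comes within `contact_tol` (default 0) of
  another group's capsule,
- **bone / orbit**: the fiber centreline comes within the grown radius +
  `contact_tol` of a bone surface or the eyeball sphere. Bone surface whose
  closest point lies within ε_att = 2Δr of the fiber's own endpoints is
  exempt, so a tube may reach the bone it attaches to.

Radii are additionally capped at the group's longest fiber rest length,
guaranteeing termination. Bone distances are exact point-to-triangle
distances evaluated at 96 samples along each centreline and precomputed once
(fibers do not move during growth); sampling the centreline rather than the
bone surface keeps the analytic fixtures (fiber 3 mm above a plane stops at
r = 3.0) exact to the step size. Growth is monotone, and halving Δr can only
lower a final radius (by at most one coarse step).

## Volumes

Capsule-union volume is computed on a voxel grid (default pitch =
radius / 5, hard error above radius / 2). Voxels are scored by linear
surface coverage — clip((r − d)/pitch + ½, 0, 1) of the voxel volume, where
d is the distance to the nearest capsule axis — which antialiases the
boundary and removes the grid-alignment bias of hard centre counting (worst
case observed ≈ 3.5% for an axis-aligned capsule; ≤ 1% with coverage
weighting at the default pitch). Fractions are normalised to sum to exactly
100%; the report is per muscle per side.

## Eyeball sphere

The orbit obstacle is the largest sphere whose radius — the smaller of the
distance to the orbit rim points and to any bone surface — is maximised over
centres constrained to the convex hull of the rim points; for a planar rim
the optimisation runs within the rim plane, so the sphere sits in the
aperture instead of bulging out of it (an inflated-hull constraint would let
the centre drift off-plane and report a spuriously large radius).
Deterministic Nelder–Mead from the rim centroid.

## Gape sweep

The mandible's sole degree of freedom is rotation about the hinge through
the jaw joints (for bilateral data, the line through the two condyle
landmarks). Positive θ opens the jaw; `HingeAxis.oriented` fixes the sign by
checking that a rostral mandibular reference point moves away from the
cranium. Strain is evaluated on the fiber centreline only — the cranial
endpoint fixed, the mandibular endpoint rigidly rotated — so the capsule
radius does not affect strain, and the fiber does not bend mid-length (a
skinned-armature deformation would; the rigid-endpoint model is the recorded
simplification). Rest length is the closed-jaw (θ = 0) length, and the
closed-jaw strain is returned as exactly 100% by definition. The grid is
θ_min + kΔθ with integer k (default 0–50° by 0.5°, 101 angles, no
accumulation drift).

Bands: green < 130% (optimal tetanic tension), yellow 130–170%, red > 170%
(maximal tetanic tension exceeded). Both printed boundaries are assigned to
yellow. Maximum gape is the largest grid angle at which every selected
fiber's strain ≤ 170%; if a fiber is already past the limit at the start of
the sweep the smallest grid angle is returned with a warning flag.

An independent cylindrical-coordinate closed form,
L(θ)² = Δz² + r₀² + r₁² − 2 r₀ r₁ cos(Δφ + θ), is shipped alongside the
rotation-based implementation and used as its oracle in the tests.

## Synthetic specimen

The generator emulates a ~60 mm cynodont-grade skull: braincase and snout
ellipsoids, a two-segment zygomatic arch bar, pterygoid flanges; mandible
from a tapering ramus tube, coronoid blade, dentary angle and condyle. Left
parts are mirrored exactly, so landmark symmetry is exact to machine
precision and the fitted plane has zero residual by construction. It provides
14 bilateral landmark pairs, 3 midline landmarks, origin/insertion patches
(12 points each, sampled deterministically on the part surfaces) for the six
core adductor subdivisions per side, and the condyle-to-condyle hinge.
m. zygomaticomandibularis is not modelled. Clearances between the coronoid
blade, braincase wall and arch are deliberately tight (0.5–0.8 mm) so bone
contact, not merging, usually terminates growth — as in a real adductor
chamber.

What the generator does **not** emulate: real bone surface texture and
muscle scars, tooth rows, cranial sutures, a fossa-shaped temporal chamber,
postdentary elements, or any specific taxon's proportions. Passing tests
therefore demonstrate the correctness of the operators and the pipeline
plumbing on topologically faithful geometry — not anatomical accuracy for
any real specimen, whose published gape and volume values additionally
depend on fossil meshes that are not redistributable.

The taphonomy injector applies a known invertible shear, deletes the
most-lateral fraction of one side's faces, and adds seeded Gaussian vertex
noise; it returns the exact inverse shear and deleted-face mask so
restoration can be scored against ground truth.

## Problem sizes and determinism

Default test/acceptance sizes: ~1800-face cranium, ~1300-face mandible,
6 muscles × 3–5 fibers, 101-angle sweeps, 0.2 mm voxel pitch on unit-radius
fixtures, 10⁶ Monte-Carlo samples for the union-volume oracle — sizes chosen
so the full pipeline runs in seconds while keeping every oracle comparison
well inside its tolerance. All randomness (patch sampling, noise, Monte
Carlo) flows from explicit integer seeds; the sweep and growth stages are
seed-free and bit-reproducible, and rerunning the pipeline with one config
yields byte-identical CSV outputs.

## Known limitations

- Capsules are straight: no wrapping around bone, no pennation, and no
  physiological cross-section or force estimation.
- Strain ignores the mid-fiber deformation a skinned armature would add.
- The jaw model is a single hinge: no propalinal translation, no cranial
  kinesis, no bite-force or moment-arm mechanics.
- Retrodeformation assumes deformation is smooth and landmark-visible;
  brittle fracture or element displacement must be handled by rearticulation
  instead.
- Growth stop conditions are evaluated against fixed centrelines; muscles do
  not deflect around obstacles they meet.
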
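"""Capsule-based jaw adductor reconstruction.

Each adductor subdivision is modelled as up to 10 straight origin-to-insertion
"muscle tubes" (capsules: cylinders with hemispherical caps) spanning the
attachment patches identified on the cranium and mandible.  All tubes of one
muscle share a radius, grown synchronously in small steps until the first of
three stop conditions: the muscle's own tubes merge into one connected body,
a tube meets a different muscle, or a tube reaches bone (or the orbital
eyeball sphere).  Volumes of the resulting capsule unions are estimated by
voxel counting and reported absolutely (mm^3) and as fractions of the total
adductor volume.

The controlled muscle vocabulary covers the six core subdivisions of the
cynodont-to-mammaliaform adductor complex (masseter, temporalis and
pterygoideus, each with two parts) plus the plesiomorphic pseudotemporalis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.optimize import minimize
from scipy.spatial import ConvexHull, Delaunay

from .geometry_core import (GeometryError, SymmetryPlane, TriangleMesh,
                            point_mesh_distance)

#: controlled adductor-subdivision names
MUSCLE_NAMES = (
    "m. mass pro",   # masseter pars profunda
    "m. mass sup",   # masseter pars superficialis
    "m. temp pro",   # temporalis pars profunda
    "m. temp sup",   # temporalis pars superficialis
    "m. ptg int",    # pterygoideus internus
    "m. ptg ext",    # pterygoideus externus
    "m. psd pro",    # pseudotemporalis pars profunda
    "m. psd sup",    # pseudotemporalis pars superficialis
)

CORE_MUSCLES = MUSCLE_NAMES[:6]

MAX_FIBERS = 10
SURFACE_TOL = 0.5  # mm: attachment points must lie this close to their bone


class MuscleError(ValueError):
    pass


@dataclass
class AttachmentPatch:
    """Sampled points of one muscle's origin or insertion on a bone surface."""

    muscle: str
    role: str  # "origin" | "insertion"
    points: np.ndarray
    bone: str = ""
    side: str = "L"

    def __post_init__(self) -> None:
        if self.muscle not in MUSCLE_NAMES:
            raise MuscleError(f"unknown muscle name {self.muscle!r}")
        if self.role not in ("origin", "insertion"):
            raise MuscleError(f"role must be origin or insertion, got {self.role!r}")
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) == 0:
            raise MuscleError("empty attachment patch")

    def validate_on_bone(self, mesh: TriangleMesh, tol: float = SURFACE_TOL) -> None:
        """Check every patch point lies within `tol` mm of the bone surface."""
        dist = point_mesh_distance(self.points, mesh)
        if np.any(dist > tol):
            raise MuscleError(
                f"{self.muscle} {self.role}: point {float(dist.max()):.3f} mm "
                f"off bone {mesh.name!r} (tol {tol} mm)")

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


@dataclass
class MuscleFiber:
    """One straight muscle tube from a cranial origin to a mandibular insertion."""

    origin: np.ndarray
    insertion: np.ndarray
    radius: float = 0.0
    muscle: str = ""
    id: int = 0

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.insertion = np.asarray(self.insertion, dtype=float).reshape(3)
        if self.rest_length <= 0:
            raise MuscleError(f"fiber {self.id}: zero rest length")
        if self.radius < 0:
            raise MuscleError(f"fiber {self.id}: negative radius")

    @property
    def rest_length(self) -> float:
        return float(np.linalg.norm(self.origin - self.insertion))


@dataclass
class MuscleGroup:
    """All fibers of one adductor subdivision on one side, sharing a radius."""

    muscle: str
    fibers: list[MuscleFiber]
    side: str = "L"

    def __post_init__(self) -> None:
        if not 1 <= len(self.fibers) <= MAX_FIBERS:
            raise MuscleError(f"{self.muscle}: need 1..{MAX_FIBERS} fibers")
        radii = {f.radius for f in self.fibers}
        if len(radii) > 1:
            raise MuscleError(f"{self.muscle}: fibers must share one radius")

    @property
    def radius(self) -> float:
        return self.fibers[0].radius

    def set_radius(self, r: float) -> None:
        for f in self.fibers:
            f.radius = r

    def segments(self) -> np.ndarray:
        """(n, 2, 3) array of fiber endpoint pairs."""
        return np.array([[f.origin, f.insertion] for f in self.fibers])


@dataclass
class EyeballSphere:
    """Orbital eyeball obstacle: muscles may not grow into the orbit."""

    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if self.radius <= 0:
            raise MuscleError("eyeball radius must be positive")


@dataclass
class VolumeReport:
    """Absolute and relative adductor volumes, per muscle (one side)."""

    muscles: list[str]
    sides: list[str]
    volumes_mm3: np.ndarray
    fractions_pct: np.ndarray
    pitch_mm: float

    def __post_init__(self) -> None:
        self.volumes_mm3 = np.asarray(self.volumes_mm3, dtype=float)
        self.fractions_pct = np.asarray(self.fractions_pct, dtype=float)
        if abs(self.fractions_pct.sum() - 100.0) > 1e-6:
            raise MuscleError("volume fractions do not sum to 100%")


# ---------------------------------------------------------------------------
# fiber seeding
# ---------------------------------------------------------------------------


def _farthest_point_sample(points: np.ndarray, n: int) -> np.ndarray:
    """Indices of n points by farthest-point sampling, seeded at the point
    nearest the patch centroid."""
    d2c = np.linalg.norm(points - points.mean(axis=0), axis=1)
    chosen = [int(np.argmin(d2c))]
    dist = np.linalg.norm(points - points[chosen[0]], axis=1)
    while len(chosen) < n:
        nxt = int(np.argmax(dist))
        chosen.append(nxt)
        dist = np.minimum(dist, np.linalg.norm(points - points[nxt], axis=1))
    return np.array(chosen)


def _principal_axis(points: np.ndarray) -> np.ndarray:
    c = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    return vt[0]


def seed_fibers(origin: AttachmentPatch, insertion: AttachmentPatch,
                n: int, seed: int = 0) -> list[MuscleFiber]:
    """Place up to `n` <= 10 fibers covering both attachment patches.

    Points are chosen on each patch by farthest-point sampling (first point =
    the patch point nearest its centroid) and paired by rank of their
    projection onto each patch's first principal axis; the two axes are
    sign-aligned so the pairing is order-preserving and fibers do not cross.
    Deterministic for fixed inputs; `seed` is accepted for interface
    uniformity but the procedure involves no randomness.
    """
    if n < 1 or n > MAX_FIBERS:
        raise MuscleError(f"fiber count must be 1..{MAX_FIBERS}")
    if origin.muscle != insertion.muscle:
        raise MuscleError("origin and insertion patches belong to different muscles")
    n_eff = min(n, len(origin.points), len(insertion.points))
    if n_eff < n:
        warnings.warn(f"{origin.muscle}: patch has fewer than {n} points; "
                      f"using {n_eff}", stacklevel=2)
    oi = _farthest_point_sample(origin.points, n_eff)
    ii = _farthest_point_sample(insertion.points, n_eff)
    opts, ipts = origin.points[oi], insertion.points[ii]
    if n_eff == 1:
        return [MuscleFiber(opts[0], ipts[0], 0.0, origin.muscle, 0)]
    ax_o = _principal_axis(opts)
    ax_i = _principal_axis(ipts)
    # sign-align the insertion axis with the origin axis so rank pairing
    # preserves order along the shared anatomical direction
    if np.dot(ax_o, ax_i) < 0:
        ax_i = -ax_i
    rank_o = np.argsort(opts @ ax_o, kind="stable")
    rank_i = np.argsort(ipts @ ax_i, kind="stable")
    return [MuscleFiber(opts[a], ipts[b], 0.0, origin.muscle, k)
            for k, (a, b) in enumerate(zip(rank_o, rank_i))]


# ---------------------------------------------------------------------------
# capsule contact primitives
# ---------------------------------------------------------------------------


def segment_distance(p1, q1, p2, q2) -> float:
    """Minimal Euclidean distance between segments [p1,q1] and [p2,q2] (mm).

    Closed-form clamped solution of the two-parameter quadratic; handles
    degenerate (point) segments and parallel axes.
    """
    p1 = np.asarray(p1, float); q1 = np.asarray(q1, float)
    p2 = np.asarray(p2, float); q2 = np.asarray(q2, float)
    d1, d2, r = q1 - p1, q2 - p2, p1 - p2
    a = float(d1 @ d1); e = float(d2 @ d2); f = float(d2 @ r)
    if a <= 1e-30 and e <= 1e-30:
        return float(np.linalg.norm(r))
    if a <= 1e-30:
        s, t = 0.0, np.clip(f / e, 0.0, 1.0)
    else:
        c = float(d1 @ r)
        if e <= 1e-30:
            t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
        else:
            b = float(d1 @ d2)
            denom = a * e - b * b
            s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > 1e-30 else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
            elif t > 1.0:
                t, s = 1.0, np.clip((b - c) / a, 0.0, 1.0)
    return float(np.linalg.norm(p1 + s * d1 - (p2 + t * d2)))


def point_segment_distance(points: np.ndarray, p: np.ndarray, q: np.ndarray
                           ) -> np.ndarray:
    """Distances from an (n,3) point set to segment [p,q], vectorised."""
    pts = np.asarray(points, float).reshape(-1, 3)
    d = q - p
    denom = float(d @ d)
    if denom <= 1e-30:
        return np.linalg.norm(pts - p, axis=1)
    t = np.clip((pts - p) @ d / denom, 0.0, 1.0)
    return np.linalg.norm(pts - (p + t[:, None] * d), axis=1)


# ---------------------------------------------------------------------------
# radius growth under the three stop conditions
# ---------------------------------------------------------------------------


def _group_merged(group: MuscleGroup, r: float) -> bool:
    """True when the group's capsules form one connected overlap component."""
    n = len(group.fibers)
    if n < 2:
        return False
    seg = group.segments()
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if segment_distance(seg[i, 0], seg[i, 1], seg[j, 0], seg[j, 1]) <= 2 * r:
                adj[i, j] = adj[j, i] = True
    # connectivity by BFS
    seen = {0}
    stack = [0]
    while stack:
        k = stack.pop()
        for m in np.nonzero(adj[k])[0]:
            if m not in seen:
                seen.add(int(m))
                stack.append(int(m))
    return len(seen) == n


def _min_intergroup_gap(a: MuscleGroup, b: MuscleGroup) -> float:
    """Min centreline distance between two groups' fibers."""
    best = np.inf
    for fa in a.fibers:
        for fb in b.fibers:
            best = min(best, segment_distance(fa.origin, fa.insertion,
                                              fb.origin, fb.insertion))
    return best


def _fiber_bone_distance(fiber: MuscleFiber, bones: list[trimesh.Trimesh],
                         eps_att: float, n_samples: int = 96) -> float:
    """Min distance from the fiber centreline to the bone surfaces, ignoring
    surface within `eps_att` of the fiber's own endpoints (so a tube may meet
    the bone it attaches to).

    Exact point-to-mesh distances are evaluated at sample points along the
    centreline; samples whose nearest surface point falls inside the
    attachment exclusion zone are discarded.
    """
    t = np.linspace(0.0, 1.0, n_samples)
    pts = fiber.origin + t[:, None] * (fiber.insertion - fiber.origin)
    best = np.inf
    for tm in bones:
        closest, dist, _ = trimesh.proximity.closest_point_naive(tm, pts)
        d_end = np.minimum(np.linalg.norm(closest - fiber.origin, axis=1),
                           np.linalg.norm(closest - fiber.insertion, axis=1))
        keep = d_end > eps_att
        if keep.any():
            best = min(best, float(dist[keep].min()))
    return best


def grow_radii(groups: list[MuscleGroup], bones: list[TriangleMesh],
               obstacles: list[EyeballSphere], dr: float,
               contact_tol: float = 0.0, eps_att: float | None = None,
               fiber_samples: int = 96, seed: int = 0) -> list[MuscleGroup]:
    """Grow each group's shared radius in synchronous steps of `dr`.

    A group stops at the first step where any of the three conditions holds:

    (a) merge — its own capsules form a single connected body (requires >=2
        fibers),
    (b) another muscle — any capsule comes within `contact_tol` of a capsule
        of a different group,
    (c) bone/orbit — any capsule comes within `contact_tol` of a bone mesh or
        the eyeball sphere, excluding bone surface within `eps_att`
        (default 2*dr) of that fiber's own endpoints.

    The final radius of a stopped group includes the triggering step.  Growth
    of the remaining groups continues; every group is additionally capped at
    its longest fiber's rest length, so the loop always terminates.  Groups
    are modified in place and returned.
    """
    if dr <= 0:
        raise MuscleError("radius increment dr must be positive")
    if eps_att is None:
        eps_att = 2.0 * dr
    tms = [b.to_trimesh() for b in bones]

    # precompute static distances: bone/obstacle per fiber (fibers are fixed,
    # only radii grow, so one exact distance per fiber suffices)
    bone_dist: dict[tuple[int, int], float] = {}
    for gi, g in enumerate(groups):
        for fi, f in enumerate(g.fibers):
            d = _fiber_bone_distance(f, tms, eps_att, fiber_samples) if tms else np.inf
            for ob in obstacles:
                d = min(d, float(point_segment_distance(
                    ob.center[None, :], f.origin, f.insertion)[0]) - ob.radius)
            bone_dist[(gi, fi)] = d

    active = [True] * len(groups)
    caps = [max(f.rest_length for f in g.fibers) for g in groups]
    while any(active):
        for gi, g in enumerate(groups):
            if not active[gi]:
                continue
            r = g.radius + dr
            g.set_radius(r)
            stop = False
            if _group_merged(g, r):                                   # (a)
                stop = True
            if not stop:                                              # (b)
                for gj, h in enumerate(groups):
                    if gj == gi:
                        continue
                    if _min_intergroup_gap(g, h) - r - h.radius <= contact_tol:
                        stop = True
                        break
            if not stop:                                              # (c)
                for fi in range(len(g.fibers)):
                    if bone_dist[(gi, fi)] - r <= contact_tol:
                        stop = True
                        break
            if r >= caps[gi]:
                g.set_radius(caps[gi])
                stop = True
            if stop:
                active[gi] = False
    return groups


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------


def muscle_volume(group: MuscleGroup, pitch: float) -> float:
    """Volume (mm^3) of the union of the group's capsules on a voxel grid.

    Voxels are scored by linear surface coverage: a voxel whose centre lies a
    distance d from the nearest capsule axis contributes
    clip((r - d)/pitch + 1/2, 0, 1) of its volume, which antialiases the
    capsule boundary and removes the grid-alignment bias of hard
    centre-in/centre-out counting.  Requires pitch <= radius/2.
    """
    r = group.radius
    if r <= 0:
        raise MuscleError("muscle_volume: radii must be grown first")
    if pitch <= 0:
        raise MuscleError("voxel pitch must be positive")
    if pitch > r / 2:
        raise MuscleError("resolution too coarse: pitch must be <= radius/2")
    segs = group.segments()
    lo = segs.reshape(-1, 3).min(axis=0) - r - pitch
    hi = segs.reshape(-1, 3).max(axis=0) + r + pitch
    axes = [np.arange(lo[k] + pitch / 2, hi[k], pitch) for k in range(3)]
    yz = np.stack(np.meshgrid(axes[1], axes[2], indexing="ij"), axis=-1).reshape(-1, 2)
    total = 0.0
    for x in axes[0]:  # slab over x to bound memory
        if not any(min(p[0], q[0]) - r - pitch <= x <= max(p[0], q[0]) + r + pitch
                   for p, q in segs):
            continue
        centers = np.column_stack([np.full(len(yz), x), yz])
        dmin = np.full(len(centers), np.inf)
        for p, q in segs:
            dmin = np.minimum(dmin, point_segment_distance(centers, p, q))
        total += float(np.clip((r - dmin) / pitch + 0.5, 0.0, 1.0).sum())
    return total * pitch ** 3


def capsule_volume_closed_form(length: float, r: float) -> float:
    """Exact volume of one capsule: pi r^2 L + (4/3) pi r^3."""
    return float(np.pi * r * r * length + 4.0 / 3.0 * np.pi * r ** 3)


def relative_volumes(groups: list[MuscleGroup], pitch: float) -> VolumeReport:
    """Per-muscle absolute volumes and fractions of total adductor volume."""
    if not groups:
        raise MuscleError("relative_volumes: no muscle groups")
    vols = np.array([muscle_volume(g, pitch) for g in groups])
    total = vols.sum()
    if total <= 0:
        raise MuscleError("relative_volumes: zero total volume")
    frac = 100.0 * vols / total
    # remove last-digit float drift so fractions sum to exactly 100
    frac[-1] = 100.0 - frac[:-1].sum()
    return VolumeReport([g.muscle for g in groups], [g.side for g in groups],
                        vols, frac, pitch)


# ---------------------------------------------------------------------------
# fiber orientation
# ---------------------------------------------------------------------------


def fiber_orientation(fiber: MuscleFiber, plane: SymmetryPlane,
                      horizontal: np.ndarray) -> float:
    """Inclination (degrees, 0..90) of the fiber in sagittal projection.

    The fiber axis is projected into the symmetry plane and the unsigned angle
    to the horizontal reference direction (also projected) is returned; ~45
    degrees is the anteroposteriorly diagonal masseter orientation typical of
    mammaliaforms.
    """
    n = plane.normal
    h = np.asarray(horizontal, dtype=float).reshape(3)
    h = h - (h @ n) * n
    if np.linalg.norm(h) < 1e-12:
        raise MuscleError("horizontal reference parallel to the plane normal")
    h = h / np.linalg.norm(h)
    axis = fiber.insertion - fiber.origin
    axis = axis - (axis @ n) * n
    if np.linalg.norm(axis) < 1e-12:
        raise MuscleError("orientation undefined in sagittal projection")
    axis = axis / np.linalg.norm(axis)
    ang = np.degrees(np.arccos(np.clip(abs(axis @ h), -1.0, 1.0)))
    return float(ang)


# ---------------------------------------------------------------------------
# orbital eyeball
# ---------------------------------------------------------------------------


def fit_eyeball(orbit_points: np.ndarray, bones: list[TriangleMesh]) -> EyeballSphere:
    """Largest sphere fitting tightly into the orbit.

    Maximises the sphere radius — the smaller of the distance to the orbit rim
    points and the distance to any bone surface — over centres constrained to
    the convex hull of the rim points (for a planar rim, the optimisation runs
    within the rim plane, so the sphere sits in the aperture rather than
    bulging out of it).  Deterministic local optimisation started from the rim
    centroid.
    """
    rim = np.asarray(orbit_points, dtype=float).reshape(-1, 3)
    if len(rim) < 4:
        raise MuscleError("fit_eyeball: need >=4 orbit rim points")
    centroid = rim.mean(axis=0)
    tms = [b.to_trimesh() for b in bones]

    centered = rim - centroid
    rank = int(np.linalg.matrix_rank(centered, tol=1e-9))
    if rank >= 3:
        basis = np.eye(3)
        proj = centered
    else:
        # planar rim: optimise within the rim's best-fit plane
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        basis = vt[:2].T  # (3, 2)
        proj = centered @ basis
    hull_dln = Delaunay(proj[ConvexHull(proj).vertices])

    def center_of(x: np.ndarray) -> np.ndarray:
        return centroid + basis @ x

    def radius_at(c: np.ndarray) -> float:
        r = float(np.linalg.norm(rim - c, axis=1).min())
        for tm in tms:
            r = min(r, float(point_mesh_distance(c[None, :], tm)[0]))
        return r

    def neg(x: np.ndarray) -> float:
        if hull_dln.find_simplex(x) < 0:
            return float(np.linalg.norm(x)) + 1.0  # outside: worse than any radius
        return -radius_at(center_of(x))

    x0 = np.zeros(basis.shape[1])
    res = minimize(neg, x0, method="Nelder-Mead",
                   options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 4000})
    best = res.x if neg(res.x) <= neg(x0) else x0
    c = center_of(best)
    r = radius_at(c)
    if r <= 0:
        raise MuscleError("fit_eyeball: no positive-radius sphere found")
    return EyeballSphere(c, r)
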
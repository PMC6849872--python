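"""Deterministic synthetic skull/jaw scenes for pipeline testing.

Fossil CT meshes are rarely redistributable, so every stage of the pipeline is
exercised on generated geometry instead: a bilaterally symmetric cynodont-grade
cranium (braincase + snout ellipsoids, zygomatic arch bar, pterygoid flange)
and mandible (ramus tube, coronoid blade, dentary angle, condyle), with
bilateral landmarks, attachment patches for the six core adductor subdivisions
and a mediolateral hinge through the condyles.  No anatomical fidelity is
claimed beyond the topological relations the pipeline needs (arch lateral to
the coronoid, pterygoid medial, condyle posterior).

A taphonomy injector applies a known shear, unilateral face loss and vertex
noise, returning the exact ground truth so restoration operators can be scored
against it.  Closed-form fiber scenarios provide analytic strain curves for
the gape sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .gape_strain import HingeAxis
from .geometry_core import GeometryError, LandmarkPair, TriangleMesh
from .muscle_model import AttachmentPatch, MuscleFiber, MuscleGroup

# left side is +y; x runs rostrally (snout = +x); z is dorsal


@dataclass
class SyntheticSkullSpec:
    """Dimensions (mm) and resolution of the generated skull/jaw scene.

    Defaults emulate a Thrinaxodon-sized skull of about 60 mm length.
    """

    skull_length: float = 60.0
    braincase_width: float = 12.0
    braincase_height: float = 16.0
    zygomatic_chord: float = 26.0
    zygomatic_sag: float = 3.0
    coronoid_height: float = 14.0
    angle_offset: float = 4.0
    resolution: int = 3000
    seed: int = 0

    def __post_init__(self) -> None:
        dims = (self.skull_length, self.braincase_width, self.braincase_height,
                self.zygomatic_chord, self.zygomatic_sag, self.coronoid_height,
                self.angle_offset)
        if any(d <= 0 for d in dims):
            raise GeometryError("all skull dimensions must be positive")
        if self.resolution < 500:
            raise GeometryError("resolution too low to place patches (need >=500)")


@dataclass
class TaphonomySpec:
    """Deformation to inject: shear, unilateral face loss and vertex noise."""

    shear: np.ndarray = field(default_factory=lambda: np.eye(3))
    side_loss: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    lost_side: str = "L"

    def __post_init__(self) -> None:
        self.shear = np.asarray(self.shear, dtype=float).reshape(3, 3)
        if np.linalg.det(self.shear) <= 0:
            raise GeometryError("shear matrix must have positive determinant")
        if not 0.0 <= self.side_loss < 1.0:
            raise GeometryError("side-loss fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise GeometryError("noise sd must be non-negative")


@dataclass
class SyntheticScene:
    """A complete generated specimen: bones, landmarks, patches and hinge."""

    cranium: TriangleMesh
    mandible: TriangleMesh
    landmarks: list[LandmarkPair]
    patches: list[AttachmentPatch]
    hinge: HingeAxis

    def copy(self) -> "SyntheticScene":
        return SyntheticScene(
            self.cranium.copy(), self.mandible.copy(),
            [LandmarkPair(p.name, p.left.copy(), p.right.copy(), p.midline)
             for p in self.landmarks],
            [AttachmentPatch(p.muscle, p.role, p.points.copy(), p.bone, p.side)
             for p in self.patches],
            HingeAxis(self.hinge.point.copy(), self.hinge.direction.copy()))


@dataclass
class TaphonomyRecord:
    """Ground truth for one taphonomy injection."""

    shear: np.ndarray
    inverse_shear: np.ndarray
    deleted_faces: dict[str, np.ndarray]  # bone name -> face indices (original)
    original: SyntheticScene
    noise_sd: float
    lost_side: str


# ---------------------------------------------------------------------------
# primitive builders
# ---------------------------------------------------------------------------


def _ellipsoid(center, semi, subdiv: int) -> trimesh.Trimesh:
    m = trimesh.creation.icosphere(subdivisions=subdiv, radius=1.0)
    m.apply_scale(semi)
    m.apply_translation(center)
    return m


def _tube(p0, p1, radius: float, sections: int) -> trimesh.Trimesh:
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    seg = p1 - p0
    h = float(np.linalg.norm(seg))
    cap = trimesh.creation.capsule(height=h, radius=radius, count=(sections, sections))
    # capsule axis is +z spanning roughly [0, h] plus caps; align to segment
    T = trimesh.geometry.align_vectors([0, 0, 1], seg / h)
    cap.apply_transform(T)
    cap.apply_translation(p0)
    return cap


def _box(center, extents) -> trimesh.Trimesh:
    m = trimesh.creation.box(extents=extents)
    m.apply_translation(center)
    return m


def _mirror_y(m: trimesh.Trimesh) -> trimesh.Trimesh:
    v = m.vertices.copy()
    v[:, 1] = -v[:, 1]
    return trimesh.Trimesh(v, m.faces[:, ::-1].copy(), process=False)


def _concat(parts: list[trimesh.Trimesh], name: str) -> TriangleMesh:
    joined = trimesh.util.concatenate(parts)
    return TriangleMesh(np.asarray(joined.vertices), np.asarray(joined.faces), name)


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------


def _patch_points(part: trimesh.Trimesh, anchor: np.ndarray, n: int,
                  spread: float, rng: np.random.Generator) -> np.ndarray:
    """n points sampled on the part surface near `anchor` (within `spread`),
    spread out by farthest-point selection; deterministic given the rng state."""
    pts, _ = trimesh.sample.sample_surface(part, 800, seed=rng)
    pts = np.asarray(pts)
    d = np.linalg.norm(pts - anchor, axis=1)
    near = pts[d <= spread]
    if len(near) < n:
        near = pts[np.argsort(d)[: max(n, 12)]]
    chosen = [int(np.argmin(np.linalg.norm(near - anchor, axis=1)))]
    dist = np.linalg.norm(near - near[chosen[0]], axis=1)
    while len(chosen) < n:
        nxt = int(np.argmax(dist))
        chosen.append(nxt)
        dist = np.minimum(dist, np.linalg.norm(near - near[nxt], axis=1))
    return near[np.array(chosen)]


def generate_skull(spec: SyntheticSkullSpec | None = None) -> SyntheticScene:
    """Generate the bilaterally symmetric synthetic specimen.

    Returns a scene with watertight cranium and mandible assemblies, 14
    bilateral landmark pairs plus 3 midline landmarks, origin/insertion
    patches for the six core adductor muscles on each side, and the jaw-joint
    hinge through the two condyle landmarks.  Identical spec (including seed)
    gives byte-identical output.
    """
    spec = spec or SyntheticSkullSpec()
    s = spec.skull_length / 60.0  # isotropic scale of the layout
    rng = np.random.default_rng(spec.seed)
    subdiv = 2 if spec.resolution < 6000 else 3
    sections = 12 if spec.resolution < 6000 else 20

    bw, bh = spec.braincase_width / 2.0, spec.braincase_height / 2.0
    zc, zs = spec.zygomatic_chord, spec.zygomatic_sag
    ch, ao = spec.coronoid_height, spec.angle_offset

    # --- cranium parts (midline + left side; left mirrored to right) ---
    braincase = _ellipsoid([14 * s, 0, 12 * s], [16.8 * s, bw, bh], subdiv)
    snout = _ellipsoid([38 * s, 0, 10 * s], [18 * s, 0.6 * bw, 0.56 * bh], subdiv)
    arch_post = _tube([6 * s, 9.5 * s, 6 * s], [6 * s + zc / 2, 9.5 * s + zs, 7 * s],
                      1.2 * s, sections)
    arch_ant = _tube([6 * s + zc / 2, 9.5 * s + zs, 7 * s], [6 * s + zc, 9 * s, 8 * s],
                     1.2 * s, sections)
    ptg = _box([22 * s, 3.5 * s, 4 * s], [6 * s, 2 * s, 4 * s])
    cran_left = [arch_post, arch_ant, ptg]
    cranium = _concat([braincase, snout] + cran_left + [_mirror_y(m) for m in cran_left],
                      "cranium")

    # --- mandible parts (left side mirrored) ---
    condyle_pt = np.array([6 * s, 7 * s, 5 * s])
    ramus = _tube(condyle_pt, [52 * s, 2.5 * s, 2 * s], 2 * s, sections)
    coronoid = _box([18 * s, 7.2 * s, (5 + ch / 2) * s],
                    [10 * s, 1.2 * s, (ch + 4) * s])
    angle = _box([10 * s, 6 * s, (5 - ao - 1) * s], [6 * s, 1.5 * s, 4 * s])
    cond = _ellipsoid(condyle_pt, [1.5 * s] * 3, subdiv)
    mand_left = [ramus, coronoid, angle, cond]
    mandible = _concat(mand_left + [_mirror_y(m) for m in mand_left], "mandible")

    # --- landmarks: left-side coordinates, mirrored exactly ---
    lm_left = {
        "condyle": condyle_pt,
        "arch_anterior": [6 * s + zc, 9 * s, 8 * s],
        "arch_mid": [6 * s + zc / 2, 9.5 * s + zs, 7 * s],
        "coronoid_tip": [18 * s, 7.2 * s, (5 + ch) * s],
        "coronoid_base": [18 * s, 7.2 * s, 7 * s],
        "dentary_angle": [10 * s, 6 * s, (5 - ao) * s],
        "ramus_mid": [29 * s, 4.75 * s, 3.5 * s],
        "snout_lateral": [44 * s, 0.55 * bw, 10 * s],
        "orbit_dorsal": [30 * s, 5 * s, 14 * s],
        "orbit_ventral": [30 * s, 6 * s, 6 * s],
        "braincase_lateral": [14 * s, bw, 12 * s],
        "pterygoid": [22 * s, 3.5 * s, 2 * s],
        "occiput_lateral": [-2 * s, 4 * s, 12 * s],
        "parietal": [8 * s, 3 * s, 12 * s + 0.8 * bh],
    }
    landmarks = []
    for name, left in lm_left.items():
        left = np.asarray(left, float)
        right = left * np.array([1.0, -1.0, 1.0])
        landmarks.append(LandmarkPair(name, left, right))
    for name, pt in (("snout_tip", [56 * s, 0, 10 * s]),
                     ("braincase_apex", [14 * s, 0, 12 * s + bh]),
                     ("occiput", [(14 - 16.8) * s, 0, 12 * s])):
        pt = np.asarray(pt, float)
        landmarks.append(LandmarkPair(name, pt, pt, midline=True))

    # --- attachment patches: (muscle, role, part, anchor, spread) ---
    ramus_lat = np.array([20 * s, 7.6 * s, 4.1 * s])
    layout = [
        ("m. temp pro", "origin", braincase, [16 * s, 0.97 * bw, 14 * s], 5 * s),
        ("m. temp pro", "insertion", coronoid, [18 * s, 7.8 * s, (5 + 0.7 * ch) * s], 4 * s),
        ("m. temp sup", "origin", braincase, [10 * s, 3 * s, 12 * s + 0.93 * bh], 5 * s),
        ("m. temp sup", "insertion", coronoid, [18 * s, 7.2 * s, (4.5 + ch) * s], 3 * s),
        ("m. mass sup", "origin", arch_ant, [(6 + 0.9 * zc) * s, 9.1 * s, 7.9 * s], 4 * s),
        ("m. mass sup", "insertion", angle, [10 * s, 6.75 * s, (5 - ao - 1) * s], 3 * s),
        ("m. mass pro", "origin", arch_post, [(6 + 0.55 * zc) * s, (9.5 + 0.9 * zs) * s, 7 * s], 5 * s),
        ("m. mass pro", "insertion", ramus, ramus_lat, 4 * s),
        ("m. ptg int", "origin", ptg, [22 * s, 3.5 * s, 2.1 * s], 3 * s),
        ("m. ptg int", "insertion", angle, [10 * s, 5.25 * s, (5 - ao - 1) * s], 3 * s),
        ("m. ptg ext", "origin", ptg, [24.5 * s, 3.6 * s, 4 * s], 3 * s),
        ("m. ptg ext", "insertion", ramus, [10 * s, 4.8 * s, 4.7 * s], 3 * s),
    ]
    patches = []
    for muscle, role, part, anchor, spread in layout:
        bone = "cranium" if role == "origin" else "mandible"
        pts = _patch_points(part, np.asarray(anchor, float), 12, spread, rng)
        patches.append(AttachmentPatch(muscle, role, pts, bone, "L"))
        patches.append(AttachmentPatch(muscle, role, pts * [1.0, -1.0, 1.0],
                                       bone, "R"))

    hinge = HingeAxis(condyle_pt * [1.0, 0.0, 1.0], [0.0, 1.0, 0.0])
    hinge = hinge.oriented(rostral_point=np.array([52 * s, 0.0, 2 * s]),
                           cranial_point=np.array([56 * s, 0.0, 10 * s]))
    return SyntheticScene(cranium, mandible, landmarks, patches, hinge)


def groups_from_patches(patches: list[AttachmentPatch], n_fibers: int = 5,
                        side: str = "L", seed: int = 0) -> list[MuscleGroup]:
    """Seed one MuscleGroup per muscle present on the requested side."""
    from .muscle_model import seed_fibers

    by_muscle: dict[str, dict[str, AttachmentPatch]] = {}
    for p in patches:
        if p.side == side:
            by_muscle.setdefault(p.muscle, {})[p.role] = p
    groups = []
    for muscle in sorted(by_muscle):
        roles = by_muscle[muscle]
        if "origin" in roles and "insertion" in roles:
            fibers = seed_fibers(roles["origin"], roles["insertion"], n_fibers, seed)
            groups.append(MuscleGroup(muscle, fibers, side))
    return groups


# ---------------------------------------------------------------------------
# taphonomy injection
# ---------------------------------------------------------------------------


def _delete_side_faces(mesh: TriangleMesh, frac: float, side: str
                       ) -> tuple[TriangleMesh, np.ndarray]:
    """Delete the most-lateral `frac` of the faces on one side (by centroid y)."""
    cent = mesh.vertices[mesh.faces].mean(axis=1)
    y = cent[:, 1] if side == "L" else -cent[:, 1]
    on_side = np.nonzero(y > 0)[0]
    k = int(round(frac * len(on_side)))
    if k == 0:
        return mesh.copy(), np.array([], dtype=int)
    order = on_side[np.argsort(-y[on_side], kind="stable")]
    deleted = np.sort(order[:k])
    keep = np.setdiff1d(np.arange(len(mesh.faces)), deleted)
    return TriangleMesh(mesh.vertices.copy(), mesh.faces[keep], mesh.name), deleted


def inject_taphonomy(scene: SyntheticScene, spec: TaphonomySpec
                     ) -> tuple[SyntheticScene, TaphonomyRecord]:
    """Apply shear + unilateral face loss + vertex noise; return ground truth.

    The record carries the exact inverse shear and the deleted face indices of
    the original meshes, sufficient to reconstruct the undeformed scene to
    noise level.
    """
    rng = np.random.default_rng(spec.seed)
    S = spec.shear
    out = scene.copy()

    def _noise(shape):
        return rng.normal(0.0, spec.noise_sd, shape) if spec.noise_sd > 0 else 0.0

    deleted: dict[str, np.ndarray] = {}
    for attr in ("cranium", "mandible"):
        mesh = getattr(out, attr)
        mesh, dele = _delete_side_faces(mesh, spec.side_loss, spec.lost_side)
        mesh = TriangleMesh(mesh.vertices @ S.T + _noise(mesh.vertices.shape),
                            mesh.faces, mesh.name)
        setattr(out, attr, mesh)
        deleted[mesh.name] = dele
    for p in out.landmarks:
        p.left = S @ p.left + _noise(3)
        p.right = (p.left if p.midline else S @ p.right + _noise(3))
    for p in out.patches:
        p.points = p.points @ S.T + _noise(p.points.shape)
    d = S @ scene.hinge.direction
    out.hinge = HingeAxis(S @ scene.hinge.point, d / np.linalg.norm(d))
    record = TaphonomyRecord(S.copy(), np.linalg.inv(S), deleted, scene.copy(),
                             spec.noise_sd, spec.lost_side)
    return out, record


# ---------------------------------------------------------------------------
# closed-form fiber fixtures
# ---------------------------------------------------------------------------


def canonical_fiber_scenarios() -> dict[str, tuple[list[MuscleGroup], HingeAxis]]:
    """Named fiber/hinge fixtures whose strain curves are known in closed form.

    - "on-axis": cranial endpoint on the hinge axis, so the fiber length is
      constant (100% at every gape).
    - "quarter-turn": both endpoints at unit radius, 90 degrees apart; at a
      30 degree gape the strain is 100*sqrt(3)/sqrt(2) = 122.474%.
    - "near-parallel": unit radii 10 degrees apart; strain crosses 170% near
      7.04 degrees, so the 0.5-degree grid gives a 7.0 degree maximum gape.
    - "masseter-*": contrasting placements about a mediolateral hinge, with
      an anterior cranial attachment (large angular separation from the
      dentary-angle insertion) versus a posterior one near the joint; the
      anterior placement restricts gape more, and an on-axis variant never
      limits it.
    """
    # axes oriented so positive theta opens the jaw (stretches the fiber)
    x_axis = HingeAxis([0.0, 0.0, 0.0], [-1.0, 0.0, 0.0])
    y_hinge = HingeAxis([0.0, 0.0, 0.0], [0.0, 1.0, 0.0])

    def grp(muscle, origin, insertion, fid=0):
        return MuscleGroup(muscle, [MuscleFiber(origin, insertion, 0.0, muscle, fid)])

    d10 = np.radians(10.0)
    scenarios = {
        "on-axis": ([grp("m. temp pro", [0, 0, 0], [0, 1, 0])], x_axis),
        "quarter-turn": ([grp("m. temp pro", [0, 0, 1], [0, 1, 0])], x_axis),
        "near-parallel": ([grp("m. temp pro", [0, 0, 1],
                               [0, np.sin(d10), np.cos(d10)])], x_axis),
        "masseter-anterior": ([grp("m. mass sup", [30, 0, 10], [20, 0, -5])], y_hinge),
        "masseter-posterior": ([grp("m. mass sup", [12, 0, 8], [20, 0, -5])], y_hinge),
        "masseter-on-axis": ([grp("m. mass sup", [0, 0, 0], [20, 0, -5])], y_hinge),
    }
    return scenarios
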
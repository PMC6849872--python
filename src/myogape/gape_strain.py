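"""Hinge-rotation gape sweep and muscle-strain classification.

The mandible's sole degree of freedom is a rotation about the mediolateral
hinge axis through the jaw joints.  For each fiber the cranial endpoint stays
fixed while the mandibular endpoint rotates; the strain ratio is the stretched
length as a percentage of the closed-jaw (rest) length.  Strains are swept
over a gape grid (default 0-50 degrees in 0.5 degree steps) and classified
against tetanic-tension bands: below 130% the muscle operates within optimal
tetanic tension (green), 130-170% approaches the contraction limit (yellow),
and above 170% contraction is no longer possible (red).  The maximum gape of
a scenario is the largest grid angle at which no selected fiber exceeds the
170% limit.

In cylindrical coordinates about the hinge (fiber endpoints at radii r0, r1,
axial offset dz, angular separation dphi) the stretched length obeys

    L(theta)^2 = dz^2 + r0^2 + r1^2 - 2 r0 r1 cos(dphi + theta)

which serves as the closed-form oracle for the implementation's rotation-based
evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .muscle_model import MuscleError, MuscleFiber, MuscleGroup

GREEN, YELLOW, RED = "green", "yellow", "red"
CLASS_RGB = {GREEN: (0, 255, 0), YELLOW: (255, 255, 0), RED: (255, 0, 0)}


@dataclass
class HingeAxis:
    """Jaw-joint rotation axis: a point on the axis and a unit direction."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float).reshape(3)
        d = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if n == 0:
            raise MuscleError("hinge direction must be nonzero")
        self.direction = d / n

    def oriented(self, rostral_point: np.ndarray, cranial_point: np.ndarray,
                 probe_deg: float = 1.0) -> "HingeAxis":
        """Return a hinge whose positive rotation opens the jaw.

        A small positive rotation must carry the rostral mandibular reference
        point away from the cranial reference; if it does not, the axis
        direction is flipped.
        """
        moved = rotate_about_hinge(np.asarray(rostral_point, float)[None, :],
                                   self, probe_deg)[0]
        c = np.asarray(cranial_point, dtype=float)
        if np.linalg.norm(moved - c) >= np.linalg.norm(rostral_point - c):
            return self
        return HingeAxis(self.point, -self.direction)


@dataclass
class GapeSweepConfig:
    """Gape grid and tetanic-tension thresholds.

    Defaults: 0-50 degrees in 0.5 degree steps; optimal tetanic tension up to
    130%, maximal tetanic tension limit 170%.
    """

    theta_min: float = 0.0
    theta_max: float = 50.0
    dtheta: float = 0.5
    optimal_upper: float = 130.0
    max_tension: float = 170.0

    def __post_init__(self) -> None:
        if not self.theta_min < self.theta_max:
            raise MuscleError("require theta_min < theta_max")
        if self.dtheta <= 0:
            raise MuscleError("require dtheta > 0")
        if not 100.0 < self.optimal_upper < self.max_tension:
            raise MuscleError("require 100 < optimal_upper < max_tension")

    def grid(self) -> np.ndarray:
        """Gape angles theta_min + k*dtheta up to and including theta_max."""
        n = int(np.floor((self.theta_max - self.theta_min) / self.dtheta + 1e-9))
        return self.theta_min + self.dtheta * np.arange(n + 1)


@dataclass
class StrainRecord:
    fiber_id: int
    muscle: str
    theta_deg: float
    strain_pct: float
    strain_class: str


@dataclass
class SweepResult:
    """All per-fiber strain records plus per-muscle maximum gapes."""

    records: list[StrainRecord]
    max_gape_per_muscle: dict[str, float]
    max_gape: float
    limiting_fiber: tuple[str, int] | None
    config: GapeSweepConfig
    hinge: "HingeAxis | None" = None
    at_limit_at_closure: bool = False

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(r.muscle, r.fiber_id, r.theta_deg, r.strain_pct, r.strain_class)
             for r in self.records],
            columns=["muscle", "fiber_id", "theta_deg", "strain_pct", "class"])


# ---------------------------------------------------------------------------


def rotate_about_hinge(points: np.ndarray, hinge: HingeAxis,
                       theta_deg: float) -> np.ndarray:
    """Rigid rotation of points by theta (degrees) about the hinge line."""
    R = Rotation.from_rotvec(np.radians(theta_deg) * hinge.direction).as_matrix()
    pts = np.asarray(points, dtype=float)
    return (pts - hinge.point) @ R.T + hinge.point


def strain_ratio(fiber: MuscleFiber, hinge: HingeAxis, theta_deg: float) -> float:
    """Fiber strain (%) at gape theta: stretched length / rest length x 100.

    The cranial origin is fixed; the mandibular insertion rotates with the
    jaw.  Rest length is measured at theta = 0 (jaw closed).
    """
    rest = fiber.rest_length
    if rest <= 0:
        raise MuscleError("zero rest length")
    if theta_deg == 0.0:
        return 100.0  # rest state by definition; avoids rounding in the pivot shift
    moved = rotate_about_hinge(fiber.insertion[None, :], hinge, theta_deg)[0]
    return 100.0 * float(np.linalg.norm(fiber.origin - moved)) / rest


def strain_ratio_cylindrical(fiber: MuscleFiber, hinge: HingeAxis,
                             theta_deg: float) -> float:
    """Closed-form strain via cylindrical coordinates about the hinge.

    L(theta)^2 = dz^2 + r0^2 + r1^2 - 2 r0 r1 cos(dphi + theta); independent
    oracle for :func:`strain_ratio`.
    """
    k = hinge.direction
    # in-plane basis perpendicular to the axis
    a = np.array([1.0, 0.0, 0.0])
    if abs(k @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = a - (a @ k) * k
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(k, e1)

    def cyl(p):
        v = p - hinge.point
        z = float(v @ k)
        x, y = float(v @ e1), float(v @ e2)
        return np.hypot(x, y), np.arctan2(y, x), z

    r0, phi0, z0 = cyl(fiber.origin)
    r1, phi1, z1 = cyl(fiber.insertion)
    dz = z1 - z0
    dphi = phi1 - phi0
    th = np.radians(theta_deg)
    L2 = dz * dz + r0 * r0 + r1 * r1 - 2 * r0 * r1 * np.cos(dphi + th)
    L0 = fiber.rest_length
    return 100.0 * float(np.sqrt(max(L2, 0.0))) / L0


def classify_strain(strain_pct: float, config: GapeSweepConfig | None = None) -> str:
    """Tetanic-tension band: green < 130%; yellow 130-170%; red > 170%.

    Both band boundaries belong to yellow, matching the printed 130-170%
    yellow interval.
    """
    cfg = config or GapeSweepConfig()
    if strain_pct <= 0:
        raise MuscleError("strain must be positive")
    if strain_pct < cfg.optimal_upper:
        return GREEN
    if strain_pct <= cfg.max_tension:
        return YELLOW
    return RED


def run_sweep(groups: list[MuscleGroup], hinge: HingeAxis,
              config: GapeSweepConfig | None = None) -> SweepResult:
    """Evaluate strain and band for every fiber at every grid angle."""
    cfg = config or GapeSweepConfig()
    if not groups or not any(g.fibers for g in groups):
        raise MuscleError("run_sweep: no fibers")
    grid = cfg.grid()
    records: list[StrainRecord] = []
    per_fiber_max: dict[tuple[str, int], float] = {}
    for g in groups:
        for f in g.fibers:
            strains = np.array([strain_ratio(f, hinge, t) for t in grid])
            for t, s in zip(grid, strains):
                records.append(StrainRecord(f.id, g.muscle, float(t), float(s),
                                            classify_strain(float(s), cfg)))
            ok = strains <= cfg.max_tension
            per_fiber_max[(g.muscle, f.id)] = (
                float(grid[np.nonzero(ok)[0].max()]) if ok.any() else float(grid[0]))

    per_muscle: dict[str, float] = {}
    for (muscle, _), mg in per_fiber_max.items():
        per_muscle[muscle] = min(per_muscle.get(muscle, float(grid[-1])), mg)
    limiting = min(per_fiber_max, key=per_fiber_max.get)  # first minimum wins
    overall = per_fiber_max[limiting]
    warn_flag = any(r.theta_deg == grid[0] and r.strain_pct > cfg.max_tension
                    for r in records)
    return SweepResult(records, per_muscle, overall, limiting, cfg, hinge,
                       warn_flag)


def max_gape(result: SweepResult, muscles: list[str] | None = None) -> float:
    """Largest grid angle with every selected fiber's strain <= the 170% limit.

    Returns theta_max when the limit is never exceeded; if a fiber is past the
    limit already at closure the smallest grid angle is returned and the
    result's warning flag is set.
    """
    if muscles is None:
        return result.max_gape
    if not muscles:
        raise MuscleError("max_gape: empty muscle selection")
    sel = [m for m in muscles if m in result.max_gape_per_muscle]
    if not sel:
        raise MuscleError("max_gape: no matching muscles in sweep")
    return min(result.max_gape_per_muscle[m] for m in sel)


def compare_placements(scenarios: dict[str, list[MuscleGroup]], hinge: HingeAxis,
                       config: GapeSweepConfig | None = None):
    """Sweep each named placement scenario; rank by maximum gape.

    Returns a DataFrame with one row per scenario: maximum gape, the limiting
    fiber (muscle name + fiber id) and the rank (1 = widest gape).
    """
    import pandas as pd

    if len(scenarios) < 2:
        raise MuscleError("compare_placements: need >=2 scenarios")
    rows = []
    for name, groups in scenarios.items():
        res = run_sweep(groups, hinge, config)
        lim_m, lim_f = res.limiting_fiber if res.limiting_fiber else ("", -1)
        rows.append((name, res.max_gape, lim_m, lim_f))
    df = pd.DataFrame(rows, columns=["scenario", "max_gape_deg",
                                     "limiting_muscle", "limiting_fiber"])
    df["rank"] = df["max_gape_deg"].rank(ascending=False, method="min").astype(int)
    return df
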
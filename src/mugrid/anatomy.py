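"""Anatomical model of a motor-unit pool in a layered cylindrical muscle.

The muscle is an idealized cylinder of parallel fibers separated from the
surface electrodes by subcutaneous fat and skin layers.  Motor-unit
territories are circular regions of the muscle cross-section; their centers
are spread with a farthest-point sampling rule (each new center maximizes its
minimum distance to all previous ones), the innervation numbers follow an
exponential ladder across the pool, and the territory radius follows from the
fiber count at a fixed fiber density.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MuscleGeometry",
    "MotorUnitAnatomy",
    "MotorUnitPool",
    "sample_motor_unit_centers",
    "assign_innervation_numbers",
    "build_pool",
    "mu_depth",
    "conduction_velocity",
]

#: printed bounds of the innervation-number ladder
N_FIBERS_MIN = 15
N_FIBERS_MAX = 1500
#: fibers per mm^2 within one territory
FIBER_DENSITY = 20.0
#: territory radius clip range, mm
TERRITORY_RADIUS_MIN = 0.2
TERRITORY_RADIUS_MAX = 9.8


@dataclass(frozen=True)
class MuscleGeometry:
    """Layered cylindrical muscle volume, dimensions in mm."""

    muscle_radius: float = 25.4
    fat_thickness: float = 5.0
    skin_thickness: float = 1.0
    fiber_length: float = 100.0

    def __post_init__(self):
        for name in ("muscle_radius", "fat_thickness", "skin_thickness", "fiber_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def outer_radius(self) -> float:
        """Radius of the skin surface, mm."""
        return self.muscle_radius + self.fat_thickness + self.skin_thickness


@dataclass(frozen=True)
class MotorUnitAnatomy:
    """One motor unit: territory center, radius, and fiber positions.

    ``center`` and ``fiber_positions`` are 2-D points (x, y) in the muscle
    cross-section, mm; ``endplate_z`` holds the axial neuromuscular-junction
    position of each fiber, mm, scattered around the fiber midpoint.
    """

    index: int
    center: np.ndarray
    territory_radius: float
    n_fibers: int
    fiber_positions: np.ndarray
    endplate_z: np.ndarray

    @property
    def n_simulated_fibers(self) -> int:
        return self.fiber_positions.shape[0]


@dataclass(frozen=True)
class MotorUnitPool:
    geometry: MuscleGeometry
    units: tuple
    seed: int

    def __len__(self) -> int:
        return len(self.units)

    def depths(self) -> np.ndarray:
        """Depth of every territory center below the skin surface, mm."""
        return np.array([mu_depth(u, self.geometry) for u in self.units])

    def to_json(self) -> str:
        """Scalar summary (centers, radii, counts) as JSON; fiber positions
        are regenerated from the seed rather than serialized."""
        return json.dumps(
            {
                "seed": self.seed,
                "geometry": {
                    "muscle_radius": self.geometry.muscle_radius,
                    "fat_thickness": self.geometry.fat_thickness,
                    "skin_thickness": self.geometry.skin_thickness,
                    "fiber_length": self.geometry.fiber_length,
                },
                "units": [
                    {
                        "index": u.index,
                        "center": [float(u.center[0]), float(u.center[1])],
                        "territory_radius": u.territory_radius,
                        "n_fibers": u.n_fibers,
                    }
                    for u in self.units
                ],
            }
        )


def sample_motor_unit_centers(
    count: int,
    muscle_radius: float = 25.4,
    seed: int = 0,
    candidates_per_center: int = 50,
    candidates: np.ndarray | None = None,
) -> np.ndarray:
    """Spread ``count`` territory centers over the muscle cross-section with
    farthest-point sampling.

    A dense candidate set of uniformly random points inside the disc is drawn
    (``candidates_per_center * count`` points unless an explicit candidate
    array is supplied); the first center is the first candidate, and each
    subsequent center is the candidate maximizing the minimum distance to all
    centers already placed.  The result is a deterministic, evenly spread,
    yet randomized layout.

    Returns an (count, 2) array of (x, y) points in mm.
    """
    count = int(count)
    if count < 1:
        raise ValueError("count must be >= 1")
    if muscle_radius <= 0:
        raise ValueError("muscle_radius must be positive")
    if candidates is None:
        rng = np.random.default_rng(seed)
        m = candidates_per_center * count
        candidates = _uniform_disc(rng, m, muscle_radius)
    else:
        candidates = np.asarray(candidates, dtype=float)
        if candidates.ndim != 2 or candidates.shape[1] != 2:
            raise ValueError("candidates must be an (m, 2) array")
    m = candidates.shape[0]
    if m < count:
        raise ValueError("candidate set smaller than requested count")
    chosen = np.empty(count, dtype=int)
    chosen[0] = 0
    # min distance of every candidate to the chosen set, updated incrementally
    d2 = np.sum((candidates - candidates[0]) ** 2, axis=1)
    d2[0] = -np.inf
    for k in range(1, count):
        nxt = int(np.argmax(d2))
        chosen[k] = nxt
        d2 = np.minimum(d2, np.sum((candidates - candidates[nxt]) ** 2, axis=1))
        d2[chosen[: k + 1]] = -np.inf
    return candidates[chosen].copy()


def _uniform_disc(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    th = 2.0 * np.pi * rng.random(n)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def assign_innervation_numbers(
    count: int, n_min: int = N_FIBERS_MIN, n_max: int = N_FIBERS_MAX
) -> np.ndarray:
    """Exponential innervation-number ladder across the pool.

    Unit ``i`` (1-based rank) innervates
    ``round(n_min * (n_max/n_min)**((i-1)/(count-1)))`` fibers, so the ladder
    runs exactly from ``n_min`` to ``n_max`` and the pre-rounding ratio
    between consecutive units is constant.
    """
    count = int(count)
    if count < 2:
        raise ValueError("count must be >= 2")
    if not n_min < n_max:
        raise ValueError("n_min must be < n_max")
    i = np.arange(count, dtype=float)
    n = n_min * (n_max / n_min) ** (i / (count - 1))
    return np.rint(n).astype(int)


def conduction_velocity(
    n_fibers: np.ndarray | int,
    cv_min: float = 3.5,
    cv_max: float = 4.5,
    n_min: int = N_FIBERS_MIN,
    n_max: int = N_FIBERS_MAX,
) -> np.ndarray | float:
    """Fiber conduction velocity (m/s) increasing with motor-unit size.

    Larger units have larger fibers and hence faster propagation; the law is
    linear in log fiber count between ``cv_min`` and ``cv_max``.
    """
    frac = (np.log(n_fibers) - np.log(n_min)) / (np.log(n_max) - np.log(n_min))
    return cv_min + (cv_max - cv_min) * np.clip(frac, 0.0, 1.0)


def build_pool(
    geometry: MuscleGeometry | None = None,
    count: int = 200,
    density: float = FIBER_DENSITY,
    seed: int = 0,
    endplate_scatter: float = 5.0,
    fit_territories: bool = True,
) -> MotorUnitPool:
    """Generate the full anatomical pool.

    Territory radii derive from the fiber count at ``density`` fibers/mm^2
    (clipped to the physiological 0.2-9.8 mm range); fibers are placed
    uniformly at random inside each territory disc intersected with the
    muscle cross-section (territories of near-boundary units may overhang the
    muscle, in which case fibers are resampled into the intersection without
    shifting the center).  Each fiber's neuromuscular junction sits at the
    fiber midpoint with a uniform +/- ``endplate_scatter`` mm axial scatter.
    Units are ordered by ascending fiber count.
    """
    geometry = geometry or MuscleGeometry()
    rng = np.random.default_rng(seed)
    centers = sample_motor_unit_centers(
        count, geometry.muscle_radius, seed=rng.integers(2**31)
    )
    n_fibers = assign_innervation_numbers(count)
    units = []
    for i in range(count):
        radius = float(
            np.clip(
                np.sqrt(n_fibers[i] / (np.pi * density)),
                TERRITORY_RADIUS_MIN,
                TERRITORY_RADIUS_MAX,
            )
        )
        center = centers[i]
        if fit_territories:
            # large territories cannot hug the boundary: pull the center
            # radially inward until the territory disc fits in the muscle
            rc = float(np.hypot(center[0], center[1]))
            r_max = max(geometry.muscle_radius - radius, 0.0)
            if rc > r_max:
                center = center * (r_max / rc if rc > 0 else 0.0)
            centers[i] = center
        fibers = _sample_fibers(
            rng, center, radius, int(n_fibers[i]), geometry.muscle_radius
        )
        endplates = rng.uniform(-endplate_scatter, endplate_scatter, size=len(fibers))
        units.append(
            MotorUnitAnatomy(
                index=i + 1,
                center=centers[i],
                territory_radius=radius,
                n_fibers=int(n_fibers[i]),
                fiber_positions=fibers,
                endplate_z=endplates,
            )
        )
    return MotorUnitPool(geometry=geometry, units=tuple(units), seed=seed)


def _sample_fibers(
    rng: np.random.Generator,
    center: np.ndarray,
    radius: float,
    n: int,
    muscle_radius: float,
) -> np.ndarray:
    """Uniform points in territory-disc intersected with muscle-disc
    (rejection sampling)."""
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        m = max(2 * (n - filled), 16)
        pts = center + _uniform_disc(rng, m, radius)
        ok = np.sum(pts**2, axis=1) <= muscle_radius**2
        pts = pts[ok][: n - filled]
        out[filled : filled + len(pts)] = pts
        filled += len(pts)
    return out


def mu_depth(unit: MotorUnitAnatomy, geometry: MuscleGeometry) -> float:
    """Depth of the territory center below the skin surface, mm.

    Equals the outer radius of the layered cylinder minus the radial distance
    of the center from the cylinder axis; the shallowest possible territory
    center (on the muscle boundary) therefore sits at fat+skin depth.
    """
    r = float(np.hypot(unit.center[0], unit.center[1]))
    if r > geometry.muscle_radius + 1e-9:
        raise ValueError("territory center outside the muscle cross-section")
    return geometry.outer_radius - r
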
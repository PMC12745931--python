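"""Nest geometry: beach cylinder, flask-shaped egg chamber, packed clutch.

Coordinates are SI metres with the origin at the sand surface on the chamber
axis and z positive downward.  The beach subdomain is a 2 m diameter x 1.5 m
deep cylinder; the egg chamber is an axisymmetric flask (cylindrical neck over
a truncated ellipsoidal bulb) whose base sits at the nest depth ``d``; the
neck length ``n`` follows d = n + chamber height, with the chamber height
fixed at 0.31 m (the constant offset observed across all field nests).

Eggs are rigid spheres arranged by a sequential gravity-deposition algorithm:
each egg is dropped from the chamber neck and settles under repeated
descend-and-project iterations until it rests on the chamber wall or on
previously placed eggs.  The outcome -- a reproducible, gravity-settled random
arrangement filling the chamber from the base upward -- is what matters to
heat transfer, not the dynamics of the fall.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChamberProfile",
    "NestGeometry",
    "ClutchLayout",
    "build_domain",
    "pack_eggs",
    "logger_positions",
    "CHAMBER_HEIGHT",
]

CHAMBER_HEIGHT = 0.31  # m; nest depth minus neck length, constant across nests
BEACH_DIAMETER = 2.0
BEACH_DEPTH = 1.5


@dataclass(frozen=True)
class ChamberProfile:
    """Axisymmetric flask: a cylindrical neck above a truncated ellipsoidal
    bulb whose base coincides with the chamber base (the nest depth).

    ``height`` is the total chamber height; the bulb is an ellipsoid of
    revolution with horizontal semi-axis ``bulb_radius`` and vertical
    semi-axis ``bulb_semi_height`` centred ``bulb_semi_height`` above the
    base.  Dimensions default to literature averages for flatback nests and
    are replaceable constants.
    """

    height: float = CHAMBER_HEIGHT
    neck_radius: float = 0.09
    bulb_radius: float = 0.13
    bulb_semi_height: float = 0.12

    def __post_init__(self) -> None:
        if self.height <= 0 or self.neck_radius <= 0 or self.bulb_radius <= 0:
            raise ValueError("chamber dimensions must be positive")
        if 2 * self.bulb_semi_height > self.height:
            raise ValueError("bulb taller than the chamber")

    def radius_at(self, s: float | np.ndarray) -> np.ndarray:
        """Chamber radius at depth ``s`` below the chamber top, s in [0, height]."""
        s = np.asarray(s, dtype=float)
        centre = self.height - self.bulb_semi_height
        u = (s - centre) / self.bulb_semi_height
        ellipse = self.bulb_radius * np.sqrt(np.clip(1.0 - u * u, 0.0, None))
        neck = np.where((s >= 0) & (s <= centre), self.neck_radius, 0.0)
        out = np.maximum(neck, np.where(np.abs(u) <= 1.0, ellipse, 0.0))
        return np.where((s < 0) | (s > self.height), 0.0, out)

    def volume(self, n: int = 4000) -> float:
        """Chamber volume by numerical integration of the profile (m3)."""
        s = np.linspace(0.0, self.height, n)
        r = self.radius_at(s)
        return float(np.trapezoid(np.pi * r * r, s))


@dataclass(frozen=True)
class NestGeometry:
    """One nest: beach cylinder + chamber at depth, plus the egg radius."""

    nest_depth: float
    egg_radius: float
    chamber: ChamberProfile = field(default_factory=ChamberProfile)
    beach_diameter: float = BEACH_DIAMETER
    beach_depth: float = BEACH_DEPTH

    def __post_init__(self) -> None:
        if self.nest_depth < self.chamber.height:
            raise ValueError(
                f"nest depth {self.nest_depth:.3f} m is shallower than the "
                f"chamber height {self.chamber.height:.3f} m"
            )
        if self.nest_depth + 0 > self.beach_depth:
            raise ValueError("chamber base below the modelled beach depth")
        if self.chamber.bulb_radius * 2 > self.beach_diameter:
            raise ValueError("chamber wider than the beach cylinder")
        if not 0.3 <= self.nest_depth <= 1.0:
            warnings.warn(
                f"nest depth {self.nest_depth:.2f} m outside the plausible "
                "0.3-1.0 m band",
                stacklevel=3,
            )

    @property
    def neck_length(self) -> float:
        """Vertical distance from the sand surface to the chamber top (m)."""
        return self.nest_depth - self.chamber.height

    @property
    def chamber_top(self) -> float:
        return self.neck_length

    def chamber_radius_at(self, z: float | np.ndarray) -> np.ndarray:
        """Chamber radius at absolute depth z (m below the sand surface)."""
        return self.chamber.radius_at(np.asarray(z) - self.chamber_top)

    def inside_chamber(self, x, y, z) -> np.ndarray:
        r = np.hypot(np.asarray(x), np.asarray(y))
        return r <= self.chamber_radius_at(z)


@dataclass(frozen=True)
class ClutchLayout:
    """Packed clutch: egg centre coordinates (N x 3, z positive down)."""

    egg_centres: np.ndarray
    egg_radius: float
    clutch_size: int

    def __post_init__(self) -> None:
        if self.egg_centres.shape != (self.clutch_size, 3):
            raise ValueError("egg_centres must be (clutch_size, 3)")

    def min_separation(self) -> float:
        """Smallest pairwise centre distance (m); inf for a single egg."""
        if self.clutch_size < 2:
            return np.inf
        d = self.egg_centres[:, None, :] - self.egg_centres[None, :, :]
        dist = np.sqrt((d * d).sum(-1))
        dist[np.diag_indices_from(dist)] = np.inf
        return float(dist.min())


def build_domain(
    nest_depth: float,
    clutch_size: int,
    egg_diameter: float = 0.0467,
    chamber: ChamberProfile | None = None,
) -> NestGeometry:
    """Build the nest geometry for a given depth and clutch.

    The neck length is derived so the chamber base sits at ``nest_depth``;
    the beach cylinder is fixed at 2 m diameter x 1.5 m depth.
    """
    if clutch_size < 1:
        raise ValueError("clutch_size must be at least 1")
    if egg_diameter <= 0:
        raise ValueError("egg diameter must be positive")
    chamber = chamber or ChamberProfile()
    geom = NestGeometry(nest_depth=nest_depth, egg_radius=egg_diameter / 2, chamber=chamber)
    clutch_volume = clutch_size * (4.0 / 3.0) * np.pi * geom.egg_radius**3
    if clutch_volume >= chamber.volume():
        raise ValueError("clutch volume exceeds the chamber volume")
    return geom


# ---------------------------------------------------------------------------
# Egg packing


def _project_centre(p: np.ndarray, geom: NestGeometry, r: float) -> np.ndarray:
    """Project an egg centre into the admissible region of the chamber.

    The admissible region is the union of the neck cylinder and the bulb
    ellipsoid, each shrunk by the egg radius so the egg fits inside.
    """
    ch = geom.chamber
    top = geom.chamber_top
    d = geom.nest_depth
    bulb_c = d - ch.bulb_semi_height
    a = ch.bulb_radius - r  # horizontal semi-axis of the shrunk bulb
    c = ch.bulb_semi_height - r
    neck_a = ch.neck_radius - r
    if a <= 0 or c <= 0:
        raise ValueError("egg larger than the chamber bulb")

    x, y, z = p
    rho = np.hypot(x, y)

    # candidate 1: shrunk bulb ellipsoid
    u = rho / a
    v = (z - bulb_c) / c
    scale = np.hypot(u, v)
    if scale <= 1.0:
        bulb_pt, bulb_ok = p, True
    else:
        # pull radially toward the bulb centre onto the ellipsoid surface
        f = 1.0 / scale
        if rho > 0:
            bx, by = x * (a * u * f) / rho, y * (a * u * f) / rho
        else:
            bx, by = 0.0, 0.0
        bulb_pt = np.array([bx, by, bulb_c + c * v * f])
        bulb_ok = False

    # candidate 2: shrunk neck cylinder (only if the neck admits an egg)
    if neck_a > 0:
        zn = np.clip(z, top + r, bulb_c)
        if rho > neck_a:
            nx, ny = x * neck_a / rho, y * neck_a / rho
        else:
            nx, ny = x, y
        neck_pt = np.array([nx, ny, zn])
        neck_ok = (top + r <= z <= bulb_c) and rho <= neck_a
    else:
        neck_pt, neck_ok = None, False

    if bulb_ok or neck_ok:
        return p
    if neck_pt is None:
        return bulb_pt
    db = np.linalg.norm(bulb_pt - p)
    dn = np.linalg.norm(neck_pt - p)
    return bulb_pt if db <= dn else neck_pt


def _resolve(p: np.ndarray, placed: np.ndarray, geom: NestGeometry, r: float,
             iters: int = 80, tol: float = 2e-5) -> np.ndarray:
    """Push a centre out of overlaps with placed eggs and chamber walls.

    Averaged constraint projection: at each pass the centre is projected into
    the chamber, then moved by the mean of the separation corrections of all
    violated egg-egg constraints.  Converges to a feasible point when one
    exists near ``p``.
    """
    for _ in range(iters):
        q = _project_centre(p, geom, r)
        if len(placed):
            delta = q - placed
            dist = np.sqrt((delta * delta).sum(-1))
            pen = 2 * r - dist
            viol = pen > tol / 2
            if viol.any():
                dirs = np.zeros_like(delta)
                dz = dist.copy()
                degenerate = dz < 1e-12
                dz[degenerate] = 1.0
                dirs = delta / dz[:, None]
                dirs[degenerate] = np.array([0.0, 0.0, -1.0])
                corr = (dirs[viol] * pen[viol, None]).mean(axis=0)
                p = q + corr
                continue
        if np.linalg.norm(q - p) < tol / 2:
            return q
        p = q
    return _project_centre(p, geom, r)


def _settle(p: np.ndarray, placed: np.ndarray, geom: NestGeometry, r: float,
            rng: np.random.Generator) -> np.ndarray:
    """Let one egg sink as far as constraints allow (steepest-descent drop
    with small random tangential nudges so eggs roll off local peaks)."""
    step = r / 2
    p = _resolve(p, placed, geom, r)
    stalls = 0
    for _ in range(800):
        trial = p + np.array([0.0, 0.0, step])
        trial = _resolve(trial, placed, geom, r)
        if trial[2] > p[2] + 1e-7:
            p = trial
            stalls = 0
        else:
            # jittered sideways nudge: emulates rolling around a contact
            nudge = rng.normal(scale=step / 2, size=2)
            trial = p + np.array([nudge[0], nudge[1], step])
            trial = _resolve(trial, placed, geom, r)
            if trial[2] > p[2] + 1e-7:
                p = trial
                stalls = 0
            else:
                step *= 0.5
                stalls += 1
                if step < 2e-5 or stalls > 40:
                    break
    return _resolve(p, placed, geom, r)


def pack_eggs(
    geometry: NestGeometry,
    clutch_size: int,
    seed: int,
    overlap_tol: float = 1e-4,
    max_attempts: int = 60,
) -> ClutchLayout:
    """Pack ``clutch_size`` eggs into the chamber under simulated gravity.

    Deterministic for a fixed seed.  Eggs are deposited sequentially from the
    chamber neck with random lateral offsets and settle to a local minimum of
    height; an egg whose final position still overlaps beyond ``overlap_tol``
    is re-dropped, and packing fails after ``max_attempts`` re-drops.
    """
    r = geometry.egg_radius
    rng = np.random.default_rng(seed)
    clutch_volume = clutch_size * (4.0 / 3.0) * np.pi * r**3
    if clutch_volume >= geometry.chamber.volume():
        raise ValueError("clutch cannot fit: clutch volume exceeds chamber volume")

    placed: list[np.ndarray] = []
    drop_r = max(geometry.chamber.neck_radius - r, 0.0)
    for i in range(clutch_size):
        arr = np.array(placed) if placed else np.zeros((0, 3))
        ok = False
        for _ in range(max_attempts):
            if i == 0:
                start = np.array([0.0, 0.0, geometry.chamber_top + r])
            else:
                ang = rng.uniform(0, 2 * np.pi)
                rad = drop_r * np.sqrt(rng.uniform())
                start = np.array(
                    [rad * np.cos(ang), rad * np.sin(ang), geometry.chamber_top + r]
                )
            pos = _settle(start, arr, geometry, r, rng)
            sep_ok = (
                len(arr) == 0
                or np.sqrt(((pos - arr) ** 2).sum(-1)).min() >= 2 * r - overlap_tol
            )
            inside = np.allclose(_project_centre(pos, geometry, r), pos, atol=overlap_tol)
            if sep_ok and inside:
                placed.append(pos)
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"packing infeasible: egg {i + 1}/{clutch_size} could not be "
                f"placed after {max_attempts} attempts"
            )
    return ClutchLayout(np.array(placed), r, clutch_size)


def logger_positions(
    geometry: NestGeometry, layout: ClutchLayout
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(base, centre, top) logger positions within the clutch.

    Base is the deepest egg centre, top the shallowest, centre the egg centre
    nearest the clutch centroid; ties break to the lowest egg index.
    """
    if layout.clutch_size == 0:
        raise ValueError("empty clutch")
    centres = layout.egg_centres
    base = centres[int(np.argmax(centres[:, 2]))]
    top = centres[int(np.argmin(centres[:, 2]))]
    centroid = centres.mean(axis=0)
    dist = np.sqrt(((centres - centroid) ** 2).sum(-1))
    centre = centres[int(np.argmin(dist))]
    return base.copy(), centre.copy(), top.copy()


def layout_to_csv(layout: ClutchLayout, path) -> None:
    """Export a layout as CSV (egg_id, x_m, y_m, z_m)."""
    import pandas as pd

    df = pd.DataFrame(layout.egg_centres, columns=["x_m", "y_m", "z_m"])
    df.insert(0, "egg_id", np.arange(layout.clutch_size))
    df.to_csv(path, index=False, float_format="%.6f")


def layout_from_csv(path, egg_radius: float) -> ClutchLayout:
    """Import a layout written by :func:`layout_to_csv`."""
    import pandas as pd

    df = pd.read_csv(path)
    centres = df[["x_m", "y_m", "z_m"]].to_numpy()
    return ClutchLayout(centres, egg_radius, len(df))
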
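"""Honeycomb-maze geometry, platform lookup and angle conventions.

The maze is a centred hexagonal tessellation of 61 hexagonal platforms
(rings of 1 + 6 + 12 + 18 + 24).  Conventions used throughout the package:

* allocentric angles in degrees, 0° along +x, counter-clockwise positive,
  wrapped to [0, 360);
* relative (egocentric) direction = head direction minus the bearing from
  the animal to the reference point, wrapped to (-180, 180]; 0° means the
  animal faces the reference point, positive values mean the point lies to
  the animal's right;
* lengths in cm, times in seconds.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ._circ import wrap_180, wrap_360

__all__ = [
    "MazeGeometry",
    "build_honeycomb",
    "bearing",
    "relative_direction",
    "wrap_180",
    "wrap_360",
]

N_RINGS = 5  # rings 0..4 -> 1 + 6 + 12 + 18 + 24 = 61 platforms


@dataclass
class MazeGeometry:
    """Geometry of the 61-platform honeycomb maze."""

    hex_side: float
    orientation_deg: float
    centers: np.ndarray  # (61, 2) cm
    adjacency: list  # list of (i, j) pairs, i < j
    goal: int | None = None
    _tree: cKDTree = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float)
        if self._tree is None:
            self._tree = cKDTree(self.centers)

    @property
    def n_platforms(self) -> int:
        return len(self.centers)

    @property
    def apothem(self) -> float:
        return np.sqrt(3.0) * self.hex_side / 2.0

    def neighbours(self, i: int) -> list:
        out = [b for a, b in self.adjacency if a == i]
        out += [a for a, b in self.adjacency if b == i]
        return sorted(out)

    def hexagon_vertices(self, i: int) -> np.ndarray:
        """(6, 2) vertex coordinates of platform *i*."""
        ang = np.deg2rad(self.orientation_deg + 30.0 + 60.0 * np.arange(6))
        return self.centers[i] + self.hex_side * np.stack(
            [np.cos(ang), np.sin(ang)], axis=1
        )

    def platform_of(self, points) -> np.ndarray:
        """Platform id containing each point, -1 if off the maze.

        The hexagonal tessellation is the Voronoi diagram of the platform
        centres, so a point can only lie in the hexagon of its nearest
        centre; containment reduces to three half-plane tests against the
        edge normals.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        _, idx = self._tree.query(pts)
        local = pts - self.centers[idx]
        th = np.deg2rad(self.orientation_deg + np.array([0.0, 60.0, 120.0]))
        normals = np.stack([np.cos(th), np.sin(th)], axis=1)  # (3, 2)
        proj = np.abs(local @ normals.T)  # (n, 3)
        inside = np.all(proj <= self.apothem + 1e-9, axis=1)
        out = np.where(inside, idx, -1).astype(int)
        if np.ndim(points) == 1:
            return out[0]
        return out

    def platform_containing(self, point):
        """Scalar convenience wrapper: platform id or None if off-maze."""
        pid = int(self.platform_of(np.asarray(point, dtype=float)))
        return None if pid < 0 else pid

    def platform_distance(self, i: int, j: int) -> float:
        """Euclidean centre-to-centre distance between two platforms."""
        return float(np.linalg.norm(self.centers[i] - self.centers[j]))

    def distance_to_goal(self, i: int) -> float:
        if self.goal is None:
            raise ValueError("maze has no goal platform set")
        return self.platform_distance(i, self.goal)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "hex_side": self.hex_side,
            "orientation": self.orientation_deg,
            "platforms": [
                {"id": i, "cx": float(c[0]), "cy": float(c[1])}
                for i, c in enumerate(self.centers)
            ],
            "adjacency": [[int(a), int(b)] for a, b in self.adjacency],
            "goal": self.goal,
        }

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "MazeGeometry":
        plats = sorted(d["platforms"], key=lambda p: p["id"])
        centers = np.array([[p["cx"], p["cy"]] for p in plats])
        return cls(
            hex_side=d["hex_side"],
            orientation_deg=d["orientation"],
            centers=centers,
            adjacency=[tuple(p) for p in d["adjacency"]],
            goal=d.get("goal"),
        )

    @classmethod
    def from_json(cls, path) -> "MazeGeometry":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def build_honeycomb(
    hex_side: float = 11.5,
    orientation_deg: float = 0.0,
    goal: int | None = None,
) -> MazeGeometry:
    """Build the 61-platform honeycomb maze.

    Adjacent platform centres are exactly ``sqrt(3) * hex_side`` apart.  The
    default orientation puts one neighbour axis along +x.  Platform ids are
    assigned ring by ring, counter-clockwise within a ring, id 0 at the
    centre.
    """
    if hex_side <= 0:
        raise ValueError("hex_side must be positive")
    spacing = np.sqrt(3.0) * hex_side
    rot = np.deg2rad(orientation_deg)
    v1 = spacing * np.array([np.cos(rot), np.sin(rot)])
    v2 = spacing * np.array([np.cos(rot + np.pi / 3), np.sin(rot + np.pi / 3)])

    cells = []
    rng_axial = range(-(N_RINGS - 1), N_RINGS)
    for a in rng_axial:
        for b in rng_axial:
            ring = (abs(a) + abs(b) + abs(a + b)) // 2
            if ring <= N_RINGS - 1:
                cells.append((ring, a, b))
    # deterministic ordering: ring, then angle counter-clockwise
    def _key(cell):
        ring, a, b = cell
        xy = a * v1 + b * v2
        ang = np.arctan2(xy[1], xy[0]) % (2 * np.pi) if ring else 0.0
        return (ring, ang)

    cells.sort(key=_key)
    centers = np.array([a * v1 + b * v2 for _, a, b in cells])

    tol = 1e-6 * spacing
    adjacency = []
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            if abs(np.linalg.norm(centers[i] - centers[j]) - spacing) < tol:
                adjacency.append((i, j))
    return MazeGeometry(hex_side, orientation_deg, centers, adjacency, goal)


def bearing(from_xy, to_xy) -> np.ndarray:
    """Allocentric bearing (degrees in [0, 360)) from one point to another."""
    f = np.asarray(from_xy, dtype=float)
    t = np.asarray(to_xy, dtype=float)
    d = t - f
    return wrap_360(np.rad2deg(np.arctan2(d[..., 1], d[..., 0])))


def relative_direction(head_dir_deg, pos, ref) -> np.ndarray:
    """Egocentric direction of *ref* relative to the animal's heading.

    ``wrap_180(head_dir - bearing(pos -> ref))``: 0° when facing the
    reference point, 180° when facing away, positive when the point lies to
    the animal's right.
    """
    pos = np.asarray(pos, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if np.any(np.all(np.isclose(np.atleast_2d(pos), np.atleast_2d(ref)), axis=-1)):
        raise ValueError("bearing undefined: position coincides with reference")
    return wrap_180(np.asarray(head_dir_deg, dtype=float) - bearing(pos, ref))
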
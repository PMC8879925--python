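"""Parametric Y-maze geometry.

The maze is three rectangular arms attached to the sides of a central
equilateral-triangle junction. Coordinates are maze-local centimetres with
the origin at the junction centroid. Arm bearings default to 90, 210 and
330 degrees (counter-clockwise from +x).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

ARM_NAMES = ("A", "B", "C")

#: integer zone codes used in vectorized zone series
ZONE_JUNCTION = 3
ZONE_CODES = {"A": 0, "B": 1, "C": 2, "junction": ZONE_JUNCTION}
ZONE_LABELS = {v: k for k, v in ZONE_CODES.items()}


class GeometryError(ValueError):
    """Raised for degenerate maze geometry (zero-area arms etc.)."""


@dataclass(frozen=True)
class MazeGeometry:
    """Three-armed maze: junction triangle plus rectangular arms.

    Parameters
    ----------
    arm_length, arm_width : float
        Inner dimensions of each arm in cm.
    arm_angles_deg : tuple of float
        Outward bearing of each arm, degrees CCW from +x; must be three
        mutually distinct angles 120 degrees apart.
    """

    arm_length: float = 25.0
    arm_width: float = 8.0
    arm_angles_deg: tuple[float, float, float] = (90.0, 210.0, 330.0)

    # derived, filled in __post_init__
    _units: tuple = field(init=False, repr=False, default=())

    def __post_init__(self):
        if self.arm_length <= 0 or self.arm_width <= 0:
            raise GeometryError("arm_length and arm_width must be positive")
        if len(self.arm_angles_deg) != 3:
            raise GeometryError("exactly three arms required")
        angles = sorted(a % 360.0 for a in self.arm_angles_deg)
        gaps = {round((angles[(i + 1) % 3] - angles[i]) % 360.0, 6) for i in range(3)}
        if gaps != {120.0}:
            raise GeometryError("arm bearings must be 120 degrees apart")
        units = tuple(
            (math.cos(math.radians(a)), math.sin(math.radians(a)))
            for a in self.arm_angles_deg
        )
        object.__setattr__(self, "_units", units)

    # --- derived scalars -------------------------------------------------
    @property
    def apothem(self) -> float:
        """Distance from origin to each junction-triangle side (arm opening)."""
        return self.arm_width / (2.0 * math.sqrt(3.0))

    # --- polygons (shapely) ---------------------------------------------
    @property
    def junction_polygon(self) -> Polygon:
        r = self.arm_width / math.sqrt(3.0)
        verts = []
        for i in range(3):
            a = math.radians(self.arm_angles_deg[i]) + math.pi / 3.0
            verts.append((r * math.cos(a), r * math.sin(a)))
        return Polygon(verts)

    def arm_polygon(self, arm: str) -> Polygon:
        i = ARM_NAMES.index(arm)
        ux, uy = self._units[i]
        nx, ny = -uy, ux
        a, L, h = self.apothem, self.arm_length, self.arm_width / 2.0
        corners = [
            (a * ux + h * nx, a * uy + h * ny),
            (a * ux - h * nx, a * uy - h * ny),
            ((a + L) * ux - h * nx, (a + L) * uy - h * ny),
            ((a + L) * ux + h * nx, (a + L) * uy + h * ny),
        ]
        return Polygon(corners)

    @property
    def polygons(self) -> dict[str, Polygon]:
        d = {name: self.arm_polygon(name) for name in ARM_NAMES}
        d["junction"] = self.junction_polygon
        return d

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full maze footprint."""
        xs, ys = [], []
        for p in self.polygons.values():
            b = p.bounds
            xs += [b[0], b[2]]
            ys += [b[1], b[3]]
        return min(xs), min(ys), max(xs), max(ys)

    def arm_waypoint(self, arm: str, frac: float = 0.75) -> tuple[float, float]:
        """Point on an arm's midline, ``frac`` of the way to the distal end."""
        i = ARM_NAMES.index(arm)
        ux, uy = self._units[i]
        d = self.apothem + frac * self.arm_length
        return d * ux, d * uy

    # --- fast analytic containment (no shapely in hot loops) -------------
    def contains(self, x: float, y: float, tol: float = 1e-9) -> bool:
        a, L, h = self.apothem, self.arm_length, self.arm_width / 2.0
        in_junction = True
        for ux, uy in self._units:
            along = x * ux + y * uy
            if along > a + tol:
                in_junction = False
            if -tol <= along - a and along <= a + L + tol:
                perp = -x * uy + y * ux
                if abs(perp) <= h + tol:
                    return True
        return in_junction

    def zone_codes_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized zone assignment.

        Returns ``(codes, snapped)`` where ``codes[k]`` is the integer zone
        of sample ``k`` and ``snapped[k]`` is True for samples outside every
        maze polygon that were assigned their nearest zone.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        n = x.shape[0]
        a, L, h = self.apothem, self.arm_length, self.arm_width / 2.0
        codes = np.full(n, -1, dtype=np.int8)
        # distance to each zone, used for snapping outsiders
        dist = np.empty((4, n))
        in_junction = np.ones(n, dtype=bool)
        for i, (ux, uy) in enumerate(self._units):
            along = x * ux + y * uy
            perp = -x * uy + y * ux
            in_junction &= along <= a + 1e-9
            in_arm = (along >= a - 1e-9) & (along <= a + L + 1e-9) & (np.abs(perp) <= h + 1e-9)
            codes = np.where((codes == -1) & in_arm, np.int8(i), codes)
            # rectangle distance in arm-local coordinates
            dx = np.maximum(np.maximum(a - along, along - (a + L)), 0.0)
            dy = np.maximum(np.abs(perp) - h, 0.0)
            dist[i] = np.hypot(dx, dy)
        codes = np.where((codes == -1) & in_junction, np.int8(ZONE_JUNCTION), codes)
        # junction distance: outside iff some along > a
        over = np.zeros(n)
        for ux, uy in self._units:
            over = np.maximum(over, x * ux + y * uy - a)
        dist[ZONE_JUNCTION] = np.maximum(over, 0.0)
        snapped = codes == -1
        if snapped.any():
            codes[snapped] = np.argmin(dist[:, snapped], axis=0).astype(np.int8)
        return codes, snapped
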
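"""Pool geometry for the Morris water maze.

Coordinates are pool-centered Cartesian, in centimetres.  The default
geometry is a 170 cm diameter circular pool with a 12 cm diameter escape
platform whose edge sits 22 cm from the wall, in the NE quadrant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

#: Quadrant labels ordered counterclockwise starting from the +x/+y quadrant.
QUADRANTS = ("NE", "NW", "SW", "SE")

_QUADRANT_SIGNS = {
    "NE": (1.0, 1.0),
    "NW": (-1.0, 1.0),
    "SW": (-1.0, -1.0),
    "SE": (1.0, -1.0),
}

_OPPOSITE = {"NE": "SW", "NW": "SE", "SW": "NE", "SE": "NW"}


@dataclass(frozen=True)
class PoolGeometry:
    """Circular pool with an escape platform.

    Parameters
    ----------
    pool_radius : float
        Pool radius in cm (default 85, i.e. a 1.70 m diameter pool).
    platform_radius : float
        Platform radius in cm (default 6, i.e. 12 cm diameter).
    platform_wall_distance : float
        Gap between the platform edge and the pool wall, in cm.
    target_quadrant : str
        Quadrant holding the platform, one of ``NE``, ``NW``, ``SW``, ``SE``.
    periphery_band_width : float
        Width of the peripheral (thigmotaxis) annulus, in cm.  The
        convention here is the outer 20 % of the radius (17 cm); the band
        is a free parameter of the analysis and is always reported.
    corridor_half_width : float
        Half-width of the optimal release-to-goal corridor used by the
        path-directness (Whishaw) index, in cm.
    platform_center : tuple of float, optional
        Explicit platform center.  When omitted it is placed on the 45°
        diagonal of ``target_quadrant`` with the platform edge
        ``platform_wall_distance`` cm from the wall.
    """

    pool_radius: float = 85.0
    platform_radius: float = 6.0
    platform_wall_distance: float = 22.0
    target_quadrant: str = "NE"
    periphery_band_width: float = 17.0
    corridor_half_width: float = 12.0
    platform_center: tuple[float, float] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.pool_radius <= 0:
            raise ValueError("pool_radius must be positive")
        if self.target_quadrant not in QUADRANTS:
            raise ValueError(f"unknown quadrant {self.target_quadrant!r}")
        if not 0 < self.periphery_band_width < self.pool_radius:
            raise ValueError("periphery_band_width must lie in (0, pool_radius)")
        if self.platform_center is None:
            r = self.pool_radius - self.platform_wall_distance - self.platform_radius
            if r <= 0:
                raise ValueError("platform does not fit inside the pool")
            sx, sy = _QUADRANT_SIGNS[self.target_quadrant]
            c = r / math.sqrt(2.0)
            object.__setattr__(self, "platform_center", (sx * c, sy * c))
        cx, cy = self.platform_center
        if math.hypot(cx, cy) + self.platform_radius > self.pool_radius + 1e-9:
            raise ValueError("platform must lie entirely inside the pool")
        if quadrant_of(cx, cy) != self.target_quadrant:
            raise ValueError("platform_center is not in target_quadrant")

    def reversed(self) -> "PoolGeometry":
        """Geometry for reversal sessions: platform point-reflected through
        the pool center, target quadrant swapped to the opposite one."""
        cx, cy = self.platform_center
        return replace(
            self,
            platform_center=(-cx, -cy),
            target_quadrant=_OPPOSITE[self.target_quadrant],
        )

    def start_position(self, label: str) -> tuple[float, float]:
        """Release position on the pool rim for a compass label N/S/E/W."""
        r = self.pool_radius
        positions = {"N": (0.0, r), "S": (0.0, -r), "E": (r, 0.0), "W": (-r, 0.0)}
        try:
            return positions[label]
        except KeyError:
            raise ValueError(f"unknown start point {label!r}") from None


def quadrant_of(x: float, y: float) -> str:
    """Quadrant label of a point; boundary points go to the
    counterclockwise-first quadrant (angle bins [0°,90°), [90°,180°), ...)."""
    theta = math.atan2(y, x) % (2.0 * math.pi)
    return QUADRANTS[int(theta // (math.pi / 2.0)) % 4]


def quadrant_labels(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized :func:`quadrant_of` over coordinate arrays."""
    theta = np.mod(np.arctan2(y, x), 2.0 * np.pi)
    idx = np.minimum((theta // (np.pi / 2.0)).astype(int), 3)
    return np.asarray(QUADRANTS, dtype=object)[idx]
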
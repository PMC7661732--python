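"""Field-of-view geometries for immobilized cell populations.

Microscopy fields of view are either circular (set by the objective and
detector) or square crops.  Both are represented as shapely regions so that
Voronoi polygons can be clipped against them and uniform placement can be
done by rejection sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Point, Polygon, box

#: segments per quarter arc used to discretize circular fields
_CIRCLE_QUAD_SEGS = 64


@dataclass(frozen=True)
class Circle:
    """Circular field of view centred on the origin.

    Parameters
    ----------
    diameter_um : float
        Diameter of the field of view in micrometres.
    """

    diameter_um: float

    @property
    def radius_um(self) -> float:
        return self.diameter_um / 2.0

    @property
    def region(self) -> Polygon:
        return Point(0.0, 0.0).buffer(self.radius_um, quad_segs=_CIRCLE_QUAD_SEGS)

    @property
    def area_um2(self) -> float:
        """Area of the (discretized) field region in square micrometres."""
        return self.region.area

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        r = self.radius_um
        return (-r, -r, r, r)

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return np.hypot(x, y) < self.radius_um

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        # exact uniform draw in a disc: sqrt-radius trick, no rejection needed
        r = self.radius_um * np.sqrt(rng.uniform(0.0, 1.0, size=n))
        theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
        return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


@dataclass(frozen=True)
class Square:
    """Square field of view centred on the origin.

    Parameters
    ----------
    side_um : float
        Side length in micrometres.
    """

    side_um: float

    @property
    def region(self) -> Polygon:
        h = self.side_um / 2.0
        return box(-h, -h, h, h)

    @property
    def area_um2(self) -> float:
        return self.side_um**2

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        h = self.side_um / 2.0
        return (-h, -h, h, h)

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        h = self.side_um / 2.0
        return (np.abs(x) < h) & (np.abs(y) < h)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        h = self.side_um / 2.0
        return rng.uniform(-h, h, size=(n, 2))


Geometry = Circle | Square


def geometry_from_dict(spec: dict) -> Geometry:
    """Build a geometry from ``{"shape": "circle", "diameter_um": 169}`` etc."""
    shape = spec.get("shape")
    if shape == "circle":
        return Circle(float(spec["diameter_um"]))
    if shape == "square":
        return Square(float(spec["side_um"]))
    raise ValueError(f"unknown geometry shape {shape!r}")


def geometry_to_dict(geom: Geometry) -> dict:
    if isinstance(geom, Circle):
        return {"shape": "circle", "diameter_um": geom.diameter_um}
    if isinstance(geom, Square):
        return {"shape": "square", "side_um": geom.side_um}
    raise TypeError(f"not a geometry: {geom!r}")


def raster_resolution_um(geom: Geometry, n_pixels: int = 512) -> float:
    """Pixel size when the field of view is binned into ``n_pixels`` squares.

    A 169-um circular field binned into a 512 x 512 raster gives
    0.33 um per pixel.
    """
    xmin, ymin, xmax, ymax = geom.bounds
    return (xmax - xmin) / n_pixels
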
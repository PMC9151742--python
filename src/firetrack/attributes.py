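"""Per-fire attributes: dominant land cover, fuel moisture at ignition,
fire-type classification, static-source flagging, and scalar properties.

Land cover uses a 7-class merged legend (water, urban, barren, forest,
shrub, grassland, agriculture).  Fire type combines the dominant class
inside the perimeter with the 1000-hr dead fuel moisture (FM-1000, percent)
at the ignition time step: moist-condition forest/shrub/grassland fires are
wildfires, dry-condition ones management (prescribed) fires, and
agriculture/urban/other classes map directly.

Rasters are single-band regular grids georeferenced in the equal-area
metre plane, stored on disk as Esri ASCII grids (plain text).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from shapely import contains_xy as _vec_contains

from firetrack.config import TrackerConfig
from firetrack.geometry import HullGeometry

if TYPE_CHECKING:  # pragma: no cover
    from firetrack.tracker import FireObject


class LandCover(enum.IntEnum):
    WATER = 1
    URBAN = 2
    BARREN = 3
    FOREST = 4
    SHRUB = 5
    GRASSLAND = 6
    AGRICULTURE = 7


class FireType(str, enum.Enum):
    FOREST_WILDFIRE = "forest_wildfire"
    FOREST_MANAGEMENT = "forest_management"
    SHRUB_WILDFIRE = "shrub_wildfire"
    SHRUB_MANAGEMENT = "shrub_management"
    AGRICULTURE = "agriculture"
    URBAN = "urban"
    OTHER = "other"


@dataclass
class Raster:
    """Single-band regular raster in the projected metre plane.

    ``data`` is row-major with row 0 at the *top* (largest y), matching the
    ASCII-grid convention.  ``xll, yll`` is the lower-left corner of the
    grid, ``cellsize`` the square cell edge in metres.
    """

    data: np.ndarray
    xll: float
    yll: float
    cellsize: float
    nodata: float = -9999.0

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (self.xll, self.yll,
                self.xll + self.ncols * self.cellsize,
                self.yll + self.nrows * self.cellsize)

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid arrays (x, y) of all cell-centre coordinates."""
        xs = self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize
        ys = self.yll + (np.arange(self.nrows)[::-1] + 0.5) * self.cellsize
        return np.meshgrid(xs, ys)

    def sample(self, x: float, y: float) -> float:
        """Value of the cell containing (x, y); nearest cell if outside."""
        col = int(np.clip((x - self.xll) // self.cellsize, 0, self.ncols - 1))
        row_from_bottom = int(np.clip((y - self.yll) // self.cellsize, 0, self.nrows - 1))
        return float(self.data[self.nrows - 1 - row_from_bottom, col])

    def write_ascii(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"ncols {self.ncols}\n")
            fh.write(f"nrows {self.nrows}\n")
            fh.write(f"xllcorner {self.xll!r}\n")
            fh.write(f"yllcorner {self.yll!r}\n")
            fh.write(f"cellsize {self.cellsize!r}\n")
            fh.write(f"NODATA_value {self.nodata!r}\n")
            np.savetxt(fh, self.data, fmt="%.6g")

    @classmethod
    def read_ascii(cls, path) -> "Raster":
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            data = np.loadtxt(fh)
        data = np.atleast_2d(data)
        return cls(data=data, xll=header["xllcorner"], yll=header["yllcorner"],
                   cellsize=header["cellsize"],
                   nodata=header.get("nodata_value", -9999.0))


#: A land-cover grid is a Raster of LandCover integer codes.
LandCoverGrid = Raster
#: A fuel-moisture field is a Raster of FM-1000 percentages (>= 0).
FuelMoistureField = Raster


@dataclass
class FireProperties:
    """Scalar per-fire attributes derived at a time step."""

    farea: float  # km2, hull area
    centroid: tuple[float, float]  # (lat, lon) of hull centroid
    pixden: float  # pixels per km2, cumulative since ignition
    meanFRP: float | None  # MW, mean over this step's new pixels (None if none)
    LCTmax: LandCover | None
    stFM1000: float | None  # percent, at ignition centroid & step
    fperim: float  # km, hull boundary length
    flinelen: float  # km, active fireline length
    duration: float  # days, t_ed - t_st


def dominant_landcover(hull: HullGeometry, grid: LandCoverGrid) -> LandCover:
    """Modal land-cover class over the cells whose centres fall inside the
    fire perimeter; for hulls too small to capture a cell centre, the class
    at the hull centroid.  Ties go to the lowest class code.
    """
    xmin, ymin, xmax, ymax = grid.bounds
    gx, gy = hull.shape.bounds[0], hull.shape.bounds[1]
    if hull.shape.bounds[2] < xmin or gx > xmax or hull.shape.bounds[3] < ymin or gy > ymax:
        raise ValueError("fire hull lies entirely outside the land-cover grid")
    cx, cy = grid.cell_centres()
    inside = _vec_contains(hull.shape, cx, cy)
    if inside.any():
        vals = grid.data[inside].astype(int)
        vals = vals[vals != int(grid.nodata)]
        if len(vals):
            codes, counts = np.unique(vals, return_counts=True)
            return LandCover(int(codes[np.argmax(counts)]))
    c = hull.shape.centroid
    return LandCover(int(grid.sample(c.x, c.y)))


def classify_fire_type(lct: LandCover, fm1000: float | None,
                       threshold: float = 12.0) -> FireType:
    """Fire type from dominant land cover and ignition-time FM-1000.

    Forest with FM-1000 >= threshold (percent) is a forest wildfire,
    below it a forest management fire; shrub and grassland likewise split
    into shrub wildfire / shrub management fire.  Agriculture, urban and
    water/barren classes map unconditionally.
    """
    lct = LandCover(lct)
    if lct is LandCover.FOREST:
        if fm1000 is None:
            raise ValueError("FM-1000 required to classify forest fires")
        return (FireType.FOREST_WILDFIRE if fm1000 >= threshold
                else FireType.FOREST_MANAGEMENT)
    if lct in (LandCover.SHRUB, LandCover.GRASSLAND):
        if fm1000 is None:
            raise ValueError("FM-1000 required to classify shrub/grassland fires")
        return (FireType.SHRUB_WILDFIRE if fm1000 >= threshold
                else FireType.SHRUB_MANAGEMENT)
    if lct is LandCover.AGRICULTURE:
        return FireType.AGRICULTURE
    if lct is LandCover.URBAN:
        return FireType.URBAN
    if lct in (LandCover.WATER, LandCover.BARREN):
        return FireType.OTHER
    raise ValueError(f"unknown land-cover class: {lct}")  # pragma: no cover


def flag_static(fire: "FireObject", config: TrackerConfig | None = None) -> bool:
    """Persistent-hotspot test: a small fire (area below the configured
    20 km2 cap) with cumulative pixel density above 20 per km2 is a static
    non-vegetation heat source (gas flare, landfill, solar reflection)."""
    config = config or TrackerConfig()
    if fire.hull is None:
        return False
    farea = fire.hull.area_km2
    if farea >= config.static_max_area or farea <= 0:
        return False
    return len(fire.pixels) / farea > config.static_min_density


def refresh_properties(fire: "FireObject",
                       fm_field: FuelMoistureField | None = None,
                       lct_grid: LandCoverGrid | None = None,
                       config: TrackerConfig | None = None) -> FireProperties:
    """Recompute the scalar attribute block of a fire from its current
    geometry and pixel sets.

    Mean FRP averages only the pixels newly detected at the current step
    (None on a step with no new pixels).  The ignition-time fuel moisture
    is sampled once, at the ignition-pixel centroid, and kept thereafter.
    The dominant land cover is re-evaluated every step as the perimeter
    grows.
    """
    config = config or TrackerConfig()
    hull = fire.hull
    c = hull.shape.centroid
    clat, clon = fire.proj.inverse(c.x, c.y)
    farea = hull.area_km2
    mean_frp = (float(np.mean([p.frp for p in fire.newpixels]))
                if fire.newpixels else None)

    lct = None
    if lct_grid is not None:
        lct = dominant_landcover(hull, lct_grid)

    st_fm = fire.properties.stFM1000 if fire.properties is not None else None
    if st_fm is None and fm_field is not None:
        ix = float(np.mean([p.x for p in fire.ignpixels]))
        iy = float(np.mean([p.y for p in fire.ignpixels]))
        st_fm = fm_field.sample(ix, iy)

    return FireProperties(
        farea=farea,
        centroid=(clat, clon),
        pixden=len(fire.pixels) / farea if farea > 0 else float("nan"),
        meanFRP=mean_frp,
        LCTmax=lct,
        stFM1000=st_fm,
        fperim=hull.boundary_km,
        flinelen=fire.fline.length_km if fire.fline is not None else 0.0,
        duration=fire.t_ed.diff_days(fire.t_st),
    )
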
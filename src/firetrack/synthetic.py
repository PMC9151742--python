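"""Ground-truthed synthetic detection scenarios.

The simulator is an observation-process emulator, not a fire-behaviour
model: a fire's true footprint grows as an ellipse (closed-form area, so
downstream checks are exact) oriented by a wind direction, and a satellite
"sees" it twice a day on a ~375 m detection grid with imperfect detection
probability, positional jitter and lognormal fire radiative power.  Static
industrial heat sources emit 1-3 detections per step at a fixed location.
Block land-cover and smooth fuel-moisture rasters complete the inputs the
tracker needs, so every module of the system is testable offline.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely import affinity, contains_xy
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

from firetrack.attributes import FuelMoistureField, LandCover, LandCoverGrid, Raster
from firetrack.config import TrackerConfig
from firetrack.geometry import AlbersEqualArea
from firetrack.ingest import Confidence, PixelRecord, TimeStep


@dataclass
class SpreadScenario:
    """Parameters of one elliptically spreading fire as observed half-daily.

    ``rate_along``/``rate_cross`` are the growth of the footprint
    semi-axes per half-day (metres), oriented by ``wind_deg`` (degrees
    clockwise from north for the along-wind axis).  Detections are laid on
    a ``spacing``-metre grid over the newly burned ring, kept with
    ``detect_prob``, jittered by a ``jitter_sd``-metre Gaussian, and given
    lognormal FRP (median ``exp(frp_mu)`` MW)."""

    ignition_lat: float = 38.0
    ignition_lon: float = -120.5
    start: TimeStep = field(default_factory=lambda: TimeStep(_dt.date(2020, 8, 1), "AM"))
    duration_steps: int = 12
    rate_along: float = 500.0  # m per half-day
    rate_cross: float = 250.0
    wind_deg: float = 45.0
    detect_prob: float = 0.95
    spacing: float = 375.0  # m, nadir detection-grid spacing
    jitter_sd: float = 40.0  # m
    frp_mu: float = 1.0  # lognormal params, MW
    frp_sigma: float = 0.8
    ignition_radius: float = 187.5  # m, footprint before any growth
    seed: int = 0

    def __post_init__(self):
        if self.rate_along < 0 or self.rate_cross < 0:
            raise ValueError("spread rates must be >= 0")
        if not 0.0 < self.detect_prob <= 1.0:
            raise ValueError("detection probability must be in (0, 1]")


@dataclass
class TruthSequence:
    """Per-step true cumulative footprints and emitted detection batches."""

    scenario: SpreadScenario
    steps: list[TimeStep]
    footprints: list[BaseGeometry]  # metre plane, cumulative (nested)
    batches: list[list[PixelRecord]] = field(default_factory=list)

    @property
    def final_footprint(self) -> BaseGeometry:
        return self.footprints[-1]

    def all_records(self) -> list[PixelRecord]:
        return [r for batch in self.batches for r in batch]


def _footprint(scn: SpreadScenario, k: int, cx: float, cy: float) -> BaseGeometry:
    """True cumulative footprint at growth step k (k = 1 at the first
    observed step; the ignition disc is a lower bound on both axes)."""
    a = max(k * scn.rate_along, scn.ignition_radius)
    b = max(k * scn.rate_cross, scn.ignition_radius)
    ell = Point(cx, cy).buffer(1.0, quad_segs=64)
    ell = affinity.scale(ell, a, b)
    # along-wind axis starts on +y (north); clockwise wind angle
    return affinity.rotate(ell, -scn.wind_deg + 90.0, origin=(cx, cy))


def simulate_spread(scn: SpreadScenario,
                    proj: AlbersEqualArea | None = None) -> TruthSequence:
    """Grow the true footprint for ``duration_steps`` half-daily steps.

    Footprints are nested by construction (semi-axes grow linearly), and
    the whole sequence is a pure function of the scenario."""
    proj = proj or AlbersEqualArea()
    cx, cy = proj.forward(scn.ignition_lat, scn.ignition_lon)
    steps = [scn.start]
    for _ in range(scn.duration_steps - 1):
        steps.append(steps[-1].next())
    footprints = [_footprint(scn, k, cx, cy) for k in range(1, len(steps) + 1)]
    return TruthSequence(scenario=scn, steps=steps, footprints=footprints)


def _overpass_utc(step: TimeStep, utc_offset_hours: float) -> _dt.datetime:
    local = _dt.datetime.combine(step.date, _dt.time(1 if step.half == "AM" else 13, 30))
    return local - _dt.timedelta(hours=utc_offset_hours)


def sample_detections(truth: TruthSequence,
                      proj: AlbersEqualArea | None = None,
                      config: TrackerConfig | None = None,
                      rng: np.random.Generator | None = None) -> TruthSequence:
    """Emit half-daily detection batches from the true footprints.

    At each step a detection grid at the scenario spacing is laid over the
    newly burned ring (current minus previous footprint; the full footprint
    at ignition).  Each node is detected with the scenario probability,
    jittered, and assigned a lognormal FRP and the step's overpass
    timestamp.  Deterministic given the scenario seed."""
    scn = truth.scenario
    proj = proj or AlbersEqualArea()
    config = config or TrackerConfig()
    rng = rng or np.random.default_rng(scn.seed)
    cx, cy = proj.forward(scn.ignition_lat, scn.ignition_lon)
    truth.batches = []
    prev = None
    for step, foot in zip(truth.steps, truth.footprints):
        ring = foot if prev is None else foot.difference(prev)
        prev = foot
        batch: list[PixelRecord] = []
        if not ring.is_empty and ring.area > 0:
            xmin, ymin, xmax, ymax = ring.bounds
            # grid aligned to the ignition point for determinism
            xs = cx + scn.spacing * np.arange(math.floor((xmin - cx) / scn.spacing),
                                              math.ceil((xmax - cx) / scn.spacing) + 1)
            ys = cy + scn.spacing * np.arange(math.floor((ymin - cy) / scn.spacing),
                                              math.ceil((ymax - cy) / scn.spacing) + 1)
            gx, gy = np.meshgrid(xs, ys)
            gx, gy = gx.ravel(), gy.ravel()
            inside = contains_xy(ring, gx, gy)
            gx, gy = gx[inside], gy[inside]
            keep = rng.random(len(gx)) <= scn.detect_prob
            gx, gy = gx[keep], gy[keep]
            jx = rng.normal(0.0, scn.jitter_sd, len(gx))
            jy = rng.normal(0.0, scn.jitter_sd, len(gx))
            frp = rng.lognormal(scn.frp_mu, scn.frp_sigma, len(gx))
            when = _overpass_utc(step, config.utc_offset_hours)
            lat, lon = proj.inverse(gx + jx, gy + jy)
            for la, lo, fr in zip(np.atleast_1d(lat), np.atleast_1d(lon),
                                  np.atleast_1d(frp)):
                batch.append(PixelRecord(lat=float(la), lon=float(lo),
                                         frp=float(fr), acq_datetime=when,
                                         anomaly_type=0,
                                         confidence=Confidence.NOMINAL))
        truth.batches.append(batch)
    return truth


def simulate_static_source(lat: float, lon: float, start: TimeStep,
                           n_steps: int, seed: int = 0,
                           config: TrackerConfig | None = None) -> list[PixelRecord]:
    """Persistent industrial hotspot: 1-3 detections per step at a fixed
    location with ~50 m jitter, for ``n_steps`` consecutive steps."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    config = config or TrackerConfig()
    rng = np.random.default_rng(seed)
    proj = AlbersEqualArea()
    cx, cy = proj.forward(lat, lon)
    records: list[PixelRecord] = []
    step = start
    for _ in range(n_steps):
        n = int(rng.integers(1, 4))
        for _ in range(n):
            x = cx + rng.normal(0.0, 50.0)
            y = cy + rng.normal(0.0, 50.0)
            la, lo = proj.inverse(x, y)
            records.append(PixelRecord(
                lat=la, lon=lo, frp=float(rng.lognormal(0.5, 0.5)),
                acq_datetime=_overpass_utc(step, config.utc_offset_hours),
                anomaly_type=0, confidence=Confidence.HIGH))
        step = step.next()
    return records


def synth_rasters(extent: tuple[float, float, float, float],
                  composition: dict[LandCover, float],
                  seed: int = 0, cellsize: float = 500.0,
                  fm_mean: float = 15.0, fm_sd: float = 1.0,
                  ) -> tuple[LandCoverGrid, FuelMoistureField]:
    """Block land-cover raster with the requested class fractions (vertical
    strips, west to east in class order) and a smooth fuel-moisture field
    around ``fm_mean`` percent, both over ``extent`` = (xmin, ymin, xmax,
    ymax) metres in the projected plane."""
    total = sum(composition.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"composition fractions must sum to 1, got {total}")
    xmin, ymin, xmax, ymax = extent
    ncols = max(int(math.ceil((xmax - xmin) / cellsize)), 1)
    nrows = max(int(math.ceil((ymax - ymin) / cellsize)), 1)
    lct = np.zeros((nrows, ncols), dtype=float)
    col = 0
    items = sorted(composition.items(), key=lambda kv: int(kv[0]))
    for i, (cls, frac) in enumerate(items):
        width = ncols - col if i == len(items) - 1 else int(round(frac * ncols))
        lct[:, col:col + width] = int(cls)
        col += width
    rng = np.random.default_rng(seed)
    noise = gaussian_filter(rng.standard_normal((nrows, ncols)), sigma=5.0)
    sd = noise.std() or 1.0
    fm = np.maximum(fm_mean + fm_sd * noise / sd, 0.0)
    lct_grid = Raster(data=lct, xll=xmin, yll=ymin, cellsize=cellsize)
    fm_field = Raster(data=fm, xll=xmin, yll=ymin, cellsize=cellsize)
    return lct_grid, fm_field


# ---------------------------------------------------------------------------
# canonical test scenarios
# ---------------------------------------------------------------------------

@dataclass
class ScenarioBundle:
    """Everything a tracking run needs: detections, truth, rasters, region."""

    records: list[PixelRecord]
    truths: list[TruthSequence]
    lct_grid: LandCoverGrid
    fm_field: FuelMoistureField
    roi: BaseGeometry  # lon/lat
    start: TimeStep
    end: TimeStep


def _bundle(truths: list[TruthSequence], extra: list[PixelRecord],
            proj: AlbersEqualArea, seed: int,
            composition: dict[LandCover, float] | None = None,
            fm_mean: float = 15.0) -> ScenarioBundle:
    from shapely.geometry import box

    scn = truths[0].scenario
    cx, cy = proj.forward(scn.ignition_lat, scn.ignition_lon)
    ext = (cx - 40_000.0, cy - 40_000.0, cx + 40_000.0, cy + 40_000.0)
    lct, fm = synth_rasters(ext, composition or {LandCover.FOREST: 1.0},
                            seed=seed, fm_mean=fm_mean)
    lat0, lon0 = proj.inverse(ext[0], ext[1])
    lat1, lon1 = proj.inverse(ext[2], ext[3])
    roi = box(min(lon0, lon1) - 0.5, min(lat0, lat1) - 0.5,
              max(lon0, lon1) + 0.5, max(lat0, lat1) + 0.5)
    records = [r for t in truths for r in t.all_records()] + extra
    return ScenarioBundle(records=records, truths=truths, lct_grid=lct,
                          fm_field=fm, roi=roi, start=truths[0].steps[0],
                          end=truths[0].steps[-1])


def default_scenario(seed: int = 0,
                     proj: AlbersEqualArea | None = None) -> ScenarioBundle:
    """One elliptically spreading forest fire observed for 6 days."""
    proj = proj or AlbersEqualArea()
    truth = sample_detections(simulate_spread(SpreadScenario(seed=seed), proj), proj)
    return _bundle([truth], [], proj, seed + 1000)


def static_scenario(seed: int = 0,
                    proj: AlbersEqualArea | None = None) -> ScenarioBundle:
    """The default spreading fire plus a persistent static hotspot ~30 km
    away, present at every step of the run."""
    proj = proj or AlbersEqualArea()
    scn = SpreadScenario(seed=seed)
    truth = sample_detections(simulate_spread(scn, proj), proj)
    static = simulate_static_source(scn.ignition_lat + 0.2,
                                    scn.ignition_lon + 0.25,
                                    truth.steps[0], len(truth.steps),
                                    seed=seed + 1)
    return _bundle([truth], static, proj, seed + 1000)


def merge_scenario(seed: int = 0, separation_m: float = 12_000.0,
                   proj: AlbersEqualArea | None = None) -> ScenarioBundle:
    """Two forest fires igniting simultaneously ``separation_m`` apart on a
    north-south axis, each spreading along that axis, so both form their
    own object and later grow into merging range of each other.

    The default 12 km separation exceeds the 5 km forest extended-area
    buffer at ignition (separate objects form) and closes below it by
    mid-run (a genuine merge with a heritage record).  Ignitions closer
    than the cluster linkage are aggregated at the clustering stage
    instead and never produce a heritage record — see
    :func:`close_ignitions_scenario`."""
    proj = proj or AlbersEqualArea()
    s1 = SpreadScenario(seed=seed, wind_deg=0.0)
    s2 = SpreadScenario(seed=seed + 1, wind_deg=0.0,
                        ignition_lat=s1.ignition_lat + separation_m / 111_000.0)
    t1 = sample_detections(simulate_spread(s1, proj), proj)
    t2 = sample_detections(simulate_spread(s2, proj), proj)
    return _bundle([t1, t2], [], proj, seed + 1000)


def close_ignitions_scenario(seed: int = 0, separation_m: float = 1000.0,
                             proj: AlbersEqualArea | None = None) -> ScenarioBundle:
    """Two forest fires igniting simultaneously ``separation_m`` (default
    1 km) apart: close enough that same-step clustering and the forest
    extended area keep them a single fire object from the start."""
    return merge_scenario(seed=seed, separation_m=separation_m, proj=proj)


def records_to_csv(records: list[PixelRecord], path) -> None:
    """Write detections in the CSV dialect the ingest module reads."""
    rows = [{
        "lat": r.lat, "lon": r.lon, "frp": r.frp,
        "acq_date": r.acq_datetime.strftime("%Y-%m-%d"),
        "acq_time": r.acq_datetime.strftime("%H%M"),
        "type": r.anomaly_type, "confidence": r.confidence.value,
    } for r in records]
    pd.DataFrame(rows, columns=["lat", "lon", "frp", "acq_date", "acq_time",
                                "type", "confidence"]).to_csv(path, index=False)
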
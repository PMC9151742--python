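"""The object lifecycle engine.

Each half-daily step, newly detected vegetation-fire pixels are grouped
into spatial clusters, each cluster is either appended to the nearest
active fire object whose *extended area* (perimeter plus a fire-type
dependent buffer: 5 km for forest fires, 1 km otherwise) it touches, or
seeds a new fire object.  Fires that grow into another active fire's
extended area are merged into the lower-id (earlier) fire; the higher-id
source is invalidated and the (source, target) pair recorded as heritage.
A fire with no new pixels for more than five consecutive days becomes
inactive and never again attracts clusters.

The engine is fully deterministic: cluster order follows record order, new
ids are issued sequentially, merges scan ascending source id to a fixpoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components
from sklearn.neighbors import NearestNeighbors

from firetrack.attributes import (
    FireProperties,
    FireType,
    FuelMoistureField,
    LandCoverGrid,
    classify_fire_type,
    flag_static,
    refresh_properties,
)
from firetrack.config import TrackerConfig, type_buffer
from firetrack.geometry import (
    AlbersEqualArea,
    FirelineGeometry,
    HullGeometry,
    active_fireline,
    fire_hull,
)
from firetrack.ingest import PixelRecord, TimeStep
from shapely.geometry import LineString, Point

logger = logging.getLogger(__name__)


@dataclass
class FirePixel:
    """One detection after assignment to a fire object."""

    x: float  # metres, projected plane
    y: float
    lat: float
    lon: float
    frp: float  # MW
    t: TimeStep
    origin: int | None = None  # fire id first assigned; set exactly once

    def assign(self, fid: int) -> None:
        if self.origin is not None:
            raise ValueError(f"pixel already assigned to fire {self.origin}")
        self.origin = fid


@dataclass
class Cluster:
    """Same-step pixels linked by chains of short gaps."""

    pixels: list[FirePixel]

    def __post_init__(self):
        if not self.pixels:
            raise ValueError("cluster must be non-empty")
        steps = {p.t for p in self.pixels}
        if len(steps) != 1:
            raise ValueError("all pixels in a cluster must share one time step")

    @property
    def points(self) -> np.ndarray:
        return np.array([[p.x, p.y] for p in self.pixels])


@dataclass
class FireObject:
    """One tracked fire event."""

    id: int
    proj: AlbersEqualArea
    pixels: list[FirePixel] = field(default_factory=list)
    newpixels: list[FirePixel] = field(default_factory=list)
    ignpixels: list[FirePixel] = field(default_factory=list)
    flinepixels: list[FirePixel] = field(default_factory=list)
    extpixels: list[FirePixel] = field(default_factory=list)
    t_st: TimeStep | None = None
    t_ed: TimeStep | None = None
    invalid: bool = False
    isactive: bool = True
    t_inactive: float = 0.0  # days since last new pixel
    hull: HullGeometry | None = None
    fline: FirelineGeometry | None = None
    ftype: FireType | None = None
    properties: FireProperties | None = None

    @property
    def duration(self) -> float:
        """Days between first and last detection."""
        if self.t_st is None or self.t_ed is None:
            return 0.0
        return self.t_ed.diff_days(self.t_st)

    def points(self) -> np.ndarray:
        return np.array([[p.x, p.y] for p in self.pixels])

    def update_geometry(self, config: TrackerConfig) -> None:
        """Recompute hull from all pixels and fireline from this step's
        new pixels; refresh the pixel sets derived from those geometries."""
        self.hull = fire_hull(self.points(), alpha=config.alpha,
                              buffer=config.hull_buffer)
        newpts = np.array([[p.x, p.y] for p in self.newpixels]).reshape(-1, 2)
        self.fline = active_fireline(self.hull, newpts,
                                     radius=config.fireline_radius)
        boundary = self.hull.shape.boundary
        self.extpixels = [p for p in self.pixels
                          if boundary.distance(Point(p.x, p.y)) <= config.fireline_radius]
        if self.fline.shape.is_empty:
            self.flinepixels = []
        else:
            self.flinepixels = [p for p in self.newpixels
                                if self.fline.shape.distance(Point(p.x, p.y))
                                <= config.fireline_radius]


@dataclass
class AllFires:
    """Region-wide tracking state at one time step."""

    t: TimeStep
    config: TrackerConfig = field(default_factory=TrackerConfig)
    proj: AlbersEqualArea | None = None
    fires: dict[int, FireObject] = field(default_factory=dict)
    heritages: list[tuple[int, int]] = field(default_factory=list)
    fids_expanded: list[int] = field(default_factory=list)
    fids_new: list[int] = field(default_factory=list)
    fids_merged: list[int] = field(default_factory=list)
    fids_invalid: list[int] = field(default_factory=list)
    next_id: int = 1

    def __post_init__(self):
        if self.proj is None:
            c = self.config
            self.proj = AlbersEqualArea(c.proj_lat0, c.proj_lon0,
                                        c.proj_lat1, c.proj_lat2)

    # -- views ---------------------------------------------------------
    def valid_fires(self) -> list[FireObject]:
        return [f for f in self.fires.values() if not f.invalid]

    def active_fires(self) -> list[FireObject]:
        return [f for f in self.valid_fires() if f.isactive]

    def issue_id(self) -> int:
        fid = self.next_id
        self.next_id += 1
        return fid


# ---------------------------------------------------------------------------
# step operations
# ---------------------------------------------------------------------------

def make_pixels(records: list[PixelRecord], step: TimeStep,
                proj: AlbersEqualArea) -> list[FirePixel]:
    """Project detection records into same-step tracker pixels."""
    out = []
    for r in records:
        x, y = proj.forward(r.lat, r.lon)
        out.append(FirePixel(x=x, y=y, lat=r.lat, lon=r.lon, frp=r.frp, t=step))
    return out


def cluster_pixels(pixels: list[FirePixel], linkage: float) -> list[Cluster]:
    """Single-linkage connected components: pixels chained by gaps of at
    most ``linkage`` metres form one cluster.  Implemented with a
    ball-tree radius-neighbour graph.  Clusters are ordered by the record
    order of their first pixel, for reproducible downstream id issuing."""
    if not pixels:
        return []
    if len(pixels) == 1:
        return [Cluster(list(pixels))]
    pts = np.array([[p.x, p.y] for p in pixels])
    tree = NearestNeighbors(radius=linkage, algorithm="ball_tree").fit(pts)
    graph = tree.radius_neighbors_graph(pts, mode="connectivity")
    n_comp, labels = connected_components(graph, directed=False)
    groups: dict[int, list[FirePixel]] = {}
    for pix, lab in zip(pixels, labels):
        groups.setdefault(int(lab), []).append(pix)
    # order clusters by first-pixel position in the input
    first_index = {lab: next(i for i, l in enumerate(labels) if l == lab)
                   for lab in groups}
    return [Cluster(groups[lab]) for lab in sorted(groups, key=first_index.get)]


def nearest_active_fire(cluster: Cluster, state: AllFires) -> tuple[int | None, float]:
    """The valid, active fire whose perimeter is nearest to the cluster and
    within that fire's type-dependent extended-area buffer; ties on
    distance go to the lower id.  Returns (None, inf) when no fire
    qualifies.  Distance is the minimum over the cluster's pixel points to
    the fire perimeter polygon (zero inside)."""
    best_fid, best_dist = None, float("inf")
    pts = [Point(p.x, p.y) for p in cluster.pixels]
    for fid in sorted(state.fires):
        fire = state.fires[fid]
        if fire.invalid or not fire.isactive or fire.hull is None:
            continue
        buf = type_buffer(fire.ftype.value if fire.ftype else None, state.config)
        d = min(fire.hull.shape.distance(pt) for pt in pts)
        if d <= buf and d < best_dist:
            best_fid, best_dist = fid, d
    return best_fid, best_dist


def apply_clusters(state: AllFires, clusters: list[Cluster]) -> AllFires:
    """Append each cluster to its nearest qualifying active fire, or create
    a new fire object from it.  Mutates and returns ``state``."""
    for cl in clusters:
        fid, _ = nearest_active_fire(cl, state)
        if fid is None:
            fid = state.issue_id()
            fire = FireObject(id=fid, proj=state.proj, t_st=state.t, t_ed=state.t)
            fire.ignpixels = list(cl.pixels)
            state.fires[fid] = fire
            state.fids_new.append(fid)
        else:
            fire = state.fires[fid]
            fire.t_ed = state.t
            if fid not in state.fids_expanded and fid not in state.fids_new:
                state.fids_expanded.append(fid)
        for p in cl.pixels:
            p.assign(fid)
        fire.pixels.extend(cl.pixels)
        fire.newpixels.extend(cl.pixels)
    return state


def merge_grown_fires(state: AllFires) -> AllFires:
    """Merge fires whose perimeters grew into another active fire's
    extended area.

    Scans source fires in ascending id, restarting after every merge until
    a fixpoint, so chains (9 into 5, then 5 into 2) resolve within one
    step.  All pixels move from the higher-id source to the lower-id
    target; the source is invalidated and (source, target) appended to the
    heritage list.  Geometries of changed targets are recomputed."""
    while True:
        merged = False
        actives = sorted(f.id for f in state.active_fires() if f.hull is not None)
        for a_id in actives:
            a = state.fires[a_id]
            if a.invalid:
                continue
            for b_id in actives:
                if b_id <= a_id:
                    continue
                b = state.fires[b_id]
                if b.invalid:
                    continue
                lo, hi = a, b
                # a pair merges when one perimeter reaches the other's
                # extended area (perimeter + that fire's type buffer)
                buf = max(type_buffer(lo.ftype.value if lo.ftype else None, state.config),
                          type_buffer(hi.ftype.value if hi.ftype else None, state.config))
                if hi.hull.shape.distance(lo.hull.shape) > buf:
                    continue
                # move pixels from hi (source) to lo (target)
                lo.pixels.extend(hi.pixels)
                lo.newpixels.extend(hi.newpixels)
                lo.t_st = min(lo.t_st, hi.t_st)
                lo.t_ed = max(lo.t_ed, hi.t_ed)
                hi.pixels, hi.newpixels = [], []
                hi.invalid = True
                hi.isactive = False
                state.heritages.append((hi.id, lo.id))
                if hi.id not in state.fids_invalid:
                    state.fids_invalid.append(hi.id)
                if lo.id not in state.fids_merged:
                    state.fids_merged.append(lo.id)
                lo.update_geometry(state.config)
                merged = True
                break
            if merged:
                break
        if not merged:
            return state


def update_activity(state: AllFires) -> AllFires:
    """Refresh each valid fire's inactivity clock and active status.

    A fire is active while its last detection is at most
    ``config.inactive_days`` days old (strictly more than 10 half-daily
    steps without new pixels turns it inactive).  Inactive fires are never
    reactivated: later nearby clusters form new fires."""
    for fire in state.fires.values():
        if fire.invalid:
            fire.isactive = False
            continue
        fire.t_inactive = state.t.diff_days(fire.t_ed)
        fire.isactive = fire.t_inactive <= state.config.inactive_days
    return state


def advance(state: AllFires, batch: list[PixelRecord], step: TimeStep,
            lct_grid: LandCoverGrid | None = None,
            fm_field: FuelMoistureField | None = None) -> AllFires:
    """Advance the tracking state by one half-daily step.

    ``step`` must be the successor of ``state.t``.  Orchestrates:
    projection, clustering, cluster-to-fire assignment, geometry updates,
    transitive merging, static-source flagging, the activity countdown,
    and attribute refresh.  The ``fids_*`` lists afterwards describe
    exactly this step's changes."""
    if step != state.t.next():
        raise ValueError(f"step {step} is not the successor of state time {state.t}")
    state.t = step
    state.fids_expanded, state.fids_new = [], []
    state.fids_merged, state.fids_invalid = [], []
    for fire in state.fires.values():
        # the new-pixel set and the fireline it defines are per-step
        fire.newpixels = []
        fire.flinepixels = []
        if fire.fline is not None and not fire.fline.shape.is_empty:
            fire.fline = FirelineGeometry(LineString())

    pixels = make_pixels(batch, step, state.proj)
    clusters = cluster_pixels(pixels, state.config.cluster_linkage)
    apply_clusters(state, clusters)

    changed = state.fids_expanded + state.fids_new
    for fid in changed:
        state.fires[fid].update_geometry(state.config)
    merge_grown_fires(state)

    # static-source screening on fires that changed this step
    for fid in state.fids_expanded + state.fids_new + state.fids_merged:
        fire = state.fires[fid]
        if not fire.invalid and flag_static(fire, state.config):
            fire.invalid = True
            fire.isactive = False
            if fid not in state.fids_invalid:
                state.fids_invalid.append(fid)
            logger.info("step %s: fire %d flagged static, invalidated", step, fid)

    update_activity(state)

    for fire in state.valid_fires():
        if fire.hull is None:
            continue
        fire.properties = refresh_properties(fire, fm_field, lct_grid, state.config)
        if fire.properties.LCTmax is not None:
            fire.ftype = classify_fire_type(
                fire.properties.LCTmax, fire.properties.stFM1000,
                threshold=state.config.fm1000_wildfire_threshold)
    logger.debug("step %s: %d new, %d expanded, %d merged, %d invalidated",
                 step, len(state.fids_new), len(state.fids_expanded),
                 len(state.fids_merged), len(state.fids_invalid))
    return state
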
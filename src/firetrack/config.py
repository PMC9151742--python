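"""Tunable parameters of the tracking system, with their operational defaults.

All distances are metres in the equal-area projected plane, areas km2,
durations days.  The defaults reproduce the operational configuration of the
California tracking system; every threshold can be overridden per run (e.g.
from the YAML file passed to the CLI).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any, Mapping


@dataclass
class TrackerConfig:
    """Configuration of the fire event tracker.

    Parameters
    ----------
    alpha : float
        Alpha-shape disk radius in metres used for perimeter delineation.
        1 km balances boundary fidelity against fragmentation of one event
        into several objects.
    hull_buffer : float
        Outward buffer applied to the concave hull, metres.  Half of the
        375 m nadir cross-track pixel width, so the perimeter accounts for
        the finite pixel footprint.
    fireline_radius : float
        Perimeter segments within this distance of a newly detected pixel
        are considered actively burning (metres).
    cluster_linkage : float
        Single-linkage distance for grouping same-step pixels into
        clusters, metres.
    buffer_forest, buffer_other : float
        Radial extension of a fire's perimeter (its *extended area*) used
        to attach new clusters and trigger merges; forest fires spread
        faster and receive the larger buffer (metres).
    inactive_days : float
        A fire with no new pixels for more than this many days becomes
        inactive and stops attracting clusters.
    static_max_area : float
        Static-source test: only fires smaller than this (km2) can be
        flagged static.
    static_min_density : float
        Static-source test: cumulative pixel density (pixels per km2)
        above which a small fire is considered a persistent non-vegetation
        heat source and invalidated.
    large_fire_km2 : float
        Final-area threshold above which a fire enters the large-fire
        time-series product (km2).
    fm1000_wildfire_threshold : float
        1000-hr dead fuel moisture (percent) at ignition separating
        wildfire (>= threshold) from management fire (< threshold) for
        forest/shrub/grassland land cover.
    utc_offset_hours : float
        Fixed offset from UTC defining local solar time of the region
        (no daylight saving), used to split days into AM/PM windows.
    boundary_closed_left : bool
        Half-day windows are closed on the left ([00:00, 12:00) local)
        when True.
    """

    alpha: float = 1000.0
    hull_buffer: float = 187.5
    fireline_radius: float = 500.0
    cluster_linkage: float = 1000.0
    buffer_forest: float = 5000.0
    buffer_other: float = 1000.0
    inactive_days: float = 5.0
    static_max_area: float = 20.0
    static_min_density: float = 20.0
    large_fire_km2: float = 4.0
    fm1000_wildfire_threshold: float = 12.0
    utc_offset_hours: float = -8.0
    boundary_closed_left: bool = True
    # Projection parameters (Albers equal-area conic on the authalic sphere);
    # defaults suit California-like mid-latitude regions.
    proj_lat0: float = 0.0
    proj_lon0: float = -120.0
    proj_lat1: float = 34.0
    proj_lat2: float = 40.5

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "TrackerConfig":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})


#: Mapping from a fire-type name to the extended-area buffer it receives.
def type_buffer(ftype: str | None, config: TrackerConfig) -> float:
    """Extended-area buffer (metres) for a fire of the given type."""
    if ftype in ("forest_wildfire", "forest_management"):
        return config.buffer_forest
    return config.buffer_other
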
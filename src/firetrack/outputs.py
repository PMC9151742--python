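"""Persistence of the four-layer fire-events data suite.

Products, per tracked season:

* **Serialization** — a versioned JSON state file per step (geometry as
  WKT, pixels as plain records).  ``load_state(save_state(s))`` restores
  the state exactly, so any file doubles as a restart checkpoint.
* **Snapshot** — per step, three GeoJSON layers sharing the fire-id key:
  ``perimeter`` (attributes + hull polygon), ``fireline`` (active front
  lines), ``newfirepix`` (new detection points).  Only valid fires.
* **Largefire** — per-step perimeter/fireline/newpixel time series for
  every fire whose final area exceeds the large-fire threshold (4 km2).
* **Summary** — a NetCDF regional time-series (fire count, total area,
  fireline length, new-pixel count per step) plus heritage and large-fire
  CSV lists.

Geometries are written in WGS84 longitude/latitude; the metre plane is
internal only.  File names follow the ``YYYYMMDDAP`` step pattern.
"""

from __future__ import annotations

import datetime as _dt
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from shapely import wkt as _wkt
from shapely.geometry import mapping as _mapping
from shapely.geometry import shape as _shape
from shapely.ops import transform as _transform

from firetrack.attributes import FireProperties, FireType, LandCover
from firetrack.config import TrackerConfig
from firetrack.geometry import AlbersEqualArea, FirelineGeometry, HullGeometry
from firetrack.ingest import TimeStep
from firetrack.tracker import AllFires, FireObject, FirePixel

STATE_FORMAT_VERSION = 1


class StateFormatError(ValueError):
    """The state file is corrupt or has an unknown version."""


# ---------------------------------------------------------------------------
# state serialization
# ---------------------------------------------------------------------------

def _pixel_to_dict(p: FirePixel) -> dict:
    return {"lat": p.lat, "lon": p.lon, "frp": p.frp,
            "t": str(p.t), "origin": p.origin}


def _pixel_from_dict(d: dict, proj: AlbersEqualArea) -> FirePixel:
    x, y = proj.forward(d["lat"], d["lon"])
    return FirePixel(x=x, y=y, lat=d["lat"], lon=d["lon"], frp=d["frp"],
                     t=TimeStep.from_string(d["t"]), origin=d["origin"])


def _fire_to_dict(f: FireObject) -> dict:
    pixels = [_pixel_to_dict(p) for p in f.pixels]
    index = {id(p): i for i, p in enumerate(f.pixels)}
    props = None
    if f.properties is not None:
        pr = f.properties
        props = {"farea": pr.farea, "centroid": list(pr.centroid),
                 "pixden": pr.pixden, "meanFRP": pr.meanFRP,
                 "LCTmax": int(pr.LCTmax) if pr.LCTmax is not None else None,
                 "stFM1000": pr.stFM1000, "fperim": pr.fperim,
                 "flinelen": pr.flinelen, "duration": pr.duration}
    return {
        "id": f.id,
        "pixels": pixels,
        "newpixels": [index[id(p)] for p in f.newpixels],
        "ignpixels": [_pixel_to_dict(p) for p in f.ignpixels],
        "flinepixels": [index[id(p)] for p in f.flinepixels],
        "extpixels": [index[id(p)] for p in f.extpixels],
        "t_st": str(f.t_st) if f.t_st else None,
        "t_ed": str(f.t_ed) if f.t_ed else None,
        "invalid": f.invalid,
        "isactive": f.isactive,
        "t_inactive": f.t_inactive,
        "hull": f.hull.shape.wkt if f.hull is not None else None,
        "fline": f.fline.shape.wkt if f.fline is not None else None,
        "ftype": f.ftype.value if f.ftype is not None else None,
        "properties": props,
    }


def _fire_from_dict(d: dict, proj: AlbersEqualArea) -> FireObject:
    pixels = [_pixel_from_dict(pd_, proj) for pd_ in d["pixels"]]
    f = FireObject(id=d["id"], proj=proj, pixels=pixels)
    f.newpixels = [pixels[i] for i in d["newpixels"]]
    f.flinepixels = [pixels[i] for i in d["flinepixels"]]
    f.extpixels = [pixels[i] for i in d["extpixels"]]
    f.ignpixels = [_pixel_from_dict(pd_, proj) for pd_ in d["ignpixels"]]
    f.t_st = TimeStep.from_string(d["t_st"]) if d["t_st"] else None
    f.t_ed = TimeStep.from_string(d["t_ed"]) if d["t_ed"] else None
    f.invalid = d["invalid"]
    f.isactive = d["isactive"]
    f.t_inactive = d["t_inactive"]
    f.hull = HullGeometry(_wkt.loads(d["hull"])) if d["hull"] else None
    f.fline = FirelineGeometry(_wkt.loads(d["fline"])) if d["fline"] else None
    f.ftype = FireType(d["ftype"]) if d["ftype"] else None
    if d["properties"] is not None:
        pr = d["properties"]
        f.properties = FireProperties(
            farea=pr["farea"], centroid=tuple(pr["centroid"]),
            pixden=pr["pixden"], meanFRP=pr["meanFRP"],
            LCTmax=LandCover(pr["LCTmax"]) if pr["LCTmax"] is not None else None,
            stFM1000=pr["stFM1000"], fperim=pr["fperim"],
            flinelen=pr["flinelen"], duration=pr["duration"])
    return f


def save_state(state: AllFires, path) -> None:
    """Serialize the full tracking state to a versioned JSON file."""
    doc = {
        "format_version": STATE_FORMAT_VERSION,
        "t": str(state.t),
        "config": state.config.to_dict(),
        "proj": state.proj.params(),
        "next_id": state.next_id,
        "heritages": [list(h) for h in state.heritages],
        "fids_expanded": state.fids_expanded,
        "fids_new": state.fids_new,
        "fids_merged": state.fids_merged,
        "fids_invalid": state.fids_invalid,
        "fires": [_fire_to_dict(state.fires[fid]) for fid in sorted(state.fires)],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_state(path) -> AllFires:
    """Restore a tracking state saved by :func:`save_state`."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as e:
        raise StateFormatError(f"corrupt state file {path}: {e}") from e
    if doc.get("format_version") != STATE_FORMAT_VERSION:
        raise StateFormatError(
            f"unsupported state format version {doc.get('format_version')!r}")
    config = TrackerConfig.from_dict(doc["config"])
    proj = AlbersEqualArea(**doc["proj"])
    state = AllFires(t=TimeStep.from_string(doc["t"]), config=config, proj=proj)
    state.next_id = doc["next_id"]
    state.heritages = [tuple(h) for h in doc["heritages"]]
    state.fids_expanded = doc["fids_expanded"]
    state.fids_new = doc["fids_new"]
    state.fids_merged = doc["fids_merged"]
    state.fids_invalid = doc["fids_invalid"]
    state.fires = {d["id"]: _fire_from_dict(d, proj) for d in doc["fires"]}
    return state


# ---------------------------------------------------------------------------
# snapshot layers
# ---------------------------------------------------------------------------

def _to_wgs84(geom, proj: AlbersEqualArea):
    return _transform(lambda x, y, z=None: tuple(reversed(proj.inverse(x, y))), geom)


def _feature(geom, props: dict) -> dict:
    return {"type": "Feature", "geometry": _mapping(geom), "properties": props}


def _fire_attr_row(f: FireObject) -> dict:
    pr = f.properties
    return {
        "fid": f.id,
        "t_st": str(f.t_st),
        "t_ed": str(f.t_ed),
        "duration": f.duration,
        "isactive": f.isactive,
        "t_inactive": f.t_inactive,
        "n_pixels": len(f.pixels),
        "n_newpixels": len(f.newpixels),
        "farea": pr.farea if pr else None,
        "pixden": pr.pixden if pr else None,
        "meanFRP": pr.meanFRP if pr else None,
        "LCTmax": int(pr.LCTmax) if pr and pr.LCTmax is not None else None,
        "stFM1000": pr.stFM1000 if pr else None,
        "ftype": f.ftype.value if f.ftype else None,
        "fperim": pr.fperim if pr else None,
        "flinelen": pr.flinelen if pr else None,
    }


def snapshot_layers(state: AllFires) -> dict[str, list[dict]]:
    """GeoJSON features for the three snapshot layers (valid fires only)."""
    perimeter, fireline, newfirepix = [], [], []
    for fid in sorted(state.fires):
        f = state.fires[fid]
        if f.invalid or f.hull is None:
            continue
        perimeter.append(_feature(_to_wgs84(f.hull.shape, state.proj),
                                  _fire_attr_row(f)))
        if f.fline is not None and not f.fline.shape.is_empty:
            fireline.append(_feature(_to_wgs84(f.fline.shape, state.proj),
                                     {"fid": f.id, "flinelen": f.fline.length_km}))
        for p in f.newpixels:
            newfirepix.append(_feature(
                _shape({"type": "Point", "coordinates": [p.lon, p.lat]}),
                {"fid": f.id, "frp": p.frp, "t": str(p.t)}))
    return {"perimeter": perimeter, "fireline": fireline, "newfirepix": newfirepix}


def _write_layer(features: list[dict], path) -> None:
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def write_snapshot(state: AllFires, step: TimeStep, outdir) -> list[str]:
    """Write the three snapshot layers for ``step`` as GeoJSON files
    ``<YYYYMMDDAP>_<layer>.geojson``; returns the paths written."""
    if step != state.t:
        raise ValueError(f"state is at {state.t}, not at requested step {step}")
    os.makedirs(outdir, exist_ok=True)
    layers = snapshot_layers(state)
    paths = []
    for name, feats in layers.items():
        path = os.path.join(outdir, f"{step}_{name}.geojson")
        _write_layer(feats, path)
        paths.append(path)
    return paths


def read_layer(path):
    """Read a GeoJSON layer into a list of (shapely geometry, properties)."""
    with open(path) as fh:
        doc = json.load(fh)
    return [(_shape(f["geometry"]), f.get("properties", {}))
            for f in doc["features"]]


# ---------------------------------------------------------------------------
# run history, large fires, summary
# ---------------------------------------------------------------------------

@dataclass
class RunHistory:
    """Per-step snapshot features accumulated over a season, from which the
    large-fire and summary products are derived."""

    steps: list[TimeStep] = field(default_factory=list)
    layers: list[dict[str, list[dict]]] = field(default_factory=list)

    def record(self, state: AllFires) -> None:
        self.steps.append(state.t)
        self.layers.append(snapshot_layers(state))

    def regional_series(self) -> pd.DataFrame:
        rows = []
        for step, lyr in zip(self.steps, self.layers):
            perim = lyr["perimeter"]
            rows.append({
                "step": str(step),
                "n_fires": len(perim),
                "total_farea": sum(f["properties"]["farea"] or 0.0 for f in perim),
                "total_flinelen": sum(f["properties"]["flinelen"] or 0.0 for f in perim),
                "n_newpixels": len(lyr["newfirepix"]),
            })
        return pd.DataFrame(rows)


def large_fire_ids(final_state: AllFires, threshold: float | None = None) -> list[int]:
    """Ids of valid fires whose final area exceeds the large-fire threshold."""
    thr = threshold if threshold is not None else final_state.config.large_fire_km2
    return sorted(f.id for f in final_state.valid_fires()
                  if f.properties is not None and f.properties.farea > thr)


def write_largefire_series(history: RunHistory, final_state: AllFires,
                           year: int, outdir,
                           size_threshold: float | None = None) -> list[str]:
    """Per-step perimeter/fireline/newpixel time series for each large
    fire, as three GeoJSON files ``LargeFires_<year>_<layer>.geojson``.
    Each feature carries the step it belongs to.  Valid empty files are
    written when the season has no large fire."""
    os.makedirs(outdir, exist_ok=True)
    large = set(large_fire_ids(final_state, size_threshold))
    out: dict[str, list[dict]] = {"perimeter": [], "fireline": [], "newfirepix": []}
    for step, lyr in zip(history.steps, history.layers):
        for name in out:
            for feat in lyr[name]:
                if feat["properties"]["fid"] in large:
                    f = dict(feat)
                    f["properties"] = {**feat["properties"], "step": str(step)}
                    out[name].append(f)
    paths = []
    for name, feats in out.items():
        path = os.path.join(outdir, f"LargeFires_{year}_{name}.geojson")
        _write_layer(feats, path)
        paths.append(path)
    return paths


def write_summary(history: RunHistory, final_state: AllFires, year: int,
                  outdir) -> dict[str, str]:
    """Season summary: NetCDF regional time series plus heritage and
    large-fire-id CSVs (``fsummary_<year>1231PM.nc``,
    ``Flist_heritage_<year>.csv``, ``Flist_large_<year>.csv``)."""
    os.makedirs(outdir, exist_ok=True)
    series = history.regional_series()
    times = [_dt.datetime.combine(s.date, _dt.time(1 if s.half == "AM" else 13, 30))
             for s in history.steps]
    ds = xr.Dataset(
        {
            "n_fires": ("time", series["n_fires"].to_numpy(dtype="int32")
                        if len(series) else np.array([], dtype="int32")),
            "total_farea": ("time", series["total_farea"].to_numpy(dtype=float)
                            if len(series) else np.array([], dtype=float)),
            "total_flinelen": ("time", series["total_flinelen"].to_numpy(dtype=float)
                               if len(series) else np.array([], dtype=float)),
            "n_newpixels": ("time", series["n_newpixels"].to_numpy(dtype="int32")
                            if len(series) else np.array([], dtype="int32")),
        },
        coords={"time": times},
        attrs={"title": f"Regional fire statistics, {year}",
               "farea_units": "km2", "flinelen_units": "km"},
    )
    nc_path = os.path.join(outdir, f"fsummary_{year}1231PM.nc")
    ds.to_netcdf(nc_path, engine="scipy")

    heritage_path = os.path.join(outdir, f"Flist_heritage_{year}.csv")
    pd.DataFrame(final_state.heritages, columns=["source_fid", "target_fid"]
                 ).to_csv(heritage_path, index=False)

    large_path = os.path.join(outdir, f"Flist_large_{year}.csv")
    pd.DataFrame({"fid": large_fire_ids(final_state)}).to_csv(large_path, index=False)
    return {"summary_nc": nc_path, "heritage_csv": heritage_path,
            "large_csv": large_path}
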
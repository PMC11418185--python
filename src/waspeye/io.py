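"""Delimited-text readers and writers for all interchange formats.

Tabular data travel as CSV with a JSON sidecar (``<name>.json`` next to
``<name>.csv``) carrying stimulus/geometry metadata; contours are written
as GeoJSON-style JSON.  Floats are written with a fixed ``%.10g`` format
so repeated runs with the same seed produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .eye_mapping import ContourLine, EyeMapGrid, FacetObservation
from .receptive_field import (BarSweepSet, KernelFit, RasterScan,
                              RasterTraces, SweepTrace)
from .stimulus import StimulusSpec

FLOAT_FMT = "%.10g"

__all__ = [
    "write_raster_scan", "read_raster_scan",
    "write_raster_traces", "read_raster_traces",
    "write_bar_sweeps", "read_bar_sweeps",
    "write_facet_observations", "read_facet_observations",
    "write_kernel_fits", "read_kernel_fits",
    "write_eye_map", "read_eye_map",
    "write_contours", "read_contours",
    "load_config",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def _write_sidecar(path: Path, meta: dict) -> None:
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True)
                              + "\n")


def _read_sidecar(path: Path) -> dict:
    return json.loads(_sidecar(path).read_text())


# -- raster grids -----------------------------------------------------------

def write_raster_scan(scan: RasterScan, path) -> None:
    path = Path(path)
    np.savetxt(path, scan.response, delimiter=",", fmt=FLOAT_FMT)
    _write_sidecar(path, {
        "kind": "raster_scan",
        "stim": scan.stim.to_dict(),
        "roi_centre": list(scan.roi_centre),
        "n_repeats": scan.n_repeats,
    })


def read_raster_scan(path) -> RasterScan:
    path = Path(path)
    meta = _read_sidecar(path)
    stim = StimulusSpec.from_dict(meta["stim"])
    grid = np.loadtxt(path, delimiter=",", ndmin=2)
    offs = stim.offsets()
    return RasterScan(response=grid, x_offsets=offs, y_offsets=offs,
                      stim=stim, n_repeats=int(meta.get("n_repeats", 1)),
                      roi_centre=tuple(meta.get("roi_centre", (0.0, 0.0))))


# -- raster traces ----------------------------------------------------------

def write_raster_traces(traces: RasterTraces, path) -> None:
    path = Path(path)
    traces.data.to_csv(path, index=False, float_format=FLOAT_FMT)
    _write_sidecar(path, {
        "kind": "raster_traces",
        "stim": traces.stim.to_dict(),
        "direction": traces.direction,
        "roi_centre": list(traces.roi_centre),
    })


def read_raster_traces(path) -> RasterTraces:
    path = Path(path)
    meta = _read_sidecar(path)
    return RasterTraces(data=pd.read_csv(path),
                        stim=StimulusSpec.from_dict(meta["stim"]),
                        direction=meta.get("direction", "lr"),
                        roi_centre=tuple(meta.get("roi_centre", (0.0, 0.0))))


# -- bar sweeps -------------------------------------------------------------

def write_bar_sweeps(sweeps: BarSweepSet, path) -> None:
    path = Path(path)
    frames = []
    starts, vels = {}, {}
    for name, tr in sweeps.traces.items():
        frames.append(pd.DataFrame({
            "time_s": tr.time, "voltage_mV": tr.voltage, "direction": name,
        }))
        starts[name] = tr.start
        vels[name] = tr.velocity
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format=FLOAT_FMT)
    _write_sidecar(path, {
        "kind": "bar_sweeps",
        "stim": sweeps.stim.to_dict(),
        "start": starts,
        "velocity": vels,
    })


def read_bar_sweeps(path) -> BarSweepSet:
    path = Path(path)
    meta = _read_sidecar(path)
    df = pd.read_csv(path)
    traces = {}
    for name, g in df.groupby("direction"):
        traces[name] = SweepTrace(
            direction=name, time=g["time_s"].to_numpy(),
            voltage=g["voltage_mV"].to_numpy(),
            start=float(meta["start"][name]),
            velocity=float(meta["velocity"][name]))
    return BarSweepSet(traces=traces,
                       stim=StimulusSpec.from_dict(meta["stim"]))


# -- facet observations -----------------------------------------------------

def write_facet_observations(obs: list[FacetObservation], path) -> None:
    pd.DataFrame({
        "longitude_deg": [o.longitude for o in obs],
        "latitude_deg": [o.latitude for o in obs],
        "facet_x": [o.facet_x for o in obs],
        "facet_y": [o.facet_y for o in obs],
        "facet_diameter_um": [o.facet_diameter for o in obs],
    }).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_facet_observations(path) -> list[FacetObservation]:
    df = pd.read_csv(path)
    return [FacetObservation(longitude=r.longitude_deg,
                             latitude=r.latitude_deg,
                             facet_x=int(r.facet_x), facet_y=int(r.facet_y),
                             facet_diameter=float(r.facet_diameter_um))
            for r in df.itertuples()]


# -- kernel fits / cell records ---------------------------------------------

def write_kernel_fits(rows: list[dict], path) -> None:
    """One row per cell: id, species, location and KernelFit summary."""
    cols = ["cell_id", "species", "eye_region", "longitude", "latitude",
            "x0", "y0", "sigma_h", "sigma_v", "delta_rho_h", "delta_rho_v",
            "amplitude", "sse", "converged"]
    df = pd.DataFrame(rows)
    df = df[[c for c in cols if c in df.columns]]
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_kernel_fits(path) -> pd.DataFrame:
    return pd.read_csv(path)


# -- eye maps ---------------------------------------------------------------

def write_eye_map(grid: EyeMapGrid, path) -> None:
    path = Path(path)
    grid.to_dataframe().to_csv(path, index=False, float_format=FLOAT_FMT)
    _write_sidecar(path, {
        "kind": "eye_map",
        "boundary": [[float(x), float(y)] for x, y in grid.boundary],
        "flags": {f"{k[0]},{k[1]}": v for k, v in grid.flags.items()},
    })


def read_eye_map(path) -> EyeMapGrid:
    path = Path(path)
    meta = _read_sidecar(path)
    df = pd.read_csv(path)
    lons = np.unique(df["longitude_deg"])
    lats = np.unique(df["latitude_deg"])
    shape = (lats.size, lons.size)

    def layer(col):
        return df.pivot_table(index="latitude_deg", columns="longitude_deg",
                              values=col, dropna=False).to_numpy()

    flags = {}
    for key, val in meta.get("flags", {}).items():
        lon, lat = key.split(",")
        flags[(float(lon), float(lat))] = val
    return EyeMapGrid(lons=lons, lats=lats,
                      density=layer("density_per_deg2").reshape(shape),
                      delta_phi=layer("delta_phi_deg").reshape(shape),
                      diameter=layer("facet_diameter_um").reshape(shape),
                      boundary=np.asarray(meta["boundary"], float),
                      flags=flags)


# -- contours ---------------------------------------------------------------

def write_contours(contours: list[ContourLine], path) -> None:
    features = [{
        "type": "Feature",
        "properties": {"level": c.level},
        "geometry": {
            "type": "LineString",
            "coordinates": [[float(x), float(y)] for x, y in c.vertices],
        },
    } for c in contours]
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features},
        indent=2, sort_keys=True) + "\n")


def read_contours(path) -> list[ContourLine]:
    data = json.loads(Path(path).read_text())
    return [ContourLine(level=float(f["properties"]["level"]),
                        vertices=np.asarray(f["geometry"]["coordinates"],
                                            float))
            for f in data["features"]]


# -- config -----------------------------------------------------------------

def load_config(path) -> dict:
    """Load a JSON or YAML pipeline configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml
        return yaml.safe_load(text)
    return json.loads(text)
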
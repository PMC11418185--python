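"""Reproducible end-to-end pipeline: synthesize -> fit -> map -> optics -> summarize.

``run_pipeline`` executes the stages named in the configuration against a
single output directory, derives every random seed deterministically from
the master seed, and writes a manifest recording the configuration hash,
seed, package versions and the SHA-256 of every output file.  Re-running
with the same configuration and seed reproduces every output byte for
byte (timings appear only in the log stream, never in outputs).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .eye_mapping import build_eye_map, interpolate_isolines
from .optics import (OmmatidiumOptics, VESPULA_GERMANICA, VESPULA_VULGARIS,
                     airy_halfwidth, optical_sensitivity, rhabdom_subtense)
from .receptive_field import acceptance_angle, fit_kernel
from .stats import summarize_acceptance_angles
from .stimulus import StimulusSpec
from .synthetic import (DensityField, GroundTruthRF, gen_bar_sweep_set,
                        gen_facet_observations, gen_raster_scan)

__all__ = ["run_pipeline", "optics_table"]

logger = logging.getLogger(__name__)

STAGES = ("synth", "rf-fit", "eye-map", "optics", "summarize")


def _child_seed(master: int, index: int) -> int:
    state = np.random.SeedSequence([int(master), int(index)]).generate_state(1)
    return int(state[0]) & 0x7FFFFFFF


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _field_from_config(cfg: dict) -> DensityField:
    kind = cfg.get("kind", "acute_zone")
    if kind == "constant":
        return DensityField.constant(cfg.get("delta_phi", 1.0),
                                     grid_spacing=cfg.get("grid_spacing", 10.0))
    if kind == "acute_zone":
        keys = ("min_delta_phi", "min_lon", "min_lat", "dorsal_delta_phi",
                "lon_gradient", "grid_spacing")
        return DensityField.acute_zone(**{k: cfg[k] for k in keys if k in cfg})
    raise ValueError(f"unknown density-field kind {kind!r}")


def optics_table(entries: list[dict] | None = None) -> pd.DataFrame:
    """Sensitivity / diffraction / subtense table for a list of ommatidia."""
    if entries is None:
        optics = [VESPULA_GERMANICA, VESPULA_VULGARIS]
    else:
        optics = [OmmatidiumOptics(**e) for e in entries]
    rows = []
    for o in optics:
        airy_rad, airy_deg = airy_halfwidth(o.wavelength, o.D)
        sub_rad, sub_deg = rhabdom_subtense(o.d, o.f)
        rows.append({
            "label": o.label, "D_um": o.D, "f_um": o.f, "d_um": o.d,
            "l_um": o.l, "k_per_um": o.k, "wavelength_um": o.wavelength,
            "S_um2_sr": optical_sensitivity(o),
            "airy_halfwidth_rad": airy_rad, "airy_halfwidth_deg": airy_deg,
            "rhabdom_subtense_rad": sub_rad, "rhabdom_subtense_deg": sub_deg,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_synth(config: dict, out: Path, seed: int) -> None:
    cfg = config.get("synth", {})
    stim = StimulusSpec.from_dict(cfg.get("stim", {}))
    cells = cfg.get("cells", [])
    meta_rows = []
    for i, cell in enumerate(cells):
        rf_kwargs = {k: cell[k] for k in
                     ("sigma_h", "sigma_v", "amplitude", "latency",
                      "noise_sd") if k in cell}
        if "delta_rho_v" in cell:
            rf = GroundTruthRF.from_acceptance_angles(
                cell.get("delta_rho_h", cell["delta_rho_v"]),
                cell["delta_rho_v"], seed=_child_seed(seed, i), **rf_kwargs)
        else:
            rf = GroundTruthRF(seed=_child_seed(seed, i), **rf_kwargs)
        cid = str(cell.get("id", f"cell{i:03d}"))
        cell_stim = StimulusSpec.from_dict({**cfg.get("stim", {}),
                                            **cell.get("stim", {})})
        io.write_raster_scan(gen_raster_scan(rf, cell_stim),
                             out / f"raster_{cid}.csv")
        io.write_bar_sweeps(gen_bar_sweep_set(rf, cell_stim),
                            out / f"sweeps_{cid}.csv")
        meta_rows.append({
            "cell_id": cid,
            "species": cell.get("species", ""),
            "eye_region": cell.get("eye_region", ""),
            "longitude": cell.get("longitude", 0.0),
            "latitude": cell.get("latitude", 0.0),
            "true_delta_rho_h": rf.delta_rho_h,
            "true_delta_rho_v": rf.delta_rho_v,
            "seed": rf.seed,
        })
    pd.DataFrame(meta_rows).to_csv(out / "cells.csv", index=False,
                                   float_format=io.FLOAT_FMT)
    if "field" in cfg or not cells:
        field = _field_from_config(cfg.get("field", {}))
        boundary = cfg.get("boundary", [[-100.0, 100.0], [-80.0, 80.0]])
        obs = gen_facet_observations(
            field, boundary=(tuple(boundary[0]), tuple(boundary[1])))
        io.write_facet_observations(obs, out / "facets.csv")
    logger.info("stage=synth cells=%d", len(cells))


def _stage_rf_fit(config: dict, out: Path) -> None:
    cells_path = out / "cells.csv"
    if not cells_path.exists():
        raise FileNotFoundError("rf-fit: missing cells.csv (run synth first "
                                "or provide inputs)")
    cells = pd.read_csv(cells_path)
    cfg = config.get("rf_fit", {})
    rows = []
    for row in cells.itertuples():
        raster = io.read_raster_scan(out / f"raster_{row.cell_id}.csv")
        fit = fit_kernel(raster, isotropic=cfg.get("isotropic", False))
        rec = {"cell_id": row.cell_id, "species": row.species,
               "eye_region": row.eye_region, "longitude": row.longitude,
               "latitude": row.latitude}
        rec.update(fit.to_dict())
        rows.append(rec)
        if not fit.converged:
            logger.warning("rf-fit: cell %s did not converge", row.cell_id)
    io.write_kernel_fits(rows, out / "kernel_fits.csv")
    logger.info("stage=rf-fit fits=%d", len(rows))


def _stage_eye_map(config: dict, out: Path) -> None:
    facets_path = out / "facets.csv"
    if not facets_path.exists():
        raise FileNotFoundError("eye-map: missing facets.csv")
    cfg = config.get("eye_map", {})
    obs = io.read_facet_observations(facets_path)
    grid = build_eye_map(obs, method=cfg.get("method", "surface"),
                         max_degree=cfg.get("max_degree", 6))
    io.write_eye_map(grid, out / "eye_map.csv")
    finite = grid.delta_phi[np.isfinite(grid.delta_phi)]
    levels = cfg.get("levels")
    if levels is None and finite.size:
        levels = list(np.arange(np.ceil(finite.min() * 4) / 4,
                                finite.max(), 0.25))
    io.write_contours(interpolate_isolines(grid, levels or []),
                      out / "contours.json")
    logger.info("stage=eye-map nodes=%d flagged=%d",
                int(np.isfinite(grid.delta_phi).sum()), len(grid.flags))


def _stage_optics(config: dict, out: Path) -> None:
    table = optics_table(config.get("optics", {}).get("entries"))
    table.to_csv(out / "optics.csv", index=False, float_format=io.FLOAT_FMT)
    logger.info("stage=optics entries=%d", len(table))


def _stage_summarize(config: dict, out: Path) -> None:
    fits_path = out / "kernel_fits.csv"
    if not fits_path.exists():
        raise FileNotFoundError("summarize: missing kernel_fits.csv")
    cfg = config.get("summarize", {})
    fits = io.read_kernel_fits(fits_path)
    summaries = summarize_acceptance_angles(
        fits, cfg.get("group_keys"), value=cfg.get("value", "delta_rho_v"),
        ci_method=cfg.get("ci_method", "notch"))
    rows = [{
        "group": "/".join(str(g) for g in s.group),
        "n": s.n, "median_deg": s.median,
        "ci_low_deg": s.ci_low, "ci_high_deg": s.ci_high,
        "q1_deg": s.q1, "q3_deg": s.q3,
        "n_outliers": s.outliers.size,
        "degenerate_ci": s.degenerate_ci,
    } for s in summaries]
    pd.DataFrame(rows).to_csv(out / "summary.csv", index=False,
                              float_format=io.FLOAT_FMT)
    logger.info("stage=summarize groups=%d", len(rows))


# ---------------------------------------------------------------------------

def run_pipeline(config: dict | str | Path, out_dir=None,
                 seed: int | None = None) -> Path:
    """Run the configured stages and write outputs plus a manifest.

    ``config`` is a dict or a path to a JSON/YAML file.  ``seed`` and
    ``out_dir`` override the config's ``seed``/``out_dir`` entries.
    A failing stage leaves earlier outputs in place; the manifest records
    the failure and the exception is re-raised.
    """
    if not isinstance(config, dict):
        config = io.load_config(config)
    out = Path(out_dir or config.get("out_dir", "waspeye_out"))
    out.mkdir(parents=True, exist_ok=True)
    master_seed = int(seed if seed is not None else config.get("seed", 0))
    stages = config.get("stages", [])
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}; valid: {STAGES}")

    status: dict[str, str] = {}
    failure: str | None = None
    try:
        for stage in stages:
            t0 = time.perf_counter()
            if stage == "synth":
                _stage_synth(config, out, master_seed)
            elif stage == "rf-fit":
                _stage_rf_fit(config, out)
            elif stage == "eye-map":
                _stage_eye_map(config, out)
            elif stage == "optics":
                _stage_optics(config, out)
            elif stage == "summarize":
                _stage_summarize(config, out)
            status[stage] = "ok"
            logger.info("stage=%s elapsed=%.2fs", stage,
                        time.perf_counter() - t0)
    except Exception as exc:
        status[stage] = "failed"
        failure = f"{stage}: {exc}"
        raise
    finally:
        import scipy
        outputs = {
            p.name: _file_hash(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        }
        manifest = {
            "config_sha256": _config_hash(config),
            "seed": master_seed,
            "stages": status,
            "failure": failure,
            "versions": {
                "waspeye": __version__,
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
            },
            "outputs": outputs,
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
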
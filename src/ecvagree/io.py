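"""Readers, writers, run configuration and the end-to-end pipeline.

Stacks travel as CF-style NetCDF (dimensions time/lat/lon, variables
``value`` and ``uncertainty`` plus a ``valid`` flag); metric maps are
written both as NetCDF and as plain multi-band TIFF with a JSON sidecar
carrying the grid geometry; tables (metric series, climatologies, trend
tests, threshold sweeps) are CSV.  Every output directory receives a
``provenance.json`` with the config hash, seed and package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import __version__
from .aggregation import AggregationSpec, multiscale_agreement
from .change import ClassificationConfig
from .consistency import (monthly_climatology, seasonal_mann_kendall,
                          spatial_agreement, temporal_agreement)
from .metrics import METRIC_NAMES
from .stack import GriddedStack, RegionSpec
from .synthetic import CLASS_NAMES, ScenarioConfig, generate
from .thresholds import precompute_changes, sweep_independent, sweep_joint, zero_bias_locus

logger = logging.getLogger(__name__)

__all__ = ["read_stack", "write_stack", "write_metrics_map", "RunConfig",
           "run_pipeline"]


def write_stack(stack: GriddedStack, path: str | Path) -> Path:
    """Write a stack to NetCDF (scipy backend, NETCDF3 classic)."""
    path = Path(path)
    ds = stack.to_dataset()
    ds.to_netcdf(path, engine="scipy")
    return path


def read_stack(path: str | Path, variable: str | None = None) -> GriddedStack:
    """Read a stack from NetCDF written by :func:`write_stack`.

    Raises
    ------
    ValueError
        If the file lacks an uncertainty variable — the framework cannot
        run on values alone.
    """
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    return GriddedStack.from_dataset(ds, variable=variable)


def write_metrics_map(ds: xr.Dataset, path: str | Path) -> Path:
    """Write a metrics map as NetCDF plus a band-per-metric TIFF sidecar."""
    path = Path(path)
    ds.to_netcdf(path, engine="scipy")
    try:
        import tifffile

        bands = [name for name in (*METRIC_NAMES, "n") if name in ds]
        cube = np.stack([ds[b].values.astype(np.float32) for b in bands])
        tif = path.with_suffix(".tif")
        tifffile.imwrite(tif, cube, metadata={"bands": bands})
        geom = {
            "bands": bands,
            "lat": [float(ds["lat"].values[0]), float(ds["lat"].values[-1])],
            "lon": [float(ds["lon"].values[0]), float(ds["lon"].values[-1])],
            "cell_size": float(ds.attrs.get("cell_size", np.nan)),
            "crs": ds.attrs.get("crs", "EPSG:4326"),
        }
        tif.with_suffix(".json").write_text(json.dumps(geom, indent=2))
    except Exception as exc:  # TIFF export is a convenience, never fatal
        logger.warning("TIFF export skipped: %s", exc)
    return path


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Either point ``lai_path``/``fapar_path`` at NetCDF stacks (with an
    optional ``landcover_path`` plain-text grid) or set ``scenario`` to
    generate synthetic inputs.
    """

    output_dir: str
    seed: int = 0
    lai_path: str | None = None
    fapar_path: str | None = None
    landcover_path: str | None = None
    scenario: dict | None = None
    confidence_threshold: float = 50.0
    joint_thresholds: tuple = (25.0, 50.0, 75.0)
    independent_sweep: bool = True
    independent_step: float = 1.0
    aggregation_sizes: tuple = ()
    min_valid_fraction: float = 0.5
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def digest(self) -> str:
        """Hash of the scientific configuration (paths of record included,
        output location and log level excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("output_dir", None)
        payload.pop("verbosity", None)
        enc = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(enc.encode()).hexdigest()[:16]


def _load_inputs(config: RunConfig):
    if config.scenario is not None:
        sc = ScenarioConfig(seed=config.seed, **config.scenario)
        lai, fapar, lc, _ = generate(sc)
        return lai, fapar, lc
    if not config.lai_path or not config.fapar_path:
        raise ValueError("config needs either a scenario or lai/fapar paths")
    for p in (config.lai_path, config.fapar_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"input stack not found: {p}")
    lai = read_stack(config.lai_path, "lai")
    fapar = read_stack(config.fapar_path, "fapar")
    lc = None
    if config.landcover_path:
        lc = np.loadtxt(config.landcover_path, dtype=np.int16)
    return lai, fapar, lc


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full analysis and write a deterministic report bundle.

    Produces: metric series per stratum (CSV), the spatial metrics map
    (NetCDF + TIFF), monthly climatologies, seasonal Mann-Kendall trend
    tables, joint and independent threshold sweeps, multi-resolution
    metrics when aggregation sizes are configured, and provenance.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    lai, fapar, lc = _load_inputs(config)
    cls_cfg = ClassificationConfig(confidence_threshold=config.confidence_threshold)
    ny, nx = lai.shape[1:]

    strata = [RegionSpec("all", np.ones((ny, nx), dtype=bool))]
    if lc is not None:
        for cls in np.unique(lc[lc > 0]):
            strata.append(RegionSpec(CLASS_NAMES.get(int(cls), f"class_{int(cls)}"),
                                     lc == cls))

    trend_rows = []
    for region in strata:
        series = temporal_agreement(lai, fapar, region, cls_cfg)
        p = out / f"series_{region.label}.csv"
        series.to_csv(p)
        outputs[f"series_{region.label}"] = p
        try:
            clim = monthly_climatology(series[list(METRIC_NAMES)])
            pc = out / f"climatology_{region.label}.csv"
            clim.to_csv(pc)
            outputs[f"climatology_{region.label}"] = pc
        except ValueError as exc:
            logger.info("climatology skipped for %s: %s", region.label, exc)
        for metric in METRIC_NAMES:
            s = series[metric].dropna()
            try:
                r = seasonal_mann_kendall(s)
                trend_rows.append({"stratum": region.label, "metric": metric,
                                   "score": r.score, "z": r.z, "p_value": r.p_value,
                                   "trend_sign": r.trend_sign})
            except ValueError:
                continue
    if trend_rows:
        pt = out / "trends.csv"
        pd.DataFrame(trend_rows).to_csv(pt, index=False)
        outputs["trends"] = pt

    metric_map = spatial_agreement(lai, fapar, cls_cfg)
    pm = out / "metrics_map.nc"
    write_metrics_map(metric_map, pm)
    outputs["metrics_map"] = pm

    cache = precompute_changes(lai, fapar)
    joint = sweep_joint(lai, fapar, config.joint_thresholds, cache=cache)
    pj = out / "sweep_joint.csv"
    joint.to_csv(pj)
    outputs["sweep_joint"] = pj
    if config.independent_sweep:
        grid = np.arange(0.0, 100.0 + config.independent_step / 2, config.independent_step)
        surface = sweep_independent(lai, fapar, grid, grid, cache=cache)
        ps = out / "bns_surface.nc"
        surface.to_netcdf(ps, engine="scipy")
        outputs["bns_surface"] = ps
        locus = zero_bias_locus(surface)
        pl = out / "zero_bias_locus.json"
        pl.write_text(json.dumps({
            "diagonal_crossing": locus.diagonal_crossing,
            "n_points": len(locus.points),
            "diagnostic": locus.diagnostic,
        }, indent=2))
        outputs["zero_bias_locus"] = pl

    if config.aggregation_sizes and lc is not None:
        specs = [AggregationSpec(s, config.min_valid_fraction)
                 for s in config.aggregation_sizes]
        ms = multiscale_agreement(lai, fapar, lc, specs, cls_cfg, CLASS_NAMES)
        pa = out / "multiscale_metrics.csv"
        ms.to_csv(pa)
        outputs["multiscale"] = pa

    prov = out / "provenance.json"
    prov.write_text(json.dumps({
        "config_hash": config.digest(),
        "seed": config.seed,
        "package_version": __version__,
    }, indent=2))
    outputs["provenance"] = prov
    return outputs
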
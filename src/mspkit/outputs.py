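"""Statistical summaries and report writing for model results.

Statistics are computed over in-area, non-nodata cells only.  Percentiles
use linear interpolation between order statistics.  Reports are written as
GeoTIFF maps, CSV tables and a JSON manifest; timestamps appear only in the
run-metadata JSON so the data files stay diffable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from .grid import GridLayer, GridError
from .geotiff import write_geotiff
from .muc import MUCResult
from .cea import CEAResult, partial_effects

__all__ = ["StatsRecord", "layer_statistics", "write_report"]

PERCENTILES = (5, 25, 50, 75, 95)


@dataclass
class StatsRecord:
    n_cells: int
    mean: float
    std: float
    min: float
    max: float
    percentiles: dict       # {"5": ..., ..., "95": ...}
    histogram_edges: list
    histogram_counts: list

    def to_dict(self) -> dict:
        return asdict(self)


def layer_statistics(layer: GridLayer, n_bins: int = 50) -> StatsRecord:
    """Summary statistics of the in-area, non-nodata cells of a layer.

    A constant layer yields a single-bin histogram whose edges collapse to
    the constant; otherwise the bin edges span [min, max] exactly.
    """
    vals = layer.values[layer.grid.area_mask]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise GridError(f"layer {layer.name!r}: no in-area non-nodata cells")
    vmin, vmax = float(vals.min()), float(vals.max())
    pct = {str(p): float(np.percentile(vals, p, method="linear"))
           for p in PERCENTILES}
    if vmin == vmax:
        edges = [vmin, vmax]
        counts = [int(vals.size)]
    else:
        counts_arr, edges_arr = np.histogram(vals, bins=n_bins, range=(vmin, vmax))
        edges = edges_arr.tolist()
        counts = counts_arr.tolist()
    return StatsRecord(
        n_cells=int(vals.size),
        mean=float(vals.mean()),
        std=float(vals.std()),
        min=vmin,
        max=vmax,
        percentiles=pct,
        histogram_edges=edges,
        histogram_counts=counts,
    )


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_report(result, out_dir) -> dict:
    """Write rasters, tables and metadata for a MUC or CEA result.

    Returns the file manifest (relative paths).  Re-running on identical
    input reproduces identical tables and raster values.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    if isinstance(result, MUCResult):
        write_geotiff(out / "muc.tif", result.score_map)
        files.append("muc.tif")
        result.pair_contributions.to_csv(out / "muc_pairs.csv", index=False)
        files.append("muc_pairs.csv")
        stats = layer_statistics(result.score_map).to_dict()
        model = "muc"
    elif isinstance(result, CEAResult):
        write_geotiff(out / "cea.tif", result.total_map)
        files.append("cea.tif")
        pdir = out / "cea_partials"
        pdir.mkdir(exist_ok=True)
        for (p, e), layer in sorted(result.partials.items()):
            rel = f"cea_partials/{p}__{e}.tif"
            write_geotiff(out / rel, layer)
            files.append(rel)
        partial_effects(result, group_by="pair").to_csv(
            out / "cea_contributions.csv", index=False)
        files.append("cea_contributions.csv")
        stats = layer_statistics(result.total_map).to_dict()
        model = "cea"
    else:
        raise TypeError(f"cannot write a report for {type(result).__name__}")

    _write_json(out / "stats.json", stats)
    files.append("stats.json")
    meta = {
        "model": model,
        "provenance": getattr(result, "provenance", {}),
        "written_at": datetime.now(timezone.utc).isoformat(),
    }
    _write_json(out / "run.json", meta)
    files.append("run.json")

    manifest = {"model": model, "files": files}
    _write_json(out / "manifest.json", manifest)
    missing = [f for f in files if not (out / f).exists()]
    assert not missing, f"manifest lists missing files: {missing}"
    return manifest
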
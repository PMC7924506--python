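"""Cumulative Effects Assessment (CEA).

Human-use intensity layers are propagated into pressure fields (weighted
Gaussian spreading beyond the use footprint, e.g. underwater noise or
marine litter travelling away from shipping lanes) and combined with
environmental-component layers through a pressure x receptor sensitivity
matrix:

    pressure_p(x) = norm( sum_{links u->p} w_u * G(U_u, d_u)(x) )
    partial_{p,e}(x) = pressure_p(x) * E_e(x) * s(p, e)
    total(x) = sum_{p,e} partial_{p,e}(x)

where ``G(., d)`` is the Gaussian propagation operator with effective
radius ``d`` meters, ``w`` is the dimensionless relative pressure weight in
[0, 1], ``E_e`` is the receptor intensity normalized to [0, 1], and ``s``
is the dimensionless sensitivity (>= 0).  The total decomposes additively
into per-(pressure, receptor) partial effects, which drive the ranking
tables ("which pressure / which habitat carries the impact").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import AnalysisGrid, GridLayer, GridError, gaussian_convolve, normalize

__all__ = [
    "PressureLink",
    "SensitivityEntry",
    "CEAResult",
    "pressure_map",
    "cea_map",
    "partial_effects",
]


@dataclass(frozen=True)
class PressureLink:
    """One use -> pressure edge: relative weight and propagation distance."""

    use: str
    pressure: str
    weight: float      # dimensionless, in [0, 1]
    distance_m: float  # propagation distance, meters, >= 0

    def __post_init__(self):
        if not np.isfinite(self.weight):
            raise ValueError(f"link {self.use}->{self.pressure}: non-finite weight")
        if self.distance_m < 0:
            raise ValueError(
                f"link {self.use}->{self.pressure}: negative distance {self.distance_m}"
            )


@dataclass(frozen=True)
class SensitivityEntry:
    """Sensitivity of one environmental component to one pressure."""

    pressure: str
    env: str
    sensitivity: float  # dimensionless, >= 0

    def __post_init__(self):
        if not np.isfinite(self.sensitivity) or self.sensitivity < 0:
            raise ValueError(
                f"sensitivity({self.pressure}, {self.env}) must be >= 0, "
                f"got {self.sensitivity}"
            )


@dataclass
class CEAResult:
    """Cumulative map, per-(pressure, env) partial-effect maps, pressure maps."""

    total_map: GridLayer
    partials: dict          # (pressure, env) -> GridLayer
    pressure_maps: dict     # pressure -> GridLayer
    provenance: dict = field(default_factory=dict)


def pressure_map(
    use_layers: dict,
    links: list,
    pressure_id: str,
    grid: AnalysisGrid,
    rescale: bool = True,
) -> GridLayer:
    """Propagate and combine use layers into one pressure field.

    ``P = norm( sum_links w * G(U, d) )`` — convolve each contributing use
    with its propagation kernel, weight, sum, and (by default) normalize the
    result to [0, 1] so that sensitivities remain the only scale carrier.
    Set ``rescale=False`` for absolute-intensity studies.
    """
    mine = [l for l in links if l.pressure == pressure_id]
    if not mine:
        raise GridError(f"no pressure links target pressure {pressure_id!r}")
    dangling = sorted({l.use for l in mine} - set(use_layers))
    if dangling:
        raise GridError(
            f"pressure {pressure_id!r}: link(s) reference unknown use(s) {dangling}"
        )
    acc = np.zeros(grid.shape, dtype=np.float64)
    for link in mine:
        layer = use_layers[link.use]
        if not layer.grid.is_aligned(grid):
            raise GridError(f"use layer {link.use!r} is not aligned to the grid")
        acc += link.weight * gaussian_convolve(layer, link.distance_m).filled(0.0)
    out = GridLayer(pressure_id, acc, grid)
    return normalize(out) if rescale else out


def cea_map(
    pressure_maps: dict,
    env_layers: dict,
    sensitivities: list,
    grid: AnalysisGrid,
) -> CEAResult:
    """Combine pressure and receptor layers through the sensitivity matrix.

    Environmental layers must already be normalized to [0, 1] (the case
    study loader does this); out-of-range receptors are an error rather than
    a silent rescale.  Cells outside the area of analysis are nodata.
    """
    for name, env in env_layers.items():
        vmax = np.nanmax(env.values) if not env.nodata_mask.all() else 0.0
        vmin = np.nanmin(env.values) if not env.nodata_mask.all() else 0.0
        if vmin < 0 or vmax > 1 + 1e-12:
            raise GridError(
                f"environmental layer {name!r} is not normalized to [0, 1] "
                f"(range [{vmin}, {vmax}])"
            )
    partials = {}
    total = np.zeros(grid.shape, dtype=np.float64)
    for entry in sensitivities:
        if entry.pressure not in pressure_maps:
            raise GridError(f"sensitivity references unknown pressure {entry.pressure!r}")
        if entry.env not in env_layers:
            raise GridError(f"sensitivity references unknown env {entry.env!r}")
        if entry.sensitivity < 0:
            raise ValueError(f"negative sensitivity for ({entry.pressure}, {entry.env})")
        p = pressure_maps[entry.pressure].filled(0.0)
        e = env_layers[entry.env].filled(0.0)
        vals = p * e * entry.sensitivity
        vals[~grid.area_mask] = np.nan
        key = (entry.pressure, entry.env)
        partials[key] = GridLayer(f"{entry.pressure}__{entry.env}", vals, grid)
        total += np.where(grid.area_mask, vals, 0.0)
    total[~grid.area_mask] = np.nan
    return CEAResult(
        total_map=GridLayer("cea", total, grid),
        partials=partials,
        pressure_maps=dict(pressure_maps),
    )


def partial_effects(result: CEAResult, group_by: str = "pair") -> pd.DataFrame:
    """Contribution table: summed partial effect, % of grand total and
    affected-cell count per pressure, per env, or per (pressure, env) pair."""
    if group_by not in ("pressure", "env", "pair"):
        raise ValueError(f"group_by must be pressure|env|pair, got {group_by!r}")
    groups: dict = {}
    for (p, e), layer in result.partials.items():
        key = (p, e) if group_by == "pair" else (p if group_by == "pressure" else e)
        total, affected = groups.setdefault(key, [0.0, None])
        vals = layer.values
        ok = ~np.isnan(vals)
        hit = (vals > 0) & ok
        groups[key][0] = total + float(vals[ok].sum())
        groups[key][1] = hit if affected is None else (affected | hit)
    rows = []
    for key, (total, affected) in groups.items():
        row = {"effect_sum": total,
               "affected_cells": int(affected.sum()) if affected is not None else 0}
        if group_by == "pair":
            row["pressure"], row["env"] = key
        else:
            row[group_by] = key
        rows.append(row)
    cols = (["pressure", "env"] if group_by == "pair" else [group_by]) + [
        "effect_sum", "affected_cells"]
    df = pd.DataFrame(rows, columns=cols)
    grand = df["effect_sum"].sum() if not df.empty else 0.0
    df["percent"] = 100.0 * df["effect_sum"] / grand if grand > 0 else 0.0
    return df
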
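"""Case-study bundles: directory format, loading, validation, subsetting
and model execution entry points.

A case study is a self-contained directory::

    casestudy.json          manifest: metadata, grid definition, layer entries
    layers/                 GeoTIFF rasters and/or GeoJSON vector footprints
    inputs/
      use_attributes.csv    use, vertical_domain (";"-joined), spatial_domain,
                            temporal_domain, mobility
      pressure_links.csv    use, pressure, weight, distance_m
      sensitivities.csv     pressure, env, sensitivity
      ruleset.json          (optional) conflict rule-table override

Each manifest layer entry is ``{"name", "role": "use"|"env"|"pressure",
"file"?, "expression"?}``.  Layers may arrive pre-gridded (GeoTIFF) or as
vector footprints plus a pre-processing expression; both converge to
aligned grid layers at load time.  Environmental and directly supplied
pressure layers are normalized to [0, 1] on load.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import shape as shapely_shape

from . import muc as muc_mod
from . import cea as cea_mod
from .grid import (
    AnalysisGrid, GridLayer, GridError,
    make_grid, rasterize, normalize, grid_from_json,
)
from .geotiff import read_geotiff, write_geotiff
from .expressions import parse_expression, evaluate_expression, ExpressionError
from .muc import UseAttributes, RuleSet, default_ruleset
from .cea import PressureLink, SensitivityEntry

__all__ = [
    "CaseStudy", "CaseStudyError", "ValidationReport",
    "load_case_study", "save_case_study", "validate_case_study",
    "subset", "run_muc", "run_cea",
]

MANIFEST = "casestudy.json"
ROLES = ("use", "env", "pressure")


class CaseStudyError(ValueError):
    pass


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


@dataclass
class CaseStudy:
    """Grid + layer registries + input tables, sufficient to run MUC/CEA."""

    grid: AnalysisGrid
    uses: dict = field(default_factory=dict)            # name -> GridLayer
    envs: dict = field(default_factory=dict)            # name -> GridLayer
    pressure_layers: dict = field(default_factory=dict) # name -> GridLayer (direct)
    use_attributes: dict = field(default_factory=dict)  # name -> UseAttributes
    pressure_links: list = field(default_factory=list)  # [PressureLink]
    sensitivities: list = field(default_factory=list)   # [SensitivityEntry]
    ruleset: RuleSet | None = None
    title: str = "untitled"
    version: str = "1"
    subset_of: dict | None = None

    @property
    def pressures(self) -> set:
        """Pressure identifiers known to this case study."""
        return {l.pressure for l in self.pressure_links} | set(self.pressure_layers)


# ---------------------------------------------------------------- loading --

def _sorted_dict(d: dict) -> dict:
    return {k: d[k] for k in sorted(d)}


def _load_layer_file(path: Path, entry: dict, grid: AnalysisGrid) -> GridLayer:
    name = entry["name"]
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        layer = read_geotiff(path, name=name)
        lg = layer.grid
        if lg.shape != grid.shape or not np.allclose(lg.extent, grid.extent) \
                or lg.resolution != grid.resolution:
            raise CaseStudyError(
                f"raster {path.name} (layer {name!r}) is not aligned to the "
                f"case-study grid: {lg.extent}@{lg.resolution} vs "
                f"{grid.extent}@{grid.resolution}"
            )
        if lg.crs != "unknown" and lg.crs.upper() != grid.crs.upper():
            raise CaseStudyError(
                f"raster {path.name} CRS {lg.crs} != grid CRS {grid.crs}"
            )
        return GridLayer(name, layer.values, grid)
    if suffix in (".json", ".geojson"):
        features = json.loads(path.read_text())
        mode = "burn_value" if entry.get("value_field") else "presence"
        return rasterize(features, grid, value_field=entry.get("value_field"),
                         mode=mode, name=name)
    raise CaseStudyError(f"unsupported layer file type {path.name!r}")


def load_case_study(path) -> CaseStudy:
    """Two-stage load: layers (rasters/vectors + expressions), then inputs
    (attributes, links, sensitivities).  Returns a validated case study."""
    root = Path(path)
    manifest_path = root / MANIFEST
    if not manifest_path.exists():
        raise CaseStudyError(f"missing manifest {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    grid = grid_from_json(manifest["grid"])
    mask_file = manifest.get("area_mask_file")
    if mask_file:
        mask_layer = read_geotiff(root / mask_file, name="area")
        grid = AnalysisGrid(grid.extent, grid.resolution, grid.crs,
                            mask_layer.filled(0.0) > 0)

    # stage 1: layers
    raw: dict[str, GridLayer] = {}
    entries = sorted(manifest.get("layers", []), key=lambda e: e["name"])
    names = [e["name"] for e in entries]
    if len(names) != len(set(names)):
        raise CaseStudyError("duplicate layer names in manifest")
    for entry in entries:
        if entry.get("role") not in ROLES:
            raise CaseStudyError(
                f"layer {entry.get('name')!r}: role must be one of {ROLES}"
            )
        if entry.get("file"):
            f = root / entry["file"]
            if not f.exists():
                raise CaseStudyError(f"layer {entry['name']!r}: missing file {f}")
            raw[entry["name"]] = _load_layer_file(f, entry, grid)

    registries: dict[str, dict] = {"use": {}, "env": {}, "pressure": {}}
    for entry in entries:
        name, role = entry["name"], entry["role"]
        expr_text = entry.get("expression")
        if expr_text:
            try:
                layer = evaluate_expression(parse_expression(expr_text), raw)
            except (ExpressionError, GridError) as exc:
                raise CaseStudyError(f"layer {name!r}: {exc}") from exc
            layer = layer.copy(name=name)
        elif name in raw:
            layer = raw[name]
        else:
            raise CaseStudyError(f"layer {name!r} has neither a file nor an expression")
        if role in ("env", "pressure"):
            layer = normalize(layer)
        registries[role][name] = GridLayer(name, layer.values, grid)

    # stage 2: inputs
    inputs = root / "inputs"
    attrs: dict[str, UseAttributes] = {}
    f = inputs / "use_attributes.csv"
    if f.exists():
        df = pd.read_csv(f)
        for row in df.itertuples(index=False):
            attrs[str(row.use)] = UseAttributes(
                vertical_domain=frozenset(str(row.vertical_domain).split(";")),
                spatial_domain=str(row.spatial_domain),
                temporal_domain=str(row.temporal_domain),
                mobility=str(row.mobility),
            )
    links: list[PressureLink] = []
    f = inputs / "pressure_links.csv"
    if f.exists():
        for row in pd.read_csv(f).itertuples(index=False):
            links.append(PressureLink(str(row.use), str(row.pressure),
                                      float(row.weight), float(row.distance_m)))
    sens: list[SensitivityEntry] = []
    f = inputs / "sensitivities.csv"
    if f.exists():
        for row in pd.read_csv(f).itertuples(index=False):
            sens.append(SensitivityEntry(str(row.pressure), str(row.env),
                                         float(row.sensitivity)))
    ruleset = None
    f = inputs / "ruleset.json"
    if f.exists():
        ruleset = RuleSet.from_dict(json.loads(f.read_text()))

    cs = CaseStudy(
        grid=grid,
        uses=_sorted_dict(registries["use"]),
        envs=_sorted_dict(registries["env"]),
        pressure_layers=_sorted_dict(registries["pressure"]),
        use_attributes=_sorted_dict(attrs),
        pressure_links=sorted(links, key=lambda l: (l.use, l.pressure)),
        sensitivities=sorted(sens, key=lambda s: (s.pressure, s.env)),
        ruleset=ruleset,
        title=manifest.get("title", "untitled"),
        version=str(manifest.get("version", "1")),
    )
    report = validate_case_study(cs)
    if report.errors:
        raise CaseStudyError("invalid case study: " + "; ".join(report.errors))
    return cs


def save_case_study(cs: CaseStudy, path) -> Path:
    """Write a case study in the documented layout.  Layers are saved as
    GeoTIFF rasters (expressions are already applied), so a load of the
    written directory reproduces every layer value bit-exactly."""
    root = Path(path)
    (root / "layers").mkdir(parents=True, exist_ok=True)
    (root / "inputs").mkdir(exist_ok=True)

    entries = []
    for role, registry in (("use", cs.uses), ("env", cs.envs),
                           ("pressure", cs.pressure_layers)):
        for name in sorted(registry):
            rel = f"layers/{role}__{name}.tif"
            write_geotiff(root / rel, registry[name])
            entries.append({"name": name, "role": role, "file": rel})

    mask_rel = None
    if not cs.grid.area_mask.all():
        mask_rel = "layers/_area_mask.tif"
        write_geotiff(root / mask_rel,
                      GridLayer("area", cs.grid.area_mask.astype(float), cs.grid))

    manifest = {
        "title": cs.title,
        "version": cs.version,
        "grid": {"extent": list(cs.grid.extent),
                 "resolution": cs.grid.resolution, "crs": cs.grid.crs},
        "layers": entries,
    }
    if mask_rel:
        manifest["area_mask_file"] = mask_rel
    (root / MANIFEST).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    pd.DataFrame(
        [{"use": n,
          "vertical_domain": ";".join(sorted(a.vertical_domain)),
          "spatial_domain": a.spatial_domain,
          "temporal_domain": a.temporal_domain,
          "mobility": a.mobility}
         for n, a in sorted(cs.use_attributes.items())]
    ).to_csv(root / "inputs/use_attributes.csv", index=False)
    pd.DataFrame(
        [{"use": l.use, "pressure": l.pressure, "weight": l.weight,
          "distance_m": l.distance_m} for l in cs.pressure_links]
    ).to_csv(root / "inputs/pressure_links.csv", index=False)
    pd.DataFrame(
        [{"pressure": s.pressure, "env": s.env, "sensitivity": s.sensitivity}
         for s in cs.sensitivities]
    ).to_csv(root / "inputs/sensitivities.csv", index=False)
    if cs.ruleset is not None:
        (root / "inputs/ruleset.json").write_text(
            json.dumps(cs.ruleset.to_dict(), indent=2, sort_keys=True) + "\n")
    return root


# ------------------------------------------------------------- validation --

def validate_case_study(cs: CaseStudy) -> ValidationReport:
    """Report structural problems: misalignment, dangling identifiers,
    out-of-range inputs, empty registries.  An empty error list means the
    case-study invariants hold."""
    rep = ValidationReport()
    for role, registry in (("use", cs.uses), ("env", cs.envs),
                           ("pressure", cs.pressure_layers)):
        for name, layer in registry.items():
            if not layer.grid.is_aligned(cs.grid):
                rep.errors.append(f"{role} layer {name!r} is not aligned to the grid")
    pressures = cs.pressures
    for link in cs.pressure_links:
        if link.use not in cs.uses:
            rep.errors.append(f"pressure link references unknown use {link.use!r}")
        if not (0.0 <= link.weight <= 1.0):
            rep.warnings.append(
                f"link {link.use}->{link.pressure}: weight {link.weight} "
                "outside [0, 1]")
        if link.distance_m < 0:
            rep.errors.append(
                f"link {link.use}->{link.pressure}: negative distance")
    for s in cs.sensitivities:
        if s.pressure not in pressures:
            rep.errors.append(
                f"sensitivity references unknown pressure {s.pressure!r}")
        if s.env not in cs.envs:
            rep.errors.append(f"sensitivity references unknown env {s.env!r}")
        if s.sensitivity < 0:
            rep.errors.append(
                f"negative sensitivity for ({s.pressure}, {s.env})")
    for name in cs.uses:
        if name not in cs.use_attributes and cs.use_attributes:
            rep.warnings.append(f"use {name!r} has no attribute row")
    if not cs.uses:
        rep.warnings.append("no use layers")
    if not cs.envs:
        rep.warnings.append("no environmental layers")
    if not cs.grid.area_mask.any():
        rep.errors.append("empty area of analysis")
    return rep


# -------------------------------------------------------------- subsetting --

def subset(cs: CaseStudy, subregion_polygon=None, uses=None, envs=None,
           pressures=None) -> CaseStudy:
    """Restrict a case study to a subregion and/or a selection of human
    uses, environmental components and pressures.  Links and sensitivities
    are filtered consistently."""
    def pick(requested, registry, what):
        if requested is None:
            return dict(registry)
        unknown = sorted(set(requested) - set(registry))
        if unknown:
            raise CaseStudyError(f"unknown {what} name(s): {unknown}")
        return {n: registry[n] for n in sorted(requested)}

    new_uses = pick(uses, cs.uses, "use")
    new_envs = pick(envs, cs.envs, "env")
    if pressures is None:
        kept_pressures = cs.pressures
        new_players = dict(cs.pressure_layers)
    else:
        unknown = sorted(set(pressures) - cs.pressures)
        if unknown:
            raise CaseStudyError(f"unknown pressure name(s): {unknown}")
        kept_pressures = set(pressures)
        new_players = {n: l for n, l in cs.pressure_layers.items()
                       if n in kept_pressures}

    grid = cs.grid
    if subregion_polygon is not None:
        if isinstance(subregion_polygon, dict):
            subregion_polygon = shapely_shape(subregion_polygon)
        sub = make_grid(grid.extent, grid.resolution, grid.crs,
                        area_polygon=subregion_polygon)
        new_mask = grid.area_mask & sub.area_mask
        if not new_mask.any():
            raise CaseStudyError("subregion does not intersect the area of analysis")
        grid = AnalysisGrid(grid.extent, grid.resolution, grid.crs, new_mask)

    def regrid(registry):
        return {n: GridLayer(n, l.values.copy(), grid) for n, l in registry.items()}

    new_links = [l for l in cs.pressure_links
                 if l.use in new_uses and l.pressure in kept_pressures]
    # a sensitivity only survives if its pressure still has a source
    sourced = {l.pressure for l in new_links} | set(new_players)

    return CaseStudy(
        grid=grid,
        uses=regrid(new_uses),
        envs=regrid(new_envs),
        pressure_layers=regrid(new_players),
        use_attributes={n: a for n, a in cs.use_attributes.items() if n in new_uses},
        pressure_links=new_links,
        sensitivities=[s for s in cs.sensitivities
                       if s.pressure in sourced and s.env in new_envs],
        ruleset=cs.ruleset,
        title=cs.title,
        version=cs.version,
        subset_of={"title": cs.title,
                   "uses": sorted(new_uses), "envs": sorted(new_envs),
                   "pressures": sorted(kept_pressures),
                   "subregion": subregion_polygon is not None},
    )


# ------------------------------------------------------------- model runs --

def _provenance(cs: CaseStudy, model: str) -> dict:
    return {
        "model": model,
        "title": cs.title,
        "version": cs.version,
        "subset": cs.subset_of,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }


def run_muc(cs: CaseStudy) -> muc_mod.MUCResult:
    """Maritime Use Conflict analysis of the case study's use layers."""
    rep = validate_case_study(cs)
    if rep.errors:
        raise CaseStudyError("invalid case study: " + "; ".join(rep.errors))
    if not cs.uses:
        zero = np.zeros(cs.grid.shape)
        zero[~cs.grid.area_mask] = np.nan
        result = muc_mod.MUCResult(
            score_map=GridLayer("muc", zero, cs.grid),
            pair_contributions=pd.DataFrame(
                columns=["use_a", "use_b", "score_sum", "cell_count"]),
        )
    else:
        missing = sorted(set(cs.uses) - set(cs.use_attributes))
        if missing:
            raise CaseStudyError(
                f"use_attributes.csv has no rows for use(s) {missing}")
        attrs = {n: cs.use_attributes[n] for n in cs.uses}
        matrix = muc_mod.conflict_matrix(attrs, cs.ruleset or default_ruleset())
        presence = muc_mod.presence_layers(cs.uses)
        result = muc_mod.muc_map(presence, matrix, cs.grid)
    result.provenance = _provenance(cs, "muc")
    return result


def run_cea(cs: CaseStudy, rescale_pressures: bool = True) -> cea_mod.CEAResult:
    """Cumulative Effects Assessment of the case study."""
    rep = validate_case_study(cs)
    if rep.errors:
        raise CaseStudyError("invalid case study: " + "; ".join(rep.errors))
    if not cs.sensitivities:
        raise CaseStudyError(
            "cannot run CEA: the sensitivities table (inputs/sensitivities.csv) "
            "is missing or empty")
    if not cs.envs:
        raise CaseStudyError("cannot run CEA: no environmental layers")
    linked = {l.pressure for l in cs.pressure_links}
    pressure_maps: dict[str, GridLayer] = {}
    for pid in sorted(cs.pressures):
        if pid in linked:
            pressure_maps[pid] = cea_mod.pressure_map(
                cs.uses, cs.pressure_links, pid, cs.grid,
                rescale=rescale_pressures)
        else:
            pressure_maps[pid] = cs.pressure_layers[pid]
    result = cea_mod.cea_map(pressure_maps, cs.envs, cs.sensitivities, cs.grid)
    result.provenance = _provenance(cs, "cea")
    return result
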
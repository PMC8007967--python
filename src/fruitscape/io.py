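"""Plain-text readers and writers: CSV tables, GeoJSON polygons, CSV rasters.

All spatial data stay in planar km coordinates; no binary raster or
geodatabase formats are used. Newick genus trees are supported for stem-age
extraction via dendropy when available.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import shape, mapping

from .gridding import Grid
from .synthdata import CountyMap, Landscape

__all__ = [
    "write_counties_geojson",
    "read_counties_geojson",
    "write_grid_geojson",
    "write_surfaces_csv",
    "read_surfaces_csv",
    "write_cell_summary_geojson",
    "genus_ages_from_newick",
]


def write_counties_geojson(counties: CountyMap, path) -> None:
    feats = [
        {
            "type": "Feature",
            "properties": {"county_id": cid, "area_km2": area},
            "geometry": mapping(poly),
        }
        for cid, poly, area in counties.units
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def read_counties_geojson(path) -> CountyMap:
    gj = json.loads(Path(path).read_text())
    units = []
    for f in gj["features"]:
        poly = shape(f["geometry"])
        props = f.get("properties", {})
        cid = props.get("county_id") or props.get("id")
        units.append((cid, poly, props.get("area_km2", poly.area)))
    return CountyMap(units=units)


def write_grid_geojson(grid: Grid, path, properties: pd.DataFrame | None = None) -> None:
    feats = []
    for cid, poly, cent, land in grid.cells:
        props = {"cell_id": cid, "land_area_km2": land,
                 "x_km": cent[0], "y_km": cent[1]}
        if properties is not None and cid in properties.index:
            row = properties.loc[cid]
            props.update({k: (None if pd.isna(v) else float(v) if np.isscalar(v) else v)
                          for k, v in row.items()})
        feats.append({"type": "Feature", "properties": props,
                      "geometry": mapping(poly)})
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


write_cell_summary_geojson = write_grid_geojson


def write_surfaces_csv(landscape: Landscape, path) -> None:
    """Long-format raster dump: surface, row, col, value (row 0 = south)."""
    ny, nx = landscape.shape
    rows, cols = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    frames = []
    for name, arr in landscape.surfaces.items():
        frames.append(pd.DataFrame({"surface": name, "row": rows.ravel(),
                                    "col": cols.ravel(), "value": arr.ravel()}))
    pd.concat(frames).to_csv(path, index=False)


def read_surfaces_csv(path, cell_km: float) -> Landscape:
    df = pd.read_csv(path)
    ny = int(df["row"].max()) + 1
    nx = int(df["col"].max()) + 1
    surfaces = {}
    for name, grp in df.groupby("surface"):
        arr = np.full((ny, nx), np.nan)
        arr[grp["row"].to_numpy(), grp["col"].to_numpy()] = grp["value"].to_numpy()
        surfaces[name] = arr
    x = (np.arange(nx) + 0.5) * cell_km
    y = (np.arange(ny) + 0.5) * cell_km
    return Landscape(cell_km=cell_km, x=x, y=y, surfaces=surfaces)


def genus_ages_from_newick(path, genus_names: list | None = None) -> pd.DataFrame:
    """Extract genus stem ages (Ma) from an ultrametric dated Newick tree.

    Tips are genera; the stem age of a tip is the age of the start of its
    subtending branch, i.e. the age of its parent node, on a tree whose
    branch lengths are in Ma and whose tips sit at time 0.
    """
    import dendropy

    tree = dendropy.Tree.get(path=str(path), schema="newick")
    tree.calc_node_ages(ultrametricity_precision=1e-3)
    rows = []
    for leaf in tree.leaf_node_iter():
        name = leaf.taxon.label if leaf.taxon else None
        if name is None:
            continue
        if genus_names is not None and name not in genus_names:
            continue
        parent = leaf.parent_node
        stem = parent.age if parent is not None else leaf.age
        rows.append({"genus_id": name, "stem_age_Ma": float(stem)})
    return pd.DataFrame(rows)
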
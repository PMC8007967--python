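"""Rasterization of polygon-level occurrences onto equal-area grids.

A species is scored present in a grid cell when the summed area of the cell's
intersections with all counties where the species occurs exceeds a presence
threshold (default 1,106.66 km^2, the area of the smallest administrative
unit in the source data). Cells with less than half their area inside the
study region, or with too few species of the analysis group, are excluded
before modelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from shapely.geometry import box
from shapely.strtree import STRtree

from .synthdata import CountyMap

__all__ = [
    "Grid",
    "PresenceMatrix",
    "build_grid",
    "rasterize",
    "filter_cells",
    "split_large_counties",
    "PRESENCE_THRESHOLD_KM2",
]

#: area of county coverage above which a cell counts as a presence (strict)
PRESENCE_THRESHOLD_KM2 = 1106.66


@dataclass
class Grid:
    """Axis-aligned square analysis grid.

    ``cells`` holds (cell_id, polygon, (cx, cy), land_area_km2); cell ids are
    ``"r{row}c{col}"`` strings. ``land_area_km2`` is the area of the cell's
    intersection with the study region.
    """

    resolution_km: float
    origin: tuple[float, float]
    cells: list = field(default_factory=list)

    @property
    def ids(self) -> list[str]:
        return [c[0] for c in self.cells]

    def centroids(self) -> np.ndarray:
        return np.array([c[2] for c in self.cells])

    def land_areas(self) -> np.ndarray:
        return np.array([c[3] for c in self.cells])

    def polygons(self) -> list:
        return [c[1] for c in self.cells]


@dataclass
class PresenceMatrix:
    """Sparse species-by-cell presence with coverage provenance.

    ``coverage`` stores the summed intersected area (km^2) behind every
    nonzero entry so presence decisions stay auditable; ``presence`` is the
    boolean matrix coverage > threshold (strict).
    """

    species_ids: list
    cell_ids: list
    coverage: sparse.csr_matrix
    threshold_km2: float

    @property
    def presence(self) -> sparse.csr_matrix:
        out = self.coverage.copy()
        out.data = (out.data > self.threshold_km2).astype(np.int8)
        out.eliminate_zeros()
        return out

    def richness(self, species_subset: list | None = None) -> np.ndarray:
        """Species count per cell, optionally over a subset of species."""
        P = self.presence
        if species_subset is not None:
            idx = {s: i for i, s in enumerate(self.species_ids)}
            rows = [idx[s] for s in species_subset if s in idx]
            P = P[rows]
        return np.asarray(P.sum(axis=0)).ravel()

    def to_triplets(self) -> pd.DataFrame:
        coo = self.coverage.tocoo()
        return pd.DataFrame(
            {
                "species_id": [self.species_ids[i] for i in coo.row],
                "cell_id": [self.cell_ids[j] for j in coo.col],
                "coverage_km2": coo.data,
                "presence": (coo.data > self.threshold_km2).astype(int),
            }
        )


def build_grid(
    extent: tuple[float, float, float, float],
    resolution_km: float,
    study_region=None,
) -> Grid:
    """Lay a square grid of edge ``resolution_km`` over ``extent``.

    ``study_region`` (a shapely polygon, default the extent rectangle)
    clips each cell to give its land area. Cells with zero land area are
    dropped; an entirely empty grid is returned with a warning.
    """
    if resolution_km <= 0:
        raise ValueError("resolution_km must be positive")
    x0, y0, x1, y1 = extent
    region = study_region if study_region is not None else box(x0, y0, x1, y1)
    ncol = int(np.ceil((x1 - x0) / resolution_km - 1e-9))
    nrow = int(np.ceil((y1 - y0) / resolution_km - 1e-9))
    cells = []
    for r in range(nrow):
        for c in range(ncol):
            cx0 = x0 + c * resolution_km
            cy0 = y0 + r * resolution_km
            poly = box(cx0, cy0, cx0 + resolution_km, cy0 + resolution_km)
            land = poly.intersection(region).area
            if land <= 0:
                continue
            cells.append(
                (f"r{r}c{c}", poly,
                 (cx0 + resolution_km / 2, cy0 + resolution_km / 2), land)
            )
    if not cells:
        warnings.warn("grid has no cells intersecting the study region")
    return Grid(resolution_km=resolution_km, origin=(x0, y0), cells=cells)


def split_large_counties(counties: CountyMap, max_county_km2: float = np.inf) -> CountyMap:
    """Guillotine-split counties larger than ``max_county_km2`` into <= 4 parts.

    Oversized units are quartered along the midlines of their bounding box;
    part ids append ``_p{k}``. Occurrence records keyed by the parent id
    apply to every part (no downscaling of distributions is attempted), so
    summed intersection areas are unchanged — the split only refines the
    geometry available to later spatial operations.
    """
    if not np.isfinite(max_county_km2):
        return counties
    units = []
    for cid, poly, area in counties.units:
        if area <= max_county_km2:
            units.append((cid, poly, area))
            continue
        x0, y0, x1, y1 = poly.bounds
        xm, ym = (x0 + x1) / 2, (y0 + y1) / 2
        k = 0
        for bb in (box(x0, y0, xm, ym), box(xm, y0, x1, ym),
                   box(x0, ym, xm, y1), box(xm, ym, x1, y1)):
            part = poly.intersection(bb)
            if part.area > 0:
                units.append((f"{cid}_p{k}", part, part.area))
                k += 1
    return CountyMap(units=units)


def _county_cell_overlaps(counties: CountyMap, grid: Grid) -> dict[str, dict[int, float]]:
    cell_polys = grid.polygons()
    tree = STRtree(cell_polys)
    table: dict[str, dict[int, float]] = {}
    for cid, poly, _ in counties.units:
        hits = tree.query(poly)
        areas = {}
        for j in hits:
            a = poly.intersection(cell_polys[int(j)]).area
            if a > 0:
                areas[int(j)] = a
        table[cid] = areas
    return table


def rasterize(
    occurrences: pd.DataFrame,
    counties: CountyMap,
    grid: Grid,
    presence_threshold_km2: float = PRESENCE_THRESHOLD_KM2,
    max_county_km2: float = np.inf,
) -> PresenceMatrix:
    """Convert county-level occurrences to a gridded presence matrix.

    For each (species, cell) pair the coverage is the sum over the species'
    occupied counties of the county-cell intersection area; the cell is a
    presence when coverage strictly exceeds ``presence_threshold_km2``.
    """
    counties = split_large_counties(counties, max_county_km2)
    known = set()
    parent_parts: dict[str, list[str]] = {}
    for cid, _, _ in counties.units:
        known.add(cid)
        base = cid.rsplit("_p", 1)[0] if "_p" in cid else cid
        parent_parts.setdefault(base, []).append(cid)

    occ_ids = occurrences["county_id"].unique()
    unknown = [c for c in occ_ids if c not in known and c not in parent_parts]
    if unknown:
        raise KeyError(f"occurrences reference unknown counties: {sorted(unknown)[:10]}")

    overlaps = _county_cell_overlaps(counties, grid)
    species_ids = sorted(occurrences["species_id"].unique())
    sp_index = {s: i for i, s in enumerate(species_ids)}

    rows, cols, vals = [], [], []
    for sp, grp in occurrences.groupby("species_id", sort=True):
        acc: dict[int, float] = {}
        for parent in grp["county_id"]:
            for part in parent_parts.get(parent, [parent]):
                for j, a in overlaps[part].items():
                    acc[j] = acc.get(j, 0.0) + a
        i = sp_index[sp]
        for j, a in acc.items():
            rows.append(i)
            cols.append(j)
            vals.append(a)
    cov = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(species_ids), len(grid.cells))
    )
    return PresenceMatrix(
        species_ids=species_ids,
        cell_ids=grid.ids,
        coverage=cov,
        threshold_km2=presence_threshold_km2,
    )


def filter_cells(
    grid: Grid,
    presence: PresenceMatrix,
    species_table: pd.DataFrame | None = None,
    min_land_fraction: float = 0.5,
    min_species: int = 5,
    group: str = "all",
) -> tuple[list[str], dict[str, int]]:
    """Apply the land-area and minimum-richness cell filters.

    A cell is retained iff its land area is at least ``min_land_fraction`` of
    the full cell area AND the richness of the analysis ``group`` strictly
    exceeds ``min_species``. Returns (retained cell ids, exclusion tallies).
    """
    if min_species < 0:
        raise ValueError("min_species must be >= 0")
    if presence.cell_ids != grid.ids:
        raise ValueError("presence matrix was built on a different grid")
    land = grid.land_areas()
    full = grid.resolution_km**2
    land_ok = land >= min_land_fraction * full

    if group == "all" or species_table is None:
        richness = presence.richness()
    else:
        members = species_table.loc[
            species_table["growth_form"] == group, "species_id"
        ].tolist()
        richness = presence.richness(members)
    rich_ok = richness > min_species

    retained = [cid for cid, a, b in zip(grid.ids, land_ok, rich_ok) if a and b]
    tallies = {
        "n_cells": len(grid.cells),
        "excluded_land": int((~land_ok).sum()),
        "excluded_richness": int((land_ok & ~rich_ok).sum()),
        "retained": len(retained),
    }
    if not retained:
        warnings.warn(f"no cells retained for group {group!r}")
    return retained, tallies
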
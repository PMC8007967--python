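"""Per-cell trait composition, height, genus age and environment summaries.

Each retained grid cell is summarized by the proportion of fleshy-fruited
species (overall and per growth form), the arithmetic mean of the maximum
mature heights of its height-eligible species, the mean stem age of the set
of genera present (each genus counted once), and the mean of every
environmental surface over the raster cells it contains. Predictors are
standardized — mean height on the log10 scale — before modelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gridding import Grid, PresenceMatrix
from .synthdata import Landscape

__all__ = [
    "GROWTH_FORM_MAP",
    "HEIGHT_EXCLUDED_FORMS",
    "ModelFrame",
    "map_growth_forms",
    "summarize_cells",
    "build_model_frame",
]

log = logging.getLogger(__name__)

#: raw growth-form label -> analysis growth form. Woody lianas are shrubs;
#: herbaceous lianas and subshrubs are herbs. Climbers and epiphytes carry no
#: self-supporting stature and are pooled with herbs; scandent shrubs with
#: shrubs. All three are excluded from height summaries.
GROWTH_FORM_MAP = {
    "tree": "tree",
    "shrub": "shrub",
    "woody liana": "shrub",
    "scandent shrub": "shrub",
    "herb": "herb",
    "herbaceous liana": "herb",
    "subshrub": "herb",
    "climber": "herb",
    "epiphyte": "herb",
}

#: labels whose species are excluded from mean-height calculations
HEIGHT_EXCLUDED_FORMS = {"climber", "scandent shrub", "epiphyte"}


def map_growth_forms(raw_labels) -> pd.Series:
    """Map raw growth-form labels onto {tree, shrub, herb}.

    Raises ``ValueError`` listing every unknown label; nothing is dropped
    silently.
    """
    s = pd.Series(raw_labels)
    unknown = sorted(set(s.unique()) - set(GROWTH_FORM_MAP))
    if unknown:
        raise ValueError(f"unknown growth-form labels: {unknown}")
    return s.map(GROWTH_FORM_MAP)


def summarize_cells(
    presence: PresenceMatrix,
    species_table: pd.DataFrame,
    genus_ages: pd.DataFrame,
    landscape: Landscape,
    grid: Grid,
) -> pd.DataFrame:
    """Build the per-cell summary table.

    One row per grid cell (cells with zero presences get zero richness),
    indexed by cell id, with centroid coordinates, per-group richness and
    fleshy counts/proportions, mean height over height-eligible species,
    mean stem age over the set of genera present, and environmental means.
    """
    P = presence.presence  # species x cells, 0/1
    if P.nnz == 0:
        raise ValueError("presence matrix is empty")
    sp = species_table.set_index("species_id").loc[presence.species_ids]
    fleshy = (sp["fruit_type"].to_numpy() == "fleshy").astype(float)

    out = pd.DataFrame(index=pd.Index(presence.cell_ids, name="cell_id"))
    cents = grid.centroids()
    out["x_km"] = cents[:, 0]
    out["y_km"] = cents[:, 1]

    groups = {"all": np.ones(len(sp), bool)}
    for g in ("herb", "shrub", "tree"):
        groups[g] = sp["growth_form"].to_numpy() == g
    for g, mask in groups.items():
        Pg = P[np.flatnonzero(mask)]
        rich = np.asarray(Pg.sum(axis=0)).ravel().astype(float)
        fl = np.asarray(Pg.T @ fleshy[mask]).ravel()
        out[f"richness_{g}"] = rich
        out[f"fleshy_{g}"] = fl
        with np.errstate(invalid="ignore", divide="ignore"):
            out[f"prop_fleshy_{g}"] = np.where(rich > 0, fl / np.maximum(rich, 1), np.nan)

    # mean max height over present, height-eligible species
    eligible = ~sp["height_excluded"].to_numpy()
    h = sp["max_height_m"].to_numpy() * eligible
    Pe = P[np.flatnonzero(eligible)]
    n_elig = np.asarray(Pe.sum(axis=0)).ravel()
    h_sum = np.asarray(P.T @ h).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        out["mean_height_m"] = np.where(n_elig > 0, h_sum / np.maximum(n_elig, 1), np.nan)
    n_empty = int(((np.asarray(P.sum(axis=0)).ravel() > 0) & (n_elig == 0)).sum())
    if n_empty:
        log.info("%d cells have no height-eligible species; mean height left missing", n_empty)

    # mean genus stem age, each genus counted once per cell
    age_map = genus_ages.set_index("genus_id")["stem_age_Ma"]
    genera = sorted(sp["genus_id"].unique())
    gidx = {g: i for i, g in enumerate(genera)}
    from scipy import sparse as _sparse

    G = _sparse.csr_matrix(
        (np.ones(len(sp)), (sp["genus_id"].map(gidx).to_numpy(), np.arange(len(sp)))),
        shape=(len(genera), len(sp)),
    )
    genus_present = (G @ P) > 0  # genera x cells boolean
    ages = age_map.reindex(genera)
    known = ages.notna().to_numpy()
    n_missing = int((~known).sum())
    if n_missing:
        log.info("%d genera lack stem ages and are omitted from cell means", n_missing)
    ages_v = np.nan_to_num(ages.to_numpy(), nan=0.0) * known
    gp = genus_present.astype(float)
    n_gen = np.asarray(gp[known].sum(axis=0)).ravel()
    age_sum = np.asarray(gp.T @ ages_v).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        out["mean_genus_age_Ma"] = np.where(n_gen > 0, age_sum / np.maximum(n_gen, 1), np.nan)

    # environmental means: average of raster cells falling in each grid cell
    gx0, gy0 = grid.origin
    res = grid.resolution_km
    rx, ry = np.meshgrid(landscape.x, landscape.y)
    col = np.floor((rx.ravel() - gx0) / res).astype(int)
    row = np.floor((ry.ravel() - gy0) / res).astype(int)
    keys = [f"r{r}c{c}" for r, c in zip(row, col)]
    cell_pos = {cid: k for k, cid in enumerate(presence.cell_ids)}
    tgt = np.array([cell_pos.get(k, -1) for k in keys])
    inside = tgt >= 0
    counts = np.bincount(tgt[inside], minlength=len(presence.cell_ids)).astype(float)
    for name, arr in landscape.surfaces.items():
        sums = np.bincount(tgt[inside], weights=arr.ravel()[inside],
                           minlength=len(presence.cell_ids))
        with np.errstate(invalid="ignore", divide="ignore"):
            out[name] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return out


@dataclass
class ModelFrame:
    """Response counts, standardized predictors and provenance for one group."""

    cell_ids: list
    successes: np.ndarray          # fleshy counts per cell
    totals: np.ndarray             # group richness per cell
    X: np.ndarray                  # n x p standardized predictor matrix
    predictors: list
    centroids: np.ndarray          # n x 2 (x_km, y_km)
    group: str = "all"
    transform_meta: dict = field(default_factory=dict)

    @property
    def proportions(self) -> np.ndarray:
        return self.successes / self.totals

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.predictors.index(name)]

    def subset(self, names: list) -> np.ndarray:
        idx = [self.predictors.index(n) for n in names]
        return self.X[:, idx]


#: predictor-name -> cell-summary column; height is log10-transformed first
PREDICTOR_COLUMNS = {
    "height": "mean_height_m",
    "age": "mean_genus_age_Ma",
    "north": "y_km",
}


def build_model_frame(
    cell_summary: pd.DataFrame,
    predictors: list,
    group: str = "all",
    retained_ids: list | None = None,
) -> ModelFrame:
    """Assemble the standardized modelling frame for one analysis group.

    Mean height is log10-transformed before z-scoring; every other predictor
    is z-scored on the raw scale, with means/sds computed over the retained
    cells of this group and stored for back-transformation. Cells with a
    missing value in any requested predictor are dropped (logged).
    """
    df = cell_summary.loc[retained_ids] if retained_ids is not None else cell_summary.copy()
    cols = {}
    for p in predictors:
        col = PREDICTOR_COLUMNS.get(p, p)
        if col not in df.columns:
            raise KeyError(f"predictor {p!r} (column {col!r}) not in cell summary")
        v = df[col].astype(float)
        if p == "height":
            if (v <= 0).any():
                raise ValueError("non-positive mean height; cannot log-transform")
            v = np.log10(v)
        cols[p] = v
    Xraw = pd.DataFrame(cols, index=df.index)
    resp = df[[f"fleshy_{group}", f"richness_{group}"]]
    keep = Xraw.notna().all(axis=1) & (resp[f"richness_{group}"] > 0)
    dropped = int((~keep).sum())
    if dropped:
        log.info("dropping %d cells with missing predictors/response (group %s)", dropped, group)
    Xraw, resp = Xraw[keep], resp[keep]

    meta = {"log10": ["height"] if "height" in predictors else [], "mean": {}, "sd": {}}
    Xs = np.empty((len(Xraw), len(predictors)))
    for j, p in enumerate(predictors):
        v = Xraw[p].to_numpy()
        m, s = v.mean(), v.std(ddof=0)
        if s <= 0 or not np.isfinite(s):
            raise ValueError(f"predictor {p!r} has zero variance over retained cells")
        meta["mean"][p] = float(m)
        meta["sd"][p] = float(s)
        Xs[:, j] = (v - m) / s

    return ModelFrame(
        cell_ids=list(Xraw.index),
        successes=resp[f"fleshy_{group}"].to_numpy(float),
        totals=resp[f"richness_{group}"].to_numpy(float),
        X=Xs,
        predictors=list(predictors),
        centroids=df.loc[Xraw.index, ["x_km", "y_km"]].to_numpy(float),
        group=group,
        transform_meta=meta,
    )
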
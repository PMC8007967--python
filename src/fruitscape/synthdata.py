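"""Synthetic study system with known generative truth.

Builds a planar landscape (km units, equal-area by construction) carrying
climate and productivity surfaces, a county tessellation with heterogeneous
areas, a species pool with growth forms, maximum heights, genus stem ages and
a logistic fruit-type model, and county-level occurrence records produced by
environmental filtering around a range centroid. Every stochastic choice is
driven by an explicit seed and the generative parameters are recorded so that
downstream estimators can be tested against known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import box

__all__ = [
    "Landscape",
    "CountyMap",
    "GenerativeTruth",
    "RangeParams",
    "make_landscape",
    "make_counties",
    "make_species_pool",
    "make_occurrences",
]

GROWTH_FORMS = ("tree", "shrub", "herb")


@dataclass
class Landscape:
    """Gridded environmental surfaces on a planar extent.

    Attributes
    ----------
    cell_km : float
        Edge length of one raster cell.
    x, y : ndarray
        Cell-centre coordinates in km; ``y`` increases northward and serves
        as the latitude proxy.
    surfaces : dict of str -> (ny, nx) ndarray
        Named environmental rasters (MAT, MTCQ, MPWQ, AI, TSN, PSN, AET,
        north_km).
    params : dict
        The generative parameters used, echoed for provenance.
    """

    cell_km: float
    x: np.ndarray
    y: np.ndarray
    surfaces: dict[str, np.ndarray]
    params: dict = field(default_factory=dict)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(x0, y0, x1, y1) bounding rectangle in km."""
        half = self.cell_km / 2.0
        return (
            float(self.x[0] - half),
            float(self.y[0] - half),
            float(self.x[-1] + half),
            float(self.y[-1] + half),
        )

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.surfaces.values())).shape

    def value_at(self, name: str, px: float, py: float) -> float:
        """Surface value of the raster cell containing point (px, py)."""
        arr = self.surfaces[name]
        j = int(np.argmin(np.abs(self.x - px)))
        i = int(np.argmin(np.abs(self.y - py)))
        return float(arr[i, j])

    def zscore(self, name: str) -> np.ndarray:
        arr = self.surfaces[name]
        return (arr - arr.mean()) / arr.std()


@dataclass
class CountyMap:
    """Rectangular administrative units tiling the landscape extent."""

    units: list  # (county_id, shapely Polygon, area_km2)

    @property
    def ids(self) -> list[str]:
        return [u[0] for u in self.units]

    @property
    def areas(self) -> np.ndarray:
        return np.array([u[2] for u in self.units])

    def centroids(self) -> np.ndarray:
        return np.array([[u[1].centroid.x, u[1].centroid.y] for u in self.units])

    def polygons(self) -> dict:
        return {u[0]: u[1] for u in self.units}


@dataclass
class GenerativeTruth:
    """Parameters of the trait/age/height generative model, recorded verbatim.

    The fruit-type model is P(fleshy) = logistic(b0 + b_height * log10(H) +
    b_env * z_opt) where H is maximum height in metres and z_opt is the
    species' environmental optimum on the standardized AET axis.
    """

    b0: float = -2.3
    b_height: float = 2.0
    b_env: float = 0.8
    # natural-log lognormal (mu, sigma) of max height per growth form, metres
    height_lognorm: dict = field(
        default_factory=lambda: {
            "tree": (2.708, 0.5),   # median ~15 m
            "shrub": (0.693, 0.5),  # median ~2 m
            "herb": (-0.799, 0.7),  # median ~0.45 m
        }
    )
    genus_age_gamma: tuple = (2.0, 20.0)  # shape, scale -> mean 40 Ma
    # correlation between log height and environmental optimum: taller
    # species prefer more productive (high-AET) regions
    rho_height_env: float = 0.7
    # optional coupling of genus age to genus-level fleshy fraction (0 = none)
    age_fleshy_coupling: float = 0.0
    species_per_genus: float = 8.0
    seed: int | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=list)


@dataclass
class RangeParams:
    """Range-building parameters for occurrence generation."""

    radius_median_km: float = 300.0
    radius_sigma: float = 0.7          # lognormal sd on the log scale
    env_tolerance: float = 1.5         # half-width on the AET z axis
    centroid_bias_sd: float = 0.5      # softness of centroid placement


def _smooth_noise(rng: np.random.Generator, shape, sd: float, sigma: float = 2.0) -> np.ndarray:
    if sd == 0:
        return np.zeros(shape)
    raw = rng.normal(0.0, 1.0, shape)
    sm = gaussian_filter(raw, sigma=sigma, mode="nearest")
    s = sm.std()
    if s > 0:
        sm = sm / s
    return sm * sd


def make_landscape(
    nx: int,
    ny: int,
    cell_km: float = 25.0,
    gradient_params: dict | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> Landscape:
    """Generate environmental surfaces on an ``ny`` x ``nx`` planar raster.

    MAT decreases linearly northward (latitudinal proxy), MPWQ increases
    eastward, and AET is a monotone increasing function of both MAT and MPWQ
    plus spatially smoothed noise. ``noise_sd`` scales every surface's noise
    amplitude; 0 gives exact deterministic gradients.
    """
    if nx < 2 or ny < 2:
        raise ValueError(f"raster must be at least 2 x 2, got {ny} x {nx}")
    if cell_km <= 0:
        raise ValueError("cell_km must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    p = {
        "mat_south": 22.0,        # deg C at y = 0
        "mat_slope": 0.02,        # deg C lost per km northward
        "mtcq_offset": 12.0,
        "mpwq_west": 100.0,       # mm at x = 0
        "mpwq_slope": 0.5,        # mm gained per km eastward
        "aet_base": 150.0,
        "aet_per_degC": 8.0,
        "aet_per_mm": 0.6,
        "noise_amp": {
            "MAT": 0.8, "MTCQ": 1.0, "MPWQ": 25.0, "AI": 0.08,
            "TSN": 1.0, "PSN": 1.0, "AET": 30.0,
        },
    }
    if gradient_params:
        for k, v in gradient_params.items():
            if k == "noise_amp":
                p["noise_amp"].update(v)
            else:
                p[k] = v

    rng = np.random.default_rng(seed)
    x = (np.arange(nx) + 0.5) * cell_km
    y = (np.arange(ny) + 0.5) * cell_km
    X, Y = np.meshgrid(x, y)

    amp = p["noise_amp"]
    mat = p["mat_south"] - p["mat_slope"] * Y + _smooth_noise(rng, Y.shape, noise_sd * amp["MAT"])
    mtcq = mat - p["mtcq_offset"] + _smooth_noise(rng, Y.shape, noise_sd * amp["MTCQ"])
    mpwq = p["mpwq_west"] + p["mpwq_slope"] * X + _smooth_noise(rng, Y.shape, noise_sd * amp["MPWQ"])
    ai = mpwq / 500.0 + _smooth_noise(rng, Y.shape, noise_sd * amp["AI"])
    tsn = 5.0 + 0.002 * Y + _smooth_noise(rng, Y.shape, noise_sd * amp["TSN"])
    psn = 50.0 - 0.01 * X + _smooth_noise(rng, Y.shape, noise_sd * amp["PSN"])
    # AET monotone increasing in both its energy (MAT) and water (MPWQ) inputs
    aet = (
        p["aet_base"]
        + p["aet_per_degC"] * mat
        + p["aet_per_mm"] * mpwq
        + _smooth_noise(rng, Y.shape, noise_sd * amp["AET"])
    )
    surfaces = {
        "MAT": mat, "MTCQ": mtcq, "MPWQ": mpwq, "AI": ai,
        "TSN": tsn, "PSN": psn, "AET": aet, "north_km": Y.astype(float),
    }
    for name, arr in surfaces.items():
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError(f"non-finite values in surface {name}")
    params = dict(p, nx=nx, ny=ny, cell_km=cell_km, noise_sd=noise_sd, seed=seed)
    return Landscape(cell_km=cell_km, x=x, y=y, surfaces=surfaces, params=params)


def _split_rect(rect: tuple, areas: np.ndarray, out: list) -> None:
    # recursive guillotine: split the rectangle proportionally to the summed
    # target areas of the two halves of the list, along the longer side
    x0, y0, x1, y1 = rect
    if len(areas) == 1:
        out.append(rect)
        return
    mid = len(areas) // 2
    frac = float(areas[:mid].sum() / areas.sum())
    if (x1 - x0) >= (y1 - y0):
        xc = x0 + frac * (x1 - x0)
        _split_rect((x0, y0, xc, y1), areas[:mid], out)
        _split_rect((xc, y0, x1, y1), areas[mid:], out)
    else:
        yc = y0 + frac * (y1 - y0)
        _split_rect((x0, y0, x1, yc), areas[:mid], out)
        _split_rect((x0, yc, x1, y1), areas[mid:], out)


def make_counties(
    landscape: Landscape, n_target: int, size_cv: float = 0.6, seed: int = 0
) -> CountyMap:
    """Tessellate the extent into ~``n_target`` rectangles by guillotine splits.

    Target areas are drawn with coefficient of variation ``size_cv`` and the
    recursion splits each rectangle proportionally to the summed targets, so
    realized areas equal the targets and tile the extent exactly.
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    ncells = landscape.shape[0] * landscape.shape[1]
    if n_target > ncells:
        raise ValueError(f"n_target={n_target} exceeds raster cell count {ncells}")
    if size_cv < 0:
        raise ValueError("size_cv must be >= 0")

    rng = np.random.default_rng(seed)
    if size_cv == 0 or n_target == 1:
        areas = np.ones(n_target)
    else:
        shape_par = 1.0 / size_cv**2
        g = rng.gamma(shape_par, 1.0, size=n_target)
        # rescale deviations so the realized CV hits size_cv exactly when the
        # draw allows it (all areas must stay positive)
        sd = g.std()
        if sd > 0:
            cand = 1.0 + size_cv * (g - g.mean()) / sd
            areas = cand if cand.min() > 0.01 else g / g.mean()
        else:
            areas = g / max(g.mean(), 1e-12)
    rng.shuffle(areas)

    x0, y0, x1, y1 = landscape.extent
    rects: list[tuple] = []
    _split_rect((x0, y0, x1, y1), np.asarray(areas, dtype=float), rects)
    units = []
    for i, (a, b, c, d) in enumerate(rects):
        poly = box(a, b, c, d)
        units.append((f"county_{i:04d}", poly, poly.area))
    total = sum(u[2] for u in units)
    expected = (x1 - x0) * (y1 - y0)
    assert abs(total - expected) <= 1e-6 * expected
    return CountyMap(units=units)


def make_species_pool(
    n_species: int,
    form_mix: dict[str, float] | None = None,
    truth: GenerativeTruth | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a species pool and its genus stem-age table.

    Returns ``(species, genus_ages)``. ``species`` has one row per species
    with raw growth-form label, mapped growth form, maximum height (lognormal
    per form, trees tallest), environmental optimum on the AET z axis
    (correlated with log height by ``truth.rho_height_env``), and a fruit
    type drawn from the logistic model recorded in ``truth``. Genus stem ages
    are gamma distributed and, by default, independent of fruit type.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    truth = truth or GenerativeTruth()
    truth.seed = seed
    form_mix = form_mix or {"herb": 0.55, "shrub": 0.27, "tree": 0.18}
    probs = np.array([form_mix.get(f, 0.0) for f in GROWTH_FORMS], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-8 or (probs < 0).any():
        raise ValueError(f"form_mix must be a probability vector over {GROWTH_FORMS}")

    rng = np.random.default_rng(seed)
    forms = rng.choice(len(GROWTH_FORMS), size=n_species, p=probs)
    growth_form = np.array(GROWTH_FORMS)[forms]

    # raw labels: mostly the canonical label, with the paper-style variants
    raw_variants = {
        "tree": [("tree", 1.0)],
        "shrub": [("shrub", 0.88), ("woody liana", 0.10), ("scandent shrub", 0.02)],
        "herb": [
            ("herb", 0.78), ("herbaceous liana", 0.08), ("subshrub", 0.10),
            ("climber", 0.03), ("epiphyte", 0.01),
        ],
    }
    raw_form = np.empty(n_species, dtype=object)
    for f in GROWTH_FORMS:
        mask = growth_form == f
        labels, w = zip(*raw_variants[f])
        raw_form[mask] = rng.choice(labels, size=mask.sum(), p=np.array(w) / sum(w))
    height_excluded = np.isin(raw_form, ["climber", "scandent shrub", "epiphyte"])

    log_h = np.empty(n_species)
    for f in GROWTH_FORMS:
        mask = growth_form == f
        mu, sig = truth.height_lognorm[f]
        log_h[mask] = rng.normal(mu, sig, mask.sum())
    height = np.exp(log_h)

    # environmental optimum on the standardized AET axis, correlated with
    # height so taller floras sit in more productive regions
    rho = truth.rho_height_env
    z_h = np.zeros(n_species)
    for f in GROWTH_FORMS:
        mask = growth_form == f
        mu, sig = truth.height_lognorm[f]
        z_h[mask] = (log_h[mask] - mu) / sig
    env_opt = rho * z_h + np.sqrt(max(0.0, 1 - rho**2)) * rng.normal(0, 1, n_species)

    eta = truth.b0 + truth.b_height * np.log10(height) + truth.b_env * env_opt
    p_fleshy = 1.0 / (1.0 + np.exp(-eta))
    fleshy = rng.random(n_species) < p_fleshy
    fruit_type = np.where(fleshy, "fleshy", "dry")

    n_genera = max(1, int(round(n_species / truth.species_per_genus)))
    n_genera = min(n_genera, n_species)
    genus_idx = np.empty(n_species, dtype=int)
    genus_idx[:n_genera] = np.arange(n_genera)  # every genus gets >= 1 species
    if n_species > n_genera:
        genus_idx[n_genera:] = rng.integers(0, n_genera, n_species - n_genera)
    perm = rng.permutation(n_species)
    genus_idx = genus_idx[perm]
    genus_id = np.array([f"genus_{g:04d}" for g in genus_idx])

    shape_par, scale = truth.genus_age_gamma
    ages = rng.gamma(shape_par, scale, n_genera)
    if truth.age_fleshy_coupling != 0.0:
        fr = pd.Series(fleshy).groupby(genus_idx).mean()
        f_g = np.zeros(n_genera)
        f_g[fr.index.to_numpy()] = fr.to_numpy()
        ages = ages * np.exp(truth.age_fleshy_coupling * (f_g - fleshy.mean()))
    genus_ages = pd.DataFrame(
        {"genus_id": [f"genus_{g:04d}" for g in range(n_genera)],
         "stem_age_Ma": ages}
    )

    species = pd.DataFrame(
        {
            "species_id": [f"sp_{i:05d}" for i in range(n_species)],
            "genus_id": genus_id,
            "raw_form": raw_form,
            "growth_form": growth_form,
            "fruit_type": fruit_type,
            "max_height_m": height,
            "height_excluded": height_excluded,
            "env_optimum": env_opt,
        }
    )
    return species, genus_ages


def make_occurrences(
    species: pd.DataFrame,
    counties: CountyMap,
    landscape: Landscape,
    range_params: RangeParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Place each species' range and record county-level occurrences.

    A centroid county is drawn with probability decaying in the distance
    between the county's standardized AET and the species' environmental
    optimum; the species then occupies every county whose centroid lies
    within its range radius and whose AET is within its tolerance. The
    centroid county is always occupied, so no species has an empty range.
    """
    rp = range_params or RangeParams()
    rng = np.random.default_rng(seed)

    cents = counties.centroids()
    zaet = landscape.zscore("AET")
    # nearest raster cell centre
    ix = np.array([int(np.argmin(np.abs(landscape.x - cx))) for cx in cents[:, 0]])
    iy = np.array([int(np.argmin(np.abs(landscape.y - cy))) for cy in cents[:, 1]])
    county_z = zaet[iy, ix]

    ids = np.array(counties.ids)
    rows_sp: list[str] = []
    rows_co: list[str] = []
    for _, sp in species.iterrows():
        opt = sp["env_optimum"]
        if rp.centroid_bias_sd > 0:
            w = np.exp(-0.5 * ((county_z - opt) / rp.centroid_bias_sd) ** 2)
            w = w + 1e-12
            w = w / w.sum()
        else:
            w = np.full(len(ids), 1.0 / len(ids))
        c0 = rng.choice(len(ids), p=w)
        radius = float(np.exp(np.log(max(rp.radius_median_km, 0.0) + 1e-300)
                              + rp.radius_sigma * rng.normal())) if rp.radius_median_km > 0 else 0.0
        dist = np.hypot(cents[:, 0] - cents[c0, 0], cents[:, 1] - cents[c0, 1])
        occ = (dist <= radius) & (np.abs(county_z - opt) <= rp.env_tolerance)
        occ[c0] = True
        for cid in ids[occ]:
            rows_sp.append(sp["species_id"])
            rows_co.append(cid)
    occ_df = pd.DataFrame({"species_id": rows_sp, "county_id": rows_co})
    occ_df = occ_df.drop_duplicates().sort_values(["species_id", "county_id"]).reset_index(drop=True)
    return occ_df
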
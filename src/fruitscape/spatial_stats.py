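"""Spatial autocorrelation statistics and spatially explicit models.

Implements distance-band spatial weights, Moran's I with randomization
inference, distance-class correlograms with a zero-crossing estimate (used
to choose SAR neighborhood distances), the modified t-test of Dutilleul /
Clifford with an effective sample size for correlations between two
autocorrelated variables, the maximum-likelihood simultaneous autoregressive
(SAR) error model, and variance inflation factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.spatial.distance import cdist

__all__ = [
    "SpatialWeights",
    "MoranResult",
    "CorrelogramResult",
    "ModifiedTTestResult",
    "SARFit",
    "build_weights",
    "morans_i",
    "correlogram",
    "modified_ttest",
    "sar_error_fit",
    "vif",
]


@dataclass
class SpatialWeights:
    """Distance-band neighbor structure.

    The neighbor relation is symmetric before row standardization
    (i ~ j iff 0 < d(i, j) <= distance_km); islands keep empty rows and are
    flagged rather than dropped.
    """

    n: int
    neighbors: list           # list of int arrays
    weights: list             # list of float arrays, aligned with neighbors
    style: str                # "binary" | "row-standardized"
    distance_km: float
    islands: list = field(default_factory=list)

    def dense(self) -> np.ndarray:
        W = np.zeros((self.n, self.n))
        for i, (nb, w) in enumerate(zip(self.neighbors, self.weights)):
            W[i, nb] = w
        return W

    @property
    def s0(self) -> float:
        return float(sum(w.sum() for w in self.weights))


def build_weights(centroids: np.ndarray, distance_km: float,
                  style: str = "row-standardized") -> SpatialWeights:
    """Distance-band weights: i ~ j iff 0 < d(i,j) <= distance_km."""
    if distance_km <= 0:
        raise ValueError("distance_km must be positive")
    if style not in ("binary", "row-standardized"):
        raise ValueError(f"unknown style {style!r}")
    pts = np.asarray(centroids, float)
    n = len(pts)
    D = cdist(pts, pts)
    neighbors, weights, islands = [], [], []
    for i in range(n):
        nb = np.flatnonzero((D[i] > 0) & (D[i] <= distance_km))
        neighbors.append(nb)
        if len(nb) == 0:
            islands.append(i)
            weights.append(np.array([]))
        elif style == "binary":
            weights.append(np.ones(len(nb)))
        else:
            weights.append(np.full(len(nb), 1.0 / len(nb)))
    if len(islands) == n:
        raise ValueError("every cell is isolated at this distance")
    if islands:
        warnings.warn(f"{len(islands)} isolated cells (no neighbors) at "
                      f"{distance_km} km; they carry zero weights")
    return SpatialWeights(n=n, neighbors=neighbors, weights=weights,
                          style=style, distance_km=distance_km, islands=islands)


@dataclass
class MoranResult:
    I: float
    expected: float
    variance: float
    z: float
    p: float
    n: int


def _moran_core(z: np.ndarray, W: np.ndarray) -> float:
    s0 = W.sum()
    return float(len(z) / s0 * (z @ W @ z) / (z @ z))


def morans_i(values: np.ndarray, weights: SpatialWeights) -> MoranResult:
    """Moran's I with expectation, randomization variance, z and two-sided p."""
    x = np.asarray(values, float)
    n = len(x)
    if n < 3:
        raise ValueError("Moran's I needs n >= 3")
    if np.std(x) == 0:
        raise ValueError("values are constant; Moran's I undefined")
    if n != weights.n:
        raise ValueError("values / weights size mismatch")
    W = weights.dense()
    z = x - x.mean()
    s0 = W.sum()
    I = _moran_core(z, W)
    EI = -1.0 / (n - 1)
    s1 = 0.5 * ((W + W.T) ** 2).sum()
    rs, cs = W.sum(axis=1), W.sum(axis=0)
    s2 = ((rs + cs) ** 2).sum()
    b2 = n * (z**4).sum() / (z**2).sum() ** 2
    num = n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2) - b2 * (
        (n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2
    )
    var = num / ((n - 1) * (n - 2) * (n - 3) * s0**2) - EI**2
    if var <= 0:
        raise ValueError("randomization variance non-positive; degenerate weights")
    zscore = (I - EI) / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(zscore))
    return MoranResult(I=I, expected=EI, variance=float(var), z=float(zscore),
                       p=float(p), n=n)


@dataclass
class CorrelogramResult:
    midpoints_km: np.ndarray
    moran: np.ndarray
    n_pairs: np.ndarray
    zero_crossing_km: float
    crossed: bool


def _class_masks(D: np.ndarray, n_classes: int, dmax: float):
    width = dmax / n_classes
    iu = np.triu_indices_from(D, k=1)
    masks = []
    for k in range(n_classes):
        lo, hi = k * width, (k + 1) * width
        m = np.zeros_like(D, dtype=bool)
        sel = (D[iu] > lo) & (D[iu] <= hi) if k > 0 else (D[iu] <= hi)
        m[iu[0][sel], iu[1][sel]] = True
        masks.append(m | m.T)
    mids = (np.arange(n_classes) + 0.5) * width
    return masks, mids


def correlogram(values: np.ndarray, centroids: np.ndarray,
                n_classes: int = 13) -> CorrelogramResult:
    """Moran's I per equal-width distance class, up to half the max distance.

    The zero crossing is interpolated between the last positive and the
    first non-positive class Moran value; if the coefficient never crosses
    zero the maximum considered distance is returned with ``crossed=False``.
    """
    if n_classes < 3:
        raise ValueError("need at least 3 distance classes")
    x = np.asarray(values, float)
    if np.std(x) == 0:
        raise ValueError("values are constant")
    pts = np.asarray(centroids, float)
    D = cdist(pts, pts)
    dmax = D.max() / 2.0
    masks, mids = _class_masks(D, n_classes, dmax)
    z = x - x.mean()
    I = np.full(n_classes, np.nan)
    npairs = np.zeros(n_classes, dtype=int)
    for k, m in enumerate(masks):
        s0 = m.sum()
        npairs[k] = s0 // 2
        if s0 > 0:
            I[k] = len(z) / s0 * (z @ m @ z) / (z @ z)

    crossed = False
    zero = float(dmax)
    valid = np.flatnonzero(~np.isnan(I))
    if len(valid) and I[valid[0]] <= 0:
        # no positive short-range autocorrelation at all
        zero = float(mids[valid[0]])
        crossed = True
    else:
        for a, b in zip(valid[:-1], valid[1:]):
            if I[a] > 0 and I[b] <= 0:
                zero = float(mids[a] + (mids[b] - mids[a]) * I[a] / (I[a] - I[b]))
                crossed = True
                break
    return CorrelogramResult(midpoints_km=mids, moran=I, n_pairs=npairs,
                             zero_crossing_km=zero, crossed=crossed)


@dataclass
class ModifiedTTestResult:
    r: float
    m_hat: float      # effective sample size
    df: float         # m_hat - 2
    t: float
    p: float
    n: int
    flag: str = ""


def modified_ttest(x: np.ndarray, y: np.ndarray, centroids: np.ndarray,
                   n_classes: int = 13, force_identity: bool = False) -> ModifiedTTestResult:
    """Correlation test with Dutilleul's spatially corrected sample size.

    Spatial correlation matrices for x and y are estimated from per-class
    Moran coefficients on equal-width distance classes spanning all pairwise
    distances; with the centering operator B the effective sample size is
    M = 1 + n^2 / trace(B Rx B Ry), clipped to (2, n]. The statistic
    t = r sqrt((M-2)/(1-r^2)) is referred to Student's t with M-2 df.
    With ``force_identity`` both correlation matrices are the identity and
    the test reduces to the classical t-test.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n < 10:
        raise ValueError("modified t-test needs n >= 10")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant variable")
    r = float(np.corrcoef(x, y)[0, 1])

    if force_identity:
        Rx = Ry = np.eye(n)
    else:
        pts = np.asarray(centroids, float)
        D = cdist(pts, pts)
        masks, _ = _class_masks(D, n_classes, D.max())
        zx = x - x.mean()
        zy = y - y.mean()
        Rx = np.eye(n)
        Ry = np.eye(n)
        for m in masks:
            s0 = m.sum()
            if s0 == 0:
                continue
            rho_x = n / s0 * (zx @ m @ zx) / (zx @ zx)
            rho_y = n / s0 * (zy @ m @ zy) / (zy @ zy)
            Rx += rho_x * m
            Ry += rho_y * m

    ones = np.ones(n)
    Bx = Rx - np.outer(ones, ones @ Rx) / n
    Bx -= np.outer(Bx @ ones, ones) / n
    By = Ry - np.outer(ones, ones @ Ry) / n
    By -= np.outer(By @ ones, ones) / n
    tr = float(np.einsum("ij,ji->", Bx, By))

    flag = ""
    if tr <= 0:
        m_hat = float(n)
        flag = "non-positive trace; effective size set to n"
    else:
        m_hat = 1.0 + n**2 / tr
    if m_hat > n:
        m_hat = float(n)
    if m_hat <= 2:
        return ModifiedTTestResult(r=r, m_hat=m_hat, df=m_hat - 2, t=np.nan,
                                   p=1.0, n=n, flag="effective sample size <= 2")
    df = m_hat - 2
    if abs(r) >= 1.0 - 1e-15:
        return ModifiedTTestResult(r=r, m_hat=m_hat, df=df, t=np.inf, p=0.0,
                                   n=n, flag="perfect correlation")
    t = r * np.sqrt(df / (1 - r**2))
    p = 2 * stats.t.sf(abs(t), df)
    return ModifiedTTestResult(r=r, m_hat=float(m_hat), df=float(df),
                               t=float(t), p=float(p), n=n, flag=flag)


@dataclass
class SARFit:
    """ML fit of the spatial error model y = X beta + u, u = lambda W u + eps."""

    lam: float
    coefficients: np.ndarray
    std_errors: np.ndarray
    names: list
    sigma2: float
    loglik: float
    aic: float
    moran_ols_residuals: MoranResult
    moran_sar_innovations: MoranResult
    boundary: bool = False


def sar_error_fit(X: np.ndarray, y: np.ndarray, weights: SpatialWeights,
                  names: list | None = None, add_intercept: bool = True) -> SARFit:
    """Maximum-likelihood SAR error model via the profiled lambda likelihood.

    For each candidate lambda the data are whitened by (I - lambda W), beta
    and sigma^2 follow by GLS, and the concentrated log-likelihood adds the
    Jacobian term sum log(1 - lambda * eig_i(W)). lambda is optimized by
    bounded Brent search inside the eigenvalue-determined interval to 1e-8.
    """
    if weights.style != "row-standardized":
        raise ValueError("SAR expects row-standardized weights")
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    D = np.column_stack([np.ones(len(y)), X]) if add_intercept else X
    if names is None:
        names = ["intercept"] + [f"x{j}" for j in range(X.shape[1])]
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise np.linalg.LinAlgError("design matrix rank deficient")
    n = len(y)
    W = weights.dense()
    eigs = np.linalg.eigvals(W)
    if np.abs(eigs.imag).max() > 1e-8:
        raise np.linalg.LinAlgError("weights matrix has complex eigenvalues")
    eigs = eigs.real
    lo = 1.0 / eigs.min() if eigs.min() < 0 else -0.999
    hi = 1.0 / eigs.max() if eigs.max() > 0 else 0.999

    def neg_profile(lam: float) -> float:
        A = np.eye(n) - lam * W
        ys = A @ y
        Xs = A @ D
        beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        e = ys - Xs @ beta
        sigma2 = (e @ e) / n
        logdet = np.sum(np.log(1.0 - lam * eigs))
        return -(-0.5 * n * (np.log(2 * np.pi * sigma2) + 1) + logdet)

    eps = 1e-6 * (hi - lo)
    res = optimize.minimize_scalar(neg_profile, bounds=(lo + eps, hi - eps),
                                   method="bounded",
                                   options={"xatol": 1e-8})
    if not res.success:
        raise RuntimeError(f"SAR profile optimization failed: {res.message}")
    lam = float(res.x)
    boundary = (lam - lo) < 1e-4 * (hi - lo) or (hi - lam) < 1e-4 * (hi - lo)
    if boundary:
        warnings.warn(f"SAR lambda at interval boundary: {lam:.4f}")

    A = np.eye(n) - lam * W
    ys, Xs = A @ y, A @ D
    XtX = Xs.T @ Xs
    beta = np.linalg.solve(XtX, Xs.T @ ys)
    e = ys - Xs @ beta
    sigma2 = float(e @ e) / n
    loglik = float(-0.5 * n * (np.log(2 * np.pi * sigma2) + 1)
                   + np.sum(np.log(1.0 - lam * eigs)))
    cov = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    npar = D.shape[1] + 2  # beta, lambda, sigma2

    beta_ols, *_ = np.linalg.lstsq(D, y, rcond=None)
    u_ols = y - D @ beta_ols
    u_sar = y - D @ beta
    moran_ols = morans_i(u_ols, weights)
    moran_innov = morans_i(A @ u_sar, weights)
    return SARFit(
        lam=lam,
        coefficients=beta,
        std_errors=se,
        names=list(names),
        sigma2=sigma2,
        loglik=loglik,
        aic=-2 * loglik + 2 * npar,
        moran_ols_residuals=moran_ols,
        moran_sar_innovations=moran_innov,
        boundary=boundary,
    )


def vif(X: np.ndarray, names: list | None = None) -> dict:
    """Variance inflation factor per column: 1 / (1 - R^2_j).

    R^2_j comes from the least-squares regression (with intercept) of
    column j on the remaining columns; perfect collinearity yields inf.
    """
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("VIF needs at least two columns")
    n, p = X.shape
    if n <= p:
        raise ValueError("need more rows than columns")
    names = names or [f"x{j}" for j in range(p)]
    out = {}
    for j in range(p):
        yj = X[:, j]
        Z = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(Z, yj, rcond=None)
        resid = yj - Z @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        if ss_tot == 0:
            out[names[j]] = np.inf
            continue
        r2 = 1 - ss_res / ss_tot
        out[names[j]] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return out
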
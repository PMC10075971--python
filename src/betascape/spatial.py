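"""Spatial attribution of beta-diversity metrics to environmental covariates.

Covariates are neighbourhood-averaged, transformed and standardized; responses
are regressed by OLS and by a simultaneous autoregressive (SAR) error model

    y = X beta + u,   u = rho W u + eps,   eps ~ N(0, sigma^2 I)

with a row-standardized distance-band weight matrix W. The SAR likelihood is
maximized by concentrating beta and sigma^2 out and searching rho, with the
log-determinant term from the eigenvalues of W (computed once per W).

Moran's I correlograms of (whitened) residuals over annular distance classes
give the minRSA criterion (summed |I| over the first 20 classes) used to pick
the neighbour distance; Akaike weights over all covariate subsets give
model-averaged standardized coefficients and variable importances; the
Clifford-Richardson (Dutilleul-style) corrected t-test assesses bivariate
correlations under spatial autocorrelation; piecewise regression summarizes
latitudinal patterns with a single continuous breakpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import pdist, squareform
from scipy.stats import t as t_dist

from .grids import ENV_COLUMNS, neighborhood, validate_cells, validate_env


class SpatialError(ValueError):
    pass


# ---------------------------------------------------------------- covariates


def prepare_covariates(
    env: pd.DataFrame,
    cells: pd.DataFrame,
    focal_ids: list[str] | None = None,
    radius: int = 2,
    neighborhood_mean: bool = True,
) -> pd.DataFrame:
    """Neighbourhood-mean, transform and z-standardize the eight covariates.

    Each focal's covariates are averaged over the focal and its available
    window neighbours, then elevational range is log10-transformed and human
    modification square-root-transformed, then every column is z-scored over
    the focal cells. Rows are indexed by cell_id in ``focal_ids`` order.
    """
    env = validate_env(env).set_index("cell_id")
    cells = validate_cells(cells)
    if focal_ids is None:
        focal_ids = cells["cell_id"].tolist()
    focal_ids = [str(c) for c in focal_ids]

    rows = []
    for focal in focal_ids:
        window = [focal] + (
            neighborhood(cells, focal, radius) if neighborhood_mean else []
        )
        missing = [c for c in window if c not in env.index]
        if missing:
            raise SpatialError(f"missing covariates for window cells {missing[:5]}")
        rows.append(env.loc[window, list(ENV_COLUMNS)].mean(axis=0))
    out = pd.DataFrame(rows, index=pd.Index(focal_ids, name="cell_id"))

    if (out["elev_range"] <= 0).any():
        raise SpatialError("non-positive elevational range under log transform")
    out["elev_range"] = np.log10(out["elev_range"])
    out["human_modification"] = np.sqrt(out["human_modification"])

    sd = out.std(ddof=1)
    if (sd <= 0).any() or sd.isna().any():
        bad = sd.index[(sd <= 0) | sd.isna()].tolist()
        raise SpatialError(f"zero-variance covariate(s) after preparation: {bad}")
    return (out - out.mean()) / sd


def standardize(y) -> np.ndarray:
    y = np.asarray(y, float)
    sd = y.std(ddof=1)
    if sd <= 0:
        raise SpatialError("zero-variance response")
    return (y - y.mean()) / sd


# ------------------------------------------------------------ spatial weights


@dataclass
class SpatialWeights:
    """Row-standardized weights from a distance band (0, d] on (x, y) km."""

    matrix: np.ndarray  # row-standardized, zero diagonal
    distance: float
    eigenvalues: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def distance_band_weights(coords: np.ndarray, d: float) -> SpatialWeights:
    coords = np.asarray(coords, float)
    D = squareform(pdist(coords))
    B = (D > 0) & (D <= d)
    deg = B.sum(axis=1)
    if (deg == 0).any():
        raise SpatialError(f"isolated cells at neighbour distance {d}")
    W = B / deg[:, None]
    # W = D^-1 B is similar to the symmetric D^-1/2 B D^-1/2: real spectrum
    s = 1.0 / np.sqrt(deg)
    eig = sla.eigh(B * np.outer(s, s), eigvals_only=True)
    return SpatialWeights(matrix=W, distance=float(d), eigenvalues=eig)


def weights_from_cells(cells: pd.DataFrame, d: float) -> SpatialWeights:
    cells = validate_cells(cells)
    return distance_band_weights(cells[["x", "y"]].to_numpy(float), d)


# ------------------------------------------------------------------ SAR / OLS


@dataclass
class SpatialModelFit:
    params: pd.Series  # coefficients incl. intercept
    bse: pd.Series
    conf_int: pd.DataFrame  # columns low, high (95%)
    rho: float  # spatial error coefficient (0 for OLS)
    loglik: float
    aic: float
    residuals: np.ndarray  # whitened innovations (I - rho W)(y - X beta)
    n: int
    mode: str
    converged: bool = True
    rho_se: float = float("nan")  # from the profile-likelihood curvature

    @property
    def k_params(self) -> int:
        # coefficients + sigma^2 (+ rho for the SAR error model)
        return len(self.params) + (2 if self.mode == "sar_error" else 1)


def _design(X: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        M = X.to_numpy(float)
    else:
        M = np.asarray(X, float)
        if M.ndim == 1:
            M = M[:, None]
        names = [f"x{j}" for j in range(M.shape[1])]
    return np.column_stack([np.ones(len(M)), M]), ["intercept"] + names


def fit_spatial_regression(
    y,
    X,
    W: SpatialWeights | None = None,
    mode: str = "ols",
    fix_rho: float | None = None,
) -> SpatialModelFit:
    """Fit y = X beta (+ SAR error term) by maximum likelihood.

    ``mode="ols"`` ignores W. ``mode="sar_error"`` profiles beta and sigma^2
    out of the likelihood and searches the error coefficient rho on the
    interval set by W's eigenvalue bounds. Standard errors for beta are the
    GLS ones conditional on the fitted rho; coefficients are standardized
    whenever X and y are.
    """
    y = np.asarray(y, float)
    M, names = _design(X)
    n, p = M.shape
    if n <= p + 2:
        raise SpatialError(f"n={n} too small for {p} parameters")
    if np.linalg.matrix_rank(M) < p:
        raise SpatialError("singular design matrix")

    if mode == "ols":
        beta, *_ = np.linalg.lstsq(M, y, rcond=None)
        resid = y - M @ beta
        sigma2 = resid @ resid / n
        ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1)
        cov = sigma2 * np.linalg.inv(M.T @ M) * n / (n - p)
        se = np.sqrt(np.diag(cov))
        return _pack_fit(beta, se, 0.0, ll, resid, names, n, "ols")

    if mode != "sar_error":
        raise SpatialError(f"unknown mode {mode!r}")
    if W is None:
        raise SpatialError("sar_error mode needs spatial weights")
    if W.n != n:
        raise SpatialError("weights not aligned with data")

    eig = W.eigenvalues
    lo = 1.0 / eig.min() + 1e-6 if eig.min() < 0 else -0.999999
    hi = 1.0 / eig.max() - 1e-6 if eig.max() > 0 else 0.999999
    Wm = W.matrix

    def concentrated_negll(rho: float) -> float:
        ys = y - rho * (Wm @ y)
        Xs = M - rho * (Wm @ M)
        beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        e = ys - Xs @ beta
        sigma2 = e @ e / n
        if sigma2 <= 0:
            return np.inf
        logdet = np.log1p(-rho * eig).sum()
        return 0.5 * n * (np.log(2 * np.pi * sigma2) + 1) - logdet

    if fix_rho is not None:
        rho, converged = float(fix_rho), True
        ll = -concentrated_negll(rho)
    else:
        res = minimize_scalar(
            concentrated_negll, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8},
        )
        rho = float(res.x)
        converged = bool(res.success) and lo + 1e-5 < rho < hi - 1e-5
        ll = -float(res.fun)

    ys = y - rho * (Wm @ y)
    Xs = M - rho * (Wm @ M)
    beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    resid = ys - Xs @ beta
    sigma2 = resid @ resid / n
    cov = sigma2 * np.linalg.inv(Xs.T @ Xs) * n / (n - p)
    se = np.sqrt(np.diag(cov))
    fit = _pack_fit(beta, se, rho, ll, resid, names, n, "sar_error", converged)
    # rho SE from the curvature of the profile log-likelihood
    h = min(1e-4, (hi - lo) / 100)
    if lo + h < rho < hi - h:
        d2 = (
            concentrated_negll(rho + h)
            - 2 * concentrated_negll(rho)
            + concentrated_negll(rho - h)
        ) / h**2
        if d2 > 0:
            fit.rho_se = float(1.0 / np.sqrt(d2))
    return fit


def _pack_fit(beta, se, rho, ll, resid, names, n, mode, converged=True) -> SpatialModelFit:
    params = pd.Series(beta, index=names)
    bse = pd.Series(se, index=names)
    z = 1.959963984540054
    ci = pd.DataFrame({"low": params - z * bse, "high": params + z * bse})
    fit = SpatialModelFit(
        params=params, bse=bse, conf_int=ci, rho=rho, loglik=ll,
        aic=np.nan, residuals=resid, n=n, mode=mode, converged=converged,
    )
    fit.aic = 2 * fit.k_params - 2 * ll
    return fit


# ------------------------------------------------------------------- Moran's I


@dataclass
class MoranProfile:
    moran_i: np.ndarray  # one value per distance class (0.0 where undefined)
    valid: np.ndarray  # bool per class: enough pairs to compute I
    class_width: float

    @property
    def min_rsa(self) -> float:
        """Summed |I| over the distance classes (minRSA criterion)."""
        return float(np.abs(self.moran_i[self.valid]).sum())


def moran_profile(
    residuals,
    cells: pd.DataFrame,
    n_classes: int = 20,
    class_width: float = 200.0,
) -> MoranProfile:
    """Moran's I of ``residuals`` per annular distance class (0, w], (w, 2w]...

    Expectation under spatial randomness is -1/(n-1) in each class. Classes
    with no pairs contribute 0 to minRSA and are flagged invalid.
    """
    z = np.asarray(residuals, float)
    z = z - z.mean()
    denom = z @ z
    if denom <= 0:
        raise SpatialError("constant residual vector: Moran's I undefined")
    cells = validate_cells(cells)
    if len(cells) != len(z):
        raise SpatialError("residuals not aligned with cells")
    n = len(z)
    D = squareform(pdist(cells[["x", "y"]].to_numpy(float)))
    cross = np.outer(z, z)
    moran = np.zeros(n_classes)
    valid = np.zeros(n_classes, dtype=bool)
    for c in range(n_classes):
        band = (D > c * class_width) & (D <= (c + 1) * class_width)
        npairs = band.sum()
        if npairs == 0:
            continue
        moran[c] = (n / npairs) * cross[band].sum() / denom
        valid[c] = True
    return MoranProfile(moran, valid, class_width)


# -------------------------------------------------------- distance selection


@dataclass
class DistanceSelection:
    best_distance: float
    table: pd.DataFrame  # per candidate: distance, min_rsa, aic, rho
    fits: dict
    profiles: dict


def select_neighbor_distance(
    y,
    X,
    cells: pd.DataFrame,
    distances=tuple(range(200, 1001, 100)),
    n_classes: int = 20,
    class_width: float = 200.0,
) -> DistanceSelection:
    """Fit a SAR error model per candidate neighbour distance and pick the one
    minimizing residual spatial autocorrelation (minRSA); ties break by lower
    AIC, then smaller distance."""
    cells = validate_cells(cells)
    rows, fits, profiles = [], {}, {}
    for d in distances:
        try:
            W = weights_from_cells(cells, float(d))
        except SpatialError as exc:
            warnings.warn(f"distance {d}: {exc}; dropped", stacklevel=2)
            continue
        fit = fit_spatial_regression(y, X, W, mode="sar_error")
        prof = moran_profile(fit.residuals, cells, n_classes, class_width)
        fits[float(d)] = fit
        profiles[float(d)] = prof
        rows.append(
            {"distance": float(d), "min_rsa": prof.min_rsa, "aic": fit.aic,
             "rho": fit.rho}
        )
    if not rows:
        raise SpatialError("no candidate neighbour distance was usable")
    table = pd.DataFrame(rows)
    order = table.sort_values(["min_rsa", "aic", "distance"]).iloc[0]
    return DistanceSelection(float(order["distance"]), table, fits, profiles)


# ------------------------------------------------------- multimodel inference


@dataclass
class ModelAverage:
    coefficients: pd.DataFrame  # per covariate: coef, ci_low, ci_high, importance
    models: pd.DataFrame  # per model: terms, loglik, aic, weight


def multimodel_average(y, X: pd.DataFrame, W: SpatialWeights) -> ModelAverage:
    """All-subsets SAR error models combined by Akaike weights.

    Every subset of covariates (intercept always included) is fitted; model
    weights are exp(-dAIC/2) normalized. A covariate's averaged coefficient is
    conditional on inclusion (weights renormalized over containing models),
    its CI uses the Burnham-Anderson unconditional variance over those models,
    and its importance is the summed weight of containing models.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, float))
        X.columns = [f"x{j}" for j in X.columns]
    covars = list(X.columns)
    if len(covars) > 12:
        raise SpatialError("more than 12 covariates: refusing 2^k enumeration")

    fits, terms = [], []
    for k in range(len(covars) + 1):
        for subset in combinations(covars, k):
            try:
                fit = fit_spatial_regression(
                    y, X[list(subset)] if subset else np.empty((len(X), 0)),
                    W, mode="sar_error",
                )
            except (SpatialError, np.linalg.LinAlgError) as exc:
                warnings.warn(f"model {subset}: {exc}; excluded", stacklevel=2)
                continue
            fits.append(fit)
            terms.append(subset)

    aics = np.array([f.aic for f in fits])
    rel = np.exp(-(aics - aics.min()) / 2)
    weights = rel / rel.sum()

    rows = []
    for cov in covars:
        idx = [i for i, t in enumerate(terms) if cov in t]
        w = weights[idx]
        importance = float(w.sum())
        wc = w / w.sum()
        betas = np.array([fits[i].params[cov] for i in idx])
        ses = np.array([fits[i].bse[cov] for i in idx])
        avg = float(wc @ betas)
        var_u = float(wc @ (ses**2 + (betas - avg) ** 2))
        half = 1.959963984540054 * np.sqrt(var_u)
        rows.append(
            {"covariate": cov, "coef": avg, "ci_low": avg - half,
             "ci_high": avg + half, "importance": importance}
        )
    models = pd.DataFrame(
        {
            "terms": ["+".join(t) if t else "(intercept)" for t in terms],
            "loglik": [f.loglik for f in fits],
            "aic": aics,
            "weight": weights,
        }
    )
    return ModelAverage(pd.DataFrame(rows).set_index("covariate"), models)


# ------------------------------------------------- spatially corrected t-test


@dataclass
class CorrelationTest:
    r: float
    eff_df: float  # effective degrees of freedom (n_eff - 2)
    p_value: float
    n_eff: float


def modified_t_test(
    a, b, cells: pd.DataFrame, n_classes: int = 13
) -> CorrelationTest:
    """Pearson correlation with a Clifford-Richardson effective sample size.

    The variance of r under spatial autocorrelation is estimated from the
    product of the two variables' distance-class correlograms; the t-test then
    uses n_eff - 2 degrees of freedom. With independent (iid) fields n_eff is
    close to n and the test reduces to the ordinary one.
    """
    x = np.asarray(a, float)
    y = np.asarray(b, float)
    n = len(x)
    if n < 10:
        raise SpatialError("need >= 10 cells for the corrected t-test")
    if x.std() == 0 or y.std() == 0:
        raise SpatialError("constant variable in correlation test")
    cells = validate_cells(cells)
    D = squareform(pdist(cells[["x", "y"]].to_numpy(float)))

    zx = (x - x.mean()) / x.std()
    zy = (y - y.mean()) / y.std()
    r = float(zx @ zy / n)

    dmax = D.max()
    edges = np.linspace(0, dmax, n_classes + 1)
    # correlogram per class from ordered pairs
    iu = np.triu_indices(n, k=1)
    d_pairs = D[iu]
    cls = np.clip(np.searchsorted(edges, d_pairs, side="left") - 1, 0, n_classes - 1)
    px = (zx[iu[0]] * zx[iu[1]])
    py = (zy[iu[0]] * zy[iu[1]])
    counts = np.bincount(cls, minlength=n_classes).astype(float)
    with np.errstate(invalid="ignore"):
        rx = np.where(counts > 0, np.bincount(cls, px, n_classes) / counts, 0.0)
        ry = np.where(counts > 0, np.bincount(cls, py, n_classes) / counts, 0.0)

    # sum over ordered pairs = 2 * sum over unordered pairs
    s = n + 2.0 * float((counts * rx * ry).sum())
    n_eff = 1.0 + n**2 / s if s > 0 else float(n)
    n_eff = float(np.clip(n_eff, 3.0, n))
    if abs(r) >= 1.0:
        return CorrelationTest(r, n_eff - 2, 0.0, n_eff)
    t_stat = r * np.sqrt((n_eff - 2) / (1 - r**2))
    p = 2 * t_dist.sf(abs(t_stat), df=n_eff - 2)
    return CorrelationTest(r, n_eff - 2, float(p), n_eff)


# ----------------------------------------------------- piecewise latitudinal


@dataclass
class PiecewiseFit:
    breakpoint: float
    slope_below: float
    slope_above: float
    intercept: float
    sse: float
    sse_linear: float


def piecewise_latitudinal_fit(y, latitude) -> PiecewiseFit:
    """Continuous two-segment least squares with a grid-searched breakpoint.

    Candidates are the interior latitude percentiles (5th-95th, step 1); the
    hinge model y = b0 + b1 lat + b2 (lat - c)+ always nests the straight
    line, so its SSE never exceeds the linear fit's.
    """
    y = np.asarray(y, float)
    lat = np.asarray(latitude, float)
    if len(y) < 20:
        raise SpatialError("need >= 20 points for a piecewise fit")
    if np.ptp(lat) <= 0:
        raise SpatialError("degenerate latitude range")

    M0 = np.column_stack([np.ones_like(lat), lat])
    b0, *_ = np.linalg.lstsq(M0, y, rcond=None)
    sse_lin = float(((y - M0 @ b0) ** 2).sum())

    best = (np.inf, None, None)
    for q in range(5, 96):
        c = np.percentile(lat, q)
        hinge = np.maximum(lat - c, 0.0)
        if hinge.std() == 0:
            continue
        M = np.column_stack([np.ones_like(lat), lat, hinge])
        beta, *_ = np.linalg.lstsq(M, y, rcond=None)
        sse = float(((y - M @ beta) ** 2).sum())
        if sse < best[0] - 1e-12:
            best = (sse, c, beta)
    if best[1] is None:
        best = (sse_lin, float(np.median(lat)), np.array([b0[0], b0[1], 0.0]))
    sse, c, beta = best
    return PiecewiseFit(
        breakpoint=float(c),
        slope_below=float(beta[1]),
        slope_above=float(beta[1] + beta[2]),
        intercept=float(beta[0]),
        sse=min(sse, sse_lin),
        sse_linear=sse_lin,
    )
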
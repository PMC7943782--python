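"""Latitudinal/longitudinal belt analysis of haplotype richness.

Belts are overlapping windows on one coordinate axis: centers every 0.5°,
each belt gathering the specimens within ±1° of its center. Within a belt,
every species with at least six specimens is scored for haplotype richness
in two sample-size-standardized ways:

(i) the rarefaction–extrapolation curve evaluated at the species' maximum
    belt sample size across all belts (theoretical richness), and
(ii) the analytic expected rarefied richness at the species' minimum
    qualifying (>5) belt sample size — the expectation of drawing one
    random subset of that size, made deterministic.

Per-belt means across species, together with mean conspecific great-circle
distances, feed an additive trend model (penalty-free regression spline on
the belt center, k = 10 basis, plus the distance as a parametric term) and
a loess smoother (tricube-weighted local quadratic, span 0.4) for
visualization of the trend and its peak.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.interpolate import BSpline
from scipy.linalg import solve_triangular

from .diversity import collapse_haplotypes, rarefied_richness, richness_at
from .io import ReferenceLibrary

EARTH_RADIUS_KM = 6371.0

#: Minimum specimens of a species within a belt for inclusion.
MIN_N_BELT = 6


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km (haversine, spherical Earth R=6371 km)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def mean_pairwise_km(lats, lons) -> float:
    """Mean over all pairs of great-circle distances; NaN below two points."""
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    n = len(lats)
    if n < 2:
        return float("nan")
    phi = np.radians(lats)
    lmb = np.radians(lons)
    i, j = np.triu_indices(n, k=1)
    a = (
        np.sin((phi[j] - phi[i]) / 2) ** 2
        + np.cos(phi[i]) * np.cos(phi[j]) * np.sin((lmb[j] - lmb[i]) / 2) ** 2
    )
    return float(np.mean(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))))


@dataclass
class Belt:
    axis: str  # "latitude" | "longitude"
    center: float
    half_width: float = 1.0
    member_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


def make_belts(
    lib: ReferenceLibrary,
    axis: str = "latitude",
    lo: float = 35.0,
    hi: float = 70.0,
    spacing: float = 0.5,
    half_width: float = 1.0,
) -> list[Belt]:
    """Overlapping belt grid with closed membership |coordinate - center| <= half_width."""
    if not lo < hi:
        raise ValueError("lo must be < hi")
    coords = np.array(
        [getattr(r, axis) for r in lib], dtype=float
    )
    centers = np.arange(lo, hi + spacing / 2, spacing)
    belts = []
    for c in centers:
        members = np.flatnonzero(np.abs(coords - c) <= half_width)
        belts.append(Belt(axis, float(c), half_width, members))
    return belts


def belt_species_table(
    lib: ReferenceLibrary,
    axis: str = "latitude",
    lo: float = 35.0,
    hi: float = 70.0,
    spacing: float = 0.5,
    half_width: float = 1.0,
    min_n: int = MIN_N_BELT,
) -> pd.DataFrame:
    """Standardized per-belt, per-species richness and conspecific distances.

    One row per qualifying (belt, species) pair with both standardizations
    and the mean pairwise great-circle distance among the species' specimens
    in the belt. Belts with no qualifying species do not appear.
    """
    records = list(lib)
    belts = make_belts(lib, axis, lo, hi, spacing, half_width)
    # per-(belt, species) record sets
    cell: dict[tuple[float, str], list] = {}
    for b in belts:
        for i in b.member_idx:
            r = records[i]
            if r.species_identified and r.has_coordinates:
                cell.setdefault((b.center, r.species), []).append(r)
    # per-species qualifying belt sample sizes -> standardization targets
    sizes: dict[str, list[int]] = {}
    for (c, sp), recs in cell.items():
        if len(recs) >= min_n:
            sizes.setdefault(sp, []).append(len(recs))
    rows = []
    for (c, sp), recs in sorted(cell.items()):
        n = len(recs)
        if n < min_n:
            continue
        m_max = max(sizes[sp])
        m_min = min(sizes[sp])
        table = collapse_haplotypes(recs, species=sp)
        rows.append(
            {
                "axis": axis,
                "center": c,
                "species": sp,
                "n": n,
                "richness_extrapolated": richness_at(table, m_max),
                "richness_subsampled": rarefied_richness(table, m_min),
                "mean_km": mean_pairwise_km(
                    [r.latitude for r in recs], [r.longitude for r in recs]
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "axis", "center", "species", "n",
            "richness_extrapolated", "richness_subsampled", "mean_km",
        ],
    )


def belt_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-belt means across the qualifying species."""
    g = records.groupby("center")
    out = g.agg(
        n_species=("species", "nunique"),
        richness_extrapolated=("richness_extrapolated", "mean"),
        richness_subsampled=("richness_subsampled", "mean"),
        mean_km=("mean_km", "mean"),
    ).reset_index()
    return out


def bspline_basis(x: np.ndarray, df: int = 9, degree: int = 3,
                  knots: np.ndarray | None = None):
    """Regression-spline basis (df columns, intercept omitted).

    Interior knots at quantiles of x; the constant-sum first basis column
    is dropped so the basis is full rank next to a separate intercept.
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        n_interior = df - degree
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(x, qs)
        lo, hi = x.min(), x.max()
        knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    xc = np.clip(x, knots[0], knots[-1])
    dm = BSpline.design_matrix(xc, knots, degree, extrapolate=False).toarray()
    return dm[:, 1:], knots


@dataclass
class TrendFit:
    mode: str
    n_obs: int
    n_belts: int
    smooth_stat: float
    smooth_df: int
    smooth_p: float
    distance_coef: float
    distance_se: float
    distance_p: float
    aic: float
    extra: dict


def _wald(coefs: np.ndarray, cov: np.ndarray) -> tuple[float, int, float]:
    stat = float(coefs @ np.linalg.solve(cov, coefs))
    df = len(coefs)
    return stat, df, float(sps.chi2.sf(stat, df))


def fit_trend(
    records: pd.DataFrame,
    response: str = "richness_extrapolated",
    mode: str = "mixed",
    k: int = 10,
) -> TrendFit:
    """Additive trend of belt richness on the axis coordinate.

    response = spline(center; basis dimension k) + linear(mean distance).

    ``mode='mixed'`` (default) fits per species-belt records with a species
    random intercept (statsmodels MixedLM). ``mode='belt-means'`` averages
    per belt and fits GLS with an exponential (continuous-AR1) residual
    correlation on belt centers, range profiled by maximum likelihood.
    The smooth term's significance is a joint Wald test on its coefficients.
    """
    centers = records["center"].to_numpy(dtype=float)
    if len(np.unique(centers)) < 12:
        raise ValueError("fit_trend requires at least 12 belts with data")

    if mode == "mixed":
        import statsmodels.api as sm

        y = records[response].to_numpy(dtype=float)
        basis, _ = bspline_basis(centers, df=k - 1)
        dist = records["mean_km"].to_numpy(dtype=float)
        X = np.column_stack([np.ones_like(y), basis, dist])
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise ValueError(f"rank-deficient design: rank {rank} < {X.shape[1]} columns")
        groups = records["species"].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM(y, X, groups=groups).fit(reml=False, method="lbfgs")
        smooth_cols = list(range(1, 1 + basis.shape[1]))
        fe = np.asarray(res.fe_params)
        cov = np.asarray(res.cov_params())[: X.shape[1], : X.shape[1]]
        stat, dfree, p = _wald(fe[smooth_cols], cov[np.ix_(smooth_cols, smooth_cols)])
        dist_i = X.shape[1] - 1
        dist_se = math.sqrt(cov[dist_i, dist_i])
        return TrendFit(
            mode="mixed",
            n_obs=len(y),
            n_belts=len(np.unique(centers)),
            smooth_stat=stat,
            smooth_df=dfree,
            smooth_p=p,
            distance_coef=float(fe[dist_i]),
            distance_se=dist_se,
            distance_p=float(2 * sps.norm.sf(abs(fe[dist_i] / dist_se))),
            aic=float(res.aic),
            extra={"group_var": float(np.asarray(res.cov_re)[0, 0])},
        )

    if mode == "belt-means":
        means = belt_summary(records)
        c = means["center"].to_numpy(dtype=float)
        y = means[response].to_numpy(dtype=float)
        basis, _ = bspline_basis(c, df=k - 1)
        X = np.column_stack([np.ones_like(y), basis, means["mean_km"].to_numpy(float)])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("rank-deficient design in belt-means mode")
        best = None
        dmat = np.abs(c[:, None] - c[None, :])
        for rho in (0.5, 1.0, 2.0, 4.0, 8.0, 16.0):
            C = np.exp(-dmat / rho)
            ll, beta, cov = _gls_ml(y, X, C)
            if best is None or ll > best[0]:
                best = (ll, beta, cov, rho)
        ll, beta, cov, rho = best
        smooth_cols = list(range(1, 1 + basis.shape[1]))
        stat, dfree, p = _wald(beta[smooth_cols], cov[np.ix_(smooth_cols, smooth_cols)])
        dist_i = X.shape[1] - 1
        dist_se = math.sqrt(cov[dist_i, dist_i])
        kpar = X.shape[1] + 2  # + sigma2, rho
        return TrendFit(
            mode="belt-means",
            n_obs=len(y),
            n_belts=len(y),
            smooth_stat=stat,
            smooth_df=dfree,
            smooth_p=p,
            distance_coef=float(beta[dist_i]),
            distance_se=dist_se,
            distance_p=float(2 * sps.norm.sf(abs(beta[dist_i] / dist_se))),
            aic=float(-2 * ll + 2 * kpar),
            extra={"rho": rho},
        )

    raise ValueError(f"unknown mode {mode!r}")


def _gls_ml(y, X, C):
    """Gaussian GLS with known correlation C; returns (ML logL, beta, cov_beta)."""
    n = len(y)
    L = np.linalg.cholesky(C)
    Xw = solve_triangular(L, X, lower=True)
    yw = solve_triangular(L, y, lower=True)
    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    logdet = 2.0 * float(np.log(np.diag(L)).sum())
    ll = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)
    cov = rss / (n - X.shape[1]) * np.linalg.inv(Xw.T @ Xw)
    return ll, beta, cov


@dataclass
class LoessCurve:
    grid: np.ndarray
    yhat: np.ndarray
    se: np.ndarray

    @property
    def band(self) -> tuple[np.ndarray, np.ndarray]:
        return self.yhat - 1.96 * self.se, self.yhat + 1.96 * self.se

    def argmax(self) -> float:
        return float(self.grid[int(np.argmax(self.yhat))])


def loess_curve(
    x, y, span: float = 0.4, grid: np.ndarray | None = None, degree: int = 2
) -> LoessCurve:
    """Tricube-weighted local polynomial smoother with a pointwise se band.

    At each grid point the ``ceil(span * n)`` nearest observations are fit
    by weighted least squares of the given degree (quadratic by default).
    The pointwise standard error uses the sandwich form of the local linear
    smoother with a global residual variance estimate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    n = len(x)
    if n < 10:
        raise ValueError("loess_curve requires at least 10 points")
    kq = int(math.ceil(span * n))
    if kq < degree + 2:
        raise ValueError(f"span {span} leaves local windows of {kq} < {degree + 2} points")
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 200)
    grid = np.asarray(grid, dtype=float)

    def local_fit(x0):
        d = np.abs(x - x0)
        h = np.sort(d)[kq - 1]
        if h == 0:
            h = max(d.max(), 1.0) * 1e-12
        w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
        use = w > 0
        xx = x[use] - x0
        X = np.vander(xx, degree + 1, increasing=True)
        W = w[use]
        XtW = X.T * W
        A = XtW @ X
        Ainv = np.linalg.pinv(A)
        l0 = (Ainv @ XtW)[0]  # smoother weights for the fitted value at x0
        yhat = float(l0 @ y[use])
        var_factor = float(l0 @ l0)
        return yhat, var_factor

    fits = np.array([local_fit(g) for g in grid])
    # residual variance from the fit evaluated at the data points
    data_fits = np.array([local_fit(xi)[0] for xi in x])
    resid = y - data_fits
    dof = max(n - (degree + 1), 1)
    sigma2 = float(resid @ resid) / dof
    return LoessCurve(grid, fits[:, 0], np.sqrt(sigma2 * fits[:, 1]))


def spatial_subsample(
    lib: ReferenceLibrary, seed: int, cell_deg: float = 1.0, cap: int = 10
) -> ReferenceLibrary:
    """Random homogeneous thinning: at most ``cap`` specimens per grid cell.

    The grid is a ``cell_deg`` lattice over latitude/longitude; within each
    cell the retained specimens are a seeded random choice. Records without
    coordinates are always kept. Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    cells: dict[tuple[int, int], list[int]] = {}
    keep: list[int] = []
    for i, r in enumerate(lib):
        if not r.has_coordinates:
            keep.append(i)
            continue
        key = (int(math.floor(r.latitude / cell_deg)), int(math.floor(r.longitude / cell_deg)))
        cells.setdefault(key, []).append(i)
    for key in sorted(cells):
        idx = cells[key]
        if len(idx) <= cap:
            keep.extend(idx)
        else:
            keep.extend(rng.choice(idx, size=cap, replace=False))
    keep = sorted(keep)
    records = [lib.records[i] for i in keep]
    return ReferenceLibrary(records, L=lib.L)
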
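"""Phylogenetic generalized least squares with Pagel's lambda.

Relates (log) haplotype richness to (log) range size and (log) specimen
count across species while modelling phylogenetic covariance of residuals.
Under Brownian motion the residual covariance between two species is the
shared root-to-tip path length; Pagel's lambda multiplies the off-diagonal
entries, interpolating between a star phylogeny (lambda = 0, ordinary least
squares) and the full Brownian expectation (lambda = 1). lambda is
estimated by profile maximum likelihood on a grid with golden-section
refinement; nested model fits are compared with the small-sample corrected
Akaike criterion (AICc), a difference above two separating models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import solve_triangular


@dataclass
class PhyloCovariance:
    species: list[str]
    V: np.ndarray  # shared root-to-tip path lengths (Brownian expectation)


def phylo_covariance(tree: dendropy.Tree, species: list[str] | None = None) -> PhyloCovariance:
    """Brownian covariance matrix from a rooted tree with branch lengths.

    V[i, j] is the depth of the most recent common ancestor of tips i and j
    (equivalently (d_i + d_j - patristic_ij) / 2); the diagonal holds the
    root-to-tip depths.
    """
    tree = tree.clone(depth=1)
    tree.calc_node_root_distances()
    tips = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter() if leaf.taxon}
    if species is None:
        species = sorted(tips)
    missing = [s for s in species if s not in tips]
    if missing:
        raise KeyError(f"species absent from tree: {missing}")
    pdm = tree.phylogenetic_distance_matrix()
    n = len(species)
    depths = np.array([tips[s].root_distance for s in species])
    V = np.zeros((n, n))
    for i in range(n):
        V[i, i] = depths[i]
        for j in range(i + 1, n):
            d = pdm.patristic_distance(tips[species[i]].taxon, tips[species[j]].taxon)
            V[i, j] = V[j, i] = 0.5 * (depths[i] + depths[j] - d)
    return PhyloCovariance(list(species), V)


def lambda_transform(V: np.ndarray, lam: float) -> np.ndarray:
    """Pagel's lambda: multiply the off-diagonal covariances, keep the diagonal."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    out = lam * V
    np.fill_diagonal(out, np.diag(V))
    return out


@dataclass
class PGLSFit:
    response: str
    predictors: list[str]
    coef: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    lambda_hat: float
    logL: float
    n: int
    r2_whitened: float
    r2_raw: float
    aicc: float

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"Estimate": self.coef, "SE": self.se, "t": self.t, "P": self.p},
            index=self.predictors,
        )


def _gls_profile(y: np.ndarray, X: np.ndarray, Vl: np.ndarray):
    """ML Gaussian GLS for a fixed covariance structure.

    Returns (logL, beta, cov_beta_unit, rss_whitened, tss_whitened) where
    cov_beta_unit is (X' Vl^-1 X)^-1 (to be scaled by the variance estimate).
    """
    n = len(y)
    L = np.linalg.cholesky(Vl)
    Xw = solve_triangular(L, X, lower=True)
    yw = solve_triangular(L, y, lower=True)
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sigma2_ml = rss / n
    logdet = 2.0 * float(np.log(np.diag(L)).sum())
    logL = -0.5 * (n * math.log(2 * math.pi * sigma2_ml) + logdet + n)
    # whitened total sum of squares about the GLS mean
    ones_w = solve_triangular(L, np.ones(n), lower=True)
    mu = float(ones_w @ yw) / float(ones_w @ ones_w)
    tss = float((yw - mu * ones_w) @ (yw - mu * ones_w))
    return logL, beta, np.linalg.inv(XtX), rss, tss


def pgls_fit(
    y,
    X,
    V: np.ndarray,
    lam: float | None = None,
    response: str = "y",
    predictors: list[str] | None = None,
    grid_size: int = 101,
) -> PGLSFit:
    """PGLS with Pagel's lambda estimated by profile maximum likelihood.

    ``X`` must contain its own intercept column. Pass ``lam`` to fix lambda
    (``lam=0`` reduces exactly to ordinary least squares). Standard errors
    use the unbiased variance estimate with n - k residual degrees of
    freedom; p-values are two-sided t tests.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, kcoef = X.shape
    if predictors is None:
        predictors = [f"x{i}" for i in range(kcoef)]
    if not (len(y) == n == V.shape[0] == V.shape[1]):
        raise ValueError("y, X and V must be row-aligned")
    if np.linalg.matrix_rank(X) < kcoef:
        raise ValueError("singular design matrix")

    def profile(lam_val: float) -> float:
        return _gls_profile(y, X, lambda_transform(V, lam_val))[0]

    if lam is None:
        grid = np.linspace(0.0, 1.0, grid_size)
        lls = np.array([profile(g) for g in grid])
        i = int(np.argmax(lls))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, grid_size - 1)]
        # golden-section refinement of the profile likelihood
        invphi = (math.sqrt(5) - 1) / 2
        a, b = lo, hi
        c, d = b - invphi * (b - a), a + invphi * (b - a)
        fc, fd = profile(c), profile(d)
        for _ in range(40):
            if fc > fd:
                b, d, fd = d, c, fc
                c = b - invphi * (b - a)
                fc = profile(c)
            else:
                a, c, fc = c, d, fd
                d = a + invphi * (b - a)
                fd = profile(d)
        lam_hat = (a + b) / 2
    else:
        lam_hat = float(lam)

    logL, beta, covu, rss, tss = _gls_profile(y, X, lambda_transform(V, lam_hat))
    dof = n - kcoef
    sigma2 = rss / dof
    se = np.sqrt(sigma2 * np.diag(covu))
    tvals = beta / se
    pvals = 2 * sps.t.sf(np.abs(tvals), dof)
    # raw-scale R^2 for reference alongside the whitened one
    resid_raw = y - X @ beta
    tss_raw = float(((y - y.mean()) ** 2).sum())
    kpar = kcoef + 1 + (1 if lam is None else 0)  # + sigma2 (+ lambda if estimated)
    return PGLSFit(
        response=response,
        predictors=list(predictors),
        coef=beta,
        se=se,
        t=tvals,
        p=pvals,
        lambda_hat=float(lam_hat),
        logL=logL,
        n=n,
        r2_whitened=1.0 - rss / tss,
        r2_raw=1.0 - float(resid_raw @ resid_raw) / tss_raw,
        aicc=aicc(logL, kpar, n),
    )


def aicc(logL: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike criterion: -2logL + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * logL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class ModelComparison:
    table: pd.DataFrame  # name, aicc, delta, distinguishable

    @property
    def best(self) -> str:
        return str(self.table.iloc[0]["model"])


def compare_models(fits: dict[str, PGLSFit]) -> ModelComparison:
    """Delta-AICc table versus the best fit; Delta > 2 separates models."""
    ns = {f.n for f in fits.values()}
    if len(ns) != 1:
        raise ValueError("fits must share n to be AICc-comparable")
    responses = {f.response for f in fits.values()}
    if len(responses) != 1:
        raise ValueError("fits must share the response")
    rows = [{"model": name, "aicc": f.aicc} for name, f in fits.items()]
    df = pd.DataFrame(rows).sort_values("aicc", kind="stable").reset_index(drop=True)
    df["delta_aicc"] = df["aicc"] - df["aicc"].iloc[0]
    df["distinguishable"] = df["delta_aicc"] > 2.0
    return ModelComparison(df)


def simulate_brownian(
    V: np.ndarray, beta: np.ndarray, X: np.ndarray, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw a response under the PGLS model: X beta + MVN(0, sigma^2 V)."""
    L = np.linalg.cholesky(V + 1e-12 * np.eye(len(V)))
    return X @ beta + sigma * (L @ rng.standard_normal(len(V)))
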
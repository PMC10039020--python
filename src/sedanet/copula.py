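"""Gaussian copula graphical model of taxon associations.

Three stages, mirroring the stacked-SDM / copula-graphical-lasso approach
to species association networks:

1. a marginal count regression per family (negative binomial by default,
   Poisson fallback) of abundance on the environmental covariates;
2. Dunn-Smyth randomised quantile residuals, mapping each discrete count
   to a standard-normal score under its fitted marginal — the copula step
   that removes the covariate-driven part of every marginal;
3. an L1-penalised precision (inverse correlation) estimate of the
   residual scores — the graphical lasso — whose nonzero off-diagonals
   are the conditional (direct) associations between taxa, free of
   effects mediated by the covariates or by third taxa.

The graphical lasso solves

    max_Theta  log det Theta - tr(S Theta) - lambda * sum_{i!=j} |Theta_ij|

by ADMM with an eigendecomposition-based Theta update and off-diagonal
soft-thresholding; the split variable carries exact zeros, giving a clean
edge support.  Zero off-diagonal precision = conditional independence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.discrete.discrete_model import NegativeBinomial

from .io import InputError


@dataclass
class MarginalFit:
    """Fitted marginal count model for one family."""

    family: str
    kind: str                 # "nb" or "poisson"
    mu: np.ndarray            # fitted mean per sample
    alpha: float | None       # NB2 dispersion (var = mu + alpha mu^2)
    params: np.ndarray
    converged: bool

    def cdf(self, y) -> np.ndarray:
        """Fitted cumulative distribution at each sample's own mean."""
        y = np.asarray(y, dtype=float)
        if self.kind == "nb":
            n = 1.0 / self.alpha
            p = n / (n + self.mu)
            return stats.nbinom.cdf(y, n, p)
        return stats.poisson.cdf(y, self.mu)


def _design(covariates: pd.DataFrame) -> np.ndarray:
    X = covariates.to_numpy(dtype=float)
    keep = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) > 0]
    X = X[:, keep]
    X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise InputError("rank-deficient covariate matrix")
    return X


def _fit_poisson(fam: str, y: np.ndarray, X: np.ndarray) -> MarginalFit:
    res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    return MarginalFit(fam, "poisson", np.asarray(res.mu), None,
                       np.asarray(res.params), bool(res.converged))


def fit_marginals(counts: pd.DataFrame, covariates: pd.DataFrame,
                  family_model: str = "nb") -> list[MarginalFit]:
    """Fit one count regression per family on the covariate matrix.

    Default is negative binomial (NB2); families whose NB fit does not
    converge, or whose dispersion collapses to ~0, fall back to Poisson
    with a warning.  Constant covariate columns are dropped (leaving an
    intercept-only, mean-matching fit in the fully degenerate case).
    """
    if family_model not in ("nb", "poisson"):
        raise InputError("family_model must be 'nb' or 'poisson'")
    if len(counts) != len(covariates):
        raise InputError("counts and covariates disagree on sample count")
    X = _design(covariates)
    fits = []
    for fam in counts.columns:
        y = counts[fam].to_numpy(dtype=float)
        if not np.allclose(y, np.round(y)) or (y < 0).any():
            raise InputError(f"{fam}: counts must be non-negative integers")
        y = np.round(y)
        if family_model == "poisson" or y.max() == 0:
            fits.append(_fit_poisson(fam, y, X))
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = NegativeBinomial(y, X).fit(disp=0, maxiter=200)
            alpha = float(res.params[-1])
            ok = bool(res.mle_retvals.get("converged", False))
            if not ok or not np.isfinite(alpha) or alpha < 1e-6:
                raise RuntimeError("NB dispersion underflow / no convergence")
            mu = np.asarray(res.predict(X))
            fits.append(MarginalFit(fam, "nb", mu, alpha,
                                    np.asarray(res.params), True))
        except Exception:
            warnings.warn(f"{fam}: negative binomial fit failed, "
                          "falling back to Poisson")
            fits.append(_fit_poisson(fam, y, X))
    return fits


def dunn_smyth_residuals(fits: list[MarginalFit], counts: pd.DataFrame,
                         seed: int = 0, eps: float = 1e-6) -> pd.DataFrame:
    """Randomised quantile residuals: normal scores of the fitted PIT.

    For observed count y, u ~ Uniform(F(y-1), F(y)) under the family's
    fitted marginal and the score is the standard-normal quantile of u,
    clamped away from 0/1 by ``eps``.  Deterministic under ``seed``.
    """
    by_name = {f.family: f for f in fits}
    missing = [c for c in counts.columns if c not in by_name]
    if missing:
        raise InputError(f"no marginal fit for: {missing}")
    rng = np.random.default_rng(seed)
    out = {}
    for fam in counts.columns:
        fit = by_name[fam]
        y = np.round(counts[fam].to_numpy(dtype=float))
        hi = fit.cdf(y)
        lo = fit.cdf(y - 1)  # = 0 for y = 0
        u = lo + rng.random(len(y)) * (hi - lo)
        out[fam] = stats.norm.ppf(np.clip(u, eps, 1 - eps))
    return pd.DataFrame(out, index=counts.index)


# ---------------------------------------------------------------------------
# graphical lasso (ADMM)
# ---------------------------------------------------------------------------

def _glasso_admm(S: np.ndarray, lam: float, rho: float = 1.0,
                 max_iter: int = 2000, tol: float = 1e-6
                 ) -> tuple[np.ndarray, np.ndarray]:
    """ADMM solver for the L1-penalised precision (off-diagonal penalty).

    Returns (Theta, Z): Theta from the smooth update (positive definite by
    construction), Z from soft-thresholding (exact zeros).  Converged when
    the primal residual and Z change are below ``tol`` element-wise.
    """
    p = S.shape[0]
    Z = np.eye(p)
    U = np.zeros_like(S)
    Theta = np.eye(p)
    off = ~np.eye(p, dtype=bool)
    for _ in range(max_iter):
        w, Q = np.linalg.eigh(rho * (Z - U) - S)
        theta_eig = (w + np.sqrt(w * w + 4.0 * rho)) / (2.0 * rho)
        Theta = (Q * theta_eig) @ Q.T
        Z_old = Z
        A = Theta + U
        Z = A.copy()
        Z[off] = np.sign(A[off]) * np.maximum(np.abs(A[off]) - lam / rho, 0.0)
        U = U + Theta - Z
        if (np.abs(Theta - Z).max() < tol
                and np.abs(Z - Z_old).max() < tol):
            break
    else:
        raise RuntimeError(
            f"graphical lasso did not converge in {max_iter} iterations "
            f"(lambda={lam}); residual {np.abs(Theta - Z).max():.2e}")
    return Theta, Z


@dataclass
class CopulaGraph:
    """Sparse precision estimate of the residual scores at one lambda."""

    lam: float
    families: list[str]
    precision: np.ndarray
    partial_corr: np.ndarray
    edges: list[tuple[str, str, float]] = field(default_factory=list)

    def edge_set(self, sign: str = "any") -> set[frozenset]:
        if sign == "positive":
            return {frozenset((a, b)) for a, b, w in self.edges if w > 0}
        if sign == "negative":
            return {frozenset((a, b)) for a, b, w in self.edges if w < 0}
        return {frozenset((a, b)) for a, b, _ in self.edges}

    def to_graph(self, sign: str = "any") -> nx.Graph:
        g = nx.Graph()
        for a, b, w in self.edges:
            if sign == "positive" and w <= 0:
                continue
            if sign == "negative" and w >= 0:
                continue
            g.add_edge(a, b, weight=w)
        return g


def graphical_lasso(scores: pd.DataFrame, lam: float,
                    zero_tol: float = 1e-6) -> CopulaGraph:
    """Penalised precision of the score correlation matrix at one lambda.

    Edges are the off-diagonal entries whose soft-thresholded magnitude
    exceeds ``zero_tol``; edge weight is the partial correlation
    -P_ij / sqrt(P_ii P_jj).
    """
    if lam < 0:
        raise InputError("lambda must be non-negative")
    X = scores.to_numpy(dtype=float)
    if np.ptp(X, axis=0).min() == 0:
        raise InputError("constant score column: correlation undefined")
    S = np.corrcoef(X, rowvar=False)
    Theta, Z = _glasso_admm(S, lam)
    prec = 0.5 * (Theta + Theta.T)
    support = np.abs(0.5 * (Z + Z.T)) > zero_tol
    np.fill_diagonal(support, True)
    prec = np.where(support, prec, 0.0)
    d = np.sqrt(np.diag(prec))
    pcor = -prec / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    fams = list(scores.columns)
    edges = [(fams[i], fams[j], float(pcor[i, j]))
             for i in range(len(fams)) for j in range(i + 1, len(fams))
             if support[i, j]]
    return CopulaGraph(float(lam), fams, prec, pcor, edges)


DEFAULT_GRID = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2))
HEADLINE_LAMBDA = 0.51


def lambda_path(scores: pd.DataFrame, grid=None) -> list[CopulaGraph]:
    """Fit the copula graph along a shrinkage grid (default 0.1-1.0 step
    0.1 plus the headline 0.51), warning if the edge count is not
    non-increasing in lambda (glasso paths are not strictly monotone)."""
    if grid is None:
        grid = sorted(set(DEFAULT_GRID) | {HEADLINE_LAMBDA})
    grid = list(grid)
    if grid != sorted(grid):
        raise InputError("lambda grid must be sorted ascending")
    graphs = [graphical_lasso(scores, lam) for lam in grid]
    counts = [len(g.edges) for g in graphs]
    if any(b > a for a, b in zip(counts, counts[1:])):
        warnings.warn("edge count not monotone along the lambda grid: "
                      f"{dict(zip(grid, counts))}")
    return graphs
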
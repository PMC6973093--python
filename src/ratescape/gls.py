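"""Maximum-likelihood phylogenetic generalized least squares (PGLS).

Under Brownian-motion residual evolution on a rooted tree, the residuals of a
cross-species regression are multivariate normal with covariance proportional
to the matrix of shared root-to-MRCA path lengths. This module provides that
covariance, an ML GLS fit for arbitrary design matrices (continuous terms,
treatment-coded categorical terms, interactions), and likelihood-ratio tests
between nested fits.

The variance estimate is the ML one, sigma2 = RSS_w / n (not REML): the
likelihood-ratio D tests and the marginal-likelihood machinery both require
the full ML log-likelihood.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .traits import TraitTable
from .tree import Phylogeny

__all__ = [
    "phylo_covariance",
    "PhyloGLS",
    "RegressionSpec",
    "GlsFit",
    "gls_fit",
    "likelihood_ratio_test",
    "build_design",
]


def phylo_covariance(tree: Phylogeny, tips=None) -> np.ndarray:
    """Brownian-motion covariance: V[i, j] = shared root-to-MRCA path length.

    ``tips`` optionally selects/orders a subset of tip labels; the default is
    the tree's own tip order. The diagonal holds root-to-tip path lengths.
    """
    labels = list(tips) if tips is not None else tree.tip_labels
    idx = []
    for lab in labels:
        if lab not in tree._tip_index:
            raise KeyError(f"unknown tip label: {lab!r}")
        idx.append(tree._tip_index[lab])
    idx = np.asarray(idx, dtype=np.intp)
    m = tree.tip_membership()
    n = len(labels)
    # the root edge (usually zero, nonzero after root-side pruning) is path
    # shared by every tip
    V = np.full((n, n), float(tree.lengths[0]))
    for node in range(1, tree.n_nodes):
        w = tree.lengths[node]
        if w == 0.0:
            continue
        members = np.nonzero(m[node][idx])[0]
        if members.size:
            V[np.ix_(members, members)] += w
    return V


class PhyloGLS(RegressorMixin, BaseEstimator):
    """scikit-learn style ML phylogenetic GLS regressor.

    Parameters
    ----------
    tree : Phylogeny
        Tree whose shared-path covariance structures the residuals. Rows of
        ``X``/``y`` passed to :meth:`fit` must be ordered like ``tip_order``
        (default: the tree's tip order).
    tip_order : sequence of str, optional
        Tip labels giving the row order of the data.
    covariance : ndarray, optional
        Pre-computed residual covariance (overrides ``tree``); useful for
        rate-scaled or whitened analyses.
    fit_intercept : bool
        Prepend a constant column (default True).

    Attributes (after ``fit``)
    --------------------------
    coef_, intercept_ : ML coefficient estimates.
    se_ : asymptotic standard errors, sigma2 * (X' V^-1 X)^-1 diagonal.
    sigma2_ : ML residual Brownian variance (trait^2 per unit path length).
    loglik_ : maximized log-likelihood.
    r2_ : 1 - RSS/TSS in the GLS-whitened space.
    """

    def __init__(self, tree=None, tip_order=None, covariance=None, fit_intercept=True):
        self.tree = tree
        self.tip_order = tip_order
        self.covariance = covariance
        self.fit_intercept = fit_intercept

    def _V(self, n: int) -> np.ndarray:
        if self.covariance is not None:
            V = np.asarray(self.covariance, float)
        elif self.tree is not None:
            V = phylo_covariance(self.tree, self.tip_order)
        else:
            raise ValueError("either tree or covariance must be supplied")
        if V.shape != (n, n):
            raise ValueError(f"covariance is {V.shape} but data has {n} rows")
        return V

    def fit(self, X, y):
        names = list(X.columns) if isinstance(X, pd.DataFrame) else None
        X = np.asarray(X, float)
        y = np.asarray(y, float).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with rows matching y")
        n = y.shape[0]
        if self.fit_intercept:
            X = np.column_stack([np.ones(n), X])
            names = ["(intercept)"] + (names or [f"x{i}" for i in range(X.shape[1] - 1)])
        elif names is None:
            names = [f"x{i}" for i in range(X.shape[1])]
        p = X.shape[1]
        if n <= p:
            raise ValueError(f"need more observations than design columns (n={n}, p={p})")

        V = self._V(n)
        try:
            L = linalg.cholesky(V, lower=True)
        except linalg.LinAlgError as exc:
            raise ValueError("singular phylogenetic covariance matrix") from exc
        Z = linalg.solve_triangular(L, X, lower=True)
        zy = linalg.solve_triangular(L, y, lower=True)

        rank = np.linalg.matrix_rank(Z)
        if rank < p:
            # name the columns involved in the collinearity via QR pivoting
            _, R, piv = linalg.qr(Z, pivoting=True, mode="economic")
            bad = [names[j] for j in piv[rank:]]
            raise ValueError(f"rank-deficient design matrix; collinear columns: {bad}")

        beta, _, _, _ = np.linalg.lstsq(Z, zy, rcond=None)
        resid = zy - Z @ beta
        rss = float(resid @ resid)
        sigma2 = rss / n
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        loglik = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)

        XtVinvX_inv = np.linalg.inv(Z.T @ Z)
        se = np.sqrt(sigma2 * np.diag(XtVinvX_inv))

        # whitened-space r^2 against the GLS intercept-only (grand mean) fit
        ones_w = linalg.solve_triangular(L, np.ones(n), lower=True)
        mu = float(ones_w @ zy) / float(ones_w @ ones_w)
        tss = float(np.sum((zy - mu * ones_w) ** 2))
        r2 = 1.0 - rss / tss if tss > 0 else np.nan

        self.n_features_in_ = p - int(self.fit_intercept)
        self.feature_names_ = names
        self.coefs_ = beta
        if self.fit_intercept:
            self.intercept_, self.coef_ = float(beta[0]), beta[1:]
        else:
            self.intercept_, self.coef_ = 0.0, beta
        self.se_ = se
        self.sigma2_ = sigma2
        self.vcov_ = sigma2 * XtVinvX_inv
        self.loglik_ = float(loglik)
        self.r2_ = float(r2)
        self.n_ = n
        self._chol_ = L
        return self

    def predict(self, X):
        X = np.asarray(X, float)
        return self.intercept_ + X @ self.coef_


# ---------------------------------------------------------------------------
# formula-level interface


@dataclass
class RegressionSpec:
    """Declarative model specification built against a TraitTable.

    ``categorical`` maps column name -> reference level (treatment coding);
    ``interactions`` pairs term names (continuous x categorical or
    continuous x continuous).
    """

    response: str = "log_testes"
    continuous: tuple[str, ...] = ("log_body",)
    categorical: dict[str, str] = field(default_factory=dict)
    interactions: tuple[tuple[str, str], ...] = ()


def build_design(spec: RegressionSpec, df: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Design matrix (no intercept column) and response vector from a table."""
    cols: dict[str, np.ndarray] = {}
    for name in spec.continuous:
        cols[name] = df[name].to_numpy(float)
    dummies: dict[str, dict[str, np.ndarray]] = {}
    for name, ref in spec.categorical.items():
        levels = [l for l in pd.unique(df[name].dropna()) if l != ref]
        present = set(df[name].dropna())
        if ref not in present:
            raise ValueError(f"reference level {ref!r} absent from column {name!r}")
        dummies[name] = {}
        for lev in sorted(levels):
            col = (df[name] == lev).to_numpy(float)
            cols[f"{name}[{lev}]"] = col
            dummies[name][lev] = col
    for a, b in spec.interactions:
        if a in dummies or b in dummies:
            cat, cont = (a, b) if a in dummies else (b, a)
            base = df[cont].to_numpy(float) if cont not in dummies else None
            if base is None:
                raise ValueError("categorical x categorical interactions not supported")
            for lev, dummy in dummies[cat].items():
                cols[f"{cont}:{cat}[{lev}]"] = base * dummy
        else:
            cols[f"{a}:{b}"] = df[a].to_numpy(float) * df[b].to_numpy(float)
    X = pd.DataFrame(cols)
    y = df[spec.response].to_numpy(float)
    return X, y


@dataclass
class GlsFit:
    """Result of an ML PGLS fit."""

    coef: pd.Series
    se: pd.Series
    sigma2: float
    loglik: float
    n: int
    r2: float
    vcov: np.ndarray
    names: list[str]
    data_signature: str
    model: PhyloGLS

    def coef_table(self) -> pd.DataFrame:
        z = self.coef / self.se
        df = self.n - len(self.names)
        p = 2 * stats.t.sf(np.abs(z), df)
        return pd.DataFrame({"estimate": self.coef, "se": self.se, "t": z, "p": p})


def _signature(tree: Phylogeny, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(tree.to_newick().encode())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:16]


def gls_fit(
    spec: RegressionSpec,
    table: TraitTable,
    tree: Phylogeny,
    covariance: np.ndarray | None = None,
) -> GlsFit:
    """Fit the specified regression by ML PGLS on ``tree``.

    Rows are aligned to the tree's tip order; every tree tip must appear in
    the table.
    """
    df = table.reindex_to(tree.tip_labels)
    X, y = build_design(spec, df)
    model = PhyloGLS(tree=tree, covariance=covariance).fit(X, y)
    return GlsFit(
        coef=pd.Series(model.coefs_, index=model.feature_names_),
        se=pd.Series(model.se_, index=model.feature_names_),
        sigma2=model.sigma2_,
        loglik=model.loglik_,
        n=model.n_,
        r2=model.r2_,
        vcov=model.vcov_,
        names=model.feature_names_,
        data_signature=_signature(tree, y),
        model=model,
    )


@dataclass
class LRTResult:
    D: float
    df: int
    p: float


def likelihood_ratio_test(fit_full: GlsFit, fit_nested: GlsFit) -> LRTResult:
    """Likelihood-ratio (D) test of nested ML PGLS fits: D = 2(ll1 - ll0)."""
    if fit_full.n != fit_nested.n or fit_full.data_signature != fit_nested.data_signature:
        raise ValueError("fits are not on the same data and tree; LRT is undefined")
    extra = set(fit_nested.names) - set(fit_full.names)
    if extra:
        raise ValueError(f"models are not nested; nested fit has extra columns {sorted(extra)}")
    df = len(fit_full.names) - len(fit_nested.names)
    D = 2.0 * (fit_full.loglik - fit_nested.loglik)
    if D < -1e-8:
        raise ValueError(f"full model has lower likelihood than nested (D={D}); not nested?")
    D = max(D, 0.0)
    # identical models: D = 0 on 0 df, p = 1 by convention
    p = 1.0 if df == 0 else float(stats.chi2.sf(D, df))
    return LRTResult(D=D, df=df, p=p)
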
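"""PCA on the correlation matrix with varimax rotation and sampling-adequacy
diagnostics (KMO, Bartlett's sphericity test).

Loadings are eigenvectors scaled by the square root of their eigenvalue, so
squared loadings partition each variable's unit variance; varimax rotates the
retained loadings orthogonally (with Kaiser row normalization) to a simple
structure without changing communalities. Component retention defaults to
cumulative explained variance ≥ 80% rather than the Kaiser eigenvalue > 1
rule — a third component just below eigenvalue 1 can still be required to
reach an interpretable share of variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._defaults import METALS
from .io import SampleTable

__all__ = ["PCAModel", "PCAResults", "varimax", "kmo_bartlett", "pca_correlation"]


def varimax(loadings: np.ndarray, *, kaiser: bool = True, tol: float = 1e-10,
            max_iter: int = 500) -> tuple[np.ndarray, np.ndarray, int]:
    """Orthogonal varimax rotation.

    Maximizes the variance of squared loadings per factor, optionally after
    Kaiser normalization (rows scaled to unit communality during rotation).
    Returns (rotated loadings, rotation matrix, iteration count). A single
    column is returned unchanged with the identity rotation.
    """
    L = np.asarray(loadings, dtype=float).copy()
    n, k = L.shape
    if k < 2:
        return L, np.eye(k), 0
    comm = np.sqrt((L ** 2).sum(axis=1))
    if kaiser:
        L = L / comm[:, None]
    R = np.eye(k)
    crit_prev = 0.0
    it = 0
    for it in range(1, max_iter + 1):
        LR = L @ R
        # gradient of the varimax criterion (Lawley & Maxwell form)
        B = L.T @ (LR ** 3 - LR @ np.diag((LR ** 2).sum(axis=0)) / n)
        U, s, Vt = np.linalg.svd(B)
        R = U @ Vt
        crit = s.sum()
        if crit_prev != 0 and (crit - crit_prev) < tol * crit_prev:
            break
        crit_prev = crit
    out = (L @ R)
    if kaiser:
        out = out * comm[:, None]
    return out, R, it


def _flip_signs(L: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    idx = np.argmax(np.abs(L), axis=0)
    signs = np.sign(L[idx, np.arange(L.shape[1])])
    signs[signs == 0] = 1.0
    return L * signs


def kmo_bartlett(data: pd.DataFrame | np.ndarray) -> tuple[float, float, float]:
    """Kaiser–Meyer–Olkin sampling adequacy and Bartlett's sphericity test.

    KMO compares observed correlations with anti-image partial correlations
    obtained from the inverse correlation matrix. Bartlett's statistic is
    χ² = −(n − 1 − (2p + 5)/6)·ln det R with p(p−1)/2 degrees of freedom.
    A singular R is handled with a ridge-regularized inverse (warned).
    """
    X = np.asarray(data, dtype=float)
    n, p = X.shape
    R = np.corrcoef(X, rowvar=False)
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError:
        import warnings

        warnings.warn("singular correlation matrix; using ridge inverse")
        Rinv = np.linalg.inv(R + 1e-8 * np.eye(p))
    d = np.sqrt(np.diag(Rinv))
    partial = -Rinv / np.outer(d, d)
    np.fill_diagonal(partial, 0.0)
    off = ~np.eye(p, dtype=bool)
    r2 = (R[off] ** 2).sum()
    q2 = (partial[off] ** 2).sum()
    kmo = r2 / (r2 + q2)

    sign, logdet = np.linalg.slogdet(R)
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) / 2.0
    pval = float(stats.chi2.sf(chi2, df))
    return float(kmo), float(chi2), pval


@dataclass
class PCAResults:
    """Rotated PCA solution plus diagnostics, in the conventional layout:
    one row per variable, one column per retained component."""

    loadings: pd.DataFrame          # rotated
    loadings_unrotated: pd.DataFrame
    eigenvalues: np.ndarray         # all p eigenvalues, descending
    variance_pct: np.ndarray        # per retained component, rotated
    cumulative_pct: np.ndarray
    kmo: float
    bartlett_chi2: float
    bartlett_p: float
    n_components: int
    rotation_iterations: int

    @property
    def communalities(self) -> pd.Series:
        return (self.loadings ** 2).sum(axis=1)

    def summary(self) -> pd.DataFrame:
        """Loading table with eigenvalue / variance footer rows."""
        tab = self.loadings.round(3).copy()
        footer = pd.DataFrame(
            [self.eigenvalues[: self.n_components].round(3),
             self.variance_pct.round(2), self.cumulative_pct.round(2)],
            index=["eigenvalue", "variance %", "cumulative %"],
            columns=tab.columns)
        return pd.concat([tab, footer])


@dataclass
class PCAModel:
    """PCA of a sample table's metal concentrations (correlation matrix).

    ``n_components=None`` retains the smallest number of components whose
    cumulative explained variance reaches ``target_variance`` (default 80%).
    """

    data: pd.DataFrame
    n_components: int | None = None
    target_variance: float = 80.0
    rotate: bool = True
    columns: tuple = field(default_factory=lambda: METALS)

    @classmethod
    def from_samples(cls, samples: SampleTable, **kw) -> "PCAModel":
        return cls(samples.concentrations(), **kw)

    def fit(self) -> PCAResults:
        X = np.asarray(self.data[list(self.columns)], dtype=float)
        n, p = X.shape
        if np.any(X.std(axis=0) == 0):
            raise ValueError("constant column; PCA on the correlation matrix "
                             "is undefined")
        R = np.corrcoef(X, rowvar=False)
        evals, evecs = np.linalg.eigh(R)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        if np.any(evals < -1e-8):
            import warnings

            warnings.warn("rank-deficient correlation matrix; eigenvalues "
                          "clipped at 0")
        evals = np.clip(evals, 0.0, None)

        cum = 100.0 * np.cumsum(evals) / p
        if self.n_components is None:
            k = int(np.searchsorted(cum, self.target_variance) + 1)
            k = min(max(k, 1), p)
        else:
            k = self.n_components
        if n < k + 1:
            raise ValueError("need at least n_components + 1 samples")

        raw = evecs[:, :k] * np.sqrt(evals[:k])
        raw = _flip_signs(raw)
        iters = 0
        if self.rotate and k >= 2:
            rot, _, iters = varimax(raw)
            rot = _flip_signs(rot)
        else:
            rot = raw
        # order rotated components by explained variance (descending)
        var_rot = (rot ** 2).sum(axis=0)
        order2 = np.argsort(var_rot)[::-1]
        rot, var_rot = rot[:, order2], var_rot[order2]

        cols = [f"PC{i + 1}" for i in range(k)]
        kmo, chi2, pval = kmo_bartlett(X)
        return PCAResults(
            loadings=pd.DataFrame(rot, index=list(self.columns), columns=cols),
            loadings_unrotated=pd.DataFrame(raw, index=list(self.columns),
                                            columns=cols),
            eigenvalues=evals,
            variance_pct=100.0 * var_rot / p,
            cumulative_pct=100.0 * np.cumsum(var_rot) / p,
            kmo=kmo, bartlett_chi2=chi2, bartlett_p=pval,
            n_components=k, rotation_iterations=iters)


def pca_correlation(samples: SampleTable, n_keep: int | None = None) -> PCAResults:
    """Unrotated PCA of the correlation matrix (spec'd convenience form)."""
    return PCAModel.from_samples(samples, n_components=n_keep, rotate=False).fit()
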
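"""Positive matrix factorization (PMF) receptor model, from scratch.

The concentration matrix X (samples × metals) is decomposed as
``X ≈ G·F`` with elementwise non-negative contributions G and source
profiles F, minimizing the uncertainty-weighted objective

    Q = Σᵢⱼ (Eᵢⱼ / Uᵢⱼ)²,   E = X − G·F,

where U holds per-cell measurement uncertainties. The solver alternates
exact non-negative weighted least-squares block updates (per-sample rows of
G, per-species columns of F), so Q is monotonically non-increasing; several
random restarts are run and the best kept. Q(true) sums all cells; Q(robust) caps each cell's scaled residual
at |E/U| = 4 so a few outlying cells cannot dominate the fit assessment —
scanning the factor count and picking the p whose Q(robust)/Q(true) ratio is
closest to 1 is the usual model-selection heuristic.

Per-cell uncertainties follow the error model of receptor-model practice:
U = (5/6)·MDL for values at or below the detection limit, and
U = √((s·c)² + (0.5·MDL)²) above it, with s the analytical relative SD.

The factorization has a scale ambiguity (G·D⁻¹·D·F = G·F); profiles are
normalized to unit row sums with compensating scaling of G, so G's columns
carry the mass and F rows are composition fingerprints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment, nnls

from ._defaults import METALS
from .io import ConfigError, MetalParams, SampleTable

__all__ = ["build_uncertainty", "snr_classes", "PMFModel", "PMFResults",
           "fit_pmf", "select_n_factors", "factor_contributions",
           "residual_diagnostics", "align_factors", "species_share_matrix"]

_EPS = 1e-12


def build_uncertainty(samples: SampleTable, params: MetalParams,
                      rsd: dict[str, float] | None = None) -> pd.DataFrame:
    """Per-cell uncertainty table U (same shape/index as the concentrations).

    ``U = (5/6)·MDL`` where c ≤ MDL, else ``U = √((s·c)² + (0.5·MDL)²)``.
    """
    rsd = dict(params.rsd) if rsd is None else rsd
    for m in METALS:
        if m not in rsd:
            raise ConfigError(f"relative SD missing for {m}")
    conc = samples.concentrations()
    out = conc.copy()
    for m in METALS:
        c = conc[m].to_numpy()
        mdl = float(params.mdl[m])
        s = float(rsd[m])
        above = np.sqrt((s * c) ** 2 + (0.5 * mdl) ** 2)
        out[m] = np.where(c <= mdl, 5.0 / 6.0 * mdl, above)
    return out


def snr_classes(conc: pd.DataFrame, unc: pd.DataFrame,
                strong: float = 1.0, weak: float = 0.5) -> pd.Series:
    """EPA-style signal-to-noise class per metal.

    S/N is the mean over samples of max(0, (c − U)/U); ≥1 → "strong",
    0.5–1 → "weak" (practice: triple the uncertainty), <0.5 → "bad"
    (exclude from the fit).
    """
    d = np.maximum((conc - unc) / unc, 0.0)
    sn = d.mean(axis=0)
    return pd.Series(np.where(sn >= strong, "strong",
                              np.where(sn >= weak, "weak", "bad")),
                     index=conc.columns, name="snr_class")


def _nndsvd_init(X: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Non-negative double SVD initialization (positive parts of the leading
    singular vectors), a strong deterministic start for factorizable data."""
    Uv, s, Vt = np.linalg.svd(X, full_matrices=False)
    n, m = X.shape
    G = np.zeros((n, p))
    F = np.zeros((p, m))
    G[:, 0] = np.sqrt(s[0]) * np.abs(Uv[:, 0])
    F[0] = np.sqrt(s[0]) * np.abs(Vt[0])
    for k in range(1, min(p, len(s))):
        u, v = Uv[:, k], Vt[k]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        mp, mn = np.linalg.norm(up) * np.linalg.norm(vp), \
            np.linalg.norm(un) * np.linalg.norm(vn)
        if mp >= mn and mp > 0:
            G[:, k] = np.sqrt(s[k] * mp) * up / np.linalg.norm(up)
            F[k] = np.sqrt(s[k] * mp) * vp / np.linalg.norm(vp)
        elif mn > 0:
            G[:, k] = np.sqrt(s[k] * mn) * un / np.linalg.norm(un)
            F[k] = np.sqrt(s[k] * mn) * vn / np.linalg.norm(vn)
    eps = X.mean() * 1e-3
    return np.maximum(G, eps), np.maximum(F, eps)


def _q_true(X, U, G, F):
    return float((((X - G @ F) / U) ** 2).sum())


def _q_robust(X, U, G, F, cap: float = 4.0):
    r2 = ((X - G @ F) / U) ** 2
    return float(np.minimum(r2, cap ** 2).sum())


@dataclass
class PMFResults:
    """A fitted PMF solution (best restart) with diagnostics."""

    G: np.ndarray                  # (n, p) contributions, F-row-normalized scale
    F: np.ndarray                  # (p, m) unit-row-sum profiles
    q_true: float
    q_robust: float
    n_factors: int
    metals: tuple
    sample_index: pd.Index
    converged: bool
    n_iter: int
    restart_q: list[float]         # best Q per restart
    q_history: np.ndarray          # objective trace of the winning restart
    X: np.ndarray = field(repr=False, default=None)
    U: np.ndarray = field(repr=False, default=None)

    @property
    def E(self) -> np.ndarray:
        """Residual matrix X − G·F."""
        return self.X - self.G @ self.F

    @property
    def scaled_residuals(self) -> np.ndarray:
        return self.E / self.U

    @property
    def dof(self) -> int:
        n, m = self.X.shape
        return n * m - self.n_factors * (n + m)

    def profiles(self) -> pd.DataFrame:
        return pd.DataFrame(self.F, columns=self.metals,
                            index=[f"F{k+1}" for k in range(self.n_factors)])

    def contributions(self) -> pd.DataFrame:
        return pd.DataFrame(self.G, index=self.sample_index,
                            columns=[f"F{k+1}" for k in range(self.n_factors)])

    def metal_shares(self) -> pd.DataFrame:
        """% of each metal's reconstructed mass per factor (columns sum 100)."""
        return factor_contributions(self)[0]

    def overall_shares(self) -> pd.Series:
        """Overall factor contribution %, the mean over metals of the
        per-metal shares."""
        return factor_contributions(self)[1]

    def summary(self) -> str:
        shares = self.overall_shares()
        lines = [
            f"PMF solution: {self.n_factors} factors, "
            f"{self.X.shape[0]} samples x {self.X.shape[1]} species",
            f"Q(true) = {self.q_true:.4g}   Q(robust) = {self.q_robust:.4g}   "
            f"Q/dof = {self.q_true / self.dof:.4g}",
            f"converged: {self.converged} after {self.n_iter} iterations "
            f"(best of {len(self.restart_q)} restarts)",
            "overall factor contributions (%): "
            + ", ".join(f"{k}: {v:.1f}" for k, v in shares.items()),
            "",
            self.profiles().round(4).to_string(),
        ]
        return "\n".join(lines)


@dataclass
class PMFModel:
    """Uncertainty-weighted non-negative factorization of a concentration
    matrix.

    Parameters
    ----------
    X, U : concentration and uncertainty tables (DataFrame or array),
        strictly positive.
    n_factors : number of sources p (p < number of species).
    restarts : random initializations; the lowest-Q solution is kept.
    seed : seeds the initialization stream.
    max_iter, tol : per-restart iteration cap and relative ΔQ stopping rule.
    """

    X: pd.DataFrame | np.ndarray
    U: pd.DataFrame | np.ndarray
    n_factors: int
    restarts: int = 20
    seed: int = 0
    max_iter: int = 500
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if isinstance(self.X, pd.DataFrame):
            self._metals = tuple(self.X.columns)
            self._index = self.X.index
        else:
            self._metals = tuple(f"V{j}" for j in range(np.shape(self.X)[1]))
            self._index = pd.RangeIndex(np.shape(self.X)[0])
        self._Xa = np.asarray(self.X, dtype=float)
        self._Ua = np.asarray(self.U, dtype=float)
        if self._Xa.shape != self._Ua.shape:
            raise ValueError("X and U shapes differ")
        if np.any(self._Xa <= 0) or np.any(self._Ua <= 0):
            raise ValueError("X and U must be strictly positive")
        if not 1 <= self.n_factors < self._Xa.shape[1] + 1:
            raise ValueError("n_factors must be in [1, n_species]")

    @classmethod
    def from_samples(cls, samples: SampleTable, params: MetalParams,
                     n_factors: int, **kw) -> "PMFModel":
        return cls(samples.concentrations(),
                   build_uncertainty(samples, params), n_factors, **kw)

    def _one_restart(self, rng: np.random.Generator):
        """Alternating non-negative weighted least squares.

        Each half-step solves its block exactly (per-row / per-column NNLS
        on uncertainty-scaled design matrices), so the objective is
        monotonically non-increasing.
        """
        X, U, p = self._Xa, self._Ua, self.n_factors
        n, m = X.shape
        Winv = 1.0 / U
        B = X * Winv                     # scaled data
        colmean = X.mean(axis=0)
        if rng is None:                  # deterministic SVD-based start
            G, F = _nndsvd_init(X, p)
        else:
            G = rng.uniform(0.1, 1.0, (n, p))
            F = rng.uniform(0.1, 1.0, (p, m)) * colmean
        q_prev = _q_true(X, U, G, F)
        history = [q_prev]
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            Ft = F.T
            for i in range(n):
                G[i], _ = nnls(Ft * Winv[i][:, None], B[i])
            # a factor may collapse to zero contributions; reseed it
            dead = G.sum(axis=0) == 0
            if dead.any():
                reseed = rng or np.random.default_rng(it)
                G[:, dead] = reseed.uniform(0.1, 1.0, (n, int(dead.sum())))
            for j in range(m):
                F[:, j], _ = nnls(G * Winv[:, j][:, None], B[:, j])
            q = _q_true(X, U, G, F)
            history.append(q)
            if q_prev - q < self.tol * max(q_prev, _EPS):
                converged = True
                break
            q_prev = q
        return G, F, np.array(history), converged, it

    def fit(self) -> PMFResults:
        rng = np.random.default_rng(self.seed)
        best = None
        restart_q = []
        # first start is deterministic (non-negative double SVD); the rest
        # are random draws from the seeded stream
        for k in range(self.restarts):
            G, F, hist, conv, it = self._one_restart(None if k == 0 else rng)
            q = _q_true(self._Xa, self._Ua, G, F)
            restart_q.append(q)
            if best is None or q < best[0]:
                best = (q, G, F, hist, conv, it)
        q, G, F, hist, conv, it = best

        # resolve scale ambiguity: unit-row-sum profiles
        rowsum = F.sum(axis=1)
        rowsum[rowsum == 0] = 1.0
        F = F / rowsum[:, None]
        G = G * rowsum[None, :]

        return PMFResults(
            G=G, F=F, q_true=q,
            q_robust=_q_robust(self._Xa, self._Ua, G, F),
            n_factors=self.n_factors, metals=self._metals,
            sample_index=self._index, converged=conv, n_iter=it,
            restart_q=restart_q, q_history=hist,
            X=self._Xa, U=self._Ua)


def fit_pmf(X, U, n_factors: int, restarts: int = 20, seed: int = 0,
            **kw) -> PMFResults:
    """Functional wrapper around :class:`PMFModel`."""
    return PMFModel(X, U, n_factors, restarts=restarts, seed=seed, **kw).fit()


def factor_contributions(sol: PMFResults) -> tuple[pd.DataFrame, pd.Series]:
    """Per-metal and overall factor contribution percentages.

    Per-metal share of factor k for metal m: Σₙ gₙₖ f_km / Σₙ Σₖ' gₙₖ' f_k'm
    (column-wise % of reconstructed mass). The overall share of a factor is
    the unweighted mean of its per-metal shares. Metals whose reconstructed
    mass is zero are reported as NaN.
    """
    mass = sol.G.sum(axis=0)[:, None] * sol.F          # (p, m)
    total = mass.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(total > 0, 100.0 * mass / total, np.nan)
    per_metal = pd.DataFrame(share, columns=sol.metals,
                             index=[f"F{k+1}" for k in range(sol.n_factors)])
    overall = per_metal.mean(axis=1)
    overall.name = "overall_share_pct"
    return per_metal, overall


def select_n_factors(X, U, scan: tuple[int, int] = (3, 5), restarts: int = 20,
                     seed: int = 0, **kw) -> tuple[int, pd.DataFrame]:
    """Scan candidate factor counts and pick p with Q(robust)/Q(true)
    closest to 1 (ties to the smaller p). Returns (p, diagnostic table)."""
    lo, hi = scan
    rows = []
    for p in range(lo, hi + 1):
        sol = fit_pmf(X, U, p, restarts=restarts, seed=seed + p, **kw)
        ratio = 1.0 if sol.q_true < _EPS else sol.q_robust / sol.q_true
        rows.append({"p": p, "q_true": sol.q_true, "q_robust": sol.q_robust,
                     "q_ratio": ratio, "q_per_dof": sol.q_true / sol.dof})
    table = pd.DataFrame(rows).set_index("p")
    dist = (table["q_ratio"] - 1.0).abs()
    # near-ties (both ratios ~1) break toward the more parsimonious model
    chosen = int(dist.index[dist <= dist.min() + 1e-9][0])
    return chosen, table


def residual_diagnostics(sol: PMFResults) -> pd.DataFrame:
    """Shapiro–Wilk normality check of the scaled residuals per metal.

    Returns statistic, p-value and a ``flagged`` marker for metals whose
    residual distribution departs from normality (statistic < 0.9 is the
    conventional visual-fit threshold). Skipped (NaN) below 3 samples.
    """
    R = sol.scaled_residuals
    rows = []
    for j, m in enumerate(sol.metals):
        col = R[:, j]
        if len(col) < 3 or np.allclose(col, col[0]):
            rows.append({"metal": m, "shapiro_w": np.nan, "p_value": np.nan,
                         "flagged": False})
            continue
        w, p = stats.shapiro(col)
        rows.append({"metal": m, "shapiro_w": float(w), "p_value": float(p),
                     "flagged": bool(w < 0.9)})
    return pd.DataFrame(rows).set_index("metal")


def species_share_matrix(G: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Per-species share matrix: fraction of each metal's reconstructed mass
    attributed to each factor (columns sum to 1). This is the scale-free
    receptor-modelling view of a solution — invariant to the G/F scale
    ambiguity, so solutions in different normalizations are comparable."""
    mass = np.asarray(G, float).sum(axis=0)[:, None] * np.asarray(F, float)
    return mass / np.maximum(mass.sum(axis=0, keepdims=True), _EPS)


def align_factors(F_est: np.ndarray, F_ref: np.ndarray,
                  G_est: np.ndarray | None = None,
                  G_ref: np.ndarray | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Match estimated factors to reference factors by maximal cosine
    similarity (Hungarian assignment on profile rows).

    When contribution matrices are given, profiles are compared as
    mass-weighted per-species shares (:func:`species_share_matrix`), which
    removes the scale ambiguity between differently normalized solutions;
    otherwise raw profile rows are compared.

    Returns (permutation such that ``F_est[perm]`` matches ``F_ref`` row by
    row, cosine similarity per matched pair).
    """
    if G_est is not None:
        A = species_share_matrix(G_est, F_est)
    else:
        A = np.asarray(F_est, float).copy()
    if G_ref is not None:
        B = species_share_matrix(G_ref, F_ref)
    else:
        B = np.asarray(F_ref, float).copy()
    An = A / np.maximum(np.linalg.norm(A, axis=1, keepdims=True), _EPS)
    Bn = B / np.maximum(np.linalg.norm(B, axis=1, keepdims=True), _EPS)
    C = Bn @ An.T                                   # (ref, est) cosine matrix
    rows, cols = linear_sum_assignment(-C)
    return cols, C[rows, cols]
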
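"""Empirical semivariogram, variogram-model fitting and ordinary kriging.

Ordinary kriging is the best linear unbiased predictor under a fitted
variogram: at each target location the weights solve

    | Γ  1 | |w|   |γ₀|
    | 1ᵀ 0 | |μ| = | 1|

where Γ holds pairwise semivariances between data points, γ₀ the
semivariances to the target, and the Lagrange multiplier μ enforces unit-sum
weights (unbiasedness). With a zero nugget the predictor interpolates the
data exactly. Strongly right-skewed concentrations are log-transformed
before kriging by default and back-transformed with the usual lognormal
bias correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial.distance import cdist, pdist, squareform

__all__ = ["empirical_variogram", "Variogram", "VariogramModel",
           "OrdinaryKriging", "KrigedSurface", "make_grid"]


def _spherical(h, nugget, psill, rng):
    h = np.asarray(h, dtype=float)
    inside = nugget + psill * (1.5 * h / rng - 0.5 * (h / rng) ** 3)
    gamma = np.where(h >= rng, nugget + psill, inside)
    return np.where(h == 0, 0.0, gamma)


def _exponential(h, nugget, psill, rng):
    h = np.asarray(h, dtype=float)
    gamma = nugget + psill * (1.0 - np.exp(-3.0 * h / rng))
    return np.where(h == 0, 0.0, gamma)


_MODELS = {"spherical": _spherical, "exponential": _exponential}


def empirical_variogram(coords: np.ndarray, values: np.ndarray,
                        lag_bins: int = 12,
                        max_dist: float | None = None) -> pd.DataFrame:
    """Binned empirical semivariance γ(h) = mean(Δz²)/2 per lag bin.

    Returns a frame with bin centre ``h``, semivariance ``gamma`` and pair
    count ``n``; empty bins are dropped. Requires ≥10 distinct locations.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    d = pdist(coords)
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 samples for a variogram")
    if np.all(d == 0):
        raise ValueError("all sample locations coincide")
    if max_dist is None:
        max_dist = d.max() / 2.0 if coords.shape[0] >= 10 else d.max()
    # include pairs exactly at max_dist in the last bin
    max_dist = np.nextafter(max_dist, np.inf)
    sq = pdist(values[:, None], metric="sqeuclidean") / 2.0
    edges = np.linspace(0, max_dist, lag_bins + 1)
    which = np.digitize(d, edges) - 1
    rows = []
    for b in range(lag_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        rows.append({"h": 0.5 * (edges[b] + edges[b + 1]),
                     "gamma": sq[mask].mean(), "n": int(mask.sum())})
    return pd.DataFrame(rows)


@dataclass
class VariogramModel:
    """Fitted (or hand-set) variogram: γ(h) with nugget, partial sill, range."""

    model: str = "spherical"
    nugget: float = 0.0
    psill: float = 1.0
    range_: float = 1.0

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.nugget < 0 or self.psill < 0 or self.range_ <= 0:
            raise ValueError("need nugget ≥ 0, partial sill ≥ 0, range > 0")

    @property
    def sill(self) -> float:
        return self.nugget + self.psill

    def __call__(self, h) -> np.ndarray:
        return _MODELS[self.model](h, self.nugget, self.psill, self.range_)


@dataclass
class Variogram:
    """Empirical variogram plus weighted-least-squares model fit.

    Weights are the pair counts per lag bin, so well-populated short lags
    dominate the fit (they matter most for kriging weights).
    """

    coords: np.ndarray
    values: np.ndarray
    lag_bins: int = 12
    model: str = "spherical"
    empirical: pd.DataFrame = field(init=False, default=None)

    def fit(self) -> VariogramModel:
        emp = empirical_variogram(self.coords, self.values, self.lag_bins)
        self.empirical = emp
        h, g, n = emp["h"].to_numpy(), emp["gamma"].to_numpy(), emp["n"].to_numpy()
        fun = _MODELS[self.model]
        var = np.asarray(self.values, float).var(ddof=1)
        p0 = (min(g[0], var * 0.1) if len(g) else 0.0, max(var, 1e-12), h[-1] * 0.7)
        bounds = ([0, 0, 1e-9], [np.inf, np.inf, np.inf])
        popt, _ = curve_fit(fun, h, g, p0=p0, sigma=1.0 / np.sqrt(n),
                            bounds=bounds, maxfev=20000)
        return VariogramModel(self.model, *popt)


@dataclass
class KrigedSurface:
    """Gridded prediction: coordinates, kriged value and kriging variance."""

    grid: np.ndarray            # (g, 2)
    prediction: np.ndarray      # (g,)
    variance: np.ndarray        # (g,)
    metal: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.grid[:, 0], "y": self.grid[:, 1],
                             "prediction": self.prediction,
                             "variance": self.variance})


def make_grid(origin: tuple[float, float], cell: float, nx: int, ny: int) -> np.ndarray:
    x0, y0 = origin
    xs = x0 + cell * (np.arange(nx) + 0.5)
    ys = y0 + cell * (np.arange(ny) + 0.5)
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


class OrdinaryKriging:
    """Ordinary kriging with a fitted :class:`VariogramModel`.

    Parameters
    ----------
    coords, values : data locations and observations.
    model : variogram model; if None one is fitted (spherical, WLS).
    log_transform : krige log-concentrations and back-transform with the
        lognormal correction exp(ẑ + σ²ₖ/2) — appropriate for right-skewed
        positive fields; disable for already-symmetric variables.
    dedup : average duplicated locations ("mean") or raise ("fail").
    """

    def __init__(self, coords: np.ndarray, values: np.ndarray,
                 model: VariogramModel | None = None, *,
                 log_transform: bool = False, lag_bins: int = 12,
                 dedup: str = "mean") -> None:
        coords = np.asarray(coords, dtype=float)
        values = np.asarray(values, dtype=float)
        if log_transform and np.any(values <= 0):
            raise ValueError("log-transform requires positive values")
        z = np.log(values) if log_transform else values

        # collapse exactly duplicated locations (singular kriging matrix)
        uniq, inverse = np.unique(coords, axis=0, return_inverse=True)
        if len(uniq) < len(coords):
            if dedup != "mean":
                raise ValueError("duplicated sample locations")
            z = np.bincount(inverse, weights=z) / np.bincount(inverse)
            coords = uniq
        self.coords, self.z = coords, z
        self.log_transform = log_transform
        self.model = model or Variogram(coords, z, lag_bins=lag_bins).fit()

        n = len(coords)
        K = np.empty((n + 1, n + 1))
        K[:n, :n] = self.model(squareform(pdist(coords)))
        K[n, :n] = K[:n, n] = 1.0
        K[n, n] = 0.0
        self._K = K

    def weights(self, target: np.ndarray) -> tuple[np.ndarray, float]:
        """Kriging weights and Lagrange multiplier for one target point."""
        g0 = self.model(cdist(self.coords, np.atleast_2d(target)).ravel())
        rhs = np.append(g0, 1.0)
        sol = np.linalg.solve(self._K, rhs)
        return sol[:-1], sol[-1]

    def predict(self, grid: np.ndarray, metal: str = "") -> KrigedSurface:
        grid = np.atleast_2d(np.asarray(grid, dtype=float))
        n = len(self.coords)
        G0 = self.model(cdist(self.coords, grid))         # (n, g)
        rhs = np.vstack([G0, np.ones(grid.shape[0])])
        sol = np.linalg.solve(self._K, rhs)
        w, mu = sol[:n], sol[n]
        pred = w.T @ self.z
        var = np.maximum((w * G0).sum(axis=0) + mu, 0.0)
        if self.log_transform:
            pred = np.exp(pred + var / 2.0)
        return KrigedSurface(grid=grid, prediction=pred, variance=var, metal=metal)

    def loo_rmse(self) -> float:
        """Leave-one-out cross-validation RMSE on the (possibly log) scale."""
        errs = []
        for i in range(len(self.coords)):
            keep = np.arange(len(self.coords)) != i
            ok = OrdinaryKriging(self.coords[keep], self.z[keep], self.model)
            errs.append(ok.predict(self.coords[i:i + 1]).prediction[0] - self.z[i])
        return float(np.sqrt(np.mean(np.square(errs))))


def write_ascii_grid(surface: KrigedSurface, path, origin, cell, nx, ny) -> None:
    """ESRI ASCII raster export of a gridded surface (row-major, north up)."""
    vals = surface.prediction.reshape(ny, nx)[::-1]
    header = (f"ncols {nx}\nnrows {ny}\nxllcorner {origin[0]}\n"
              f"yllcorner {origin[1]}\ncellsize {cell}\nNODATA_value -9999\n")
    body = "\n".join(" ".join(f"{v:.6g}" for v in row) for row in vals)
    with open(path, "w") as fh:
        fh.write(header + body + "\n")
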
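"""Semivariograms, variogram-model fitting and ordinary kriging.

The spatial structure of plot-level change is summarized by the Matheron
empirical semivariogram, a parametric model is fitted by weighted least
squares over five model families (Spherical, Exponential, Gaussian, Matérn,
and Matérn in Stein's parameterization, the latter two with an automatic
smoothness search), and the best model drives ordinary kriging onto a
regular grid (100 m cells by default).

Model conventions
-----------------
gamma(h) = nugget + partial_sill * f(h / range) with f(0+) = 0 and f -> 1 at
large h.  The exponential family uses f = 1 - exp(-h/a) (practical range
~ 3a); the Matérn family uses the Bessel-K form with smoothness kappa; the
Stein form rescales distance by 2*sqrt(kappa) so that the range parameter is
roughly smoothness-invariant.  gamma(0) = 0 exactly (measurement at zero
distance), which makes kriging an exact interpolator at data locations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, spatial, special
from scipy.linalg import lu_factor, lu_solve

from .grids import RasterGrid

__all__ = [
    "EmpiricalVariogram",
    "VariogramModel",
    "FAMILIES",
    "KAPPA_GRID",
    "empirical_semivariogram",
    "fit_variogram",
    "ordinary_kriging",
    "kriging_weights",
    "prediction_grid",
    "compare_patterns",
    "simulate_gaussian_field",
]

FAMILIES = ("Spherical", "Exponential", "Gaussian", "Matern", "Stein")
KAPPA_GRID = (0.05, 0.1, 0.2, 0.3, 0.5, 0.7, 1.0, 1.5, 2.0, 3.0, 5.0, 10.0)


@dataclass
class EmpiricalVariogram:
    lags_m: np.ndarray
    semivariance: np.ndarray
    pair_counts: np.ndarray
    cutoff_m: float


@dataclass
class VariogramModel:
    family: str
    nugget: float
    partial_sill: float
    range_m: float
    kappa: float | None = None
    fit_error: float = np.nan

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def __call__(self, h) -> np.ndarray:
        """gamma(h); gamma(0) = 0 exactly."""
        h = np.asarray(h, dtype=float)
        g = self.nugget + self.partial_sill * _structure(self.family, h, self.range_m, self.kappa)
        return np.where(h > 0, g, 0.0)

    def covariance(self, h) -> np.ndarray:
        """C(h) = sill - gamma(h) for h > 0; C(0) = sill."""
        h = np.asarray(h, dtype=float)
        return np.where(h > 0, self.sill - self(h), self.sill)

    def effective_range(self, level: float = 0.95) -> float:
        """Lag at which gamma reaches ``level`` of the sill above the nugget."""
        if self.partial_sill == 0:
            return 0.0
        f = lambda h: _structure(self.family, np.array([h]), self.range_m, self.kappa)[0] - level
        hi = self.range_m
        while f(hi) < 0:
            hi *= 2
            if hi > 1e6 * self.range_m:  # pragma: no cover - pathological
                return np.inf
        return float(optimize.brentq(f, 1e-12 * self.range_m, hi))


def _structure(family: str, h: np.ndarray, a: float, kappa: float | None) -> np.ndarray:
    """Normalized variogram structure f(h) in [0, 1], f(0) = 0."""
    h = np.abs(np.asarray(h, dtype=float))
    if family == "Spherical":
        x = np.minimum(h / a, 1.0)
        return 1.5 * x - 0.5 * x ** 3
    if family == "Exponential":
        return 1.0 - np.exp(-h / a)
    if family == "Gaussian":
        return 1.0 - np.exp(-((h / a) ** 2))
    if family in ("Matern", "Stein"):
        if kappa is None:
            raise ValueError(f"{family} requires a kappa")
        x = h / a
        if family == "Stein":
            x = 2.0 * np.sqrt(kappa) * x
        out = np.ones_like(x)
        pos = x > 0
        xp = x[pos]
        corr = (2 ** (1 - kappa) / special.gamma(kappa)) * xp ** kappa * special.kv(kappa, xp)
        out[pos] = 1.0 - np.nan_to_num(corr, nan=0.0)
        out[~pos] = 0.0
        return np.clip(out, 0.0, 1.0)
    raise ValueError(f"unknown variogram family {family!r}")


def empirical_semivariogram(points: np.ndarray, values: np.ndarray, n_bins: int = 15,
                            cutoff: float | None = None) -> EmpiricalVariogram:
    """Matheron estimator on equal-width lag bins; empty bins are dropped.

    The default cutoff is one-third of the maximum inter-point distance.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    d = spatial.distance.pdist(points)
    if d.max() == 0:
        raise ValueError("all points are coincident")
    if cutoff is None:
        cutoff = d.max() / 3.0
    sq = spatial.distance.pdist(values[:, None], metric="sqeuclidean")
    keep = (d <= cutoff) & (d > 0)
    d, sq = d[keep], sq[keep]
    edges = np.linspace(0, cutoff, n_bins + 1)
    idx = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    gamma = np.zeros(n_bins)
    np.add.at(gamma, idx, sq)
    nonempty = counts > 0
    gamma[nonempty] = gamma[nonempty] / (2.0 * counts[nonempty])
    centers = 0.5 * (edges[:-1] + edges[1:])
    return EmpiricalVariogram(centers[nonempty], gamma[nonempty], counts[nonempty], cutoff)


def _fit_one(emp: EmpiricalVariogram, family: str, kappa: float | None) -> VariogramModel | None:
    h, g, n = emp.lags_m, emp.semivariance, emp.pair_counts
    w = np.sqrt(n / h ** 2)
    sill0 = float(np.mean(g[-3:])) if len(g) >= 3 else float(g.mean())
    nug0 = float(min(g[0], sill0))
    starts = [
        (nug0, max(sill0 - nug0, 1e-10 * max(sill0, 1.0), 0.0), emp.cutoff_m / 2),
        (0.0, max(sill0, 1e-12), emp.cutoff_m / 4),
    ]

    def residual(p):
        nugget, psill, a = p
        return w * (nugget + psill * _structure(family, h, a, kappa) - g)

    best = None
    for x0 in starts:
        try:
            res = optimize.least_squares(
                residual, x0=x0,
                bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            continue
        sse = float(np.sum(res.fun ** 2))
        if best is None or sse < best.fit_error:
            best = VariogramModel(family, float(res.x[0]), float(res.x[1]), float(res.x[2]),
                                  kappa, sse)
    return best


def fit_variogram(emp: EmpiricalVariogram, families=FAMILIES,
                  kappa_grid=KAPPA_GRID) -> VariogramModel:
    """Best weighted-least-squares model over the candidate families.

    Weights are N_j / h_j^2 (many close pairs dominate).  The Matérn and
    Stein families are scanned over the kappa grid (automatic smoothness
    selection).  Ties in fit error are broken by family order.
    """
    if len(emp.lags_m) < 4:
        raise ValueError("need at least 4 non-empty lag bins to fit a variogram")
    candidates: list[VariogramModel] = []
    for family in families:
        kappas = kappa_grid if family in ("Matern", "Stein") else (None,)
        fits = [m for k in kappas if (m := _fit_one(emp, family, k)) is not None]
        if fits:
            candidates.append(min(fits, key=lambda m: m.fit_error))
    if not candidates:
        raise RuntimeError("variogram fitting failed for every candidate family")
    order = {f: i for i, f in enumerate(families)}
    return min(candidates, key=lambda m: (m.fit_error, order[m.family]))


def _deduplicate(points: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average values at duplicated coordinates (keeps the kriging matrix regular)."""
    uniq, inverse = np.unique(points, axis=0, return_inverse=True)
    if len(uniq) == len(points):
        return points, values
    sums = np.zeros(len(uniq))
    counts = np.zeros(len(uniq))
    np.add.at(sums, inverse, values)
    np.add.at(counts, inverse, 1.0)
    return uniq, sums / counts


def kriging_weights(points: np.ndarray, model: VariogramModel,
                    targets: np.ndarray) -> np.ndarray:
    """Ordinary-kriging weights, shape (n_points, n_targets); columns sum to 1."""
    points = np.asarray(points, dtype=float)
    targets = np.asarray(targets, dtype=float)
    n = len(points)
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = model(spatial.distance.squareform(spatial.distance.pdist(points)))
    A[n, :], A[:, n] = 1.0, 1.0
    A[n, n] = 0.0
    B = np.empty((n + 1, len(targets)))
    B[:n] = model(spatial.distance.cdist(points, targets))
    B[n] = 1.0
    try:
        sol = lu_solve(lu_factor(A), B)
    except Exception:
        sol = np.linalg.lstsq(A, B, rcond=None)[0]
    return sol[:n]


def prediction_grid(points: np.ndarray, cellsize_m: float = 100.0,
                    pad_cells: int = 1) -> RasterGrid:
    """Empty grid covering the bounding box of ``points`` plus padding."""
    points = np.asarray(points, dtype=float)
    xmin, ymin = points.min(axis=0) - pad_cells * cellsize_m
    xmax, ymax = points.max(axis=0) + pad_cells * cellsize_m
    ncols = max(int(np.ceil((xmax - xmin) / cellsize_m)), 1)
    nrows = max(int(np.ceil((ymax - ymin) / cellsize_m)), 1)
    return RasterGrid(np.full((nrows, ncols), np.nan), xmin, ymin, cellsize_m)


def ordinary_kriging(points: np.ndarray, values: np.ndarray, model: VariogramModel,
                     grid: RasterGrid | None = None, cellsize_m: float = 100.0,
                     max_neighbors: int | None = None) -> RasterGrid:
    """Ordinary kriging of point data onto a grid.

    With ``max_neighbors`` unset (recommended up to a few thousand points) a
    single global system is factorized and reused for every cell; otherwise
    each cell solves a local system over its nearest neighbors.
    """
    points, values = _deduplicate(np.asarray(points, float), np.asarray(values, float))
    if len(points) < 2:
        raise ValueError("ordinary kriging needs at least 2 distinct data points")
    if grid is None:
        grid = prediction_grid(points, cellsize_m)
    gx, gy = grid.cell_centers()
    targets = np.column_stack([gx.ravel(), gy.ravel()])
    if max_neighbors is None or max_neighbors >= len(points):
        w = kriging_weights(points, model, targets)
        pred = values @ w
    else:
        tree = spatial.cKDTree(points)
        _, nbr = tree.query(targets, k=max_neighbors)
        pred = np.empty(len(targets))
        for i, t in enumerate(targets):
            idx = np.atleast_1d(nbr[i])
            w = kriging_weights(points[idx], model, t[None, :])
            pred[i] = values[idx] @ w[:, 0]
    out = RasterGrid(pred.reshape(grid.values.shape), grid.xll_m, grid.yll_m,
                     grid.cellsize_m, grid.nodata_value)
    return out


def compare_patterns(raster_a: RasterGrid, raster_b: RasterGrid) -> tuple[float, float]:
    """(RMSE, trend congruence %) between two co-registered change surfaces.

    Trend congruence is the share of valid cells whose change keeps the same
    sign in both rasters (zero is congruent only with zero).
    """
    a, b = raster_a.values, raster_b.values
    if a.shape != b.shape:
        raise ValueError(f"grid shapes differ: {a.shape} vs {b.shape}")
    valid = ~(np.isnan(a) | np.isnan(b))
    if not valid.any():
        raise ValueError("no jointly valid cells")
    da, db = a[valid], b[valid]
    rmse = float(np.sqrt(np.mean((da - db) ** 2)))
    congruence = float(100.0 * np.mean(np.sign(da) == np.sign(db)))
    return rmse, congruence


def simulate_gaussian_field(points: np.ndarray, model: VariogramModel,
                            rng: np.random.Generator) -> np.ndarray:
    """Zero-mean Gaussian random field with the model's covariance (test oracle).

    Dense Cholesky simulation; the nugget is added as independent noise.
    """
    points = np.asarray(points, dtype=float)
    d = spatial.distance.squareform(spatial.distance.pdist(points))
    C = model.partial_sill * (1.0 - _structure(model.family, d, model.range_m, model.kappa))
    C[np.diag_indices_from(C)] = model.partial_sill
    L = np.linalg.cholesky(C + 1e-10 * model.partial_sill * np.eye(len(points)))
    z = L @ rng.standard_normal(len(points))
    if model.nugget > 0:
        z = z + np.sqrt(model.nugget) * rng.standard_normal(len(points))
    return z
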
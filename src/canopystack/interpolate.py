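"""Footprint-to-surface interpolation: ordinary kriging, sequential Gaussian
conditional simulation, and inverse-distance weighting with exponent tuning.

Each method can predict onto a :class:`~canopystack.grids.GridSpec` or onto
arbitrary points; surfaces are evaluated on a seeded 80/20 hold-out split and
gated at R² >= 0.50 before entering the downstream feature set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .grids import GridSpec, Raster
from .variogram import VariogramModel, semivariance

__all__ = [
    "KrigingResult",
    "RealizationStack",
    "IDWOptimizerConfig",
    "InterpolationReport",
    "ordinary_kriging",
    "sgcs",
    "realization_cv",
    "select_convergent_n",
    "idw",
    "optimize_beta",
    "evaluate_interpolation",
    "resample_nearest",
    "r_squared",
]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# helpers


def _dedupe_obs(xy: np.ndarray, z: np.ndarray):
    """Average values at duplicated coordinates (kriging systems need distinct points)."""
    uniq, inverse = np.unique(np.round(xy, 9), axis=0, return_inverse=True)
    if uniq.shape[0] == xy.shape[0]:
        return xy, z
    sums = np.bincount(inverse, weights=z)
    counts = np.bincount(inverse)
    return uniq, sums / counts


def _targets_to_points(targets):
    if isinstance(targets, GridSpec):
        xs, ys = targets.center_mesh()
        return np.column_stack([xs.ravel(), ys.ravel()]), targets
    pts = np.asarray(targets, dtype=float)
    return pts.reshape(-1, 2), None


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SSE/SST about the observed mean."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    sse = np.sum((obs - pred) ** 2)
    sst = np.sum((obs - obs.mean()) ** 2)
    if sst == 0:
        return 1.0 if sse == 0 else -np.inf
    return float(1.0 - sse / sst)


# ---------------------------------------------------------------------------
# ordinary kriging


@dataclass
class KrigingResult:
    estimates: Raster | np.ndarray
    variances: Raster | np.ndarray
    neighbors_used: int


def ordinary_kriging(
    obs_xy,
    obs_z,
    targets,
    model: VariogramModel,
    max_neighbors: int = 25,
) -> KrigingResult:
    """Solve the OK system at each target from the nearest observations.

    Weights satisfy the unbiasedness constraint (sum to one). A target that
    coincides with an observation returns that observation with zero variance
    (exactness, regardless of nugget).
    """
    xy = np.asarray(obs_xy, dtype=float).reshape(-1, 2)
    z = np.asarray(obs_z, dtype=float)
    if xy.shape[0] < 2:
        raise ValueError("ordinary kriging needs at least 2 observations")
    xy, z = _dedupe_obs(xy, z)
    n_obs = xy.shape[0]
    k = min(max_neighbors, n_obs)

    pts, out_grid = _targets_to_points(targets)
    tree = cKDTree(xy)
    dist, idx = tree.query(pts, k=k)
    dist = np.atleast_2d(dist)
    idx = np.atleast_2d(idx)

    est = np.empty(pts.shape[0])
    var = np.empty(pts.shape[0])
    for t in range(pts.shape[0]):
        di, ii = dist[t], idx[t]
        if di[0] < 1e-9:  # exactness at a conditioning point
            est[t] = z[ii[0]]
            var[t] = 0.0
            continue
        nb = xy[ii]
        gamma_t = semivariance(model, di)
        d_nb = np.linalg.norm(nb[:, None, :] - nb[None, :, :], axis=-1)
        G = semivariance(model, d_nb)
        np.fill_diagonal(G, 0.0)
        A = np.empty((k + 1, k + 1))
        A[:k, :k] = G
        A[k, :k] = 1.0
        A[:k, k] = 1.0
        A[k, k] = 0.0
        b = np.append(gamma_t, 1.0)
        try:
            sol = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular kriging system at target {t}"
            ) from exc
        lam, mu = sol[:k], sol[k]
        est[t] = lam @ z[ii]
        var[t] = max(float(lam @ gamma_t + mu), 0.0)

    if out_grid is not None:
        return KrigingResult(
            Raster(out_grid, est.reshape(out_grid.shape)),
            Raster(out_grid, var.reshape(out_grid.shape)),
            k,
        )
    return KrigingResult(est, var, k)


def _simple_kriging_point(target, nb_xy, nb_z, model: VariogramModel, mean: float):
    """Simple-kriging conditional mean/variance at one point (covariance form)."""
    d_t = np.linalg.norm(nb_xy - target, axis=1)
    c_t = model.covariance(d_t)
    d_nb = np.linalg.norm(nb_xy[:, None, :] - nb_xy[None, :, :], axis=-1)
    C = model.covariance(d_nb)
    np.fill_diagonal(C, model.sill + 1e-10 * max(model.sill, 1.0))
    try:
        lam = np.linalg.solve(C, c_t)
    except np.linalg.LinAlgError:
        lam = np.linalg.lstsq(C, c_t, rcond=None)[0]
    mu = mean + lam @ (nb_z - mean)
    var = max(float(model.sill - lam @ c_t), 0.0)
    return mu, var


# ---------------------------------------------------------------------------
# sequential Gaussian conditional simulation


@dataclass
class RealizationStack:
    realizations: list[Raster]
    model: VariogramModel
    seed: int

    def __post_init__(self) -> None:
        grids = {r.grid for r in self.realizations}
        if len(grids) > 1:
            raise ValueError("realizations must share one grid")

    def as_array(self) -> np.ndarray:
        return np.stack([r.values for r in self.realizations])

    def mean_raster(self) -> Raster:
        return self.realizations[0].copy_with(self.as_array().mean(axis=0))


class _NormalScore:
    """Empirical normal-score transform with linear interpolation and
    linear tail extrapolation on the back-transform."""

    def __init__(self, values: np.ndarray):
        order = np.argsort(values, kind="stable")
        self.sorted_vals = values[order]
        n = values.size
        from scipy.stats import norm

        p = (np.arange(1, n + 1) - 0.5) / n
        self.scores = norm.ppf(p)
        # forward mapping for the data themselves
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(n)
        self.data_scores = self.scores[ranks]

    def backward(self, y):
        return np.interp(y, self.scores, self.sorted_vals)


def sgcs(
    obs_xy,
    obs_z,
    grid: GridSpec,
    model: VariogramModel,
    n_realizations: int = 100,
    seed: int = 0,
    max_neighbors: int = 16,
    transform: str = "normal",
) -> RealizationStack:
    """Sequential Gaussian conditional simulation on the grid.

    Visits cells along a seeded random path; at each cell the conditional
    mean/variance come from simple kriging on the nearest conditioning data
    (observations plus previously simulated cells) and a Gaussian residual is
    drawn. Observation cells are assigned their (transformed) data values, so
    every realization honors the data. ``transform='normal'`` applies the
    empirical normal-score transform first (``'none'`` simulates the raw
    values directly, appropriate when they are already Gaussian).

    Randomness for realization ``i`` derives from ``(seed, i)`` so stacks are
    reproducible and extensible.
    """
    if n_realizations < 1:
        raise ValueError("need at least one realization")
    xy = np.asarray(obs_xy, dtype=float).reshape(-1, 2)
    z = np.asarray(obs_z, dtype=float)
    xy, z = _dedupe_obs(xy, z)

    if model.sill == 0:
        warnings.warn("zero-sill model: realizations are a constant surface")
        const = np.full(grid.shape, float(z.mean()))
        rasters = [Raster(grid, const.copy()) for _ in range(n_realizations)]
        return RealizationStack(rasters, model, seed)

    if transform == "normal":
        ns = _NormalScore(z)
        zg = ns.data_scores
        g_model = VariogramModel(model.kind, model.structural_ratio, 1.0 - model.structural_ratio, model.range_m)
        g_mean = 0.0
    elif transform == "none":
        ns = None
        zg = z
        g_model = model
        g_mean = float(z.mean())
    else:
        raise ValueError(f"unknown transform {transform!r}")

    xs, ys = grid.center_mesh()
    cells = np.column_stack([xs.ravel(), ys.ravel()])
    n_cells = cells.shape[0]

    # conditioning data snapped to cells: a cell containing an observation is
    # fixed at the (averaged) observed value in every realization
    row, col = grid.cell_of(xy[:, 0], xy[:, 1])
    inside = (row >= 0) & (row < grid.n_rows) & (col >= 0) & (col < grid.n_cols)
    flat = row[inside] * grid.n_cols + col[inside]
    fixed_vals = np.full(n_cells, np.nan)
    sums = np.bincount(flat, weights=zg[inside], minlength=n_cells)
    cnts = np.bincount(flat, minlength=n_cells)
    has = cnts > 0
    fixed_vals[has] = sums[has] / cnts[has]
    free = np.nonzero(~has)[0]

    tree_all = cKDTree(cells)
    fixed_idx = np.nonzero(has)[0]
    tree_fixed = cKDTree(cells[fixed_idx]) if fixed_idx.size else None
    k_search = min(4 * max_neighbors + 1, n_cells)

    rasters = []
    for r_i in range(n_realizations):
        rng = np.random.default_rng([seed, r_i])
        sim = fixed_vals.copy()
        known = has.copy()
        path = free.copy()
        rng.shuffle(path)
        for c_i in path:
            _, ii = tree_all.query(cells[c_i], k=k_search)
            ii = np.atleast_1d(ii)
            nb = ii[known[ii]][:max_neighbors]
            if nb.size == 0 and tree_fixed is not None:
                # early in the path: condition on the nearest data cells
                k = min(max_neighbors, fixed_idx.size)
                _, jj = tree_fixed.query(cells[c_i], k=k)
                nb = fixed_idx[np.atleast_1d(jj)]
            if nb.size == 0:
                mu, var = g_mean, g_model.sill
            else:
                mu, var = _simple_kriging_point(
                    cells[c_i], cells[nb], sim[nb], g_model, g_mean
                )
            sim[c_i] = mu + np.sqrt(var) * rng.standard_normal()
            known[c_i] = True
        vals = sim if ns is None else ns.backward(sim)
        rasters.append(Raster(grid, vals.reshape(grid.shape).copy()))
    return RealizationStack(rasters, model, seed)


def realization_cv(stack: RealizationStack, epsilon: float = 1e-9) -> float:
    """Global coefficient of variation: spatial mean of per-cell sd/|mean|
    across realizations, skipping cells whose |mean| is below ``epsilon``."""
    arr = stack.as_array()
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 realizations for a CV")
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    ok = np.abs(mean) > epsilon
    if not ok.any():
        return 0.0
    return float(np.mean(sd[ok] / np.abs(mean[ok])))


def select_convergent_n(
    obs_xy,
    obs_z,
    grid: GridSpec,
    model: VariogramModel,
    candidate_ns,
    tol: float,
    seed: int = 0,
    **sgcs_kwargs,
):
    """Smallest realization count at which the global CV stabilizes.

    Returns ``(chosen_n, cv_trace, converged)``; if no successive pair is
    within ``tol``, the largest candidate is returned with ``converged=False``.
    Realizations are shared across candidates (the stack is grown, not
    regenerated), matching how the convergence check is run in practice.
    """
    candidate_ns = list(candidate_ns)
    if len(candidate_ns) < 2:
        raise ValueError("need at least two candidate realization counts")
    if any(b <= a for a, b in zip(candidate_ns, candidate_ns[1:])):
        raise ValueError("candidate counts must be strictly increasing")
    full = sgcs(obs_xy, obs_z, grid, model, candidate_ns[-1], seed, **sgcs_kwargs)
    trace = {}
    for n in candidate_ns:
        sub = RealizationStack(full.realizations[:n], model, seed)
        trace[n] = realization_cv(sub)
    for prev, n in zip(candidate_ns, candidate_ns[1:]):
        if abs(trace[n] - trace[prev]) <= tol:
            return n, trace, True
    return candidate_ns[-1], trace, False


# ---------------------------------------------------------------------------
# inverse distance weighting


def idw(obs_xy, obs_z, targets, beta: float = 2.0, k_neighbors: int | None = None):
    """IDW prediction with weights d^(-beta); a target at an observation
    returns the observed value exactly."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    xy = np.asarray(obs_xy, dtype=float).reshape(-1, 2)
    z = np.asarray(obs_z, dtype=float)
    if xy.shape[0] == 0:
        raise ValueError("no observations")
    pts, out_grid = _targets_to_points(targets)
    k = xy.shape[0] if k_neighbors is None else min(k_neighbors, xy.shape[0])
    tree = cKDTree(xy)
    dist, idx = tree.query(pts, k=k)
    dist = np.atleast_2d(dist)
    idx = np.atleast_2d(idx)
    with np.errstate(divide="ignore", over="ignore"):
        w = dist ** (-beta)
    exact = dist[:, 0] < 1e-9
    pred = np.empty(pts.shape[0])
    finite_w = np.where(np.isfinite(w), w, 0.0)
    denom = finite_w.sum(axis=1)
    safe = ~exact & (denom > 0)
    pred[safe] = (finite_w[safe] * z[idx[safe]]).sum(axis=1) / denom[safe]
    pred[exact] = z[idx[exact, 0]]
    if out_grid is not None:
        return Raster(out_grid, pred.reshape(out_grid.shape))
    return pred


@dataclass
class IDWOptimizerConfig:
    method: str = "grid"
    beta_init: tuple[float, float] = (0.1, 5.0)
    beta_bounds: tuple[float, float] = (0.1, 10.0)
    swarm_size: int = 15
    pso_iters: int = 50
    inertia: float = 0.8
    c1: float = 1.5
    c2: float = 1.5
    ga_pop: int = 15
    ga_gens: int = 50
    p_crossover: float = 0.8
    p_mutation: float = 0.1
    grid_lo: float = 0.5
    grid_hi: float = 5.0
    grid_step: float = 0.1
    cv_folds: int = 5
    k_neighbors: int | None = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in {"pso", "ga", "grid"}:
            raise ValueError(f"unknown optimizer method {self.method!r}")
        if self.cv_folds < 2:
            raise ValueError("need at least 2 CV folds")
        lo, hi = self.beta_bounds
        if not (lo <= self.beta_init[0] and self.beta_init[1] <= hi):
            raise ValueError("beta bounds must contain the init range")


def _cv_rmse(xy, z, beta, folds, seed, k_neighbors):
    rng = np.random.default_rng(seed)
    n = xy.shape[0]
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[order] = np.arange(n) % folds
    sq = 0.0
    for f in range(folds):
        test = fold_of == f
        pred = idw(xy[~test], z[~test], xy[test], beta, k_neighbors)
        sq += float(np.sum((pred - z[test]) ** 2))
    return np.sqrt(sq / n)


def optimize_beta(obs_xy, obs_z, config: IDWOptimizerConfig):
    """Tune the IDW exponent by minimizing 5-fold CV RMSE.

    Returns ``(beta_star, trace)`` where the trace lists every
    ``(beta, objective)`` evaluation. The fold assignment is fixed by
    ``config.seed`` so all three optimizers face the same objective.
    """
    xy = np.asarray(obs_xy, dtype=float).reshape(-1, 2)
    z = np.asarray(obs_z, dtype=float)
    if xy.shape[0] < config.cv_folds:
        raise ValueError("need at least cv_folds observations")
    lo, hi = config.beta_bounds
    if np.ptp(z) == 0:
        warnings.warn("constant observation values: objective is degenerate")
        return lo, [(lo, 0.0)]

    cache: dict[float, float] = {}
    trace: list[tuple[float, float]] = []

    def objective(beta: float) -> float:
        beta = float(np.clip(beta, lo, hi))
        key = round(beta, 12)
        if key not in cache:
            cache[key] = _cv_rmse(xy, z, beta, config.cv_folds, config.seed, config.k_neighbors)
        trace.append((beta, cache[key]))
        return cache[key]

    rng = np.random.default_rng(config.seed)

    if config.method == "grid":
        n_steps = int(round((config.grid_hi - config.grid_lo) / config.grid_step))
        betas = config.grid_lo + config.grid_step * np.arange(n_steps + 1)
        vals = [objective(b) for b in betas]
        best = int(np.argmin(vals))  # argmin returns the first (lowest beta) tie
        return float(betas[best]), trace

    i_lo, i_hi = config.beta_init
    if config.method == "pso":
        pos = rng.uniform(i_lo, i_hi, config.swarm_size)
        vmax = hi - lo
        vel = rng.uniform(-vmax, vmax, config.swarm_size) * 0.1
        pbest = pos.copy()
        pcost = np.array([objective(p) for p in pos])
        g = int(np.argmin(pcost))
        gbest, gcost = pbest[g], pcost[g]
        for _ in range(config.pso_iters):
            r1 = rng.random(config.swarm_size)
            r2 = rng.random(config.swarm_size)
            vel = (
                config.inertia * vel
                + config.c1 * r1 * (pbest - pos)
                + config.c2 * r2 * (gbest - pos)
            )
            vel = np.clip(vel, -vmax, vmax)
            pos = np.clip(pos + vel, lo, hi)
            cost = np.array([objective(p) for p in pos])
            better = cost < pcost
            pbest[better] = pos[better]
            pcost[better] = cost[better]
            g = int(np.argmin(pcost))
            if pcost[g] < gcost:
                gbest, gcost = pbest[g], pcost[g]
        return float(gbest), trace

    # genetic algorithm: real-valued gene, tournament selection (size 2),
    # blend crossover, Gaussian mutation with sd = 5% of the bound width
    pop = rng.uniform(i_lo, i_hi, config.ga_pop)
    fit = np.array([objective(p) for p in pop])
    sd_mut = 0.05 * (hi - lo)
    best_b, best_f = float(pop[np.argmin(fit)]), float(fit.min())
    for _ in range(config.ga_gens):
        children = np.empty(config.ga_pop)
        for i in range(config.ga_pop):
            a, b = rng.integers(0, config.ga_pop, 2)
            p1 = pop[a] if fit[a] <= fit[b] else pop[b]
            a, b = rng.integers(0, config.ga_pop, 2)
            p2 = pop[a] if fit[a] <= fit[b] else pop[b]
            if rng.random() < config.p_crossover:
                alpha = rng.random()
                child = alpha * p1 + (1 - alpha) * p2
            else:
                child = p1
            if rng.random() < config.p_mutation:
                child += rng.normal(0, sd_mut)
            children[i] = np.clip(child, lo, hi)
        pop = children
        fit = np.array([objective(p) for p in pop])
        i = int(np.argmin(fit))
        if fit[i] < best_f:
            best_b, best_f = float(pop[i]), float(fit[i])
        # elitism: keep the best-so-far alive
        j = int(np.argmax(fit))
        pop[j], fit[j] = best_b, best_f
    return best_b, trace


# ---------------------------------------------------------------------------
# evaluation and harmonization


@dataclass
class InterpolationReport:
    metric: str
    method: str
    r2_test: float
    n_train: int
    n_test: int
    retained: bool

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "method": self.method,
            "r2_test": self.r2_test,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "retained": self.retained,
        }


METHODS = ("ok", "sgcs", "idw", "pso-idw", "ga-idw", "gs-idw")


def _predict_method(method, train_xy, train_z, test_xy, model, n_realizations, seed, grid):
    if method == "ok":
        return ordinary_kriging(train_xy, train_z, test_xy, model).estimates
    if method == "sgcs":
        if grid is None:
            raise ValueError("sgcs evaluation needs a grid to simulate on")
        stack = sgcs(train_xy, train_z, grid, model, n_realizations, seed)
        return np.atleast_1d(stack.mean_raster().sample(test_xy[:, 0], test_xy[:, 1]))
    if method == "idw":
        return idw(train_xy, train_z, test_xy, beta=2.0, k_neighbors=15)
    optimizer = {"pso-idw": "pso", "ga-idw": "ga", "gs-idw": "grid"}[method]
    cfg = IDWOptimizerConfig(method=optimizer, seed=seed)
    beta, _ = optimize_beta(train_xy, train_z, cfg)
    return idw(train_xy, train_z, test_xy, beta=beta, k_neighbors=15)


def evaluate_interpolation(
    footprints: pd.DataFrame,
    metric: str,
    method: str,
    model: VariogramModel | None = None,
    grid: GridSpec | None = None,
    split_frac: float = 0.8,
    threshold: float = 0.5,
    n_realizations: int = 25,
    seed: int = 0,
) -> InterpolationReport:
    """Seeded 80/20 split, fit on train, R² at the held-out footprints.

    ``retained`` is True iff the test R² reaches ``threshold``.
    """
    if method not in METHODS:
        raise ValueError(f"unknown interpolation method {method!r}")
    n = len(footprints)
    if n < 10:
        raise ValueError("need at least 10 footprints to evaluate")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(split_frac * n))
    train, test = perm[:n_train], perm[n_train:]
    xy = footprints[["x", "y"]].to_numpy(float)
    z = footprints[metric].to_numpy(float)
    if model is None and method in {"ok", "sgcs"}:
        from .variogram import empirical_variogram, fit_variogram

        ev = empirical_variogram(footprints.iloc[train], metric)
        model = fit_variogram(ev)[0].model
    pred = _predict_method(
        method, xy[train], z[train], xy[test], model, n_realizations, seed, grid
    )
    pred = np.asarray(pred, dtype=float)
    ok = np.isfinite(pred)
    r2 = r_squared(z[test][ok], pred[ok])
    return InterpolationReport(
        metric=metric,
        method=method,
        r2_test=r2,
        n_train=len(train),
        n_test=len(test),
        retained=bool(r2 >= threshold),
    )


def resample_nearest(raster: Raster, target: GridSpec) -> Raster:
    """Nearest-neighbor harmonization onto ``target``: every output cell takes
    the value of the nearest source cell center, so no new values appear."""
    g = raster.grid
    xs, ys = target.center_mesh()
    col = np.round((xs - g.origin_x) / g.cell_size - 0.5).astype(int)
    row = np.round((g.origin_y - ys) / g.cell_size - 0.5).astype(int)
    out = np.full(target.shape, raster.nodata)
    ok = (row >= 0) & (row < g.n_rows) & (col >= 0) & (col < g.n_cols)
    if not ok.any():
        warnings.warn("disjoint extents: resampled raster is all nodata")
        return Raster(target, out, raster.nodata)
    out[ok] = raster.values[row[ok], col[ok]]
    return Raster(target, out, raster.nodata)
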
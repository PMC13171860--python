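"""Empirical semivariograms, theoretical model fitting and spatial-dependence classes.

Theoretical models are parameterized by nugget ``c0``, partial sill ``c`` and
``range_m``. For the exponential and Gaussian kinds ``range_m`` is the
*effective* range: the lag at which the curve reaches 95% of the sill.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist

__all__ = [
    "VariogramModel",
    "EmpiricalVariogram",
    "VariogramFitReport",
    "empirical_variogram",
    "fit_variogram",
    "classify_spatial_dependence",
    "semivariance",
]

MODEL_KINDS = ("spherical", "exponential", "gaussian")


@dataclass(frozen=True)
class VariogramModel:
    kind: str
    nugget: float
    partial_sill: float
    range_m: float

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown variogram kind {self.kind!r}")
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValueError("nugget and partial sill must be non-negative")
        if self.range_m <= 0:
            raise ValueError("range must be positive")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    @property
    def structural_ratio(self) -> float:
        """Nugget-to-sill ratio C0/(C0+C); 0 for the degenerate zero-sill model."""
        if self.sill == 0:
            return 0.0
        return self.nugget / self.sill

    def __call__(self, h):
        return semivariance(self, h)

    def covariance(self, h):
        """Covariance C(h) = sill - gamma(h) of the associated stationary field."""
        return self.sill - semivariance(self, h)


def semivariance(model: VariogramModel, h):
    """Closed-form gamma(h); gamma(0) = 0 exactly for every kind.

    The spherical model reaches the sill exactly at ``range_m``; exponential
    and Gaussian reach 95% of it there (effective-range convention).
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("lag distances must be non-negative")
    c0, c, a = model.nugget, model.partial_sill, model.range_m
    if model.kind == "spherical":
        hr = np.clip(h / a, 0.0, 1.0)
        struct = c * (1.5 * hr - 0.5 * hr**3)
    elif model.kind == "exponential":
        struct = c * (1.0 - np.exp(-3.0 * h / a))
    else:  # gaussian
        struct = c * (1.0 - np.exp(-3.0 * (h / a) ** 2))
    gamma = np.where(h > 0, c0 + struct, 0.0)
    return gamma if gamma.ndim else float(gamma)


@dataclass
class EmpiricalVariogram:
    lag_centers: np.ndarray
    semivariances: np.ndarray
    pair_counts: np.ndarray

    def __post_init__(self) -> None:
        self.lag_centers = np.asarray(self.lag_centers, dtype=float)
        self.semivariances = np.asarray(self.semivariances, dtype=float)
        self.pair_counts = np.asarray(self.pair_counts, dtype=int)
        if np.any(np.diff(self.lag_centers) <= 0):
            raise ValueError("lag centers must be strictly increasing")
        if np.any(self.semivariances < 0) or np.any(self.pair_counts < 0):
            raise ValueError("semivariances and pair counts must be non-negative")


@dataclass
class VariogramFitReport:
    model: VariogramModel
    r2: float
    rss: float

    def to_dict(self) -> dict:
        m = self.model
        return {
            "kind": m.kind,
            "nugget": m.nugget,
            "partial_sill": m.partial_sill,
            "range_m": m.range_m,
            "sill": m.sill,
            "structural_ratio": m.structural_ratio,
            "category": classify_spatial_dependence(m),
            "r2": self.r2,
            "rss": self.rss,
        }


def _extract_xyz(points, metric: str | None):
    if isinstance(points, pd.DataFrame):
        x = points["x"].to_numpy(float)
        y = points["y"].to_numpy(float)
        z = points[metric].to_numpy(float)
    else:
        x, y, z = (np.asarray(a, dtype=float) for a in points)
    return x, y, z


def empirical_variogram(
    points,
    metric: str | None = None,
    lag_width: float | None = None,
    max_lag: float | None = None,
) -> EmpiricalVariogram:
    """Matheron estimator binned into lag classes of width ``lag_width``.

    ``points`` is a DataFrame with x/y columns plus the named metric, or an
    ``(x, y, z)`` triple. Bins with no pairs are dropped. Defaults: lag width
    = half the mean nearest-neighbor spacing, max lag = half the domain
    diagonal.
    """
    x, y, z = _extract_xyz(points, metric)
    if x.size < 2:
        raise ValueError("need at least two points")
    xy = np.column_stack([x, y])
    d = pdist(xy)
    if np.all(d == 0):
        raise ValueError("all points coincident: no positive lags")
    if max_lag is None:
        span = np.hypot(x.max() - x.min(), y.max() - y.min())
        max_lag = span / 2.0
    if lag_width is None:
        from scipy.spatial import cKDTree

        nn = cKDTree(xy).query(xy, k=2)[0][:, 1]
        lag_width = max(float(np.mean(nn)) / 2.0, 1e-12)
    if lag_width <= 0:
        raise ValueError("lag_width must be positive")

    sq = pdist(z[:, None], metric="sqeuclidean")
    keep = (d > 0) & (d <= max_lag)
    d = d[keep]
    sq = sq[keep]
    bins = np.floor(d / lag_width).astype(int)
    n_bins = int(bins.max()) + 1 if bins.size else 0
    counts = np.bincount(bins, minlength=n_bins)
    sums = np.bincount(bins, weights=sq, minlength=n_bins)
    occupied = counts > 0
    gamma = sums[occupied] / (2.0 * counts[occupied])
    centers = (np.nonzero(occupied)[0] + 0.5) * lag_width
    return EmpiricalVariogram(centers, gamma, counts[occupied])


def _fit_one_kind(ev: EmpiricalVariogram, kind: str, weighted: bool):
    h = ev.lag_centers
    g = ev.semivariances
    w = np.sqrt(ev.pair_counts.astype(float)) if weighted else np.ones_like(g)

    sill0 = max(float(np.mean(g[-max(1, len(g) // 3):])), 1e-12)
    hmax = float(h.max())

    def residuals(theta):
        c0, c, a = theta
        m = VariogramModel(kind, max(c0, 0.0), max(c, 0.0), max(a, 1e-9))
        return w * (semivariance(m, h) - g)

    best = None
    # deterministic multi-start over plausible ranges
    for a0 in (hmax / 4, hmax / 2, hmax):
        for f0 in (0.0, 0.25, 0.5):
            x0 = np.array([f0 * sill0, (1 - f0) * sill0, a0])
            try:
                sol = least_squares(
                    residuals,
                    x0,
                    bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, 100 * hmax]),
                    method="trf",
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise RuntimeError(f"optimizer failed for kind {kind!r}")
    c0, c, a = best.x
    model = VariogramModel(kind, float(c0), float(c), float(a))
    resid = semivariance(model, h) - g
    rss = float(np.sum(resid**2))
    tss = float(np.sum((g - g.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else -np.inf)
    return VariogramFitReport(model, r2, rss)


def fit_variogram(
    ev: EmpiricalVariogram,
    kinds=MODEL_KINDS,
    weighted: bool = True,
):
    """Least-squares fit of each candidate kind; returns (best, all candidates).

    Weighted fits use Cressie-style pair-count weights. Best = highest R²,
    ties broken by lower RSS then by the order spherical, exponential,
    gaussian.
    """
    if len(ev.lag_centers) < 4:
        raise ValueError("need at least 4 usable lags to fit a variogram")
    candidates: dict[str, VariogramFitReport | None] = {}
    for kind in MODEL_KINDS:
        if kind not in kinds:
            continue
        try:
            candidates[kind] = _fit_one_kind(ev, kind, weighted)
        except Exception:
            candidates[kind] = None  # flagged failure; others still returned
    fitted = [(k, rep) for k, rep in candidates.items() if rep is not None]
    if not fitted:
        raise RuntimeError("all variogram model fits failed")
    order = {k: i for i, k in enumerate(MODEL_KINDS)}
    best = min(fitted, key=lambda kr: (-kr[1].r2, kr[1].rss, order[kr[0]]))[1]
    return best, candidates


def classify_spatial_dependence(m: VariogramModel) -> str:
    """Nugget-to-sill ratio < 0.25 -> strong, <= 0.75 -> moderate, else weak."""
    ratio = m.structural_ratio
    if ratio < 0.25:
        return "strong"
    if ratio <= 0.75:
        return "moderate"
    return "weak"
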
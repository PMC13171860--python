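"""Synthetic inputs: autocorrelated fields, track-sampled footprints, plots, QC.

The generators make every downstream stage testable offline. Footprints are
laid out on parallel tracks mimicking spaceborne-LiDAR sampling (~60 m
along-track, ~600 m across-track); plot volumes are a documented nonlinear
response of the structural fields.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .grids import GridSpec, Raster
from .variogram import VariogramModel, semivariance

__all__ = [
    "simulate_gaussian_field",
    "sample_footprints",
    "simulate_plots",
    "filter_footprints",
    "default_plot_response",
]

_CHOLESKY_MAX_CELLS = 10_000


def _cholesky_field(grid: GridSpec, model: VariogramModel, rng) -> np.ndarray:
    xs, ys = grid.center_mesh()
    pts = np.column_stack([xs.ravel(), ys.ravel()])
    from scipy.spatial.distance import cdist

    h = cdist(pts, pts)
    cov = model.covariance(h)
    # nugget acts only at exactly zero lag
    np.fill_diagonal(cov, model.sill)
    # jitter for numerical positive-definiteness
    cov[np.diag_indices_from(cov)] += 1e-10 * max(model.sill, 1.0)
    L = np.linalg.cholesky(cov)
    z = L @ rng.standard_normal(pts.shape[0])
    return z.reshape(grid.shape)


def _circulant_field(grid: GridSpec, model: VariogramModel, rng) -> np.ndarray:
    """Approximate circulant-embedding simulation for large grids.

    Negative embedding eigenvalues are clamped to zero and the field is
    rescaled to the model sill; adequate for fixture generation.
    """
    n, m = grid.n_rows, grid.n_cols
    N, M = 2 * n, 2 * m
    dr = np.minimum(np.arange(N), N - np.arange(N)) * grid.cell_size
    dc = np.minimum(np.arange(M), M - np.arange(M)) * grid.cell_size
    h = np.hypot(dr[:, None], dc[None, :])
    cov = model.covariance(h)
    cov[0, 0] = model.sill
    lam = np.fft.fft2(cov).real
    neg = lam < 0
    if neg.any():
        lam = np.where(neg, 0.0, lam)
    noise = rng.standard_normal((N, M)) + 1j * rng.standard_normal((N, M))
    fld = np.fft.fft2(np.sqrt(lam / (N * M)) * noise).real[:n, :m]
    sd = fld.std()
    if sd > 0:
        fld *= np.sqrt(model.sill) / sd
    return fld


def simulate_gaussian_field(
    grid: GridSpec, model: VariogramModel, mean: float = 0.0, seed: int = 0
) -> Raster:
    """Stationary Gaussian random field whose variogram equals ``model``.

    Exact dense-Cholesky factorization for grids up to ~10^4 cells; a
    circulant-embedding FFT method (documented approximation) above that.
    Identical arguments give bit-identical output.
    """
    rng = np.random.default_rng(seed)
    if model.sill == 0:
        return Raster(grid, np.full(grid.shape, float(mean)))
    n_cells = grid.n_rows * grid.n_cols
    if n_cells <= _CHOLESKY_MAX_CELLS:
        z = _cholesky_field(grid, model, rng)
    else:
        z = _circulant_field(grid, model, rng)
    return Raster(grid, z + mean)


def _as_field_dict(fields) -> dict[str, Raster]:
    if isinstance(fields, Raster):
        return {"value": fields}
    return dict(fields)


def sample_footprints(
    fields,
    grid: GridSpec | None = None,
    along_m: float = 60.0,
    across_m: float = 600.0,
    noise_sd: float = 0.0,
    qc_fail_fraction: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample the fields at footprints on parallel tracks.

    Tracks run at a small random orientation with random phase; each metric is
    the field value at the footprint center plus N(0, noise_sd) noise. A
    ``qc_fail_fraction`` of footprints is given failing sensitivity or
    quality_flag so the QC filter has something to remove.
    """
    fields = _as_field_dict(fields)
    if grid is None:
        grid = next(iter(fields.values())).grid
    for name, r in fields.items():
        if r.grid != grid:
            raise ValueError(f"field {name!r} is not on the common grid")
    rng = np.random.default_rng(seed)

    width, height = grid.width_m, grid.height_m
    if across_m > max(width, height) or along_m > max(width, height):
        warnings.warn("track spacing exceeds grid extent; returning empty table")
        return _empty_footprint_table(fields)

    theta = rng.uniform(-0.05, 0.05)  # near-vertical tracks, slight tilt
    phase_across = rng.uniform(0, across_m)
    phase_along = rng.uniform(0, along_m)

    cx = grid.origin_x + width / 2.0
    cy = grid.origin_y - height / 2.0
    diag = np.hypot(width, height)
    u = np.arange(-diag / 2 + phase_across, diag / 2, across_m)  # across-track
    v = np.arange(-diag / 2 + phase_along, diag / 2, along_m)  # along-track
    uu, vv = np.meshgrid(u, v, indexing="ij")
    # track direction (sin t, cos t): v runs along-track, u across
    x = cx + uu * np.cos(theta) + vv * np.sin(theta)
    y = cy - uu * np.sin(theta) + vv * np.cos(theta)
    x, y = x.ravel(), y.ravel()
    inside = grid.contains(x, y)
    x, y = x[inside], y[inside]
    n = x.size
    if n == 0:
        warnings.warn("no footprints fell inside the grid")
        return _empty_footprint_table(fields)

    rec: dict[str, np.ndarray] = {
        "id": np.array([f"fp{i:06d}" for i in range(n)]),
        "x": x,
        "y": y,
    }
    for name, r in fields.items():
        vals = np.atleast_1d(r.sample(x, y))
        if noise_sd > 0:
            vals = vals + rng.normal(0.0, noise_sd, size=n)
        rec[name] = vals

    fail = rng.random(n) < qc_fail_fraction
    sensitivity = np.where(fail, rng.uniform(0.5, 0.9, n), rng.uniform(0.901, 1.0, n))
    quality = np.ones(n, dtype=int)
    # half of the failing records fail via the quality flag instead
    flag_fail = fail & (rng.random(n) < 0.5)
    sensitivity[flag_fail] = rng.uniform(0.901, 1.0, flag_fail.sum())
    quality[flag_fail] = 0
    rec["sensitivity"] = sensitivity
    rec["quality_flag"] = quality
    df = pd.DataFrame(rec)
    df.attrs["track_theta"] = float(theta)
    df.attrs["phase_across"] = float(phase_across)
    df.attrs["phase_along"] = float(phase_along)
    df.attrs["seed"] = int(seed)
    return df


def _empty_footprint_table(fields) -> pd.DataFrame:
    cols = ["id", "x", "y", *fields.keys(), "sensitivity", "quality_flag"]
    return pd.DataFrame({c: [] for c in cols})


def default_plot_response(height: np.ndarray, cover: np.ndarray) -> np.ndarray:
    """Documented nonlinear volume response used by the default generator.

    A saturating function of a height-like field scaled by a cover-like
    fraction: ``300 * (1 - exp(-height/15)) * clip(cover, 0, 1)``, in m³/ha.
    """
    return 300.0 * (1.0 - np.exp(-np.asarray(height) / 15.0)) * np.clip(cover, 0.0, 1.0)


def simulate_plots(
    fields,
    n: int,
    coeffs=None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Plots uniform over the grid with volume = g(fields at location) + noise.

    ``coeffs`` is a callable mapping the dict of sampled field values to
    volume per ha; the default expects fields named ``height`` and ``cover``
    and applies :func:`default_plot_response`. Volumes are clipped at 0.
    """
    fields = _as_field_dict(fields)
    grid = next(iter(fields.values())).grid
    if n < 1:
        raise ValueError("n must be at least 1")
    if n > grid.n_rows * grid.n_cols:
        raise ValueError("more plots requested than grid cells")
    rng = np.random.default_rng(seed)
    x = rng.uniform(grid.origin_x, grid.origin_x + grid.width_m, n)
    y = rng.uniform(grid.origin_y - grid.height_m, grid.origin_y, n)
    sampled = {name: np.atleast_1d(r.sample(x, y)) for name, r in fields.items()}
    if coeffs is None:
        vol = default_plot_response(sampled["height"], sampled["cover"])
    else:
        vol = np.asarray(coeffs(sampled), dtype=float)
    if noise_sd > 0:
        vol = vol + rng.normal(0.0, noise_sd, n)
    vol = np.clip(vol, 0.0, None)
    mean_dbh = np.clip(8.0 + 0.15 * vol + rng.normal(0, 1.0, n), 5.0, None)
    return pd.DataFrame(
        {
            "id": [f"plot{i:04d}" for i in range(n)],
            "x": x,
            "y": y,
            "mean_dbh": mean_dbh,
            "volume_per_ha": vol,
        }
    )


def filter_footprints(
    table: pd.DataFrame,
    sensitivity_min: float = 0.9,
    require_quality: bool = True,
) -> pd.DataFrame:
    """Retain records with sensitivity strictly above the threshold and, if
    required, quality_flag == 1. Row order is preserved; idempotent."""
    for col in ("sensitivity", "quality_flag"):
        if col not in table.columns:
            raise KeyError(f"footprint table lacks required column {col!r}")
    keep = table["sensitivity"] > sensitivity_min
    if require_quality:
        keep &= table["quality_flag"] == 1
    return table.loc[keep].copy()
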
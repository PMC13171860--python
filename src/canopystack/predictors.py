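"""Optical, texture and terrain predictor derivation plus the two-stage
(VIF then SHAP) feature screen.

Band inputs are surface reflectance on the common grid. Vegetation indices
use the standard published formulas (SAVI soil factor L = 0.5; EVI
coefficients G = 2.5, C1 = 6, C2 = 7.5, L = 1). Texture features are the
eight gray-level co-occurrence statistics commonly used in forestry work:
mean, variance, homogeneity, contrast, dissimilarity, entropy, angular
second moment and correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.feature import graycomatrix

from .grids import GridSpec, Raster
from ._treeshap import expected_value, tree_shap_values

__all__ = [
    "scale_reflectance",
    "vegetation_indices",
    "glcm_textures",
    "terrain",
    "extract_at_points",
    "assemble_candidate_rasters",
    "vif_select",
    "shap_rank",
    "SelectionReport",
    "INDEX_NAMES",
    "TEXTURE_NAMES",
]

REFLECTANCE_SCALE = 0.0000275
REFLECTANCE_OFFSET = -0.2

INDEX_NAMES = (
    "ndvi", "dvi", "rvi", "evi", "savi", "arvi", "tvi", "rdvi", "vdvi", "ngbdi", "npci",
)
TEXTURE_NAMES = (
    "mean", "variance", "homogeneity", "contrast",
    "dissimilarity", "entropy", "asm", "correlation",
)


def scale_reflectance(dn):
    """Digital number -> surface reflectance: 0.0000275 * dn - 0.2."""
    dn = np.asarray(dn, dtype=float)
    out = REFLECTANCE_SCALE * dn + REFLECTANCE_OFFSET
    return out if out.ndim else float(out)


def _safe_div(num, den):
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den
    out[~np.isfinite(out)] = np.nan
    return out


def vegetation_indices(bands: dict[str, Raster]) -> dict[str, Raster]:
    """The 11 spectral indices, from blue/green/red/nir reflectance rasters.

    Division-by-zero cells become nodata (NaN) in the affected index.
    """
    for required in ("blue", "green", "red", "nir"):
        if required not in bands:
            raise KeyError(f"vegetation indices need band {required!r}")
    b = bands["blue"].masked()
    g = bands["green"].masked()
    r = bands["red"].masked()
    nir = bands["nir"].masked()
    grid = bands["nir"].grid

    out = {
        "ndvi": _safe_div(nir - r, nir + r),
        "dvi": nir - r,
        "rvi": _safe_div(nir, r),
        "evi": _safe_div(2.5 * (nir - r), nir + 6.0 * r - 7.5 * b + 1.0),
        "savi": _safe_div(1.5 * (nir - r), nir + r + 0.5),
        "arvi": _safe_div(nir - (2 * r - b), nir + (2 * r - b)),
        "tvi": 0.5 * (120.0 * (nir - g) - 200.0 * (r - g)),
        "rdvi": _safe_div(nir - r, np.sqrt(np.clip(nir + r, 0, None))),
        "vdvi": _safe_div(2 * g - r - b, 2 * g + r + b),
        "ngbdi": _safe_div(g - b, g + b),
        "npci": _safe_div(r - b, r + b),
    }
    return {name: Raster(grid, vals, nodata=np.nan) for name, vals in out.items()}


def _glcm_features(P: np.ndarray) -> dict[str, float]:
    """The eight statistics of one normalized symmetric co-occurrence matrix."""
    levels = P.shape[0]
    i = np.arange(levels)[:, None]
    j = np.arange(levels)[None, :]
    mean = float(np.sum(i * P))
    var = float(np.sum((i - mean) ** 2 * P))
    homogeneity = float(np.sum(P / (1.0 + (i - j) ** 2)))
    contrast = float(np.sum((i - j) ** 2 * P))
    dissimilarity = float(np.sum(np.abs(i - j) * P))
    pos = P[P > 0]
    entropy = float(-np.sum(pos * np.log(pos)))
    asm = float(np.sum(P**2))
    if var > 0:
        correlation = float(np.sum((i - mean) * (j - mean) * P) / var)
    else:
        correlation = 1.0  # constant window: perfect correlation by convention
    return {
        "mean": mean,
        "variance": var,
        "homogeneity": homogeneity,
        "contrast": contrast,
        "dissimilarity": dissimilarity,
        "entropy": entropy,
        "asm": asm,
        "correlation": correlation,
    }


def quantize(values: np.ndarray, levels: int) -> np.ndarray:
    """Linear quantization of a band to ``levels`` gray levels over its range."""
    lo = np.nanmin(values)
    hi = np.nanmax(values)
    if hi == lo:
        return np.zeros(values.shape, dtype=np.uint8)
    q = np.floor((values - lo) / (hi - lo) * levels).astype(int)
    return np.clip(q, 0, levels - 1).astype(np.uint8)


def glcm_textures(
    band: Raster,
    window: int = 5,
    levels: int = 64,
    displacement: int = 1,
) -> dict[str, Raster]:
    """Per-cell co-occurrence texture in a sliding window.

    The matrix is symmetric, normalized and averaged over the four
    orientations (0, 45, 90, 135 degrees) at the given displacement.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if levels < 2:
        raise ValueError("need at least 2 gray levels")
    n_rows, n_cols = band.grid.shape
    if window > n_rows or window > n_cols:
        raise ValueError("window larger than the raster")
    q = quantize(band.masked(), levels)
    half = window // 2
    padded = np.pad(q, half, mode="reflect")
    angles = [0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4]
    out = {name: np.empty((n_rows, n_cols)) for name in TEXTURE_NAMES}
    for r in range(n_rows):
        for c in range(n_cols):
            win = padded[r : r + window, c : c + window]
            glcm = graycomatrix(
                win, [displacement], angles, levels=levels, symmetric=True
            )[:, :, 0, :].sum(axis=-1).astype(float)
            total = glcm.sum()
            if total > 0:
                glcm /= total
            feats = _glcm_features(glcm)
            for name, val in feats.items():
                out[name][r, c] = val
    return {name: Raster(band.grid, vals, nodata=np.nan) for name, vals in out.items()}


def terrain(dem: Raster) -> dict[str, Raster]:
    """Slope (degrees) and aspect (degrees clockwise from north) by Horn's
    3x3 finite differences; flat cells get the aspect sentinel -1."""
    n_rows, n_cols = dem.grid.shape
    if n_rows < 3 or n_cols < 3:
        raise ValueError("DEM must be at least 3x3")
    z = np.pad(dem.masked(), 1, mode="edge")
    cell = dem.grid.cell_size

    nw, n_, ne = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    w_, e_ = z[1:-1, :-2], z[1:-1, 2:]
    sw, s_, se = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]

    gx = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8 * cell)  # d z / d east
    gy = ((nw + 2 * n_ + ne) - (sw + 2 * s_ + se)) / (8 * cell)  # d z / d north

    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    # aspect = compass bearing of the downhill vector (-gx, -gy)
    aspect = np.degrees(np.arctan2(-gx, -gy)) % 360.0
    flat = (gx == 0) & (gy == 0)
    aspect[flat] = -1.0
    return {
        "slope": Raster(dem.grid, slope, nodata=np.nan),
        "aspect": Raster(dem.grid, aspect, nodata=np.nan),
        "elevation": dem,
    }


def extract_at_points(rasters: dict[str, Raster], pts: pd.DataFrame) -> pd.DataFrame:
    """Cell-center lookup of every raster at the plot locations.

    Plots outside the grid extent (or over nodata in any layer) are dropped
    with a warning; remaining non-coordinate plot columns are carried along.
    """
    grids = {r.grid for r in rasters.values()}
    if len(grids) != 1:
        raise ValueError("all rasters must share one grid")
    x = pts["x"].to_numpy(float)
    y = pts["y"].to_numpy(float)
    cols = {name: np.atleast_1d(r.sample(x, y)) for name, r in rasters.items()}
    table = pd.DataFrame(cols, index=pts.index)
    keep = table.notna().all(axis=1)
    if not keep.all():
        warnings.warn(f"dropped {int((~keep).sum())} plots outside the valid extent")
    carried = pts.drop(columns=["x", "y"], errors="ignore")
    out = pd.concat([pts[["x", "y"]], table, carried], axis=1)
    out = out.loc[keep]
    out = out.loc[:, ~out.columns.duplicated()]
    if len(out) == 0:
        raise ValueError("no plots fall inside the raster extent")
    return out


DEFAULT_BAND_ROLES = {"blue": "b2", "green": "b3", "red": "b4", "nir": "b5"}


def assemble_candidate_rasters(
    gedi_surfaces: dict[str, Raster],
    bands: dict[str, Raster],
    dem: Raster,
    band_roles: dict[str, str] | None = None,
    glcm_kwargs: dict | None = None,
) -> dict[str, Raster]:
    """Assemble the full candidate predictor stack on one grid.

    Groups: gated LiDAR surfaces (prefixed ``gedi_``), three terrain
    derivatives, the single-band reflectances, the 11 spectral indices, and
    8 co-occurrence textures of the NIR band. With 6 gated surfaces and 7
    bands this yields 6 + 3 + 7 + 11 + 8 = 35 columns.
    """
    roles = band_roles or DEFAULT_BAND_ROLES
    named = {role: bands[bid] for role, bid in roles.items()}
    stack: dict[str, Raster] = {}
    for name, r in gedi_surfaces.items():
        stack[f"gedi_{name}"] = r
    stack.update(terrain(dem))
    for bid, r in bands.items():
        stack[bid] = r
    stack.update(vegetation_indices(named))
    textures = glcm_textures(named["nir"], **(glcm_kwargs or {}))
    for tname, r in textures.items():
        stack[f"tex_{tname}"] = r
    return stack


@dataclass
class SelectionReport:
    vif_trace: list[tuple[str, float]] = field(default_factory=list)
    retained_after_vif: list[str] = field(default_factory=list)
    final_vifs: dict[str, float] = field(default_factory=dict)
    shap_ranking: list[tuple[str, float]] = field(default_factory=list)
    final_features: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "vif_trace": [[n, v] for n, v in self.vif_trace],
            "retained_after_vif": self.retained_after_vif,
            "final_vifs": self.final_vifs,
            "shap_ranking": [[n, v] for n, v in self.shap_ranking],
            "final_features": self.final_features,
        }


_VIF_CAP = 1e12


def _vif_one(X: np.ndarray, i: int) -> float:
    """VIF of column i: 1/(1-R²) from regressing it on the other columns."""
    y = X[:, i]
    others = np.delete(X, i, axis=1)
    if np.ptp(y) == 0:
        return np.inf
    A = np.column_stack([np.ones(len(y)), others])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    sse = float(np.sum(resid**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst
    if r2 >= 1.0 - 1.0 / _VIF_CAP:
        return _VIF_CAP
    return 1.0 / (1.0 - r2)


def vif_select(
    table: pd.DataFrame,
    threshold: float = 5.0,
    response: str = "volume_per_ha",
    exclude: tuple[str, ...] = ("x", "y", "id"),
) -> SelectionReport:
    """Stepwise collinearity screen: while any VIF exceeds the threshold,
    drop the worst offender and recompute. Constant columns are removed
    first with an infinite-VIF tag."""
    features = [
        c for c in table.columns
        if c not in exclude and c != response and pd.api.types.is_numeric_dtype(table[c])
    ]
    if len(features) < 2:
        raise ValueError("need at least 2 predictors")
    report = SelectionReport()
    current = list(features)
    while len(current) > 1:
        X = table[current].to_numpy(float)
        vifs = np.array([_vif_one(X, i) for i in range(len(current))])
        worst = int(np.argmax(vifs))
        if vifs[worst] > threshold:
            report.vif_trace.append((current[worst], float(vifs[worst])))
            current.pop(worst)
        else:
            break
    X = table[current].to_numpy(float)
    report.final_vifs = {
        name: float(_vif_one(X, i)) for i, name in enumerate(current)
    } if len(current) > 1 else {current[0]: 1.0}
    report.retained_after_vif = current
    return report


def shap_rank(
    table: pd.DataFrame,
    report: SelectionReport,
    top_k: int = 6,
    response: str = "volume_per_ha",
    seed: int = 0,
    n_trees: int = 100,
    max_depth: int = 6,
) -> SelectionReport:
    """Rank the VIF-retained predictors by mean |SHAP| under a seeded
    random-forest fit and keep the top ``top_k``."""
    from sklearn.ensemble import RandomForestRegressor

    names = report.retained_after_vif
    if not names:
        raise ValueError("run vif_select first")
    X = table[names].to_numpy(float)
    y = table[response].to_numpy(float)
    rf = RandomForestRegressor(
        n_estimators=n_trees, max_depth=max_depth, random_state=seed
    )
    rf.fit(X, y)
    phi = tree_shap_values(rf, X)
    importance = np.abs(phi).mean(axis=0)
    order = np.argsort(-importance, kind="stable")
    report.shap_ranking = [(names[i], float(importance[i])) for i in order]
    if top_k > len(names):
        warnings.warn("top_k exceeds the retained predictor count; keeping all")
        top_k = len(names)
    report.final_features = [n for n, _ in report.shap_ranking[:top_k]]
    return report
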
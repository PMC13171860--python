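"""Temporal and areal harmonization of plot volumes.

Plot volumes measured at one date are carried to the mapping year with a
localized stand-volume growth curve (ratio projection), and per-hectare
volumes are rescaled to the per-pixel support of the analysis grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GrowthParams",
    "stand_density_index",
    "stand_volume",
    "project_volume",
    "areal_scale",
    "harmonize_plots",
]


@dataclass(frozen=True)
class GrowthParams:
    """Coefficients of the stand-density index and volume growth curves."""

    a1: float = 17.6139
    a2: float = 0.06798776
    a3: float = -0.39435932
    a4: float = -1.5839
    a5: float = 0.0906281
    site_index: float = 18.39
    d0: float = 12.0  # standard diameter, cm
    sdi_coefficient: float = 407181.974
    sdi_exponent: float = -2.209

    def __post_init__(self) -> None:
        if self.a1 <= 0 or self.a5 <= 0 or self.d0 <= 0:
            raise ValueError("a1, a5 and d0 must be positive")


DEFAULT_GROWTH = GrowthParams()


def stand_density_index(d_cm, params: GrowthParams = DEFAULT_GROWTH):
    """SDI = coefficient * (D0/D)^exponent, strictly increasing in D."""
    d = np.asarray(d_cm, dtype=float)
    if np.any(d <= 0):
        raise ValueError("mean diameter must be positive")
    sdi = params.sdi_coefficient * (params.d0 / d) ** params.sdi_exponent
    return sdi if sdi.ndim else float(sdi)


def stand_volume(si, sdi, t_years, params: GrowthParams = DEFAULT_GROWTH):
    """Stand volume growth curve V'(t) = a1*SI^a2 / (1 - a3*SDI^a4*exp(-a5*t))."""
    si = np.asarray(si, dtype=float)
    sdi = np.asarray(sdi, dtype=float)
    t = np.asarray(t_years, dtype=float)
    if np.any(si <= 0) or np.any(sdi <= 0) or np.any(t < 0):
        raise ValueError("SI and SDI must be positive and t non-negative")
    denom = 1.0 - params.a3 * sdi**params.a4 * np.exp(-params.a5 * t)
    if np.any(denom <= 0):
        raise ValueError("growth-curve denominator is non-positive")
    v = params.a1 * si**params.a2 / denom
    return v if v.ndim else float(v)


def project_volume(
    v_base,
    si,
    sdi,
    t_base,
    delta_t,
    params: GrowthParams = DEFAULT_GROWTH,
):
    """Ratio projection: v_base * V'(t_base + delta_t) / V'(t_base).

    ``t_base`` is the stand age at measurement; the projected volume keeps
    the measured level and applies only the modeled relative growth.
    """
    v_base = np.asarray(v_base, dtype=float)
    t_base = np.asarray(t_base, dtype=float)
    if np.any(t_base <= 0):
        raise ValueError("stand age at measurement must be supplied and positive")
    factor = stand_volume(si, sdi, t_base + delta_t, params) / stand_volume(
        si, sdi, t_base, params
    )
    out = v_base * factor
    return out if out.ndim else float(out)


def areal_scale(v_per_ha, cell_size: float = 30.0):
    """Convert m³/ha to m³ per pixel: factor = cell_size² / 10,000.

    At 30 m the factor is 900/10,000 = 0.09; at 100 m it is 1 (one-hectare
    pixel). Exactly invertible by dividing the result by the factor.
    """
    v = np.asarray(v_per_ha, dtype=float)
    if np.any(v < 0):
        raise ValueError("volume per hectare must be non-negative")
    out = v * (cell_size**2 / 10_000.0)
    return out if out.ndim else float(out)


def harmonize_plots(
    plots: pd.DataFrame,
    delta_t: float,
    cell_size: float = 30.0,
    params: GrowthParams = DEFAULT_GROWTH,
    stand_age_column: str = "stand_age",
) -> pd.DataFrame:
    """Augment a plot table with SDI, projected volume and per-pixel volume."""
    out = plots.copy()
    sdi = stand_density_index(out["mean_dbh"].to_numpy(float), params)
    out["sdi"] = sdi
    if delta_t != 0:
        if stand_age_column not in out.columns:
            raise KeyError(
                f"temporal projection needs a {stand_age_column!r} column "
                "(stand age in years at measurement)"
            )
        out["volume_projected"] = project_volume(
            out["volume_per_ha"].to_numpy(float),
            params.site_index,
            sdi,
            out[stand_age_column].to_numpy(float),
            delta_t,
            params,
        )
    else:
        out["volume_projected"] = out["volume_per_ha"]
    out["volume_per_pixel"] = areal_scale(out["volume_projected"].to_numpy(float), cell_size)
    return out
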
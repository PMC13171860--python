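"""Published reference values shipped with the tool.

Per-metric reference numbers for the 14 LiDAR-derived variables used at
county scale: hold-out R² of each interpolation route and the fitted
spatial-dependence ratios. They serve as fixed inputs for verifying the
retention gate and the dependence classification, not as things the tool
recomputes.
"""

from __future__ import annotations

__all__ = [
    "INTERPOLATION_R2",
    "SGCS_R2",
    "STRUCTURAL_RATIOS",
    "GATE_THRESHOLD",
]

GATE_THRESHOLD = 0.50

# hold-out R² per metric and interpolation route
INTERPOLATION_R2: dict[str, dict[str, float]] = {
    "cover":              {"ok": 0.314, "sgcs": 0.61,  "idw": 0.0962, "pso-idw": 0.0983, "gs-idw": 0.0962, "ga-idw": 0.0983},
    "fhd_normal":         {"ok": 0.163, "sgcs": 0.688, "idw": 0.1515, "pso-idw": 0.1542, "gs-idw": 0.152,  "ga-idw": 0.154},
    "elevation":          {"ok": 0.932, "sgcs": 0.919, "idw": 0.911,  "pso-idw": 0.920,  "gs-idw": 0.919,  "ga-idw": 0.920},
    "pai":                {"ok": 0.284, "sgcs": 0.481, "idw": 0.241,  "pso-idw": 0.241,  "gs-idw": 0.241,  "ga-idw": 0.241},
    "pgap_theta":         {"ok": 0.106, "sgcs": 0.113, "idw": 0.124,  "pso-idw": 0.125,  "gs-idw": 0.124,  "ga-idw": 0.125},
    "rg":                 {"ok": 0.137, "sgcs": 0.621, "idw": 0.135,  "pso-idw": 0.140,  "gs-idw": 0.142,  "ga-idw": 0.142},
    "rh98":               {"ok": 0.157, "sgcs": 0.833, "idw": 0.180,  "pso-idw": 0.183,  "gs-idw": 0.181,  "ga-idw": 0.181},
    "rv":                 {"ok": 0.272, "sgcs": 0.126, "idw": 0.322,  "pso-idw": 0.324,  "gs-idw": 0.323,  "ga-idw": 0.323},
    "sensitivity":        {"ok": 0.176, "sgcs": 0.389, "idw": 0.169,  "pso-idw": 0.171,  "gs-idw": 0.170,  "ga-idw": 0.170},
    "landsat_treecover":  {"ok": 0.137, "sgcs": 0.417, "idw": 0.132,  "pso-idw": 0.139,  "gs-idw": 0.132,  "ga-idw": 0.135},
    "leaf_off_doy":       {"ok": 0.371, "sgcs": 0.346, "idw": 0.326,  "pso-idw": 0.353,  "gs-idw": 0.347,  "ga-idw": 0.323},
    "leaf_on_doy":        {"ok": 0.472, "sgcs": 0.490, "idw": 0.418,  "pso-idw": 0.436,  "gs-idw": 0.433,  "ga-idw": 0.429},
    "modis_nonvegetated": {"ok": 0.342, "sgcs": 0.523, "idw": 0.318,  "pso-idw": 0.330,  "gs-idw": 0.329,  "ga-idw": 0.329},
    "modis_treecover":    {"ok": 0.534, "sgcs": 0.320, "idw": 0.507,  "pso-idw": 0.517,  "gs-idw": 0.514,  "ga-idw": 0.508},
}

SGCS_R2: dict[str, float] = {m: v["sgcs"] for m, v in INTERPOLATION_R2.items()}

# fitted nugget-to-sill ratios (fractions) for the same 14 variables
STRUCTURAL_RATIOS: dict[str, float] = {
    "cover": 0.127,
    "fhd_normal": 0.143,
    "elevation": 0.0005,
    "pai": 0.128,
    "pgap_theta": 0.128,
    "rg": 0.074,
    "rh98": 0.132,
    "rv": 0.135,
    "sensitivity": 0.132,
    "landsat_treecover": 0.124,
    "leaf_off_doy": 0.127,
    "leaf_on_doy": 0.131,
    "modis_nonvegetated": 0.124,
    "modis_treecover": 0.150,
}
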
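import numpy as np
import pandas as pd
import pytest

from canopystack.grids import GridSpec, Raster
from canopystack.predictors import (
    INDEX_NAMES,
    TEXTURE_NAMES,
    _glcm_features,
    extract_at_points,
    glcm_textures,
    scale_reflectance,
    terrain,
    vegetation_indices,
    vif_select,
)


class TestReflectance:
    def test_zero_dn_gives_offset(self):
        assert scale_reflectance(0) == -0.2

    def test_dn_20000(self):
        assert scale_reflectance(20000) == pytest.approx(0.35)

    def test_affine_identity(self):
        a, b = 1234.0, 9876.0
        assert scale_reflectance(a) + scale_reflectance(b) - scale_reflectance(0) == \
            pytest.approx(scale_reflectance(a + b))


def _bands(grid, blue, green, red, nir):
    def mk(v):
        return Raster(grid, np.full(grid.shape, float(v)))
    return {"blue": mk(blue), "green": mk(green), "red": mk(red), "nir": mk(nir)}


class TestIndices:
    def test_index_count_and_names(self, small_grid):
        out = vegetation_indices(_bands(small_grid, 0.05, 0.1, 0.08, 0.4))
        assert set(out) == set(INDEX_NAMES)
        assert len(out) == 11

    def test_ndvi_zero_when_nir_equals_red(self, small_grid):
        out = vegetation_indices(_bands(small_grid, 0.05, 0.1, 0.3, 0.3))
        np.testing.assert_allclose(out["ndvi"].values, 0.0)

    def test_ndvi_hand_value(self, small_grid):
        out = vegetation_indices(_bands(small_grid, 0.05, 0.1, 0.2, 0.4))
        np.testing.assert_allclose(out["ndvi"].values, 1.0 / 3.0)

    def test_bounded_indices(self, small_grid):
        rng = np.random.default_rng(0)
        g = small_grid

        def mk():
            return Raster(g, rng.uniform(0.01, 0.6, g.shape))
        bands = {"blue": mk(), "green": mk(), "red": mk(), "nir": mk()}
        out = vegetation_indices(bands)
        for name in ("ndvi", "vdvi", "ngbdi"):
            v = out[name].values
            assert np.nanmin(v) >= -1.0 and np.nanmax(v) <= 1.0

    def test_missing_band_schema_error(self, small_grid):
        bands = _bands(small_grid, 0.05, 0.1, 0.2, 0.4)
        del bands["nir"]
        with pytest.raises(KeyError, match="nir"):
            vegetation_indices(bands)

    def test_division_by_zero_is_nodata(self, small_grid):
        out = vegetation_indices(_bands(small_grid, 0.0, 0.1, 0.0, 0.0))
        assert np.all(np.isnan(out["ndvi"].values))


class TestGLCM:
    def test_constant_window(self):
        g = GridSpec(0, 0, 30.0, 7, 7)
        tex = glcm_textures(Raster(g, np.ones((7, 7))))
        c = (3, 3)
        assert tex["contrast"].values[c] == 0.0
        assert tex["dissimilarity"].values[c] == 0.0
        assert tex["homogeneity"].values[c] == 1.0
        assert tex["entropy"].values[c] == 0.0
        assert tex["asm"].values[c] == 1.0

    def test_hand_tabulated_two_level_patch(self):
        # vertical stripes of 0/1: hand-build the 0-degree co-occurrence matrix
        patch = np.array([
            [0, 1, 0, 1, 0],
            [0, 1, 0, 1, 0],
            [0, 1, 0, 1, 0],
            [0, 1, 0, 1, 0],
            [0, 1, 0, 1, 0],
        ])
        # horizontal direction, displacement 1, symmetric: every adjacent pair
        # differs, so P is all off-diagonal: P01 = P10 = 0.5
        P = np.array([[0.0, 0.5], [0.5, 0.0]])
        feats = _glcm_features(P)
        assert feats["contrast"] == pytest.approx(1.0)
        assert feats["dissimilarity"] == pytest.approx(1.0)
        assert feats["homogeneity"] == pytest.approx(0.5)
        assert feats["asm"] == pytest.approx(0.5)
        assert feats["entropy"] == pytest.approx(-2 * 0.5 * np.log(0.5))
        assert feats["mean"] == pytest.approx(0.5)
        assert feats["variance"] == pytest.approx(0.25)
        assert feats["correlation"] == pytest.approx(-1.0)

        # and the sliding-window version with only the 0-degree angle agrees
        from skimage.feature import graycomatrix

        glcm = graycomatrix(patch.astype(np.uint8), [1], [0.0], levels=2,
                            symmetric=True)[:, :, 0, 0].astype(float)
        glcm /= glcm.sum()
        np.testing.assert_allclose(glcm, P)

    def test_symmetric_in_displacement_direction(self):
        rng = np.random.default_rng(1)
        g = GridSpec(0, 0, 30.0, 9, 9)
        band = Raster(g, rng.random((9, 9)))
        a = glcm_textures(band, levels=8)
        b = glcm_textures(Raster(g, band.values[::-1, ::-1]), levels=8)
        for name in TEXTURE_NAMES:
            np.testing.assert_allclose(a[name].values, b[name].values[::-1, ::-1],
                                       atol=1e-12)

    def test_window_checks(self):
        g = GridSpec(0, 0, 30.0, 3, 3)
        band = Raster(g, np.zeros((3, 3)))
        with pytest.raises(ValueError):
            glcm_textures(band, window=4)
        with pytest.raises(ValueError):
            glcm_textures(band, window=5)

    def test_feature_count(self):
        g = GridSpec(0, 0, 30.0, 6, 6)
        tex = glcm_textures(Raster(g, np.arange(36.0).reshape(6, 6)))
        assert len(tex) == 8


class TestTerrain:
    def test_flat_dem(self):
        g = GridSpec(0, 0, 30.0, 6, 6)
        out = terrain(Raster(g, np.full((6, 6), 100.0)))
        assert np.all(out["slope"].values == 0.0)
        assert np.all(out["aspect"].values == -1.0)

    def test_analytic_plane(self):
        g = GridSpec(0, 0, 10.0, 10, 10)
        xs, _ = g.center_mesh()
        out = terrain(Raster(g, 0.1 * xs))
        interior = (slice(2, -2), slice(2, -2))
        np.testing.assert_allclose(out["slope"].values[interior],
                                   np.degrees(np.arctan(0.1)), rtol=1e-9)
        np.testing.assert_allclose(out["aspect"].values[interior], 270.0)

    def test_horn_kernel_hand_arithmetic(self):
        patch = np.array([
            [10.0, 12.0, 14.0],
            [11.0, 13.0, 15.0],
            [12.0, 14.0, 16.0],
        ])
        g = GridSpec(0, 0, 30.0, 3, 3)
        out = terrain(Raster(g, patch))
        gx = ((14 + 2 * 15 + 16) - (10 + 2 * 11 + 12)) / (8 * 30.0)
        gy = ((10 + 2 * 12 + 14) - (12 + 2 * 14 + 16)) / (8 * 30.0)
        expected_slope = np.degrees(np.arctan(np.hypot(gx, gy)))
        assert out["slope"].values[1, 1] == pytest.approx(expected_slope)
        expected_aspect = np.degrees(np.arctan2(-gx, -gy)) % 360
        assert out["aspect"].values[1, 1] == pytest.approx(expected_aspect)

    def test_small_raster_rejected(self):
        g = GridSpec(0, 0, 30.0, 2, 2)
        with pytest.raises(ValueError):
            terrain(Raster(g, np.zeros((2, 2))))

    def test_slope_range(self):
        rng = np.random.default_rng(2)
        g = GridSpec(0, 0, 30.0, 15, 15)
        out = terrain(Raster(g, rng.uniform(0, 3000, (15, 15))))
        s = out["slope"].values
        assert np.all((s >= 0) & (s < 90))


class TestExtract:
    def test_point_at_cell_center(self, gaussian_field):
        g = gaussian_field.grid
        x, y = g.cell_center(3, 4)
        pts = pd.DataFrame({"id": ["p0"], "x": [x], "y": [y],
                            "volume_per_ha": [10.0]})
        out = extract_at_points({"f": gaussian_field}, pts)
        assert out["f"].iloc[0] == gaussian_field.values[3, 4]

    def test_outside_point_dropped(self, gaussian_field):
        pts = pd.DataFrame({"id": ["a", "b"], "x": [15.0, 1e6], "y": [-15.0, 0.0],
                            "volume_per_ha": [1.0, 2.0]})
        with pytest.warns(UserWarning):
            out = extract_at_points({"f": gaussian_field}, pts)
        assert len(out) == 1

    def test_matches_direct_indexing_oracle(self, gaussian_field):
        rng = np.random.default_rng(6)
        g = gaussian_field.grid
        x = rng.uniform(0, g.width_m, 40)
        y = rng.uniform(-g.height_m, 0, 40)
        pts = pd.DataFrame({"x": x, "y": y, "volume_per_ha": np.zeros(40)})
        out = extract_at_points({"f": gaussian_field}, pts)
        for _, row in out.iterrows():
            r, c = g.cell_of(row["x"], row["y"])
            assert row["f"] == gaussian_field.values[int(r), int(c)]

    def test_all_outside_error(self, gaussian_field):
        pts = pd.DataFrame({"x": [1e6], "y": [1e6], "volume_per_ha": [0.0]})
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                extract_at_points({"f": gaussian_field}, pts)


class TestVIF:
    def test_orthogonal_predictors_kept(self):
        rng = np.random.default_rng(0)
        n = 200
        q, _ = np.linalg.qr(rng.normal(size=(n, 4)))
        df = pd.DataFrame(q, columns=list("abcd"))
        df["volume_per_ha"] = rng.normal(size=n)
        rep = vif_select(df)
        assert rep.retained_after_vif == list("abcd")
        # orthonormal columns are only near-orthogonal after centering
        assert all(v == pytest.approx(1.0, abs=0.05) for v in rep.final_vifs.values())

    def test_duplicated_column_removed_first(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"a": rng.normal(size=50), "c": rng.normal(size=50)})
        df["b"] = df["a"]
        df["volume_per_ha"] = rng.normal(size=50)
        rep = vif_select(df)
        removed = {name for name, _ in rep.vif_trace}
        assert removed & {"a", "b"}
        assert len(rep.retained_after_vif) == 2

    def test_vif_matches_per_column_regression_oracle(self):
        rng = np.random.default_rng(2)
        n = 300
        base = rng.normal(size=n)
        df = pd.DataFrame({
            "p1": base + 0.5 * rng.normal(size=n),
            "p2": base + 0.5 * rng.normal(size=n),
            "p3": rng.normal(size=n),
        })
        df["volume_per_ha"] = rng.normal(size=n)
        rep = vif_select(df, threshold=100.0)  # high threshold: nothing removed
        from sklearn.linear_model import LinearRegression

        X = df[["p1", "p2", "p3"]].to_numpy()
        for i, name in enumerate(["p1", "p2", "p3"]):
            others = np.delete(X, i, axis=1)
            r2 = LinearRegression().fit(others, X[:, i]).score(others, X[:, i])
            assert rep.final_vifs[name] == pytest.approx(1.0 / (1.0 - r2), rel=1e-6)

    def test_retained_vifs_below_threshold(self):
        rng = np.random.default_rng(3)
        n = 150
        base = rng.normal(size=(n, 2))
        df = pd.DataFrame({
            "a": base[:, 0],
            "b": base[:, 0] * 0.95 + 0.05 * rng.normal(size=n),
            "c": base[:, 1],
            "d": base[:, 1] * 0.9 + 0.1 * rng.normal(size=n),
            "e": rng.normal(size=n),
        })
        df["volume_per_ha"] = rng.normal(size=n)
        rep = vif_select(df, threshold=5.0)
        assert all(v < 5.0 for v in rep.final_vifs.values())

    def test_constant_column_tagged_infinite(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"a": rng.normal(size=40), "b": np.ones(40),
                           "c": rng.normal(size=40)})
        df["volume_per_ha"] = rng.normal(size=40)
        rep = vif_select(df)
        assert rep.vif_trace[0][0] == "b"
        assert not np.isfinite(rep.vif_trace[0][1]) or rep.vif_trace[0][1] >= 1e12
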
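"""Variogram fitting, ordinary kriging, CSM arithmetic, ExG segmentation."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from uavqtl.raster import Affine, Raster
from uavqtl.surface import (
    VariogramModel,
    compute_csm,
    excess_green,
    fit_variogram,
    krige_dem,
    krige_points,
    vegetation_mask,
)


def dense_ok_oracle(points, variogram, target):
    """Brute-force ordinary kriging: assemble and solve the full
    (n+1) x (n+1) system directly."""
    coords, z = points[:, :2], points[:, 2]
    n = len(coords)
    a = np.zeros((n + 1, n + 1))
    a[:n, :n] = variogram(cdist(coords, coords))
    a[n, :n] = a[:n, n] = 1.0
    b = np.append(variogram(cdist([target], coords)[0]), 1.0)
    sol = np.linalg.solve(a, b)
    return float(sol[:n] @ z), sol[:n]


# ---------------------------------------------------------------- variogram

def test_variogram_invariants_enforced():
    with pytest.raises(ValueError):
        VariogramModel("exponential", nugget=-1, sill=1, range_=1)
    with pytest.raises(ValueError):
        VariogramModel("exponential", nugget=2, sill=1, range_=1)
    with pytest.raises(ValueError):
        VariogramModel("cubic", nugget=0, sill=1, range_=1)


def test_constant_elevations_give_flagged_nugget_only_model():
    rng = np.random.default_rng(0)
    pts = np.column_stack([rng.uniform(0, 10, 50), rng.uniform(0, 10, 50),
                           np.full(50, 7.0)])
    v = fit_variogram(pts)
    assert v.degenerate and v.sill == v.nugget


def test_degenerate_binning_rejected():
    rng = np.random.default_rng(0)
    pts = rng.uniform(0, 10, (50, 3))
    with pytest.raises(ValueError):
        fit_variogram(pts, n_lags=1)


def test_exponential_model_recovery():
    """Draws from a known exponential-covariance field (range 10, sill 4,
    nugget 0) are refit within broad factor-two bounds."""
    rng = np.random.default_rng(42)
    xy = rng.uniform(0, 50, (500, 2))
    cov = 4.0 * np.exp(-3.0 * cdist(xy, xy) / 10.0)
    z = np.linalg.cholesky(cov + 1e-10 * np.eye(500)) @ rng.normal(size=500)
    v = fit_variogram(np.column_stack([xy, z]), family="exponential")
    assert 5.0 <= v.range_ <= 20.0
    assert 2.0 <= v.sill <= 6.0


# ------------------------------------------------------------------ kriging

def test_constant_field_predicts_constant():
    """Weights summing to one force a constant surface through constant data."""
    rng = np.random.default_rng(1)
    pts = np.column_stack([rng.uniform(0, 100, 40), rng.uniform(0, 100, 40),
                           np.full(40, 123.0)])
    v = VariogramModel("exponential", 0.0, 5.0, 30.0)
    pred = krige_points(pts, v, rng.uniform(0, 100, (25, 2)))
    np.testing.assert_allclose(pred, 123.0, rtol=1e-9)


def test_four_corner_center_matches_dense_oracle():
    pts = np.array([[0, 0, 1.0], [1, 0, 2.0], [0, 1, 3.0], [1, 1, 2.5]])
    v = VariogramModel("exponential", 0.0, 2.0, 1.5)
    got = krige_points(pts, v, np.array([[0.5, 0.5]]))[0]
    want, w = dense_ok_oracle(pts, v, np.array([0.5, 0.5]))
    assert got == pytest.approx(want, rel=1e-10)
    assert w.sum() == pytest.approx(1.0, abs=1e-10)


def test_exact_interpolation_at_data_points_zero_nugget():
    rng = np.random.default_rng(3)
    pts = np.column_stack([rng.uniform(0, 10, 20), rng.uniform(0, 10, 20),
                           rng.normal(5, 2, 20)])
    v = VariogramModel("spherical", 0.0, 4.0, 6.0)
    pred = krige_points(pts, v, pts[:, :2])
    np.testing.assert_allclose(pred, pts[:, 2], rtol=1e-8, atol=1e-8)


def test_neighborhood_equals_dense_solve_small_instance():
    """With max_neighbors >= n the neighborhood path must agree with an
    independent dense-system solve to 1e-8 relative tolerance."""
    rng = np.random.default_rng(4)
    n = 50
    pts = np.column_stack([rng.uniform(0, 30, n), rng.uniform(0, 30, n),
                           rng.normal(0, 3, n)])
    v = VariogramModel("exponential", 0.1, 3.0, 12.0)
    targets = rng.uniform(0, 30, (15, 2))
    got = krige_points(pts, v, targets, max_neighbors=n)
    want = np.array([dense_ok_oracle(pts, v, t)[0] for t in targets])
    np.testing.assert_allclose(got, want, rtol=1e-8)


def test_neighborhood_limited_close_to_dense():
    rng = np.random.default_rng(5)
    n = 40
    pts = np.column_stack([rng.uniform(0, 30, n), rng.uniform(0, 30, n),
                           rng.normal(0, 3, n)])
    v = VariogramModel("exponential", 0.0, 3.0, 12.0)
    targets = rng.uniform(5, 25, (10, 2))
    limited = krige_points(pts, v, targets, max_neighbors=16)
    dense = np.array([dense_ok_oracle(pts, v, t)[0] for t in targets])
    np.testing.assert_allclose(limited, dense, atol=0.5)


def test_krige_dem_grid_output():
    rng = np.random.default_rng(6)
    pts = np.column_stack([rng.uniform(0, 10, 30), rng.uniform(0, 10, 30),
                           rng.normal(100, 1, 30)])
    v = VariogramModel("exponential", 0.0, 1.0, 5.0)
    grid = Raster(np.zeros((8, 8)), Affine.north_up(0, 10, 1.25))
    dem = krige_dem(pts, v, grid)
    assert dem.shape == (8, 8)
    assert np.all(np.abs(dem.values - 100) < 5)


def test_krige_requires_three_points():
    v = VariogramModel("exponential", 0.0, 1.0, 5.0)
    with pytest.raises(ValueError):
        krige_points(np.array([[0, 0, 1.0], [1, 1, 2.0]]), v, [[0.5, 0.5]])


# ---------------------------------------------------------------------- csm

def grid(values, pixel=1.0):
    values = np.asarray(values, dtype=float)
    return Raster(values, Affine.north_up(0, values.shape[-2] * pixel, pixel))


def test_csm_identity_offset_and_bump():
    dem = grid(np.full((6, 6), 500.0))
    assert np.all(compute_csm(dem, dem).values == 0.0)
    dsm = dem.copy_with(dem.values + 150.0)
    assert np.all(compute_csm(dsm, dem).values == 150.0)
    bump = dem.values.copy()
    bump[3, 3] += 150.0
    assert compute_csm(dem.copy_with(bump), dem).values.max() == 150.0


def test_csm_clamps_negatives_and_propagates_nodata(caplog):
    dem = grid(np.full((4, 4), 10.0))
    dsm_vals = np.full((4, 4), 9.0)
    dsm_vals[0, 0] = -9999.0
    dsm = Raster(dsm_vals, dem.transform)
    with caplog.at_level("WARNING"):
        csm = compute_csm(dsm, dem)
    assert "clamped" in caplog.text
    assert csm.values[0, 0] == csm.nodata
    assert np.all(csm.values[1:] == 0.0)


def test_csm_geometry_mismatch():
    with pytest.raises(ValueError):
        compute_csm(grid(np.zeros((4, 4))), grid(np.zeros((5, 5))))


def test_csm_optional_smoothing():
    dem = grid(np.zeros((5, 5)))
    vals = np.zeros((5, 5))
    vals[2, 2] = 9.0
    smoothed = compute_csm(dem.copy_with(vals), dem, smooth_window=3)
    assert smoothed.values[2, 2] == pytest.approx(1.0)  # 9 spread over 3x3
    with pytest.raises(ValueError):
        compute_csm(dem.copy_with(vals), dem, smooth_window=2)


def test_csm_linear_before_clamp():
    rng = np.random.default_rng(7)
    dem = grid(np.zeros((5, 5)))
    a, b = rng.uniform(1, 5, (5, 5)), rng.uniform(1, 5, (5, 5))
    lhs = compute_csm(dem.copy_with(2 * a + 3 * b), dem).values
    rhs = 2 * compute_csm(dem.copy_with(a), dem).values + \
        3 * compute_csm(dem.copy_with(b), dem).values
    np.testing.assert_allclose(lhs, rhs)


# ------------------------------------------------------------ ExG and mask

def rgb_raster(r, g, b):
    vals = np.stack([np.full((2, 2), float(r)), np.full((2, 2), float(g)),
                     np.full((2, 2), float(b))])
    return Raster(vals, Affine.north_up(0, 2, 1))


@pytest.mark.parametrize("r,g,b,expected", [
    (0, 255, 0, 2.0),       # pure green: index maximum
    (128, 128, 128, 0.0),   # grey: symmetric channels cancel
    (100, 150, 50, 0.5),    # worked chromatic-coordinate example
])
def test_excess_green_values(r, g, b, expected):
    out = excess_green(rgb_raster(r, g, b))
    np.testing.assert_allclose(out.values, expected, atol=1e-12)


def test_excess_green_intensity_invariance():
    base = excess_green(rgb_raster(60, 160, 60)).values
    scaled = excess_green(rgb_raster(6, 16, 6)).values
    np.testing.assert_allclose(base, scaled, atol=1e-12)


def test_excess_green_zero_sum_is_nodata_and_band_check():
    out = excess_green(rgb_raster(0, 0, 0))
    assert np.all(out.values == out.nodata)
    with pytest.raises(ValueError):
        excess_green(Raster(np.zeros((4, 4)), Affine.north_up(0, 4, 1)))


def test_mask_otsu_separates_bimodal_and_fixed_threshold():
    vals = np.full((4, 4), -0.2)
    vals[1:3, 1:3] = 1.0
    exg = Raster(vals, Affine.north_up(0, 4, 1), units="index")
    mask = vegetation_mask(exg, method="otsu")
    np.testing.assert_array_equal(mask.values == 1, vals == 1.0)
    fixed = vegetation_mask(exg, method="fixed", threshold=0.0)
    np.testing.assert_array_equal(fixed.values, mask.values)
    with pytest.raises(ValueError):
        vegetation_mask(exg, method="fixed")


def test_otsu_threshold_lies_between_cluster_means():
    rng = np.random.default_rng(8)
    soil = rng.normal(-0.05, 0.02, 200)
    leaf = rng.normal(0.7, 0.05, 200)
    vals = np.concatenate([soil, leaf]).reshape(20, 20)
    exg = Raster(vals, Affine.north_up(0, 20, 1), units="index")
    mask = vegetation_mask(exg, method="otsu")
    assert soil.mean() < mask.threshold < leaf.mean()
    # hence pixels at or beyond the cluster means are classified correctly
    assert np.all(mask.values[vals <= soil.mean()] == 0)
    assert np.all(mask.values[vals >= leaf.mean()] == 1)
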
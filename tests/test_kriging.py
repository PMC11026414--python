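"""Ordinary kriging against a brute-force solve of the augmented system."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vsprofile.kriging import (SingularKrigingSystem, build_system,
                               krige_grid, krige_point, loocv)
from vsprofile.variogram import VariogramModel

from conftest import random_model, random_points


def brute_force_krige(x, y, z, model, tx, ty):
    """Independent dense solve of the ordinary-kriging equations.

    Builds the augmented covariance system directly from C(h) = C(0) -
    gamma(h) and solves it with a generic linear solver; used as the
    oracle for the production path.
    """
    n = len(z)
    A = np.zeros((n + 1, n + 1))
    for i in range(n):
        for j in range(n):
            h = np.hypot(x[i] - x[j], y[i] - y[j])
            A[i, j] = model.sill - (model.gamma([h])[0] if h > 0 else 0.0)
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    b = np.zeros(n + 1)
    for i in range(n):
        h = np.hypot(x[i] - tx, y[i] - ty)
        b[i] = model.sill - (model.gamma([h])[0] if h > 0 else 0.0)
    b[n] = 1.0
    sol = np.linalg.solve(A, b)
    w, mu = sol[:n], sol[n]
    zstar = float(w @ z)
    var = model.sill - (float(w @ b[:n]) + mu)
    return zstar, max(var, 0.0), w


@given(st.integers(min_value=0, max_value=2**31 - 1))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_matches_brute_force_solve(seed):
    """krige_point agrees with an independent dense solve for n <= 12."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 13))
    model = random_model(rng)
    x, y, z = random_points(rng, n)
    tx, ty = rng.uniform(0, 1, 2)
    system = build_system(x, y, z, model)
    zstar, var, w = krige_point(system, tx, ty)
    zb, vb, wb = brute_force_krige(x, y, z, model, tx, ty)
    assert zstar == pytest.approx(zb, abs=1e-8)
    assert var == pytest.approx(vb, abs=1e-8)
    assert np.allclose(w, wb, atol=1e-8)


@given(st.integers(min_value=0, max_value=2**31 - 1))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_weights_sum_to_one(seed):
    """The unbiasedness constraint holds for every solved target."""
    rng = np.random.default_rng(seed)
    model = random_model(rng)
    x, y, z = random_points(rng, int(rng.integers(4, 30)))
    system = build_system(x, y, z, model)
    for _ in range(5):
        _, _, w = krige_point(system, *rng.uniform(-0.2, 1.2, 2))
        assert abs(w.sum() - 1.0) < 1e-8


def test_two_equidistant_points_split_weight():
    model = VariogramModel("exponential", 0.0, 1.0, 0.3)
    system = build_system([0.0, 1.0], [0.0, 0.0], [0.7, 0.7], model)
    zstar, _, w = krige_point(system, 0.5, 0.0)
    assert zstar == pytest.approx(0.7)
    assert np.allclose(w, [0.5, 0.5], atol=1e-10)


def test_single_point_rejected():
    model = VariogramModel("exponential", 0.0, 1.0, 0.3)
    with pytest.raises(ValueError):
        build_system([0.5], [0.5], [1.0], model)


def test_exact_interpolation_without_nugget():
    """Zero-nugget kriging reproduces every datum with zero variance."""
    rng = np.random.default_rng(5)
    model = VariogramModel("gaussian", 0.0, 1.2, 0.4)
    x, y, z = random_points(rng, 15)
    system = build_system(x, y, z, model)
    for i in range(15):
        zstar, var, _ = krige_point(system, x[i], y[i])
        assert zstar == pytest.approx(z[i], abs=1e-7)
        assert var <= 1e-8


def test_duplicate_coordinates_raise():
    model = VariogramModel("exponential", 0.0, 1.0, 0.3)
    with pytest.raises(SingularKrigingSystem, match="duplicate"):
        build_system([0.1, 0.1, 0.5], [0.2, 0.2, 0.5], [1, 2, 3], model)


def test_linearity_in_z():
    """The prediction operator is linear in the data values."""
    rng = np.random.default_rng(7)
    model = random_model(rng)
    x, y, _ = random_points(rng, 10)
    z1 = rng.normal(size=10)
    z2 = rng.normal(size=10)
    tx, ty = 0.4, 0.6
    p1, _, _ = krige_point(build_system(x, y, z1, model), tx, ty)
    p2, _, _ = krige_point(build_system(x, y, z2, model), tx, ty)
    p12, _, _ = krige_point(build_system(x, y, z1 + z2, model), tx, ty)
    assert p12 == pytest.approx(p1 + p2, abs=1e-9)


def test_grid_shapes_and_finiteness():
    rng = np.random.default_rng(3)
    model = VariogramModel("spherical", 0.05, 1.0, 0.3)
    x, y, z = random_points(rng, 20)
    grid = krige_grid(x, y, z, model, chain_length=10,
                      y_grid=np.linspace(0, 1, 11))
    assert grid.z_pred.shape == (11, 10)
    assert grid.variance.shape == (11, 10)
    assert np.isfinite(grid.z_pred).all()
    assert (grid.variance >= 0).all()
    assert np.allclose(grid.x_grid, np.arange(1, 11) / 10)


def test_constant_data_predicts_constant():
    model = VariogramModel("exponential", 0.1, 0.8, 0.2)
    rng = np.random.default_rng(0)
    x, y, _ = random_points(rng, 12)
    grid = krige_grid(x, y, np.full(12, 0.42), model, chain_length=25)
    assert np.allclose(grid.z_pred, 0.42, atol=1e-9)


def test_far_field_limit_is_gls_mean_and_sill():
    """Beyond the correlation range the prediction tends to the
    generalized least squares mean and the variance to the sill."""
    rng = np.random.default_rng(21)
    model = VariogramModel("gaussian", 0.0, 1.0, 0.02)
    x = rng.uniform(0, 0.2, 100)
    y = rng.uniform(0, 0.2, 100)
    z = rng.normal(1.0, 0.5, 100)
    system = build_system(x, y, z, model)
    from scipy.spatial.distance import pdist, squareform
    C = model.covariance(squareform(pdist(np.column_stack([x, y]))))
    np.fill_diagonal(C, model.sill)
    Ci = np.linalg.inv(C)
    gls_mean = float(np.ones(100) @ Ci @ z) / float(np.ones(100) @ Ci @
                                                    np.ones(100))
    zstar, var, _ = krige_point(system, 50.0, 50.0)
    assert zstar == pytest.approx(gls_mean, rel=0.05)
    assert var == pytest.approx(model.sill, rel=0.05)


class TestLoocv:
    def test_matches_explicit_point_removal(self, small_points):
        """The fast leave-one-out path equals refitting without each
        point."""
        x, y, z = small_points
        model = VariogramModel("exponential", 0.05, 1.0, 0.3)
        res = loocv(x, y, z, model)
        for i in range(0, len(z), 7):
            keep = np.arange(len(z)) != i
            system = build_system(x[keep], y[keep], z[keep], model)
            zstar, var, _ = krige_point(system, x[i], y[i])
            assert res.predictions[i] == pytest.approx(zstar, abs=1e-8)
            assert res.variances[i] == pytest.approx(var, abs=1e-8)

    def test_needs_four_points(self):
        model = VariogramModel("exponential", 0.0, 1.0, 0.3)
        with pytest.raises(ValueError):
            loocv([0, 1, 2], [0, 1, 2], [1, 2, 3], model)

    def test_smooth_field_high_r(self, exp_truth):
        from vsprofile.data import select_spatial
        from vsprofile.synthetic import SyntheticConfig, simulate_dataset

        model = VariogramModel("gaussian", 0.0, 1.0, 0.4)
        ds = simulate_dataset(SyntheticConfig(
            n_variants=50, seed=3, variogram=model, replicate_sd=0.0))
        pts = select_spatial(ds, "monomer", "activity", "vehicle")
        res = loocv(pts["x"].to_numpy(), pts["y"].to_numpy(),
                    pts["z"].to_numpy(), model)
        assert res.pearson_r >= 0.9

    def test_permuted_z_has_no_skill(self, exp_truth):
        """Breaking the coordinate-value link kills the LOOCV r."""
        from vsprofile.data import select_spatial
        from vsprofile.synthetic import SyntheticConfig, simulate_dataset

        hits = 0
        for seed in range(20):
            ds = simulate_dataset(SyntheticConfig(
                n_variants=60, seed=seed, variogram=exp_truth))
            pts = select_spatial(ds, "monomer", "activity", "vehicle")
            rng = np.random.default_rng(seed + 1000)
            zperm = rng.permutation(pts["z"].to_numpy())
            res = loocv(pts["x"].to_numpy(), pts["y"].to_numpy(), zperm,
                        exp_truth)
            hits += abs(res.pearson_r) < 0.3
        assert hits >= 18

    def test_constant_z_warns_and_returns_nan(self):
        model = VariogramModel("exponential", 0.1, 1.0, 0.3)
        rng = np.random.default_rng(1)
        x, y = rng.uniform(0, 1, (2, 10))
        with pytest.warns(UserWarning, match="zero variance"):
            res = loocv(x, y, np.ones(10), model)
        assert np.isnan(res.pearson_r)
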
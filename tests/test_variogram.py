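"""Variogram cloud, binning, families, and fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vsprofile.variogram import (EmpiricalVariogram, VariogramModel,
                                 bin_cloud, fit_variogram,
                                 range_in_residues, variogram_cloud)


class TestModel:
    @pytest.mark.parametrize("family", ["spherical", "exponential",
                                        "gaussian"])
    def test_limits(self, family):
        m = VariogramModel(family, 0.05, 1.0, 0.2)
        assert m.gamma(0.0) == 0.0
        assert m.gamma(1e3) == pytest.approx(m.sill, abs=1e-6)
        assert m.covariance(0.0) == pytest.approx(m.sill)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_and_covariance_identity(self, seed):
        rng = np.random.default_rng(seed)
        family = str(rng.choice(["spherical", "exponential", "gaussian"]))
        m = VariogramModel(family, float(rng.uniform(0, 0.5)),
                           float(rng.uniform(0, 2)),
                           float(rng.uniform(0.01, 2)))
        h = np.sort(rng.uniform(0, 3, 50))
        g = m.gamma(h)
        assert (np.diff(g) >= -1e-12).all()
        assert np.allclose(m.covariance(h), m.sill - g)
        assert (m.covariance(h) >= -1e-12).all()

    def test_effective_range_exponential(self):
        m = VariogramModel("exponential", 0.0, 1.0, 0.3)
        # gamma reaches 95% of the sill at about three range parameters
        assert m.effective_range == pytest.approx(0.3 * np.log(20))

    def test_effective_range_spherical_at_sill(self):
        m = VariogramModel("spherical", 0.0, 1.0, 0.5)
        assert 0 < m.effective_range <= 0.5
        assert m.gamma(m.effective_range) == pytest.approx(0.95, abs=1e-9)

    def test_pure_nugget(self):
        m = VariogramModel("pure_nugget", 0.3, 0.0)
        assert m.gamma(0.5) == 0.3
        assert m.covariance(0.5) == 0.0
        assert m.effective_range == 0.0

    def test_range_to_residues(self):
        assert range_in_residues(0.11, 418) == 46


class TestCloud:
    def test_pair_geometry(self):
        cloud = variogram_cloud([0.0, 0.3, 9.0], [0.0, 0.4, 9.0],
                                [0.0, 1.0, 5.0])
        assert cloud.h[0] == pytest.approx(0.5)
        assert cloud.gamma[0] == pytest.approx(0.5)

    def test_pair_count(self):
        rng = np.random.default_rng(0)
        cloud = variogram_cloud(rng.uniform(size=72), rng.uniform(size=72),
                                rng.normal(size=72))
        assert len(cloud) == 72 * 71 // 2

    def test_equal_z_gives_zero_gamma(self):
        cloud = variogram_cloud([0, 1, 2], [0, 0, 0], [0.7, 0.7, 0.7])
        assert np.all(cloud.gamma == 0.0)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(1)
        x, y, z = rng.uniform(size=(3, 20))
        c1 = variogram_cloud(x, y, z)
        perm = rng.permutation(20)
        c2 = variogram_cloud(x[perm], y[perm], z[perm])
        assert np.allclose(np.sort(c1.h), np.sort(c2.h))
        assert np.allclose(np.sort(c1.gamma), np.sort(c2.gamma))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            variogram_cloud([0, 1, np.nan], [0, 1, 2], [0, 1, 2])

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            variogram_cloud([0, 1], [0, 1], [0, 1])


class TestBinning:
    def test_single_occupied_bin(self):
        rng = np.random.default_rng(2)
        # equilateral-ish triangle: all pairs at the same distance
        x = np.array([0.0, 1.0, 0.5])
        y = np.array([0.0, 0.0, np.sqrt(3) / 2])
        cloud = variogram_cloud(x, y, [0.0, 2.0, 0.0])
        emp = bin_cloud(cloud, n_bins=5, max_lag=1.5)
        occupied = emp.n_pairs > 0
        assert occupied.sum() == len(emp)
        assert len(emp) == 1
        assert emp.n_pairs[0] == 3

    def test_constant_gamma_bin_has_zero_sem(self):
        x = np.array([0.0, 1.0, 0.5])
        y = np.array([0.0, 0.0, np.sqrt(3) / 2])
        cloud = variogram_cloud(x, y, [1.0, 3.0, 1.0])
        emp = bin_cloud(cloud, n_bins=3, max_lag=2.0)
        assert len(emp) == 1
        assert emp.n_pairs[0] == 3
        # all three pairs sit at h = 1 with gammas {2, 2, 0}
        assert emp.mean_gamma[0] == pytest.approx(4.0 / 3.0)
        cloud2 = variogram_cloud(x, y, [1.0, 1.0, 1.0])
        emp2 = bin_cloud(cloud2, n_bins=3, max_lag=2.0)
        assert emp2.mean_gamma[0] == 0.0
        assert emp2.sem_gamma[0] == 0.0

    def test_bin_centers_equal_width(self):
        rng = np.random.default_rng(3)
        cloud = variogram_cloud(rng.uniform(size=40), rng.uniform(size=40),
                                rng.normal(size=40))
        emp = bin_cloud(cloud, n_bins=10, max_lag=1.0)
        expected = np.arange(10) * 0.1 + 0.05
        assert np.all(np.isin(np.round(emp.lag_center, 10),
                              np.round(expected, 10)))

    def test_pure_noise_is_flat_at_sample_variance(self):
        """For iid z the binned variogram is flat at the realized variance
        of the draw (which the semivariance estimates, not the ensemble
        value)."""
        rng = np.random.default_rng(4)
        n = 400
        z = rng.normal(0, 0.7, n)
        cloud = variogram_cloud(rng.uniform(size=n), rng.uniform(size=n), z)
        emp = bin_cloud(cloud, n_bins=10)
        assert np.all(np.abs(emp.mean_gamma - z.var()) <= 3 * emp.sem_gamma)

    def test_max_lag_validation(self):
        rng = np.random.default_rng(5)
        cloud = variogram_cloud(rng.uniform(size=10), rng.uniform(size=10),
                                rng.normal(size=10))
        with pytest.raises(ValueError):
            bin_cloud(cloud, max_lag=0.0)
        with pytest.raises(ValueError):
            bin_cloud(cloud, n_bins=2)


class TestFit:
    def test_recovers_simulated_structure(self, exp_truth):
        """Range and sill recovered from a dense simulated field, judged
        over repeated seeds (single realizations fluctuate strongly)."""
        from vsprofile.data import select_spatial
        from vsprofile.synthetic import SyntheticConfig, simulate_dataset

        hits = 0
        n_seeds = 8
        for seed in range(n_seeds):
            ds = simulate_dataset(SyntheticConfig(
                n_variants=300, seed=seed, variogram=exp_truth))
            pts = select_spatial(ds, "monomer", "activity", "vehicle")
            x, y, z = (pts[c].to_numpy() for c in "xyz")
            m = fit_variogram(bin_cloud(variogram_cloud(x, y, z)),
                              data=(x, y, z))
            ok_range = abs(m.effective_range - exp_truth.effective_range) \
                <= 0.5 * exp_truth.effective_range
            ok_sill = abs(m.sill - exp_truth.sill) <= 0.5 * exp_truth.sill
            hits += ok_range and ok_sill
        assert hits >= n_seeds // 2

    def test_iid_noise_selects_nugget(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x, y = rng.uniform(0, 1, (2, 200))
            z = rng.normal(0, 1, 200)
            m = fit_variogram(bin_cloud(variogram_cloud(x, y, z)),
                              data=(x, y, z))
            hits += (m.family == "pure_nugget"
                     or m.partial_sill <= 0.1 * m.nugget)
        assert hits >= 8

    def test_needs_three_bins(self):
        emp = EmpiricalVariogram(np.array([0.1, 0.2]), np.array([1.0, 1.0]),
                                 np.array([0.0, 0.0]), np.array([5, 5]), 0.4)
        with pytest.raises(ValueError):
            fit_variogram(emp)
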
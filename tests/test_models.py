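"""Continuous/discontinuous model fits and effect-size extraction."""

import numpy as np
import pytest

from bndd.gp import ObservedData, OptimizerConfig, fit_gp
from bndd.kernels import (ExponentialKernel, LinearKernel, Matern32Kernel,
                          Partition, RBFKernel)
from bndd.models import (arc_length_samples, fit_continuous,
                         fit_discontinuous, geo_effect_curve,
                         its_effect_curve, rd_effect_size, side_posterior)
from bndd.synthetic import RDSimConfig, generate_rd_dataset


class TestFitDiscontinuous:
    def test_its_joint_marginal_is_sum_of_sides(self, small_rd_data, fast_config):
        m1 = fit_discontinuous(small_rd_data, small_rd_data.partition,
                               Matern32Kernel(), mode="its", config=fast_config)
        assert m1.log_marginal == pytest.approx(
            m1.pre.log_marginal + m1.post.log_marginal, abs=1e-12)
        assert m1.n_hyperparameters == (m1.pre.n_hyperparameters
                                        + m1.post.n_hyperparameters)

    def test_cross_side_predictive_covariance_zero(self, small_rd_data, fast_config):
        m1 = fit_discontinuous(small_rd_data, small_rd_data.partition,
                               Matern32Kernel(), mode="rd", config=fast_config)
        Xs = np.array([[-0.4], [0.4]])  # one point per side
        _, cov = m1.predict(Xs, full_cov=True)
        assert abs(cov[0, 1]) < 1e-10

    def test_side_with_single_point_rejected(self, fast_config):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.uniform(-1, 0, 10), [0.5]])
        data = ObservedData(x, rng.normal(size=11))
        with pytest.raises(ValueError, match="post"):
            fit_discontinuous(data, Partition(threshold=0.0),
                              Matern32Kernel(), mode="rd", config=fast_config)

    def test_jump_recovered_at_threshold(self, fast_config):
        """d = 4 jump: the per-side posterior means at x0 differ by about 4."""
        ms = []
        for seed in range(8):
            data = generate_rd_dataset(RDSimConfig(
                function_name="linear", d=4.0, sigma=1.0, n=100, seed=seed))
            m1 = fit_discontinuous(data, data.partition, ExponentialKernel(),
                                   mode="rd", config=fast_config)
            eff = rd_effect_size(m1, 0.0)
            ms.append(eff.m)
            assert abs(eff.m - 4.0) < 3.0 * np.sqrt(eff.s2)
        assert abs(np.median(ms) - 4.0) < 1.0

    def test_unknown_mode_rejected(self, small_rd_data, fast_config):
        with pytest.raises(ValueError, match="mode"):
            fit_discontinuous(small_rd_data, small_rd_data.partition,
                              Matern32Kernel(), mode="fuzzy", config=fast_config)


class TestRDEffectSize:
    def test_variance_is_twice_noise_for_stationary_kernel(
            self, small_rd_data, fast_config):
        m1 = fit_discontinuous(small_rd_data, small_rd_data.partition,
                               Matern32Kernel(), mode="rd", config=fast_config)
        eff = rd_effect_size(m1, 0.0)
        assert eff.s2 == 2.0 * m1.noise_variance

    def test_nonstationary_kernel_falls_back_to_predictive_variance(
            self, small_rd_data, fast_config):
        m1 = fit_discontinuous(small_rd_data, small_rd_data.partition,
                               LinearKernel(), mode="rd", config=fast_config)
        eff = rd_effect_size(m1, 0.0)
        xs = np.array([[0.0]])
        _, v_pre = side_posterior(m1, "pre", xs)
        _, v_post = side_posterior(m1, "post", xs)
        assert eff.s2 == pytest.approx(float(v_pre[0] + v_post[0]), abs=1e-12)

    def test_mirror_symmetric_data_has_near_zero_effect(self, fast_config):
        """Continuous data mirrored about x0: no jump to detect."""
        ms = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            xh = rng.uniform(0, 1, 100)
            yh = np.sin(2 * xh) + rng.normal(0, 1, 100)
            x = np.concatenate([-xh[::-1], xh])
            y = np.concatenate([yh[::-1], yh])
            data = ObservedData(x, y, partition=Partition(threshold=0.0))
            m1 = fit_discontinuous(data, data.partition, Matern32Kernel(),
                                   mode="rd", config=fast_config)
            ms.append(rd_effect_size(m1, 0.0).m)
        assert abs(np.median(ms)) < 0.2

    def test_effect_mean_matches_dense_oracle(self, small_rd_data, fast_config):
        """m equals the difference of blockwise closed-form posterior means."""
        m1 = fit_discontinuous(small_rd_data, small_rd_data.partition,
                               Matern32Kernel(), mode="rd", config=fast_config)
        eff = rd_effect_size(m1, 0.0)
        kern = m1.gp.kernel.base
        sn2 = m1.noise_variance
        mu = m1.gp.mean(small_rd_data.x)[0]
        z = small_rd_data.partition.labels(small_rd_data.x)
        sides = []
        for sel in (~z, z):
            Xs, ys = small_rd_data.x[sel], small_rd_data.y[sel]
            K = kern(Xs)
            jitter = 1e-6 * np.mean(np.diag(K))
            Kinv = np.linalg.inv(K + (sn2 + jitter) * np.eye(sel.sum()))
            ks = kern(Xs, np.array([[0.0]])).ravel()
            sides.append(mu + float(ks @ Kinv @ (ys - mu)))
        assert eff.m == pytest.approx(sides[1] - sides[0], abs=1e-8)

    def test_effect_mean_equivariant_to_constant_shift(
            self, small_rd_data, fast_config):
        m1 = fit_discontinuous(small_rd_data, small_rd_data.partition,
                               Matern32Kernel(), mode="rd", config=fast_config)
        shifted = ObservedData(small_rd_data.x, small_rd_data.y + 100.0,
                               partition=small_rd_data.partition)
        m1s = fit_discontinuous(shifted, shifted.partition, Matern32Kernel(),
                                mode="rd", config=fast_config)
        assert rd_effect_size(m1s, 0.0).m == pytest.approx(
            rd_effect_size(m1, 0.0).m, abs=0.05)


class TestITSEffectCurve:
    def test_zero_effect_when_signal_continues(self, fast_config):
        """Same smooth latent on both sides: m(x) stays near zero."""
        rng = np.random.default_rng(3)
        x = np.linspace(-1, 1, 120)
        y = np.sin(3 * x) + rng.normal(0, 0.05, 120)
        data = ObservedData(x, y, partition=Partition(threshold=0.0))
        m1 = fit_discontinuous(data, data.partition, RBFKernel(), mode="its",
                               config=fast_config)
        grid = np.linspace(0, 0.8, 50)  # inside the data: no extrapolation
        eff = its_effect_curve(m1, grid)
        assert np.max(np.abs(eff.m)) < 0.25

    def test_variance_is_sum_of_side_noises(self, small_rd_data, fast_config):
        m1 = fit_discontinuous(small_rd_data, small_rd_data.partition,
                               Matern32Kernel(), mode="its", config=fast_config)
        eff = its_effect_curve(m1, np.linspace(0, 1, 20))
        assert eff.s2 == pytest.approx(
            m1.pre.noise_variance + m1.post.noise_variance, abs=1e-14)

    def test_summary_is_max_abs_of_curve(self, small_rd_data, fast_config):
        m1 = fit_discontinuous(small_rd_data, small_rd_data.partition,
                               Matern32Kernel(), mode="its", config=fast_config)
        eff = its_effect_curve(m1, np.linspace(0, 1, 20))
        assert abs(eff.summary) == pytest.approx(np.max(np.abs(eff.m)), abs=1e-14)

    def test_empty_grid_rejected(self, small_rd_data, fast_config):
        m1 = fit_discontinuous(small_rd_data, small_rd_data.partition,
                               Matern32Kernel(), mode="its", config=fast_config)
        with pytest.raises(ValueError, match="grid"):
            its_effect_curve(m1, [])


class TestGeoEffectCurve:
    @staticmethod
    def _surface(rng, n, offset_south=0.0):
        """Smooth 2-D surface with an optional additive offset below y=0."""
        X = rng.uniform(-1, 1, size=(n, 2))
        y = np.sin(1.5 * X[:, 0]) + 0.5 * np.cos(2.0 * X[:, 1])
        y = y + offset_south * (X[:, 1] < 0) + rng.normal(0, 0.05, n)
        return ObservedData(X, y)

    BOUNDARY = np.array([[-1.0, 0.0], [1.0, 0.0]])

    def test_shared_surface_gives_small_effect(self, fast_config):
        maxs = []
        for seed in range(5):
            data = self._surface(np.random.default_rng(seed), 150)
            part = Partition(boundary=self.BOUNDARY)
            m1 = fit_discontinuous(data, part, RBFKernel(), mode="geo",
                                   config=fast_config)
            pts = arc_length_samples(self.BOUNDARY, 20)
            eff = geo_effect_curve(m1, pts)
            maxs.append(np.max(np.abs(eff.m) / (3 * np.sqrt(eff.s2))))
        assert np.median(maxs) < 1.0

    def test_constant_offset_recovered_along_boundary(self, fast_config):
        data = self._surface(np.random.default_rng(7), 400, offset_south=2.0)
        part = Partition(boundary=self.BOUNDARY)
        m1 = fit_discontinuous(data, part, RBFKernel(), mode="geo",
                               config=fast_config)
        # interior of the boundary, away from data-sparse ends
        pts = arc_length_samples(self.BOUNDARY, 41)[10:31]
        eff = geo_effect_curve(m1, pts)
        side_sign = 1.0 if part.labels(np.array([[0.0, -0.5]]))[0] else -1.0
        offs = side_sign * np.asarray(eff.m)
        assert np.all(np.abs(offs - 2.0) < 0.2)

    def test_reduces_to_rd_for_embedded_1d_data(self, fast_config):
        """1-D data on the line y = 0 with a vertical boundary reproduces
        the scalar RD effect at the crossing point."""
        rng = np.random.default_rng(11)
        x = rng.uniform(-1, 1, 80)
        y = 0.3 * x + 1.5 * (x >= 0) + rng.normal(0, 0.2, 80)
        X2 = np.column_stack([x, np.zeros_like(x)])
        boundary = np.array([[0.0, -1.0], [0.0, 1.0]])
        part2 = Partition(boundary=boundary)
        data2 = ObservedData(X2, y)

        kern = RBFKernel(variance=1.0, lengthscale=0.5)
        cfg = OptimizerConfig(n_restarts=1, seed=0, maxiter=0)  # frozen theta
        m_geo = fit_discontinuous(data2, part2, kern.copy(), mode="geo",
                                  config=cfg)
        eff_geo = geo_effect_curve(m_geo, np.array([[0.0, 0.0]]))

        data1 = ObservedData(x, y, partition=Partition(threshold=0.0))
        m_rd = fit_discontinuous(data1, data1.partition, kern.copy(),
                                 mode="rd", config=cfg)
        eff_rd = rd_effect_size(m_rd, 0.0)
        # the polyline orientation fixes which side is "post"; the jump
        # magnitude must agree with the 1-D analysis either way
        assert abs(float(np.asarray(eff_geo.m)[0])) == pytest.approx(
            abs(eff_rd.m), abs=1e-6)


def test_fit_continuous_equals_fit_gp(small_rd_data, fast_config):
    m_a = fit_continuous(small_rd_data, Matern32Kernel(), config=fast_config)
    m_b = fit_gp(small_rd_data, Matern32Kernel(), config=fast_config)
    assert m_a.log_marginal == m_b.log_marginal
    assert np.array_equal(m_a.gp.get_unconstrained(), m_b.gp.get_unconstrained())
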
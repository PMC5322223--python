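import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from coartsim import (ConfigurationError, CoarticulationSpec, GaussianParams,
                      RejectionExhaustedError, coarticulated_density,
                      coarticulation_moments, product_gaussian_oracle,
                      sample_coarticulated, sample_signaling)


def numeric_product_moments(means, variances, span=12.0, n=40001):
    """Independent oracle: integrate the pointwise product on a fine grid."""
    lo = min(means) - span
    hi = max(means) + span
    x = np.linspace(lo, hi, n)
    dens = np.ones_like(x)
    for m, v in zip(means, variances):
        dens *= stats.norm.pdf(x, m, np.sqrt(v))
    dens /= np.trapezoid(dens, x)
    mean = np.trapezoid(x * dens, x)
    var = np.trapezoid((x - mean) ** 2 * dens, x)
    return mean, var


class TestProductGaussianOracle:
    def test_single_component_identity(self):
        gp = product_gaussian_oracle([GaussianParams([0.3], [0.7])])
        np.testing.assert_allclose(gp.mean, [0.3])
        np.testing.assert_allclose(gp.var, [0.7])

    @pytest.mark.parametrize("means,variances,exp_mean,exp_var", [
        ((0.0, 2.0), (1.0, 1.0), 1.0, 0.5),
        ((0.0, 0.0), (1.0, 4.0), 0.0, 0.8),
    ])
    def test_known_products(self, means, variances, exp_mean, exp_var):
        comps = [GaussianParams([m], [v]) for m, v in zip(means, variances)]
        gp = product_gaussian_oracle(comps)
        np.testing.assert_allclose(gp.mean, [exp_mean], atol=1e-12)
        np.testing.assert_allclose(gp.var, [exp_var], atol=1e-12)
        # cross-check against numerical integration of the pointwise product
        num_mean, num_var = numeric_product_moments(means, variances)
        np.testing.assert_allclose(gp.mean[0], num_mean, atol=1e-6)
        np.testing.assert_allclose(gp.var[0], num_var, atol=1e-6)

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            product_gaussian_oracle([])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.floats(-3, 3), st.floats(0.1, 4.0)),
                    min_size=1, max_size=4))
    def test_product_properties(self, comps):
        gps = [GaussianParams([m], [v]) for m, v in comps]
        out = product_gaussian_oracle(gps)
        # precision accumulates: variance no larger than any component's
        assert out.var[0] <= min(v for _, v in comps) + 1e-12
        # mean is a convex combination of component means
        ms = [m for m, _ in comps]
        assert min(ms) - 1e-9 <= out.mean[0] <= max(ms) + 1e-9


class TestCoarticulatedDensity:
    def test_identical_gaussians_halve_variance(self, make_lib_1d, spec_1d):
        lib = make_lib_1d(0.0, 1.0, 0.0, 1.0)
        spec = spec_1d()
        x = np.linspace(-4, 4, 801)
        dens = np.array([coarticulated_density(np.array([xi]), 100.0, lib, spec)
                         for xi in x])
        dens /= np.trapezoid(dens, x)
        np.testing.assert_allclose(dens, stats.norm.pdf(x, 0.0, np.sqrt(0.5)),
                                   atol=1e-6)

    def test_shifted_product_matches_precision_weighting(self, make_lib_1d, spec_1d):
        lib = make_lib_1d(0.0, 1.0, 2.0, 1.0)
        x = np.linspace(-4, 6, 1001)
        dens = np.array([coarticulated_density(np.array([xi]), 0.0, lib, spec_1d())
                         for xi in x])
        dens /= np.trapezoid(dens, x)
        np.testing.assert_allclose(dens, stats.norm.pdf(x, 1.0, np.sqrt(0.5)),
                                   atol=1e-6)

    def test_zero_weight_reduces_to_primary(self, make_lib_1d, spec_1d):
        lib = make_lib_1d(0.0, 1.0, 2.0, 1.0)
        x = np.linspace(-8, 8, 1601)
        dens = np.array([coarticulated_density(np.array([xi]), 0.0, lib, spec_1d(w=0.0))
                         for xi in x])
        dens /= np.trapezoid(dens, x)
        np.testing.assert_allclose(dens, stats.norm.pdf(x, 0.0, 1.0), atol=1e-6)

    def test_time_domain_error(self, make_lib_1d, spec_1d):
        lib = make_lib_1d(0.0, 1.0, 2.0, 1.0)
        with pytest.raises(ValueError, match="outside"):
            coarticulated_density(np.array([0.0]), 2000.0, lib, spec_1d())


class TestRejectionSampler:
    def sample_many(self, lib, spec, n, seed, sampler=sample_coarticulated):
        rng = np.random.default_rng(seed)
        return np.array([sampler(100.0, lib, spec, rng)[0] for _ in range(n)])

    def test_matches_product_oracle(self, make_lib_1d, spec_1d):
        lib = make_lib_1d(0.0, 1.0, 2.0, 1.0)
        xs = self.sample_many(lib, spec_1d(), 20000, seed=42)
        se = np.sqrt(0.5 / xs.size)
        assert abs(xs.mean() - 1.0) < 3 * se
        assert abs(xs.var() - 0.5) / 0.5 < 0.05
        stat = stats.kstest(xs, stats.norm(1.0, np.sqrt(0.5)).cdf).statistic
        assert stat < 1.628 / np.sqrt(xs.size)  # 1% critical value

    def test_convexity_of_accepted_mean(self, make_lib_1d, spec_1d):
        lib = make_lib_1d(-1.0, 0.5, 1.5, 2.0)
        xs = self.sample_many(lib, spec_1d(), 5000, seed=7)
        assert -1.0 < xs.mean() < 1.5

    def test_weight_monotonicity_toward_future_mean(self, make_lib_1d, spec_1d):
        # With linear Eq.-style weights the accepted law jumps from the
        # primary (w=0) to the product (any w>0) and is then invariant:
        # the mean moves (weakly) monotonically toward the future mean.
        lib = make_lib_1d(0.0, 1.0, 2.0, 1.0)
        means = [self.sample_many(lib, spec_1d(w=w), 4000, seed=3).mean()
                 for w in (0.0, 0.3, 1.0)]
        assert means[0] < 0.1
        for lo, hi in zip(means, means[1:]):
            assert hi >= lo - 0.05  # non-strict within Monte-Carlo error

    def test_disjoint_primitives_exhaust(self, make_lib_1d, spec_1d):
        lib = make_lib_1d(0.0, 0.01, 10.0, 0.01)
        rng = np.random.default_rng(0)
        with pytest.raises(RejectionExhaustedError):
            sample_coarticulated(100.0, lib, spec_1d(), rng, max_tries=1000)

    def test_seeded_determinism(self, make_lib_1d, spec_1d):
        lib = make_lib_1d(0.0, 1.0, 2.0, 1.0)
        a = self.sample_many(lib, spec_1d(), 200, seed=9)
        b = self.sample_many(lib, spec_1d(), 200, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_masked_channels_only(self, lib, cfg):
        # wrist channels never participate in the cross-primitive factor
        from coartsim import coarticulation_spec_from_config
        spec = coarticulation_spec_from_config(cfg, lib, "grasp_to_pour")
        wrist = lib.group_channels(["wrist"])
        rng = np.random.default_rng(1)
        xs = np.array([sample_coarticulated(750.0, lib, spec, rng)
                       for _ in range(3000)])
        m_reach, _ = lib.channel_moments("reach_to_grasp", 750.0)
        np.testing.assert_allclose(xs[:, wrist].mean(axis=0), m_reach[wrist],
                                   atol=0.01)

    def test_moments_helper_matches_sampler(self, lib, cfg):
        from coartsim import coarticulation_spec_from_config
        spec = coarticulation_spec_from_config(cfg, lib, "grasp_to_move")
        gp = coarticulation_moments(750.0, lib, spec)
        rng = np.random.default_rng(2)
        xs = np.array([sample_coarticulated(750.0, lib, spec, rng)
                       for _ in range(4000)])
        digits = lib.group_channels(["index", "thumb"])
        np.testing.assert_allclose(xs[:, digits].mean(axis=0), gp.mean[digits],
                                   atol=0.01)
        np.testing.assert_allclose(xs[:, digits].var(axis=0), gp.var[digits],
                                   rtol=0.15)


class TestSignalingSampler:
    def test_pushed_away_from_future_primitive(self, make_lib_1d, spec_1d):
        lib = make_lib_1d(0.0, 1.0, 2.0, 1.0)
        rng = np.random.default_rng(5)
        xs = np.array([sample_signaling(100.0, lib, spec_1d(), rng)[0]
                       for _ in range(8000)])
        assert xs.mean() < -0.05

    def test_zero_weight_is_identity(self, make_lib_1d, spec_1d):
        lib = make_lib_1d(0.0, 1.0, 2.0, 1.0)
        rng = np.random.default_rng(6)
        xs = np.array([sample_signaling(100.0, lib, spec_1d(w=0.0), rng)[0]
                       for _ in range(10000)])
        stat = stats.kstest(xs, stats.norm(0.0, 1.0).cdf).statistic
        assert stat < 1.628 / np.sqrt(xs.size)

    def test_mirror_symmetry_flips_sign(self, make_lib_1d, spec_1d):
        rng = np.random.default_rng(7)
        lib_pos = make_lib_1d(0.0, 1.0, 2.0, 1.0)
        lib_neg = make_lib_1d(0.0, 1.0, -2.0, 1.0)
        xs_pos = np.array([sample_signaling(0.0, lib_pos, spec_1d(), rng)[0]
                           for _ in range(6000)])
        xs_neg = np.array([sample_signaling(0.0, lib_neg, spec_1d(), rng)[0]
                           for _ in range(6000)])
        assert xs_pos.mean() < 0 < xs_neg.mean()

    def test_opposition_to_coarticulation(self, make_lib_1d, spec_1d):
        # signaling and coarticulated means sit on opposite sides of m_i
        lib = make_lib_1d(0.0, 1.0, 2.0, 1.0)
        rng = np.random.default_rng(8)
        coa = np.array([sample_coarticulated(0.0, lib, spec_1d(), rng)[0]
                        for _ in range(6000)])
        sig = np.array([sample_signaling(0.0, lib, spec_1d(), rng)[0]
                        for _ in range(6000)])
        assert sig.mean() < 0.0 < coa.mean()


class TestSpecValidation:
    @pytest.mark.parametrize("kwargs", [
        {"window_ms": (500.0, 500.0)},
        {"dof_channels": np.array([], int)},
        {"weights": {"p": 1.0, "d": 1.5}},
        {"weights": {"p": 0.0, "d": 1.0}},
        {"max_tries": 0},
    ])
    def test_invalid_spec_raises(self, kwargs):
        base = dict(primary="p", future=("d",), weights={"p": 1.0, "d": 1.0},
                    window_ms=(500.0, 1000.0), dof_channels=np.array([0]))
        base.update(kwargs)
        with pytest.raises(ConfigurationError):
            CoarticulationSpec(**base)
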
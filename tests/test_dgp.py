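"""Primary-study data-generating process: sampling laws and OLS estimates."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from pubbias.dgp import (
    BetaSpec,
    ConditionSpec,
    SimConstants,
    draw_sample_size,
    fit_ols,
    make_colliders,
    sample_effect_table,
    simulate_dataset,
)


def truncated_abs_normal_mean(mu: float, sd: float, cut: float) -> float:
    """Numeric oracle: E[|X|] for X ~ N(mu, sd) conditioned on |X| > cut."""
    dens = lambda t: stats.norm.pdf(t, mu, sd) + stats.norm.pdf(-t, mu, sd)
    num, _ = integrate.quad(lambda t: t * dens(t), cut, np.inf)
    den, _ = integrate.quad(dens, cut, np.inf)
    return num / den


class TestSampleSize:
    def test_always_exceeds_truncation_bound(self, constants, rng):
        draws = draw_sample_size(100, constants, rng, size=50_000)
        assert draws.min() > constants.n_min

    @pytest.mark.parametrize("mu", [100.0, 500.0])
    def test_mean_matches_truncated_folded_normal(self, mu, constants, rng):
        # rounding happens before truncation, so the effective cut is 30.5
        oracle = truncated_abs_normal_mean(mu, constants.n_sd, constants.n_min + 0.5)
        draws = draw_sample_size(mu, constants, rng, size=200_000)
        assert draws.mean() == pytest.approx(oracle, rel=0.02)

    def test_invalid_mu_raises(self, constants, rng):
        with pytest.raises(ValueError):
            draw_sample_size(-5, constants, rng)

    def test_scalar_and_shaped_draws(self, constants, rng):
        assert isinstance(draw_sample_size(100, constants, rng), int)
        assert draw_sample_size(100, constants, rng, size=(3, 4)).shape == (3, 4)


class TestSimulateDataset:
    @pytest.mark.parametrize(
        "beta", [0.0, 0.5, 1.0, 2.0], ids=lambda b: f"beta={b}"
    )
    def test_xy_correlation_matches_closed_form(self, beta, constants, rng):
        # corr(x, y) = beta*sigma_x / sqrt(beta^2 sigma_x^2 + sigma_eps^2)
        expected = beta * constants.sigma_x / np.hypot(
            beta * constants.sigma_x, constants.sigma_eps
        )
        data = simulate_dataset(BetaSpec.fixed(beta), 400_000, constants, rng)
        observed = np.corrcoef(data.x, data.y)[0, 1]
        assert observed == pytest.approx(expected, abs=0.005)

    def test_rejects_sample_size_at_or_below_bound(self, constants, rng):
        with pytest.raises(ValueError):
            simulate_dataset(BetaSpec.fixed(0.0), 30, constants, rng)

    def test_heterogeneous_spec_draws_study_level_slopes(self, rng):
        spec = BetaSpec.heterogeneous()
        draws = spec.draw(rng, 50_000)
        assert 0 <= draws.min() and draws.max() <= 2
        assert np.mean(draws) == pytest.approx(1.0, abs=0.02)
        assert np.var(draws) == pytest.approx(1 / 3, abs=0.02)

    def test_discrete_mixture_option(self, rng):
        spec = BetaSpec.discrete([0.0, 0.5, 1.0, 1.5, 2.0])
        draws = spec.draw(rng, 10_000)
        assert set(np.unique(draws)) == {0.0, 0.5, 1.0, 1.5, 2.0}


class TestColliders:
    def test_moment_structure(self, constants, rng):
        data = simulate_dataset(BetaSpec.fixed(1.0), 400_000, constants, rng)
        data = make_colliders(data, constants, rng)
        assert len(data.z) == 3
        g, gy = constants.gamma, constants.gamma_y
        var_x = constants.sigma_x**2
        var_y = constants.sigma_x**2 + constants.sigma_eps**2  # beta = 1
        cov_xy = constants.sigma_x**2
        cov_xz = g * var_x + gy * cov_xy
        var_z = (g**2 * var_x + gy**2 * var_y + 2 * g * gy * cov_xy
                 + constants.sigma_z**2)
        z1 = data.z[0]
        assert np.cov(data.x, z1)[0, 1] == pytest.approx(cov_xz, abs=0.05)
        assert np.var(z1) == pytest.approx(var_z, rel=0.01)
        # distinct colliders share only the common (x, y) component
        resid_cov = np.cov(data.z[0], data.z[1])[0, 1] - (
            g**2 * var_x + gy**2 * var_y + 2 * g * gy * cov_xy
        )
        assert resid_cov == pytest.approx(0.0, abs=0.5)


class TestFitOLS:
    def test_hand_computed_bivariate_slope(self):
        from pubbias.dgp import Dataset

        data = Dataset(x=np.array([0.0, 1, 2, 3]), y=np.array([0.0, 1, 2, 4]))
        est = fit_ols(data)
        assert est.es == pytest.approx(1.3, abs=1e-12)  # 6.5 / 5

    def test_exact_linear_relation_recovered(self):
        from pubbias.dgp import Dataset

        x = np.linspace(-3, 3, 40)
        est = fit_ols(Dataset(x=x, y=2 * x))
        assert est.es == pytest.approx(2.0, abs=1e-10)
        assert est.se < 1e-8  # residuals at floating-point rounding level

    def test_matches_statsmodels_on_random_designs(self, constants, rng):
        for subset in [(), (0,), (0, 2), (0, 1, 2)]:
            data = simulate_dataset(BetaSpec.fixed(0.7), 120, constants, rng)
            data = make_colliders(data, constants, rng)
            est = fit_ols(data, subset)
            X = sm.add_constant(
                np.column_stack([data.x] + [data.z[j] for j in subset])
            )
            ref = sm.OLS(data.y, X).fit()
            assert est.es == pytest.approx(ref.params[1], abs=1e-10)
            assert est.se == pytest.approx(ref.bse[1], abs=1e-10)
            assert est.p_two_sided == pytest.approx(ref.pvalues[1], abs=1e-10)

    def test_null_significant_positive_rate(self, constants, rng):
        # P(p < .05 and slope > 0) = alpha/2 exactly under the null
        n = draw_sample_size(100, constants, rng, size=30_000)
        table = sample_effect_table(0.0, n, constants, rng)
        hits = int(np.sum((table.p < 0.05) & (table.es > 0)))
        assert stats.binomtest(hits, 30_000, 0.025).pvalue > 0.01


class TestSamplingLawFastPath:
    """The direct (es, se) sampling law must match fitting real datasets."""

    def test_distributional_equivalence_with_data_route(self, constants, rng):
        m = 3000
        n = draw_sample_size(100, constants, rng, size=m)
        fast = sample_effect_table(1.0, n, constants, rng)
        slow_es = np.empty(m)
        slow_se = np.empty(m)
        for i in range(m):
            est = fit_ols(simulate_dataset(BetaSpec.fixed(1.0), int(n[i]), constants, rng))
            slow_es[i], slow_se[i] = est.es, est.se
        assert stats.ks_2samp(fast.es, slow_es).pvalue > 1e-3
        assert stats.ks_2samp(fast.se, slow_se).pvalue > 1e-3

    def test_null_p_values_uniform(self, constants, rng):
        n = draw_sample_size(500, constants, rng, size=20_000)
        table = sample_effect_table(0.0, n, constants, rng)
        assert stats.kstest(table.p, "uniform").pvalue > 1e-3


@settings(max_examples=25, derandomize=True, deadline=None)
@given(mu=st.floats(min_value=40, max_value=800), seed=st.integers(0, 2**20))
def test_sample_size_truncation_property(mu, seed):
    draws = draw_sample_size(mu, SimConstants(), np.random.default_rng(seed), size=64)
    assert (draws > 30).all()


def test_condition_spec_validation():
    with pytest.raises(ValueError):
        ConditionSpec(BetaSpec.fixed(0), 100, 100, 0.0, "file_drawer")
    with pytest.raises(ValueError):
        ConditionSpec(BetaSpec.fixed(0), 100, 100, 0.5, "none")
    with pytest.raises(ValueError):
        SimConstants(alpha=1.5)
    with pytest.raises(ValueError):
        SimConstants(caliper_widths=(0.05, 1.5))
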
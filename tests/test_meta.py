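"""Fixed-effect pooling, heterogeneity, prevalence and deflation summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pubbias.dgp import BetaSpec, ConditionSpec, EffectTable
from pubbias.meta import (
    MetaSample,
    assemble_meta_sample,
    deflation_factor,
    fixed_effect_meta,
    i_squared,
    prevalence_shares,
    read_effect_table,
    summarize_meta_sample,
)


def _table(es, se):
    es = np.asarray(es, dtype=float)
    se = np.asarray(se, dtype=float)
    z = es / se
    p = 2 * stats.norm.sf(np.abs(z))
    return EffectTable(es=es, se=se, p=p, n=np.full(es.size, 100),
                       df=np.full(es.size, 98))


class TestFixedEffect:
    @pytest.mark.parametrize(
        "es,se,theta",
        [
            ([1, 3], [1, 1], 2.0),          # equal weights: plain mean
            ([1, 3], [1, 2], 1.4),          # (1 + 0.75) / 1.25
            ([2.5, 2.5, 2.5], [1, 2, 3], 2.5),
        ],
    )
    def test_hand_computed_estimates(self, es, se, theta):
        fe = fixed_effect_meta(np.array(es, float), np.array(se, float))
        assert fe.theta == pytest.approx(theta, abs=1e-12)

    def test_equal_weight_standard_error(self):
        fe = fixed_effect_meta(np.array([1.0, 3.0]), np.array([1.0, 1.0]))
        assert fe.se == pytest.approx(1 / np.sqrt(2), abs=1e-12)

    def test_requires_two_estimates(self):
        with pytest.raises(ValueError):
            fixed_effect_meta(np.array([1.0]), np.array([1.0]))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 2**20))
    def test_pooled_estimate_within_range(self, seed):
        r = np.random.default_rng(seed)
        es = r.normal(size=8)
        se = r.uniform(0.1, 3, size=8)
        fe = fixed_effect_meta(es, se)
        assert es.min() - 1e-12 <= fe.theta <= es.max() + 1e-12


class TestISquared:
    def test_identical_estimates_give_zero(self):
        assert i_squared(np.full(5, 1.3), np.ones(5)) == 0.0

    def test_hand_computed_two_study_case(self):
        # w = 1 each, theta = 2, Q = 8, I2 = (8 - 1)/8 = 87.5%
        assert i_squared(np.array([0.0, 4.0]), np.array([1.0, 1.0])) == pytest.approx(87.5)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 2**20), st.floats(0.05, 50))
    def test_scale_invariance(self, seed, scale):
        r = np.random.default_rng(seed)
        es = r.normal(size=12)
        se = r.uniform(0.2, 2, size=12)
        assert i_squared(es * scale, se * scale) == pytest.approx(
            i_squared(es, se), abs=1e-8
        )


class TestDeflation:
    def test_exactly_one_without_selection(self, constants, rng):
        cond = ConditionSpec(BetaSpec.fixed(0.5), 100, 200, 0.0, "none")
        sample = assemble_meta_sample(cond, constants, rng)
        assert deflation_factor(sample) == 1.0

    def test_single_flipped_estimate_matches_direct_ratio(self, constants):
        firsts = _table([0.1, -0.2, 0.3, 0.0], [0.5, 0.5, 0.5, 0.5])
        published = firsts.copy()
        published.es[1] = 1.4  # one study's selected re-run
        cond = ConditionSpec(BetaSpec.fixed(0.0), 100, 4, 0.5, "file_drawer")
        sample = MetaSample(cond, published, firsts,
                            committed=np.array([False, True, False, False]),
                            successful=np.array([False, True, False, False]))
        direct = (fixed_effect_meta(published.es, published.se).p
                  / fixed_effect_meta(firsts.es, firsts.se).p)
        assert deflation_factor(sample) == pytest.approx(direct, rel=1e-9)


class TestPrevalence:
    def test_share_arithmetic(self, constants):
        cond = ConditionSpec(BetaSpec.fixed(0.0), 100, 100, 0.5, "file_drawer")
        committed = np.zeros(100, bool)
        successful = np.zeros(100, bool)
        committed[:50] = True
        successful[:20] = True
        t = _table(np.zeros(100) + 0.1, np.ones(100))
        sample = MetaSample(cond, t, t.copy(), committed, successful)
        assert prevalence_shares(sample) == pytest.approx((0.5, 0.2, 0.4))

    def test_zero_committed_flagged(self, constants):
        cond = ConditionSpec(BetaSpec.fixed(0.0), 100, 10, 0.0, "none")
        t = _table(np.zeros(10) + 0.1, np.ones(10))
        sample = MetaSample(cond, t, t.copy(), np.zeros(10, bool), np.zeros(10, bool))
        assert np.isnan(prevalence_shares(sample)[2])


class TestAssembly:
    @pytest.mark.parametrize("form,intent", [("none", 0.0), ("file_drawer", 1.0),
                                             ("p_hacking", 1.0)])
    def test_k_estimates_regardless_of_retries(self, form, intent, constants, rng):
        cond = ConditionSpec(BetaSpec.fixed(0.0), 100, 250, intent, form)
        sample = assemble_meta_sample(cond, constants, rng)
        assert len(sample.published) == len(sample.firsts) == 250

    def test_no_bias_published_are_first_attempts(self, constants, rng):
        cond = ConditionSpec(BetaSpec.heterogeneous(), 100, 150, 0.0, "none")
        sample = assemble_meta_sample(cond, constants, rng)
        np.testing.assert_array_equal(sample.published.es, sample.firsts.es)
        assert sample.committed_count == 0 and sample.successful_count == 0

    def test_expected_committed_count_under_full_intent(self, constants, rng):
        cond = ConditionSpec(BetaSpec.fixed(0.0), 100, 400, 1.0, "file_drawer")
        sample = assemble_meta_sample(cond, constants, rng)
        assert stats.binomtest(sample.committed_count, 400, 0.975).pvalue > 1e-3

    def test_reference_method_agrees_on_structure(self, constants, rng):
        cond = ConditionSpec(BetaSpec.fixed(1.0), 100, 40, 0.5, "p_hacking")
        sample = assemble_meta_sample(cond, constants, rng, method="reference")
        summary = summarize_meta_sample(sample)
        assert 0 <= summary.committed_share <= 1
        assert 0 <= summary.i2 <= 100


class TestEffectTableIO:
    def test_csv_round_trip(self, tmp_path):
        path = tmp_path / "es.csv"
        path.write_text("es,se,n\n0.5,0.2,100\n-0.1,0.3,50\n")
        table = read_effect_table(path)
        assert table.es.tolist() == [0.5, -0.1]
        assert table.n.tolist() == [100, 50]
        assert np.all((table.p > 0) & (table.p <= 1))

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("effect,se\n0.5,0.2\n")
        with pytest.raises(ValueError, match="es"):
            read_effect_table(path)

    def test_nonpositive_se_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("es,se\n0.5,0.2\n0.1,0\n")
        with pytest.raises(ValueError, match="line.* 3"):
            read_effect_table(path)
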
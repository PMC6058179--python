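"""Category probabilities, information, SE/reliability, and log-likelihood."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from depcat import (category_probs, item_information,
                    reliability_from_information, response_loglikelihood,
                    se_from_information)
from depcat import test_information as total_information
from depcat.bank import ItemParameters
from depcat.models import QuadratureGrid, category_prob_derivs

# ---------------------------------------------------------------------------
# hypothesis strategies: random valid items of every model
# ---------------------------------------------------------------------------

finite = st.floats(-2.0, 2.0, allow_nan=False)


@st.composite
def random_item(draw, models=("GRM", "GPCM", "PCM", "RSM", "NRM")):
    model = draw(st.sampled_from(models))
    K = draw(st.integers(2, 5))
    a = draw(st.floats(0.3, 3.0))
    if model == "GRM":
        base = draw(st.lists(finite, min_size=K - 1, max_size=K - 1))
        b = np.sort(np.array(base)) + np.arange(K - 1) * 0.05
        return ItemParameters("h", model, K, a=a, b=tuple(b))
    if model in ("GPCM", "PCM"):
        steps = draw(st.lists(finite, min_size=K - 1, max_size=K - 1))
        return ItemParameters("h", model, K, a=a, steps=tuple(steps))
    if model == "RSM":
        taus = draw(st.lists(finite, min_size=K - 1, max_size=K - 1))
        loc = draw(finite)
        return ItemParameters("h", model, K, a=a, location=loc,
                              taus=tuple(taus))
    slopes = [0.0] + draw(st.lists(finite, min_size=K - 1, max_size=K - 1))
    icpts = [0.0] + draw(st.lists(finite, min_size=K - 1, max_size=K - 1))
    return ItemParameters("h", model, K, slopes=tuple(slopes),
                          intercepts=tuple(icpts))


class TestCategoryProbs:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(item=random_item(), theta=st.floats(-6.0, 6.0))
    def test_probabilities_normalize_for_every_model(self, item, theta):
        P = category_probs(item, theta)
        assert P.shape == (item.n_categories,)
        assert np.all(P >= 0) and np.all(P <= 1)
        assert abs(P.sum() - 1.0) < 1e-12

    def test_grm_cumulative_half_at_own_threshold(self, table4_bank):
        # logistic(a(θ-b)) = 1/2 exactly at θ = b
        item1 = table4_bank.items[0]
        P = category_probs(item1, -0.67)
        p_ge_1 = P[1:].sum()
        assert p_ge_1 == pytest.approx(0.5, abs=1e-12)

    def test_grm_matches_two_logistic_hand_evaluation(self, table4_bank):
        # direct arithmetic with the cumulative-logistic formula, item 13
        item13 = table4_bank.items[table4_bank.index_of("13")]
        a, b = 2.32, (0.36, 1.62, 2.50)

        def cum(bk):
            return 1.0 / (1.0 + math.exp(-a * (0.0 - bk)))

        expected = [1.0 - cum(b[0]), cum(b[0]) - cum(b[1]),
                    cum(b[1]) - cum(b[2]), cum(b[2])]
        np.testing.assert_allclose(category_probs(item13, 0.0), expected,
                                   atol=1e-12)

    def test_nrm_zero_parameters_are_uniform(self):
        item = ItemParameters("n", "NRM", 4, slopes=(0.0,) * 4,
                              intercepts=(0.0,) * 4)
        np.testing.assert_allclose(category_probs(item, 1.3), [0.25] * 4)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(item=random_item(models=("GRM",)),
           th=st.floats(-4.0, 3.9))
    def test_grm_cumulative_monotone_in_theta_and_category(self, item, th):
        P_lo = category_probs(item, th)
        P_hi = category_probs(item, th + 0.1)
        cum_lo = P_lo[::-1].cumsum()[::-1]        # P(score >= k)
        cum_hi = P_hi[::-1].cumsum()[::-1]
        assert np.all(np.diff(cum_lo[1:]) <= 1e-12)   # decreasing in k
        assert np.all(cum_hi[1:] >= cum_lo[1:] - 1e-12)  # increasing in θ

    def test_unknown_model_rejected(self):
        item = ItemParameters("x", "RASCH", 2)
        assert item.violations()
        with pytest.raises(ValueError):
            category_probs(item, 0.0)


class TestModelNesting:
    def test_pcm_is_gpcm_with_common_slope(self):
        steps = (-0.5, 0.2, 1.1)
        pcm = ItemParameters("p", "PCM", 4, a=1.3, steps=steps)
        gpcm = ItemParameters("p", "GPCM", 4, a=1.3, steps=steps)
        th = np.linspace(-4, 4, 33)
        np.testing.assert_allclose(category_probs(pcm, th),
                                   category_probs(gpcm, th), atol=1e-14)

    def test_rsm_is_pcm_with_location_plus_shared_offsets(self):
        taus = (-0.7, 0.1, 0.6)
        loc = 0.4
        rsm = ItemParameters("r", "RSM", 4, a=1.0, location=loc, taus=taus)
        pcm = ItemParameters("r", "PCM", 4, a=1.0,
                             steps=tuple(loc + t for t in taus))
        th = np.linspace(-4, 4, 33)
        np.testing.assert_allclose(category_probs(rsm, th),
                                   category_probs(pcm, th), atol=1e-14)


class TestInformation:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(item=random_item(), theta=st.floats(-4.0, 4.0))
    def test_information_matches_finite_difference_oracle(self, item, theta):
        eps = 1e-5
        P = category_probs(item, theta)
        dP = (category_probs(item, theta + eps)
              - category_probs(item, theta - eps)) / (2 * eps)
        oracle = float((dP ** 2 / np.maximum(P, 1e-10)).sum())
        assert item_information(item, theta) == pytest.approx(oracle,
                                                              abs=1e-6)

    def test_information_nonnegative_across_grid(self, table4_bank):
        grid = np.linspace(-4, 4, 100)
        for item in table4_bank:
            assert np.all(item_information(item, grid) >= 0)

    def test_information_vanishes_in_logistic_tails(self, table4_bank):
        # information decays like a^2 exp(-a|θ-b|) beyond the outermost
        # threshold; the lower tail is already negligible at θ=-8, while
        # the upper tail needs more room (one item has b3=5.39, a=0.84)
        for item in table4_bank:
            assert item_information(item, -8.0) < 5e-3
            assert item_information(item, 20.0) < 1e-4
            assert item_information(item, -20.0) < 1e-6
            assert item_information(item, 8.0) < item_information(
                item, max(item.b))

    def test_derivatives_sum_to_zero(self, table4_bank):
        _, dP = category_prob_derivs(table4_bank.items[10], 0.7)
        assert abs(dP.sum()) < 1e-12


class TestTestInformation:
    def test_singleton_subset_equals_item_information(self, table4_bank):
        theta = 0.5
        got = total_information(table4_bank, ["13"], theta)
        want = item_information(
            table4_bank.items[table4_bank.index_of("13")], theta)
        assert got == pytest.approx(want, rel=1e-14)

    def test_full_bank_equals_per_item_summation_oracle(self, table4_bank):
        theta = 0.0
        brute = sum(item_information(it, theta) for it in table4_bank)
        assert total_information(table4_bank, None, theta) == pytest.approx(
            brute, rel=1e-12)

    def test_additive_in_disjoint_subsets(self, table4_bank):
        s1 = table4_bank.item_ids[:10]
        s2 = table4_bank.item_ids[10:25]
        theta = -0.8
        assert total_information(table4_bank, s1 + s2, theta) == \
            pytest.approx(total_information(table4_bank, s1, theta)
                          + total_information(table4_bank, s2, theta),
                          rel=1e-12)

    def test_empty_subset_is_zero(self, table4_bank):
        assert total_information(table4_bank, [], 0.0) == 0.0


class TestSeAndReliability:
    def test_se_closed_forms(self):
        assert se_from_information(25.0) == pytest.approx(0.2)
        assert se_from_information(4.0) == pytest.approx(0.5)

    def test_se_undefined_at_zero_information(self):
        with pytest.raises(ValueError):
            se_from_information(0.0)

    def test_reliability_closed_forms(self):
        assert reliability_from_information(25.0) == pytest.approx(0.96)
        assert reliability_from_information(1.0) == pytest.approx(0.0)

    def test_reliability_pairs_with_se(self):
        # mean SE 0.20 pairs with marginal reliability 1 - 0.20^2 = 0.96
        info = 1.0 / 0.20 ** 2
        r = reliability_from_information(info)
        assert r == pytest.approx(1.0 - se_from_information(info) ** 2,
                                  abs=1e-12)
        assert r == pytest.approx(0.96)

    def test_low_information_warns_not_clips(self):
        with pytest.warns(RuntimeWarning):
            r = reliability_from_information(0.5)
        assert r == pytest.approx(-1.0)


class TestResponseLoglikelihood:
    def test_single_item_is_log_probability(self, table4_bank):
        item = table4_bank.items[0]
        theta = 0.3
        p = category_probs(item, theta)[2]
        ll = response_loglikelihood([2], [item], theta)
        assert ll == pytest.approx(np.log(p), abs=1e-12)

    def test_all_missing_is_zero(self, table4_bank):
        ll = response_loglikelihood([-1] * 5, table4_bank.items[:5], 1.1)
        assert ll == 0.0

    def test_matches_product_of_probabilities_oracle(self, table4_bank):
        items = table4_bank.items[:5]
        pattern = [0, 3, 1, 2, 2]
        theta = -0.4
        prod = 1.0
        for x, item in zip(pattern, items):
            prod *= category_probs(item, theta)[x]
        assert response_loglikelihood(pattern, items, theta) == \
            pytest.approx(math.log(prod), abs=1e-10)

    def test_out_of_range_category_rejected(self, table4_bank):
        with pytest.raises(ValueError):
            response_loglikelihood([4], table4_bank.items[:1], 0.0)


class TestQuadratureGrid:
    def test_default_grid_normalized_and_increasing(self):
        g = QuadratureGrid.standard_normal()
        assert len(g) == 61
        assert g.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(g.nodes) > 0)

    def test_decreasing_nodes_rejected(self):
        with pytest.raises(ValueError):
            QuadratureGrid(np.array([0.0, -1.0]), np.array([0.5, 0.5]))
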
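import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from irtval.banks import Item, ItemBank, QuadratureGrid
from irtval.grm import (
    category_probabilities,
    eap_score,
    eap_scores,
    item_information,
    log_likelihood,
)
from irtval.grm import test_information as bank_information


def random_item(draw):
    a = draw(st.floats(0.2, 4.0))
    k = draw(st.integers(2, 6))
    cuts = sorted(draw(st.lists(st.floats(-3.0, 3.0), min_size=k - 1,
                                max_size=k - 1, unique=True)))
    if any(y - x < 1e-3 for x, y in zip(cuts, cuts[1:])):
        cuts = [c + 0.01 * i for i, c in enumerate(cuts)]
    return Item(id="it", a=a, b=tuple(cuts))


class TestCategoryProbabilities:
    @settings(max_examples=50, derandomize=True)
    @given(st.data())
    def test_sum_to_one_and_nonnegative(self, data):
        item = random_item(data.draw)
        theta = data.draw(st.floats(-4, 4))
        p = category_probabilities(item, theta)
        assert p.shape == (item.n_categories,)
        assert np.all(p >= 0)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(st.data())
    def test_cumulative_curves_ordered_and_increasing(self, data):
        """P(X>=k) decreases in k and increases in theta for a > 0."""
        item = random_item(data.draw)
        thetas = np.linspace(-4, 4, 40)
        p = category_probabilities(item, thetas)
        cum = np.cumsum(p[:, ::-1], axis=1)[:, ::-1]  # P(X >= k)
        assert np.all(np.diff(cum[:, 1:], axis=1) <= 1e-12)
        assert np.all(np.diff(cum[:, 1:], axis=0) >= -1e-12)

    def test_half_probability_at_threshold(self):
        item = Item(id="x", a=1.0, b=(-0.7, 0.4, 1.1))
        for k, bk in enumerate(item.b):
            p = category_probabilities(item, bk)
            assert np.sum(p[k + 1:]) == pytest.approx(0.5, abs=1e-12)

    def test_symmetric_item_values(self):
        """a=2, b=(-1,0,1) at theta=0: outer categories 1/(1+e^2)."""
        item = Item(id="x", a=2.0, b=(-1.0, 0.0, 1.0))
        p = category_probabilities(item, 0.0)
        lo = 1.0 / (1.0 + np.exp(2.0))
        np.testing.assert_allclose(p, [lo, 0.5 - lo, 0.5 - lo, lo], atol=1e-12)

    def test_rejects_nonfinite_theta(self):
        item = Item(id="x", a=1.0, b=(0.0,))
        with pytest.raises(ValueError):
            category_probabilities(item, np.nan)


class TestLogLikelihood:
    def bank(self):
        return ItemBank([
            Item(id="a", a=1.5, b=(-1.0, 0.2, 1.0)),
            Item(id="b", a=0.8, b=(-0.5, 0.5, 1.5)),
            Item(id="c", a=2.2, b=(-2.0, -1.0, 0.0)),
        ])

    def test_empty_response_set_is_zero(self):
        bank = self.bank()
        assert log_likelihood(bank, np.empty((0, 3)), []) == 0.0

    def test_uniform_item_gives_log_inverse_k(self):
        """An item whose thresholds sit at the logit quartile points makes
        every category equally likely at theta=0, so any single response
        contributes log(1/K)."""
        logit = lambda p: np.log(p / (1 - p))
        b = tuple(-logit(1 - k / 4) for k in (1, 2, 3))
        bank = ItemBank([Item(id="a", a=1.0, b=b)])
        for cat in (1, 2, 3, 4):
            ll = log_likelihood(bank, np.array([[float(cat)]]), [0.0])
            assert ll == pytest.approx(np.log(1 / 4), abs=1e-12)

    def test_matches_per_cell_loop(self):
        """Vectorized likelihood equals an explicit per-cell accumulation
        written directly from the logistic GRM formula."""
        bank = self.bank()
        rng = np.random.default_rng(5)
        X = rng.integers(1, 5, size=(20, 3)).astype(float)
        thetas = rng.normal(size=20)
        expected = 0.0
        for i in range(20):
            for j, it in enumerate(bank):
                b = np.concatenate([[-np.inf], it.b, [np.inf]])
                k = int(X[i, j])
                hi = expit(it.a * (thetas[i] - b[k - 1])) if np.isfinite(b[k - 1]) else 1.0
                lo = expit(it.a * (thetas[i] - b[k])) if np.isfinite(b[k]) else 0.0
                expected += np.log(hi - lo)
        assert log_likelihood(bank, X, thetas) == pytest.approx(expected, rel=1e-10)

    def test_out_of_range_category_raises(self):
        bank = self.bank()
        with pytest.raises(ValueError, match="out of range"):
            log_likelihood(bank, np.array([[5.0, 1.0, 1.0]]), [0.0])


class TestInformation:
    def test_flat_item_has_no_information(self):
        weak = Item(id="x", a=1e-4, b=(-1.0, 1.0))
        assert item_information(weak, 0.5) == pytest.approx(0.0, abs=1e-6)

    def test_binary_item_information_scales_as_a_squared_at_threshold(self):
        b = (0.3,)
        i1 = item_information(Item(id="x", a=1.0, b=b), 0.3)
        i2 = item_information(Item(id="x", a=2.0, b=b), 0.3)
        assert i2 / i1 == pytest.approx(4.0, rel=1e-10)

    def test_test_information_is_sum_of_items(self):
        bank = ItemBank([Item(id="a", a=1.5, b=(-1.0, 0.5)),
                         Item(id="b", a=2.5, b=(0.0, 1.0))])
        total = bank_information(bank, 0.7)
        parts = sum(item_information(it, 0.7) for it in bank)
        assert total == pytest.approx(parts, rel=1e-12)

    @settings(max_examples=30, derandomize=True)
    @given(st.data())
    def test_expected_score_monotone_in_theta(self, data):
        item = random_item(data.draw)
        thetas = np.linspace(-4, 4, 60)
        p = category_probabilities(item, thetas)
        escore = p @ np.arange(1, item.n_categories + 1)
        assert np.all(np.diff(escore) >= -1e-10)


class TestEAP:
    def symmetric_bank(self):
        return ItemBank([
            Item(id="a", a=1.4, b=(-1.5, -0.5, 0.5, 1.5)),
            Item(id="b", a=2.0, b=(-2.0, -1.0, 1.0, 2.0)),
        ])

    def test_symmetric_pattern_scores_at_center(self):
        bank = self.symmetric_bank()
        est = eap_score(bank, {"a": 3, "b": 3})
        assert est.theta == pytest.approx(0.0, abs=1e-10)
        assert est.t_score == pytest.approx(50.0, abs=1e-8)

    def test_subset_scoring_uses_only_covered_items(self):
        bank = self.symmetric_bank()
        est = eap_score(bank, {"a": 5})
        assert est.n_items_used == 1
        assert est.theta > 0

    def test_empty_response_vector_rejected(self):
        bank = self.symmetric_bank()
        with pytest.raises(ValueError):
            eap_score(bank, {})

    def test_all_maximum_pattern_is_finite_with_large_se(self):
        """Ceiling responders get a prior-dominated but finite estimate."""
        from irtval.banks import peer_bank
        bank = peer_bank()
        top = {it.id: it.n_categories for it in bank}
        mid = {it.id: 3 for it in bank}
        est_top = eap_score(bank, top)
        est_mid = eap_score(bank, mid)
        assert np.isfinite(est_top.theta) and np.isfinite(est_top.se)
        assert est_top.se > est_mid.se

    def test_se_weakly_decreases_as_items_accumulate(self):
        from irtval.banks import peer_bank
        from irtval.datasets import SimulationConfig, generate_responses
        bank = peer_bank()
        rm = generate_responses(SimulationConfig(
            n_respondents=20, ceiling_fraction=0.0, seed=9)).recoded(bank)
        for i in range(10):
            row = rm.data.iloc[i]
            prev_se = np.inf
            for k in (3, 6, 10, 15):
                ids = bank.item_ids[:k]
                est = eap_score(bank, {j: row[j] for j in ids})
                assert est.se <= prev_se + 1e-9
                prev_se = est.se
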
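import numpy as np
import pandas as pd
import pytest

from irtval.banks import Item, ItemBank, QuadratureGrid, peer_bank
from irtval.datasets import (
    DIFSpec,
    SimulationConfig,
    generate_legacy_instrument,
    generate_responses,
    generate_two_group,
)
from irtval.grm import category_probabilities
from irtval.metrics import score_legacy


class TestGenerateResponses:
    def test_seeded_output_is_bit_reproducible(self):
        cfg = SimulationConfig(n_respondents=100, seed=7)
        a = generate_responses(cfg)
        b = generate_responses(cfg)
        pd.testing.assert_frame_equal(a.data, b.data)
        np.testing.assert_array_equal(a.true_theta, b.true_theta)

    def test_full_ceiling_forces_every_cell_to_top(self):
        cfg = SimulationConfig(n_respondents=40, ceiling_fraction=1.0, seed=0)
        rm = generate_responses(cfg)
        assert (rm.data.to_numpy() == 5).all()

    def test_easy_item_concentrates_in_top_category(self):
        """a=3, thresholds (-4,-3,-2,-1): most responses land in the top
        category, and the sample fraction matches the analytic category
        probability integrated over N(0,1) by quadrature."""
        item = Item(id="easy", a=3.0, b=(-4.0, -3.0, -2.0, -1.0))
        grid = QuadratureGrid.normal_prior(2001, -8, 8)
        p_top = float(np.sum(grid.weights
                             * category_probabilities(item, grid.nodes)[:, -1]))
        assert p_top > 0.75  # the marginal (integrated) value is ~0.806
        cfg = SimulationConfig(n_respondents=5000, item_bank=ItemBank([item]),
                               ceiling_fraction=0.0, seed=13)
        frac = (generate_responses(cfg).data["easy"] == 5).mean()
        assert frac == pytest.approx(p_top, abs=0.02)

    def test_study_scale_ceiling_subgroup_size(self):
        """6.3% of 527 respondents are forced to all-maximum (33 people)."""
        cfg = SimulationConfig(n_respondents=527, ceiling_fraction=0.063, seed=2)
        rm = generate_responses(cfg)
        all_max = (rm.data.to_numpy() == 5).all(axis=1).sum()
        natural = (generate_responses(
            SimulationConfig(n_respondents=527, ceiling_fraction=0.0, seed=2)
        ).data.to_numpy() == 5).all(axis=1).sum()
        assert all_max >= 33
        assert all_max <= 33 + natural + 5

    def test_category_frequencies_converge_to_model(self):
        item = Item(id="x", a=1.6, b=(-1.2, -0.3, 0.5, 1.4))
        cfg = SimulationConfig(n_respondents=50_000, item_bank=ItemBank([item]),
                               ceiling_fraction=0.0, seed=19)
        rm = generate_responses(cfg)
        grid = QuadratureGrid.normal_prior(401, -8, 8)
        marginal = grid.weights @ category_probabilities(item, grid.nodes)
        observed = np.bincount(rm.data["x"], minlength=6)[1:] / 50_000
        np.testing.assert_allclose(observed, marginal, atol=0.01)

    def test_true_theta_population_moments(self):
        cfg = SimulationConfig(n_respondents=20_000, theta_mean=0.4,
                               theta_sd=1.3, ceiling_fraction=0.0, seed=23)
        th = generate_responses(cfg).true_theta.to_numpy()
        assert th.mean() == pytest.approx(0.4, abs=3 * 1.3 / np.sqrt(20_000))
        assert th.std() == pytest.approx(1.3, rel=0.05)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_respondents=0)
        with pytest.raises(ValueError):
            SimulationConfig(n_respondents=10, ceiling_fraction=1.5)
        with pytest.raises(ValueError, match="unknown items"):
            SimulationConfig(n_respondents=10,
                             dif_spec=DIFSpec(threshold_shift={"nope": 0.5}))


class TestTwoGroup:
    def test_identical_configs_are_exchangeable(self):
        bank = peer_bank()
        cfg_a = SimulationConfig(n_respondents=4000, item_bank=bank,
                                 ceiling_fraction=0.0, seed=31)
        cfg_b = SimulationConfig(n_respondents=4000, item_bank=bank,
                                 ceiling_fraction=0.0, seed=32)
        rm = generate_two_group(cfg_a, cfg_b)
        assert list(rm.group.unique()) == ["A", "B"]
        for item in ("peer01", "peer08"):
            fa = rm.data[rm.group == "A"][item].value_counts(normalize=True)
            fb = rm.data[rm.group == "B"][item].value_counts(normalize=True)
            diff = (fa.reindex(range(1, 6), fill_value=0)
                    - fb.reindex(range(1, 6), fill_value=0)).abs().max()
            assert diff < 0.04

    def test_threshold_shift_lowers_group_b_responses_at_matched_theta(self):
        bank = peer_bank()
        cfg_a = SimulationConfig(n_respondents=5000, item_bank=bank,
                                 ceiling_fraction=0.0, seed=33)
        cfg_b = SimulationConfig(n_respondents=5000, item_bank=bank,
                                 ceiling_fraction=0.0, seed=34,
                                 dif_spec=DIFSpec(threshold_shift={"peer05": 0.6}))
        rm = generate_two_group(cfg_a, cfg_b)
        theta = rm.true_theta.to_numpy()
        mid = (theta > -0.5) & (theta < 0.5)
        grp_b = (rm.group == "B").to_numpy()
        mean_a = rm.data.loc[mid & ~grp_b, "peer05"].mean()
        mean_b = rm.data.loc[mid & grp_b, "peer05"].mean()
        assert mean_b < mean_a - 0.1

    def test_discrimination_ratio_weakens_item_trait_correlation(self):
        bank = peer_bank()
        cfg_a = SimulationConfig(n_respondents=5000, item_bank=bank,
                                 ceiling_fraction=0.0, seed=35)
        cfg_b = SimulationConfig(n_respondents=5000, item_bank=bank,
                                 ceiling_fraction=0.0, seed=36,
                                 dif_spec=DIFSpec(discrimination_ratio={"peer06": 0.5}))
        rm = generate_two_group(cfg_a, cfg_b)
        grp_b = (rm.group == "B").to_numpy()
        theta = rm.true_theta.to_numpy()
        r_a = np.corrcoef(rm.data.loc[~grp_b, "peer06"], theta[~grp_b])[0, 1]
        r_b = np.corrcoef(rm.data.loc[grp_b, "peer06"], theta[grp_b])[0, 1]
        assert r_b < r_a - 0.05

    def test_mismatched_banks_rejected(self):
        small = ItemBank([Item(id="x", a=1.0, b=(0.0,))])
        cfg_a = SimulationConfig(n_respondents=10, item_bank=small, seed=0,
                                 ceiling_fraction=0.0)
        cfg_b = SimulationConfig(n_respondents=10, seed=1)
        with pytest.raises(ValueError, match="same item identifiers"):
            generate_two_group(cfg_a, cfg_b)


class TestLegacyInstrument:
    def base_responses(self, n=5000, seed=41):
        return generate_responses(SimulationConfig(
            n_respondents=n, ceiling_fraction=0.0, seed=seed))

    def test_layout_is_23_items_in_8_5_5_5_subscales(self):
        rm = self.base_responses(n=200)
        leg = generate_legacy_instrument(rm, target_r=0.8, seed=1)
        assert len(leg.item_ids) == 23
        counts = {name: sum(c.startswith(name) for c in leg.item_ids)
                  for name in ("physical", "emotional", "social", "school")}
        assert counts == {"physical": 8, "emotional": 5, "social": 5, "school": 5}

    def test_strong_target_r_gives_strong_subscale_correlation(self):
        rm = self.base_responses()
        leg = generate_legacy_instrument(rm, target_r=0.99, seed=2)
        scores = score_legacy(leg)
        r = np.corrcoef(scores["social"], rm.true_theta)[0, 1]
        # a 5-item ordinal subscale attenuates the latent 0.99 to ~0.89
        assert r > 0.85

    def test_weak_target_r_gives_near_zero_correlation(self):
        rm = self.base_responses()
        leg = generate_legacy_instrument(rm, target_r=0.01, seed=3)
        scores = score_legacy(leg)
        r = np.corrcoef(scores["social"], rm.true_theta)[0, 1]
        assert abs(r) < 0.1

    def test_target_r_must_be_in_open_unit_interval(self):
        rm = self.base_responses(n=50)
        for bad in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                generate_legacy_instrument(rm, target_r=bad, seed=0)
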
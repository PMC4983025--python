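"""Consensus index aggregation: means, sign scenarios, ranks, identities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pmpotency as pm
from pmpotency.exceptions import ConfigurationError, InsufficientDataError
from pmpotency.integrate import HI, LO

finite_beta = st.floats(min_value=-1.0, max_value=1.0, allow_nan=False)
beta_lists = st.lists(finite_beta, min_size=1, max_size=8)


def simple_config():
    roles = {
        "U/CYT-A": "pro_inflammatory",
        "U/IL-6": "dual_inflammatory",
        "U/IL-10": "anti_inflammatory",
        "U/VIA": "viability",
    }
    return pm.ScenarioConfig(roles=roles)


class TestCombiners:
    def test_viability_is_plain_mean(self):
        assert pm.combine_viability([-0.1, -0.2, -0.3, -0.4]) == pytest.approx(-0.25)
        assert pm.combine_viability([-0.17]) == -0.17

    def test_cells_level_viability_averages_units(self):
        assert pm.combine_viability([-0.25, -0.15]) == pytest.approx(-0.20)

    def test_reactivity_is_mean_of_absolutes(self):
        assert pm.combine_reactivity([-0.1, 0.2, -0.3, 0.05]) == pytest.approx(0.1625)
        assert pm.combine_reactivity([0.0, 0.0]) == 0.0

    @given(betas=beta_lists)
    def test_reactivity_dominates_absolute_viability(self, betas):
        assert pm.combine_reactivity(betas) >= abs(pm.combine_viability(betas)) - 1e-15

    def test_empty_inputs_are_insufficient(self):
        for fn in (pm.combine_viability, pm.combine_reactivity):
            with pytest.raises(InsufficientDataError):
                fn([])
            with pytest.raises(InsufficientDataError):
                fn([np.nan])

    def test_missing_inputs_shrink_the_denominator(self):
        assert pm.combine_viability([-0.2, np.nan, -0.4]) == pytest.approx(-0.3)


class TestReactivityCells:
    def test_stated_formula_with_scaled_ahr(self):
        cfg = simple_config()
        out = pm.combine_reactivity_cells({"A": 0.2, "B": 0.1}, 2.0, cfg)
        assert out == pytest.approx(np.mean([0.2, 0.1, 0.1]))

    def test_without_ahr_term(self):
        cfg = simple_config()
        cfg.include_ahr_in_reactivity = False
        assert pm.combine_reactivity_cells({"A": 0.2, "B": 0.1}, 2.0, cfg) == (
            pytest.approx(0.15)
        )

    def test_ahr_abs_flag_semantics(self):
        cfg = simple_config()
        with_abs = pm.combine_reactivity_cells({"A": 0.0, "B": 0.0}, -0.4, cfg)
        assert with_abs == pytest.approx(0.02 / 3)
        cfg.ahr_abs_in_reactivity = False
        signed = pm.combine_reactivity_cells({"A": 0.0, "B": 0.0}, -0.4, cfg)
        assert signed == pytest.approx(-0.02 / 3)


class TestInflammation:
    def test_hi_lo_signed_means(self):
        cfg = simple_config()
        betas = {"CYT-A": 0.2, "IL-6": 0.1, "IL-10": 0.05}
        assert pm.combine_inflammation(betas, cfg, HI) == pytest.approx(
            (0.2 + 0.1 - 0.05) / 3
        )
        assert pm.combine_inflammation(betas, cfg, LO) == pytest.approx(
            (0.2 - 0.1 - 0.05) / 3
        )

    def test_all_zero_betas_give_zero(self):
        cfg = simple_config()
        betas = dict.fromkeys(["CYT-A", "IL-6", "IL-10"], 0.0)
        assert pm.combine_inflammation(betas, cfg, HI) == 0.0
        assert pm.combine_inflammation(betas, cfg, LO) == 0.0

    @given(
        pro=finite_beta, il6=finite_beta, il10=finite_beta
    )
    def test_hi_minus_lo_is_twice_il6_over_n(self, pro, il6, il10):
        cfg = simple_config()
        betas = {"CYT-A": pro, "IL-6": il6, "IL-10": il10}
        hi = pm.combine_inflammation(betas, cfg, HI)
        lo = pm.combine_inflammation(betas, cfg, LO)
        assert hi - lo == pytest.approx(2 * il6 / 3, abs=1e-12)

    def test_unsigned_cytokine_is_a_configuration_error(self):
        cfg = simple_config()
        with pytest.raises(ConfigurationError):
            pm.combine_inflammation({"MYSTERY": 0.1}, cfg, HI)

    def test_anti_inflammatory_sign_invariants_enforced(self):
        with pytest.raises(ConfigurationError):
            pm.ScenarioConfig(
                roles={"U/IL-10": "anti_inflammatory"}, hi_signs={"IL-10": +1}
            )
        with pytest.raises(ConfigurationError):
            pm.ScenarioConfig(
                roles={"U/IL-6": "dual_inflammatory"}, lo_signs={"IL-6": +1}
            )


class TestIntegratedAndInvivo:
    def test_integrate_unit_is_a_mean(self):
        assert pm.integrate_unit(0.16, 0.08) == pytest.approx(0.12)
        assert pm.integrate_unit(0.3, 0.3) == 0.3

    @given(r=finite_beta, hi=finite_beta, lo=finite_beta)
    def test_grand_index_identity(self, r, hi, lo):
        grand = (pm.integrate_unit(r, hi) + pm.integrate_unit(r, lo)) / 2
        assert grand == pytest.approx(r / 2 + (hi + lo) / 4, abs=1e-12)

    def test_invivo_toxicity_sign_map(self):
        signs = {"protein": 1, "LDH": 1, "macrophages": -1}
        betas = {"protein": 0.1, "LDH": 0.2, "macrophages": -0.3}
        assert pm.combine_invivo_toxicity(betas, signs) == pytest.approx(0.2)
        flipped = dict(signs, macrophages=+1)
        assert pm.combine_invivo_toxicity(betas, flipped) == pytest.approx(0.0)

    def test_invivo_toxicity_all_zero(self):
        signs = {"protein": 1, "macrophages": -1}
        assert pm.combine_invivo_toxicity({"protein": 0.0, "macrophages": 0.0}, signs) == 0.0

    def test_unsigned_marker_rejected(self):
        with pytest.raises(ConfigurationError):
            pm.combine_invivo_toxicity({"protein": 0.1}, {})

    def test_invivo_single_cytokine_equals_its_beta_in_both_scenarios(self):
        cfg = simple_config()
        for scenario in (HI, LO):
            assert pm.combine_invivo_inflammation(
                {"CYT-A": 0.21}, cfg, scenario
            ) == pytest.approx(0.21)

    @given(
        bt=finite_beta, pro=finite_beta, il6=finite_beta, il10=finite_beta
    )
    def test_invivo_grand_index_matches_hand_computation(self, bt, pro, il6, il10):
        cfg = simple_config()
        betas = {"CYT-A": pro, "IL-6": il6, "IL-10": il10}
        hi = pm.combine_invivo_inflammation(betas, cfg, HI)
        lo = pm.combine_invivo_inflammation(betas, cfg, LO)
        beta_i = (hi + lo) / 2
        hand = ((pro + il6 - il10) / 3 + (pro - il6 - il10) / 3) / 2
        assert beta_i == pytest.approx(hand, abs=1e-12)
        assert (bt + beta_i) / 2 == pytest.approx(np.mean([bt, beta_i]), abs=1e-12)


class TestRanks:
    def test_largest_value_gets_rank_one(self):
        ranks = pm.rank_particles({"a": 0.5, "b": 0.1, "c": 0.3})
        assert ranks.to_dict() == {"a": 1.0, "b": 3.0, "c": 2.0}

    def test_ties_take_midranks(self):
        ranks = pm.rank_particles({"a": 0.2, "b": 0.2})
        assert ranks.to_dict() == {"a": 1.5, "b": 1.5}

    def test_single_particle_rejected(self):
        with pytest.raises(InsufficientDataError):
            pm.rank_particles({"a": 0.2})

    def test_monotone_transform_preserves_ranks(self):
        vals = {"a": 0.5, "b": 0.1, "c": 0.3, "d": 0.9, "e": 0.7}
        transformed = {k: np.expm1(3 * v) for k, v in vals.items()}
        pd.testing.assert_series_equal(
            pm.rank_particles(vals), pm.rank_particles(transformed)
        )


class TestTableIntegration:
    def test_every_combined_index_is_the_mean_of_its_inputs(
        self, noise_free_dataset
    ):
        """Re-derive the hierarchy by independent arithmetic from the potency
        table and compare field by field."""
        fe = pm.compute_fold_effect(noise_free_dataset.measurements)
        pot = pm.fit_all(fe)
        roles = {
            "U/CYT": "pro_inflammatory",
            "U/VIA": "viability",
            "U/ANTI": "anti_inflammatory",
        }
        cfg = pm.ScenarioConfig(roles=roles)
        idx = pm.integrate_invitro(pot, cfg)
        b = pot.set_index(["particle", "endpoint"])["beta"]
        for particle in idx.index:
            bv = b.loc[(particle, "VIA")]
            assert idx.loc[particle, "beta_v_U"] == pytest.approx(bv)
            assert idx.loc[particle, "beta_r_U"] == pytest.approx(abs(bv))
            iv_cyt = b.loc[(particle, "CYT")] - bv
            iv_anti = b.loc[(particle, "ANTI")] - bv
            hi = (iv_cyt - iv_anti) / 2
            assert idx.loc[particle, "beta_iv_hi_U"] == pytest.approx(hi)
            assert idx.loc[particle, "beta_iv_cells"] == pytest.approx(
                (idx.loc[particle, "beta_iv_hi"] + idx.loc[particle, "beta_iv_lo"]) / 2
            )
            assert idx.loc[particle, "ibeta"] == pytest.approx(
                (idx.loc[particle, "ibeta_hi"] + idx.loc[particle, "ibeta_lo"]) / 2
            )
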
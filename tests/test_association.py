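"""Pearson/Spearman concordance, t-approximation and exact permutation p."""

from itertools import permutations
from math import factorial, gamma, pi, sqrt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import spearmanr

import pmpotency as pm
from pmpotency.exceptions import InsufficientDataError, ValidationError
from pmpotency.reference_data import PUBLISHED_RANKS


def t_density(x, df):
    """Student t pdf written out, for an integration-based p oracle."""
    c = gamma((df + 1) / 2) / (sqrt(df * pi) * gamma(df / 2))
    return c * (1 + x * x / df) ** (-(df + 1) / 2)


def brute_force_exact_p(rx, ry, tail="one"):
    """Enumeration oracle using the d^2 formula (untied ranks only)."""
    n = len(rx)

    def rho(perm):
        d2 = sum((a - b) ** 2 for a, b in zip(rx, perm))
        return 1 - 6 * d2 / (n * (n * n - 1))

    obs = rho(ry)
    if tail == "one":
        hits = sum(rho(p) >= obs - 1e-12 for p in permutations(ry))
    else:
        hits = sum(abs(rho(p)) >= abs(obs) - 1e-12 for p in permutations(ry))
    return hits / factorial(n)


class TestPearson:
    def test_perfect_linearity(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = pm.pearson_correlation(x, 2 * x + 1)
        assert res.coefficient == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0, abs=1e-12)

    def test_known_vector_pair_with_integration_oracle(self):
        res = pm.pearson_correlation([1, 2, 3, 4], [1, 3, 2, 4], tail="two")
        assert res.coefficient == pytest.approx(0.8)
        t_obs = 0.8 * sqrt(2 / (1 - 0.64))
        p_oracle = 2 * quad(t_density, t_obs, np.inf, args=(2,))[0]
        assert res.p == pytest.approx(p_oracle, abs=1e-9)
        one = pm.pearson_correlation([1, 2, 3, 4], [1, 3, 2, 4], tail="one")
        assert one.p == pytest.approx(p_oracle / 2, abs=1e-9)

    def test_sign_antisymmetry(self):
        x = np.array([0.1, 0.4, 0.2, 0.9, 0.5])
        y = np.array([1.0, 2.0, 1.5, 3.0, 2.5])
        assert pm.pearson_correlation(x, -y).coefficient == pytest.approx(
            -pm.pearson_correlation(x, y).coefficient
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            pm.pearson_correlation([1, 1, 1], [1, 2, 3])

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            pm.pearson_correlation([1, 2], [1, 2])


class TestSpearman:
    def test_identical_rank_vectors(self):
        res = pm.spearman_correlation([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.coefficient == 1.0
        assert res.p == 0.0

    def test_d2_formula_equals_pearson_on_ranks(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.permutation(6) + 1
            y = rng.permutation(6) + 1
            d2 = np.sum((x - y) ** 2)
            expected = 1 - 6 * d2 / (6 * 35)
            res = pm.spearman_correlation(x, y)
            assert res.coefficient == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_as_independent_cross_check(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        res = pm.spearman_correlation(x, y, tail="two")
        ref = spearmanr(x, y)
        assert res.coefficient == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    @given(st.permutations(list(range(5))))
    def test_monotone_transform_invariance(self, perm):
        x = np.arange(5, dtype=float)
        y = np.array(perm, dtype=float)
        before = pm.spearman_correlation(x, y).coefficient
        after = pm.spearman_correlation(np.exp(x), 7 * y + 2).coefficient
        assert after == pytest.approx(before, abs=1e-12)
        assert pm.spearman_correlation(np.exp(x), np.exp(y)).coefficient == (
            pytest.approx(before, abs=1e-12)
        )

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_exact_permutation_p_matches_enumeration_oracle(self, n):
        rng = np.random.default_rng(n)
        for _ in range(3):
            x = rng.permutation(n) + 1
            y = rng.permutation(n) + 1
            for tail in ("one", "two"):
                res = pm.spearman_correlation(
                    x, y, tail=tail, method="exact_permutation"
                )
                assert res.p == brute_force_exact_p(list(x), list(y), tail)

    def test_exact_refused_above_n8(self):
        x = np.arange(9)
        with pytest.raises(ValidationError, match="t_approx"):
            pm.spearman_correlation(x, x, method="exact_permutation")

    def test_exact_and_t_p_are_both_monotone_in_rho(self):
        """For n=5 the two p-methods order rank vectors identically."""
        x = np.arange(1, 6)
        ys = [np.array(p) for p in permutations(range(1, 6))]
        rows = []
        for y in ys[:40]:
            rho = pm.spearman_correlation(x, y).coefficient
            pt = pm.spearman_correlation(x, y).p
            pe = pm.spearman_correlation(x, y, method="exact_permutation").p
            rows.append((rho, pt, pe))
        rows.sort(key=lambda r: r[0])
        pts = [r[1] for r in rows]
        pes = [r[2] for r in rows]
        assert all(a >= b - 1e-12 for a, b in zip(pts, pts[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(pes, pes[1:]))


class TestPublishedRankAnalysis:
    def test_inflammation_all_particles(self):
        ranks = PUBLISHED_RANKS["inflammation"]
        res = pm.rank_concordance(ranks["in_vitro"], ranks["in_vivo"])
        assert res.coefficient == pytest.approx(0.800, abs=1e-12)
        assert round(res.p, 3) == 0.052

    def test_exact_permutation_alternative_at_rho_08_n5(self):
        ranks = PUBLISHED_RANKS["inflammation"]
        res = pm.rank_concordance(
            ranks["in_vitro"], ranks["in_vivo"], method="exact_permutation"
        )
        assert res.p == pytest.approx(48 / 720)

    def test_toxicity_excluding_cristobalite_is_perfectly_concordant(self):
        ranks = PUBLISHED_RANKS["toxicity"]
        res = pm.rank_concordance(ranks["in_vitro"], ranks["in_vivo"],
                                  exclude=("CRI",))
        assert res.coefficient == 1.0
        assert res.p < 0.001


class TestConcordanceTable:
    def test_identical_models_report_unit_coefficients(self):
        idx = pd.DataFrame(
            {
                "beta_r_cells": [0.1, 0.3, 0.2, 0.5, 0.4],
                "beta_iv_cells": [0.2, 0.6, 0.4, 1.0, 0.8],
                "ibeta": [0.15, 0.45, 0.3, 0.75, 0.6],
            },
            index=[f"P{i}" for i in range(5)],
        )
        vivo = idx.rename(
            columns={
                "beta_r_cells": "beta_t",
                "beta_iv_cells": "beta_i",
                "ibeta": "ibeta_invivo",
            }
        )
        table = pm.concordance_table(idx, vivo)
        assert np.allclose(table["coefficient"], 1.0)

    def test_exclusion_subsets_present(self):
        rng = np.random.default_rng(0)
        idx = pd.DataFrame(
            rng.uniform(0, 1, size=(5, 3)),
            columns=["beta_r_cells", "beta_iv_cells", "ibeta"],
            index=[f"P{i}" for i in range(5)],
        )
        vivo = pd.DataFrame(
            rng.uniform(0, 1, size=(5, 3)),
            columns=["beta_t", "beta_i", "ibeta_invivo"],
            index=idx.index,
        )
        table = pm.concordance_table(idx, vivo, exclusions=["P0"])
        assert set(table["subset"]) == {"all", "no P0"}
        assert set(table["n"]) == {5, 4}

    def test_fewer_than_three_shared_particles_rejected(self):
        idx = pd.DataFrame({"ibeta": [1.0, 2.0]}, index=["a", "b"])
        vivo = pd.DataFrame({"ibeta_invivo": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(InsufficientDataError):
            pm.concordance_table(idx, vivo)
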
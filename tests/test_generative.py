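"""Latent-response network simulation: covariance structure, threshold
rule and marginal helping probabilities."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr
from scipy.stats import pearsonr

from gssrm.generative import (
    GSSRMParameters,
    NetworkStructure,
    RandomEffectRealization,
    draw_random_effects,
    latent_response,
    simulate_network,
    transpose_dataset,
)
from gssrm.inference import balanced_design, default_experiment_parameters


class TestParameters:
    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            GSSRMParameters(var_u=-0.1)

    def test_out_of_range_correlation_rejected(self):
        with pytest.raises(ValueError):
            GSSRMParameters(rho_hh=1.2)

    def test_negative_correlation_representable(self):
        params = GSSRMParameters(var_a1=1.0, var_b1=1.0, rho_a1b1=-0.5)
        assert params.rho_a1b1 == -0.5


class TestRandomEffects:
    def test_zero_variances_give_zero_effects(self):
        design = balanced_design(4, 2)
        structure = NetworkStructure.from_design(design)
        effects = draw_random_effects(
            GSSRMParameters(), structure, np.random.default_rng(0)
        )
        for block in ("a2", "b2", "a1", "b1", "c", "d", "h", "u"):
            assert np.all(getattr(effects, block) == 0.0)

    def test_household_pair_correlation_recovered(self):
        """sigma_h^2 = 1, rho_hh = 0.88 across 1e5 household pairs."""
        rng = np.random.default_rng(42)
        n = 100_000
        params = GSSRMParameters(var_h=1.0, rho_hh=0.88)

        class FakeStructure:
            n_households = 0
            n_individuals = 0
            n_cd_pairs = 0
            n_hh_pairs = n
            n_dyads = 0

        effects = draw_random_effects(params, FakeStructure(), rng)
        r = pearsonr(effects.h[:, 0], effects.h[:, 1]).statistic
        assert r == pytest.approx(0.88, abs=0.01)

    def test_block_moments_match_generating_covariance(self):
        """Empirical moments of every block at 1e5 draws."""
        rng = np.random.default_rng(7)
        params = default_experiment_parameters()
        n = 100_000

        class FakeStructure:
            n_households = n
            n_individuals = n
            n_cd_pairs = n
            n_hh_pairs = n
            n_dyads = n

        eff = draw_random_effects(params, FakeStructure(), rng)
        tol = 3e-2
        assert eff.a2.var() == pytest.approx(params.var_a2, rel=tol)
        assert eff.b2.var() == pytest.approx(params.var_b2, rel=tol)
        assert eff.a1.var() == pytest.approx(params.var_a1, rel=tol)
        assert eff.b1.var() == pytest.approx(params.var_b1, rel=tol)
        assert eff.c.var() == pytest.approx(params.var_c, rel=tol)
        assert eff.d.var() == pytest.approx(params.var_d, rel=tol)
        assert eff.u.var() == pytest.approx(params.var_u, rel=tol)
        assert pearsonr(eff.a2, eff.b2).statistic == pytest.approx(
            params.rho_a2b2, abs=0.01
        )
        assert pearsonr(eff.a1, eff.b1).statistic == pytest.approx(
            params.rho_a1b1, abs=0.01
        )
        assert pearsonr(eff.c, eff.d).statistic == pytest.approx(
            params.rho_cd, abs=0.01
        )

    def test_cd_pairing_couples_actor_with_foreign_household(self):
        """c indexes (actor, partner household) and d indexes (partner,
        actor household) into the same pair list, so the correlation
        couples i's giving to household l with l's giving back to i."""
        design = balanced_design(3, 2)
        s = NetworkStructure.from_design(design)
        for r in range(s.n_rows):
            i, l = s.ia[r], s.kb[r]
            j, k = s.ib[r], s.ka[r]
            assert s.cd_pairs[s.cg[r]] == (i, l)
            assert s.cd_pairs[s.dg[r]] == (j, k)


class TestLatentResponse:
    def _tiny(self):
        design = balanced_design(2, 1)
        s = NetworkStructure.from_design(design)
        effects = draw_random_effects(GSSRMParameters(), s, np.random.default_rng(0))
        return design, s, effects

    def test_all_zero_terms_give_y_one(self):
        design, s, effects = self._tiny()
        ystar = latent_response(
            design.X, np.array([0.0]), effects, s, residual=np.zeros(s.n_rows)
        )
        assert np.all(ystar == 0.0)
        assert np.all((ystar >= 0).astype(int) == 1)

    def test_published_intercept_gives_y_zero(self):
        design, s, effects = self._tiny()
        ystar = latent_response(
            design.X, np.array([-2.07]), effects, s, residual=np.zeros(s.n_rows)
        )
        assert np.all(ystar == -2.07)
        assert np.all((ystar >= 0).astype(int) == 0)

    def test_additivity_in_single_effect(self):
        design, s, effects = self._tiny()
        base = latent_response(design.X, np.array([0.3]), effects, s)
        effects.a1 = effects.a1 + np.array([1.5, 0.0])
        shifted = latent_response(design.X, np.array([0.3]), effects, s)
        rows_of_actor0 = s.ia == 0
        assert np.allclose(shifted[rows_of_actor0] - base[rows_of_actor0], 1.5)
        assert np.allclose(shifted[~rows_of_actor0], base[~rows_of_actor0])


class TestSimulateNetwork:
    def test_zero_beta_gives_half_helping(self):
        design = balanced_design(10, 4)
        ds = simulate_network(
            design, GSSRMParameters(), np.random.default_rng(0)
        )
        assert ds.y.mean() == pytest.approx(0.5, abs=0.02)

    def test_intercept_only_matches_normal_cdf(self):
        """beta_0 = -2.07, no random effects: helping rate Phi(-2.07)."""
        design = balanced_design(25, 10)  # 60k rows
        params = GSSRMParameters(beta={"intercept": -2.07})
        ds = simulate_network(design, params, np.random.default_rng(3))
        assert ds.y.mean() == pytest.approx(float(ndtr(-2.07)), abs=0.005)

    def test_dyadic_variance_induces_latent_reciprocity(self):
        """With only the symmetric dyad effect active, the latent
        correlation between a dyad's two directions is var_u/(var_u+1)."""
        rng = np.random.default_rng(11)
        params = GSSRMParameters(var_u=1.52)
        design = balanced_design(40, 5)
        s = NetworkStructure.from_design(design)
        effects = draw_random_effects(params, s, rng)
        ystar = latent_response(
            design.X, np.array([0.0]), effects, s, rng.standard_normal(s.n_rows)
        )
        frame = pd.DataFrame({"ud": s.ud, "low": s.ia < s.ib, "ystar": ystar})
        wide = frame.pivot_table(index="ud", columns="low", values="ystar")
        r = pearsonr(wide[True], wide[False]).statistic
        assert r == pytest.approx(1.52 / 2.52, abs=0.02)

    def test_degenerate_nesting_reduces_to_conventional_srm(self):
        """Zeroing all group-level variances leaves draws identical to a
        model with individual and dyad effects only."""
        design = balanced_design(6, 3)
        s = NetworkStructure.from_design(design)
        params = default_experiment_parameters()
        reduced = GSSRMParameters(
            beta=params.beta,
            var_a1=params.var_a1,
            var_b1=params.var_b1,
            var_u=params.var_u,
            rho_a1b1=params.rho_a1b1,
        )
        eff = draw_random_effects(reduced, s, np.random.default_rng(0))
        assert np.all(eff.a2 == 0) and np.all(eff.h == 0)
        contribution = eff.row_sum(s)
        manual = eff.a1[s.ia] + eff.b1[s.ib] + eff.u[s.ud]
        assert np.allclose(contribution, manual)

    def test_nominations_round_trip(self, tmp_path):
        design = balanced_design(4, 2)
        ds = simulate_network(design, GSSRMParameters(), np.random.default_rng(5))
        path = tmp_path / "noms.csv"
        ds.to_csv(path)
        back = pd.read_csv(path, dtype={"ego": str, "alter": str})
        assert back["y"].tolist() == ds.y.tolist()
        assert back["ego"].tolist() == ds.table["actor"].tolist()

    def test_transpose_swaps_roles(self):
        design = balanced_design(4, 2)
        ds = simulate_network(design, GSSRMParameters(), np.random.default_rng(5))
        flipped = transpose_dataset(ds)
        assert flipped.framing == "donor"
        assert flipped.table["actor"].tolist() == ds.table["partner"].tolist()
        assert flipped.table["actor_household"].tolist() == ds.table[
            "partner_household"
        ].tolist()
        assert flipped.y.tolist() == ds.y.tolist()
        twice = transpose_dataset(flipped)
        assert twice.framing == "recipient"
        assert twice.table["actor"].tolist() == ds.table["actor"].tolist()


class TestExchangeability:
    def test_household_relabelling_is_a_relabelling(self):
        """Permuting household labels before building the structure
        permutes the index maps without changing dyad topology."""
        design = balanced_design(5, 2)
        table = design.table.copy()
        mapping = {f"h{k:02d}": f"H{(k * 3) % 5:02d}" for k in range(5)}
        table["actor_household"] = table["actor_household"].map(mapping)
        table["partner_household"] = table["partner_household"].map(mapping)
        s0 = NetworkStructure(design.table)
        s1 = NetworkStructure(table)
        assert s0.n_hh_pairs == s1.n_hh_pairs
        assert s0.n_cd_pairs == s1.n_cd_pairs
        assert np.array_equal(s0.ud, s1.ud)
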
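"""Dyadic predictor construction: bespoke kinship covariates and the
per-model design matrices."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gssrm.community import Community
from gssrm.covariates import (
    MODEL_COLUMNS,
    affinal_r,
    average_household_relatedness,
    build_design,
    dyad_distance,
    godparent_indicator,
    infidelity_ties,
)
from gssrm.pedigree import Pedigree, PedigreeRecord, relatedness_matrix


def _family_community():
    """Man married into a three-generation matriline, plus unrelated pair."""
    ped = Pedigree(
        [
            PedigreeRecord("grandma"),
            PedigreeRecord("grandpa"),
            PedigreeRecord("wm", "grandma", "grandpa"),  # wife's mother
            PedigreeRecord("wf"),
            PedigreeRecord("wife", "wm", "wf"),
            PedigreeRecord("man"),
            PedigreeRecord("child", "wife", "man"),
            PedigreeRecord("out1"),
            PedigreeRecord("out2"),
        ]
    )
    individuals = pd.DataFrame(
        {
            "id": ["grandma", "wm", "wife", "man", "child", "out1", "out2"],
            "household": ["h1", "h1", "h2", "h2", "h2", "h3", "h3"],
            "male": [0, 0, 0, 1, 0, 1, 0],
            "age": [70.0, 50.0, 28.0, 30.0, 18.0, 40.0, 38.0],
            "bmi": [22, 24, 23, 25, 21, 26, 24],
            "skin": [50, 52, 51, 49, 53, 48, 50],
        }
    )
    households = pd.DataFrame(
        {
            "id": ["h1", "h2", "h3"],
            "wealth": [1.2, 0.4, 2.5],
            "x": [0.0, 1000.0, 0.0],
            "y": [0.0, 0.0, 500.0],
        }
    )
    unions = pd.DataFrame(
        {
            "spouse_a": ["man", "grandma"],
            "spouse_b": ["wife", "grandpa"],
            "status": ["current", "current"],
        }
    )
    community = Community(
        individuals=individuals,
        households=households,
        unions=unions,
        pedigree=ped,
    )
    relmat = relatedness_matrix(ped, list(individuals["id"]))
    return community, relmat


class TestAffinalR:
    def test_man_and_wifes_mother(self):
        community, relmat = _family_community()
        assert affinal_r("man", "wm", community, relmat) == pytest.approx(0.5)

    def test_man_and_wifes_grandmother(self):
        community, relmat = _family_community()
        assert affinal_r("man", "grandma", community, relmat) == pytest.approx(0.25)

    def test_consanguineal_tie_suppresses_affinal_value(self):
        # mother <-> own child: affinal candidate 0.5 through her spouse,
        # but the direct r of 0.5 is not doubled, so the variable is 0
        community, relmat = _family_community()
        assert affinal_r("wife", "child", community, relmat) == 0.0

    def test_no_spouses_gives_zero(self):
        community, relmat = _family_community()
        assert affinal_r("out1", "out2", community, relmat) == 0.0

    def test_symmetric(self):
        community, relmat = _family_community()
        ids = list(community.individuals["id"])
        for i, j in itertools.combinations(ids, 2):
            assert affinal_r(i, j, community, relmat) == affinal_r(
                j, i, community, relmat
            )


class TestGodparentIndicator:
    def test_godparent_of_child_counts(self):
        community, _ = _family_community()
        links = pd.DataFrame({"godparent": ["out1"], "godchild": ["child"]})
        # out1 is godparent of wife's child, so the (out1, wife) dyad scores
        assert godparent_indicator("out1", "wife", links, community.pedigree)
        assert godparent_indicator("wife", "out1", links, community.pedigree)

    def test_no_links_false(self):
        community, _ = _family_community()
        empty = pd.DataFrame(columns=["godparent", "godchild"])
        assert not godparent_indicator("man", "out1", empty, community.pedigree)

    def test_matches_brute_force_on_random_links(self):
        community, _ = _family_community()
        ped = community.pedigree
        ids = list(community.individuals["id"])
        rng = np.random.default_rng(0)
        links = pd.DataFrame(
            {
                "godparent": rng.choice(ids, 6),
                "godchild": rng.choice(ped.ids, 6),
            }
        )
        pairs = set(zip(links["godparent"], links["godchild"]))

        def brute(i, j):
            child_sets = {
                p: {c for c in ped.ids if p in [x for x in ped.parents(c) if x]}
                for p in ped.ids
            }
            for a, b in ((i, j), (j, i)):
                if (a, b) in pairs:
                    return True
                if any((a, c) in pairs for c in child_sets.get(b, ())):
                    return True
            return False

        for i, j in itertools.combinations(ids, 2):
            assert godparent_indicator(i, j, links, ped) == brute(i, j)
            assert godparent_indicator(i, j, links, ped) == godparent_indicator(
                j, i, links, ped
            )


class TestInfidelityTies:
    def _ped_with_affair(self):
        # "affair_child" conceived by married "mom" with "lover";
        # lover's legitimate child is the half-sibling
        return Pedigree(
            [
                PedigreeRecord("mom"),
                PedigreeRecord("husband"),
                PedigreeRecord("lover"),
                PedigreeRecord("lover_wife"),
                PedigreeRecord("affair_child", "mom", "lover", extra_pair=True),
                PedigreeRecord("legit_child", "lover_wife", "lover"),
            ]
        )

    def test_half_sibling_in_other_household(self):
        ped = self._ped_with_affair()
        membership = {"affair_child": "k", "legit_child": "l"}
        assert infidelity_ties("k", "l", ped, membership)
        assert infidelity_ties("l", "k", ped, membership)

    def test_no_flags_no_ties(self):
        ped = Pedigree(
            [
                PedigreeRecord("a"),
                PedigreeRecord("b"),
                PedigreeRecord("c", "a", "b"),
            ]
        )
        assert not infidelity_ties("k", "l", ped, {"a": "k", "c": "l"})

    def test_full_siblings_do_not_count(self):
        # flagged child and a FULL sibling: two shared parents, not a half-sib
        ped = Pedigree(
            [
                PedigreeRecord("mom"),
                PedigreeRecord("lover"),
                PedigreeRecord("kid1", "mom", "lover", extra_pair=True),
                PedigreeRecord("kid2", "mom", "lover"),
            ]
        )
        assert not infidelity_ties("k", "l", ped, {"kid1": "k", "kid2": "l"})

    def test_matches_exhaustive_scan(self, small_community):
        ped = small_community.pedigree
        membership = small_community.membership
        households = sorted(set(membership.values()))

        def brute(k, l):
            for child, hh in membership.items():
                if hh not in (k, l) or not ped.extra_pair.get(child, False):
                    continue
                other = l if hh == k else k
                for sib, shh in membership.items():
                    if shh != other or sib == child:
                        continue
                    shared = sum(
                        1
                        for pa, pb in zip(ped.parents(child), ped.parents(sib))
                        if pa is not None and pa == pb
                    )
                    if shared == 1:
                        return True
            return False

        for k, l in itertools.combinations(households, 2):
            assert infidelity_ties(k, l, ped, membership) == brute(k, l)


class TestHouseholdCovariates:
    def test_average_relatedness_arithmetic(self):
        relmat = pd.DataFrame(
            0.25, index=["a", "b", "c", "d"], columns=["a", "b", "c", "d"]
        )
        members = {"k": ["a", "b"], "l": ["c", "d"]}
        value = average_household_relatedness("k", "l", relmat, members)
        assert value == pytest.approx(np.log(0.25))

    def test_zero_mean_hits_floor(self):
        relmat = pd.DataFrame(0.0, index=["a", "b"], columns=["a", "b"])
        members = {"k": ["a"], "l": ["b"]}
        value = average_household_relatedness("k", "l", relmat, members)
        assert value == pytest.approx(np.log(1e-4))

    def test_empty_household_raises(self):
        relmat = pd.DataFrame(0.0, index=["a"], columns=["a"])
        with pytest.raises(ValueError):
            average_household_relatedness("k", "l", relmat, {"k": ["a"], "l": []})

    def test_distance_log_metres(self):
        coords = pd.DataFrame({"id": ["k", "l"], "x": [0.0, 1000.0], "y": [0.0, 0.0]})
        assert dyad_distance("k", "l", coords) == pytest.approx(6.908, abs=1e-3)
        assert dyad_distance("k", "l", coords) == dyad_distance("l", "k", coords)

    def test_coincident_houses_floored(self):
        coords = pd.DataFrame({"id": ["k", "l"], "x": [5.0, 5.0], "y": [1.0, 1.0]})
        assert dyad_distance("k", "l", coords) == 0.0


class TestDesignMatrix:
    def test_model_column_counts(self):
        # coefficient rosters: beta_0..beta_20 for the base covariate model,
        # then the interaction extensions
        assert len(MODEL_COLUMNS[0]) == 1
        assert len(MODEL_COLUMNS[1]) == 1
        assert len(MODEL_COLUMNS[2]) == 21
        assert len(MODEL_COLUMNS[3]) == 25
        assert len(MODEL_COLUMNS[4]) == 25
        assert len(MODEL_COLUMNS[5]) == 22
        assert len(MODEL_COLUMNS[6]) == 24

    def test_unknown_model_raises(self, small_community):
        with pytest.raises(ValueError):
            build_design(small_community, model_id=9)

    def test_female_dyad_has_zero_male_terms(self, small_design):
        table = small_design.table
        roster = small_design.table
        females = table[(table["male_i"] == 0) & (table["male_j"] == 0)]
        assert len(females) > 0
        assert (females["male_i_x_male_j"] == 0).all()

    def test_zscore_columns_standardized(self, small_community):
        design = build_design(small_community, model_id=2)
        roster = small_community.individuals
        n = len(roster)
        for col in ("age", "bmi", "skin"):
            z = (roster[col] - roster[col].mean()) / roster[col].std(ddof=1)
            assert z.mean() == pytest.approx(0.0, abs=1e-9)
            assert z.std(ddof=1) == pytest.approx(1.0)
        # quadratic columns are squares of the z-scores
        idx = design.table.set_index(["actor", "partner"])
        assert np.allclose(idx["age2_i"], idx["age_i"] ** 2)

    def test_symmetric_covariates_shared_across_directions(self, small_design):
        table = small_design.table.set_index(["actor", "partner"])
        symmetric = ["relatedness", "affinal_r", "godparent", "distance",
                     "avg_relatedness", "infidelity"]
        seen = 0
        for (i, j), row in table.iterrows():
            if (j, i) not in table.index:
                continue
            rev = table.loc[(j, i)]
            for col in symmetric:
                assert row[col] == pytest.approx(rev[col]), (i, j, col)
            seen += 1
        assert seen == len(table)

    def test_dyad_counts_match_enumeration(self, small_community):
        design = build_design(small_community, model_id=2)
        members = small_community.household_members
        sizes = [len(m) for m in members.values() if m]
        n = sum(sizes)
        expected = n * (n - 1) - sum(s * (s - 1) for s in sizes)
        assert len(design.table) == expected
        k = len(sizes)
        assert k * (k - 1) // 2 == len(
            list(itertools.combinations([h for h, m in members.items() if m], 2))
        )

    def test_scenario_vector_defaults_and_overrides(self, small_design):
        x = small_design.scenario_vector({})
        cols = small_design.columns
        assert x[cols.index("intercept")] == 1.0
        assert x[cols.index("male_i")] == 0.0
        # override a factor: the product column follows
        x2 = small_design.scenario_vector({"male_i": 1.0, "male_j": 1.0})
        assert x2[cols.index("male_i_x_male_j")] == 1.0
        # age override propagates to the quadratic
        x3 = small_design.scenario_vector({"age_i": 2.0})
        assert x3[cols.index("age2_i")] == 4.0
        with pytest.raises(KeyError):
            small_design.scenario_vector({"not_a_column": 1.0})
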
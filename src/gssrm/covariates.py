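"""Dyadic fixed-effect predictors and per-model design matrices.

Builds every covariate used in the support-network models: individual
attributes (sex, age, BMI, skin colour, z-scored over the roster),
household wealth (log thousands of cordobas), log inter-household
distance, pedigree relatedness, the affinal-relatedness construct, the
godparent indicator, log average inter-household relatedness (centred),
the infidelity-tie indicator, and the interaction terms of the wealth x
relatedness and relatedness x household-relatedness models.

Only inter-household directed dyads enter the design: relations within
a household are near-saturated in roster interviews and are excluded
from the analysis by construction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import Community
from .pedigree import Pedigree

__all__ = [
    "affinal_r",
    "godparent_indicator",
    "infidelity_ties",
    "average_household_relatedness",
    "dyad_distance",
    "build_design",
    "DesignMatrix",
    "MODEL_COLUMNS",
]

#: Default floor applied to a zero mean relatedness before the log.
DEFAULT_RELATEDNESS_FLOOR = 1e-4
#: Floor (metres) applied to coincident house coordinates before the log.
DISTANCE_FLOOR_M = 1.0

_BASE_COLUMNS = [
    "intercept",
    "male_i",
    "male_j",
    "male_i_x_male_j",
    "age_i",
    "age2_i",
    "age_j",
    "age2_j",
    "bmi_i",
    "bmi_j",
    "bmi_i_x_bmi_j",
    "skin_i",
    "skin_j",
    "skin_i_x_skin_j",
    "godparent",
    "wealth_k",
    "wealth_l",
    "distance",
    "relatedness",
    "affinal_r",
    "avg_relatedness",
]

#: Fixed-effect column roster per model id.  Models 0 and 1 are the
#: "empty" (intercept-only) specifications; models 2-6 follow the
#: published coefficient roster, with all lower-order terms of every
#: interaction always included.
MODEL_COLUMNS: dict[int, list[str]] = {
    0: ["intercept"],
    1: ["intercept"],
    2: list(_BASE_COLUMNS),
    3: _BASE_COLUMNS
    + [
        "wealth_k_x_wealth_l",
        "relatedness_x_wealth_k",
        "relatedness_x_wealth_l",
        "relatedness_x_wealth_k_x_wealth_l",
    ],
    4: _BASE_COLUMNS
    + [
        "wealth_k_x_wealth_l",
        "avg_relatedness_x_wealth_k",
        "avg_relatedness_x_wealth_l",
        "avg_relatedness_x_wealth_k_x_wealth_l",
    ],
    5: _BASE_COLUMNS + ["infidelity"],
    6: _BASE_COLUMNS
    + [
        "infidelity",
        "relatedness_x_avg_relatedness",
        "affinal_r_x_avg_relatedness",
    ],
}

#: Columns that derive from binary indicators; scenario defaults use the
#: reference category (0) rather than the sample mean for these.
INDICATOR_COLUMNS = {
    "male_i",
    "male_j",
    "male_i_x_male_j",
    "godparent",
    "infidelity",
}


def affinal_r(
    i: str,
    j: str,
    community: Community,
    relmatrix: pd.DataFrame,
) -> float:
    """Strongest relatedness between one dyad member and the other's spouse.

    Scans all *current* spouses s of i (candidate r(s, j)) and of j
    (candidate r(s, i)) and takes the maximum; 0 with no spouses.  When
    the dyad also has a direct consanguineal tie r(i, j) > 0, the
    affinal value is suppressed to 0 unless it is at least twice the
    consanguineal value, so close blood kin are not double-counted as
    affines.  Symmetric in (i, j) by construction.
    """
    candidates = [0.0]
    for s in community.current_spouses(i):
        if s in relmatrix.index and j in relmatrix.columns:
            candidates.append(float(relmatrix.loc[s, j]))
    for s in community.current_spouses(j):
        if s in relmatrix.index and i in relmatrix.columns:
            candidates.append(float(relmatrix.loc[s, i]))
    best = max(candidates)
    direct = float(relmatrix.loc[i, j]) if i in relmatrix.index and j in relmatrix.index else 0.0
    if direct > 0.0 and best < 2.0 * direct:
        return 0.0
    return best


def godparent_indicator(
    i: str,
    j: str,
    godparents: pd.DataFrame,
    pedigree: Pedigree | None = None,
) -> bool:
    """True iff one dyad member is godparent of the other or of the
    other's child (in either direction).  Symmetric."""
    pairs = {
        (str(a), str(b))
        for a, b in zip(godparents["godparent"], godparents["godchild"])
    }

    def _one_way(gp: str, person: str) -> bool:
        if (gp, person) in pairs:
            return True
        if pedigree is not None and person in pedigree:
            return any((gp, child) in pairs for child in pedigree.children(person))
        return False

    return _one_way(i, j) or _one_way(j, i)


def infidelity_ties(
    k: str,
    l: str,
    pedigree: Pedigree,
    membership: dict[str, str],
) -> bool:
    """True iff an extra-pair-conceived individual resides in one of the
    two households and at least one of its half-siblings (exactly one
    shared recorded parent) resides in the other.  Symmetric."""
    if k == l:
        return False
    for child, hh in membership.items():
        if hh not in (k, l):
            continue
        if child not in pedigree or not pedigree.extra_pair.get(child, False):
            continue
        other = l if hh == k else k
        for sib in pedigree.half_siblings(child):
            if membership.get(sib) == other:
                return True
    return False


def average_household_relatedness(
    k: str,
    l: str,
    relmatrix: pd.DataFrame,
    members: dict[str, list[str]],
    floor: float = DEFAULT_RELATEDNESS_FLOOR,
) -> float:
    """Natural log of the mean pairwise relatedness between the members
    of two households, with ``floor`` applied before the log when the
    mean is 0.  Centring at the sample mean happens in the design
    builder, which stores the constant for reuse in predictions."""
    mem_k = members.get(k, [])
    mem_l = members.get(l, [])
    if not mem_k or not mem_l:
        raise ValueError(f"household {k if not mem_k else l!r} has no members")
    block = relmatrix.loc[mem_k, mem_l].to_numpy(dtype=float)
    mean_r = float(block.mean())
    return float(np.log(max(mean_r, floor)))


def dyad_distance(k: str, l: str, coordinates: pd.DataFrame) -> float:
    """Natural log of the Euclidean distance in metres between two
    houses, with a 1 m floor for coincident coordinates.  Symmetric."""
    coords = coordinates.set_index("id") if "id" in coordinates.columns else coordinates
    dx = float(coords.loc[k, "x"]) - float(coords.loc[l, "x"])
    dy = float(coords.loc[k, "y"]) - float(coords.loc[l, "y"])
    dist = float(np.hypot(dx, dy))
    return float(np.log(max(dist, DISTANCE_FLOOR_M)))


@dataclass
class DesignMatrix:
    """Per-model dyadic design: one row per directed inter-household dyad.

    ``table`` carries the id columns (actor, actor_household, partner,
    partner_household) plus one column per fixed effect in ``columns``
    (the coefficient order).  ``metadata`` records the transform
    constants (z-score means/sds, the average-relatedness centring
    constant, log floors) so that predictions reuse the training-data
    scaling.  ``defaults`` holds the covariate-holding convention for
    counterfactual scenarios: indicator columns at the reference level
    0, every other column at its sample mean (so quadratic and product
    columns default to the mean of the constructed column, not the
    square/product of the means).
    """

    model_id: int
    table: pd.DataFrame
    columns: list[str]
    metadata: dict = field(default_factory=dict)
    defaults: dict[str, float] = field(default_factory=dict)

    @property
    def X(self) -> np.ndarray:
        return self.table[self.columns].to_numpy(dtype=float)

    def scenario_vector(self, scenario: dict[str, float] | None = None) -> np.ndarray:
        """Covariate vector for a counterfactual scenario.

        Unnamed columns take their default; product (``_x_``) columns
        are recomputed from the current values of their factors whenever
        any factor is overridden, and ``age2_*`` follows an overridden
        ``age_*``.
        """
        scenario = dict(scenario or {})
        unknown = set(scenario) - set(self.columns)
        if unknown:
            raise KeyError(f"unknown design columns: {sorted(unknown)}")
        values = dict(self.defaults)
        values.update(scenario)
        for col in self.columns:
            if col in scenario:
                continue
            if col.startswith("age2_"):
                base = "age_" + col.split("_")[-1]
                if base in scenario:
                    values[col] = scenario[base] ** 2
            elif "_x_" in col:
                factors = col.split("_x_")
                if any(f in scenario for f in factors):
                    values[col] = float(np.prod([values[f] for f in factors]))
        return np.array([values[c] for c in self.columns], dtype=float)


def _zscore(series: pd.Series) -> tuple[pd.Series, float, float]:
    mean = float(series.mean())
    sd = float(series.std(ddof=1))
    if sd == 0.0:
        return series * 0.0, mean, 1.0
    return (series - mean) / sd, mean, sd


def build_design(
    community: Community,
    model_id: int,
    relmatrix: pd.DataFrame | None = None,
    relatedness_floor: float = DEFAULT_RELATEDNESS_FLOOR,
) -> DesignMatrix:
    """Assemble the directed-dyad design matrix for one model.

    Age, BMI and skin colour are z-scored over the roster (age is
    standardized first, then squared); wealth is the log of thousands
    of cordobas; average inter-household relatedness is log-transformed
    and centred at its sample mean over household dyads.  Symmetric
    covariates are computed once per unordered pair and shared by both
    directions.
    """
    if model_id not in MODEL_COLUMNS:
        raise ValueError(f"unknown model id {model_id!r} (expected 0-6)")
    if relmatrix is None:
        if community.pedigree is None:
            raise ValueError("community has no pedigree; pass relmatrix explicitly")
        from .pedigree import relatedness_matrix

        relmatrix = relatedness_matrix(community.pedigree, list(community.individuals["id"]))

    roster = community.individuals.set_index("id", drop=False)
    z_age, age_mean, age_sd = _zscore(roster["age"].astype(float))
    z_bmi, bmi_mean, bmi_sd = _zscore(roster["bmi"].astype(float))
    z_skin, skin_mean, skin_sd = _zscore(roster["skin"].astype(float))
    households = community.households.set_index("id", drop=False)
    log_wealth = np.log(households["wealth"].astype(float))
    if not np.isfinite(log_wealth).all():
        raise ValueError("household wealth must be positive before the log transform")

    members = community.household_members
    membership = community.membership
    hh_ids = [h for h, mem in members.items() if mem]

    # Symmetric household-pair covariates, computed once per unordered pair.
    log_avg_rel: dict[tuple[str, str], float] = {}
    log_dist: dict[tuple[str, str], float] = {}
    infidelity: dict[tuple[str, str], bool] = {}
    for k, l in itertools.combinations(hh_ids, 2):
        key = (k, l)
        log_avg_rel[key] = average_household_relatedness(
            k, l, relmatrix, members, floor=relatedness_floor
        )
        log_dist[key] = dyad_distance(k, l, community.households)
        infidelity[key] = (
            infidelity_ties(k, l, community.pedigree, membership)
            if community.pedigree is not None
            else False
        )
    avg_rel_center = float(np.mean(list(log_avg_rel.values()))) if log_avg_rel else 0.0

    def _pair(table: dict, k: str, l: str):
        return table[(k, l)] if (k, l) in table else table[(l, k)]

    rows: list[dict] = []
    ids = list(roster["id"])
    for i in ids:
        k = membership[i]
        for j in ids:
            if i == j or membership[j] == k:
                continue
            l = membership[j]
            row: dict = {
                "actor": i,
                "actor_household": k,
                "partner": j,
                "partner_household": l,
                "intercept": 1.0,
            }
            if model_id >= 2:
                ai, aj = float(z_age[i]), float(z_age[j])
                bi, bj = float(z_bmi[i]), float(z_bmi[j])
                si, sj = float(z_skin[i]), float(z_skin[j])
                mi, mj = float(roster.loc[i, "male"]), float(roster.loc[j, "male"])
                rel = float(relmatrix.loc[i, j])
                aff = affinal_r(i, j, community, relmatrix)
                god = float(
                    godparent_indicator(i, j, community.godparents, community.pedigree)
                )
                wk, wl = float(log_wealth[k]), float(log_wealth[l])
                avg = _pair(log_avg_rel, k, l) - avg_rel_center
                row.update(
                    male_i=mi,
                    male_j=mj,
                    male_i_x_male_j=mi * mj,
                    age_i=ai,
                    age2_i=ai * ai,
                    age_j=aj,
                    age2_j=aj * aj,
                    bmi_i=bi,
                    bmi_j=bj,
                    bmi_i_x_bmi_j=bi * bj,
                    skin_i=si,
                    skin_j=sj,
                    skin_i_x_skin_j=si * sj,
                    godparent=god,
                    wealth_k=wk,
                    wealth_l=wl,
                    distance=_pair(log_dist, k, l),
                    relatedness=rel,
                    affinal_r=aff,
                    avg_relatedness=avg,
                    wealth_k_x_wealth_l=wk * wl,
                    relatedness_x_wealth_k=rel * wk,
                    relatedness_x_wealth_l=rel * wl,
                    relatedness_x_wealth_k_x_wealth_l=rel * wk * wl,
                    avg_relatedness_x_wealth_k=avg * wk,
                    avg_relatedness_x_wealth_l=avg * wl,
                    avg_relatedness_x_wealth_k_x_wealth_l=avg * wk * wl,
                    infidelity=float(_pair(infidelity, k, l)),
                    relatedness_x_avg_relatedness=rel * avg,
                    affinal_r_x_avg_relatedness=aff * avg,
                )
            rows.append(row)

    columns = MODEL_COLUMNS[model_id]
    table = pd.DataFrame(rows)
    table = table[["actor", "actor_household", "partner", "partner_household"] + columns]

    defaults = {"intercept": 1.0}
    for col in columns[1:]:
        defaults[col] = (
            0.0 if col in INDICATOR_COLUMNS else float(table[col].mean())
        )
    metadata = {
        "age_mean": age_mean,
        "age_sd": age_sd,
        "bmi_mean": bmi_mean,
        "bmi_sd": bmi_sd,
        "skin_mean": skin_mean,
        "skin_sd": skin_sd,
        "avg_relatedness_center": avg_rel_center,
        "relatedness_floor": relatedness_floor,
        "distance_floor_m": DISTANCE_FLOOR_M,
    }
    return DesignMatrix(
        model_id=model_id,
        table=table,
        columns=columns,
        metadata=metadata,
        defaults=defaults,
    )
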
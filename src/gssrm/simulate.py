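"""Synthetic community generator.

Produces pedigree, roster, households, unions and godparent links with
the statistical texture of a small endogamous horticulturalist village:
a few dozen households, roughly a hundred resident adults spanning
three generations, moderate mean pairwise relatedness, monogamous
unions with occasional extra-pair conceptions, an uxorilocal residence
bias, log-normal household wealth and houses scattered over a few
hundred metres.

The demography is intentionally stylized — fixed generation count,
Poisson offspring numbers, marriage either to an unrelated community
member or to an immigrant — because the point is the covariate and
kinship structure fed to the network models, not demographic realism.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import Community
from .covariates import infidelity_ties
from .pedigree import Pedigree, PedigreeRecord, relatedness_matrix

__all__ = ["CommunityConfig", "simulate_community", "summarize_community"]


@dataclass(frozen=True)
class CommunityConfig:
    """Knobs of the stylized demography.

    Defaults target a community of ~108 resident adults in 32
    households with mean pairwise relatedness around 0.05.  Ages, BMI,
    skin reflectance and wealth are drawn to match the field-study
    summary moments (adult age mean ~34.5, BMI ~23.9, melanin index
    ~51.6, log-wealth mean -0.92 sd 1.07 in thousands of cordobas).
    """

    n_households: int = 32
    target_adults: int = 108
    generations: int = 3
    founder_couples: int = 8
    offspring_mean: float = 4.5
    adult_survival: float = 0.85
    marriage_rate: float = 0.8
    local_marriage_prob: float = 0.7
    max_spouse_r: float = 0.06
    extra_pair_prob: float = 0.05
    former_union_prob: float = 0.05
    uxorilocal_bias: float = 0.6
    godparent_prob: float = 0.5
    wealth_log_mean: float = -0.92
    wealth_log_sd: float = 1.07
    spatial_extent_m: float = 700.0
    generation_age_means: tuple[float, ...] = (58.0, 36.0, 20.0)
    generation_age_sd: float = 6.0
    bmi_mean: float = 23.9
    bmi_sd: float = 2.6
    skin_mean: float = 51.6
    skin_sd: float = 4.65
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "adult_survival",
            "marriage_rate",
            "local_marriage_prob",
            "extra_pair_prob",
            "former_union_prob",
            "uxorilocal_bias",
            "godparent_prob",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("n_households", "target_adults", "generations", "founder_couples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if len(self.generation_age_means) < self.generations:
            raise ValueError("need an age mean per generation")


class _Person:
    __slots__ = ("id", "male", "generation", "mother", "father", "extra_pair", "spouse")

    def __init__(self, pid, male, generation, mother=None, father=None, extra_pair=False):
        self.id = pid
        self.male = male
        self.generation = generation
        self.mother = mother
        self.father = father
        self.extra_pair = extra_pair
        self.spouse = None


def simulate_community(
    config: CommunityConfig | None = None, rng: np.random.Generator | None = None
) -> Community:
    """Generate one synthetic community; bit-identical under a fixed seed."""
    cfg = config or CommunityConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    people: dict[str, _Person] = {}
    counter = itertools.count()

    def new_person(male, generation, mother=None, father=None, extra_pair=False):
        p = _Person(f"i{next(counter):04d}", male, generation, mother, father, extra_pair)
        people[p.id] = p
        return p

    couples: list[tuple[_Person, _Person]] = []
    for _ in range(cfg.founder_couples):
        wife = new_person(False, 0)
        husband = new_person(True, 0)
        wife.spouse, husband.spouse = husband.id, wife.id
        couples.append((wife, husband))

    generation_members: dict[int, list[_Person]] = {0: [p for c in couples for p in c]}

    for gen in range(1, cfg.generations):
        parents = [c for c in couples if c[0].generation == gen - 1 or c[1].generation == gen - 1]
        married_men = [h for _, h in parents]
        children: list[_Person] = []
        for wife, husband in parents:
            n_kids = rng.poisson(cfg.offspring_mean)
            for _ in range(n_kids):
                if rng.random() >= cfg.adult_survival:
                    continue
                genetic_father = husband
                extra = False
                if (
                    len(married_men) > 1
                    and rng.random() < cfg.extra_pair_prob
                ):
                    others = [m for m in married_men if m.id != husband.id]
                    genetic_father = others[rng.integers(len(others))]
                    extra = True
                children.append(
                    new_person(
                        bool(rng.random() < 0.5),
                        gen,
                        mother=wife.id,
                        father=genetic_father.id,
                        extra_pair=extra,
                    )
                )
        generation_members[gen] = children

        # marriage within the new generation
        ped = _pedigree_from(people)
        singles = [p for p in children if p.spouse is None]
        order = rng.permutation(len(singles))
        for idx in order:
            person = singles[idx]
            if person.spouse is not None or rng.random() >= cfg.marriage_rate:
                continue
            partner = None
            if rng.random() < cfg.local_marriage_prob:
                candidates = [
                    q
                    for q in singles
                    if q.spouse is None
                    and q.male != person.male
                    and q.id != person.id
                    and ped.relatedness(person.id, q.id) <= cfg.max_spouse_r
                ]
                if candidates:
                    partner = candidates[rng.integers(len(candidates))]
            if partner is None:
                partner = new_person(not person.male, gen)
                generation_members[gen].append(partner)
            person.spouse, partner.spouse = partner.id, person.id
            pair = (person, partner) if not person.male else (partner, person)
            couples.append(pair)

    # dissolve a few unions
    unions = []
    for wife, husband in couples:
        status = "former" if rng.random() < cfg.former_union_prob else "current"
        if status == "former":
            wife.spouse = husband.spouse = None
        unions.append({"spouse_a": wife.id, "spouse_b": husband.id, "status": status})

    # ages and adult roster
    ages = {}
    for gen, members in generation_members.items():
        mean = cfg.generation_age_means[gen]
        for p in members:
            ages[p.id] = float(
                np.clip(rng.normal(mean, cfg.generation_age_sd), 1.0, 90.0)
            )
    adults = [p for p in people.values() if ages[p.id] >= 18.0]
    if len(adults) > cfg.target_adults:
        keep = rng.choice(len(adults), size=cfg.target_adults, replace=False)
        adults = [adults[i] for i in sorted(keep)]
    resident = {p.id for p in adults}
    if len({p.id for p in adults}) < 2 * cfg.n_households // 4:
        raise ValueError("infeasible config: too few resident adults for the household count")

    # households: couples seed units, uxorilocal join to the wife's
    # parents where possible, unmarried adults join resident kin
    unit_of: dict[str, int] = {}
    units: list[list[str]] = []

    def new_unit(members: list[str]) -> int:
        units.append(members)
        idx = len(units) - 1
        for m in members:
            unit_of[m] = idx
        return idx

    def join(member: str, unit: int) -> None:
        units[unit].append(member)
        unit_of[member] = unit

    for wife, husband in couples:
        if wife.id not in resident and husband.id not in resident:
            continue
        if wife.spouse is None:  # dissolved
            continue
        members = [p for p in (wife.id, husband.id) if p in resident]
        anchor_parents = (
            [people[wife.id].mother, people[wife.id].father]
            if rng.random() < cfg.uxorilocal_bias
            else [people[husband.id].mother, people[husband.id].father]
        )
        target = None
        for par in anchor_parents:
            if par is not None and par in unit_of:
                target = unit_of[par]
                break
        if target is None:
            new_unit(members)
        else:
            for m in members:
                join(m, target)

    for p in adults:
        if p.id in unit_of:
            continue
        target = None
        for relative in (p.mother, p.father):
            if relative is not None and relative in unit_of:
                target = unit_of[relative]
                break
        if target is None:
            for child in people.values():
                if child.mother == p.id or child.father == p.id:
                    if child.id in unit_of:
                        target = unit_of[child.id]
                        break
        if target is None:
            new_unit([p.id])
        else:
            join(p.id, target)

    occupied = [sorted(u) for u in units if u]
    # adjust to the configured household count
    while len(occupied) > cfg.n_households:
        occupied.sort(key=len)
        smallest = occupied.pop(0)
        occupied[0] = sorted(occupied[0] + smallest)
    while len(occupied) < cfg.n_households:
        occupied.sort(key=len, reverse=True)
        largest = occupied[0]
        if len(largest) < 2:
            raise ValueError("infeasible config: cannot reach the household count")
        half = len(largest) // 2
        occupied[0] = largest[:half] or largest[:1]
        occupied.append(largest[half:])
        occupied = [sorted(u) for u in occupied]

    household_ids = [f"h{idx:02d}" for idx in range(len(occupied))]
    membership = {}
    for hid, members in zip(household_ids, occupied):
        for m in members:
            membership[m] = hid

    # attributes
    individuals = pd.DataFrame(
        {
            "id": [p.id for p in adults],
            "household": [membership[p.id] for p in adults],
            "male": [int(p.male) for p in adults],
            "age": [round(ages[p.id], 1) for p in adults],
            "bmi": np.round(
                np.clip(rng.normal(cfg.bmi_mean, cfg.bmi_sd, len(adults)), 15.0, 40.0), 2
            ),
            "skin": np.round(rng.normal(cfg.skin_mean, cfg.skin_sd, len(adults)), 2),
        }
    )
    side = cfg.spatial_extent_m
    households = pd.DataFrame(
        {
            "id": household_ids,
            "wealth": np.round(
                np.exp(rng.normal(cfg.wealth_log_mean, cfg.wealth_log_sd, len(household_ids))),
                4,
            ),
            "x": np.round(rng.uniform(0.0, side, len(household_ids)), 1),
            "y": np.round(rng.uniform(0.0, side, len(household_ids)), 1),
        }
    )

    pedigree = _pedigree_from(people)

    # godparent links, preferentially among non-kin resident adults
    god_rows = []
    resident_list = sorted(resident)
    for p in people.values():
        if p.mother is None and p.father is None:
            continue
        if rng.random() >= cfg.godparent_prob:
            continue
        weights = []
        for cand in resident_list:
            if cand in (p.id, p.mother, p.father):
                weights.append(0.0)
            else:
                weights.append(1.0 if pedigree.relatedness(cand, p.id) < 0.125 else 0.1)
        weights = np.asarray(weights)
        if weights.sum() == 0:
            continue
        pick = rng.choice(len(resident_list), p=weights / weights.sum())
        god_rows.append({"godparent": resident_list[pick], "godchild": p.id})
    godparents = pd.DataFrame(god_rows, columns=["godparent", "godchild"])

    return Community(
        individuals=individuals,
        households=households,
        unions=pd.DataFrame(unions, columns=["spouse_a", "spouse_b", "status"]),
        godparents=godparents,
        pedigree=pedigree,
    )


def _pedigree_from(people: dict[str, _Person]) -> Pedigree:
    return Pedigree(
        PedigreeRecord(p.id, p.mother, p.father, p.extra_pair)
        for p in people.values()
    )


def summarize_community(community: Community) -> pd.DataFrame:
    """Descriptive table: mean/sd/min/max per variable plus dyad counts.

    Dyad-level variables (relatedness, distance, infidelity ties) are
    summarized over inter-household pairs only, mirroring how the
    design matrix uses them.
    """
    ind = community.individuals
    members = community.household_members
    membership = community.membership
    relmat = (
        relatedness_matrix(community.pedigree, list(ind["id"]))
        if community.pedigree is not None
        else None
    )

    ids = list(ind["id"])
    inter_pairs = [
        (a, b)
        for a, b in itertools.combinations(ids, 2)
        if membership[a] != membership[b]
    ]
    rel_values = (
        np.array([relmat.loc[a, b] for a, b in inter_pairs]) if relmat is not None else np.array([])
    )

    hh = community.households.set_index("id")
    hh_ids = [h for h, mem in members.items() if mem]
    hh_pairs = list(itertools.combinations(hh_ids, 2))
    log_dists = np.array(
        [
            np.log(
                max(
                    np.hypot(
                        hh.loc[k, "x"] - hh.loc[l, "x"], hh.loc[k, "y"] - hh.loc[l, "y"]
                    ),
                    1.0,
                )
            )
            for k, l in hh_pairs
        ]
    )
    infid = (
        np.array(
            [
                float(infidelity_ties(k, l, community.pedigree, membership))
                for k, l in hh_pairs
            ]
        )
        if community.pedigree is not None
        else np.array([])
    )

    def stats(name, values, n):
        values = np.asarray(values, dtype=float)
        return {
            "variable": name,
            "n": n,
            "mean": values.mean() if values.size else np.nan,
            "sd": values.std(ddof=1) if values.size > 1 else 0.0,
            "min": values.min() if values.size else np.nan,
            "max": values.max() if values.size else np.nan,
        }

    n_ind = len(ids)
    rows = [
        stats("age", ind["age"], n_ind),
        stats("male", ind["male"], n_ind),
        stats("bmi", ind["bmi"], n_ind),
        stats("skin", ind["skin"], n_ind),
        stats("relatedness", rel_values, len(inter_pairs)),
        stats("log_wealth", np.log(hh.loc[hh_ids, "wealth"]), len(hh_ids)),
        stats("log_distance", log_dists, len(hh_pairs)),
        stats("infidelity_ties", infid, len(hh_pairs)),
        {
            "variable": "n_households",
            "n": len(hh_ids),
            "mean": np.nan,
            "sd": np.nan,
            "min": np.nan,
            "max": np.nan,
        },
        {
            "variable": "n_individual_dyads",
            "n": len(inter_pairs),
            "mean": np.nan,
            "sd": np.nan,
            "min": np.nan,
            "max": np.nan,
        },
        {
            "variable": "n_household_dyads",
            "n": len(hh_pairs),
            "mean": np.nan,
            "sd": np.nan,
            "min": np.nan,
            "max": np.nan,
        },
    ]
    return pd.DataFrame(rows).set_index("variable")
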
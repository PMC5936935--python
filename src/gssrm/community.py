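"""In-memory bundle for one study community.

Holds the adult roster, household attributes, marital unions, godparent
links and the pedigree — everything the covariate builder needs to turn
a community into a dyadic design matrix.  All tables are plain pandas
DataFrames with string ids; nothing here assumes integer or contiguous
identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .pedigree import Pedigree

INDIVIDUAL_COLUMNS = ["id", "household", "male", "age", "bmi", "skin"]
HOUSEHOLD_COLUMNS = ["id", "wealth", "x", "y"]
UNION_COLUMNS = ["spouse_a", "spouse_b", "status"]
GODPARENT_COLUMNS = ["godparent", "godchild"]


@dataclass
class Community:
    """Roster + households + unions + godparent links + pedigree.

    ``individuals``: one row per adult on the roster with columns
    ``id, household, male (0/1), age (years), bmi (kg/m^2), skin
    (melanin M index)``.  ``households``: ``id, wealth`` (thousands of
    cordobas, pre-log) and planar coordinates ``x, y`` in metres.
    ``unions``: ``spouse_a, spouse_b, status`` with status ``current``
    or ``former``.  ``godparents``: ``godparent, godchild``.
    """

    individuals: pd.DataFrame
    households: pd.DataFrame
    unions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=UNION_COLUMNS)
    )
    godparents: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=GODPARENT_COLUMNS)
    )
    pedigree: Pedigree | None = None

    def __post_init__(self) -> None:
        self.individuals = self.individuals.copy()
        self.individuals["id"] = self.individuals["id"].astype(str)
        self.individuals["household"] = self.individuals["household"].astype(str)
        self.households = self.households.copy()
        self.households["id"] = self.households["id"].astype(str)
        missing = set(INDIVIDUAL_COLUMNS) - set(self.individuals.columns)
        if missing:
            raise ValueError(f"individuals table missing columns: {sorted(missing)}")
        missing = set(HOUSEHOLD_COLUMNS) - set(self.households.columns)
        if missing:
            raise ValueError(f"households table missing columns: {sorted(missing)}")
        unknown = set(self.individuals["household"]) - set(self.households["id"])
        if unknown:
            raise ValueError(f"individuals reference unknown households: {sorted(unknown)}")
        if self.individuals["id"].duplicated().any():
            dup = self.individuals.loc[self.individuals["id"].duplicated(), "id"]
            raise ValueError(f"duplicate individual ids: {sorted(dup)}")

    @property
    def membership(self) -> dict[str, str]:
        """individual id -> household id."""
        return dict(zip(self.individuals["id"], self.individuals["household"]))

    @property
    def household_members(self) -> dict[str, list[str]]:
        """household id -> list of resident adult ids (possibly empty)."""
        members: dict[str, list[str]] = {h: [] for h in self.households["id"]}
        for ind, hh in zip(self.individuals["id"], self.individuals["household"]):
            members[hh].append(ind)
        return members

    def current_spouses(self, individual: str) -> list[str]:
        """Current marriage partners of ``individual`` (usually 0 or 1)."""
        out = []
        for a, b, status in self.unions[UNION_COLUMNS].itertuples(index=False):
            if str(status) != "current":
                continue
            if str(a) == individual:
                out.append(str(b))
            elif str(b) == individual:
                out.append(str(a))
        return out
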
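"""File formats and validation.

Everything is UTF-8 CSV with a header row: individuals, households,
unions, godparents, pedigree, and nomination edge lists.  Ids are
opaque strings.  ``read_community`` enforces cross-referential
integrity and raises a named validation error listing the offending
rows; ``read_nominations`` additionally drops intra-household edges
(the models cover inter-household relations only) with a logged count.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from .community import (
    GODPARENT_COLUMNS,
    HOUSEHOLD_COLUMNS,
    INDIVIDUAL_COLUMNS,
    UNION_COLUMNS,
    Community,
)
from .pedigree import Pedigree

logger = logging.getLogger("gssrm")

__all__ = [
    "ValidationError",
    "read_community",
    "write_community",
    "read_nominations",
    "write_nominations",
]


class ValidationError(ValueError):
    """Cross-referential integrity violation in input tables."""


def _read_csv(path, required: list[str], what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{what} file not found: {path}")
    frame = pd.read_csv(path, dtype=str)
    missing = set(required) - set(frame.columns)
    if missing:
        raise ValidationError(f"{what} file {path} missing columns: {sorted(missing)}")
    return frame


def read_community(
    individuals_path,
    households_path,
    unions_path=None,
    godparents_path=None,
    pedigree_path=None,
) -> Community:
    """Load and validate a community bundle from CSV files."""
    ind = _read_csv(individuals_path, INDIVIDUAL_COLUMNS, "individuals")
    for col in ("age", "bmi", "skin"):
        ind[col] = pd.to_numeric(ind[col])
    ind["male"] = pd.to_numeric(ind["male"]).astype(int)
    hh = _read_csv(households_path, HOUSEHOLD_COLUMNS, "households")
    for col in ("wealth", "x", "y"):
        hh[col] = pd.to_numeric(hh[col])

    unions = (
        _read_csv(unions_path, UNION_COLUMNS, "unions")
        if unions_path is not None
        else pd.DataFrame(columns=UNION_COLUMNS)
    )
    godparents = (
        _read_csv(godparents_path, GODPARENT_COLUMNS, "godparents")
        if godparents_path is not None
        else pd.DataFrame(columns=GODPARENT_COLUMNS)
    )
    pedigree = Pedigree.from_csv(pedigree_path) if pedigree_path is not None else None

    roster = set(ind["id"])
    unknown_hh = set(ind["household"]) - set(hh["id"])
    if unknown_hh:
        raise ValidationError(
            f"individuals reference unknown households: {sorted(unknown_hh)}"
        )
    if pedigree is not None:
        absent = [i for i in roster if i not in pedigree]
        if absent:
            raise ValidationError(
                f"roster individuals missing from pedigree: {sorted(absent)[:10]}"
            )
    bad_union = [
        (a, b)
        for a, b in zip(unions["spouse_a"], unions["spouse_b"])
        if a == b
    ]
    if bad_union:
        raise ValidationError(f"self-unions are invalid: {bad_union}")
    bad_god = [
        (g, c)
        for g, c in zip(godparents["godparent"], godparents["godchild"])
        if g == c
    ]
    if bad_god:
        raise ValidationError(f"self-godparenthood is invalid: {bad_god}")

    try:
        return Community(
            individuals=ind,
            households=hh,
            unions=unions,
            godparents=godparents,
            pedigree=pedigree,
        )
    except ValueError as exc:  # uniform error type for callers
        raise ValidationError(str(exc)) from exc


def write_community(community: Community, directory) -> dict[str, Path]:
    """Write the bundle as CSV files; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "individuals": directory / "individuals.csv",
        "households": directory / "households.csv",
        "unions": directory / "unions.csv",
        "godparents": directory / "godparents.csv",
    }
    community.individuals.to_csv(paths["individuals"], index=False)
    community.households.to_csv(paths["households"], index=False)
    community.unions.to_csv(paths["unions"], index=False)
    community.godparents.to_csv(paths["godparents"], index=False)
    if community.pedigree is not None:
        paths["pedigree"] = directory / "pedigree.csv"
        community.pedigree.to_csv(paths["pedigree"])
    return paths


def read_nominations(path, community: Community) -> pd.DataFrame:
    """Load a nomination edge list and validate it against the roster.

    Intra-household rows are excluded (with a logged count): the models
    describe inter-household relations only.
    """
    frame = _read_csv(path, ["ego", "alter", "y"], "nominations")
    frame["y"] = pd.to_numeric(frame["y"]).astype(int)
    roster = set(community.individuals["id"])
    unknown = (set(frame["ego"]) | set(frame["alter"])) - roster
    if unknown:
        raise ValidationError(
            f"nominations reference ids not on the roster: {sorted(unknown)[:10]}"
        )
    if not frame["y"].isin((0, 1)).all():
        raise ValidationError("nomination responses must be binary 0/1")
    membership = community.membership
    intra = frame.apply(
        lambda row: membership[row["ego"]] == membership[row["alter"]], axis=1
    )
    if intra.any():
        logger.info("excluded %d intra-household nomination rows", int(intra.sum()))
        frame = frame.loc[~intra].reset_index(drop=True)
    return frame


def write_nominations(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def log_run_config(config, path) -> None:
    """Serialize a run configuration (dataclass or dict) into a log file."""
    payload = dataclasses.asdict(config) if dataclasses.is_dataclass(config) else dict(config)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, default=str)
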
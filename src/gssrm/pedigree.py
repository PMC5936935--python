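"""Pedigrees and genealogical relatedness.

A pedigree is a table of parent links (mother, father, either possibly
unknown) plus a flag marking individuals conceived in extra-marital
unions.  From it we compute Malecot's kinship coefficient phi by the
standard tabular recursion and Wright's coefficient of relatedness

    r(a, b) = 2 phi(a, b) / sqrt((1 + F_a)(1 + F_b)),

where F is an individual's inbreeding coefficient (the kinship of its
parents).  Unknown parents are treated as unique, mutually unrelated
founders, so half-relationships through unrecorded parents contribute
nothing.  In largely outbred communities r is essentially 2 phi.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PedigreeError",
    "UnknownIndividualError",
    "PedigreeCycleError",
    "PedigreeRecord",
    "Pedigree",
    "kinship_coefficient",
    "wrights_r",
    "relatedness_matrix",
]


class PedigreeError(ValueError):
    """Base class for pedigree validation failures."""


class UnknownIndividualError(PedigreeError):
    """An id was requested that is not present in the pedigree."""


class PedigreeCycleError(PedigreeError):
    """The parent links contain a cycle (someone is their own ancestor)."""


@dataclass(frozen=True)
class PedigreeRecord:
    """One row of a pedigree table.

    ``mother_id``/``father_id`` are ``None`` for founders (or unrecorded
    parents).  ``extra_pair`` marks a child conceived during an
    adulterous union, i.e. whose genetic father is not the mother's
    spouse.
    """

    id: str
    mother_id: str | None = None
    father_id: str | None = None
    extra_pair: bool = False


def _normalise_parent(value) -> str | None:
    if value is None:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    text = str(value).strip()
    return text or None


class Pedigree:
    """Validated parent-link structure with cached kinship recursion.

    Input row order is free: generation order is resolved internally by
    topological sort, and a cycle anywhere in the parent links raises
    :class:`PedigreeCycleError` at construction time.
    """

    def __init__(self, records: Iterable[PedigreeRecord]):
        self.mother: dict[str, str | None] = {}
        self.father: dict[str, str | None] = {}
        self.extra_pair: dict[str, bool] = {}
        for rec in records:
            if rec.id in self.mother:
                raise PedigreeError(f"duplicate individual id {rec.id!r}")
            self.mother[rec.id] = _normalise_parent(rec.mother_id)
            self.father[rec.id] = _normalise_parent(rec.father_id)
            self.extra_pair[rec.id] = bool(rec.extra_pair)
        # Parents referenced but not listed become implicit founders.
        for parents in (self.mother, self.father):
            for pid in list(parents.values()):
                if pid is not None and pid not in self.mother:
                    self.mother[pid] = None
                    self.father[pid] = None
                    self.extra_pair[pid] = False
        self._depth = self._toposort_depths()
        self._phi_cache: dict[tuple[str, str], float] = {}

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Pedigree":
        """Build from a 4-column table (id, mother_id, father_id, extra_pair)."""
        required = {"id", "mother_id", "father_id"}
        missing = required - set(frame.columns)
        if missing:
            raise PedigreeError(f"pedigree table missing columns: {sorted(missing)}")
        extra = (
            frame["extra_pair"].fillna(0).astype(int).astype(bool)
            if "extra_pair" in frame.columns
            else pd.Series(False, index=frame.index)
        )
        return cls(
            PedigreeRecord(str(row.id), row.mother_id, row.father_id, bool(flag))
            for row, flag in zip(frame.itertuples(index=False), extra)
        )

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        return cls.from_frame(pd.read_csv(path, dtype={"id": str, "mother_id": str, "father_id": str}))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": list(self.mother),
                "mother_id": [self.mother[i] for i in self.mother],
                "father_id": [self.father[i] for i in self.mother],
                "extra_pair": [int(self.extra_pair[i]) for i in self.mother],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    # -- structure ------------------------------------------------------------

    @property
    def ids(self) -> list[str]:
        return list(self.mother)

    def __contains__(self, individual: str) -> bool:
        return individual in self.mother

    def __len__(self) -> int:
        return len(self.mother)

    def parents(self, individual: str) -> tuple[str | None, str | None]:
        self._check(individual)
        return self.mother[individual], self.father[individual]

    def children(self, individual: str) -> list[str]:
        self._check(individual)
        return [
            c
            for c in self.mother
            if self.mother[c] == individual or self.father[c] == individual
        ]

    def half_siblings(self, individual: str) -> list[str]:
        """Individuals sharing exactly one recorded parent with ``individual``."""
        self._check(individual)
        m, f = self.mother[individual], self.father[individual]
        out = []
        for other in self.mother:
            if other == individual:
                continue
            om, of = self.mother[other], self.father[other]
            shared = sum(
                1
                for a, b in ((m, om), (f, of))
                if a is not None and a == b
            )
            if shared == 1:
                out.append(other)
        return out

    def _check(self, individual: str) -> None:
        if individual not in self.mother:
            raise UnknownIndividualError(f"unknown individual id {individual!r}")

    def _toposort_depths(self) -> dict[str, int]:
        """Kahn's algorithm over parent->child edges; detects cycles."""
        indeg = {i: 0 for i in self.mother}
        for child in self.mother:
            for par in (self.mother[child], self.father[child]):
                if par is not None:
                    indeg[child] += 1
        queue = [i for i, d in indeg.items() if d == 0]
        depth = {i: 0 for i in queue}
        seen = 0
        while queue:
            nxt: list[str] = []
            for node in queue:
                seen += 1
                for child in self.mother:
                    if self.mother[child] == node or self.father[child] == node:
                        indeg[child] -= (self.mother[child] == node) + (
                            self.father[child] == node
                        )
                        cand = depth[node] + 1
                        depth[child] = max(depth.get(child, 0), cand)
                        if indeg[child] == 0:
                            nxt.append(child)
            queue = nxt
        if seen < len(self.mother):
            raise PedigreeCycleError("pedigree parent links contain a cycle")
        return depth

    # -- kinship --------------------------------------------------------------

    def kinship(self, id_a: str, id_b: str) -> float:
        """Malecot's kinship coefficient phi(a, b)."""
        self._check(id_a)
        self._check(id_b)
        return self._phi(id_a, id_b)

    def _phi(self, a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        cached = self._phi_cache.get(key)
        if cached is not None:
            return cached
        if a == b:
            m, f = self.mother[a], self.father[a]
            phi = 0.5 * (1.0 + (self._phi(m, f) if m and f else 0.0))
        else:
            # Recurse on the individual further from the founders so the
            # other is never one of its descendants.
            if self._depth[a] < self._depth[b]:
                a, b = b, a
            m, f = self.mother[a], self.father[a]
            phi = 0.5 * (
                (self._phi(m, b) if m else 0.0) + (self._phi(f, b) if f else 0.0)
            )
        self._phi_cache[key] = phi
        return phi

    def inbreeding(self, individual: str) -> float:
        """F = kinship of the individual's parents (0 if either unknown)."""
        m, f = self.parents(individual)
        if m is None or f is None:
            return 0.0
        return self._phi(m, f)

    def relatedness(self, id_a: str, id_b: str) -> float:
        """Wright's coefficient of relatedness r(a, b), in [0, 1]."""
        phi = self.kinship(id_a, id_b)
        if phi == 0.0:
            return 0.0
        denom = np.sqrt((1.0 + self.inbreeding(id_a)) * (1.0 + self.inbreeding(id_b)))
        return 2.0 * phi / denom


def kinship_coefficient(pedigree: Pedigree, id_a: str, id_b: str) -> float:
    """Kinship phi between two pedigree members (functional spelling)."""
    return pedigree.kinship(id_a, id_b)


def wrights_r(pedigree: Pedigree, id_a: str, id_b: str) -> float:
    """Wright's relatedness r between two pedigree members."""
    return pedigree.relatedness(id_a, id_b)


def relatedness_matrix(
    pedigree: Pedigree, id_list: Sequence[str] | None = None
) -> pd.DataFrame:
    """Symmetric matrix of pairwise Wright's r over ``id_list``.

    The diagonal equals 1 for non-inbred individuals (and exactly
    ``2 phi(a,a) / (1+F_a) = 1`` in general); downstream covariates use
    only the off-diagonal entries.
    """
    ids = list(id_list) if id_list is not None else pedigree.ids
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            r = pedigree.relatedness(ids[i], ids[j])
            mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=ids, columns=ids)
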
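"""Pedigree bookkeeping: kinship and identity-by-descent inbreeding.

Kinship f(i, j) follows the classic tabular recursion:

    f(i, i) = (1 + F_i) / 2,  F_i = f(sire_i, dam_i)
    f(i, j) = (f(sire_i, j) + f(dam_i, j)) / 2   (i not an ancestor of j)

Founders carry a baseline inbreeding value ``founder_f`` (self-kinship
(1 + f)/2), and known relationships between specific founder pairs can be
declared directly as founder kinships — e.g. a reintroduction whose six
founders included a mother-son pair and a sibling pair (kinship 1/4 each)
even though the parents themselves are not in the pedigree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["Pedigree", "PedigreeError", "read_pedigree", "write_pedigree"]

UNKNOWN = -1  # founder marker for parent ids


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Directed parent links with founder baselines.

    parents: id -> (sire_id, dam_id); UNKNOWN (-1) marks a founder side.
    founder_f: baseline inbreeding for founders (default 0).
    founder_kinships: {frozenset({i, j}): kinship} between founders.
    """

    parents: dict[int, tuple[int, int]] = field(default_factory=dict)
    founder_f: dict[int, float] = field(default_factory=dict)
    founder_kinships: dict[frozenset, float] = field(default_factory=dict)

    def __post_init__(self):
        self._kin_cache: dict[tuple[int, int], float] = {}
        self._depth_cache: dict[int, int] = {}
        self.validate()

    # -- construction -----------------------------------------------------

    def add_founder(self, i: int, founder_f: float = 0.0) -> None:
        if i in self.parents:
            raise PedigreeError(f"id {i} already in pedigree")
        self.parents[i] = (UNKNOWN, UNKNOWN)
        if founder_f:
            self.founder_f[i] = float(founder_f)
        self._depth_cache.clear()

    def add_member(self, i: int, sire: int, dam: int) -> None:
        if i in self.parents:
            raise PedigreeError(f"id {i} already in pedigree")
        for p in (sire, dam):
            if p != UNKNOWN and p not in self.parents:
                raise PedigreeError(f"parent {p} of {i} not in pedigree")
        self.parents[i] = (sire, dam)
        self._kin_cache.clear()
        self._depth_cache.clear()

    def declare_founder_kinship(self, i: int, j: int, kinship: float) -> None:
        for x in (i, j):
            if not self.is_founder(x):
                raise PedigreeError(f"{x} is not a founder")
        self.founder_kinships[frozenset((i, j))] = float(kinship)
        self._kin_cache.clear()

    # -- structure --------------------------------------------------------

    @property
    def members(self) -> list[int]:
        return list(self.parents)

    @property
    def founders(self) -> list[int]:
        return [i for i, (s, d) in self.parents.items() if s == UNKNOWN and d == UNKNOWN]

    def is_founder(self, i: int) -> bool:
        s, d = self.parents[i]
        return s == UNKNOWN and d == UNKNOWN

    def validate(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.parents)
        for child, (s, d) in self.parents.items():
            for p in (s, d):
                if p == UNKNOWN:
                    continue
                if p not in self.parents:
                    raise PedigreeError(f"parent {p} of {child} unknown")
                g.add_edge(p, child)
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise PedigreeError(f"pedigree contains a cycle: {cyc}")

    def _depth(self, i: int) -> int:
        d = self._depth_cache.get(i)
        if d is not None:
            return d
        s, dam = self.parents[i]
        if s == UNKNOWN and dam == UNKNOWN:
            d = 0
        else:
            d = 1 + max(self._depth(p) for p in (s, dam) if p != UNKNOWN)
        self._depth_cache[i] = d
        return d

    # -- kinship / inbreeding --------------------------------------------

    def kinship(self, i: int, j: int) -> float:
        for x in (i, j):
            if x not in self.parents:
                raise PedigreeError(f"unknown id {x}")
        return self._kinship(i, j)

    def _kinship(self, i: int, j: int) -> float:
        key = (i, j) if i <= j else (j, i)
        val = self._kin_cache.get(key)
        if val is not None:
            return val
        if i == j:
            val = 0.5 * (1.0 + self._inbreeding(i))
        elif self.is_founder(i) and self.is_founder(j):
            val = self.founder_kinships.get(frozenset((i, j)), 0.0)
        else:
            # recurse on the deeper individual: it cannot be an ancestor of
            # the shallower one
            a, b = (i, j) if self._depth(i) >= self._depth(j) else (j, i)
            s, d = self.parents[a]
            fs = self._kinship(s, b) if s != UNKNOWN else 0.0
            fd = self._kinship(d, b) if d != UNKNOWN else 0.0
            val = 0.5 * (fs + fd)
        self._kin_cache[key] = val
        return val

    def _inbreeding(self, i: int) -> float:
        s, d = self.parents[i]
        if s == UNKNOWN and d == UNKNOWN:
            return self.founder_f.get(i, 0.0)
        if s == UNKNOWN or d == UNKNOWN:
            # single known parent: the unknown side is an unrelated founder
            return 0.0
        return self._kinship(s, d)

    def inbreeding_coefficient(self, i: int) -> float:
        """F_i = kinship of the parents; founders return their baseline."""
        if i not in self.parents:
            raise PedigreeError(f"unknown id {i}")
        return self._inbreeding(i)

    def kinship_matrix(self, ids=None) -> pd.DataFrame:
        ids = list(ids) if ids is not None else self.members
        m = np.zeros((len(ids), len(ids)))
        for a, i in enumerate(ids):
            for b, j in enumerate(ids[a:], start=a):
                m[a, b] = m[b, a] = self.kinship(i, j)
        return pd.DataFrame(m, index=ids, columns=ids)


def write_pedigree(ped: Pedigree, path) -> None:
    """3-column CSV (id, sire, dam) plus founder attributes.

    Founder baselines are stored in a founder_f column; declared founder
    kinships in extra rows of a trailing block is avoided by using a wide
    column 'founder_kinships' (i:j:value; semicolon-separated) on the first
    row only.
    """
    rows = []
    fk = ";".join(
        f"{min(p)}:{max(p)}:{v}" for p, v in sorted(ped.founder_kinships.items(), key=lambda kv: sorted(kv[0]))
    )
    for n, (i, (s, d)) in enumerate(ped.parents.items()):
        rows.append(
            (i, s, d, ped.founder_f.get(i, 0.0) if ped.is_founder(i) else "", fk if n == 0 else "")
        )
    pd.DataFrame(rows, columns=["id", "sire", "dam", "founder_f", "founder_kinships"]).to_csv(
        path, index=False
    )


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, keep_default_na=False)
    ped = Pedigree()
    deferred = []
    for _, row in df.iterrows():
        i, s, d = int(row["id"]), int(row["sire"]), int(row["dam"])
        if s == UNKNOWN and d == UNKNOWN:
            f = float(row["founder_f"]) if str(row.get("founder_f", "")).strip() else 0.0
            ped.add_founder(i, f)
        else:
            deferred.append((i, s, d))
    # parents may appear after children in the file; insert in passes
    while deferred:
        progressed = False
        rest = []
        for i, s, d in deferred:
            if all(p == UNKNOWN or p in ped.parents for p in (s, d)):
                ped.add_member(i, s, d)
                progressed = True
            else:
                rest.append((i, s, d))
        if not progressed:
            raise PedigreeError(f"unresolvable parent references: {rest[:5]}")
        deferred = rest
    fk = str(df["founder_kinships"].iloc[0]).strip() if "founder_kinships" in df.columns and len(df) else ""
    if fk:
        for part in fk.split(";"):
            a, b, v = part.split(":")
            ped.declare_founder_kinship(int(a), int(b), float(v))
    return ped
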
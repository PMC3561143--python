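"""Pedigree structures, validation, and meiotic-distance weights.

An extended pedigree is a directed ancestry graph over individuals. The
statistic downstream weights each unordered pair of genotyped cases by
``d_jk``, the number of meioses (parent-child transmissions) on the shortest
path connecting the pair through the pedigree: siblings have d=2, first
cousins d=4, and so on. When marriage loops create several connecting paths
the minimum path length is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable

import networkx as nx
import numpy as np

__all__ = [
    "Individual",
    "Pedigree",
    "PairWeightMatrix",
    "PedigreeError",
    "load_pedigree",
    "load_pedigrees",
]


class PedigreeError(ValueError):
    """Structural problem in a pedigree definition."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``father`` and ``mother`` are both ``None`` for founders; individuals
    with exactly one recorded parent are rejected because gene-dropping
    requires two founder gametes per non-founder. ``status`` is binary:
    affected individuals are "case", everyone else "unknown". Only cases
    are genotyped.
    """

    iid: str
    father: str | None = None
    mother: str | None = None
    sex: str = "unknown"  # male / female / unknown
    is_case: bool = False
    genotyped: bool = False

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


@dataclass
class Pedigree:
    """A validated pedigree with at least two genotyped cases.

    ``case_ids`` preserves input order; all pairwise-distance and weight
    queries are expressed against this ordering.
    """

    individuals: dict[str, Individual]
    case_ids: list[str]
    family_id: str = "1"
    _ug: nx.Graph = field(default=None, repr=False, compare=False)

    @classmethod
    def from_individuals(
        cls, individuals: Iterable[Individual], family_id: str = "1"
    ) -> "Pedigree":
        index: dict[str, Individual] = {}
        for ind in individuals:
            if ind.iid in index:
                raise PedigreeError(f"duplicate individual id {ind.iid!r}")
            index[ind.iid] = ind
        ped = cls(
            individuals=index,
            case_ids=[i.iid for i in index.values() if i.is_case],
            family_id=family_id,
        )
        ped.validate()
        return ped

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        dg = nx.DiGraph()
        for ind in self.individuals.values():
            if (ind.father is None) != (ind.mother is None):
                raise PedigreeError(
                    f"individual {ind.iid!r} has a single recorded parent; "
                    "both parents or none are required"
                )
            dg.add_node(ind.iid)
            for parent in (ind.father, ind.mother):
                if parent is None:
                    continue
                if parent not in self.individuals:
                    raise PedigreeError(
                        f"individual {ind.iid!r} references missing parent {parent!r}"
                    )
                dg.add_edge(parent, ind.iid)
        if not nx.is_directed_acyclic_graph(dg):
            cyc = nx.find_cycle(dg)
            raise PedigreeError(f"ancestry cycle detected: {cyc}")
        if len(self.case_ids) < 2:
            raise PedigreeError(
                f"fewer than 2 cases (found {len(self.case_ids)}); "
                "sharing analysis needs at least one case pair"
            )
        ug = dg.to_undirected()
        for j, k in combinations(self.case_ids, 2):
            if not nx.has_path(ug, j, k):
                raise PedigreeError(f"cases {j!r} and {k!r} are not connected")
        self._ug = ug

    # -- graph views --------------------------------------------------------

    @property
    def undirected_graph(self) -> nx.Graph:
        if self._ug is None:
            self.validate()
        return self._ug

    @property
    def founders(self) -> list[str]:
        return [i.iid for i in self.individuals.values() if i.is_founder]

    @property
    def n_cases(self) -> int:
        return len(self.case_ids)

    def topological_order(self) -> list[str]:
        """Individuals ordered parents-before-children."""
        dg = nx.DiGraph()
        dg.add_nodes_from(self.individuals)
        for ind in self.individuals.values():
            for parent in (ind.father, ind.mother):
                if parent is not None:
                    dg.add_edge(parent, ind.iid)
        # stable: break ties by insertion order of the input file
        order = {iid: n for n, iid in enumerate(self.individuals)}
        return list(nx.lexicographical_topological_sort(dg, key=order.get))

    # -- distances ----------------------------------------------------------

    def meiotic_distance(self, j: str, k: str) -> int:
        """Meioses separating two individuals (shortest connecting path)."""
        if j == k:
            raise PedigreeError("meiotic distance requires two distinct individuals")
        for iid in (j, k):
            if iid not in self.individuals:
                raise PedigreeError(f"unknown individual {iid!r}")
        try:
            return nx.shortest_path_length(self.undirected_graph, j, k)
        except nx.NetworkXNoPath:
            raise PedigreeError(f"{j!r} and {k!r} are not connected") from None

    def pair_weights(self) -> "PairWeightMatrix":
        """Meiosis counts d_jk for every unordered case pair."""
        pairs = list(combinations(self.case_ids, 2))
        d = np.array([self.meiotic_distance(j, k) for j, k in pairs], dtype=np.int64)
        return PairWeightMatrix(case_ids=list(self.case_ids), pairs=pairs, d=d)

    def total_connecting_meioses(self) -> int:
        """Distinct parent-child edges in the union of one canonical
        shortest path per case pair — the "N cases connected by M meioses"
        summary used to describe extended pedigrees."""
        edges: set[frozenset[str]] = set()
        for j, k in combinations(self.case_ids, 2):
            path = nx.shortest_path(self.undirected_graph, j, k)
            edges.update(frozenset(e) for e in zip(path[:-1], path[1:]))
        return len(edges)


@dataclass
class PairWeightMatrix:
    """Symmetric meiosis-count weights over the case pairs of one pedigree."""

    case_ids: list[str]
    pairs: list[tuple[str, str]]
    d: np.ndarray  # (n_pairs,) positive ints, aligned with ``pairs``

    def __post_init__(self) -> None:
        if np.any(self.d < 1):
            raise PedigreeError("meiosis counts must be >= 1")

    def distance(self, j: str, k: str) -> int:
        key = {j, k}
        for (a, b), val in zip(self.pairs, self.d):
            if {a, b} == key:
                return int(val)
        raise KeyError(f"pair ({j}, {k}) not present")

    def as_matrix(self) -> np.ndarray:
        n = len(self.case_ids)
        idx = {iid: i for i, iid in enumerate(self.case_ids)}
        m = np.zeros((n, n), dtype=np.int64)
        for (a, b), val in zip(self.pairs, self.d):
            m[idx[a], idx[b]] = m[idx[b], idx[a]] = val
        return m


# -- file loading -----------------------------------------------------------

_SEX = {"1": "male", "2": "female", "0": "unknown"}


def _parse_rows(path) -> dict[str, list[Individual]]:
    families: dict[str, list[Individual]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens or tokens[0].startswith("#"):
                continue
            if len(tokens) < 6:
                raise PedigreeError(
                    f"{path}:{ln}: expected 6 columns "
                    "(family, individual, father, mother, sex, status)"
                )
            fam, iid, fid, mid, sex, status = tokens[:6]
            if fid == iid or mid == iid:
                raise PedigreeError(
                    f"{path}:{ln}: individual {iid!r} lists itself as a parent "
                    "(ancestry cycle)"
                )
            is_case = status == "2"
            families.setdefault(fam, []).append(
                Individual(
                    iid=iid,
                    father=None if fid == "0" else fid,
                    mother=None if mid == "0" else mid,
                    sex=_SEX.get(sex, "unknown"),
                    is_case=is_case,
                    genotyped=is_case,
                )
            )
    if not families:
        raise PedigreeError(f"{path}: no pedigree rows found")
    return families


def load_pedigrees(path) -> dict[str, Pedigree]:
    """Load every family in a whitespace-delimited pedigree file.

    Columns: family-id, individual-id, father-id, mother-id, sex (1/2/0),
    status (2=case, 0/1=unknown); "0" denotes an absent parent.
    """
    return {
        fam: Pedigree.from_individuals(rows, family_id=fam)
        for fam, rows in _parse_rows(path).items()
    }


def load_pedigree(path, family: str | None = None) -> Pedigree:
    """Load a single validated pedigree (see :func:`load_pedigrees`)."""
    families = _parse_rows(path)
    if family is None:
        if len(families) != 1:
            raise PedigreeError(
                f"{path} contains {len(families)} families; pass family="
            )
        family = next(iter(families))
    if family not in families:
        raise PedigreeError(f"family {family!r} not found in {path}")
    return Pedigree.from_individuals(families[family], family_id=family)
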
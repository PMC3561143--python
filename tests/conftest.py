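"""Shared fixtures: tiny pedigrees, genotype files, and random generators."""

from __future__ import annotations

import numpy as np
import pytest

from psgs.pedigree import Individual, Pedigree


@pytest.fixture
def sib_pedigree() -> Pedigree:
    """Nuclear family: two founders, two case children."""
    return Pedigree.from_individuals(
        [
            Individual("F", sex="male"),
            Individual("M", sex="female"),
            Individual("C1", "F", "M", "female", True, True),
            Individual("C2", "F", "M", "female", True, True),
        ]
    )


@pytest.fixture
def sibs_plus_cousin_pedigree() -> Pedigree:
    """Two case sibs plus their first-cousin case: weights {2, 4, 4}."""
    return Pedigree.from_individuals(
        [
            Individual("G1", sex="male"),
            Individual("G2", sex="female"),
            Individual("P1", "G1", "G2", "male"),
            Individual("P2", "G1", "G2", "female"),
            Individual("S1", sex="female"),
            Individual("S2", sex="male"),
            Individual("C1", "P1", "S1", "female", True, True),
            Individual("C2", "P1", "S1", "female", True, True),
            Individual("C3", "S2", "P2", "female", True, True),
        ]
    )


def random_pedigree(rng: np.random.Generator, n_extra: int = 16) -> Pedigree:
    """Random multi-generation pedigree for property tests.

    Starts from a founder couple and repeatedly marries founders into the
    tree, guaranteeing all individuals stay connected; a random subset of
    at least two leaves becomes cases.
    """
    inds = [Individual("I0", sex="male"), Individual("I1", sex="female")]
    males = ["I0"]
    females = ["I1"]
    children = []
    for i in range(2, 2 + n_extra):
        father = str(rng.choice(males))
        mother = str(rng.choice(females))
        child = f"I{i}"
        sex = "male" if rng.integers(2) else "female"
        inds.append(Individual(child, father, mother, sex))
        children.append(child)
        (males if sex == "male" else females).append(child)
    n_cases = int(rng.integers(2, min(5, len(children)) + 1))
    case_ids = rng.choice(children, size=n_cases, replace=False)
    out = []
    for ind in inds:
        if ind.iid in case_ids:
            out.append(
                Individual(ind.iid, ind.father, ind.mother, ind.sex, True, True)
            )
        else:
            out.append(ind)
    return Pedigree.from_individuals(out)


def bfs_distance_oracle(ped: Pedigree, a: str, b: str) -> int:
    """Plain breadth-first search on an adjacency dict built from scratch."""
    adj: dict[str, set[str]] = {iid: set() for iid in ped.individuals}
    for ind in ped.individuals.values():
        for parent in (ind.father, ind.mother):
            if parent is not None:
                adj[ind.iid].add(parent)
                adj[parent].add(ind.iid)
    frontier = {a}
    seen = {a}
    dist = 0
    while frontier:
        if b in frontier:
            return dist
        frontier = {n for x in frontier for n in adj[x]} - seen
        seen |= frontier
        dist += 1
    raise AssertionError("disconnected")


def write_ped_file(path, rows: str) -> str:
    path.write_text(rows)
    return str(path)
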
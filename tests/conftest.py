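"""Shared fixtures and independent oracles.

The brute-force fragment oracle enumerates every simple path with
networkx, keeps only paths realizing the endpoint graph distance, and
canonicalizes exactly like the production code is supposed to — but
through an entirely separate code path (string assembly from path lists,
no shared helpers beyond the bond-symbol table).
"""

from __future__ import annotations

from collections import Counter
from typing import Dict

import networkx as nx
import numpy as np
import pytest

from ionoqspr.structures import Atom, MolecularGraph

BOND_CHAR = {1: "-", 2: "=", 3: "#"}


def brute_force_fragments(g: MolecularGraph, min_atoms: int = 2,
                          max_atoms: int = 9) -> Dict[str, int]:
    """All simple paths, filtered to shortest, canonicalized by min(s, reverse)."""
    nxg = g.to_networkx()
    dist = dict(nx.all_pairs_shortest_path_length(nxg))
    counts: Counter = Counter()
    nodes = sorted(nxg.nodes)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            d = dist[u].get(v)
            if d is None or not (min_atoms - 1 <= d <= max_atoms - 1):
                continue
            for path in nx.all_simple_paths(nxg, u, v, cutoff=d):
                if len(path) - 1 != d:
                    continue
                tokens = []
                for k, node in enumerate(path):
                    tokens.append(g.atoms[node].symbol)
                    if k + 1 < len(path):
                        tokens.append(BOND_CHAR[g.bond_order(path[k], path[k + 1])])
                s = "".join(tokens)
                r = "".join(reversed(tokens))
                counts[min(s, r)] += 1
    return dict(counts)


def random_molecular_graph(rng: np.random.Generator, max_atoms: int = 8) -> MolecularGraph:
    """Random connected labeled graph; not necessarily chemically sensible.

    The fragmenter operates on arbitrary labeled graphs, so the oracle
    battery deliberately includes valence-illegal structures and two-letter
    element symbols.
    """
    n = int(rng.integers(2, max_atoms + 1))
    elements = ["C", "N", "O", "P", "S", "Cl", "Br"]
    atoms = [Atom(str(rng.choice(elements))) for _ in range(n)]
    bonds = {}
    for j in range(1, n):  # random spanning tree keeps the graph connected
        i = int(rng.integers(0, j))
        bonds[(i, j)] = int(rng.integers(1, 4))
    extra = int(rng.integers(0, n))
    for _ in range(extra):
        i, j = sorted(rng.choice(n, size=2, replace=False).tolist())
        bonds.setdefault((int(i), int(j)), int(rng.integers(1, 4)))
    return MolecularGraph(atoms=atoms, bonds=bonds, name="rand")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def ethane() -> MolecularGraph:
    return MolecularGraph(atoms=[Atom("C"), Atom("C")], bonds={(0, 1): 1}, name="ethane")


@pytest.fixture
def propane() -> MolecularGraph:
    return MolecularGraph(
        atoms=[Atom("C")] * 3, bonds={(0, 1): 1, (1, 2): 1}, name="propane"
    )


@pytest.fixture
def benzene() -> MolecularGraph:
    bonds = {(0, 1): 2, (1, 2): 1, (2, 3): 2, (3, 4): 1, (4, 5): 2, (0, 5): 1}
    return MolecularGraph(atoms=[Atom("C")] * 6, bonds=bonds, name="benzene")
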
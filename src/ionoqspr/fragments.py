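"""Shortest-path substructure fragment descriptors.

A fragment is the atom/bond sequence along a shortest path between two
atoms of the hydrogen-suppressed graph, written as alternating element and
bond symbols ("C-C-P-C=C-C"; "-" single, "=" double, "#" triple) and
canonicalized to the lexicographically smaller of the string and its
token-wise reversal. Paths of 2-9 atoms are counted by default; when a
pair of atoms is joined by several equally short paths (antipodal atoms of
an even ring), every distinct shortest path contributes one count — this
makes the counts invariant under atom relabeling.

The molecule × fragment count matrix built here is the predictor block of
the sensitivity regression.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import networkx as nx
import pandas as pd

from .structures import BOND_SYMBOL, MolecularGraph

PathLike = Union[str, Path]


def canonical_fragment(symbols: Sequence[str], orders: Sequence[int]) -> str:
    """Canonical string for an atom path: min of forward and reversed text.

    ``symbols`` are the element symbols along the path, ``orders`` the bond
    orders between consecutive atoms (``len(orders) == len(symbols) - 1``).
    Reversal is token-wise, so two-letter elements (Cl, Br) stay intact;
    comparison is plain byte order on the assembled strings.
    """
    if len(orders) != len(symbols) - 1:
        raise ValueError("need exactly one bond order between consecutive atoms")
    tokens: List[str] = []
    for k, sym in enumerate(symbols):
        tokens.append(sym)
        if k < len(orders):
            tokens.append(BOND_SYMBOL[orders[k]])
    forward = "".join(tokens)
    backward = "".join(reversed(tokens))
    return forward if forward <= backward else backward


def fragment_length(fragment: str) -> int:
    """Number of atoms in a canonical fragment string."""
    return sum(fragment.count(b) for b in "-=#") + 1


def enumerate_fragments(g: MolecularGraph, min_atoms: int = 2, max_atoms: int = 9,
                        atoms_only: bool = False) -> Dict[str, int]:
    """Count canonical shortest-path fragments of ``min_atoms``..``max_atoms``.

    For every unordered atom pair at graph distance d with
    ``min_atoms - 1 <= d <= max_atoms - 1``, each distinct shortest path
    adds one count to its canonical fragment. An empty or single-atom graph
    yields an empty map.

    ``atoms_only`` drops the bond symbols from the fragment strings
    (element-sequence variant); off by default.
    """
    if not (2 <= min_atoms <= max_atoms):
        raise ValueError(f"invalid atom-count bounds [{min_atoms}, {max_atoms}]")
    counts: Counter = Counter()
    n = g.n_atoms
    if n < 2:
        return dict(counts)
    nxg = g.to_networkx()
    cutoff = max_atoms - 1
    symbols = [a.symbol for a in g.atoms]
    for u in range(n):
        dist = nx.single_source_shortest_path_length(nxg, u, cutoff=cutoff)
        for v, d in dist.items():
            if v <= u or d < min_atoms - 1:
                continue
            for path in nx.all_shortest_paths(nxg, u, v):
                syms = [symbols[i] for i in path]
                if atoms_only:
                    fwd = "".join(syms)
                    frag = min(fwd, fwd[::-1])
                else:
                    orders = [g.bond_order(path[k], path[k + 1]) for k in range(len(path) - 1)]
                    frag = canonical_fragment(syms, orders)
                counts[frag] += 1
    return dict(counts)


def build_descriptor_matrix(graphs: Sequence[MolecularGraph],
                            vocabulary: Optional[Sequence[str]] = None,
                            min_atoms: int = 2, max_atoms: int = 9,
                            atoms_only: bool = False) -> pd.DataFrame:
    """Build the molecule × fragment integer count matrix.

    Training mode (``vocabulary is None``): columns are the union of all
    fragments over the graphs, in lexicographic order. Prediction mode:
    columns are exactly ``vocabulary`` in the given order; fragments of a
    graph outside the vocabulary are ignored and vocabulary fragments
    absent from a graph count zero.
    """
    if len(graphs) == 0:
        raise ValueError("need at least one molecule")
    ids = []
    for k, g in enumerate(graphs):
        ids.append(g.name if g.name else f"mol{k}")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate molecule ids in descriptor matrix")
    maps = [enumerate_fragments(g, min_atoms, max_atoms, atoms_only=atoms_only) for g in graphs]
    if vocabulary is None:
        columns = sorted(set().union(*maps)) if maps else []
    else:
        columns = list(vocabulary)
    data = [[m.get(f, 0) for f in columns] for m in maps]
    return pd.DataFrame(data, index=pd.Index(ids, name="id"), columns=columns, dtype=int)


def fragment_support(matrix: pd.DataFrame, fragment: str) -> int:
    """Number of molecules (rows) in which ``fragment`` occurs at least once."""
    if fragment not in matrix.columns:
        raise KeyError(f"fragment {fragment!r} not in vocabulary")
    return int((matrix[fragment] > 0).sum())


def write_descriptor_matrix(matrix: pd.DataFrame, path: PathLike, sparse: bool = False) -> None:
    """Write the count matrix as CSV, or as sparse triplets (id, fragment, count)."""
    if sparse:
        stacked = matrix.stack()
        trip = stacked[stacked > 0].reset_index()
        trip.columns = ["id", "fragment", "count"]
        trip.to_csv(path, index=False)
    else:
        matrix.to_csv(path)


def read_descriptor_matrix(path: PathLike, sparse: bool = False) -> pd.DataFrame:
    """Inverse of :func:`write_descriptor_matrix` (sparse readers re-densify)."""
    if sparse:
        trip = pd.read_csv(path, dtype={"id": str, "fragment": str, "count": int})
        matrix = trip.pivot(index="id", columns="fragment", values="count").fillna(0).astype(int)
        matrix = matrix.reindex(columns=sorted(matrix.columns))
        matrix.columns.name = None
        return matrix
    matrix = pd.read_csv(path, index_col="id")
    return matrix.astype(int)
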
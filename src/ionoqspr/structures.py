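"""Hydrogen-suppressed molecular graphs parsed from SMILES.

Ionophore structures enter the pipeline as SMILES strings and are held as
labeled undirected graphs: atoms carry an element symbol and formal charge,
bonds carry a Kekulé order (single/double/triple). Aromatic rings are
resolved to alternating localized bonds at parse time, because the fragment
strings downstream are written in Kekulé notation ("C-C=C", not "C:C:C").

Kekulization is made reproducible across different SMILES writings of the
same molecule by renumbering atoms into RDKit's canonical order before the
aromaticity is localized: any remaining tie is between automorphic atoms,
so the resulting graphs are isomorphic and fragment counts are identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Tuple

import networkx as nx
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # parse errors are surfaced as exceptions

#: bond order (1, 2, 3) → fragment bond symbol
BOND_SYMBOL = {1: "-", 2: "=", 3: "#"}

_RDKIT_ORDER = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
}


class ParseError(ValueError):
    """SMILES string could not be parsed."""


class KekulizationError(ValueError):
    """Aromatic system could not be resolved to alternating bonds."""


@dataclass(frozen=True)
class Atom:
    symbol: str
    charge: int = 0


@dataclass
class MolecularGraph:
    """Hydrogen-suppressed labeled graph of one ionophore.

    ``atoms`` is an ordered list (indices 0..n-1); ``bonds`` maps the
    ordered pair ``(i, j)`` with ``i < j`` to the bond order in {1, 2, 3}.
    """

    atoms: List[Atom]
    bonds: Dict[Tuple[int, int], int]
    name: str = ""
    _adj: Dict[int, Dict[int, int]] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for (i, j), order in self.bonds.items():
            if i == j:
                raise ValueError(f"self-loop on atom {i}")
            if not (0 <= i < j < n):
                raise ValueError(f"bond ({i},{j}) out of range or unordered")
            if order not in BOND_SYMBOL:
                raise ValueError(f"bond ({i},{j}) has non-Kekulé order {order!r}")
        adj: Dict[int, Dict[int, int]] = {i: {} for i in range(n)}
        for (i, j), order in self.bonds.items():
            adj[i][j] = order
            adj[j][i] = order
        object.__setattr__(self, "_adj", adj)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, i: int) -> Dict[int, int]:
        """Neighbor index → bond order."""
        return self._adj[i]

    def bond_order(self, i: int, j: int) -> int:
        return self.bonds[(i, j) if i < j else (j, i)]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(name=self.name)
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from((i, j, {"order": o}) for (i, j), o in self.bonds.items())
        return g

    def relabeled(self, perm: List[int]) -> "MolecularGraph":
        """Return the graph with atom ``i`` moved to index ``perm[i]``."""
        atoms = [None] * self.n_atoms
        for i, a in enumerate(self.atoms):
            atoms[perm[i]] = a
        bonds = {}
        for (i, j), o in self.bonds.items():
            pi, pj = perm[i], perm[j]
            bonds[(pi, pj) if pi < pj else (pj, pi)] = o
        return MolecularGraph(atoms=atoms, bonds=bonds, name=self.name)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)


def _canonical_kekulized(mol: Chem.Mol) -> Chem.Mol:
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True))
    order = [i for _, i in sorted((r, i) for i, r in enumerate(ranks))]
    mol = Chem.RenumberAtoms(mol, order)
    Chem.Kekulize(mol, clearAromaticFlags=True)
    return mol


def parse_structure(smiles: str, id: str = "") -> MolecularGraph:
    """Parse a SMILES string into a kekulized, hydrogen-suppressed graph.

    Deterministic: the same SMILES always yields the same atom ordering and
    the same Kekulé assignment. Explicit hydrogens are removed; formal
    charges are retained on atoms.

    Raises
    ------
    ParseError
        If the SMILES is syntactically invalid (the message names ``id``).
    KekulizationError
        If an aromatic system admits no alternating-bond assignment.
    """
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        raise ParseError(f"unparseable SMILES for {id or 'input'!r}: {smiles!r}")
    try:
        Chem.SanitizeMol(mol)
    except Chem.KekulizeException as exc:
        raise KekulizationError(f"cannot kekulize {id or 'input'!r}: {smiles!r}") from exc
    except Exception as exc:  # valence and other sanitization failures
        raise ParseError(f"invalid structure for {id or 'input'!r}: {smiles!r} ({exc})") from exc
    mol = Chem.RemoveHs(mol)
    try:
        mol = _canonical_kekulized(mol)
    except Chem.KekulizeException as exc:
        raise KekulizationError(f"cannot kekulize {id or 'input'!r}: {smiles!r}") from exc

    atoms = [Atom(a.GetSymbol(), a.GetFormalCharge()) for a in mol.GetAtoms()]
    bonds: Dict[Tuple[int, int], int] = {}
    for b in mol.GetBonds():
        order = _RDKIT_ORDER.get(b.GetBondType())
        if order is None:
            raise KekulizationError(
                f"non-Kekulé bond {b.GetBondType()} survived parsing of {id or 'input'!r}"
            )
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        bonds[(i, j) if i < j else (j, i)] = order
    return MolecularGraph(atoms=atoms, bonds=bonds, name=id)
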
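"""Heavy-atom molecular graphs and the graph-distance machinery behind
topological descriptors.

A :class:`MolecularGraph` is the minimal structure the descriptor layer
needs: heavy atoms labelled with element and hybridization, an undirected
bond list, and (when the source provides them) 3D coordinates and atomic
masses.  Structures are parsed with RDKit from SMILES or MOL/SDF V2000
records; the graph algorithms run on a NetworkX view of the bond list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Atom",
    "MolecularGraph",
    "DistanceMatrix",
    "MoleculeParseError",
    "read_structure",
    "read_structures",
    "topological_distance_matrix",
    "reciprocal_square_distance_matrix",
    "path_count",
    "alpha_sum",
    "KIER_ALPHA",
]

HYBRIDIZATIONS = ("sp3", "sp2", "sp", "aromatic")

# Kier's alpha contributions alpha_i = r_i / r(C sp3) - 1 from his published
# covalent radii (r(C sp3) = 0.77 A).  Aromatic atoms take the sp2 value.
# Version 1 of this table; extend rather than edit in place.
KIER_ALPHA: dict[tuple[str, str], float] = {
    ("C", "sp3"): 0.0,
    ("C", "sp2"): -0.13,
    ("C", "aromatic"): -0.13,
    ("C", "sp"): -0.22,
    ("N", "sp3"): -0.04,
    ("N", "sp2"): -0.20,
    ("N", "aromatic"): -0.20,
    ("N", "sp"): -0.29,
    ("O", "sp3"): -0.04,
    ("O", "sp2"): -0.20,
    ("O", "aromatic"): -0.20,
    ("F", "sp3"): -0.07,
    ("Cl", "sp3"): 0.29,
    ("Br", "sp3"): 0.48,
    ("I", "sp3"): 0.73,
    ("P", "sp3"): 0.43,
    ("S", "sp3"): 0.35,
    ("S", "sp2"): 0.22,
    ("S", "aromatic"): 0.22,
    ("H", "sp3"): -0.05,
}


class MoleculeParseError(ValueError):
    """Raised when a structure record cannot be parsed into a single molecule."""


@dataclass(frozen=True)
class Atom:
    element: str
    hybridization: str

    def __post_init__(self) -> None:
        if self.hybridization not in HYBRIDIZATIONS:
            raise ValueError(
                f"unknown hybridization {self.hybridization!r} for {self.element}; "
                f"expected one of {HYBRIDIZATIONS}"
            )


@dataclass
class MolecularGraph:
    """Connected heavy-atom graph of a single molecule.

    Parameters
    ----------
    atoms
        One :class:`Atom` per heavy atom.
    bonds
        Unordered ``(i, j, order)`` triples; ``order`` is the bond order
        (aromatic bonds carry 1.5).
    coords
        Optional ``(A, 3)`` array of Cartesian coordinates in angstroms.
    masses
        Optional length-``A`` array of atomic masses in amu.
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int, float]]
    coords: Optional[np.ndarray] = None
    masses: Optional[np.ndarray] = None
    coords_are_2d: bool = False
    name: str = ""
    _graph: Optional[nx.Graph] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        a = len(self.atoms)
        if a < 1:
            raise ValueError("a molecular graph needs at least one atom")
        seen: set[tuple[int, int]] = set()
        for i, j, _order in self.bonds:
            if i == j:
                raise ValueError(f"self-loop on atom {i}")
            if not (0 <= i < a and 0 <= j < a):
                raise ValueError(f"bond ({i}, {j}) out of range for {a} atoms")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)
        if a > 1 and not nx.is_connected(self.to_networkx()):
            raise ValueError("molecular graph must be connected")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (a, 3):
                raise ValueError("coords must have shape (n_atoms, 3)")
        if self.masses is not None:
            self.masses = np.asarray(self.masses, dtype=float)
            if self.masses.shape != (a,):
                raise ValueError("masses must have one entry per atom")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def to_networkx(self) -> nx.Graph:
        if self._graph is None:
            g = nx.Graph()
            g.add_nodes_from(range(len(self.atoms)))
            g.add_edges_from((i, j) for i, j, _ in self.bonds)
            self._graph = g
        return self._graph

    def degrees(self) -> np.ndarray:
        g = self.to_networkx()
        return np.array([g.degree(i) for i in range(self.n_atoms)])


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise atom-distance table.

    ``mode`` is ``"topological"`` (integer shortest-path bond counts) or
    ``"reciprocal_square"`` (off-diagonal ``1/d**2`` weights in ``(0, 1]``).
    """

    values: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if self.mode not in ("topological", "reciprocal_square"):
            raise ValueError(f"unknown mode {self.mode!r}")
        off = v[~np.eye(v.shape[0], dtype=bool)]
        if self.mode == "topological":
            if off.size and (np.any(off != np.round(off)) or np.any(off < 1)):
                raise ValueError("topological distances must be positive integers")
        else:
            if off.size and (np.any(off <= 0) or np.any(off > 1)):
                raise ValueError("reciprocal-square entries must lie in (0, 1]")

    @property
    def n_atoms(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n_atoms, k=1)
        return self.values[iu]


def _hybridization_tag(atom) -> str:
    from rdkit import Chem

    if atom.GetIsAromatic():
        return "aromatic"
    hyb = atom.GetHybridization()
    mapping = {
        Chem.HybridizationType.SP3: "sp3",
        Chem.HybridizationType.SP2: "sp2",
        Chem.HybridizationType.SP: "sp",
    }
    # Unhybridized/other centres (halogens, some S/P states) behave as sp3
    # for the covalent-radius lookup.
    return mapping.get(hyb, "sp3")


def _mol_to_graph(mol, source: str, keep_hydrogens: bool = False) -> MolecularGraph:
    from rdkit import Chem

    frags = Chem.GetMolFrags(mol)
    if len(frags) > 1:
        raise MoleculeParseError(
            f"multi-fragment input (salts/solvates unsupported): {source!r}"
        )
    if not keep_hydrogens:
        mol = Chem.RemoveHs(mol)
    idx_map: dict[int, int] = {}
    atoms: list[Atom] = []
    for atom in mol.GetAtoms():
        if not keep_hydrogens and atom.GetAtomicNum() == 1:
            continue
        idx_map[atom.GetIdx()] = len(atoms)
        atoms.append(Atom(atom.GetSymbol(), _hybridization_tag(atom)))
    if not atoms:
        raise MoleculeParseError(f"no heavy atoms in {source!r}")
    bonds: list[tuple[int, int, float]] = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in idx_map and j in idx_map:
            bonds.append((idx_map[i], idx_map[j], bond.GetBondTypeAsDouble()))
    coords = None
    is_2d = False
    if mol.GetNumConformers() > 0:
        conf = mol.GetConformer()
        coords = np.array(
            [list(conf.GetAtomPosition(k)) for k in sorted(idx_map, key=idx_map.get)]
        )
        is_2d = not conf.Is3D()
    masses = np.array(
        [mol.GetAtomWithIdx(k).GetMass() for k in sorted(idx_map, key=idx_map.get)]
    )
    name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
    return MolecularGraph(
        atoms=atoms, bonds=bonds, coords=coords, masses=masses,
        coords_are_2d=is_2d, name=name,
    )


def read_structure(source: str, keep_hydrogens: bool = False) -> MolecularGraph:
    """Parse a single SMILES string or MOL/SDF V2000 record into a graph.

    MOL blocks are recognised by an embedded newline or the ``V2000`` tag;
    anything else is treated as SMILES.  Hydrogens are suppressed unless
    ``keep_hydrogens`` is set (explicit-H graphs are only used for
    sensitivity checks of the descriptor conventions).
    """
    from rdkit import Chem

    text = source.strip("\n")
    if "\n" in source or "V2000" in source:
        mol = Chem.MolFromMolBlock(source, removeHs=not keep_hydrogens)
    else:
        mol = Chem.MolFromSmiles(text)
        if mol is not None and keep_hydrogens:
            mol = Chem.AddHs(mol)
    if mol is None:
        head = text.splitlines()[0] if text else ""
        raise MoleculeParseError(f"could not parse structure record {head!r}")
    return _mol_to_graph(mol, source=text.splitlines()[0] if text else "",
                         keep_hydrogens=keep_hydrogens)


def read_structures(
    records: Iterable[tuple[str, str]] | str,
    keep_hydrogens: bool = False,
) -> Iterator[tuple[str, MolecularGraph]]:
    """Yield ``(identifier, MolecularGraph)`` pairs.

    ``records`` is either an iterable of ``(identifier, source)`` pairs or
    the text of a multi-record SDF file, in which case identifiers come
    from each record's title line.
    """
    if isinstance(records, str):
        blocks = [b for b in records.split("$$$$") if b.strip()]
        for n, block in enumerate(blocks):
            g = read_structure(block.lstrip("\n") + "\n", keep_hydrogens=keep_hydrogens)
            yield (g.name or f"mol_{n}"), g
    else:
        for ident, source in records:
            g = read_structure(source, keep_hydrogens=keep_hydrogens)
            g.name = ident
            yield ident, g


def topological_distance_matrix(g: MolecularGraph) -> DistanceMatrix:
    """All-pairs shortest-path bond counts (the graph-theoretic D matrix)."""
    a = g.n_atoms
    d = np.zeros((a, a))
    for i, lengths in nx.all_pairs_shortest_path_length(g.to_networkx()):
        for j, dij in lengths.items():
            d[i, j] = dij
    return DistanceMatrix(values=d, mode="topological")


def reciprocal_square_distance_matrix(g: MolecularGraph) -> DistanceMatrix:
    """Distance matrix with off-diagonal entries 1/d**2.

    Near pairs dominate: a bonded pair contributes 1, a pair three bonds
    apart only 1/9.
    """
    if g.n_atoms < 2:
        raise ValueError("reciprocal-square distances need at least two atoms")
    topo = topological_distance_matrix(g).values
    with np.errstate(divide="ignore"):
        recip = 1.0 / topo**2
    np.fill_diagonal(recip, 0.0)
    return DistanceMatrix(values=recip, mode="reciprocal_square")


def path_count(g: MolecularGraph, length: int) -> int:
    """Number of distinct simple paths with ``length`` bonds.

    Each undirected path is counted once.  ``path_count(g, 2)`` is the P
    appearing in the second-order kappa denominator.
    """
    if length < 1:
        raise ValueError("path length must be >= 1")
    if length == 1:
        return g.n_bonds
    adj: dict[int, list[int]] = {i: [] for i in range(g.n_atoms)}
    for i, j, _ in g.bonds:
        adj[i].append(j)
        adj[j].append(i)

    def extend(node: int, visited: set[int], remaining: int) -> int:
        if remaining == 0:
            return 1
        total = 0
        for nxt in adj[node]:
            if nxt not in visited:
                visited.add(nxt)
                total += extend(nxt, visited, remaining - 1)
                visited.remove(nxt)
        return total

    directed = sum(extend(start, {start}, length) for start in adj)
    return directed // 2


def alpha_sum(g: MolecularGraph) -> float:
    """Sum of Kier alpha contributions over the heavy atoms.

    alpha_i = r_i / r(C sp3) - 1, looked up from :data:`KIER_ALPHA`.
    All-sp3-carbon skeletons give exactly 0.
    """
    total = 0.0
    for idx, atom in enumerate(g.atoms):
        key = (atom.element, atom.hybridization)
        if key not in KIER_ALPHA:
            raise KeyError(
                f"no Kier alpha value for atom {idx} "
                f"({atom.element}, {atom.hybridization})"
            )
        total += KIER_ALPHA[key]
    return total
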
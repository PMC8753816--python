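"""Molecular graphs and r-radius subgraph fingerprints.

A compound is an undirected heavy-atom graph G = (N, E).  Each atom and each
bond is assigned the integer id of the canonical signature of its r-radius
subgraph: the induced subgraph of everything within shortest-path distance r.
Signatures are computed by iterative neighborhood relabeling (Weisfeiler-
Lehman style): r rounds of re-hashing every atom's label together with the
sorted multiset of its (bond type, neighbor label) pairs.  Two r-radius
subgraphs get the same id exactly when the relabeling cannot tell them
apart, which makes the ids invariant under atom reindexing.

Id 0 is reserved for UNK in both the node and the edge table, so a frozen
vocabulary can still fingerprint molecules containing never-seen
substructures.
"""

from __future__ import annotations

import hashlib
import json
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # rdkit warns loudly on its own stderr

BOND_TYPES = ("single", "double", "triple", "aromatic")

_RDKIT_BOND = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}

UNK_ID = 0


class SmilesParseError(ValueError):
    pass


@dataclass(frozen=True)
class Atom:
    """Heavy-atom descriptor: element symbol plus aromaticity flag."""
    symbol: str
    aromatic: bool


@dataclass
class MolecularGraph:
    """Undirected heavy-atom graph of one compound.

    ``bonds`` stores each bond once as (i, j, bond_type) with i < j;
    ``adjacency[i]`` lists (neighbor, bond_index) pairs so every bond is
    traversable from both ends.
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int, str]]
    adjacency: list[list[tuple[int, int]]] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.atoms)
        seen_pairs = set()
        for i, j, bt in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) endpoint out of range")
            if i == j:
                raise ValueError(f"self-loop at atom {i}")
            if i > j:
                raise ValueError(f"bond ({i},{j}) not stored with i<j")
            if (i, j) in seen_pairs:
                raise ValueError(f"duplicate bond ({i},{j})")
            if bt not in BOND_TYPES:
                raise ValueError(f"unknown bond type {bt!r}")
            seen_pairs.add((i, j))
        if not self.adjacency:
            adj: list[list[tuple[int, int]]] = [[] for _ in range(n)]
            for b, (i, j, _) in enumerate(self.bonds):
                adj[i].append((j, b))
                adj[j].append((i, b))
            self.adjacency = adj

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def permuted(self, perm: list[int]) -> "MolecularGraph":
        """Relabel atoms: new index of old atom i is perm[i]."""
        atoms = [None] * self.n_atoms
        for old, new in enumerate(perm):
            atoms[new] = self.atoms[old]
        bonds = []
        for i, j, bt in self.bonds:
            a, b = sorted((perm[i], perm[j]))
            bonds.append((a, b, bt))
        return MolecularGraph(atoms=list(atoms), bonds=bonds)


def parse_smiles(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a heavy-atom :class:`MolecularGraph`.

    Hydrogens stay implicit; atom order follows RDKit's canonical order for
    the input, so parsing is deterministic for a fixed string.
    """
    if not smiles:
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    atoms = [Atom(a.GetSymbol(), a.GetIsAromatic()) for a in mol.GetAtoms()]
    bonds = []
    for b in mol.GetBonds():
        i, j = sorted((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        bt = _RDKIT_BOND.get(b.GetBondType())
        if bt is None:
            raise SmilesParseError(
                f"unsupported bond type {b.GetBondType()} in {smiles!r}")
        bonds.append((i, j, bt))
    bonds.sort()
    return MolecularGraph(atoms=atoms, bonds=bonds)


def neighborhoods(graph: MolecularGraph, r: int) -> list[set[int]]:
    """S(i, r): all atoms within shortest-path distance r of atom i (BFS)."""
    if r < 0:
        raise ValueError("radius must be nonnegative")
    out = []
    for start in range(graph.n_atoms):
        dist = {start: 0}
        q = deque([start])
        while q:
            u = q.popleft()
            if dist[u] == r:
                continue
            for v, _ in graph.adjacency[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    q.append(v)
        out.append(set(dist))
    return out


def _digest(s: str) -> str:
    return hashlib.sha1(s.encode()).hexdigest()[:16]


def _wl_labels(graph: MolecularGraph, rounds: int) -> list[list[str]]:
    """labels[k][i]: canonical signature of atom i's k-radius subgraph."""
    labels = [[f"{a.symbol}|{int(a.aromatic)}" for a in graph.atoms]]
    for _ in range(rounds):
        prev = labels[-1]
        nxt = []
        for i in range(graph.n_atoms):
            env = sorted(
                (graph.bonds[b][2], prev[j]) for j, b in graph.adjacency[i]
            )
            nxt.append(_digest(prev[i] + "!" + ";".join(f"{bt},{l}" for bt, l in env)))
        labels.append(nxt)
    return labels


def node_signatures(graph: MolecularGraph, r: int) -> list[str]:
    """Canonical signature of every atom's r-radius subgraph."""
    return _wl_labels(graph, r)[r]


def edge_signatures(graph: MolecularGraph, r: int) -> list[str]:
    """Canonical signature of every bond's r-radius subgraph.

    For r = 0 the signature is the bond type alone; for r >= 1 it combines
    the bond type with the unordered pair of the endpoints' (r-1)-radius
    signatures, i.e. the union of what each endpoint sees at radius r-1.
    """
    if r == 0:
        return [bt for _, _, bt in graph.bonds]
    node_lab = _wl_labels(graph, r - 1)[r - 1]
    sigs = []
    for i, j, bt in graph.bonds:
        a, b = sorted((node_lab[i], node_lab[j]))
        sigs.append(_digest(f"{bt}#{a}#{b}"))
    return sigs


@dataclass
class SubgraphVocabulary:
    """Canonical r-radius subgraph signatures mapped to dense integer ids.

    Id 0 is the reserved UNK in both tables; real signatures start at 1.
    """

    radius: int
    node_table: dict[str, int] = field(default_factory=dict)
    edge_table: dict[str, int] = field(default_factory=dict)
    frozen: bool = False

    @property
    def node_vocab_size(self) -> int:
        return len(self.node_table) + 1  # + UNK

    @property
    def edge_vocab_size(self) -> int:
        return len(self.edge_table) + 1

    def freeze(self) -> None:
        self.frozen = True

    def _lookup(self, table: dict[str, int], sig: str, grow: bool) -> int:
        got = table.get(sig)
        if got is not None:
            return got
        if grow:
            table[sig] = len(table) + 1
            return table[sig]
        return UNK_ID

    def to_json(self) -> str:
        return json.dumps({
            "radius": self.radius,
            "node_table": self.node_table,
            "edge_table": self.edge_table,
        })

    @classmethod
    def from_json(cls, text: str) -> "SubgraphVocabulary":
        obj = json.loads(text)
        return cls(radius=int(obj["radius"]),
                   node_table={k: int(v) for k, v in obj["node_table"].items()},
                   edge_table={k: int(v) for k, v in obj["edge_table"].items()},
                   frozen=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "SubgraphVocabulary":
        return cls.from_json(Path(path).read_text())


@dataclass
class FingerprintedGraph:
    """A molecular graph plus per-atom and per-bond fingerprint ids."""

    graph: MolecularGraph
    node_ids: list[int]
    edge_ids: list[int]

    def __post_init__(self):
        if len(self.node_ids) != self.graph.n_atoms:
            raise ValueError("node id count does not match atom count")
        if len(self.edge_ids) != self.graph.n_bonds:
            raise ValueError("edge id count does not match bond count")


def assign_fingerprints(graph: MolecularGraph, r: int,
                        vocab: SubgraphVocabulary,
                        allow_grow: bool = False) -> FingerprintedGraph:
    """Fingerprint every atom and bond of ``graph`` at radius r.

    Unseen signatures get fresh ids when ``allow_grow``; with a frozen
    vocabulary they map to UNK (id 0) instead.
    """
    if vocab.radius != r:
        raise ValueError(f"vocabulary built for radius {vocab.radius}, got r={r}")
    if vocab.frozen and allow_grow:
        raise ValueError("cannot grow a frozen vocabulary")
    node_ids = [vocab._lookup(vocab.node_table, s, allow_grow)
                for s in node_signatures(graph, r)]
    edge_ids = [vocab._lookup(vocab.edge_table, s, allow_grow)
                for s in edge_signatures(graph, r)]
    return FingerprintedGraph(graph=graph, node_ids=node_ids, edge_ids=edge_ids)
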
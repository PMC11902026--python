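"""Molecular similarity kernels: Tanimoto, atom-pair Tanimoto, and MCS.

Three similarity measures between ligand structures, all symmetric and in
[0, 1] with self-similarity 1:

* fingerprint Tanimoto — |A ∩ B| / |A ∪ B| over the set bits of hashed
  path fingerprints (RDKit, default 2048 bits, paths up to 7 bonds);
* atom-pair Tanimoto — Σ min / Σ max over a multiset of
  (atom descriptor, atom descriptor, topological distance) triples, the
  classical atom-pair scheme with descriptors
  (element, heavy-neighbor count, aromatic flag);
* MCS similarity — m / (e_a + e_b − m) where m is the edge count of the
  connected maximal common edge subgraph, atoms matched on element and
  aromaticity, bonds on order.

Hydrogens are implicit throughout.  The MCS search is exact (branch and
bound) up to a wall-clock timeout, beyond which a seeded randomized search
takes over and the result is flagged approximate.
"""

from __future__ import annotations

import random
import time
import warnings
from dataclasses import dataclass, field

import networkx as nx
from rdkit import Chem
from rdkit.Chem import rdmolops

from .nqr import ValidationError

__all__ = [
    "MolecularGraph",
    "Fingerprint",
    "AtomPairMultiset",
    "MCSResult",
    "ParseError",
    "parse_structure",
    "path_fingerprint",
    "tanimoto",
    "atom_pair_multiset",
    "atom_pair_tanimoto",
    "max_common_edge_subgraph",
    "mcs_similarity",
]

ATOM_PAIR_SCHEME = "element+degree+aromatic/topological"
PATH_FP_SCHEME = "rdkit-path"


class ParseError(ValidationError):
    """Malformed structure input."""


@dataclass(frozen=True)
class MolecularGraph:
    """Heavy-atom molecular graph with perceived aromaticity.

    ``atoms`` is a list of (element symbol, formal charge, aromatic flag);
    ``bonds`` of (i, j, order) where order is 1, 2, 3 or the string "ar"
    for aromatic bonds.  Hydrogens are implicit.
    """

    atoms: tuple[tuple[str, int, bool], ...]
    bonds: tuple[tuple[int, int, object], ...]
    provenance: str = ""
    _mol: object | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen = set()
        for i, j, _order in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValidationError(f"bond ({i}, {j}) references missing atom")
            if i == j:
                raise ValidationError(f"self-bond on atom {i}")
            key = frozenset((i, j))
            if key in seen:
                raise ValidationError(f"duplicate bond between atoms {i} and {j}")
            seen.add(key)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for idx, (element, charge, aromatic) in enumerate(self.atoms):
            g.add_node(idx, element=element, charge=charge, aromatic=aromatic)
        for i, j, order in self.bonds:
            g.add_edge(i, j, order=order)
        return g


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length hashed fingerprint as a set of on-bit indices."""

    bits: frozenset[int]
    length: int = 2048
    max_path: int = 7
    scheme: str = PATH_FP_SCHEME

    @property
    def parameters(self) -> tuple[int, int, str]:
        return (self.length, self.max_path, self.scheme)


@dataclass(frozen=True)
class AtomPairMultiset:
    """Multiset of (descriptor, descriptor, topological distance) triples."""

    counts: dict
    scheme: str = ATOM_PAIR_SCHEME


@dataclass(frozen=True)
class MCSResult:
    """Outcome of a common-edge-subgraph search."""

    edges: int
    similarity: float
    exact: bool


_BOND_ORDER = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: "ar",
}


def parse_structure(text: str) -> MolecularGraph:
    """Parse a SMILES string into a heavy-atom molecular graph."""
    if not isinstance(text, str) or not text.strip():
        raise ParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(text, sanitize=True)
    if mol is None:
        # re-parse without sanitization to locate the failure where possible
        probe = Chem.MolFromSmiles(text, sanitize=False)
        detail = ("invalid chemistry (sanitization failed)"
                  if probe is not None else "syntax error")
        raise ParseError(f"cannot parse SMILES {text!r}: {detail}")
    atoms = tuple(
        (a.GetSymbol(), a.GetFormalCharge(), a.GetIsAromatic())
        for a in mol.GetAtoms()
    )
    bonds = tuple(
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
         _BOND_ORDER.get(b.GetBondType(), float(b.GetBondTypeAsDouble())))
        for b in mol.GetBonds()
    )
    return MolecularGraph(atoms=atoms, bonds=bonds, provenance=text, _mol=mol)


# ---------------------------------------------------------------------------
# fingerprint Tanimoto
# ---------------------------------------------------------------------------

def path_fingerprint(graph: MolecularGraph, length: int = 2048,
                     max_path: int = 7) -> Fingerprint:
    """Hashed path fingerprint (RDKit path enumeration) of a parsed structure."""
    mol = graph._mol
    if mol is None:
        mol = Chem.MolFromSmiles(graph.provenance)
        if mol is None:
            raise ValidationError(
                "graph lacks structure provenance; build it via parse_structure"
            )
    bv = rdmolops.RDKFingerprint(mol, fpSize=length, maxPath=max_path)
    return Fingerprint(bits=frozenset(bv.GetOnBits()), length=length,
                       max_path=max_path)


def tanimoto(fp_a: Fingerprint, fp_b: Fingerprint) -> float:
    """|A ∩ B| / |A ∪ B| over set bits; 1.0 when both sets are empty."""
    if fp_a.parameters != fp_b.parameters:
        raise ValidationError(
            f"fingerprint parameter mismatch: {fp_a.parameters} vs "
            f"{fp_b.parameters}"
        )
    union = fp_a.bits | fp_b.bits
    if not union:
        return 1.0
    return len(fp_a.bits & fp_b.bits) / len(union)


# ---------------------------------------------------------------------------
# atom-pair Tanimoto
# ---------------------------------------------------------------------------

def _atom_descriptor(g: nx.Graph, node: int) -> tuple:
    return (g.nodes[node]["element"], g.degree[node], g.nodes[node]["aromatic"])


def atom_pair_multiset(graph: MolecularGraph) -> AtomPairMultiset:
    """Atom-pair descriptors over all heavy-atom pairs at distance ≥ 1."""
    g = graph.to_networkx()
    counts: dict = {}
    lengths = dict(nx.all_pairs_shortest_path_length(g))
    nodes = sorted(g.nodes)
    for ai in range(len(nodes)):
        for bi in range(ai + 1, len(nodes)):
            a, b = nodes[ai], nodes[bi]
            dist = lengths.get(a, {}).get(b)
            if dist is None or dist < 1:
                continue  # disconnected fragments carry no pair
            da, db = sorted((_atom_descriptor(g, a), _atom_descriptor(g, b)))
            key = (da, db, dist)
            counts[key] = counts.get(key, 0) + 1
    return AtomPairMultiset(counts=counts)


def atom_pair_tanimoto(a: AtomPairMultiset, b: AtomPairMultiset) -> float:
    """Multiset Tanimoto: Σ min(count) / Σ max(count) over the key union."""
    if a.scheme != b.scheme:
        raise ValidationError(
            f"atom-pair scheme mismatch: {a.scheme!r} vs {b.scheme!r}"
        )
    keys = set(a.counts) | set(b.counts)
    if not keys:
        return 1.0
    mins = sum(min(a.counts.get(k, 0), b.counts.get(k, 0)) for k in keys)
    maxs = sum(max(a.counts.get(k, 0), b.counts.get(k, 0)) for k in keys)
    return mins / maxs


# ---------------------------------------------------------------------------
# connected maximum common edge subgraph
# ---------------------------------------------------------------------------

def _atoms_match(ga: nx.Graph, a: int, gb: nx.Graph, b: int) -> bool:
    return (ga.nodes[a]["element"] == gb.nodes[b]["element"]
            and ga.nodes[a]["aromatic"] == gb.nodes[b]["aromatic"])


def _bond_match(ga: nx.Graph, a1: int, a2: int, gb: nx.Graph,
                b1: int, b2: int) -> bool:
    return ga.edges[a1, a2]["order"] == gb.edges[b1, b2]["order"]


class _Timeout(Exception):
    pass


def _mces_exact(ga: nx.Graph, gb: nx.Graph, deadline: float) -> int:
    """Exact connected MCES size by branch and bound over node mappings.

    Grows a connected common subgraph one compatible node pair at a time;
    each added pair contributes every label-matching edge to the already
    mapped nodes.  Branching forbids previously tried pairs in the same
    subtree, so no mapping is revisited.
    """
    best = 0
    upper = min(ga.number_of_edges(), gb.number_of_edges())

    seed_pairs = [
        (a, b) for a in ga.nodes for b in gb.nodes if _atoms_match(ga, a, gb, b)
    ]

    def extend(mapping: dict, edges: int, forbidden: frozenset) -> None:
        nonlocal best
        if time.monotonic() > deadline:
            raise _Timeout
        if edges > best:
            best = edges
        if best == upper:
            return
        candidates = []
        mapped_b = set(mapping.values())
        for a in set().union(*(ga.adj[m] for m in mapping)) - mapping.keys():
            for b in set().union(*(gb.adj[mapping[m]] for m in mapping)) - mapped_b:
                if (a, b) in forbidden or not _atoms_match(ga, a, gb, b):
                    continue
                gained = sum(
                    1
                    for ma, mb in mapping.items()
                    if ga.has_edge(a, ma) and gb.has_edge(b, mb)
                    and _bond_match(ga, a, ma, gb, b, mb)
                )
                if gained >= 1:
                    candidates.append((a, b, gained))
        candidates.sort(key=lambda c: -c[2])
        tried: list[tuple[int, int]] = []
        for a, b, gained in candidates:
            extend(
                {**mapping, a: b},
                edges + gained,
                forbidden | frozenset(tried),
            )
            tried.append((a, b))

    tried_seeds: list[tuple[int, int]] = []
    for a, b in seed_pairs:
        if best == upper:
            break
        extend({a: b}, 0, frozenset(tried_seeds))
        tried_seeds.append((a, b))
    return best


def _mces_randomized(ga: nx.Graph, gb: nx.Graph, seed: int,
                     restarts: int = 200) -> int:
    """Seeded multi-start greedy growth; lower bound on the true MCES size."""
    rng = random.Random(seed)
    seed_pairs = [
        (a, b) for a in ga.nodes for b in gb.nodes if _atoms_match(ga, a, gb, b)
    ]
    if not seed_pairs:
        return 0
    best = 0
    for _ in range(restarts):
        a0, b0 = rng.choice(seed_pairs)
        mapping = {a0: b0}
        edges = 0
        while True:
            mapped_b = set(mapping.values())
            candidates = []
            for a in set().union(*(ga.adj[m] for m in mapping)) - mapping.keys():
                for b in (set().union(*(gb.adj[mapping[m]] for m in mapping))
                          - mapped_b):
                    if not _atoms_match(ga, a, gb, b):
                        continue
                    gained = sum(
                        1
                        for ma, mb in mapping.items()
                        if ga.has_edge(a, ma) and gb.has_edge(b, mb)
                        and _bond_match(ga, a, ma, gb, b, mb)
                    )
                    if gained >= 1:
                        candidates.append((a, b, gained))
            if not candidates:
                break
            top = max(c[2] for c in candidates)
            a, b, gained = rng.choice([c for c in candidates if c[2] == top])
            mapping[a] = b
            edges += gained
        best = max(best, edges)
    return best


def max_common_edge_subgraph(
    g_a: MolecularGraph,
    g_b: MolecularGraph,
    timeout: float = 10.0,
    seed: int = 0,
) -> MCSResult:
    """Connected maximal common edge subgraph of two molecular graphs.

    Atoms match on (element, aromatic flag), bonds on order.  The search is
    exact within ``timeout`` seconds; on expiry a seeded randomized greedy
    search supplies a lower bound and the result is flagged ``exact=False``.
    """
    if g_a.n_atoms == 0 or g_b.n_atoms == 0:
        raise ValidationError("MCS of an empty graph is undefined")
    ga, gb = g_a.to_networkx(), g_b.to_networkx()
    ea, eb = ga.number_of_edges(), gb.number_of_edges()
    if ea == 0 or eb == 0:
        # no common edge is possible; similarity degenerates to an atom check
        has_common_atom = any(
            _atoms_match(ga, a, gb, b) for a in ga.nodes for b in gb.nodes
        )
        sim = 1.0 if (ea == eb == 0 and has_common_atom) else 0.0
        return MCSResult(edges=0, similarity=sim, exact=True)

    deadline = time.monotonic() + timeout
    try:
        m = _mces_exact(ga, gb, deadline)
        exact = True
    except _Timeout:
        m = _mces_randomized(ga, gb, seed=seed)
        exact = False
    sim = m / (ea + eb - m)
    return MCSResult(edges=m, similarity=sim, exact=exact)


def mcs_similarity(g_a: MolecularGraph, g_b: MolecularGraph,
                   timeout: float = 10.0, seed: int = 0) -> float:
    """MCS similarity m / (e_a + e_b − m); warns if the search timed out."""
    result = max_common_edge_subgraph(g_a, g_b, timeout=timeout, seed=seed)
    if not result.exact:
        warnings.warn(
            "MCS search timed out; similarity is a randomized lower bound",
            stacklevel=2,
        )
    return result.similarity
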
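"""MinHashed atom-pair fingerprints and a kNN -> MST chemical-space tree.

Fingerprint: for every pair of heavy atoms (i < j), shingles of the form
``"<substructure at i>|<topological distance>|<substructure at j>"`` are
collected, where the substructures are the canonical SMILES of the circular
environments of radius 1 and 2 around each atom and the two substructure
strings are sorted so the shingle is invariant to atom numbering. The
shingle set is MinHashed into ``d`` hash minima (default 1024) under a
seeded affine family over 64-bit pre-hashes, and Jaccard similarity between
two molecules is estimated as the fraction of equal minima.

Chemical-space tree: an exact k-nearest-neighbor graph under estimated
Jaccard distance (1 - similarity) is built, its minimum spanning forest is
extracted with Kruskal's algorithm (ties broken lexicographically by
molecule id), and a deterministic radial layout assigns 2D coordinates
(angular wedges proportional to subtree leaf counts, radius proportional
to depth). This trades the original tree-map tool's LSH forest and
force-based layout for exact, reproducible equivalents at the scale of a
few thousand molecules.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .errors import ConfigError, EmptySketchError, StructureError

DEFAULT_DIMENSIONS = 1024
DEFAULT_RADII = (1, 2)
DEFAULT_K = 10

_HASH_CACHE: dict[str, int] = {}


# ---------------------------------------------------------------------------
# shingling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShingleSet:
    """Atom-pair shingle set of one molecule."""

    molecule_id: str
    shingles: frozenset[str]

    def __len__(self) -> int:
        return len(self.shingles)


def _atom_environments(mol: Chem.Mol, radii: Sequence[int]) -> list[dict[int, str]]:
    """Per-atom canonical substructure SMILES at each radius (missing when
    the molecule has no environment of exactly that radius around the atom)."""
    envs: list[dict[int, str]] = []
    for idx in range(mol.GetNumAtoms()):
        per_atom: dict[int, str] = {}
        for r in radii:
            bond_ids = Chem.FindAtomEnvironmentOfRadiusN(mol, r, idx)
            if not bond_ids:
                continue
            amap: dict[int, int] = {}
            submol = Chem.PathToSubmol(mol, bond_ids, atomMap=amap)
            if idx not in amap:
                continue
            per_atom[r] = Chem.MolToSmiles(
                submol, rootedAtAtom=amap[idx], canonical=True
            )
        envs.append(per_atom)
    return envs


def shingle(smiles: str, molecule_id: str = "", radii: Sequence[int] = DEFAULT_RADII
            ) -> ShingleSet:
    """Compute the atom-pair shingle set of a molecule.

    Invariant to atom renumbering; empty only for single-atom molecules.
    Raises :class:`StructureError` for unparseable SMILES.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparseable SMILES {smiles!r}")
    return shingle_mol(mol, molecule_id=molecule_id or smiles, radii=radii)


def shingle_mol(mol: Chem.Mol, molecule_id: str = "",
                radii: Sequence[int] = DEFAULT_RADII) -> ShingleSet:
    """:func:`shingle` on an already-parsed RDKit molecule."""
    n = mol.GetNumAtoms()
    if n < 2:
        return ShingleSet(molecule_id=molecule_id, shingles=frozenset())
    envs = _atom_environments(mol, radii)
    dist = Chem.GetDistanceMatrix(mol)
    shingles: set[str] = set()
    for i in range(n):
        ei = envs[i]
        for j in range(i + 1, n):
            ej = envs[j]
            d = int(dist[i, j])
            for r in radii:
                if r in ei and r in ej:
                    a, b = sorted((ei[r], ej[r]))
                    shingles.add(f"{a}|{d}|{b}")
    return ShingleSet(molecule_id=molecule_id, shingles=frozenset(shingles))


# ---------------------------------------------------------------------------
# MinHash
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FingerprintSketch:
    """MinHash signature of a shingle set."""

    molecule_id: str
    minima: np.ndarray        # shape (d,), uint64
    dimensions: int
    seed: int

    def __post_init__(self):
        object.__setattr__(self, "minima", np.ascontiguousarray(self.minima, dtype=np.uint64))


def _stable_hash(s: str) -> int:
    """Process-independent 64-bit hash of a shingle string."""
    h = _HASH_CACHE.get(s)
    if h is None:
        h = int.from_bytes(hashlib.blake2b(s.encode(), digest_size=8).digest(), "little")
        _HASH_CACHE[s] = h
    return h


def _hash_family(d: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Seeded affine permutations x -> a*x + b (mod 2**64), a odd."""
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 2**63, size=d, dtype=np.uint64) * np.uint64(2) + np.uint64(1)
    b = rng.integers(0, 2**64, size=d, dtype=np.uint64)
    return a, b


def minhash(s: ShingleSet, d: int = DEFAULT_DIMENSIONS, seed: int = 0) -> FingerprintSketch:
    """MinHash a shingle set into ``d`` hash minima.

    Deterministic for (set, d, seed); raises :class:`EmptySketchError` on an
    empty set (single-atom molecules have no atom pairs).
    """
    if d < 16:
        raise ConfigError("MinHash dimension d must be >= 16")
    if not s.shingles:
        raise EmptySketchError(f"empty shingle set for {s.molecule_id!r}")
    x = np.fromiter(
        (_stable_hash(t) for t in s.shingles), dtype=np.uint64, count=len(s.shingles)
    )
    a, b = _hash_family(d, seed)
    minima = _affine_minima(x, a, b)
    return FingerprintSketch(molecule_id=s.molecule_id, minima=minima,
                             dimensions=d, seed=seed)


def _affine_minima(x: np.ndarray, a: np.ndarray, b: np.ndarray,
                   chunk: int = 256) -> np.ndarray:
    """Row minima of a[:,None]*x[None,:] + b[:,None] (mod 2**64), chunked."""
    d = a.shape[0]
    out = np.empty(d, dtype=np.uint64)
    with np.errstate(over="ignore"):
        for lo in range(0, d, chunk):
            hi = min(lo + chunk, d)
            h = a[lo:hi, None] * x[None, :] + b[lo:hi, None]
            out[lo:hi] = h.min(axis=1)
    return out


def minhash_many(sets: Sequence[ShingleSet], d: int = DEFAULT_DIMENSIONS,
                 seed: int = 0) -> list[FingerprintSketch]:
    """MinHash several shingle sets under one shared hash family."""
    if d < 16:
        raise ConfigError("MinHash dimension d must be >= 16")
    a, b = _hash_family(d, seed)
    out = []
    for s in sets:
        if not s.shingles:
            raise EmptySketchError(f"empty shingle set for {s.molecule_id!r}")
        x = np.fromiter(
            (_stable_hash(t) for t in s.shingles), dtype=np.uint64, count=len(s.shingles)
        )
        out.append(
            FingerprintSketch(molecule_id=s.molecule_id,
                              minima=_affine_minima(x, a, b),
                              dimensions=d, seed=seed)
        )
    return out


def estimate_jaccard(a: FingerprintSketch, b: FingerprintSketch) -> float:
    """Estimated Jaccard similarity: fraction of equal hash minima."""
    if a.dimensions != b.dimensions or a.seed != b.seed:
        raise ConfigError("sketches come from different hash families")
    return float(np.mean(a.minima == b.minima))


# ---------------------------------------------------------------------------
# kNN graph -> minimum spanning tree -> radial layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpaceTree:
    """Spanning forest of the kNN similarity graph with 2D coordinates."""

    ids: tuple[str, ...]
    coordinates: Mapping[str, tuple[float, float]]
    edges: tuple[tuple[str, str, float], ...]   # (id_u, id_v, Jaccard distance)
    metadata: Mapping[str, object] = field(default_factory=dict)


def _pairwise_distances(sketches: Sequence[FingerprintSketch]) -> np.ndarray:
    mat = np.stack([s.minima for s in sketches])
    n, d = mat.shape
    dist = np.empty((n, n), dtype=float)
    for i in range(n):
        dist[i] = 1.0 - (mat[i] == mat).mean(axis=1)
    np.fill_diagonal(dist, 0.0)
    return dist


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> bool:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        self.parent[rj] = ri
        return True


def build_space_tree(sketches: Sequence[FingerprintSketch], k: int = DEFAULT_K,
                     layout_seed: int = 0) -> SpaceTree:
    """Exact kNN graph under estimated Jaccard distance, Kruskal MST with
    lexicographic tie-breaking, deterministic radial layout.

    All-identical sketches yield a valid star tree with zero-weight edges.
    """
    if len(sketches) < 2:
        raise ConfigError("need at least two sketches")
    if k < 1:
        raise ConfigError("k must be >= 1")
    ids = [s.molecule_id for s in sketches]
    if len(set(ids)) != len(ids):
        raise ConfigError("molecule ids must be unique")
    n = len(ids)
    dist = _pairwise_distances(sketches)

    # exact kNN, ties broken by lexicographic molecule id
    id_rank = np.argsort(np.argsort(np.array(ids, dtype=object)))
    edges: dict[tuple[int, int], float] = {}
    kk = min(k, n - 1)
    for i in range(n):
        order = np.lexsort((id_rank, dist[i]))
        order = order[order != i][:kk]
        for j in order:
            key = (min(i, int(j)), max(i, int(j)))
            edges[key] = dist[key[0], key[1]]

    # Kruskal with deterministic ordering: (weight, id_u, id_v) lexicographic
    sorted_edges = sorted(
        edges.items(),
        key=lambda kv: (kv[1], *sorted((ids[kv[0][0]], ids[kv[0][1]]))),
    )
    uf = _UnionFind(n)
    tree_edges: list[tuple[int, int, float]] = []
    for (i, j), w in sorted_edges:
        if uf.union(i, j):
            tree_edges.append((i, j, w))

    coords = _radial_layout(n, ids, tree_edges)
    named_edges = tuple(
        (*sorted((ids[i], ids[j])), float(w)) for i, j, w in tree_edges
    )
    return SpaceTree(
        ids=tuple(ids),
        coordinates=coords,
        edges=named_edges,
        metadata={
            "k": k,
            "layout_seed": layout_seed,
            "dimensions": sketches[0].dimensions,
            "hash_seed": sketches[0].seed,
            "layout": "radial-subtree-wedge",
            "mst_algorithm": "kruskal/lexicographic-ties",
        },
    )


def _radial_layout(n: int, ids: Sequence[str],
                   tree_edges: Sequence[tuple[int, int, float]]
                   ) -> dict[str, tuple[float, float]]:
    """Deterministic radial tree layout.

    Per connected component: root at the node of highest degree (ties by
    lexicographic id), children sorted by id, each subtree assigned an
    angular wedge proportional to its leaf count, radius equal to depth.
    Components are placed left to right.
    """
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    for i, j, _ in tree_edges:
        adj[i].append(j)
        adj[j].append(i)

    coords: dict[str, tuple[float, float]] = {}
    seen = [False] * n
    x_offset = 0.0
    for start in sorted(range(n), key=lambda i: ids[i]):
        if seen[start]:
            continue
        comp = _component(adj, start, seen)
        root = max(comp, key=lambda i: (len(adj[i]), ids[i]))
        leaves = _leaf_counts(adj, root)
        depth = _depths(adj, root)
        max_depth = max(depth.values()) if depth else 0
        # assign wedges by DFS
        pos: dict[int, tuple[float, float]] = {root: (0.0, 0.0)}
        stack = [(root, root, 0.0, 2 * np.pi)]
        while stack:
            node, parent, a0, a1 = stack.pop()
            children = sorted(
                (c for c in adj[node] if c != parent), key=lambda c: ids[c]
            )
            if not children:
                continue
            total = sum(leaves[c] for c in children)
            a = a0
            for c in children:
                width = (a1 - a0) * leaves[c] / total
                angle = a + width / 2
                r = float(depth[c])
                pos[c] = (r * np.cos(angle), r * np.sin(angle))
                stack.append((c, node, a, a + width))
                a += width
        span = max_depth if max_depth > 0 else 1.0
        for i, (x, y) in pos.items():
            coords[ids[i]] = (float(x + x_offset + span), float(y))
        x_offset += 2 * span + 1.0
    return coords


def _component(adj, start, seen) -> list[int]:
    comp, stack = [], [start]
    seen[start] = True
    while stack:
        i = stack.pop()
        comp.append(i)
        for j in adj[i]:
            if not seen[j]:
                seen[j] = True
                stack.append(j)
    return comp


def _leaf_counts(adj, root) -> dict[int, int]:
    counts: dict[int, int] = {}

    def walk(node, parent):
        children = [c for c in adj[node] if c != parent]
        if not children:
            counts[node] = 1
            return 1
        counts[node] = sum(walk(c, node) for c in children)
        return counts[node]

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10000))
    try:
        walk(root, root)
    finally:
        sys.setrecursionlimit(old)
    return counts


def _depths(adj, root) -> dict[int, int]:
    depth = {root: 0}
    stack = [root]
    while stack:
        i = stack.pop()
        for j in adj[i]:
            if j not in depth:
                depth[j] = depth[i] + 1
                stack.append(j)
    return depth


# ---------------------------------------------------------------------------
# rendering and CSV round trip
# ---------------------------------------------------------------------------

_CLASS_COLORS = {
    "virtual": "#b0b0b0",       # grey
    "active": "#e66a0e",        # orange
    "inactive": "#2d6cb5",      # blue
    "NA": "#74b87a",            # designed, activity unknown
}


def member_class(provenance: str, activity: str) -> str:
    if provenance == "virtual":
        return "virtual"
    if activity == "+":
        return "active"
    if activity == "-":
        return "inactive"
    return "NA"


def coordinates_frame(tree: SpaceTree, members: Mapping[str, tuple[str, str]]
                      ) -> pd.DataFrame:
    """(id, x, y, provenance, activity) table; ``members`` maps molecule id
    to (provenance, activity), defaulting to virtual/NA."""
    rows = []
    for mid in tree.ids:
        x, y = tree.coordinates[mid]
        prov, act = members.get(mid, ("virtual", "NA"))
        rows.append({"id": mid, "x": x, "y": y, "provenance": prov, "activity": act})
    return pd.DataFrame(rows)


def write_coordinates_csv(tree: SpaceTree, members: Mapping[str, tuple[str, str]],
                          path) -> pd.DataFrame:
    df = coordinates_frame(tree, members)
    # default float repr is shortest-round-trip: reload gives identical values
    df.to_csv(path, index=False)
    return df


def write_edges_csv(tree: SpaceTree, path) -> None:
    pd.DataFrame(tree.edges, columns=["id_u", "id_v", "distance"]).to_csv(
        path, index=False
    )


def render_map(tree: SpaceTree, members: Mapping[str, tuple[str, str]],
               png_path=None, csv_path=None, title: str = "chemical-space tree map"):
    """Scatter/tree rendering with the virtual / active / inactive color code.

    Returns the matplotlib figure; optionally writes the PNG/SVG and the
    coordinate CSV.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import LineCollection

    df = coordinates_frame(tree, members)
    fig, ax = plt.subplots(figsize=(9, 9))
    segs = [
        (tree.coordinates[u], tree.coordinates[v]) for u, v, _ in tree.edges
    ]
    ax.add_collection(LineCollection(segs, colors="#d8d8d8", linewidths=0.6, zorder=1))
    classes = [member_class(p, a) for p, a in zip(df["provenance"], df["activity"])]
    df = df.assign(cls=classes)
    for cls in ("virtual", "NA", "inactive", "active"):
        sub = df[df["cls"] == cls]
        if sub.empty:
            continue
        ax.scatter(sub["x"], sub["y"], s=14 if cls == "virtual" else 40,
                   c=_CLASS_COLORS[cls], label=cls, zorder=2,
                   edgecolors="none" if cls == "virtual" else "black",
                   linewidths=0.4)
    ax.legend(loc="upper right", frameon=False)
    ax.set_title(title)
    ax.set_aspect("equal")
    ax.axis("off")
    if csv_path is not None:
        write_coordinates_csv(tree, members, csv_path)
    if png_path is not None:
        fig.savefig(png_path, dpi=150, bbox_inches="tight")
    return fig
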
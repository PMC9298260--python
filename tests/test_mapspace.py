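"""Fingerprint shingling, MinHash estimation and the kNN/MST tree layout."""

import itertools

import numpy as np
import pytest
from rdkit import Chem

from dendrimap.errors import ConfigError, EmptySketchError, StructureError
from dendrimap.mapspace import (
    FingerprintSketch,
    ShingleSet,
    build_space_tree,
    estimate_jaccard,
    member_class,
    minhash,
    minhash_many,
    render_map,
    shingle,
    shingle_mol,
    write_coordinates_csv,
)


def _random_sketches(n, rng, d=64):
    """Sketches of random shingle sets over a small string universe."""
    universe = [f"shingle-{i}" for i in range(60)]
    sets = [
        ShingleSet(f"m{i:02d}", frozenset(rng.choice(universe, 25, replace=False)))
        for i in range(n)
    ]
    return minhash_many(sets, d=d, seed=7)


class TestShingling:
    def test_ethane_single_pair_shingle(self):
        s = shingle("CC")
        assert s.shingles == frozenset({"CC|1|CC"})

    def test_methane_is_degenerate(self):
        assert len(shingle("C")) == 0

    def test_renumbering_invariance(self):
        mol = Chem.MolFromSmiles("CCO[C@@H](N)CC(=O)O")
        renumbered = Chem.RenumberAtoms(mol, list(range(mol.GetNumAtoms()))[::-1])
        assert shingle_mol(mol).shingles == shingle_mol(renumbered).shingles

    def test_unparseable_smiles(self):
        with pytest.raises(StructureError):
            shingle("not-a-molecule(((")

    def test_shingle_format(self):
        for sh in shingle("CCO").shingles:
            a, d, b = sh.split("|")
            assert a <= b and int(d) >= 1


class TestMinHash:
    def test_identical_sets_estimate_one(self):
        s = ShingleSet("x", frozenset({"a", "b", "c"}))
        t = ShingleSet("y", frozenset({"a", "b", "c"}))
        a, b = minhash_many([s, t], d=64, seed=1)
        assert estimate_jaccard(a, b) == 1.0

    def test_disjoint_sets_estimate_near_zero(self):
        d = 1024
        s = ShingleSet("x", frozenset(f"a{i}" for i in range(100)))
        t = ShingleSet("y", frozenset(f"b{i}" for i in range(100)))
        a, b = minhash_many([s, t], d=d, seed=2)
        assert estimate_jaccard(a, b) <= 3 / np.sqrt(d)

    def test_deterministic_for_same_inputs(self):
        s = ShingleSet("x", frozenset({"p", "q", "r", "s"}))
        a = minhash(s, d=32, seed=5)
        b = minhash(s, d=32, seed=5)
        np.testing.assert_array_equal(a.minima, b.minima)
        c = minhash(s, d=32, seed=6)
        assert not np.array_equal(a.minima, c.minima)

    def test_empty_set_raises(self):
        with pytest.raises(EmptySketchError):
            minhash(ShingleSet("x", frozenset()), d=64)

    def test_dimension_floor(self):
        with pytest.raises(ConfigError):
            minhash(ShingleSet("x", frozenset({"a"})), d=8)

    def test_mixed_hash_families_rejected(self):
        s = ShingleSet("x", frozenset({"a"}))
        with pytest.raises(ConfigError):
            estimate_jaccard(minhash(s, d=32, seed=0), minhash(s, d=32, seed=1))


class TestSpaceTree:
    def test_tree_has_n_minus_one_edges(self):
        rng = np.random.default_rng(0)
        sketches = _random_sketches(12, rng)
        tree = build_space_tree(sketches, k=11)
        assert len(tree.edges) == 11
        assert set(tree.ids) == {s.molecule_id for s in sketches}

    def test_duplicate_molecule_joined_at_zero_distance(self):
        rng = np.random.default_rng(1)
        sketches = _random_sketches(6, rng)
        dup = FingerprintSketch("m00-copy", sketches[0].minima.copy(),
                                sketches[0].dimensions, sketches[0].seed)
        tree = build_space_tree(sketches + [dup], k=6)
        zero_edges = [e for e in tree.edges if e[2] == 0.0]
        assert any({"m00", "m00-copy"} == {u, v} for u, v, _ in zero_edges)

    def test_all_identical_sketches_star_tree(self):
        base = minhash(ShingleSet("a", frozenset({"x", "y"})), d=32, seed=0)
        sketches = [
            FingerprintSketch(f"mol{i}", base.minima.copy(), 32, 0) for i in range(5)
        ]
        tree = build_space_tree(sketches, k=2)
        assert len(tree.edges) == 4
        assert all(w == 0.0 for _, _, w in tree.edges)

    def test_mst_matches_exhaustive_minimum(self):
        """Kruskal weight equals brute force over all spanning trees (k=n-1)."""
        rng = np.random.default_rng(3)
        for n in (4, 5, 6):
            sketches = _random_sketches(n, rng)
            tree = build_space_tree(sketches, k=n - 1)
            got = sum(w for _, _, w in tree.edges)
            mat = np.stack([s.minima for s in sketches])
            dist = {
                (i, j): 1.0 - float((mat[i] == mat[j]).mean())
                for i in range(n) for j in range(i + 1, n)
            }
            best = min(
                sum(dist[e] for e in combo)
                for combo in itertools.combinations(dist, n - 1)
                if _spans(combo, n)
            )
            assert got == pytest.approx(best, abs=1e-12)

    def test_layout_deterministic(self, tmp_path):
        rng = np.random.default_rng(4)
        sketches = _random_sketches(15, rng)
        t1 = build_space_tree(sketches, k=4)
        t2 = build_space_tree(sketches, k=4)
        p1, p2 = tmp_path / "c1.csv", tmp_path / "c2.csv"
        write_coordinates_csv(t1, {}, p1)
        write_coordinates_csv(t2, {}, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_coordinate_csv_round_trip(self, tmp_path):
        import pandas as pd

        rng = np.random.default_rng(5)
        tree = build_space_tree(_random_sketches(8, rng), k=3)
        path = tmp_path / "coords.csv"
        df = write_coordinates_csv(tree, {}, path)
        loaded = pd.read_csv(path)
        for mid, x, y in zip(loaded["id"], loaded["x"], loaded["y"]):
            assert tree.coordinates[mid] == (x, y)
        assert list(loaded.columns) == ["id", "x", "y", "provenance", "activity"]


def _spans(edges, n):
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    count = n
    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
            count -= 1
    return count == 1


class TestRendering:
    def test_color_classes(self):
        assert member_class("virtual", "+") == "virtual"
        assert member_class("designed", "+") == "active"
        assert member_class("designed", "-") == "inactive"
        assert member_class("designed", "NA") == "NA"

    def test_render_writes_outputs(self, tmp_path):
        import matplotlib

        matplotlib.use("Agg")
        rng = np.random.default_rng(6)
        tree = build_space_tree(_random_sketches(10, rng), k=3)
        meta = {"m00": ("designed", "+"), "m01": ("designed", "-")}
        png, csv = tmp_path / "map.png", tmp_path / "coords.csv"
        fig = render_map(tree, meta, png_path=png, csv_path=csv)
        assert png.exists() and csv.exists()
        import matplotlib.pyplot as plt

        plt.close(fig)
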
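import itertools

import numpy as np
import pytest

from barcode_eval.distances import DistanceMatrix, distance_matrix
from barcode_eval.errors import InputError, TreeError
from barcode_eval.io import AlignedMatrix
from barcode_eval.trees import (Tree, bootstrap_supports, exclude_undefined,
                                nj_tree, parse_newick, read_tree)
from barcode_eval.trees import test_monophyly as species_monophyly

from conftest import (make_dataset, quartet_ls_error, quartet_splits,
                      random_additive_tree)


def dm_from(values, ids, model="p"):
    return DistanceMatrix(ids, model, np.asarray(values, float))


def oracle_bipartitions(tree: Tree):
    """Independent edge-removal enumeration over the raw edge list."""
    adj = {}
    for u, v, _w in tree.edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    sides = []
    for u, v, _w in tree.edges:
        comp, stack = {v}, [v]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if y != u and y not in comp:
                    comp.add(y)
                    stack.append(y)
        sides.append(frozenset(tree.leaf_labels[n] for n in comp
                               if n in tree.leaf_labels))
    return sides


class TestNJ:
    def test_three_taxon_branch_lengths(self):
        t = nj_tree(dm_from([[0, 2, 3], [2, 0, 4], [3, 4, 0]],
                            ["A", "B", "C"]))
        pl = t.path_length_matrix(["A", "B", "C"])
        assert np.allclose(pl, [[0, 2, 3], [2, 0, 4], [3, 4, 0]])
        # star branches solve the three pairwise-sum equations
        assert t.to_newick(include_supports=False) == \
            "(A:0.5,B:1.5,C:2.5);"

    def test_four_taxon_additive_split_and_paths(self):
        # generating tree ((A:1,B:2):1,(C:3,D:4))
        D = np.array([[0, 3, 5, 6],
                      [3, 0, 6, 7],
                      [5, 6, 0, 7],
                      [6, 7, 7, 0]], float)
        ids = ["A", "B", "C", "D"]
        t = nj_tree(dm_from(D, ids))
        assert frozenset(["C", "D"]) in t.bipartitions()
        assert np.allclose(t.path_length_matrix(ids), D, atol=1e-12)

    def test_all_zero_matrix_deterministic(self):
        ids = list("ABCDE")
        t1 = nj_tree(dm_from(np.zeros((5, 5)), ids))
        t2 = nj_tree(dm_from(np.zeros((5, 5)), ids))
        assert t1.to_newick() == t2.to_newick()
        assert all(w == 0.0 for _u, _v, w in t1.edges)

    def test_random_additive_recovery(self, rng):
        """NJ is exact on additive matrices: topology and path lengths."""
        for _ in range(10):
            n = int(rng.integers(4, 9))
            edges, labels = random_additive_tree(n, rng)
            true = Tree(edges, labels)
            ids = true.tips
            D = true.path_length_matrix(ids)
            est = nj_tree(dm_from(D, ids))
            assert est.bipartitions() == true.bipartitions()
            assert np.allclose(est.path_length_matrix(ids), D, atol=1e-9)

    def test_four_taxon_agrees_with_least_squares(self, rng):
        """Brute force over the 3 unrooted quartet topologies."""
        for _ in range(10):
            edges, labels = random_additive_tree(4, rng)
            true = Tree(edges, labels)
            ids = true.tips
            D = true.path_length_matrix(ids)
            best = min(quartet_splits(ids),
                       key=lambda split: quartet_ls_error(D, ids, split))
            est_split = next(iter(nj_tree(dm_from(D, ids)).bipartitions()))
            assert est_split in (frozenset(best[0]), frozenset(best[1]))

    def test_independent_nj_implementation_agrees(self, rng):
        """Cross-check against scikit-bio's neighbour joining on an
        additive matrix: both must reproduce the generating metric."""
        skbio = pytest.importorskip("skbio")
        edges, labels = random_additive_tree(7, rng)
        true = Tree(edges, labels)
        ids = true.tips
        D = true.path_length_matrix(ids)
        D = 0.5 * (D + D.T)   # exact symmetry for skbio's validator
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(D, ids))
        ours = nj_tree(dm_from(D, ids))
        for a, b in itertools.combinations(ids, 2):
            sk_d = sk_tree.find(a).distance(sk_tree.find(b))
            assert ours.path_length_matrix([a, b])[0, 1] == pytest.approx(
                sk_d, abs=1e-9)

    def test_undefined_pair_rejected(self):
        v = np.array([[0, np.nan], [np.nan, 0]])
        dm = DistanceMatrix(["a", "b"], "p", v, {frozenset(("a", "b"))})
        with pytest.raises(TreeError):
            nj_tree(dm)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(TreeError):
            nj_tree(dm_from(np.zeros((2, 2)), ["a", "b"]))


class TestExcludeUndefined:
    def test_drops_minimal_roster(self):
        ids = ["a", "b", "c", "d"]
        v = np.zeros((4, 4))
        v[0, 1] = v[1, 0] = np.nan
        v[0, 2] = v[2, 0] = np.nan
        dm = DistanceMatrix(ids, "k2p", v,
                            {frozenset(("a", "b")), frozenset(("a", "c"))})
        reduced, excluded = exclude_undefined(dm)
        assert excluded == ["a"]
        assert reduced.ids == ["b", "c", "d"]
        assert not reduced.undefined_pairs


class TestMonophyly:
    def two_species_tree(self, newick):
        return parse_newick(newick)

    def test_clean_split_both_monophyletic(self):
        t = parse_newick("((A1:1,A2:1):1,(B1:1,B2:1):1);")
        res = {m.species: m for m in species_monophyly(
            t, {"A1": "A", "A2": "A", "B1": "B", "B2": "B"})}
        assert res["A"].monophyletic and res["B"].monophyletic

    def test_interleaved_both_non_monophyletic(self):
        t = parse_newick("((A1:1,B1:1):1,(A2:1,B2:1):1);")
        res = {m.species: m for m in species_monophyly(
            t, {"A1": "A", "A2": "A", "B1": "B", "B2": "B"})}
        assert not res["A"].monophyletic and not res["B"].monophyletic

    def test_nested_species_paraphyly(self):
        # B nests inside A (with outgroup C anchoring the unrooted shape):
        # the nested species is monophyletic, the surrounding one is not
        t = parse_newick(
            "((A1:1,C1:1):1,(A2:1,((B1:1,B2:1):1,A3:1):1):1);")
        res = {m.species: m for m in species_monophyly(
            t, {"A1": "A", "A2": "A", "A3": "A",
                "B1": "B", "B2": "B", "C1": "C"})}
        assert res["B"].monophyletic
        assert not res["A"].monophyletic

    def test_singleton_trivially_monophyletic(self):
        t = parse_newick("((A1:1,A2:1):1,(B1:1,C1:1):1);")
        res = {m.species: m for m in species_monophyly(
            t, {"A1": "A", "A2": "A", "B1": "B", "C1": "C"})}
        assert res["B"].monophyletic and res["B"].support is None
        assert res["B"].n_tips == 1

    def test_unmapped_tip_rejected(self):
        t = parse_newick("((A1:1,A2:1):1,(B1:1,B2:1):1);")
        with pytest.raises(InputError, match="B2"):
            species_monophyly(t, {"A1": "A", "A2": "A", "B1": "B"})

    def test_agrees_with_edge_enumeration_oracle(self, rng):
        """Exhaustive try-every-edge oracle on random trees <= 12 tips."""
        for _ in range(30):
            n = int(rng.integers(4, 13))
            edges, labels = random_additive_tree(n, rng)
            tree = Tree(edges, labels)
            tips = tree.tips
            species = {t: f"sp{rng.integers(0, 4)}" for t in tips}
            sides = oracle_bipartitions(tree)
            results = species_monophyly(tree, species)
            for res in results:
                members = {t for t in tips if species[t] == res.species}
                expected = (len(members) == 1 or
                            any(s == members or
                                set(tips) - s == members for s in sides))
                assert res.monophyletic == expected, (species, res)


class TestBootstrap:
    def clusters_dataset(self):
        # two 4-specimen clusters differing at 50 of 100 sites
        a = "A" * 100
        b = "G" * 25 + "C" * 25 + "A" * 50
        rows = [(f"a{i}", a) for i in range(4)] + \
               [(f"b{i}", b) for i in range(4)]
        species = {f"a{i}": "A sp" for i in range(4)}
        species.update({f"b{i}": "B sp" for i in range(4)})
        return make_dataset("toy", rows, species)

    def test_clean_split_support_100(self):
        ds = self.clusters_dataset()
        tree = bootstrap_supports(ds, model="p", n_reps=50, seed=11)
        central = frozenset(f"b{i}" for i in range(4))
        assert tree.supports[tree.canonical(central)] == 100.0

    def test_zero_reps_rejected(self):
        with pytest.raises(InputError):
            bootstrap_supports(self.clusters_dataset(), n_reps=0, seed=1)

    def test_same_seed_identical_output(self):
        ds = self.clusters_dataset()
        t1 = bootstrap_supports(ds, model="p", n_reps=30, seed=7)
        t2 = bootstrap_supports(ds, model="p", n_reps=30, seed=7)
        assert t1.to_newick() == t2.to_newick()
        assert t1.supports == t2.supports

    def test_supports_within_range_and_monotone(self, rng):
        """Support of the central split grows with between-cluster signal."""
        supports = []
        for n_diff in (2, 10, 40):
            a = "A" * 100
            b = "G" * n_diff + "A" * (100 - n_diff)
            rows = [(f"a{i}", a) for i in range(3)] + \
                   [(f"b{i}", b) for i in range(3)]
            species = {sid: sid[0] for sid, _ in rows}
            ds = make_dataset("toy", rows, species)
            tree = bootstrap_supports(ds, model="p", n_reps=100, seed=3)
            central = tree.canonical(frozenset(f"b{i}" for i in range(3)))
            supports.append(tree.supports.get(central, 0.0))
        assert all(0.0 <= s <= 100.0 for s in supports)
        assert supports == sorted(supports)


class TestNewickIO:
    def test_parse_supports(self):
        t = parse_newick("((A:1,B:1)90:1,(C:1,D:1)85:1);")
        assert t.n_tips == 4
        # in a 4-tip unrooted tree AB|CD is a single bipartition, so the
        # two printed labels name the same edge
        ab = t.canonical(frozenset(("A", "B")))
        assert len(t.supports) == 1
        assert t.supports[ab] in (90.0, 85.0)

    def test_roundtrip_topology_lengths_supports(self, tmp_path):
        text = "((A:1,B:2)90:1.5,(C:3,D:4)85:0.5,E:2);"
        t = parse_newick(text)
        p = tmp_path / "t.nwk"
        t.write(p)
        back = read_tree(p)
        assert back.bipartitions() == t.bipartitions()
        ids = t.tips
        assert np.allclose(back.path_length_matrix(ids),
                           t.path_length_matrix(ids))
        assert back.supports == t.supports

    def test_tip_mismatch_rejected(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A:1,B:1):1,(C:1,D:1):1);\n")
        with pytest.raises(InputError, match="mismatch"):
            read_tree(p, expected_tips=["A", "B", "C", "E"])
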
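import numpy as np
import pytest

from barcode_eval.distances import distance_matrix, p_distance
from barcode_eval.errors import InputError
from barcode_eval.io import AlignedMatrix, bind_dataset
from barcode_eval.multilocus import (concatenate, evaluate_combination,
                                     evaluate_combinations, shared_specimens)

from conftest import make_dataset, make_records


def toy_datasets():
    """Two loci with overlapping specimen rosters."""
    species = {"a1": "A sp", "a2": "A sp", "b1": "B sp", "b2": "B sp",
               "c1": "C sp"}
    x = [("a1", "AAAA"), ("a2", "AAAT"), ("b1", "GGGG"), ("c1", "TTTT")]
    y = [("a2", "CCCCCC"), ("b1", "GGGGGG"), ("b2", "GGGGGT"),
         ("c1", "AAAAAA")]
    return {"locX": make_dataset("locX", x, species),
            "locY": make_dataset("locY", y, species)}


class TestSharedSpecimens:
    def test_intersection(self):
        ds = toy_datasets()
        assert shared_specimens(ds, ["locX", "locY"]) == {"a2", "b1", "c1"}

    def test_unknown_locus(self):
        with pytest.raises(InputError, match="locZ"):
            shared_specimens(toy_datasets(), ["locX", "locZ"])

    def test_single_locus_rejected(self):
        with pytest.raises(InputError):
            shared_specimens(toy_datasets(), ["locX"])


class TestConcatenate:
    def test_length_additivity_and_partition(self):
        ds = toy_datasets()
        concat, partition = concatenate(ds, ["locY", "locX"], {"a2", "b1", "c1"})
        assert concat.length == 4 + 6
        # canonical sorted locus order regardless of the requested order
        assert partition == {"locX": (0, 4), "locY": (4, 10)}

    def test_partition_roundtrip_recovers_loci(self):
        ds = toy_datasets()
        shared = {"a2", "b1", "c1"}
        concat, partition = concatenate(ds, ["locX", "locY"], shared)
        for locus, (lo, hi) in partition.items():
            original = ds[locus].matrix.subset(sorted(shared))
            sliced = concat.trim(lo, hi)
            assert sliced.sequences == original.sequences
            assert sliced.ids == original.ids

    def test_missing_specimen_rejected(self):
        with pytest.raises(InputError, match="a1"):
            concatenate(toy_datasets(), ["locX", "locY"], {"a1", "b1"})

    def test_single_specimen_rejected(self):
        with pytest.raises(InputError):
            concatenate(toy_datasets(), ["locX", "locY"], {"b1"})

    def test_self_concatenation_preserves_p_distance(self):
        species = {"a1": "A", "b1": "B", "c1": "C"}
        rows = [("a1", "AAGGCCTT"), ("b1", "AAGGCCTA"), ("c1", "ATGGCTTT")]
        d1 = make_dataset("L1", rows, species)
        d2 = make_dataset("L2", rows, species)
        concat, _ = concatenate({"L1": d1, "L2": d2}, ["L1", "L2"],
                                {"a1", "b1", "c1"})
        for i, (ia, sa) in enumerate(rows):
            for ib, sb in rows[i + 1:]:
                assert p_distance(concat.row(ia), concat.row(ib)) == \
                    pytest.approx(p_distance(sa, sb))

    def test_identical_specimens_stay_at_zero(self):
        species = {"a1": "A", "a2": "A", "b1": "B"}
        rows = [("a1", "ACGT"), ("a2", "ACGT"), ("b1", "AGGT")]
        d1 = make_dataset("L1", rows, species)
        d2 = make_dataset("L2", rows, species)
        concat, _ = concatenate({"L1": d1, "L2": d2}, ["L1", "L2"],
                                {"a1", "a2", "b1"})
        assert p_distance(concat.row("a1"), concat.row("a2")) == 0.0


class TestEvaluateCombinations:
    def test_six_loci_arity_two_enumerates_fifteen(self):
        species = {f"s{i}": f"sp{i % 2}" for i in range(4)}
        rows = [(f"s{i}", "ACGTACGT" if i % 2 else "ACGAACGA")
                for i in range(4)]
        datasets = {f"L{k}": make_dataset(f"L{k}", rows, species)
                    for k in range(6)}
        results = evaluate_combinations(datasets, {2}, n_reps=0, seed=1)
        assert len(results) == 15

    def test_disjoint_loci_skipped(self):
        species = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        d1 = make_dataset("L1", [("a1", "ACGT"), ("a2", "ACGT")], species)
        d2 = make_dataset("L2", [("b1", "ACGT"), ("b2", "ACGT")], species)
        assert evaluate_combination({"L1": d1, "L2": d2},
                                    ("L1", "L2")) is None

    def test_single_species_combination_skipped(self):
        species = {"a1": "A", "a2": "A", "a3": "A"}
        rows = [("a1", "ACGT"), ("a2", "ACGT"), ("a3", "ACGT")]
        datasets = {"L1": make_dataset("L1", rows, species),
                    "L2": make_dataset("L2", rows, species)}
        assert evaluate_combination(datasets, ("L1", "L2")) is None

    def test_complementary_loci_resolve_all_species(self):
        """One locus separates species 1-2, the other species 3-4; the
        concatenation recovers all four as monophyletic."""
        base = "A" * 24
        def variant(positions):
            s = list(base)
            for p in positions:
                s[p] = "G"
            return "".join(s)
        species = {}
        rows_a, rows_b = [], []
        for k, sp in enumerate(["sp1", "sp2", "sp3", "sp4"]):
            for j in (1, 2):
                sid = f"{sp}_{j}"
                species[sid] = sp
                if sp in ("sp1", "sp2"):
                    rows_a.append((sid, variant(range(6 * k, 6 * k + 6))))
                    rows_b.append((sid, base))
                else:
                    rows_a.append((sid, base))
                    rows_b.append((sid, variant(range(6 * (k - 2),
                                                      6 * (k - 2) + 6))))
        datasets = {"locA": make_dataset("locA", rows_a, species),
                    "locB": make_dataset("locB", rows_b, species)}
        res = evaluate_combination(datasets, ("locA", "locB"), model="p",
                                   n_reps=0)
        mono = {m.species: m.monophyletic for m in res.monophyly}
        assert mono == {"sp1": True, "sp2": True, "sp3": True, "sp4": True}

    def test_results_independent_of_locus_input_order(self):
        ds = toy_datasets()
        r1 = evaluate_combinations(ds, {2}, n_reps=0, seed=3)
        ds_rev = dict(reversed(list(ds.items())))
        r2 = evaluate_combinations(ds_rev, {2}, n_reps=0, seed=3)
        assert [(r.loci, r.shared_specimens) for r in r1] == \
            [(r.loci, r.shared_specimens) for r in r2]
        assert [r.gap_rows for r in r1] == [r.gap_rows for r in r2]

    def test_constant_second_locus_preserves_monophyly(self):
        species = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        informative = [("a1", "AAAAAAAA"), ("a2", "AAAAAAAT"),
                       ("b1", "GGGGGGGG"), ("b2", "GGGGGGGT")]
        constant = [(sid, "CCCCCCCC") for sid, _ in informative]
        datasets = {"L1": make_dataset("L1", informative, species),
                    "L2": make_dataset("L2", constant, species)}
        solo = evaluate_combination(
            {"L1": datasets["L1"], "L2": datasets["L1"]}, ("L1", "L2"),
            model="p", n_reps=0)
        combo = evaluate_combination(datasets, ("L1", "L2"), model="p",
                                     n_reps=0)
        solo_mono = {m.species for m in solo.monophyly if m.monophyletic}
        combo_mono = {m.species for m in combo.monophyly if m.monophyletic}
        assert solo_mono <= combo_mono

    def test_unsupported_arity_rejected(self):
        with pytest.raises(InputError):
            evaluate_combinations(toy_datasets(), {7})
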
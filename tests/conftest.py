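import numpy as np
import pytest

from barcode_eval.io import AlignedMatrix, SpecimenRecord, bind_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20170411)


def make_records(species_of: dict[str, str], status: str = "native"):
    return [SpecimenRecord(sid, sp, status) for sid, sp in species_of.items()]


def make_dataset(locus: str, rows: list[tuple[str, str]],
                 species_of: dict[str, str]):
    matrix = AlignedMatrix(locus, rows)
    return bind_dataset(matrix, make_records(species_of))


@pytest.fixture
def two_species_dataset():
    """Two species x two specimens with an unambiguous split."""
    rows = [
        ("a1", "AAAAAAAAAACCCCC"),
        ("a2", "AAAAAAAAAACCCCT"),
        ("b1", "GGGGGGGGGGCCCCC"),
        ("b2", "GGGGGGGGGGCCCCT"),
    ]
    species_of = {"a1": "Species alpha", "a2": "Species alpha",
                  "b1": "Species beta", "b2": "Species beta"}
    return make_dataset("toy", rows, species_of)


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """Random unrooted binary tree topology with positive branch lengths.

    Returns (edges, leaf_labels) in the same representation trees.Tree
    uses.  Built by sequential leaf attachment to a random edge.
    """
    labels = {i: f"t{i}" for i in range(n_taxa)}
    # start from a 3-leaf star around internal node n_taxa
    next_node = n_taxa
    edges = [[next_node, 0, _blen(rng)], [next_node, 1, _blen(rng)],
             [next_node, 2, _blen(rng)]]
    next_node += 1
    for leaf in range(3, n_taxa):
        k = rng.integers(0, len(edges))
        u, v, w = edges.pop(int(k))
        mid = next_node
        next_node += 1
        split = w * float(rng.uniform(0.25, 0.75))
        edges.append([u, mid, split])
        edges.append([mid, v, w - split])
        edges.append([mid, leaf, _blen(rng)])
    return [(u, v, w) for u, v, w in edges], labels


def _blen(rng) -> float:
    return float(rng.uniform(0.5, 3.0))


def quartet_splits(ids):
    """The three unrooted topologies over four taxa."""
    a, b, c, d = ids
    return [((a, b), (c, d)), ((a, c), (b, d)), ((a, d), (b, c))]


def quartet_ls_error(D, ids, split):
    """Least-squares fit error of a quartet topology to a metric."""
    import itertools
    (p, q), (r, s) = split
    idx = {t: i for i, t in enumerate(ids)}
    pairs = list(itertools.combinations(ids, 2))
    A = np.zeros((6, 5))
    y = np.zeros(6)
    cols = {p: 0, q: 1, r: 2, s: 3}
    for row, (x, z) in enumerate(pairs):
        A[row, cols[x]] = 1
        A[row, cols[z]] = 1
        if {x, z} not in ({p, q}, {r, s}):
            A[row, 4] = 1
        y[row] = D[idx[x], idx[z]]
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(np.sum((A @ coef - y) ** 2))
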
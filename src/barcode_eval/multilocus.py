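"""Multilocus combination analyses.

Combinations of loci are evaluated on the specimens sequenced at *every*
member locus (shared-specimen intersection, not a missing-as-gaps
supermatrix).  For each viable subset the per-locus alignments are
concatenated in canonical (sorted) locus order, and the usual single-locus
machinery — distance matrix, NJ + bootstrap, monophyly, gap summary — is
rerun on the supermatrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .errors import InputError
from .gap import GapSummaryRow, species_gap_summary
from .io import AlignedMatrix, LocusDataset
from .distances import distance_matrix
from .trees import (MonophylyResult, bootstrap_supports, exclude_undefined,
                    nj_tree, test_monophyly)

logger = logging.getLogger(__name__)

ARITY_NAMES = {2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}

# Minimum viability for a combination analysis: below this the NJ tree or
# the gap summary is degenerate.  Configurable via evaluate_combinations.
MIN_SHARED_SPECIMENS = 3
MIN_SPECIES = 2


def shared_specimens(datasets: dict[str, LocusDataset],
                     loci: list[str] | tuple[str, ...]) -> set[str]:
    """Specimens sequenced at every named locus."""
    if len(loci) < 2:
        raise InputError("a combination needs >= 2 loci")
    unknown = [l for l in loci if l not in datasets]
    if unknown:
        raise InputError(f"unknown loci: {unknown}")
    shared = set(datasets[loci[0]].matrix.ids)
    for locus in loci[1:]:
        shared &= set(datasets[locus].matrix.ids)
    return shared


def concatenate(datasets: dict[str, LocusDataset],
                loci: list[str] | tuple[str, ...],
                specimens: set[str] | list[str]) -> tuple[AlignedMatrix,
                                                          dict[str, tuple[int, int]]]:
    """Column-wise join over a common specimen set.

    Loci are joined in canonical sorted order; the returned partition map
    gives each locus's half-open column range in the supermatrix.  Every
    requested specimen must be present at every locus (pre-intersect with
    :func:`shared_specimens`).
    """
    loci = sorted(loci)
    ids = sorted(specimens)
    if len(ids) < 2:
        raise InputError("concatenation needs >= 2 specimens")
    for locus in loci:
        missing = [s for s in ids if s not in set(datasets[locus].matrix.ids)]
        if missing:
            raise InputError(f"specimens missing at locus {locus!r}: {missing}")
    parts = {sid: [] for sid in ids}
    partition: dict[str, tuple[int, int]] = {}
    offset = 0
    for locus in loci:
        matrix = datasets[locus].matrix
        for sid in ids:
            parts[sid].append(matrix.row(sid))
        partition[locus] = (offset, offset + matrix.length)
        offset += matrix.length
    name = "+".join(loci)
    concat = AlignedMatrix(name, [(sid, "".join(parts[sid])) for sid in ids])
    return concat, partition


@dataclass
class CombinationResult:
    """Outcome of one locus-combination analysis."""

    loci: tuple[str, ...]
    arity: str
    shared_specimens: int
    monophyly: list[MonophylyResult] = field(default_factory=list)
    gap_rows: list[GapSummaryRow] = field(default_factory=list)

    @property
    def monophyletic_species(self) -> list[tuple[str, float | None]]:
        """(species, support) for species found monophyletic with >= 2 tips."""
        return [(m.species, m.support) for m in self.monophyly
                if m.monophyletic and m.n_tips >= 2]


def evaluate_combination(datasets: dict[str, LocusDataset],
                         loci: tuple[str, ...], model: str = "k2p",
                         n_reps: int = 100,
                         rng: np.random.Generator | None = None,
                         min_specimens: int = MIN_SHARED_SPECIMENS,
                         min_species: int = MIN_SPECIES) -> CombinationResult | None:
    """Run the full single-locus analysis suite on one concatenation.

    Returns None (with a logged reason) when the subset is not viable:
    too few shared specimens or too few species among them.
    """
    shared = shared_specimens(datasets, list(loci))
    label = "+".join(sorted(loci))
    if len(shared) < min_specimens:
        logger.info("skipping %s: %d shared specimens < %d",
                    label, len(shared), min_specimens)
        return None
    species_map = {sid: datasets[loci[0]].species_map[sid] for sid in shared}
    n_species = len(set(species_map.values()))
    if n_species < min_species:
        logger.info("skipping %s: %d species < %d", label, n_species, min_species)
        return None
    concat, _partition = concatenate(datasets, loci, shared)
    dataset = LocusDataset(concat, species_map,
                           frozenset(sp for sp in set(species_map.values())
                                     if sum(1 for v in species_map.values()
                                            if v == sp) == 1))
    dm = distance_matrix(dataset, model)
    result = CombinationResult(loci=tuple(sorted(loci)),
                               arity=ARITY_NAMES[len(loci)],
                               shared_specimens=len(shared))
    result.gap_rows = species_gap_summary(dm, species_map)
    dm_ok, _excluded = exclude_undefined(dm)
    if len(dm_ok.ids) >= 3:
        if n_reps > 0:
            tree = bootstrap_supports(dataset, model, n_reps=n_reps, rng=rng)
        else:
            tree = nj_tree(dm_ok)
        tree_species = {sid: species_map[sid] for sid in tree.tips}
        result.monophyly = test_monophyly(tree, tree_species)
    return result


def evaluate_combinations(datasets: dict[str, LocusDataset],
                          arities: set[int] = frozenset({2}),
                          model: str = "k2p", n_reps: int = 100,
                          seed: int | None = None,
                          min_specimens: int = MIN_SHARED_SPECIMENS,
                          min_species: int = MIN_SPECIES) -> list[CombinationResult]:
    """Evaluate every locus subset of the requested arities.

    Results are sorted by arity then locus names and are independent of
    the input ordering of ``datasets``.
    """
    bad = [a for a in arities if a not in ARITY_NAMES]
    if bad:
        raise InputError(f"unsupported arities {sorted(bad)}; "
                         f"supported: {sorted(ARITY_NAMES)}")
    loci_names = sorted(datasets)
    if len(loci_names) < 2:
        raise InputError("need >= 2 loci for combination analysis")
    rng = np.random.default_rng(seed)
    results = []
    for arity in sorted(arities):
        for subset in combinations(loci_names, arity):
            res = evaluate_combination(datasets, subset, model=model,
                                       n_reps=n_reps, rng=rng,
                                       min_specimens=min_specimens,
                                       min_species=min_species)
            if res is not None:
                results.append(res)
    return results
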
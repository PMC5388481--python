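"""Per-locus alignment summary statistics.

Counts variable and parsimony-informative sites and indel events, the
quantities usually tabulated when ranking candidate barcode loci.  Site
classification considers unambiguous nucleotides only: gaps and IUPAC
ambiguity codes do not contribute states.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum

from .io import AlignedMatrix


class SiteClass(Enum):
    CONSTANT = "constant"
    VARIABLE_UNINFORMATIVE = "variable_uninformative"
    PARSIMONY_INFORMATIVE = "parsimony_informative"


@dataclass(frozen=True)
class LocusStats:
    locus: str
    aligned_length: int
    variable_sites: int
    informative_sites: int
    indel_events: int
    n_sequences: int

    def __post_init__(self) -> None:
        assert 0 <= self.informative_sites <= self.variable_sites <= self.aligned_length


def site_classification(column: list[str]) -> SiteClass:
    """Classify one alignment column.

    A site is variable when ≥ 2 distinct unambiguous nucleotides occur;
    parsimony-informative when ≥ 2 of those states each occur in ≥ 2
    sequences.  An all-gap/all-ambiguous column is constant by convention.
    """
    if not column:
        raise ValueError("empty column")
    counts = Counter(c for c in (r.upper() for r in column) if c in "ACGT")
    if len(counts) < 2:
        return SiteClass.CONSTANT
    if sum(1 for n in counts.values() if n >= 2) >= 2:
        return SiteClass.PARSIMONY_INFORMATIVE
    return SiteClass.VARIABLE_UNINFORMATIVE


def _gap_runs(sequence: str) -> list[tuple[int, int]]:
    """Maximal gap runs as half-open (start, end) column ranges."""
    runs = []
    start = None
    for i, ch in enumerate(sequence):
        if ch == "-":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(sequence)))
    return runs


def count_indel_events(matrix: AlignedMatrix, per_sequence: bool = False) -> int:
    """Number of indel events in the alignment.

    Default convention: distinct maximal gap runs keyed by (start, end)
    coordinates, so the same deletion shared by several sequences counts
    once.  With ``per_sequence=True`` every run in every row counts.
    Published locus tables rarely state their convention, so both are
    offered; the coordinate-keyed count is the default.
    """
    if per_sequence:
        return sum(len(_gap_runs(seq)) for seq in matrix.sequences)
    distinct: set[tuple[int, int]] = set()
    for seq in matrix.sequences:
        distinct.update(_gap_runs(seq))
    return len(distinct)


def locus_stats(matrix: AlignedMatrix, indels_per_sequence: bool = False) -> LocusStats:
    """Column-scan summary of one locus alignment."""
    variable = informative = 0
    columns = zip(*matrix.sequences)
    for column in columns:
        cls = site_classification(list(column))
        if cls is not SiteClass.CONSTANT:
            variable += 1
        if cls is SiteClass.PARSIMONY_INFORMATIVE:
            informative += 1
    return LocusStats(
        locus=matrix.locus,
        aligned_length=matrix.length,
        variable_sites=variable,
        informative_sites=informative,
        indel_events=count_indel_events(matrix, per_sequence=indels_per_sequence),
        n_sequences=matrix.n_sequences,
    )
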
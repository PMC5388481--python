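"""Aligned FASTA and specimen-metadata input/output.

The pipeline consumes pre-aligned per-locus matrices (one sequence per
specimen, ``-`` for gaps) together with a TSV metadata table mapping each
specimen to a species and an invasive/native status.  Alignment itself
(e.g. ClustalW/MAFFT) and primer trimming are upstream concerns; a simple
column-range trim is provided as a convenience.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, InputError

VALID_STATUS = frozenset({"invasive", "native"})

# Nucleotide byte codes.  A/G (purines) share the high bit pattern 0x, C/T
# (pyrimidines) share 1x, so ``code >> 1`` identifies the chemical class and
# two unequal codes < 4 are a transition iff their ``>> 1`` values agree.
CODE_A, CODE_G, CODE_C, CODE_T = 0, 1, 2, 3
CODE_GAP = 4
CODE_AMBIG = 5

_ENCODE = np.full(256, CODE_AMBIG, dtype=np.uint8)
for _ch, _code in (("A", CODE_A), ("G", CODE_G), ("C", CODE_C), ("T", CODE_T),
                   ("-", CODE_GAP)):
    _ENCODE[ord(_ch)] = _code
_DECODE = np.array(list("AGCT-N"), dtype="U1")


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an upper-case aligned sequence as a uint8 vector."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


@dataclass(frozen=True)
class SpecimenRecord:
    """One collected specimen: unique id, binomial species, weed status."""

    specimen_id: str
    species: str
    status: str
    locus_presence: Mapping[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.specimen_id:
            raise InputError("specimen_id must be non-empty")
        if not self.species:
            raise InputError(
                f"specimen {self.specimen_id!r}: species must be non-empty")
        if self.status not in VALID_STATUS:
            raise InputError(
                f"specimen {self.specimen_id!r}: status {self.status!r} "
                f"not in {sorted(VALID_STATUS)}")


class AlignedMatrix:
    """Species-agnostic aligned sequence matrix for a single locus.

    All rows have identical length; sequences are stored upper-cased over
    the alphabet {A, C, G, T, -, N and IUPAC ambiguity codes}.  Row order
    is preserved from input.
    """

    def __init__(self, locus: str, rows: Iterable[tuple[str, str]]):
        self.locus = locus
        self.ids: list[str] = []
        self.sequences: list[str] = []
        seen: set[str] = set()
        for sid, seq in rows:
            if sid in seen:
                raise InputError(f"duplicate specimen id {sid!r} in locus "
                                 f"{locus!r}")
            seen.add(sid)
            self.ids.append(sid)
            self.sequences.append(seq.upper())
        if not self.ids:
            raise InputError(f"locus {locus!r}: alignment has no sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(
                f"locus {locus!r}: ragged alignment, row lengths {sorted(lengths)}")
        self.length = lengths.pop()
        if self.length < 1:
            raise AlignmentError(f"locus {locus!r}: zero-length alignment")
        self._codes: np.ndarray | None = None

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def codes(self) -> np.ndarray:
        """(n_sequences, length) uint8 code matrix, computed lazily."""
        if self._codes is None:
            self._codes = np.vstack([encode_sequence(s) for s in self.sequences])
        return self._codes

    def row(self, specimen_id: str) -> str:
        return self.sequences[self.ids.index(specimen_id)]

    def subset(self, specimen_ids: Iterable[str]) -> "AlignedMatrix":
        """New matrix restricted to the given specimens, in the given order."""
        index = {sid: i for i, sid in enumerate(self.ids)}
        rows = []
        for sid in specimen_ids:
            if sid not in index:
                raise InputError(
                    f"specimen {sid!r} absent from locus {self.locus!r}")
            rows.append((sid, self.sequences[index[sid]]))
        return AlignedMatrix(self.locus, rows)

    def trim(self, start: int, end: int) -> "AlignedMatrix":
        """Restrict to columns [start, end) — e.g. to drop primer reads."""
        if not (0 <= start < end <= self.length):
            raise InputError(
                f"trim range [{start}, {end}) invalid for length {self.length}")
        return AlignedMatrix(
            self.locus, [(sid, seq[start:end])
                         for sid, seq in zip(self.ids, self.sequences)])

    def __repr__(self) -> str:
        return (f"AlignedMatrix(locus={self.locus!r}, "
                f"n={self.n_sequences}, length={self.length})")


@dataclass
class LocusDataset:
    """An AlignedMatrix bound to a total specimen → species map."""

    matrix: AlignedMatrix
    species_map: dict[str, str]
    singleton_species: frozenset[str]

    @property
    def locus(self) -> str:
        return self.matrix.locus

    def species_of(self, specimen_id: str) -> str:
        return self.species_map[specimen_id]

    def species_groups(self) -> dict[str, list[str]]:
        """Species → specimen ids, preserving matrix row order."""
        groups: dict[str, list[str]] = {}
        for sid in self.matrix.ids:
            groups.setdefault(self.species_map[sid], []).append(sid)
        return groups


def read_alignment(path: str | Path, locus: str) -> AlignedMatrix:
    """Read an aligned FASTA file into a validated matrix.

    Record order is preserved; sequences are upper-cased.  Ragged rows
    raise :class:`AlignmentError`; an empty file or duplicated ids raise
    :class:`InputError`.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"alignment file not found: {path}")
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return AlignedMatrix(locus, records)


def write_alignment(matrix: AlignedMatrix, path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=sid, description="")
               for sid, seq in zip(matrix.ids, matrix.sequences)]
    SeqIO.write(records, str(Path(path)), "fasta")


def read_metadata(path: str | Path) -> list[SpecimenRecord]:
    """Read the specimen metadata TSV.

    Mandatory columns: ``specimen_id``, ``species``, ``status``.  Optional
    per-locus presence columns named ``locus:<name>`` hold 0/1 flags; any
    other extra column is ignored.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"metadata file not found: {path}")
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"specimen_id", "species", "status"} - set(table.columns)
    if missing:
        raise InputError(f"metadata missing mandatory columns: {sorted(missing)}")
    locus_cols = [c for c in table.columns if c.startswith("locus:")]
    records: list[SpecimenRecord] = []
    seen: set[str] = set()
    for row_no, row in enumerate(table.to_dict("records"), start=2):
        sid = row["specimen_id"]
        if sid in seen:
            raise InputError(f"metadata line {row_no}: duplicate specimen_id {sid!r}")
        seen.add(sid)
        status = row["status"]
        if status not in VALID_STATUS:
            raise InputError(
                f"metadata line {row_no} (specimen {sid!r}): "
                f"status {status!r} not in {sorted(VALID_STATUS)}")
        presence = {c[len("locus:"):]: str(row[c]) in ("1", "True", "true")
                    for c in locus_cols}
        records.append(SpecimenRecord(sid, row["species"], status, presence))
    return records


def write_metadata(records: Iterable[SpecimenRecord], path: str | Path) -> None:
    records = list(records)
    loci = sorted({l for r in records for l in r.locus_presence})
    rows = []
    for r in records:
        row = {"specimen_id": r.specimen_id, "species": r.species,
               "status": r.status}
        for l in loci:
            row[f"locus:{l}"] = int(bool(r.locus_presence.get(l, False)))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def bind_dataset(matrix: AlignedMatrix,
                 records: Iterable[SpecimenRecord]) -> LocusDataset:
    """Attach species annotations to an alignment.

    Every matrix row must map to a known specimen; species represented by
    a single sequenced specimen are flagged as singletons (their maximum
    intraspecific distance is undefined downstream).
    """
    by_id = {r.specimen_id: r for r in records}
    unmapped = [sid for sid in matrix.ids if sid not in by_id]
    if unmapped:
        raise InputError(
            f"locus {matrix.locus!r}: specimens missing from metadata: {unmapped}")
    species_map = {sid: by_id[sid].species for sid in matrix.ids}
    counts: dict[str, int] = {}
    for sp in species_map.values():
        counts[sp] = counts.get(sp, 0) + 1
    singletons = frozenset(sp for sp, n in counts.items() if n == 1)
    return LocusDataset(matrix, species_map, singletons)
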
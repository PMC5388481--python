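"""Pairwise genetic distances: uncorrected p and Kimura 2-parameter.

Distances use pairwise deletion: a site contributes to a pair only when
both residues are unambiguous nucleotides (A/C/G/T).  The K2P model
corrects the observed transition proportion P and transversion proportion
Q for multiple hits,

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q),

and is undefined (saturation) when either logarithm argument is
non-positive.  Undefined pairs are recorded, never silently dropped.
Distances are stored as proportions; reports render them as percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import InputError, UndefinedDistanceError
from .io import AlignedMatrix, LocusDataset, encode_sequence

MODELS = ("p", "k2p")


def _pair_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """(comparable sites, transitions, transversions) for two code vectors."""
    if a.shape != b.shape:
        raise InputError("sequences have unequal aligned lengths")
    comparable = (a < 4) & (b < 4)
    diff = comparable & (a != b)
    # codes: A=0, G=1, C=2, T=3 — equal high bit means same chemical class
    transitions = diff & ((a >> 1) == (b >> 1))
    return int(comparable.sum()), int(transitions.sum()), int(diff.sum() - transitions.sum())


def p_distance(a: str, b: str) -> float:
    """Proportion of mismatches over comparable (both A/C/G/T) sites."""
    n, ts, tv = _pair_counts(encode_sequence(a.upper()), encode_sequence(b.upper()))
    if n == 0:
        raise UndefinedDistanceError("no comparable sites after pairwise deletion")
    return (ts + tv) / n


def k2p_from_proportions(P: float, Q: float) -> float:
    """Evaluate the K2P correction at transition/transversion proportions."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise UndefinedDistanceError(
            f"K2P saturation: 1-2P-Q={w1:.4f}, 1-2Q={w2:.4f}")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2p_distance(a: str, b: str) -> float:
    """Kimura 2-parameter distance between two aligned sequences."""
    n, ts, tv = _pair_counts(encode_sequence(a.upper()), encode_sequence(b.upper()))
    if n == 0:
        raise UndefinedDistanceError("no comparable sites after pairwise deletion")
    return k2p_from_proportions(ts / n, tv / n)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with undefined pairs tracked.

    ``values[i, j]`` is NaN exactly for the pairs in ``undefined_pairs``;
    the diagonal is zero and symmetry is exact by construction.
    """

    ids: list[str]
    model: str
    values: np.ndarray
    undefined_pairs: set[frozenset[str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise InputError(f"unknown distance model {self.model!r}")
        self._index = {sid: i for i, sid in enumerate(self.ids)}

    def get(self, a: str, b: str) -> float:
        """Distance between two specimens; NaN when undefined."""
        return float(self.values[self._index[a], self._index[b]])

    def is_defined(self, a: str, b: str) -> bool:
        return frozenset((a, b)) not in self.undefined_pairs

    def submatrix(self, ids: Iterable[str]) -> "DistanceMatrix":
        ids = list(ids)
        idx = [self._index[i] for i in ids]
        sub = self.values[np.ix_(idx, idx)]
        kept = set(ids)
        undef = {p for p in self.undefined_pairs if p <= kept}
        return DistanceMatrix(ids, self.model, sub, undef)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_long(self) -> pd.DataFrame:
        """Long-format table (id_a, id_b, model, distance), upper triangle."""
        rows = []
        for i, a in enumerate(self.ids):
            for j in range(i + 1, len(self.ids)):
                rows.append({"id_a": a, "id_b": self.ids[j],
                             "model": self.model,
                             "distance": self.values[i, j]})
        return pd.DataFrame(rows, columns=["id_a", "id_b", "model", "distance"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="specimen_id")


def counts_matrix(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised all-pairs (comparable, transition, transversion) counts.

    ``codes`` is the (n, L) uint8 matrix of an alignment.  Returns three
    (n, n) integer arrays.  Memory is O(n²·L) transiently; fine for the
    matrix sizes barcode studies use (tens to low hundreds of specimens).
    """
    ok = codes < 4
    a = codes[:, None, :]
    b = codes[None, :, :]
    comparable = ok[:, None, :] & ok[None, :, :]
    diff = comparable & (a != b)
    transitions = diff & ((a >> 1) == (b >> 1))
    n_comp = comparable.sum(axis=2)
    n_ts = transitions.sum(axis=2)
    n_tv = diff.sum(axis=2) - n_ts
    return n_comp, n_ts, n_tv


def distances_from_counts(n_comp: np.ndarray, n_ts: np.ndarray,
                          n_tv: np.ndarray, model: str) -> np.ndarray:
    """Elementwise distance matrix; NaN where the model is undefined."""
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(n_comp > 0, n_ts / np.maximum(n_comp, 1), np.nan)
        Q = np.where(n_comp > 0, n_tv / np.maximum(n_comp, 1), np.nan)
        if model == "p":
            d = P + Q
        else:
            w1 = 1.0 - 2.0 * P - Q
            w2 = 1.0 - 2.0 * Q
            d = np.where((w1 > 0) & (w2 > 0),
                         -0.5 * np.log(np.maximum(w1, 1e-300))
                         - 0.25 * np.log(np.maximum(w2, 1e-300)),
                         np.nan)
    np.fill_diagonal(d, 0.0)
    return d


def distance_matrix(dataset: LocusDataset | AlignedMatrix,
                    model: str = "k2p",
                    deletion: str = "pairwise") -> DistanceMatrix:
    """Full pairwise distance matrix for one locus.

    ``deletion`` is "pairwise" (default: each pair uses the sites where
    both residues are unambiguous) or "complete" (columns containing any
    gap or ambiguity anywhere are removed before all comparisons).
    Undefined pairs (no comparable sites, or K2P saturation) become NaN
    entries listed in ``undefined_pairs`` rather than raising.
    """
    matrix = dataset.matrix if isinstance(dataset, LocusDataset) else dataset
    if model not in MODELS:
        raise InputError(f"unknown distance model {model!r}")
    if deletion not in ("pairwise", "complete"):
        raise InputError(f"unknown deletion mode {deletion!r}")
    if matrix.n_sequences < 2:
        raise InputError("distance matrix needs at least 2 sequences")
    codes = matrix.codes
    if deletion == "complete":
        codes = codes[:, (codes < 4).all(axis=0)]
    n_comp, n_ts, n_tv = counts_matrix(codes)
    values = distances_from_counts(n_comp, n_ts, n_tv, model)
    # enforce exact symmetry/diagonal regardless of float evaluation order
    values = np.triu(values, 1)
    values = values + values.T
    undefined = set()
    nan_i, nan_j = np.nonzero(np.isnan(values))
    for i, j in zip(nan_i, nan_j):
        if i < j:
            undefined.add(frozenset((matrix.ids[i], matrix.ids[j])))
    return DistanceMatrix(list(matrix.ids), model, values, undefined)
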
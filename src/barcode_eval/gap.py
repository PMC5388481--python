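"""Barcode-gap analysis.

For each species the summary compares the maximum intraspecific distance
D_intra with the minimum distance to any heterospecific specimen D_NN
(nearest neighbour).  A species shows a barcode gap when D_NN strictly
exceeds D_intra; a locus shows a clear gap when the smallest D_NN over
all species exceeds the largest defined D_intra, i.e. the two clouds do
not overlap.

Distances here are percentages (proportion × 100), the scale on which
such summaries are conventionally reported; comparisons use full float
precision, rounding happens only in report writers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .distances import DistanceMatrix
from .errors import InputError


@dataclass(frozen=True)
class GapSummaryRow:
    """Per-species distance summary (distances in percent).

    ``d_intra`` is None for singleton species (a single sequenced
    specimen has no intraspecific comparison); ``gap_present`` is then
    None as well.  ``computable`` is False when every heterospecific
    distance of the species is undefined under the model.
    """

    species: str
    d_intra: float | None
    nearest_species: str | None
    d_nn: float | None
    n_specimens: int
    computable: bool = True

    @property
    def gap_present(self) -> bool | None:
        if not self.computable or self.d_intra is None:
            return None
        return self.d_nn > self.d_intra


def gap_present(row: GapSummaryRow) -> bool | None:
    """Strict-inequality gap flag; None when D_intra is unavailable."""
    return row.gap_present


def species_gap_summary(dm: DistanceMatrix,
                        species_map: Mapping[str, str]) -> list[GapSummaryRow]:
    """One GapSummaryRow per species, sorted by species name.

    D_intra is the max over defined conspecific pairs, D_NN the min over
    defined heterospecific pairs involving the species; ties on D_NN are
    broken by lexicographic nearest-species name.  Undefined distances
    are excluded from both extrema.
    """
    unmapped = [sid for sid in dm.ids if sid not in species_map]
    if unmapped:
        raise InputError(f"specimens missing from species map: {unmapped}")
    species = sorted({species_map[sid] for sid in dm.ids})
    if len(species) < 2:
        raise InputError("gap analysis needs at least 2 species")
    members = {sp: [sid for sid in dm.ids if species_map[sid] == sp]
               for sp in species}
    rows = []
    for sp in species:
        own = members[sp]
        d_intra: float | None = None
        if len(own) >= 2:
            intra = [dm.get(a, b)
                     for i, a in enumerate(own) for b in own[i + 1:]
                     if dm.is_defined(a, b)]
            if intra:
                d_intra = 100.0 * max(intra)
        d_nn = math.inf
        nearest: str | None = None
        for other in species:
            if other == sp:
                continue
            for a in own:
                for b in members[other]:
                    if not dm.is_defined(a, b):
                        continue
                    d = 100.0 * dm.get(a, b)
                    if d < d_nn or (d == d_nn and nearest is not None
                                    and other < nearest):
                        d_nn, nearest = d, other
        if nearest is None:
            rows.append(GapSummaryRow(sp, d_intra, None, None, len(own),
                                      computable=False))
        else:
            rows.append(GapSummaryRow(sp, d_intra, nearest, d_nn, len(own)))
    return rows


def locus_gap_assessment(rows: list[GapSummaryRow]) -> bool:
    """Locus-level gap: min D_NN across species > max defined D_intra."""
    usable = [r for r in rows if r.computable]
    intra = [r.d_intra for r in usable if r.d_intra is not None]
    if not intra:
        raise InputError("locus gap undefined: every species is a singleton "
                         "or incomputable")
    d_nn_min = min(r.d_nn for r in usable)
    return d_nn_min > max(intra)
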
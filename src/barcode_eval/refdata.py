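"""Bundled case-study reference values.

A published evaluation of six candidate barcode loci (atpF intron, matK,
ndhK-ndhC spacer, psbE-petL spacer, ETS and ITS) across 66 specimens of
twelve eastern Australian grass species — five invasive, seven native —
provides the reference conditions this package ships with:

* ``GAP_TABLE``: per-locus, per-species maximum intraspecific distance
  (D_intra, percent; None for singleton species) with the nearest
  neighbour species and distance (D_NN, percent).  These printed
  summaries exercise the gap logic without sequence data.
* ``PCR_SUCCESS``: per-species, per-locus PCR success rates, the dropout
  probabilities the simulator's case-study fixture uses.
* ``SPECIMEN_COUNTS`` / ``SPECIES_STATUS``: study design.
* ``LOCUS_LENGTHS``: aligned lengths (nt) of the six locus matrices.
"""

from __future__ import annotations

LOCI = ("ETS", "ITS", "atpF", "matK", "ndhK", "psbE")

LOCUS_LENGTHS = {"ETS": 491, "ITS": 687, "atpF": 457,
                 "matK": 838, "ndhK": 356, "psbE": 687}

SPECIES_STATUS = {
    "Austrostipa densiflora": "native",
    "Chloris gayana": "invasive",
    "Anthosachne scabra": "native",
    "Eragrostis curvula": "invasive",
    "Hyparrhenia hirta": "invasive",
    "Microlaena stipoides": "native",
    "Nassella neesiana": "invasive",
    "Nassella trichotoma": "invasive",
    "Poa sieberiana": "native",
    "Rytidosperma caespitosum": "native",
    "Rytidosperma pallidum": "native",
    "Themeda triandra": "native",
}

SPECIMEN_COUNTS = {
    "Austrostipa densiflora": 2,
    "Chloris gayana": 3,
    "Anthosachne scabra": 4,
    "Eragrostis curvula": 18,
    "Hyparrhenia hirta": 6,
    "Microlaena stipoides": 3,
    "Nassella neesiana": 12,
    "Nassella trichotoma": 8,
    "Poa sieberiana": 2,
    "Rytidosperma caespitosum": 2,
    "Rytidosperma pallidum": 4,
    "Themeda triandra": 2,
}

# species -> locus -> PCR success probability
PCR_SUCCESS = {
    "Austrostipa densiflora":   {"atpF": 1.00, "ETS": 1.00, "ITS": 0.00, "matK": 1.00, "ndhK": 1.00, "psbE": 0.00},
    "Chloris gayana":           {"atpF": 1.00, "ETS": 0.67, "ITS": 1.00, "matK": 0.00, "ndhK": 0.33, "psbE": 0.00},
    "Anthosachne scabra":       {"atpF": 0.75, "ETS": 0.00, "ITS": 0.00, "matK": 1.00, "ndhK": 0.25, "psbE": 0.75},
    "Eragrostis curvula":       {"atpF": 0.39, "ETS": 0.00, "ITS": 1.00, "matK": 0.78, "ndhK": 0.89, "psbE": 0.33},
    "Hyparrhenia hirta":        {"atpF": 1.00, "ETS": 0.33, "ITS": 0.00, "matK": 0.33, "ndhK": 0.83, "psbE": 0.83},
    "Microlaena stipoides":     {"atpF": 1.00, "ETS": 0.00, "ITS": 0.00, "matK": 1.00, "ndhK": 0.67, "psbE": 0.00},
    "Nassella neesiana":        {"atpF": 1.00, "ETS": 0.92, "ITS": 0.00, "matK": 0.83, "ndhK": 0.92, "psbE": 0.92},
    "Nassella trichotoma":      {"atpF": 1.00, "ETS": 1.00, "ITS": 0.13, "matK": 0.75, "ndhK": 0.88, "psbE": 0.75},
    "Poa sieberiana":           {"atpF": 1.00, "ETS": 0.00, "ITS": 0.00, "matK": 1.00, "ndhK": 0.00, "psbE": 0.00},
    "Rytidosperma caespitosum": {"atpF": 1.00, "ETS": 0.00, "ITS": 0.00, "matK": 1.00, "ndhK": 0.00, "psbE": 0.00},
    "Rytidosperma pallidum":    {"atpF": 1.00, "ETS": 0.00, "ITS": 0.00, "matK": 1.00, "ndhK": 0.00, "psbE": 0.00},
    "Themeda triandra":         {"atpF": 1.00, "ETS": 0.00, "ITS": 0.00, "matK": 1.00, "ndhK": 0.00, "psbE": 0.00},
}

# locus -> list of (species, D_intra percent or None, nearest species, D_NN percent)
GAP_TABLE = {
    "matK": [
        ("Anthosachne scabra", 0.9, "Rytidosperma pallidum", 0.38),
        ("Austrostipa densiflora", 0.12, "Nassella trichotoma", 1.43),
        ("Eragrostis curvula", 1.28, "Hyparrhenia hirta", 4.49),
        ("Hyparrhenia hirta", 0.56, "Eragrostis curvula", 4.49),
        ("Microlaena stipoides", 1.28, "Austrostipa densiflora", 6.21),
        ("Nassella neesiana", 0.66, "Nassella trichotoma", 0.11),
        ("Nassella trichotoma", 0.97, "Nassella neesiana", 0.11),
        ("Poa sieberiana", 0.45, "Anthosachne scabra", 4.84),
        ("Rytidosperma caespitosum", 9.71, "Rytidosperma pallidum", 0.0),
        ("Rytidosperma pallidum", 9.45, "Rytidosperma caespitosum", 0.0),
        ("Themeda triandra", 6.47, "Rytidosperma pallidum", 0.0),
    ],
    "ETS": [
        ("Austrostipa densiflora", 0.77, "Nassella neesiana", 7.09),
        ("Chloris gayana", 0.0, "Hyparrhenia hirta", 27.31),
        ("Hyparrhenia hirta", 0.7, "Chloris gayana", 27.31),
        ("Nassella neesiana", 0.21, "Nassella trichotoma", 2.92),
        ("Nassella trichotoma", 0.21, "Nassella neesiana", 2.92),
    ],
    "ITS": [
        ("Chloris gayana", 0.87, "Eragrostis curvula", 16.74),
        ("Eragrostis curvula", 5.21, "Chloris gayana", 16.74),
        ("Nassella trichotoma", None, "Eragrostis curvula", 20.7),
    ],
    "atpF": [
        ("Anthosachne scabra", 0.25, "Austrostipa densiflora", 2.7),
        ("Austrostipa densiflora", 0.2, "Nassella trichotoma", 0.22),
        ("Chloris gayana", 0.0, "Eragrostis curvula", 3.03),
        ("Eragrostis curvula", 5.8, "Chloris gayana", 3.03),
        ("Hyparrhenia hirta", 0.38, "Eragrostis curvula", 4.73),
        ("Microlaena stipoides", 0.63, "Nassella neesiana", 4.34),
        ("Nassella neesiana", 1.05, "Nassella trichotoma", 0.0),
        ("Nassella trichotoma", 0.48, "Nassella neesiana", 0.0),
        ("Poa sieberiana", 0.0, "Themeda triandra", 2.45),
        ("Rytidosperma caespitosum", 0.83, "Rytidosperma pallidum", 0.9),
        ("Rytidosperma pallidum", 1.38, "Rytidosperma caespitosum", 0.9),
        ("Themeda triandra", 0.0, "Poa sieberiana", 2.45),
    ],
    "ndhK": [
        ("Anthosachne scabra", None, "Austrostipa densiflora", 2.13),
        ("Austrostipa densiflora", 0.0, "Nassella neesiana", 0.26),
        ("Chloris gayana", None, "Eragrostis curvula", 2.53),
        ("Eragrostis curvula", 2.79, "Chloris gayana", 2.53),
        ("Hyparrhenia hirta", 0.75, "Eragrostis curvula", 3.2),
        ("Microlaena stipoides", 0.82, "Eragrostis curvula", 3.37),
        ("Nassella neesiana", 2.83, "Nassella trichotoma", 0.0),
        ("Nassella trichotoma", 4.85, "Nassella neesiana", 0.0),
    ],
    "psbE": [
        ("Anthosachne scabra", 0.47, "Nassella neesiana", 42.41),
        ("Eragrostis curvula", 0.63, "Hyparrhenia hirta", 5.16),
        ("Hyparrhenia hirta", 1.16, "Eragrostis curvula", 5.16),
        ("Nassella neesiana", 2.07, "Nassella trichotoma", 0.0),
        ("Nassella trichotoma", 0.29, "Nassella neesiana", 0.0),
    ],
}


def gap_rows(locus: str):
    """Reference GapSummaryRow list for one locus."""
    from .gap import GapSummaryRow
    rows = []
    for species, d_intra, nearest, d_nn in GAP_TABLE[locus]:
        n = SPECIMEN_COUNTS[species] if d_intra is not None else 1
        rows.append(GapSummaryRow(species, d_intra, nearest, d_nn,
                                  n_specimens=n))
    return rows
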
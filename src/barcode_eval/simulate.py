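"""Synthetic multi-locus barcode datasets with known truth.

The generator emulates the kind of field study this pipeline targets:
a dozen grass species, a handful to a few dozen specimens each, several
loci of different lengths and evolutionary rates, and heavy per-locus,
per-species PCR dropout.

Sequences evolve under the same Kimura 2-parameter substitution process
the distance engine assumes (transition/transversion rate ratio κ), so
the design divergences are recoverable in expectation by the K2P
estimator.  A uniform-random root sequence is evolved down a species
tree whose branch lengths are expected substitutions per site; each
specimen then receives a private terminal branch of length
``intraspecific_scale / 2``, i.e. within-species variation is a star
with expected pairwise divergence ``intraspecific_scale``.  Per-locus
rate multipliers scale every branch (species tree and terminal fans)
alike, so divergence *ratios* are locus-independent.

Dropout is specimen-level Bernoulli, independent across loci.  Indels
are off by default; when enabled they are inserted as species-shared gap
runs so the emitted matrices remain valid alignments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .errors import InputError
from .io import (AlignedMatrix, LocusDataset, SpecimenRecord, bind_dataset,
                 write_alignment, write_metadata)
from . import refdata

_ALPHABET = "AGCT"  # index == nucleotide code


@dataclass(frozen=True)
class SpeciesConfig:
    name: str
    n_specimens: int
    status: str


@dataclass(frozen=True)
class LocusConfig:
    name: str
    length: int
    rate: float = 1.0


@dataclass
class SimConfig:
    """Full specification of one synthetic study.

    ``species_tree`` is a Newick string over the species names with
    branch lengths in expected substitutions per site (before locus rate
    multipliers).  ``dropout`` maps (locus, species) to a PCR success
    probability; missing entries default to 1.0.
    """

    seed: int
    species: list[SpeciesConfig]
    species_tree: str
    loci: list[LocusConfig]
    intraspecific_scale: float = 0.005
    kappa: float = 2.0
    dropout: dict[tuple[str, str], float] = field(default_factory=dict)
    indel_rate: float = 0.0

    def validate(self) -> None:
        if self.seed is None:
            raise InputError("simulation seed is mandatory")
        if self.kappa <= 0:
            raise InputError("kappa must be > 0")
        if self.intraspecific_scale < 0:
            raise InputError("intraspecific_scale must be >= 0")
        if not self.species or not self.loci:
            raise InputError("need at least one species and one locus")
        for sp in self.species:
            if sp.n_specimens < 1:
                raise InputError(f"{sp.name}: n_specimens must be >= 1")
        for lc in self.loci:
            if lc.length < 50:
                raise InputError(f"locus {lc.name}: length must be >= 50 nt")
            if lc.rate <= 0:
                raise InputError(f"locus {lc.name}: rate must be > 0")
        for key, p in self.dropout.items():
            if not 0.0 <= p <= 1.0:
                raise InputError(f"dropout probability {key}: {p} not in [0,1]")
        if self.indel_rate < 0:
            raise InputError("indel_rate must be >= 0")
        tree = _parse_species_tree(self.species_tree)
        tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        names = {sp.name for sp in self.species}
        if tips != names:
            raise InputError(
                f"species tree tips != species list: only-in-tree="
                f"{sorted(tips - names)}, only-in-list={sorted(names - tips)}")

    def success(self, locus: str, species: str) -> float:
        return self.dropout.get((locus, species), 1.0)


@dataclass
class SimTruth:
    """Design quantities realised by one simulated dataset."""

    species_divergence: dict[tuple[str, str], float]   # nominal path lengths
    intraspecific_scale: float
    design_nearest: dict[str, tuple[str, float]]       # species -> (NN, path)
    locus_rates: dict[str, float]
    present: dict[str, list[str]]                      # locus -> specimen ids
    species_of: dict[str, str]

    def design_divergence(self, sp_a: str, sp_b: str) -> float:
        return self.species_divergence[tuple(sorted((sp_a, sp_b)))]

    def to_json(self) -> str:
        payload = {
            "intraspecific_scale": self.intraspecific_scale,
            "locus_rates": self.locus_rates,
            "species_divergence": {f"{a}|{b}": d for (a, b), d
                                   in sorted(self.species_divergence.items())},
            "design_nearest": {sp: {"nearest": nn, "divergence": d}
                               for sp, (nn, d) in sorted(self.design_nearest.items())},
            "present": {loc: ids for loc, ids in sorted(self.present.items())},
            "species_of": dict(sorted(self.species_of.items())),
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _parse_species_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True)


def _k2p_step_probs(d: float, kappa: float) -> tuple[float, float]:
    """(transition prob, per-target transversion prob) after branch d."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = np.exp(-4.0 * beta * d)
    e2 = np.exp(-2.0 * (alpha + beta) * d)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    return float(p_ts), float(p_tv)


def _evolve(codes: np.ndarray, d: float, kappa: float,
            rng: np.random.Generator) -> np.ndarray:
    """Evolve a code vector for branch length d (expected subs/site)."""
    if d <= 0:
        return codes.copy()
    p_ts, p_tv = _k2p_step_probs(d, kappa)
    u = rng.random(codes.shape[0])
    p_same = 1.0 - p_ts - 2.0 * p_tv
    out = codes.copy()
    ts = (u >= p_same) & (u < p_same + p_ts)
    tv1 = (u >= p_same + p_ts) & (u < p_same + p_ts + p_tv)
    tv2 = u >= p_same + p_ts + p_tv
    # code ^ 1 is the transition partner; ^2 and ^3 the two transversions
    out[ts] ^= 1
    out[tv1] ^= 2
    out[tv2] ^= 3
    return out


def _codes_to_str(codes: np.ndarray) -> str:
    lookup = np.array(list(_ALPHABET + "-"), dtype="U1")
    return "".join(lookup[codes])


def simulate_dataset(cfg: SimConfig) -> tuple[dict[str, LocusDataset],
                                              list[SpecimenRecord], SimTruth]:
    """Generate per-locus datasets, a metadata table, and the truth record.

    Output is byte-deterministic for a fixed config (including seed):
    loci are processed in config order, species and specimens in listed
    order, and all randomness flows from one seeded generator.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    tree = _parse_species_tree(cfg.species_tree)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    names = [sp.name for sp in cfg.species]
    divergence = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            divergence[tuple(sorted((a, b)))] = float(
                pdm.patristic_distance(taxa[a], taxa[b]))
    design_nearest = {}
    if len(names) >= 2:
        for a in names:
            best = min((d, b) for (x, y), d in divergence.items()
                       for b in ((y,) if x == a else (x,) if y == a else ()))
            design_nearest[a] = (best[1], best[0])

    # stable specimen ids: ww00001, ww00002, ... in species-list order
    specimen_ids: dict[str, list[str]] = {}
    records: list[SpecimenRecord] = []
    counter = 1
    for sp in cfg.species:
        ids = [f"ww{counter + k:05d}" for k in range(sp.n_specimens)]
        counter += sp.n_specimens
        specimen_ids[sp.name] = ids
    species_of = {sid: sp.name for sp in cfg.species
                  for sid in specimen_ids[sp.name]}

    datasets: dict[str, LocusDataset] = {}
    present: dict[str, list[str]] = {}
    for locus in cfg.loci:
        seqs = _simulate_locus(cfg, tree, locus, specimen_ids, rng)
        keep: list[str] = []
        for sp in cfg.species:
            p = cfg.success(locus.name, sp.name)
            for sid in specimen_ids[sp.name]:
                if rng.random() < p:
                    keep.append(sid)
        present[locus.name] = keep
        if len(keep) >= 1:
            matrix = AlignedMatrix(locus.name, [(sid, seqs[sid]) for sid in keep])
            datasets[locus.name] = matrix  # bound below once records exist

    for sp in cfg.species:
        for sid in specimen_ids[sp.name]:
            presence = {loc.name: sid in present[loc.name] for loc in cfg.loci}
            records.append(SpecimenRecord(sid, sp.name, sp.status, presence))
    datasets = {loc: bind_dataset(mat, records) for loc, mat in datasets.items()}

    truth = SimTruth(
        species_divergence=divergence,
        intraspecific_scale=cfg.intraspecific_scale,
        design_nearest=design_nearest,
        locus_rates={lc.name: lc.rate for lc in cfg.loci},
        present=present,
        species_of=species_of,
    )
    return datasets, records, truth


def _simulate_locus(cfg: SimConfig, tree: dendropy.Tree, locus: LocusConfig,
                    specimen_ids: dict[str, list[str]],
                    rng: np.random.Generator) -> dict[str, str]:
    """Evolve one locus for every specimen; returns id -> sequence."""
    L = locus.length
    root_seq = rng.integers(0, 4, size=L).astype(np.uint8)
    node_seq: dict = {}
    species_seq: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node_seq[node] = root_seq
        else:
            d = (node.edge.length or 0.0) * locus.rate
            node_seq[node] = _evolve(node_seq[node.parent_node], d,
                                     cfg.kappa, rng)
        if node.is_leaf():
            species_seq[node.taxon.label] = node_seq[node]
    tip_branch = 0.5 * cfg.intraspecific_scale * locus.rate
    seqs: dict[str, np.ndarray] = {}
    for sp in cfg.species:
        base = species_seq[sp.name]
        for sid in specimen_ids[sp.name]:
            seqs[sid] = _evolve(base, tip_branch, cfg.kappa, rng)
    if cfg.indel_rate > 0:
        _insert_indels(cfg, locus, specimen_ids, seqs, rng)
    return {sid: _codes_to_str(codes) for sid, codes in seqs.items()}


def _insert_indels(cfg: SimConfig, locus: LocusConfig,
                   specimen_ids: dict[str, list[str]],
                   seqs: dict[str, np.ndarray],
                   rng: np.random.Generator) -> None:
    """Species-shared gap runs; alignment columns stay consistent."""
    gap_code = np.uint8(4)
    for sp in cfg.species:
        n_events = rng.poisson(cfg.indel_rate * locus.length)
        for _ in range(n_events):
            run = 1 + int(rng.geometric(0.4))
            start = int(rng.integers(0, max(1, locus.length - run)))
            for sid in specimen_ids[sp.name]:
                seqs[sid] = seqs[sid].copy()
                seqs[sid][start:start + run] = gap_code


# -- case-study fixture ---------------------------------------------------

# Nominal species tree (expected substitutions/site before locus rates).
# The two Nassella congeners are near sisters at divergence 0.01, 2x the
# default within-species scale — by design too close for plastid-rate loci
# to resolve; every other species pair diverges by >= 0.1.
CASE_STUDY_TREE = (
    "(((((Nassella_neesiana:0.005,Nassella_trichotoma:0.005):0.05,"
    "Austrostipa_densiflora:0.055):0.04,Microlaena_stipoides:0.095):0.03,"
    "(Poa_sieberiana:0.08,Anthosachne_scabra:0.08):0.045):0.04,"
    "((Eragrostis_curvula:0.09,Chloris_gayana:0.09):0.04,"
    "((Hyparrhenia_hirta:0.08,Themeda_triandra:0.08):0.03,"
    "(Rytidosperma_caespitosum:0.05,Rytidosperma_pallidum:0.05):0.06):0.02)"
    ":0.035);"
)

# Per-locus rate multipliers: nuclear spacers evolve several-fold faster
# than the plastid loci, echoing the divergence ranges the six real loci
# display (plastid D_NN mostly < 7%, nuclear D_NN up to ~27%).
CASE_STUDY_RATES = {"ETS": 1.2, "ITS": 1.0, "atpF": 0.5,
                    "matK": 0.35, "ndhK": 0.5, "psbE": 0.6}


def case_study_fixture(seed: int = 0) -> SimConfig:
    """The bundled case-study configuration.

    Twelve grass species with the real study's specimen counts (66 in
    total), six loci with the real aligned lengths, and per-(locus,
    species) dropout probabilities equal to the published PCR success
    rates.  Within-species scale 0.005 expected subs/site; κ = 2.
    """
    species = [SpeciesConfig(name, refdata.SPECIMEN_COUNTS[name],
                             refdata.SPECIES_STATUS[name])
               for name in sorted(refdata.SPECIMEN_COUNTS)]
    loci = [LocusConfig(name, refdata.LOCUS_LENGTHS[name],
                        CASE_STUDY_RATES[name])
            for name in refdata.LOCI]
    dropout = {(locus, sp): refdata.PCR_SUCCESS[sp][locus]
               for sp in refdata.PCR_SUCCESS for locus in refdata.LOCI}
    return SimConfig(seed=seed, species=species, species_tree=CASE_STUDY_TREE,
                     loci=loci, intraspecific_scale=0.005, kappa=2.0,
                     dropout=dropout)


def write_dataset(datasets: dict[str, LocusDataset],
                  records: list[SpecimenRecord], truth: SimTruth,
                  outdir: str | Path) -> None:
    """Write FASTA per locus + metadata TSV + truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for locus, ds in sorted(datasets.items()):
        write_alignment(ds.matrix, outdir / f"{locus}.fasta")
    write_metadata(records, outdir / "specimens.tsv")
    (outdir / "truth.json").write_text(truth.to_json() + "\n")
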
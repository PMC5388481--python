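"""Report writers and the full-pipeline orchestrator.

``run_all`` drives the evaluation sequence — alignment statistics,
distance matrices, barcode-gap summaries, NJ trees with bootstrap,
monophyly tests, multilocus combinations — and emits publication-style
TSV tables, Newick trees, scatter data, figures, and one deterministic
machine-readable JSON summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alnstats import LocusStats, locus_stats
from .distances import distance_matrix
from .errors import InputError
from .gap import GapSummaryRow, locus_gap_assessment, species_gap_summary
from .io import LocusDataset, bind_dataset, read_alignment, read_metadata
from .multilocus import CombinationResult, evaluate_combinations
from .trees import bootstrap_supports, exclude_undefined, nj_tree, test_monophyly

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative configuration of one full pipeline run."""

    loci: dict[str, str]               # locus name -> aligned FASTA path
    metadata: str
    outdir: str
    model: str = "k2p"
    bootstrap_reps: int = 1000
    support_threshold: float = 70.0
    arities: list[int] = field(default_factory=lambda: [2])
    seed: int = 0
    deletion: str = "pairwise"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        try:
            return cls(**raw)
        except TypeError as exc:
            raise InputError(f"bad run config {path}: {exc}") from exc

    def validate(self) -> None:
        if self.bootstrap_reps < 0:
            raise InputError("bootstrap_reps must be >= 0")
        for locus, path in self.loci.items():
            if not Path(path).exists():
                raise InputError(f"alignment for {locus!r} not found: {path}")
        if not Path(self.metadata).exists():
            raise InputError(f"metadata not found: {self.metadata}")


# -- table writers --------------------------------------------------------

def stats_frame(stats: list[LocusStats]) -> pd.DataFrame:
    return pd.DataFrame([{
        "locus": s.locus, "aligned_length": s.aligned_length,
        "variable_sites": s.variable_sites,
        "informative_sites": s.informative_sites,
        "indel_events": s.indel_events, "n_sequences": s.n_sequences,
    } for s in stats])


def gap_frame(rows: list[GapSummaryRow]) -> pd.DataFrame:
    def fmt(x):
        return "N/A" if x is None else round(x, 2)
    return pd.DataFrame([{
        "species": r.species,
        "d_intra": fmt(r.d_intra),
        "nearest_species": r.nearest_species or "N/A",
        "d_nn": fmt(r.d_nn),
        "n_specimens": r.n_specimens,
        "gap_present": "N/A" if r.gap_present is None else r.gap_present,
    } for r in rows])


def read_gap_tsv(path: str | Path) -> list[GapSummaryRow]:
    """Inverse of the gap writer (values at report precision)."""
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    rows = []
    for rec in table.to_dict("records"):
        d_intra = None if rec["d_intra"] == "N/A" else float(rec["d_intra"])
        d_nn = None if rec["d_nn"] == "N/A" else float(rec["d_nn"])
        nearest = None if rec["nearest_species"] == "N/A" else rec["nearest_species"]
        rows.append(GapSummaryRow(rec["species"], d_intra, nearest, d_nn,
                                  int(rec["n_specimens"]),
                                  computable=nearest is not None))
    return rows


def monophyly_frame(results, locus: str,
                    threshold: float = 70.0) -> pd.DataFrame:
    return pd.DataFrame([{
        "locus": locus, "species": m.species, "n_tips": m.n_tips,
        "monophyletic": m.monophyletic,
        "support": "N/A" if m.support is None else round(m.support, 1),
        "well_supported": m.well_supported(threshold),
    } for m in results])


def combination_frame(results: list[CombinationResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "loci": "+".join(r.loci), "arity": r.arity,
        "shared_specimens": r.shared_specimens,
        "monophyletic_species": "; ".join(
            f"{sp} ({'N/A' if sup is None else round(sup, 1)})"
            for sp, sup in r.monophyletic_species),
    } for r in results])


def plot_gap_scatter(rows: list[GapSummaryRow], locus: str,
                     path: str | Path) -> bool:
    """Scatter of (D_intra, D_NN) per species with the identity line.

    Points above the line show a barcode gap.  Returns False (no file)
    when no row has a defined D_intra.
    """
    pts = [(r.d_intra, r.d_nn, r.species) for r in rows
           if r.d_intra is not None and r.d_nn is not None]
    if not pts:
        logger.warning("no plottable gap rows for %s; figure skipped", locus)
        return False
    fig, ax = plt.subplots(figsize=(5, 5))
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    lim = 1.1 * max(max(xs), max(ys), 1e-6)
    ax.plot([0, lim], [0, lim], ls="--", c="grey", lw=1)
    ax.scatter(xs, ys, c="tab:blue", zorder=3)
    for x, y, label in pts:
        ax.annotate(label, (x, y), fontsize=6,
                    xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("max intraspecific distance D$_{intra}$ (%)")
    ax.set_ylabel("nearest neighbour distance D$_{NN}$ (%)")
    ax.set_title(locus)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return True


# -- summary validation ---------------------------------------------------

def validate_summary(summary: dict) -> None:
    """Structural validation of the run summary.

    Mirrors the published schema in ``docs/summary.schema.json``; raises
    :class:`InputError` on the first violation.  (A standalone JSON-Schema
    validator is deliberately not required at run time.)
    """
    def need(obj, key, types, where):
        if key not in obj:
            raise InputError(f"summary{where}: missing key {key!r}")
        if not isinstance(obj[key], types):
            raise InputError(f"summary{where}.{key}: bad type "
                             f"{type(obj[key]).__name__}")

    need(summary, "version", str, "")
    need(summary, "seed", int, "")
    need(summary, "model", str, "")
    if summary["model"] not in ("p", "k2p"):
        raise InputError(f"summary.model: {summary['model']!r}")
    need(summary, "bootstrap_reps", int, "")
    need(summary, "skipped", list, "")
    need(summary, "loci", dict, "")
    for locus, entry in summary["loci"].items():
        where = f".loci[{locus}]"
        need(entry, "n_sequences", int, where)
        need(entry, "length", int, where)
        for m in entry.get("monophyly", []):
            need(m, "species", str, where + ".monophyly[]")
            need(m, "monophyletic", bool, where + ".monophyly[]")
            need(m, "n_tips", int, where + ".monophyly[]")
            need(m, "support", (float, int, type(None)), where + ".monophyly[]")
        for r in entry.get("gap_rows", []):
            need(r, "species", str, where + ".gap_rows[]")
    for combo in summary.get("combinations", []):
        need(combo, "loci", list, ".combinations[]")
        need(combo, "arity", str, ".combinations[]")
        need(combo, "shared_specimens", int, ".combinations[]")
        need(combo, "monophyletic_species", list, ".combinations[]")


# -- orchestrator ---------------------------------------------------------

def run_all(cfg: RunConfig) -> dict:
    """Execute the full evaluation; returns the JSON-ready summary dict.

    Reruns with an identical config (including seed) produce
    byte-identical ``summary.json`` and Newick outputs.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logging.getLogger("barcode_eval").addHandler(handler)
    rng = np.random.default_rng(cfg.seed)
    summary: dict = {"version": __version__, "seed": cfg.seed,
                     "model": cfg.model, "bootstrap_reps": cfg.bootstrap_reps,
                     "loci": {}, "skipped": []}
    try:
        records = read_metadata(cfg.metadata)
        datasets: dict[str, LocusDataset] = {}
        for locus in sorted(cfg.loci):
            matrix = read_alignment(cfg.loci[locus], locus)
            datasets[locus] = bind_dataset(matrix, records)

        all_stats = [locus_stats(ds.matrix) for _l, ds in sorted(datasets.items())]
        stats_frame(all_stats).to_csv(outdir / "locus_stats.tsv", sep="\t",
                                      index=False)

        for locus in sorted(datasets):
            summary["loci"][locus] = _run_locus(cfg, datasets[locus], outdir,
                                                rng, summary)

        if len(datasets) >= 2 and cfg.arities:
            combos = evaluate_combinations(
                datasets, arities=set(cfg.arities), model=cfg.model,
                n_reps=cfg.bootstrap_reps, seed=int(rng.integers(2**31)))
            combination_frame(combos).to_csv(outdir / "combinations.tsv",
                                             sep="\t", index=False)
            summary["combinations"] = [{
                "loci": list(r.loci), "arity": r.arity,
                "shared_specimens": r.shared_specimens,
                "monophyletic_species": [
                    {"species": sp, "support": sup}
                    for sp, sup in r.monophyletic_species],
            } for r in combos]

        validate_summary(summary)
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n")
    finally:
        logging.getLogger("barcode_eval").removeHandler(handler)
        handler.close()
    return summary


def _run_locus(cfg: RunConfig, ds: LocusDataset, outdir: Path,
               rng: np.random.Generator, summary: dict) -> dict:
    locus = ds.locus
    entry: dict = {"n_sequences": ds.matrix.n_sequences,
                   "length": ds.matrix.length}
    dm = distance_matrix(ds, cfg.model, deletion=cfg.deletion)
    dm.write_tsv(outdir / f"dist_{locus}.tsv")
    dm.to_long().to_csv(outdir / f"dist_{locus}_long.tsv", sep="\t",
                        index=False)
    n_species = len(set(ds.species_map.values()))
    if n_species >= 2:
        rows = species_gap_summary(dm, ds.species_map)
        gap_frame(rows).to_csv(outdir / f"gap_{locus}.tsv", sep="\t",
                               index=False)
        scatter = pd.DataFrame([{"species": r.species, "d_intra": r.d_intra,
                                 "d_nn": r.d_nn} for r in rows
                                if r.d_intra is not None and r.d_nn is not None])
        scatter.to_csv(outdir / f"gap_scatter_{locus}.csv", index=False)
        plot_gap_scatter(rows, locus, outdir / f"gap_{locus}.png")
        try:
            entry["locus_gap"] = locus_gap_assessment(rows)
        except InputError as exc:
            entry["locus_gap"] = None
            summary["skipped"].append(f"{locus}: gap assessment ({exc})")
        entry["gap_rows"] = [{
            "species": r.species, "d_intra": r.d_intra,
            "nearest_species": r.nearest_species, "d_nn": r.d_nn,
            "gap_present": r.gap_present} for r in rows]
    else:
        summary["skipped"].append(f"{locus}: < 2 species, gap analysis skipped")

    dm_ok, excluded = exclude_undefined(dm)
    if excluded:
        entry["excluded_specimens"] = excluded
    if len(dm_ok.ids) >= 3:
        if cfg.bootstrap_reps > 0:
            tree = bootstrap_supports(ds, cfg.model,
                                      n_reps=cfg.bootstrap_reps,
                                      rng=rng)
        else:
            tree = nj_tree(dm_ok)
        tree.write(outdir / f"nj_{locus}.nwk")
        species_map = {sid: ds.species_map[sid] for sid in tree.tips}
        mono = test_monophyly(tree, species_map, cfg.support_threshold)
        monophyly_frame(mono, locus, cfg.support_threshold).to_csv(
            outdir / f"monophyly_{locus}.tsv", sep="\t", index=False)
        entry["monophyly"] = [{
            "species": m.species, "monophyletic": m.monophyletic,
            "support": m.support, "n_tips": m.n_tips,
            "well_supported": m.well_supported(cfg.support_threshold)}
            for m in mono]
    else:
        summary["skipped"].append(f"{locus}: < 3 usable taxa, tree skipped")
    return entry
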
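"""End-to-end audit orchestration.

``run_audit`` chains the stages — data binding, K2P distances,
haplotype collapsing, divergence classes and diagnostics, NJ tree with
bootstrap supports, monophyly census and problem clades — into one
report bundle, written as deterministic TSV/newick files plus a
JSON-lines run log that records every seed, version and warning
counter needed to reproduce the bundle bit for bit.

``run_dedup_audit`` runs the identical analysis on the subset retaining
at most two specimens per (species, haplotype), i.e. on haplotype
diversity instead of haplotype frequency.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from barcodeaudit import __version__
from barcodeaudit.dataio import Dataset, bind, read_fasta, read_metadata, write_report
from barcodeaudit.distances import DEFAULT_MIN_OVERLAP, pairwise_matrix
from barcodeaudit.divergence import (
    CONGENERIC,
    INTERGENERIC,
    INTRA,
    classify_pairs,
    class_pair_counts,
    detect_gap,
    diagnostics_frame,
    flag_failures,
    species_diagnostics,
    summarize_class,
    summary_frame,
)
from barcodeaudit.haplotypes import accumulation_curve, collapse, dedup_max_two
from barcodeaudit.njtree import bootstrap_support, monophyly_census, problem_clades


@dataclass
class RunConfig:
    """All knobs of one audit run; every random procedure has a seed."""

    fasta: str | Path | None = None
    metadata: str | Path | None = None
    outlier_quantiles: tuple[float, float] = (2.5, 97.5)
    min_overlap: int = DEFAULT_MIN_OVERLAP
    dedup_mode: str = "deterministic"
    bootstrap_reps: int = 500
    bootstrap_seed: int = 1
    accumulation_permutations: int = 1000
    accumulation_seed: int = 1
    accumulation_top_m: int = 3
    clade_threshold: float = 0.015
    output_prefix: str | Path | None = None


@dataclass
class AuditBundle:
    """In-memory results of one audit run."""

    counts: dict
    pair_counts: dict
    summaries: list
    gap: object
    diagnostics: list
    flagged: list
    haplotypes: object
    curves: dict
    tree: object | None
    census: object | None
    clades: list
    log: list = field(default_factory=list)
    files: list = field(default_factory=list)


def load_dataset(config: RunConfig) -> Dataset:
    if config.fasta is None or config.metadata is None:
        raise ValueError("config.fasta and config.metadata are required")
    return bind(read_fasta(config.fasta), read_metadata(config.metadata))


def _curve_species(dataset: Dataset, m: int) -> list[str]:
    """The m most-sampled species (ties broken alphabetically)."""
    counts: dict[str, int] = {}
    for r in dataset.records:
        counts[r.species] = counts.get(r.species, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [sp for sp, _ in ranked[:m]]


def run_audit(
    config: RunConfig,
    dataset: Dataset | None = None,
    label: str = "haplotype-frequency mode",
) -> AuditBundle:
    """Execute the full audit and (optionally) write the report bundle.

    Datasets of fewer than three specimens get the distance and
    divergence stages only: NJ requires n >= 3, so tree, census and
    clade reports are omitted and the omission is logged.
    """
    if dataset is None:
        dataset = load_dataset(config)
    log: list[dict] = [
        {
            "event": "start",
            "label": label,
            "version": __version__,
            "config": {
                "outlier_quantiles": list(config.outlier_quantiles),
                "min_overlap": config.min_overlap,
                "bootstrap_reps": config.bootstrap_reps,
                "bootstrap_seed": config.bootstrap_seed,
                "accumulation_permutations": config.accumulation_permutations,
                "accumulation_seed": config.accumulation_seed,
                "clade_threshold": config.clade_threshold,
            },
        }
    ]
    counts = dataset.counts()
    log.append({"event": "bind", **counts})

    if dataset.n_specimens < 2:
        raise ValueError("at least 2 specimens required")

    matrix = pairwise_matrix(dataset.alignment, min_overlap=config.min_overlap)
    log.append(
        {
            "event": "distances",
            "n_saturated": matrix.n_saturated,
            "n_no_overlap": matrix.n_no_overlap,
            "n_low_confidence": int(matrix.low_confidence.sum() // 2),
        }
    )
    classes = classify_pairs(dataset)
    pair_counts = class_pair_counts(classes)
    q = config.outlier_quantiles
    intra = summarize_class(matrix, classes, INTRA, quantiles=q)
    congeneric = summarize_class(matrix, classes, CONGENERIC, quantiles=q)
    intergeneric = summarize_class(matrix, classes, INTERGENERIC, quantiles=q)
    interspecific = summarize_class(
        matrix, classes, (CONGENERIC, INTERGENERIC), quantiles=q
    )
    summaries = [intra, congeneric, intergeneric, interspecific]
    if intra.empty or interspecific.empty:
        gap = None
        log.append({"event": "gap", "skipped": "empty divergence class"})
    else:
        gap = detect_gap(intra, interspecific)
        log.append(
            {
                "event": "gap",
                "intra_upper": gap.intra_upper,
                "inter_lower": gap.inter_lower,
                "gap_exists": gap.gap_exists,
                "threshold": gap.threshold,
            }
        )

    diagnostics = species_diagnostics(dataset, matrix)
    flagged = flag_failures(diagnostics)
    log.append({"event": "diagnostics", "n_flagged": len(flagged)})

    haplotypes = collapse(dataset, scope="global")
    log.append(
        {
            "event": "haplotypes",
            "n_haplotypes": haplotypes.n_haplotypes,
            "n_shared": len(haplotypes.shared()),
        }
    )

    curves = {}
    for sp in _curve_species(dataset, config.accumulation_top_m):
        seqs = [
            row
            for row, rec in zip(dataset.alignment.rows, dataset.records)
            if rec.species == sp
        ]
        curves[sp] = accumulation_curve(
            seqs,
            n_permutations=config.accumulation_permutations,
            seed=config.accumulation_seed,
        )

    tree = census = None
    clades: list = []
    if dataset.n_specimens >= 3:
        boot = bootstrap_support(
            dataset.alignment,
            n_reps=config.bootstrap_reps,
            seed=config.bootstrap_seed,
            min_overlap=config.min_overlap,
        )
        tree = boot.tree
        log.append(
            {
                "event": "bootstrap",
                "n_replicates": boot.n_replicates,
                "n_retained": boot.n_retained,
                "n_dropped": boot.n_dropped,
                "n_clamped_branches": tree.n_clamped,
            }
        )
        census = monophyly_census(tree, dataset)
        log.append(
            {
                "event": "monophyly",
                "percent": None
                if math.isnan(census.percent_monophyletic)
                else census.percent_monophyletic,
                "n_multi_specimen_species": census.n_multi,
            }
        )
        clades = problem_clades(
            tree, diagnostics, dataset, matrix, threshold=config.clade_threshold
        )
        log.append({"event": "problem_clades", "n_clades": len(clades)})
    else:
        log.append({"event": "tree", "skipped": "fewer than 3 specimens"})

    bundle = AuditBundle(
        counts=counts,
        pair_counts=pair_counts,
        summaries=summaries,
        gap=gap,
        diagnostics=diagnostics,
        flagged=flagged,
        haplotypes=haplotypes,
        curves=curves,
        tree=tree,
        census=census,
        clades=clades,
        log=log,
    )
    if config.output_prefix is not None:
        bundle.files = write_bundle(bundle, dataset, config.output_prefix)
    return bundle


def run_dedup_audit(config: RunConfig, dataset: Dataset | None = None) -> AuditBundle:
    """Audit on the at-most-two-specimens-per-haplotype subset."""
    if dataset is None:
        dataset = load_dataset(config)
    reduced = dedup_max_two(dataset, mode=config.dedup_mode)
    prefix = config.output_prefix
    if prefix is not None:
        config = RunConfig(**{**config.__dict__, "output_prefix": f"{prefix}.dedup"})
    return run_audit(config, dataset=reduced, label="haplotype-diversity mode")


def _clade_frame(clades) -> pd.DataFrame:
    rows = []
    for c in clades:
        rows.append(
            {
                "clade": c.clade_id,
                "species": "; ".join(
                    f"{sp} ({n})" for sp, n in sorted(c.species_counts.items())
                ),
                "min_bsd_range_pct": ""
                if math.isnan(c.min_bsd_range[0])
                else f"{100 * c.min_bsd_range[0]:.2f}-{100 * c.min_bsd_range[1]:.2f}",
                "min_bsd_mean_pct": ""
                if math.isnan(c.min_bsd_mean)
                else f"{100 * c.min_bsd_mean:.2f}",
                "bp_value": "" if c.support is None else f"{c.support:.0f}",
                "min_bsd_closest_pct": ""
                if math.isnan(c.min_bsd_to_closest)
                else f"{100 * c.min_bsd_to_closest:.2f}",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "clade", "species", "min_bsd_range_pct", "min_bsd_mean_pct",
            "bp_value", "min_bsd_closest_pct",
        ],
    )


def _census_frame(census) -> pd.DataFrame:
    if census is None:
        return pd.DataFrame(columns=["species", "monophyletic", "bp_value"])
    rows = []
    for sp in sorted(census.verdicts):
        support = census.supports.get(sp)
        rows.append(
            {
                "species": sp,
                "monophyletic": census.verdicts[sp],
                "bp_value": "" if support is None else f"{support:.0f}",
            }
        )
    return pd.DataFrame(rows, columns=["species", "monophyletic", "bp_value"])


def _curves_frame(curves) -> pd.DataFrame:
    rows = []
    for sp in sorted(curves):
        c = curves[sp]
        for n, m in zip(c.n, c.mean_haplotypes):
            rows.append({"species": sp, "n": int(n), "mean_haplotypes": round(float(m), 4)})
    return pd.DataFrame(rows, columns=["species", "n", "mean_haplotypes"])


def write_bundle(bundle: AuditBundle, dataset: Dataset, prefix: str | Path) -> list[Path]:
    tables = {
        "summary": summary_frame(bundle.summaries),
        "diagnostics": diagnostics_frame(bundle.diagnostics, dataset),
        "haplotypes": bundle.haplotypes.to_frame(),
        "accumulation": _curves_frame(bundle.curves),
        "clades": _clade_frame(bundle.clades),
        "monophyly": _census_frame(bundle.census),
    }
    trees = {}
    if bundle.tree is not None:
        trees["nj"] = bundle.tree.newick(with_supports=True)
    files = write_report(tables, trees, prefix)
    log_path = Path(f"{prefix}.runlog.jsonl")
    with open(log_path, "w") as fh:
        for entry in bundle.log:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")
    files.append(log_path)
    return files
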
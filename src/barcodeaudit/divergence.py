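"""Divergence classes, summary statistics, species diagnostics and the barcode gap.

Every unordered specimen pair falls into exactly one class:
intraspecific (same species), congeneric (same genus, different
species) or intergeneric (different genera).  Placeholder species
("sp. <code>") count as distinct species, so two placeholders in one
genus form a congeneric pair.

Per species the module computes Max-WSD (maximum within-species
divergence) and Min-BSD (minimum divergence from any heterospecific
specimen).  A species fails the diagnostic when Max-WSD >= Min-BSD:
its internal variation reaches its distance to another species, so
nearest-neighbour assignment can mislead.  The barcode gap is the
interval, after trimming distributional outliers, between the largest
intraspecific and the smallest interspecific distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from barcodeaudit.dataio import Dataset
from barcodeaudit.distances import DistanceMatrix

INTRA = 0
CONGENERIC = 1
INTERGENERIC = 2
CLASS_NAMES = {INTRA: "intraspecific", CONGENERIC: "congeneric", INTERGENERIC: "intergeneric"}

#: Whisker quantiles: values outside this interval are outliers.
DEFAULT_QUANTILES = (2.5, 97.5)


@dataclass
class DivergenceSummary:
    """Distribution summary of one divergence class (proportions).

    ``ci_low``/``ci_high`` are the whisker percentiles (2.5th and
    97.5th by default, linear interpolation between order statistics);
    outliers are the values falling outside that interval.
    """

    class_name: str
    n_pairs: int
    mean: float
    median: float
    min: float
    max: float
    ci_low: float
    ci_high: float
    outliers: list[tuple[tuple[str, str], float]] = field(default_factory=list)
    quantiles: tuple[float, float] = DEFAULT_QUANTILES
    values: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    @property
    def empty(self) -> bool:
        return self.n_pairs == 0


@dataclass
class SpeciesDiagnostics:
    """Per-species barcode diagnostics.

    ``max_wsd`` is ``nan`` for singletons (no conspecific pair exists);
    singletons are therefore never flagged.  ``nearest_species`` lists
    every species attaining Min-BSD, sorted lexicographically.
    """

    species: str
    n_specimens: int
    n_haplotypes: int
    max_wsd: float
    min_bsd: float
    nearest_species: list[str]
    failure_flag: bool


@dataclass
class GapReport:
    """Barcode-gap verdict after outlier trimming.

    ``intra_upper`` is the largest intraspecific distance at or below
    the upper whisker; ``inter_lower`` the smallest interspecific
    distance at or above the lower whisker.  The gap exists when
    ``intra_upper < inter_lower``; ``threshold`` is then the midpoint,
    a natural assignment cutoff.
    """

    intra_upper: float
    inter_lower: float
    gap_exists: bool
    threshold: float | None
    quantiles: tuple[float, float] = DEFAULT_QUANTILES


def classify_pairs(dataset: Dataset) -> np.ndarray:
    """Class code matrix (n x n) over specimen pairs; diagonal -1.

    Classification uses only the species and genus strings, so the
    intra + congeneric + intergeneric counts always sum to C(N, 2).
    """
    species = np.array(dataset.species)
    genera = np.array(dataset.genera)
    if (genera == "").any():
        raise ValueError("missing genus in metadata")
    same_sp = species[:, None] == species[None, :]
    same_gen = genera[:, None] == genera[None, :]
    classes = np.full(same_sp.shape, INTERGENERIC, dtype=np.int8)
    classes[same_gen] = CONGENERIC
    classes[same_sp] = INTRA
    np.fill_diagonal(classes, -1)
    return classes


def class_pair_counts(classes: np.ndarray) -> dict[str, int]:
    iu = np.triu_indices(classes.shape[0], k=1)
    upper = classes[iu]
    return {CLASS_NAMES[c]: int((upper == c).sum()) for c in (INTRA, CONGENERIC, INTERGENERIC)}


def _class_values(
    matrix: DistanceMatrix, classes: np.ndarray, which: int | tuple[int, ...]
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Defined distances of one or more classes with their specimen-id pairs."""
    codes = (which,) if isinstance(which, int) else tuple(which)
    n = len(matrix.ids)
    iu = np.triu_indices(n, k=1)
    mask = np.isin(classes[iu], codes) & matrix.defined[iu]
    vals = matrix.values[iu][mask]
    ii, jj = iu[0][mask], iu[1][mask]
    pairs = [(matrix.ids[a], matrix.ids[b]) for a, b in zip(ii, jj)]
    return vals, pairs


def summarize_class(
    matrix: DistanceMatrix,
    classes: np.ndarray,
    which: int | tuple[int, ...],
    quantiles: tuple[float, float] = DEFAULT_QUANTILES,
) -> DivergenceSummary:
    """Summary statistics and outliers for one divergence class.

    ``which`` may also be a tuple of class codes to pool, e.g.
    ``(CONGENERIC, INTERGENERIC)`` for the interspecific distribution.
    Only defined distances enter the summary; an empty class yields an
    all-``nan`` sentinel summary with ``n_pairs = 0``.
    """
    vals, pairs = _class_values(matrix, classes, which)
    name = CLASS_NAMES[which] if isinstance(which, int) else "interspecific"
    if vals.size == 0:
        nan = math.nan
        return DivergenceSummary(name, 0, nan, nan, nan, nan, nan, nan, [], quantiles)
    vals = np.asarray(vals, dtype=float)
    lo, hi = np.percentile(vals, quantiles)  # linear interpolation
    outliers = [
        (pair, float(v))
        for pair, v in zip(pairs, vals)
        if v < lo or v > hi
    ]
    return DivergenceSummary(
        class_name=name,
        n_pairs=int(vals.size),
        mean=float(vals.mean()),
        median=float(np.median(vals)),
        min=float(vals.min()),
        max=float(vals.max()),
        ci_low=float(lo),
        ci_high=float(hi),
        outliers=outliers,
        quantiles=quantiles,
        values=vals,
    )


def species_diagnostics(
    dataset: Dataset, matrix: DistanceMatrix
) -> list[SpeciesDiagnostics]:
    """Max-WSD / Min-BSD diagnostics for every species.

    Min-BSD is taken at specimen level — the minimum defined distance
    between any member and any heterospecific specimen — then the
    attaining species are reported (all ties, sorted).  Undefined
    distances are excluded from both extrema.
    """
    from barcodeaudit.haplotypes import collapse  # local import, avoids cycle

    species = np.array(dataset.species)
    order = {sid: i for i, sid in enumerate(matrix.ids)}
    idx_of_specimen = np.array([order[r.specimen_id] for r in dataset.records])
    # distance matrix rows aligned to dataset record order
    vals = matrix.values[np.ix_(idx_of_specimen, idx_of_specimen)]
    defined = matrix.defined[np.ix_(idx_of_specimen, idx_of_specimen)]
    hap_counts = collapse(dataset, scope="per-species").per_species_counts()

    out: list[SpeciesDiagnostics] = []
    for sp in sorted({str(s) for s in species}):
        members = np.where(species == sp)[0]
        others = np.where(species != sp)[0]
        # Max-WSD over conspecific pairs
        if members.size >= 2:
            sub = vals[np.ix_(members, members)]
            subdef = defined[np.ix_(members, members)]
            iu = np.triu_indices(members.size, k=1)
            wvals = sub[iu][subdef[iu]]
            max_wsd = float(wvals.max()) if wvals.size else math.nan
        else:
            max_wsd = math.nan
        # Min-BSD over member x heterospecific pairs
        cross = vals[np.ix_(members, others)]
        crossdef = defined[np.ix_(members, others)]
        cvals = cross[crossdef]
        if cvals.size:
            min_bsd = float(cvals.min())
            hit_cols = np.where((cross == min_bsd) & crossdef)[1]
            nearest = sorted({dataset.records[others[c]].species for c in hit_cols})
        else:
            min_bsd = math.nan
            nearest = []
        flag = (not math.isnan(max_wsd)) and (not math.isnan(min_bsd)) and max_wsd >= min_bsd
        out.append(
            SpeciesDiagnostics(
                species=sp,
                n_specimens=int(members.size),
                n_haplotypes=int(hap_counts.get(sp, 0)),
                max_wsd=max_wsd,
                min_bsd=min_bsd,
                nearest_species=nearest,
                failure_flag=flag,
            )
        )
    return out


def flag_failures(diagnostics: list[SpeciesDiagnostics]) -> list[str]:
    """Species whose Max-WSD equals or exceeds Min-BSD (singletons exempt)."""
    return sorted(d.species for d in diagnostics if d.failure_flag)


def detect_gap(
    intra_summary: DivergenceSummary,
    inter_summary: DivergenceSummary,
) -> GapReport:
    """Barcode-gap detection after outlier trimming.

    Trims intraspecific values above the upper whisker and
    interspecific values below the lower whisker (quantiles from the
    intra summary's policy), then compares the trimmed extremes.  When
    a gap exists, the suggested assignment threshold is its midpoint.
    """
    intra_values = intra_summary.values
    inter_values = inter_summary.values
    if intra_values.size == 0 or inter_values.size == 0:
        raise ValueError("both divergence classes must be non-empty")
    q = intra_summary.quantiles
    intra_hi = np.percentile(intra_values, q[1])
    inter_lo = np.percentile(inter_values, q[0])
    intra_trimmed = intra_values[intra_values <= intra_hi]
    inter_trimmed = inter_values[inter_values >= inter_lo]
    intra_upper = float(intra_trimmed.max())
    inter_lower = float(inter_trimmed.min())
    exists = intra_upper < inter_lower
    return GapReport(
        intra_upper=intra_upper,
        inter_lower=inter_lower,
        gap_exists=exists,
        threshold=(intra_upper + inter_lower) / 2 if exists else None,
        quantiles=q,
    )


def diagnostics_frame(diagnostics: list[SpeciesDiagnostics], dataset: Dataset) -> pd.DataFrame:
    """Diagnostics as a report table, percentages with two decimals."""
    genus_of = {r.species: r.genus for r in dataset.records}
    rows = []
    for d in diagnostics:
        rows.append(
            {
                "genus": genus_of.get(d.species, ""),
                "species": d.species,
                "n_specimens": d.n_specimens,
                "n_haplotypes": d.n_haplotypes,
                "max_wsd_pct": "" if math.isnan(d.max_wsd) else f"{100 * d.max_wsd:.2f}",
                "min_bsd_pct": "" if math.isnan(d.min_bsd) else f"{100 * d.min_bsd:.2f}",
                "nearest_species": ";".join(d.nearest_species),
                "failure_flag": d.failure_flag,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "genus", "species", "n_specimens", "n_haplotypes",
            "max_wsd_pct", "min_bsd_pct", "nearest_species", "failure_flag",
        ],
    )


def summary_frame(summaries: list[DivergenceSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "class": s.class_name,
                "n_pairs": s.n_pairs,
                "mean_pct": f"{100 * s.mean:.2f}" if not s.empty else "",
                "median_pct": f"{100 * s.median:.2f}" if not s.empty else "",
                "min_pct": f"{100 * s.min:.2f}" if not s.empty else "",
                "max_pct": f"{100 * s.max:.2f}" if not s.empty else "",
                "ci_low_pct": f"{100 * s.ci_low:.2f}" if not s.empty else "",
                "ci_high_pct": f"{100 * s.ci_high:.2f}" if not s.empty else "",
                "n_outliers": len(s.outliers),
            }
        )
    return pd.DataFrame(rows)
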
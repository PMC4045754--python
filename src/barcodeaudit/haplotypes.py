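"""Haplotype collapsing, accumulation curves and haplotype-diversity resampling.

A haplotype is a unique sequence variant.  Equality is exact full-string
identity of the aligned sequences: the relation is transitive and
order-independent, unlike zero K2P distance under pairwise deletion
(which an ambiguous site can make intransitive).  A sequence containing
ambiguity codes is therefore its own haplotype unless another specimen
matches it character for character.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from barcodeaudit.dataio import Dataset


@dataclass
class HaplotypeTable:
    """Partition of specimens into identical-sequence classes.

    Haplotypes are numbered by first occurrence in alignment row order.
    ``scope`` records whether the collapse ran across the whole dataset
    ("global", detecting between-species sharing) or within each
    species separately ("per-species").
    """

    scope: str
    haplotype_of: dict[str, int]          # specimen_id -> haplotype_id
    members: dict[int, list[str]]         # haplotype_id -> specimen_ids
    representative: dict[int, str]        # haplotype_id -> sequence
    species_of: dict[int, list[str]]      # haplotype_id -> sorted species list

    @property
    def n_haplotypes(self) -> int:
        return len(self.members)

    def shared(self) -> dict[int, list[str]]:
        """Haplotypes carried by more than one species (global scope only)."""
        return {h: sp for h, sp in self.species_of.items() if len(sp) > 1}

    def per_species_counts(self) -> dict[str, int]:
        """Number of distinct haplotypes observed within each species."""
        counts: Counter[str] = Counter()
        seen: set[tuple[str, int]] = set()
        for h, specs in self.species_of.items():
            for sp in specs:
                if (sp, h) not in seen:
                    seen.add((sp, h))
                    counts[sp] += 1
        return dict(counts)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for h in sorted(self.members):
            rows.append(
                {
                    "haplotype_id": h,
                    "n_members": len(self.members[h]),
                    "species": ";".join(self.species_of[h]),
                    "specimen_ids": ";".join(sorted(self.members[h])),
                }
            )
        return pd.DataFrame(
            rows, columns=["haplotype_id", "n_members", "species", "specimen_ids"]
        )


@dataclass
class AccumulationCurve:
    """Mean distinct haplotypes among the first n of a random specimen order.

    ``mean_haplotypes[n-1]`` is the permutation average at subsample
    size n; at n = N it equals the total haplotype count exactly.
    """

    n: np.ndarray
    mean_haplotypes: np.ndarray
    n_permutations: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n": self.n, "mean_haplotypes": self.mean_haplotypes}
        )


def collapse(dataset: Dataset, scope: str = "global") -> HaplotypeTable:
    """Collapse specimens into haplotypes by exact sequence identity.

    With ``scope="global"`` one numbering spans the dataset, so a
    haplotype shared between species appears once with both species
    listed; with ``scope="per-species"`` identical sequences in
    different species are distinct haplotypes.
    """
    if scope not in ("global", "per-species"):
        raise ValueError(f"unknown scope {scope!r}")
    haplotype_of: dict[str, int] = {}
    members: dict[int, list[str]] = defaultdict(list)
    representative: dict[int, str] = {}
    species_sets: dict[int, set[str]] = defaultdict(set)
    key_to_id: dict[object, int] = {}
    next_id = 0
    for sid, row, rec in zip(
        dataset.alignment.ids, dataset.alignment.rows, dataset.records
    ):
        key = row if scope == "global" else (rec.species, row)
        if key not in key_to_id:
            key_to_id[key] = next_id
            representative[next_id] = row
            next_id += 1
        h = key_to_id[key]
        haplotype_of[sid] = h
        members[h].append(sid)
        species_sets[h].add(rec.species)
    return HaplotypeTable(
        scope=scope,
        haplotype_of=haplotype_of,
        members=dict(members),
        representative=representative,
        species_of={h: sorted(s) for h, s in species_sets.items()},
    )


def accumulation_curve(
    sequences: list[str], n_permutations: int = 1000, seed: int = 0
) -> AccumulationCurve:
    """Haplotype accumulation curve by random permutation subsampling.

    For each subsample size n, the curve value is the mean (over
    ``n_permutations`` uniformly random orderings of the specimens) of
    the number of distinct haplotypes among the first n specimens.
    """
    if not sequences:
        raise ValueError("at least one specimen required")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    # map sequences to small integer labels once
    labels: dict[str, int] = {}
    coded = np.array([labels.setdefault(s, len(labels)) for s in sequences])
    n_total = len(coded)
    n_hap = len(labels)
    rng = np.random.default_rng(seed)
    acc = np.zeros(n_total)
    for _ in range(n_permutations):
        perm = coded[rng.permutation(n_total)]
        # first position at which each haplotype label appears
        first_seen = np.full(n_hap, n_total, dtype=np.int64)
        np.minimum.at(first_seen, perm, np.arange(n_total))
        # cumulative distinct count = #labels first seen at position <= k
        counts = np.bincount(first_seen[first_seen < n_total], minlength=n_total)
        acc += np.cumsum(counts)
    return AccumulationCurve(
        n=np.arange(1, n_total + 1),
        mean_haplotypes=acc / n_permutations,
        n_permutations=n_permutations,
        seed=seed,
    )


def dedup_max_two(
    dataset: Dataset, mode: str = "deterministic", seed: int | None = None
) -> Dataset:
    """Retain at most two specimens per (species, haplotype) cell.

    Down-weighting repeated haplotypes makes the divergence summaries
    reflect haplotype diversity rather than haplotype frequency.  The
    default retention is deterministic (lexicographically smallest
    specimen ids); ``mode="random"`` with a seed draws the retained
    pair uniformly, for sensitivity analysis.
    """
    if mode not in ("deterministic", "random"):
        raise ValueError(f"unknown mode {mode!r}")
    table = collapse(dataset, scope="per-species")
    rng = np.random.default_rng(seed) if mode == "random" else None
    keep: list[str] = []
    for h in sorted(table.members):
        ids = sorted(table.members[h])
        if len(ids) <= 2:
            keep.extend(ids)
        elif rng is None:
            keep.extend(ids[:2])
        else:
            keep.extend(sorted(rng.choice(ids, size=2, replace=False)))
    return dataset.subset(keep)
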
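"""Kimura two-parameter distances under pairwise deletion.

The K2P model corrects observed divergence for multiple hits while
distinguishing transitions (A<->G, C<->T; observed proportion P) from
transversions (proportion Q):

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

Pairwise deletion means a column contributes to a pair's comparison only
when both sequences carry an unambiguous A/C/G/T there; gaps, N and
IUPAC ambiguity codes exclude the column for that pair alone, so each
pair has its own effective sequence length.

Distances are stored as proportions throughout; report layers format
them as percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from barcodeaudit.dataio import BarcodeAlignment

#: Pairs with fewer compared sites than this are kept but flagged
#: low-confidence.
DEFAULT_MIN_OVERLAP = 100

#: Reasons a pairwise distance can be undefined.
NO_OVERLAP = "no-overlap"
SATURATED = "saturated"


@dataclass(frozen=True)
class SiteClassCounts:
    """Per-pair site tallies under pairwise deletion.

    ``n_compared`` counts columns where both sequences have an
    unambiguous base; transitions are A<->G / C<->T differences,
    transversions all other differences.
    """

    n_compared: int
    n_transitions: int
    n_transversions: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_transitions + self.n_transversions <= self.n_compared:
            raise ValueError("site class counts violate 0 <= ts+tv <= compared")

    @property
    def p(self) -> float:
        """Observed transition proportion P."""
        return self.n_transitions / self.n_compared

    @property
    def q(self) -> float:
        """Observed transversion proportion Q."""
        return self.n_transversions / self.n_compared

    @property
    def mismatch(self) -> float:
        """Raw uncorrected mismatch proportion (P + Q)."""
        return (self.n_transitions + self.n_transversions) / self.n_compared


def count_site_classes(seq_a: str, seq_b: str) -> SiteClassCounts:
    """Tally compared / transition / transversion sites for one pair.

    Reference (scalar) implementation of the pairwise-deletion rule;
    :func:`pairwise_matrix` uses an equivalent vectorised kernel.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"sequence lengths differ: {len(seq_a)} vs {len(seq_b)}"
        )
    bases = frozenset("ACGT")
    purines = frozenset("AG")
    n_comp = n_ts = n_tv = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a not in bases or b not in bases:
            continue
        n_comp += 1
        if a == b:
            continue
        if (a in purines) == (b in purines):
            n_ts += 1
        else:
            n_tv += 1
    return SiteClassCounts(n_comp, n_ts, n_tv)


def undefined_reason(counts: SiteClassCounts) -> str | None:
    """Why :func:`k2p` is undefined for these counts, or None if defined."""
    if counts.n_compared == 0:
        return NO_OVERLAP
    if 1 - 2 * counts.p - counts.q <= 0 or 1 - 2 * counts.q <= 0:
        return SATURATED
    return None


def k2p(counts: SiteClassCounts) -> float:
    """K2P distance as a proportion; ``nan`` when undefined.

    Undefined cases are zero overlap (no columns compared) and
    saturation (either logarithm argument non-positive); use
    :func:`undefined_reason` to distinguish them.
    """
    if undefined_reason(counts) is not None:
        return math.nan
    d = -0.5 * math.log(1 - 2 * counts.p - counts.q) - 0.25 * math.log(
        1 - 2 * counts.q
    )
    return d + 0.0  # normalise -0.0 from identical sequences


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with a defined-entry contract.

    ``values[i, j]`` is the K2P proportion for the (i, j) specimen pair,
    ``nan`` where undefined; ``defined`` is the boolean mask of usable
    entries (diagonal True).  ``n_compared`` records each pair's
    effective overlap and ``low_confidence`` marks pairs whose overlap
    fell below the configured minimum.
    """

    ids: list[str]
    values: np.ndarray
    defined: np.ndarray
    n_compared: np.ndarray
    low_confidence: np.ndarray
    n_saturated: int = 0
    n_no_overlap: int = 0

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("values shape does not match ids")
        self._index = {sid: i for i, sid in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def get(self, id_a: str, id_b: str) -> float:
        return float(self.values[self._index[id_a], self._index[id_b]])

    def condensed(self) -> tuple[np.ndarray, np.ndarray]:
        """Upper-triangle (i<j) values and defined flags in row-major order."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu], self.defined[iu]

    def subset(self, keep_ids: Sequence[str]) -> "DistanceMatrix":
        idx = np.array([self._index[i] for i in keep_ids])
        return DistanceMatrix(
            list(keep_ids),
            self.values[np.ix_(idx, idx)],
            self.defined[np.ix_(idx, idx)],
            self.n_compared[np.ix_(idx, idx)],
            self.low_confidence[np.ix_(idx, idx)],
            self.n_saturated,
            self.n_no_overlap,
        )

    def to_lower_triangle_csv(self, path) -> None:
        """Export as lower-triangle CSV with a header row of specimen ids."""
        with open(path, "w") as fh:
            fh.write("," + ",".join(self.ids) + "\n")
            for i, sid in enumerate(self.ids):
                cells = [
                    "" if not self.defined[i, j] else f"{self.values[i, j]:.8f}"
                    for j in range(i)
                ]
                fh.write(sid + "," + ",".join(cells) + "\n")


def k2p_from_counts_arrays(
    n_comp: np.ndarray, n_ts: np.ndarray, n_tv: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised K2P over count arrays.

    Returns (distances, defined mask, saturated mask); zero-overlap
    entries are undefined but not saturated.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_comp > 0, n_ts / np.maximum(n_comp, 1), np.nan)
        q = np.where(n_comp > 0, n_tv / np.maximum(n_comp, 1), np.nan)
        a1 = 1 - 2 * p - q
        a2 = 1 - 2 * q
        d = np.where((a1 > 0) & (a2 > 0), -0.5 * np.log(np.maximum(a1, 1e-300))
                     - 0.25 * np.log(np.maximum(a2, 1e-300)), np.nan)
        d = d + 0.0  # normalise -0.0 from identical sequences
    has_overlap = n_comp > 0
    saturated = has_overlap & ((a1 <= 0) | (a2 <= 0))
    defined = has_overlap & ~saturated
    return d, defined, saturated


def pairwise_matrix(
    alignment: BarcodeAlignment,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> DistanceMatrix:
    """K2P distance matrix over all specimen pairs under pairwise deletion.

    Undefined entries (saturated or zero-overlap pairs) are flagged, not
    silently zeroed; pairs with overlap below ``min_overlap`` are marked
    low-confidence but remain usable.
    """
    n = len(alignment)
    if n < 2:
        raise ValueError("pairwise_matrix requires at least 2 sequences")
    codes = alignment.codes
    values = np.zeros((n, n))
    defined = np.ones((n, n), dtype=bool)
    n_compared = np.zeros((n, n), dtype=np.int64)
    n_sat = 0
    n_nov = 0
    np.fill_diagonal(n_compared, (codes != 255).sum(axis=1))
    for i in range(n - 1):
        # compare row i against rows i+1..n-1
        block = codes[i + 1:]
        row = codes[i]
        valid = (block != 255) & (row != 255)
        diffm = (block != row) & valid
        # with A,C,G,T -> 0..3 the transitions (A<->G, C<->T) are exactly
        # the differing pairs of equal parity
        tsm = diffm & ((block & 1) == (row & 1))
        comp = valid.sum(axis=1)
        ts = tsm.sum(axis=1)
        tv = (diffm & ~tsm).sum(axis=1)
        d, dmask, sat = k2p_from_counts_arrays(comp, ts, tv)
        n_sat += int(sat.sum())
        n_nov += int((comp == 0).sum())
        values[i, i + 1:] = d
        values[i + 1:, i] = d
        defined[i, i + 1:] = dmask
        defined[i + 1:, i] = dmask
        n_compared[i, i + 1:] = comp
        n_compared[i + 1:, i] = comp
    low_conf = (n_compared < min_overlap) & ~np.eye(n, dtype=bool)
    return DistanceMatrix(
        list(alignment.ids), values, defined, n_compared, low_conf,
        n_saturated=n_sat, n_no_overlap=n_nov,
    )


def raw_mismatch(seq_a: str, seq_b: str) -> float:
    """Uncorrected mismatch proportion over compared columns (p-distance)."""
    c = count_site_classes(seq_a, seq_b)
    if c.n_compared == 0:
        return math.nan
    return c.mismatch
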
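"""Query identification against a barcode reference library.

A query sequence (unaligned, possibly partial) is globally aligned to
the library's consensus, projected onto the library's fixed column
frame, and compared against every reference specimen by K2P distance
under pairwise deletion.  Hits are ranked by distance and an assignment
rule turns them into a species call: a single species within the
threshold neighbourhood of the best hit gives a species assignment,
several give a species-group assignment (the honest answer when
barcodes cannot separate close species), and no hit within the
threshold gives "no-match".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Seq import Seq

from barcodeaudit.dataio import BarcodeAlignment, Dataset
from barcodeaudit.distances import count_site_classes, k2p

#: Fallback assignment threshold (proportion) when no barcode gap was
#: detected: the conventional 1.5% cutoff below which interspecific
#: divergence is considered exceptionally low.
DEFAULT_THRESHOLD = 0.015

#: Minimum number of reference columns a query must align to.
MIN_MATCHED_COLUMNS = 100


class UnalignableError(ValueError):
    """Query could not be aligned to the reference frame."""


@dataclass
class Hit:
    specimen_id: str
    species: str
    distance: float      # K2P proportion
    similarity: float    # percent, 100 * (1 - raw mismatch proportion)


@dataclass
class IdentificationResult:
    query_id: str
    hits: list[Hit]
    assignment: str | list[str]   # species, species-group list, or "no-match"
    threshold_used: float


def consensus_sequence(alignment: BarcodeAlignment) -> str:
    """Majority unambiguous base per column; ties broken alphabetically.

    Columns with no unambiguous base at all become 'N'.
    """
    cons = []
    codes = alignment.codes
    for col in range(alignment.columns):
        counts = np.bincount(codes[:, col][codes[:, col] != 255], minlength=4)
        if counts.sum() == 0:
            cons.append("N")
        else:
            cons.append("ACGT"[int(np.argmax(counts))])  # argmax -> first max
    return "".join(cons)


def _make_aligner(
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    # free end gaps so partial fragments and overhangs are not penalised
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older PairwiseAligner attribute names
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def _project(alignment_obj, width: int) -> tuple[str, int]:
    """Project an aligned query onto the reference column frame.

    Returns the projected row (gaps where the query is absent; query
    insertions relative to the consensus dropped) and the number of
    reference columns covered by query bases.
    """
    target_idx = 0
    out = ["-"] * width
    covered = 0
    t_aln, q_aln = alignment_obj[0], alignment_obj[1]
    for t_ch, q_ch in zip(t_aln, q_aln):
        if t_ch == "-":
            continue  # insertion in query relative to frame: dropped
        if q_ch != "-":
            out[target_idx] = q_ch
            covered += 1
        target_idx += 1
    return "".join(out), covered


def align_query(
    query_seq: str,
    reference_alignment: BarcodeAlignment,
    auto_reverse_complement: bool = False,
    min_matched_columns: int = MIN_MATCHED_COLUMNS,
) -> str:
    """Globally align a raw query to the reference frame.

    The query is aligned against the majority consensus of the
    reference alignment and projected onto its fixed columns; positions
    the query does not cover become '-', which pairwise deletion then
    excludes.  With ``auto_reverse_complement`` both orientations are
    tried and the higher-scoring one kept.
    """
    query = query_seq.upper().replace("U", "T")
    width = reference_alignment.columns
    if len(query) > width + 100:
        raise UnalignableError(
            f"query length {len(query)} exceeds reference width {width} + 100"
        )
    consensus = consensus_sequence(reference_alignment)
    aligner = _make_aligner()
    candidates = [query]
    if auto_reverse_complement:
        candidates.append(str(Seq(query).reverse_complement()))
    best_row: str | None = None
    best_covered = -1
    best_score = -math.inf
    for cand in candidates:
        aln = aligner.align(consensus, cand)
        top = aln[0]
        row, covered = _project(top, width)
        if top.score > best_score:
            best_score = top.score
            best_row, best_covered = row, covered
    matched = count_site_classes(best_row, consensus).n_compared
    if matched < min_matched_columns:
        raise UnalignableError(
            f"query aligns with only {matched} matched columns "
            f"(minimum {min_matched_columns}); wrong orientation or not a barcode?"
        )
    return best_row


def rank_hits(
    aligned_query: str, dataset: Dataset, k: int = 10
) -> list[Hit]:
    """K2P distance from the query to every reference specimen, top-k.

    Ties in distance are ordered by specimen id so rankings are
    deterministic.  Similarity is the uncorrected percent identity over
    compared columns.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    from barcodeaudit.dataio import _ENCODE
    from barcodeaudit.distances import k2p_from_counts_arrays

    q = _ENCODE[
        np.frombuffer(aligned_query.upper().encode("ascii"), dtype=np.uint8)
    ]
    codes = dataset.alignment.codes
    valid = (codes != 255) & (q != 255)
    diff = (codes != q) & valid
    ts = diff & ((codes & 1) == (q & 1))
    comp = valid.sum(axis=1)
    n_ts = ts.sum(axis=1)
    n_tv = (diff & ~ts).sum(axis=1)
    d, defined_mask, _ = k2p_from_counts_arrays(comp, n_ts, n_tv)
    with np.errstate(invalid="ignore"):
        sim = np.where(
            comp > 0, 100.0 * (1.0 - (n_ts + n_tv) / np.maximum(comp, 1)), np.nan
        )
    hits = [
        Hit(sid, rec.species, float(d[i]), float(sim[i]))
        for i, (sid, rec) in enumerate(zip(dataset.alignment.ids, dataset.records))
        if defined_mask[i]
    ]
    hits.sort(key=lambda h: (h.distance, h.specimen_id))
    return hits[:k]


def assign(
    hits: Sequence[Hit], threshold: float = DEFAULT_THRESHOLD
) -> str | list[str]:
    """Turn ranked hits into a species / species-group / no-match call.

    If the best distance exceeds the threshold the call is "no-match".
    Otherwise every species whose hit lies within ``threshold`` of the
    best distance joins the candidate set: one candidate gives a
    species assignment, several give a sorted species-group list.
    """
    if not hits:
        raise ValueError("hits must be non-empty")
    best = hits[0].distance
    if best > threshold:
        return "no-match"
    species = sorted({h.species for h in hits if h.distance <= best + threshold})
    return species[0] if len(species) == 1 else species


def identify_queries(
    queries: BarcodeAlignment | list[tuple[str, str]],
    dataset: Dataset,
    k: int = 10,
    threshold: float = DEFAULT_THRESHOLD,
    auto_reverse_complement: bool = False,
) -> list[IdentificationResult]:
    """Identify each query sequence against the reference dataset.

    ``queries`` is either an aligned block in the reference frame or a
    list of (id, raw sequence) pairs, which are aligned first.
    """
    if isinstance(queries, BarcodeAlignment):
        items = list(zip(queries.ids, queries.rows))
        prealigned = queries.columns == dataset.alignment.columns
    else:
        items = list(queries)
        prealigned = False
    results = []
    for qid, seq in items:
        if prealigned:
            row = seq
        else:
            row = align_query(
                seq, dataset.alignment, auto_reverse_complement=auto_reverse_complement
            )
        hits = rank_hits(row, dataset, k=k)
        call = assign(hits, threshold=threshold) if hits else "no-match"
        results.append(
            IdentificationResult(
                query_id=qid, hits=hits, assignment=call, threshold_used=threshold
            )
        )
    return results
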
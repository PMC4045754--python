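"""Reading, validation and reporting for barcode libraries.

A library consists of two files: a FASTA of pre-aligned, equal-length
nucleotide sequences (one row per specimen) and a TSV metadata table
carrying at least ``specimen_id``, ``species`` and ``genus`` columns.
The two are joined on specimen id into a :class:`Dataset`, the container
every downstream stage consumes.

Sequences must already be aligned: the toolkit audits a fixed-width
barcode fragment (classically the 658-bp 5' COI region) and performs no
multiple sequence alignment itself.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# Allowed residues: canonical bases, IUPAC ambiguity codes, N and the gap
# character.  'U' is accepted on input and canonicalised to 'T'.
ALPHABET = frozenset("ACGTRYSWKMBDHVN-")

# Encoding used by the numeric distance kernel: A,C,G,T -> 0..3, everything
# else (ambiguity, N, gap) -> 255, excluded per pair by pairwise deletion.
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i


class AlignmentWidthError(ValueError):
    """Rows of an alignment do not all share the same length."""


class AlphabetError(ValueError):
    """A sequence contains a character outside the IUPAC alphabet."""


class SchemaError(ValueError):
    """A metadata table is missing a mandatory column."""


class UniquenessError(ValueError):
    """Duplicate specimen ids within one source."""


class JoinError(ValueError):
    """Alignment and metadata specimen ids do not match exactly."""


@dataclass(frozen=True)
class SpecimenRecord:
    """One barcoded individual with its taxonomy and collection metadata.

    ``species`` is either a binomial ("Aphis fabae") or a placeholder of
    the form ``"sp. <code>"`` for specimens identified only to genus;
    placeholders are treated as distinct species and never merged.
    """

    specimen_id: str
    species: str
    genus: str
    subfamily: str | None = None
    host_plant: str | None = None
    country: str | None = None
    extra: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.specimen_id:
            raise ValueError("specimen_id must be non-empty")
        if not self.species or not self.genus:
            raise ValueError(
                f"specimen {self.specimen_id!r}: species and genus must be non-empty"
            )


class BarcodeAlignment:
    """Fixed-width nucleotide matrix over specimens.

    Rows are stored as uppercase strings over the IUPAC alphabet; a
    parallel ``uint8`` code matrix (A,C,G,T -> 0..3, other -> 255) is
    kept for the distance kernel.
    """

    def __init__(self, ids: Sequence[str], rows: Sequence[str]):
        ids = list(ids)
        if len(ids) != len(rows):
            raise ValueError("ids and rows must have equal length")
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise UniquenessError(f"duplicate specimen ids: {dupes}")
        clean: list[str] = []
        width: int | None = None
        for row_idx, (sid, raw) in enumerate(zip(ids, rows)):
            seq = raw.upper().replace("U", "T")
            if width is None:
                width = len(seq)
            elif len(seq) != width:
                raise AlignmentWidthError(
                    f"row {sid!r} has length {len(seq)}, expected {width}"
                )
            for col, ch in enumerate(seq):
                if ch not in ALPHABET:
                    raise AlphabetError(
                        f"illegal character {ch!r} in row {sid!r} "
                        f"(row {row_idx}, column {col})"
                    )
            clean.append(seq)
        self.ids: list[str] = ids
        self.rows: list[str] = clean
        self.columns: int = width if width is not None else 0
        if clean:
            buf = np.frombuffer(
                "".join(clean).encode("ascii"), dtype=np.uint8
            ).reshape(len(clean), self.columns)
            self.codes: np.ndarray = _ENCODE[buf]
        else:
            self.codes = np.empty((0, 0), dtype=np.uint8)
        self._index = {sid: i for i, sid in enumerate(ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def row(self, specimen_id: str) -> str:
        return self.rows[self._index[specimen_id]]

    def subset(self, keep_ids: Iterable[str]) -> "BarcodeAlignment":
        keep = set(keep_ids)
        pairs = [(i, r) for i, r in zip(self.ids, self.rows) if i in keep]
        missing = keep - {i for i, _ in pairs}
        if missing:
            raise KeyError(f"unknown specimen ids: {sorted(missing)}")
        return BarcodeAlignment([i for i, _ in pairs], [r for _, r in pairs])


@dataclass
class Dataset:
    """A barcode alignment joined with one metadata record per row."""

    alignment: BarcodeAlignment
    records: list[SpecimenRecord]

    def __post_init__(self) -> None:
        if len(self.records) != len(self.alignment):
            raise JoinError("one record per alignment row required")
        by_id = {r.specimen_id: r for r in self.records}
        if set(by_id) != set(self.alignment.ids):
            raise JoinError("record ids do not match alignment ids")
        # records follow alignment row order
        self.records = [by_id[sid] for sid in self.alignment.ids]
        self._by_id = {r.specimen_id: r for r in self.records}

    def record(self, specimen_id: str) -> SpecimenRecord:
        return self._by_id[specimen_id]

    @property
    def species(self) -> list[str]:
        return [r.species for r in self.records]

    @property
    def genera(self) -> list[str]:
        return [r.genus for r in self.records]

    @property
    def n_specimens(self) -> int:
        return len(self.records)

    @property
    def n_species(self) -> int:
        return len(set(self.species))

    @property
    def n_genera(self) -> int:
        return len(set(self.genera))

    def counts(self) -> dict[str, int]:
        """Specimen / species / genus totals, the library's headline sizes."""
        return {
            "specimens": self.n_specimens,
            "species": self.n_species,
            "genera": self.n_genera,
        }

    def subset(self, keep_ids: Iterable[str]) -> "Dataset":
        keep = set(keep_ids)
        return Dataset(
            self.alignment.subset(keep),
            [r for r in self.records if r.specimen_id in keep],
        )


def read_fasta(path: str | Path) -> BarcodeAlignment:
    """Read an aligned FASTA into a :class:`BarcodeAlignment`.

    The first whitespace-delimited token of each header is the specimen
    id.  Rows must be equal length; characters outside the IUPAC
    alphabet raise :class:`AlphabetError` naming the row and column.
    """
    ids: list[str] = []
    rows: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq))
    return BarcodeAlignment(ids, rows)


def write_fasta(alignment: BarcodeAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(alignment.ids, alignment.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


_MANDATORY = ("specimen_id", "species", "genus")
_OPTIONAL = ("subfamily", "host_plant", "country")


def read_metadata(path: str | Path, sep: str = "\t") -> list[SpecimenRecord]:
    """Read a delimited metadata table (TSV by default).

    Mandatory columns: ``specimen_id``, ``species``, ``genus``.  Known
    optional columns are mapped onto record fields; any further columns
    are preserved in ``record.extra``.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(f"metadata missing mandatory columns: {missing}")
    dupes = df["specimen_id"][df["specimen_id"].duplicated()].tolist()
    if dupes:
        raise UniquenessError(f"duplicate specimen ids in metadata: {sorted(set(dupes))}")
    extra_cols = [c for c in df.columns if c not in _MANDATORY + _OPTIONAL]
    records = []
    for rowd in df.to_dict("records"):
        records.append(
            SpecimenRecord(
                specimen_id=rowd["specimen_id"],
                species=rowd["species"],
                genus=rowd["genus"],
                subfamily=rowd.get("subfamily") or None,
                host_plant=rowd.get("host_plant") or None,
                country=rowd.get("country") or None,
                extra={c: rowd[c] for c in extra_cols},
            )
        )
    return records


def write_metadata(records: Sequence[SpecimenRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        d = {
            "specimen_id": r.specimen_id,
            "species": r.species,
            "genus": r.genus,
            "subfamily": r.subfamily or "",
            "host_plant": r.host_plant or "",
            "country": r.country or "",
        }
        d.update(r.extra)
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def bind(alignment: BarcodeAlignment, records: Sequence[SpecimenRecord]) -> Dataset:
    """Join an alignment with metadata records on specimen id.

    Ids must match exactly in both directions; offenders on either side
    are listed in the raised :class:`JoinError`.
    """
    align_ids = set(alignment.ids)
    meta_ids = {r.specimen_id for r in records}
    if len(meta_ids) != len(records):
        seen: set[str] = set()
        dupes = sorted(
            {r.specimen_id for r in records if r.specimen_id in seen or seen.add(r.specimen_id)}
        )
        raise UniquenessError(f"duplicate specimen ids in metadata: {dupes}")
    only_align = sorted(align_ids - meta_ids)
    only_meta = sorted(meta_ids - align_ids)
    if only_align or only_meta:
        raise JoinError(
            f"id mismatch between alignment and metadata: "
            f"alignment-only={only_align}, metadata-only={only_meta}"
        )
    return Dataset(alignment, list(records))


def _sort_key(dataset: Dataset, specimen_id: str) -> tuple[str, str, str]:
    r = dataset.record(specimen_id)
    return (r.genus, r.species, r.specimen_id)


def write_report(
    tables: Mapping[str, pd.DataFrame],
    trees: Mapping[str, str],
    path_prefix: str | Path,
) -> list[Path]:
    """Write report tables (TSV) and newick trees deterministically.

    Tables with ``genus``/``species``/``specimen_id`` columns are sorted
    on those columns so repeated runs produce byte-identical files.
    Returns the list of files written.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, df in tables.items():
        sort_cols = [c for c in ("genus", "species", "specimen_id") if c in df.columns]
        if sort_cols:
            df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
        out = Path(f"{prefix}.{name}.tsv")
        buf = io.StringIO()
        df.to_csv(buf, sep="\t", index=False, lineterminator="\n")
        out.write_text(buf.getvalue())
        written.append(out)
    for name, newick in trees.items():
        out = Path(f"{prefix}.{name}.nwk")
        out.write_text(newick if newick.endswith("\n") else newick + "\n")
        written.append(out)
    return written
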
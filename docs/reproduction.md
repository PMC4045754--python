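# Reproducing the full-scale reference-library audit

The package's tests and acceptance script run on synthetic libraries
generated at run time.  The full-scale audit targets a real curated
reference library of European aphid COI barcodes: 1020 specimens, 274
species, 87 genera, 658 aligned columns.  Those files are too large to
ship inside this repository and must be fetched once.

## Obtaining the data

1. Download the nucleotide records for GenBank accessions
   KF638720–KF639739 (1020 sequences) in FASTA format, e.g. with EDirect:

       efetch -db nuccore -id KF638720:KF639739 -format fasta > raw.fasta

2. Obtain the specimen taxonomy (specimen id, species, genus, and
   optionally subfamily, host plant, country).  It is distributed with
   the library's BOLD project ("ACEA") and in the supplementary tables
   of the originating survey.  Format it as a TSV with a header row
   containing at least `specimen_id`, `species`, `genus`.

3. Align the sequences to the standard 658-column COI frame (they have
   no length variation; mafft with `--keeplength` against any complete
   record suffices) and name each FASTA record by its specimen id.
   Four records are incomplete at the 5' or 3' end; pad them with
   leading/trailing `N` or `-` to 658 columns — pairwise deletion
   excludes those columns per pair, so padding choice only affects
   those four specimens' effective overlap.

4. Place the files at `data/reference/library.fasta` and
   `data/reference/library.tsv`.

## Running

    barcodeaudit audit \
        --fasta data/reference/library.fasta \
        --metadata data/reference/library.tsv \
        --out results/reference --seed 1

and the haplotype-diversity variant with `audit-dedup`.  The dedicated
test `tests/test_acceptance.py::test_full_reference_library_reproduction`
runs the headline checks automatically once the files are present.

## What to expect, and known caveats

Headline statistics of this library reported by its curators: mean
intraspecific K2P divergence 0.29% (range 0–3.9%), congeneric 6.4%,
intergeneric 9.8%; 457 haplotypes among 1020 barcodes; an imperfect
barcode gap between 0.7% and 2.6% after outlier trimming; 77.8% of
multi-specimen species monophyletic on the NJ tree; 41 species with
Max-WSD >= Min-BSD, 39 of them falling into 14 poorly discriminated
clades.

Two caveats when comparing:

- The published pair counts are internally inconsistent: 8205
  intraspecific + 515571 interspecific = 523776, but C(1020,2) =
  519690.  This pipeline reports its own computed counts and does not
  force a reconciliation.
- The monophyly percentage is sensitive to NJ tie-breaking and to how
  the four incomplete sequences are padded; agreement within ±2
  species of the printed percentage should be considered a successful
  reproduction.
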
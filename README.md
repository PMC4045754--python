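# barcodeaudit

Audit toolkit for DNA-barcode reference libraries, built for curators
and users of COI barcode collections (the standard 658-bp 5' fragment
of mitochondrial cytochrome c oxidase I) who need to know *where* in a
library sequence-based identification can be trusted — and for
identifying query sequences against such a library.

## What it computes

Given an aligned barcode FASTA plus a specimen metadata table
(specimen id, species, genus, ...), the audit runs:

- **K2P distances under pairwise deletion.**  For each specimen pair,
  with P and Q the transition and transversion difference proportions
  over columns where both sequences have an unambiguous base,

      d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

  Saturated or non-overlapping pairs are flagged undefined, never
  zeroed.
- **Haplotype analysis.**  Exact-identity collapsing (detecting
  haplotypes shared between species), permutation-based accumulation
  curves, and a haplotype-diversity mode keeping at most two specimens
  per (species, haplotype).
- **Divergence classes and the barcode gap.**  Intraspecific /
  congeneric / intergeneric summaries with 2.5/97.5-percentile
  whiskers and outliers; gap detection after outlier trimming with a
  suggested assignment threshold.
- **Max-WSD / Min-BSD diagnostics.**  A species fails when its maximum
  within-species divergence reaches its minimum divergence to another
  species — the condition under which nearest-neighbour identification
  can mislead.
- **NJ tree, bootstrap, monophyly, problem clades.**  Deterministic
  neighbor joining, column-bootstrap node supports, species-monophyly
  census via unrooted bipartitions, and grouping of failing species
  into poorly discriminated clades with their tree support.
- **Query identification.**  Consensus-anchored alignment of raw query
  sequences into the library frame, ranked K2P hits, and a species /
  species-group / no-match call.
- **Synthetic libraries.**  A hierarchical K80 simulator with known
  truth (class means, monophyly, engineered haplotype sharing) so the
  whole pipeline is testable without any downloads.

## Worked example

Simulate a library with deliberately confusable species (each
congeneric species pair shares a haplotype with probability 0.2), then
audit it:

```python
from barcodeaudit.synthetic_data import SimConfig, simulate
from barcodeaudit.pipeline import RunConfig, run_audit

ds, truth = simulate(SimConfig(seed=1, p_share=0.2))
bundle = run_audit(RunConfig(bootstrap_reps=100, output_prefix="demo"),
                   dataset=ds)
```

This prints nothing; the numbers live in the bundle and the `demo.*`
report files:

    specimens: 61  species: 20  genera: 5
    intraspecific: n=88   mean=1.12%  max=8.23%
    congeneric:    n=275  mean=6.34%  max=8.95%
    intergeneric:  n=1467 mean=9.25%  max=12.21%
    gap exists: False
    flagged: ['Genus01 species01', 'Genus01 species03', 'Genus04 species01',
              'Genus04 species02', 'Genus04 species03', 'Genus04 species04']
    monophyletic %: 57.1
    clade A ['Genus01 species01', 'Genus01 species03']  support 95   min_bsd_mean 2.89%
    clade B ['Genus04 species01', ..., 'Genus04 species04']  support 100  min_bsd_mean 0.00%

Reading it: the engineered haplotype sharing drags the intraspecific
maximum (8.23%) far past the smallest interspecific distances, so no
barcode gap exists; exactly the six species given shared haplotypes
are flagged; they fall into two problem clades whose internal
species-to-species minimum distances (0–2.89% mean) sit inside the
intraspecific range, and only 57% of multi-specimen species remain
monophyletic.  Rerun with `p_share=0` and the library is clean: a gap
appears, no species is flagged, and monophyly is 100%.

The same audit is available from the shell:

    barcodeaudit simulate --out lib --seed 1 --p-share 0.2
    barcodeaudit audit --fasta lib.fasta --metadata lib.tsv --out demo --seed 1
    barcodeaudit identify --library lib.fasta --metadata lib.tsv --query q.fasta

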
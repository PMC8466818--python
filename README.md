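# cansynth

Tools for analyzing the *cannabinoid synthase* gene family of *Cannabis
sativa*.  The three synthases — THCAS, CBDAS and CBCAS, which convert the
common precursor CBGA into THCA, CBDA and CBCA — are near-identical
single-exon paralogs (≈84–96% identity between classes, >99% within a class),
so telling them apart hinges on a handful of clade-fixed diagnostic SNPs.
`cansynth` is for molecular breeders and plant geneticists who need to:

* classify cloned or assembled coding sequences into gene classes
  (CBCAS / THCAS / CBDAS) from diagnostic positions — e.g. cds positions 13,
  18 and 1628 separate CBCAS from THCAS;
* call chemotype-associated marker genotypes (the B-locus multiplex whose
  1080/1081-bp band marks a functional CBDAS, B_D, and whose 1192-bp band
  marks a functional THCAS, B_T) by in-silico PCR;
* annotate SNPs and amino-acid substitutions against a reference cds,
  including the activity-critical residues Arg110–His114 and Cys176;
* build neighbor-joining trees with bootstrap support from co-linear cds
  (p-distance, JC69 or TN93 with pairwise deletion);
* quantify transcripts by RT-qPCR with the standard-curve method:
  `E = 10^(−1/slope) − 1`, per-replicate normalization to the geometric mean
  of reference-gene quantities (RQ), reference-gene stability ranking, and
  Student's t-tests against a baseline genotype.

Because the original plant material and clones are not required, a
first-class synthetic-data module generates gene-family panels and qPCR
plates with known ground truth (seeded, byte-reproducible), which is also how
the test suite exercises every stage end to end.

## Worked example

Simulate a two-clade family (10 CBCAS-like + 10 THCAS-like sequences, 3–8
private SNPs each) and type it:

```sh
$ cansynth simulate family --seed 42 --out-dir sim
wrote 20 sequences to sim
$ cansynth type-seqs sim/family.fasta --profiles sim/profiles.yaml --out-dir typed
20 records; 20 complete cds; 20 assigned, 0 unknown; 20 unique sequences
```

`typed/clade_calls.tsv` holds one call per complete cds:

```
query_id   assigned  identity_CBCAS  identity_THCAS  diag_match_CBCAS  diag_match_THCAS
CBCAS_001  CBCAS     99.69           99.51           1.0               0.0
CBCAS_002  CBCAS     99.63           99.45           1.0               0.0
CBCAS_003  CBCAS     99.82           99.63           1.0               0.0
```

A sequence is assigned to a clade only when *all* diagnostic alleles match
and identity to the clade reference is ≥97% — here CBCAS_003 sits 99.82% from
its clade reference (3 private SNPs over 1638 nt) but only 99.63% from the
THCAS reference, and its three diagnostic alleles exclude THCAS outright.

Simulate a qPCR plate for the 13 study genotypes and quantify:

```sh
$ cansynth simulate plate --seed 7 --out-dir qsim
wrote 732 wells to qsim/plate.csv
$ cansynth qpcr qsim/plate.csv --targets THCAS,CBDAS,CBCAS \
    --references CsClathrin,CsRAN --baseline CINRO --out-dir quant
curves for 6 gene(s); RQ for 3 target(s) written to quant
```

The THCAS rows of `quant/rq.csv`:

```
genotype   rq         sem       stars
CINBOL     15.488764  0.349931  ***
CINRO      1.191533   0.032647
Ermo       n.d.
...(all hemp genotypes n.d.)
```

THCAS transcription is detected only in the two drug-type varieties, roughly
13× higher in the chemotype-I genotype than in the chemotype-II baseline
(p < 0.001, pooled t-test on log RQ); hemp genotypes, which lack a functional
THCAS, are reported `n.d.`.  This is the generated plate's ground-truth
pattern recovered through the full pipeline: standard curves → Cq
interpolation → geometric-mean normalization → per-genotype means ± SEM →
significance stars.

Other subcommands: `cansynth genotype` (multiplex marker calls per genotype),
`cansynth insilico-pcr` (amplicon prediction for primer pairs), `cansynth
phylo` (NJ tree with optional bootstrap, Newick out).  Every run writes a
`manifest.json` with the inputs, parameters and seed needed to reproduce it.

## Layout

```
src/cansynth/
  seq.py       records, FASTA I/O, ORF scan, cds classification, translation
  variants.py  SNP calling, percent identity, substitution effects, critical residues
  clades.py    diagnostic-position discovery, clade classification, inventories
  pcr.py       binding sites, product prediction, marker calls, specificity
  phylo.py     distances, neighbor joining, bootstrap, Newick I/O
  qpcr.py      standard curves, stability ranking, RQ, significance
  simulate.py  gene-family / plate / panel generators with ground truth
  cli.py       `cansynth` command-line interface
```

See `docs/methods.md` for the models, defaults and their rationale.
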
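# unisearch

Desk-scale de Bruijn graph assembly and accession-wide k-mer search.

Petabase-scale sequence repositories are made explorable by assembling
every sequencing dataset ("accession") into unitigs and contigs, then
indexing the unitig k-mer content so that any short query sequence can be
located across millions of accessions in seconds. `unisearch` implements
that whole pipeline faithfully at a scale that fits on one machine, so
the algorithms — not the cloud plumbing — can be studied, tested and
reused:

* **Unitigs** — maximal non-branching paths of the reads de Bruijn graph
  (k = 31 by default; nodes are canonical k-mers seen ≥ 2 times, edges
  are (k−1)-overlaps witnessed by a (k+1)-mer in the reads). Near-lossless:
  every solid k-mer appears in exactly one unitig, exactly once.
* **Abundances** — per-k-mer coverage estimated from (k+1)-mer counts
  (sum over containing (k+1)-mers, divided by two) and stored through an
  8-bit codec with ≤ 5% relative error and saturation at 50,000; unitig
  headers carry the mean.
* **Contigs** — unitigs after conservative SPAdes-style simplification
  (tip clipping, bubble popping onto the major allele, weak-link
  removal), with circular contigs detected by their terminal
  (k−1)-mer duplication and optionally trimmed.
* **Search** — one Bloom filter per accession over canonical s-mers
  (s = k − z), queried with the Findere composition (a k-mer is present
  iff all z+1 of its s-mers are) so the effective per-k-mer
  false-positive rate meets a 0.005% target; a query returns every
  accession containing at least a user-set fraction of its k-mers.
* **Formats** — BCALM2-style FASTA link headers (`L:+:12:-`), GFA 1.0
  export, gzip-transparent FASTQ/FASTA, N50/assembly statistics.

A seeded simulator (genomes, error-bearing reads, SNP haplotypes) plus a
brute-force string-based assembly oracle make every stage testable with
no downloads.

## Worked example

Assemble a simulated 3 kb circular genome sequenced at 30× with 0.5%
substitution errors, then index and search it:

```
$ unisearch simulate --genome-length 3000 --circular --coverage 30 \
    --error-rate 0.005 --seed 7 -o reads.fq.gz --genome-out genome.fa
[unisearch] wrote 900 reads (90000 bp) to reads.fq.gz

$ unisearch assemble reads.fq.gz -k 21 -o unitigs.fa --gfa unitigs.gfa
[unisearch] 35 unitigs, 3895 bp -> unitigs.fa

$ unisearch contig unitigs.fa -k 21 --trim-circular -o contigs.fa
[unisearch] 1 contigs -> contigs.fa

$ head -1 contigs.fa
>0 LN:i:3000 km:f:21.70 L:+:0:+ L:-:0:- circ:Z:true tr:i:20
```

The 35 unitigs (3,895 bp — the genome plus error-induced branches)
simplify to a single contig. Its self-links (`L:+:0:+ L:-:0:-`) mark the
path closing onto itself: the molecule is circular (`circ:Z:true`), the
duplicated terminal 20-mer has been trimmed (`tr:i:20`), and the
recovered length is exactly the simulated 3,000 bp. `km:f:21.70` is the
mean k-mer coverage — below the nominal 30× because a k-mer is only as
covered as the error-free reads that span all 21 of its bases.

```
$ unisearch index unitigs.fa --accession DEMO1 -o demo.usix
[unisearch] indexed DEMO1: 2965 distinct s-mers

$ unisearch search demo.usix query.fa --threshold 0.5   # 300 bp of the genome
query   accession  fraction  n_found  n_total  metadata
q0      DEMO1      0.9259    250      270
```

250 of the query's 270 k-mers are found in the accession: the remainder
fall in a stretch whose k-mers were lost to the singleton filter, which
is exactly the kind of partial hit the coverage-fraction semantics are
designed to report. `unisearch stats unitigs.fa contigs.fa` prints
per-file N50, total length, longest sequence and raw/compressed sizes;
`unisearch extract` retrieves the exact unitigs sharing k-mers with a
query.

## Layout

```
src/unisearch/
  kmer.py      canonical k-mer codes, scanning, exact counting
  codec.py     8-bit abundance quantisation
  assembly.py  compacted de Bruijn graph (unitigs, links, abundances)
  simplify.py  tips/bubbles/weak links, circularity, trimming, emission
  seq_io.py    FASTA/FASTQ/GFA/stats I/O
  index.py     Bloom filters, Findere queries, accession search
  sim.py       seeded simulators and the brute-force oracle
  cli.py       the `unisearch` command
```

See `docs/methods.md` for the model, parameter choices and limitations.
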
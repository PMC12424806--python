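# Methods

## The graph model

All computation is over canonical k-mers: a k-mer and its reverse
complement are one object, represented by the numerically smaller 2-bit
packing (A=0, C=1, G=2, T=3, most significant base first). k defaults to
31 and is capped there so codes fit one 64-bit word; k must be odd
unless explicitly overridden, which guarantees no k-mer equals its own
reverse complement and removes palindrome special-casing from the graph
walk.

The assembly graph is the **reads de Bruijn graph**: nodes are canonical
k-mers occurring at least `min_count` (default 2) times — k-mers seen
once in an accession are discarded as probable errors — and an edge
between two k-mers exists only when the (k+1)-mer spelling their overlap
occurs in the reads. This edge-witnessed definition matches how
edge-centric compaction tools (BCALM2, Cuttlefish2) construct the graph,
and it matters: defining edges by mere (k−1)-overlap admits
repeat-induced and hairpin edges the data never supports, which at small
k visibly fragments unitigs. `build_compacted_graph` accepts the
witnessed-edge set and falls back to overlap probing only when none is
supplied.

Unitigs are maximal non-branching paths under mutual-unique extension;
each solid canonical k-mer lands in exactly one unitig exactly once (a
tested invariant). Output is deterministic: walks start from the
smallest unvisited canonical code, records are ordered by (length
descending, sequence ascending), and each unitig is stored on its
lexicographically smaller strand. Links are recorded BCALM2-style
(`L:<from-orient>:<to-id>:<to-orient>`) and exported to GFA 1.0 with
`(k−1)M` overlaps.

## Abundance estimation and the 8-bit codec

Per-k-mer abundance is approximated from (k+1)-mer counts: the counts of
all distinct canonical (k+1)-mers containing the k-mer as prefix or
suffix on either strand are summed and divided by two. A read-internal
occurrence contributes two (k+1)-mers, so the halving cancels and the
estimator converges on the k-mer read coverage; occurrences at read ends
contribute one, giving a half-count per end. Quantitatively the
estimator measures k-mer coverage, which for base coverage c, read
length `rl` and word length k is `c·(rl−k+1)/rl` — about 0.8c at
rl=100, k=21, and within 10% of c only once rl ≳ 10k. Tests assert the
exact expectation and, separately, the within-10% regime at long read
length.

Each per-k-mer value passes through an 8-bit codec before averaging over
the unitig, mirroring construction-time storage. The codec is a hybrid
ladder: code 0 ↔ count 0; codes 1..64 store counts exactly (small counts
drive the singleton filter and low-coverage estimates, where relative
error is the wrong guarantee); codes 65..255 are a geometric ladder from
64 to the saturation ceiling 50,000, integer-rounded and forced strictly
increasing, with the top code decoding to exactly 50,000. The step ratio
(50,000/64)^(1/191) ≈ 1.036 bounds worst-case round-trip error at ~2%,
comfortably inside the 5% contract; the bound is verified by exhaustive
sweep over all 50,000 counts, and counts at or above the ceiling encode
to the top code.

## Simplification into contigs

Three conservative passes alternate (default up to 10 rounds),
recompacting the unitig graph after each, until a fixpoint:

* **Tips** — a node with exactly one dead end, length ≤ 2.5·k nt, and
  mean abundance below its through-neighbour's is deleted. Isolated
  nodes (two dead ends) are never tips.
* **Bubbles** — two single-node arms joining the same pair of incidences
  with path-length difference ≤ 3 nt: the minor arm is removed when
  minor/major mean abundance ≤ 0.5 (ties broken toward the
  lexicographically smaller canonical sequence). Superbubbles are out of
  scope.
* **Weak links** — a junction link is cut when the weaker flank's mean
  abundance is strictly below 0.1× the stronger's *and* at least one of
  the link's two incidences has another link (a plain bridge between two
  degree-1 ends is never cut — removing it could only disconnect the
  graph, and a chimeric join always leaves an alternative continuation
  at its junction).

All thresholds are deliberate inventions in the conservative register of
short-read practice — the upstream tools publish the heuristic family,
not values — and every one is exposed on `SimplifyParams` and as a CLI
flag. Node merges concatenate sequences over the (k−1) overlap and add
abundance sums, so a merged contig's mean is the k-mer-weighted mean of
its parts.

**Circularity.** A contig assembled from a circular molecule closes onto
itself: it carries a 3′→5′ self-link and its sequence ends with its own
first (k−1) bases. Circular contigs are emitted untrimmed with a
`circ:Z:true` tag; trimming is a separate explicit step that removes the
largest terminal repeat r (r_min ≤ r ≤ len/2, prefix = suffix),
restoring the exact molecule length. A companion screen flags circular
candidates whose terminal repeat is > 50% covered by exact tandem runs
of period ≤ 5 spanning ≥ 8 bases — such "circles" are usually
low-complexity artefacts, not replicons. The tandem-run definition is
this package's own concrete reading of a low-complexity screen whose
published description names only the rule, not the measure.

**Emission.** Default: a contig is discarded iff it is non-circular,
shorter than 150 bp *and* isolated. Strict mode (`--strict-emission`)
keeps only contigs longer than 150 bp that are connected to at least one
other contig; a circular self-link counts as connected, since a
complete small replicon is the opposite of an artefactual fragment. The
two formulations genuinely differ (a long isolated linear contig
survives only the default rule); both appear in the pipeline this
mirrors, so both are implemented with the permissive one as default.

## The accession index

Each accession's unitigs are indexed by their distinct canonical s-mers,
s = k − z (default 31 − 3 = 28), in one Bloom filter sized by the
standard optimum `m = ⌈−n·ln p/(ln 2)²⌉`, `h = round(ln 2·m/n)`. The
per-s-mer rate is `p = target^(1/(z+1))` so that the Findere composition
— a k-mer answers present iff all z+1 constituent s-mers do — meets the
per-k-mer target of 0.005% (5×10⁻⁵): a random absent k-mer needs z+1
near-independent false positives to slip through. Two consequences are
tested: no false negatives ever (every indexed k-mer answers true), and
the effective k-mer rate never exceeds the raw s-mer rate. Construction
false positives (phantom k-mers assembled from true s-mers of different
contexts) are included in the measured rate. Integer rounding of h
leaves the realised per-s-mer rate a percent or two off the nominal
optimum, so the composed rate lands near, not exactly on, the target;
the acceptance check therefore accepts the target within three binomial
standard deviations of the two-million-probe measurement.

Hashing is splitmix64 double hashing with fixed seeds recorded in the
index container, so index bytes and query results are reproducible
bit-for-bit. The container is a versioned binary: magic bytes, a JSON
header echoing the full spec and per-accession metadata manifest, then
the raw bitsets; truncation or version mismatch fails loudly.

Queries score each accession by the fraction of the query's valid k-mer
windows found; the threshold is user-set and required — there is no
defensible universal default, so the CLI refuses to invent one. Queries
above 1,000 nt are refused unless explicitly allowed (long queries make
the fraction statistic progressively less interpretable). Exact
matching-sequence retrieval (`extract`) bypasses the filters and
intersects canonical k-mer sets directly.

## The simulator and what passing tests mean

`sim.py` generates i.i.d. genomes at a chosen GC, optionally rejection
re-sampled until all k-mers are unique (the clean single-unitig regime),
and uniform-coverage substitution-error reads. For linear genomes, read
starts range over `[1−rl, L−1]` with truncation at both boundaries:
this keeps expected coverage uniform across the whole genome, whereas
interior-only starts would ramp coverage to near zero over the last read
length and make exact end recovery impossible for any assembler.
Circular genomes wrap reads across the origin. Defaults (5 kb genomes,
30× coverage, 100 bp reads, substitution-only errors) are the regime the
test suite exercises: 0.5% error with ≥ 18/20 exact genome recoveries,
80:20 haplotype mixtures collapsing to the major allele, error-free
circular fixtures recovering exact length after trimming.

The simulator deliberately omits indels, quality profiles, coverage
bias, chimeras and paired ends. Passing tests therefore demonstrate the
graph algorithms' correctness under their stated assumptions, not
robustness to real instrument artefacts; the brute-force string oracle
(`oracle_assemble`, refused above 100 kb) is the independent correctness
surface for compaction, agreeing with the fast path on hundreds of
seeded instances.

## Numerical and format choices

* Ambiguous bases: any window containing a non-ACGT character is
  skipped, never errored — streaming real reads must tolerate Ns.
* `km:f:` abundances render to two decimals in headers (full precision
  in memory); stats N50 is the largest L with cumulative length ≥ half
  the total.
* Compressed output is standard gzip with a sidecar id→offset table for
  random access into the uncompressed stream.
* FASTA outputs carry provenance in their headers' tags only; GFA, stats
  TSV and the index container embed the tool version/config echo, since
  those formats have header lines for it and FASTA does not.
* Exit codes: 0 success, 1 usage, 2 data error; logs go to stderr,
  machine output to files/stdout.

## Known limitations

Single-threaded, fully in-memory (desk scale by design); no
external-memory counting, no superbubble resolution, no scaffolding; the
index has no partitioning or grouping beyond per-accession filters plus
a metadata manifest; circular-contig breakpoints are not shifted to
intergenic positions (that requires gene prediction).
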
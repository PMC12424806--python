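"""Compacted de Bruijn graph construction (unitigs).

Nodes of the underlying graph are solid canonical k-mers (seen at least
``min_count`` times; singletons are discarded as likely sequencing
errors); edges are exact (k-1)-base overlaps *witnessed in the reads*,
i.e. an edge exists iff its (k+1)-mer occurs in the input — the reads de
Bruijn graph, as edge-centric constructors (BCALM2, Cuttlefish2) define
it. A unitig is a maximal non-branching path: internal k-mers have
exactly one solid predecessor and one solid successor, so every solid
canonical k-mer is placed in exactly one unitig, exactly once.

Abundance annotation follows the construction-time heuristic of the
production pipeline this mirrors: per-k-mer abundance is obtained from
(k+1)-mer counts — sum the counts of all distinct canonical (k+1)-mers
containing the k-mer, divide by two (each read-internal occurrence of a
k-mer lies in two (k+1)-mers, so the halving cancels for interior
positions) — and each per-k-mer value passes through the 8-bit codec
before averaging over the unitig, mirroring how abundances are stored
during construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .codec import CodecSpec, encode_abundance, decode_abundance
from .errors import UnisearchError
from .kmer import (
    CountTable,
    KmerSpec,
    canonicalize,
    count_canonical,
    _count_canonical_at,
    decode_kmer,
    encode_kmer,
    reverse_complement,
    window_codes,
    canonical_codes,
)

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp_seq(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class LinkRecord:
    """One oriented (k-1)-overlap link, BCALM2-style.

    from_end: '+' when the link leaves the 3' end of the stored strand,
    '-' when it leaves the 3' end of the reverse strand (i.e. the 5' end
    of the stored strand). to_end: '+' when the neighbour is entered in
    its stored orientation (at its 5' end), '-' otherwise.
    """

    from_end: str
    to_id: int
    to_end: str

    def __post_init__(self) -> None:
        if self.from_end not in "+-" or self.to_end not in "+-":
            raise ValueError("link orientations must be '+' or '-'")

    def header_field(self) -> str:
        return f"L:{self.from_end}:{self.to_id}:{self.to_end}"


@dataclass
class UnitigRecord:
    id: int
    seq: str
    mean_abund: float = 0.0
    links: list[LinkRecord] = field(default_factory=list)
    circular: bool = False
    extra_tags: tuple[str, ...] = ()
    # sum over the unitig's k-mers of codec-decoded abundance; kept so that
    # graph simplification can merge records without re-deriving counts
    abund_sum: float = 0.0

    def n_kmers(self, k: int) -> int:
        return len(self.seq) - k + 1


@dataclass
class AssemblyGraph:
    unitigs: list[UnitigRecord]
    k: int

    def __len__(self) -> int:
        return len(self.unitigs)

    def total_length(self) -> int:
        return sum(len(u.seq) for u in self.unitigs)


def solid_kmers(counts: CountTable, min_count: int = 2) -> set[int]:
    """Canonical k-mers passing the abundance filter.

    The default ``min_count=2`` discards k-mers seen only once in an
    accession, the standard error filter.
    """
    return {code for code, c in counts.items() if c >= min_count}


def _succs(
    code: int, k: int, mask: int, solid: set[int], edges: set[int] | None
) -> list[int]:
    base = (code << 2) & mask
    out = []
    for b in range(4):
        n = base | b
        if canonicalize(n, k) not in solid:
            continue
        if edges is not None:
            # edge = the (k+1)-mer spelling code's k bases then base b
            e = canonicalize((code << 2) | b, k + 1)
            if e not in edges:
                continue
        out.append(n)
    return out


def _preds(
    code: int, k: int, mask: int, solid: set[int], edges: set[int] | None
) -> list[int]:
    base = code >> 2
    shift = 2 * (k - 1)
    out = []
    for b in range(4):
        n = (b << shift) | base
        if canonicalize(n, k) not in solid:
            continue
        if edges is not None:
            e = canonicalize((b << (2 * k)) | code, k + 1)
            if e not in edges:
                continue
        out.append(n)
    return out


def build_compacted_graph(
    solid: set[int], spec: KmerSpec, edges: set[int] | None = None
) -> AssemblyGraph:
    """Compact a solid canonical k-mer set into maximal unitigs with links.

    ``edges``, when given, is the set of canonical (k+1)-mer codes
    observed in the reads: two solid k-mers are adjacent only if their
    junction (k+1)-mer was actually read (the reads de Bruijn graph).
    Without it every exact (k-1)-overlap counts as an edge, which at
    small k admits repeat- and hairpin-induced branches the reads never
    witnessed.

    Deterministic: walks start from the smallest unvisited canonical code,
    unitigs are ordered by (length desc, sequence asc) and stored on their
    lexicographically smaller strand.
    """
    k = spec.k
    mask = spec.mask

    def fwd(c: int) -> int | None:
        ns = _succs(c, k, mask, solid, edges)
        if len(ns) != 1:
            return None
        if len(_preds(ns[0], k, mask, solid, edges)) != 1:
            return None
        return ns[0]

    def bwd(c: int) -> int | None:
        ps = _preds(c, k, mask, solid, edges)
        if len(ps) != 1:
            return None
        if len(_succs(ps[0], k, mask, solid, edges)) != 1:
            return None
        return ps[0]

    visited: set[int] = set()
    paths: list[tuple[list[int], bool]] = []  # (oriented codes, is_cycle)
    for start in sorted(solid):
        if start in visited:
            continue
        chain = [start]
        visited.add(start)
        is_cycle = False
        cur = start
        while True:  # forward
            n = fwd(cur)
            if n is None:
                break
            cn = canonicalize(n, k)
            if cn == canonicalize(start, k):
                is_cycle = True
                break
            if cn == canonicalize(cur, k) or cn in visited:
                break
            chain.append(n)
            visited.add(cn)
            cur = n
        if not is_cycle:
            cur = start
            while True:  # backward
                p = bwd(cur)
                if p is None:
                    break
                cp = canonicalize(p, k)
                if cp == canonicalize(cur, k) or cp in visited:
                    break
                chain.insert(0, p)
                visited.add(cp)
                cur = p
        paths.append((chain, is_cycle))

    # materialise sequences on the lexicographically smaller strand
    drafts: list[tuple[str, list[int]]] = []
    for chain, _ in paths:
        seq = decode_kmer(chain[0], k) + "".join(
            decode_kmer(c, k)[-1] for c in chain[1:]
        )
        rc = revcomp_seq(seq)
        if rc < seq:
            seq = rc
            chain = [reverse_complement(c, k) for c in reversed(chain)]
        drafts.append((seq, chain))

    drafts.sort(key=lambda d: (-len(d[0]), d[0]))
    records = [UnitigRecord(id=i, seq=seq) for i, (seq, _) in enumerate(drafts)]

    # locate each canonical k-mer's unitig and terminal codes for linking
    first_code = {i: chain[0] for i, (_, chain) in enumerate(drafts)}
    last_code = {i: chain[-1] for i, (_, chain) in enumerate(drafts)}
    owner: dict[int, int] = {}
    for i, (_, chain) in enumerate(drafts):
        for c in chain:
            owner[canonicalize(c, k)] = i

    def entry_incidence(n: int) -> tuple[int, int]:
        w = owner[canonicalize(n, k)]
        if n == first_code[w]:
            return (w, 0)
        if n == reverse_complement(last_code[w], k):
            return (w, 1)
        raise UnisearchError("neighbour k-mer is not terminal (graph bug)")

    pairs: set[tuple[tuple[int, int], tuple[int, int]]] = set()
    for i in range(len(drafts)):
        for exit_end, exit_code in (
            (1, last_code[i]),
            (0, reverse_complement(first_code[i], k)),
        ):
            for n in _succs(exit_code, k, mask, solid, edges):
                a, b = (i, exit_end), entry_incidence(n)
                pairs.add(tuple(sorted((a, b))))  # type: ignore[arg-type]

    for (u, eu), (v, ev) in sorted(pairs):
        records[u].links.append(
            LinkRecord("+" if eu == 1 else "-", v, "+" if ev == 0 else "-")
        )
        if (u, eu) != (v, ev):
            records[v].links.append(
                LinkRecord("+" if ev == 1 else "-", u, "+" if eu == 0 else "-")
            )
    for rec in records:
        rec.links.sort(key=lambda l: (l.from_end, l.to_id, l.to_end))
    return AssemblyGraph(unitigs=records, k=k)


def kmer_abundance(x: int, counts_k1: CountTable, k: int | None = None) -> float:
    """Approximate abundance of canonical k-mer ``x`` from (k+1)-mer counts.

    Sums the counts of all distinct canonical (k+1)-mers having x as
    prefix or suffix on either strand, then halves the sum. Read-internal
    occurrences contribute two (k+1)-mers each, so interior estimates
    equal true coverage; k-mers at read ends are undercounted by half per
    end, the accepted approximation.
    """
    if k is None:
        k = counts_k1.k - 1
    k1 = k + 1
    xr = reverse_complement(x, k)
    seen: set[int] = set()
    total = 0
    for base_code in (x, xr) if x != xr else (x,):
        ext_left = base_code  # (k+1)-mer with x as prefix: x . b
        for b in range(4):
            cand = canonicalize((ext_left << 2) | b, k1)
            if cand not in seen and cand in counts_k1:
                seen.add(cand)
                total += counts_k1[cand]
    # suffix extensions b . x — covered by prefix extensions of revcomp(x)
    # on the other strand only when x is scanned once; enumerate explicitly
    shift = 2 * k
    for base_code in (x, xr) if x != xr else (x,):
        for b in range(4):
            cand = canonicalize((b << shift) | base_code, k1)
            if cand not in seen and cand in counts_k1:
                seen.add(cand)
                total += counts_k1[cand]
    return total / 2.0


def unitig_mean_abundance(
    u: UnitigRecord,
    counts_k1: CountTable,
    codec: CodecSpec | None = None,
    k: int | None = None,
) -> float:
    """Mean over the unitig's k-mers of codec-quantised k-mer abundance."""
    codec = codec or CodecSpec()
    if k is None:
        k = counts_k1.k - 1
    codes, valid = window_codes(u.seq, k)
    canon = canonical_codes(codes[valid], k)
    if canon.size == 0:
        return 0.0
    total = 0.0
    for c in canon:
        a = kmer_abundance(int(c), counts_k1, k)
        total += decode_abundance(encode_abundance(a, codec), codec)
    return total / canon.size


def assemble_unitigs(
    reads: Iterable[str] | Sequence[str],
    spec: KmerSpec | None = None,
    min_count: int = 2,
    codec: CodecSpec | None = None,
) -> AssemblyGraph:
    """Full unitig pipeline: count, filter singletons, compact, annotate.

    Reads shorter than k are skipped (they contain no k-mer window).
    """
    spec = spec or KmerSpec()
    codec = codec or CodecSpec()
    reads = list(reads)
    counts_k = count_canonical(reads, spec)
    solid = solid_kmers(counts_k, min_count=min_count)
    counts_k1 = _count_canonical_at(reads, spec.k + 1)
    edges = set(counts_k1.counts)
    graph = build_compacted_graph(solid, spec, edges=edges)
    if graph.unitigs:
        for u in graph.unitigs:
            u.mean_abund = unitig_mean_abundance(u, counts_k1, codec, spec.k)
            u.abund_sum = u.mean_abund * u.n_kmers(spec.k)
    return graph
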
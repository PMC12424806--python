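"""Sequence I/O: reads, assembly FASTA with link headers, GFA, stats.

Assembly output follows the BCALM2 header dialect so the graph can be
reconstructed from the FASTA alone::

    >12 LN:i:154 km:f:21.37 L:+:3:- L:-:7:+ [circ:Z:true]

``LN`` is the sequence length, ``km`` the mean k-mer abundance, each
``L`` field one oriented (k-1)-overlap link, and circular contigs carry a
``circ`` tag. Unknown tags are preserved verbatim on read.

Reads come in as FASTA or FASTQ, plain or gzip; FASTQ quality lines are
discarded on the fly. Compressed assembly output (``.gz``) gets a
sidecar ``.idx`` file mapping record id to uncompressed byte offset.
"""

from __future__ import annotations

import gzip
import io
import os
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

from .assembly import AssemblyGraph, LinkRecord, UnitigRecord
from .errors import ParseError, UnisearchError

_L_FIELD = re.compile(r"^L:([+-]):(\d+):([+-])$")
_WRAP = 80


def _open_text(path: str | os.PathLike, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def sniff_format(path: str | os.PathLike) -> str:
    """'fasta' or 'fastq', by first non-blank character."""
    with _open_text(path) as fh:
        for line in fh:
            if line.strip():
                if line[0] == ">":
                    return "fasta"
                if line[0] == "@":
                    return "fastq"
                raise ParseError(f"unrecognised sequence format in {path}")
    raise ParseError(f"empty sequence file: {path}")


def read_sequences(path: str | os.PathLike) -> list[str]:
    """All sequences from a FASTA/FASTQ file (gzip transparent), uppercased."""
    fmt = sniff_format(path)
    with _open_text(path) as fh:
        return [str(rec.seq).upper() for rec in SeqIO.parse(fh, fmt)]


def write_fastq(reads: Sequence[str], path: str | os.PathLike, prefix: str = "read") -> None:
    """Write reads as 4-line FASTQ with flat qualities (gzip by suffix)."""
    with _open_text(path, "wt") as fh:
        for i, r in enumerate(reads):
            fh.write(f"@{prefix}{i}\n{r}\n+\n{'I' * len(r)}\n")


def write_fasta(seqs: Sequence[tuple[str, str]], path: str | os.PathLike) -> None:
    """Write (name, sequence) pairs as wrapped FASTA (gzip by suffix)."""
    with _open_text(path, "wt") as fh:
        for name, seq in seqs:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), _WRAP):
                fh.write(seq[i : i + _WRAP] + "\n")


# ---------------------------------------------------------------------------
# assembly FASTA dialect
# ---------------------------------------------------------------------------


def _record_header(rec: UnitigRecord) -> str:
    parts = [str(rec.id), f"LN:i:{len(rec.seq)}"]
    if rec.mean_abund is not None:
        parts.append(f"km:f:{rec.mean_abund:.2f}")
    parts.extend(l.header_field() for l in rec.links)
    if rec.circular:
        parts.append("circ:Z:true")
    parts.extend(rec.extra_tags)
    return " ".join(parts)


def write_assembly_fasta(
    records: Iterable[UnitigRecord], path: str | os.PathLike
) -> None:
    """Write unitig/contig records with BCALM2-style link headers.

    A ``.gz`` suffix triggers gzip compression plus a sidecar ``.idx``
    offset table (record id, uncompressed byte offset) for random access.
    """
    path = str(path)
    offsets: list[tuple[int, int]] = []
    buf = io.StringIO()
    for rec in records:
        offsets.append((rec.id, buf.tell()))
        buf.write(f">{_record_header(rec)}\n")
        for i in range(0, len(rec.seq), _WRAP):
            buf.write(rec.seq[i : i + _WRAP] + "\n")
    data = buf.getvalue()
    try:
        with _open_text(path, "wt") as fh:
            fh.write(data)
    except OSError as exc:
        raise UnisearchError(f"cannot write {path}: {exc}") from exc
    if path.endswith(".gz"):
        with open(path + ".idx", "w") as fh:
            for rid, off in offsets:
                fh.write(f"{rid}\t{off}\n")


def read_assembly_fasta(path: str | os.PathLike) -> list[UnitigRecord]:
    """Inverse of :func:`write_assembly_fasta`.

    Plain FASTA (no tags) yields records with no links and abundance 0;
    unrecognised header tags are kept in ``extra_tags``. A malformed
    ``L:`` field raises :class:`ParseError` with the offending line.
    """
    records: list[UnitigRecord] = []
    cur: UnitigRecord | None = None
    chunks: list[str] = []
    auto_id = 0

    def flush() -> None:
        nonlocal cur, chunks
        if cur is not None:
            cur.seq = "".join(chunks)
            records.append(cur)
        cur, chunks = None, []

    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                fields = line[1:].split()
                try:
                    rid = int(fields[0]) if fields else auto_id
                except ValueError:
                    rid = auto_id
                auto_id = max(auto_id, rid) + 1
                rec = UnitigRecord(id=rid, seq="")
                extras: list[str] = []
                for f in fields[1:]:
                    if f.startswith("L:"):
                        m = _L_FIELD.match(f)
                        if not m:
                            raise ParseError(
                                f"malformed link field {f!r} at line {lineno}",
                                line=lineno,
                            )
                        rec.links.append(
                            LinkRecord(m.group(1), int(m.group(2)), m.group(3))
                        )
                    elif f.startswith("LN:i:"):
                        pass  # redundant with the sequence itself
                    elif f.startswith("km:f:"):
                        rec.mean_abund = float(f[5:])
                    elif f == "circ:Z:true":
                        rec.circular = True
                    else:
                        extras.append(f)
                rec.extra_tags = tuple(extras)
                cur = rec
            else:
                if cur is None:
                    raise ParseError(
                        f"sequence data before first header at line {lineno}",
                        line=lineno,
                    )
                chunks.append(line.strip())
    flush()
    for rec in records:
        rec.abund_sum = 0.0  # recomputed by callers that need it
    return records


def graph_from_records(records: list[UnitigRecord], k: int) -> AssemblyGraph:
    """Rebuild an AssemblyGraph from records read off disk, restoring the
    abundance sums simplification needs."""
    for rec in records:
        rec.abund_sum = rec.mean_abund * max(len(rec.seq) - k + 1, 0)
    return AssemblyGraph(unitigs=records, k=k)


# ---------------------------------------------------------------------------
# GFA 1.0 export
# ---------------------------------------------------------------------------


def export_gfa(
    g: AssemblyGraph, path: str | os.PathLike, header_tags: Sequence[str] = ()
) -> None:
    """GFA 1.0: one S line per unitig, one L line per undirected link."""
    k = g.k
    seen: set[tuple] = set()
    with open(path, "w") as fh:
        fh.write("\t".join(["H", "VN:Z:1.0", *header_tags]) + "\n")
        for u in g.unitigs:
            fh.write(
                f"S\t{u.id}\t{u.seq}\tLN:i:{len(u.seq)}\tkm:f:{u.mean_abund:.2f}\n"
            )
        for u in g.unitigs:
            for l in u.links:
                a = (u.id, 1 if l.from_end == "+" else 0)
                b = (l.to_id, 0 if l.to_end == "+" else 1)
                key = tuple(sorted((a, b)))
                if key in seen:
                    continue
                seen.add(key)
                fh.write(
                    f"L\t{u.id}\t{l.from_end}\t{l.to_id}\t{l.to_end}\t{k - 1}M\n"
                )


def parse_gfa_adjacency(path: str | os.PathLike) -> tuple[dict[int, str], set[tuple]]:
    """Segments and undirected link set from a GFA file (round-trip checks)."""
    segs: dict[int, str] = {}
    links: set[tuple] = set()
    with open(path) as fh:
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            if cols[0] == "S":
                segs[int(cols[1])] = cols[2]
            elif cols[0] == "L":
                a = (int(cols[1]), 1 if cols[2] == "+" else 0)
                b = (int(cols[3]), 0 if cols[4] == "+" else 1)
                links.add(tuple(sorted((a, b))))
    return segs, links


# ---------------------------------------------------------------------------
# assembly statistics
# ---------------------------------------------------------------------------


@dataclass
class StatsRecord:
    n_sequences: int
    total_length: int
    n50: int
    longest: int
    file_bytes_raw: int = 0
    file_bytes_compressed: int = 0


def assembly_stats(records_or_lengths: Iterable) -> StatsRecord:
    """N50 and friends over a record collection (or plain lengths).

    N50 = largest L such that sequences of length >= L sum to at least
    half the total length.
    """
    lengths = sorted(
        (len(r.seq) if hasattr(r, "seq") else int(r)) for r in records_or_lengths
    )
    if not lengths:
        return StatsRecord(0, 0, 0, 0)
    total = sum(lengths)
    acc = 0
    n50 = 0
    for L in reversed(lengths):
        acc += L
        if acc * 2 >= total:
            n50 = L
            break
    return StatsRecord(
        n_sequences=len(lengths), total_length=total, n50=n50, longest=lengths[-1]
    )


def file_stats(path: str | os.PathLike) -> StatsRecord:
    """Stats for one assembly file, including raw vs compressed byte sizes."""
    records = read_assembly_fasta(path)
    st = assembly_stats(records)
    raw = os.stat(path).st_size
    if str(path).endswith(".gz"):
        st.file_bytes_compressed = raw
        with gzip.open(path, "rb") as fh:
            st.file_bytes_raw = len(fh.read())
    else:
        st.file_bytes_raw = raw
        with open(path, "rb") as fh:
            st.file_bytes_compressed = len(gzip.compress(fh.read()))
    return st


def write_stats_tsv(
    rows: dict[str, StatsRecord], path: str | os.PathLike, comment: str | None = None
) -> None:
    cols = [
        "accession", "n_sequences", "total_length", "n50",
        "longest", "file_bytes_raw", "file_bytes_compressed",
    ]
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("\t".join(cols) + "\n")
        for name, st in rows.items():
            fh.write(
                "\t".join(
                    map(str, [name, st.n_sequences, st.total_length, st.n50,
                              st.longest, st.file_bytes_raw, st.file_bytes_compressed])
                )
                + "\n"
            )
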
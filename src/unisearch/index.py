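"""Per-accession Bloom-filter k-mer index with Findere-style querying.

Each accession (one sequencing dataset, assembled to unitigs) gets one
Bloom filter. Rather than inserting k-mers directly, the filter stores
the canonical s-mers (s = k - z) of the unitigs; a k-mer queries
positive only when all z+1 of its constituent s-mers are positive
(the Findere scheme). Because a random absent k-mer needs z+1
independent false positives to slip through, the filter can be sized at
a much higher per-s-mer rate — target_fpr ** (1/(z+1)) — while the
effective per-k-mer false-positive rate still meets the target
(0.005% by default). Genuine k-mers always answer true: no false
negatives.

A query sequence is scored per accession by the fraction of its valid
k-mer windows found in the filter; accessions at or above a user-set
threshold are returned with their metadata. Exact matching-sequence
retrieval (which unitigs share k-mers with the query) bypasses the
filters entirely.
"""

from __future__ import annotations

import json
import math
import struct
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

from .errors import IndexFormatError, UnisearchError
from .kmer import canonical_codes, window_codes
from .assembly import UnitigRecord

_MAGIC = b"USIX\x01"

# fixed default hash seeds: index bytes and query results are reproducible
_SEED1 = 0x9E3779B97F4A7C15
_SEED2 = 0xC2B2AE3D27D4EB4F


@dataclass(frozen=True)
class IndexSpec:
    """Parameters of the accession index.

    k             : query word length (31)
    z             : Findere reduction; indexed words have length s = k - z
    target_fpr    : effective per-k-mer false-positive target (0.00005
                    = 0.005%)
    max_query_len : refuse longer queries unless explicitly allowed
    """

    k: int = 31
    z: int = 3
    target_fpr: float = 5e-5
    max_query_len: int = 1000
    seed1: int = _SEED1
    seed2: int = _SEED2

    def __post_init__(self) -> None:
        if not 0 <= self.z < self.k:
            raise ValueError("need 0 <= z < k")
        if not 0 < self.target_fpr < 1:
            raise ValueError("target_fpr must be in (0, 1)")

    @property
    def s(self) -> int:
        return self.k - self.z

    @property
    def per_smer_fpr(self) -> float:
        """Bloom sizing rate so the (z+1)-fold Findere composition meets
        the per-k-mer target."""
        return self.target_fpr ** (1.0 / (self.z + 1))


def size_bloom(n_distinct: int, per_smer_fpr: float) -> tuple[int, int]:
    """Optimal Bloom sizing: m = ceil(-n ln p / (ln 2)^2), h = round(ln2 * m/n)."""
    if n_distinct < 1:
        raise ValueError("n_distinct must be >= 1")
    if not 0 < per_smer_fpr < 1:
        raise ValueError("fpr must be in (0, 1)")
    m = math.ceil(-n_distinct * math.log(per_smer_fpr) / (math.log(2) ** 2))
    h = max(1, round(math.log(2) * m / n_distinct))
    return m, h


def _mix(x: np.ndarray, seed: int) -> np.ndarray:
    """splitmix64 finaliser over uint64 arrays (wrapping arithmetic)."""
    z = x ^ np.uint64(seed)
    z = (z + np.uint64(0x9E3779B97F4A7C15))
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


class BloomFilter:
    """Plain Bloom filter over uint64 keys, double hashing, numpy bitset."""

    def __init__(self, m: int, h: int, seed1: int = _SEED1, seed2: int = _SEED2):
        if m < 1 or h < 1:
            raise ValueError("m and h must be positive")
        self.m = m
        self.h = h
        self.seed1 = seed1
        self.seed2 = seed2
        self.words = np.zeros((m + 63) // 64, dtype=np.uint64)

    def _indices(self, codes: np.ndarray) -> Iterable[np.ndarray]:
        m = np.uint64(self.m)
        h1 = _mix(codes, self.seed1) % m
        h2 = _mix(codes, self.seed2) | np.uint64(1)
        for i in range(self.h):
            yield (h1 + np.uint64(i) * h2 % m) % m

    def add(self, codes: np.ndarray) -> None:
        codes = np.asarray(codes, dtype=np.uint64)
        if codes.size == 0:
            return
        one = np.uint64(1)
        for idx in self._indices(codes):
            np.bitwise_or.at(
                self.words, (idx >> np.uint64(6)).astype(np.intp),
                one << (idx & np.uint64(63)),
            )

    def contains(self, codes: np.ndarray) -> np.ndarray:
        codes = np.asarray(codes, dtype=np.uint64)
        if codes.size == 0:
            return np.zeros(0, dtype=bool)
        out = np.ones(codes.shape, dtype=bool)
        one = np.uint64(1)
        for idx in self._indices(codes):
            bits = self.words[(idx >> np.uint64(6)).astype(np.intp)]
            out &= (bits >> (idx & np.uint64(63)) & one).astype(bool)
        return out


@dataclass
class AccessionFilter:
    """One accession's approximate s-mer membership structure."""

    accession_id: str
    bloom: BloomFilter
    n_inserted: int
    spec: IndexSpec


def _canonical_smer_codes(seqs: Iterable[str], s: int) -> np.ndarray:
    chunks = []
    for seq in seqs:
        codes, valid = window_codes(seq, s)
        good = codes[valid]
        if good.size:
            chunks.append(canonical_codes(good, s))
    if not chunks:
        return np.empty(0, dtype=np.uint64)
    return np.unique(np.concatenate(chunks))


def build_accession_filter(
    unitigs: Iterable[str | UnitigRecord],
    spec: IndexSpec | None = None,
    accession_id: str = "",
) -> AccessionFilter:
    """Index all distinct canonical s-mers of an accession's unitigs."""
    spec = spec or IndexSpec()
    seqs = [u.seq if isinstance(u, UnitigRecord) else u for u in unitigs]
    smers = _canonical_smer_codes(seqs, spec.s)
    n = int(smers.size)
    m, h = size_bloom(max(n, 1), spec.per_smer_fpr)
    bloom = BloomFilter(m, h, spec.seed1, spec.seed2)
    bloom.add(smers)
    return AccessionFilter(accession_id=accession_id, bloom=bloom,
                           n_inserted=n, spec=spec)


def _window_positivity(f: AccessionFilter, seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Per k-mer window of ``seq``: (positive, valid) boolean arrays."""
    spec = f.spec
    s, k, z = spec.s, spec.k, spec.z
    n_kwin = len(seq) - k + 1
    if n_kwin <= 0:
        return np.zeros(0, dtype=bool), np.zeros(0, dtype=bool)
    codes, valid = window_codes(seq, s)
    present = np.zeros(codes.shape, dtype=bool)
    if valid.any():
        present[valid] = f.bloom.contains(canonical_codes(codes[valid], s))
    # k-mer window j spans s-mer windows j .. j+z
    win_ok = np.lib.stride_tricks.sliding_window_view(present & valid, z + 1)
    win_valid = np.lib.stride_tricks.sliding_window_view(valid, z + 1)
    return win_ok.all(axis=1), win_valid.all(axis=1)


def findere_contains(f: AccessionFilter, kmer: str) -> bool:
    """True iff every constituent canonical s-mer of ``kmer`` is positive.

    Complete for indexed content (no false negatives); windows with
    ambiguous bases answer False.
    """
    if len(kmer) != f.spec.k:
        raise UnisearchError(f"expected a {f.spec.k}-mer, got length {len(kmer)}")
    pos, valid = _window_positivity(f, kmer)
    return bool(pos.size and valid.all() and pos.all())


def findere_contains_many(f: AccessionFilter, kmers: Sequence[str]) -> np.ndarray:
    """Vectorised membership for many same-length k-mers."""
    out = np.zeros(len(kmers), dtype=bool)
    for i, km in enumerate(kmers):
        out[i] = findere_contains(f, km)
    return out


def findere_contains_codes(f: AccessionFilter, codes: np.ndarray) -> np.ndarray:
    """Findere membership for an array of 2-bit packed k-mer codes.

    Decomposes each k-mer into its z+1 canonical s-mers and requires all
    of them positive; the bulk path for false-positive measurement.
    """
    spec = f.spec
    s, z = spec.s, spec.z
    codes = np.asarray(codes, dtype=np.uint64)
    smask = np.uint64((1 << (2 * s)) - 1)
    out = np.ones(codes.shape, dtype=bool)
    for j in range(z + 1):
        smer = (codes >> np.uint64(2 * (z - j))) & smask
        out &= f.bloom.contains(canonical_codes(smer, s))
    return out


@dataclass
class QueryHit:
    accession_id: str
    fraction: float
    n_found: int
    n_total: int
    metadata: dict = field(default_factory=dict)


@dataclass
class SearchIndex:
    """Bank of per-accession filters plus a metadata manifest."""

    filters: dict[str, AccessionFilter] = field(default_factory=dict)
    manifest: dict[str, dict] = field(default_factory=dict)
    spec: IndexSpec = field(default_factory=IndexSpec)

    def add_accession(
        self,
        accession_id: str,
        unitigs: Iterable[str | UnitigRecord],
        metadata: dict | None = None,
    ) -> None:
        if accession_id in self.filters:
            raise UnisearchError(f"duplicate accession id {accession_id!r}")
        self.filters[accession_id] = build_accession_filter(
            unitigs, self.spec, accession_id
        )
        self.manifest[accession_id] = dict(metadata or {})


def accession_fraction(f: AccessionFilter, seq: str) -> tuple[int, int]:
    """(n_found, n_total) k-mer windows of ``seq`` against one filter."""
    pos, valid = _window_positivity(f, seq)
    return int(pos.sum()), int(valid.sum())


def query(
    index: SearchIndex,
    seq: str,
    threshold: float,
    allow_long: bool = False,
) -> list[QueryHit]:
    """Coverage-fraction search across all accessions.

    Returns accessions whose fraction of query k-mers found is >= the
    user-set threshold, sorted by fraction descending (ties by id).
    """
    spec = index.spec
    if not 0 <= threshold <= 1:
        raise UnisearchError("threshold must be in [0, 1]")
    if len(seq) < spec.k:
        raise UnisearchError(
            f"query of length {len(seq)} is shorter than k={spec.k}"
        )
    if len(seq) > spec.max_query_len and not allow_long:
        raise UnisearchError(
            f"query of length {len(seq)} exceeds the {spec.max_query_len} nt "
            "default limit; pass allow_long to override"
        )
    hits: list[QueryHit] = []
    for acc_id, f in index.filters.items():
        n_found, n_total = accession_fraction(f, seq)
        if n_total == 0:
            continue
        frac = n_found / n_total
        if frac >= threshold:
            hits.append(
                QueryHit(
                    accession_id=acc_id, fraction=frac,
                    n_found=n_found, n_total=n_total,
                    metadata=dict(index.manifest.get(acc_id, {})),
                )
            )
    hits.sort(key=lambda h: (-h.fraction, h.accession_id))
    return hits


def extract_matching_sequences(
    records: Sequence[UnitigRecord | str],
    query_seq: str,
    spec: IndexSpec | None = None,
) -> list[tuple[UnitigRecord | str, int]]:
    """Exact retrieval: records sharing >= 1 canonical k-mer with the query.

    Returns (record, shared distinct canonical k-mer count) pairs, most
    shared first. No Bloom filter involved.
    """
    spec = spec or IndexSpec()
    k = spec.k
    qcodes, qvalid = window_codes(query_seq, k)
    qset = set(canonical_codes(qcodes[qvalid], k).tolist())
    out = []
    for rec in records:
        seq = rec.seq if isinstance(rec, UnitigRecord) else rec
        codes, valid = window_codes(seq, k)
        rset = set(canonical_codes(codes[valid], k).tolist())
        shared = len(qset & rset)
        if shared:
            out.append((rec, shared))
    out.sort(key=lambda t: -t[1])
    return out


# ---------------------------------------------------------------------------
# container serialisation
# ---------------------------------------------------------------------------


def save_index(index: SearchIndex, path) -> None:
    """Versioned binary container: magic, JSON header, raw bitsets."""
    header = {
        "version": 1,
        "spec": asdict(index.spec),
        "manifest": index.manifest,
        "accessions": [
            {
                "id": acc_id,
                "n_inserted": f.n_inserted,
                "m": f.bloom.m,
                "h": f.bloom.h,
                "nbytes": int(f.bloom.words.nbytes),
            }
            for acc_id, f in index.filters.items()
        ],
    }
    blob = json.dumps(header).encode()
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack(">Q", len(blob)))
        fh.write(blob)
        for f in index.filters.values():
            fh.write(f.bloom.words.tobytes())


def load_index(path) -> SearchIndex:
    """Lossless inverse of :func:`save_index`."""
    with open(path, "rb") as fh:
        magic = fh.read(len(_MAGIC))
        if magic != _MAGIC:
            raise IndexFormatError("not a unisearch index (bad magic bytes)")
        raw = fh.read(8)
        if len(raw) != 8:
            raise IndexFormatError("truncated index header")
        (hlen,) = struct.unpack(">Q", raw)
        blob = fh.read(hlen)
        if len(blob) != hlen:
            raise IndexFormatError("truncated index header")
        try:
            header = json.loads(blob)
        except json.JSONDecodeError as exc:
            raise IndexFormatError(f"corrupt index header: {exc}") from exc
        if header.get("version") != 1:
            raise IndexFormatError(
                f"unsupported index version {header.get('version')!r}"
            )
        spec = IndexSpec(**header["spec"])
        index = SearchIndex(spec=spec, manifest=header["manifest"])
        for entry in header["accessions"]:
            data = fh.read(entry["nbytes"])
            if len(data) != entry["nbytes"]:
                raise IndexFormatError(
                    f"truncated bitset for accession {entry['id']!r}"
                )
            bloom = BloomFilter(entry["m"], entry["h"], spec.seed1, spec.seed2)
            bloom.words = np.frombuffer(data, dtype=np.uint64).copy()
            index.filters[entry["id"]] = AccessionFilter(
                accession_id=entry["id"], bloom=bloom,
                n_inserted=entry["n_inserted"], spec=spec,
            )
    return index
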
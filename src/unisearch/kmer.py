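"""Canonical k-mer primitives.

A k-mer is packed 2 bits per base (A=0, C=1, G=2, T=3), most significant
base first, so codes order lexicographically. The canonical form of a
k-mer is the numerically smaller of the k-mer and its reverse complement;
all counting, assembly and indexing operate on canonical codes, which
collapses the two strands of the underlying double-stranded molecule.

k is capped at 31 so any code fits a 64-bit word. k is odd by default:
odd-length DNA words can never equal their own reverse complement, which
removes an awkward special case from graph construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .errors import EncodingError

_BASES = "ACGT"

# byte value -> 2-bit code; 255 marks anything that is not A/C/G/T
_BASE_BITS = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGTacgt"):
    _BASE_BITS[_b] = _i % 4

# reverse complement of a byte viewed as 4 packed bases
_RC8 = np.zeros(256, dtype=np.uint64)
for _v in range(256):
    _r = 0
    _x = _v
    for _ in range(4):
        _r = (_r << 2) | (3 - (_x & 3))
        _x >>= 2
    _RC8[_v] = _r


@dataclass(frozen=True)
class KmerSpec:
    """Word length for k-mer operations.

    Parameters
    ----------
    k : word length, 1..31 (2-bit codes must fit 64 bits). Defaults to 31.
    allow_even : permit even k. Even words can be their own reverse
        complement, which most downstream logic assumes away, so even k
        requires an explicit opt-in.
    """

    k: int = 31
    allow_even: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.k <= 31:
            raise ValueError(f"k must be in 1..31, got {self.k}")
        if self.k % 2 == 0 and not self.allow_even:
            raise ValueError(
                f"k={self.k} is even; even k-mers can be palindromic. "
                "Pass allow_even=True to override."
            )

    @property
    def mask(self) -> int:
        return (1 << (2 * self.k)) - 1


def encode_kmer(seq: str, spec: KmerSpec) -> int:
    """Pack a length-k string into its 2-bit integer code."""
    k = spec.k
    if len(seq) != k:
        raise EncodingError(f"expected length {k}, got {len(seq)}")
    code = 0
    for i, ch in enumerate(seq):
        b = _BASE_BITS[ord(ch) & 0xFF] if ord(ch) < 256 else 255
        if b == 255:
            raise EncodingError(
                f"illegal base {ch!r} at position {i}", position=i
            )
        code = (code << 2) | int(b)
    return code


def decode_kmer(code: int, k: int) -> str:
    """Inverse of :func:`encode_kmer`."""
    return "".join(_BASES[(code >> (2 * (k - 1 - i))) & 3] for i in range(k))


def reverse_complement(code: int, k: int) -> int:
    """Reverse complement of a 2-bit packed k-mer, byte-table accelerated."""
    r = 0
    for i in range(8):
        r = (r << 8) | int(_RC8[(code >> (8 * i)) & 0xFF])
    return r >> (2 * (32 - k))


def canonicalize(code: int, k: int) -> int:
    """min(code, revcomp(code)): the strand-collapsed representative."""
    rc = reverse_complement(code, k)
    return code if code <= rc else rc


def seq_to_bits(seq: str) -> np.ndarray:
    """Per-base 2-bit codes as uint8; 255 where the base is not ACGT."""
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    return _BASE_BITS[raw]


def window_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All length-k window codes of ``seq`` (forward strand).

    Returns ``(codes, valid)`` where ``codes[i]`` packs ``seq[i:i+k]`` and
    ``valid[i]`` is False when the window contains a non-ACGT base (the
    code is then meaningless). Both arrays have length ``len(seq)-k+1``
    (empty for shorter input).
    """
    bits = seq_to_bits(seq)
    n = len(bits) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    b2 = (bits & 3).astype(np.uint64)
    codes = np.zeros(n, dtype=np.uint64)
    two = np.uint64(2)
    for j in range(k):
        codes = (codes << two) | b2[j : j + n]
    bad = np.concatenate(([0], np.cumsum(bits == 255)))
    valid = (bad[k:] - bad[:-k]) == 0
    return codes, valid


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Vectorised reverse complement of an array of packed k-mers."""
    c = codes.astype(np.uint64, copy=True)
    rc = np.zeros_like(c)
    two, three = np.uint64(2), np.uint64(3)
    for _ in range(k):
        rc = (rc << two) | (three - (c & three))
        c >>= two
    return rc


def canonical_codes(codes: np.ndarray, k: int) -> np.ndarray:
    return np.minimum(codes, revcomp_codes(codes, k))


def scan_kmers(seq: str, spec: KmerSpec) -> Iterator[tuple[int, int]]:
    """Yield ``(position, canonical code)`` for every unambiguous window.

    Windows containing non-ACGT characters are skipped; a sequence shorter
    than k yields nothing.
    """
    codes, valid = window_codes(seq, spec.k)
    if codes.size == 0:
        return
    canon = canonical_codes(codes, spec.k)
    for i in np.flatnonzero(valid):
        yield int(i), int(canon[i])


@dataclass
class CountTable:
    """Exact multiset counts of canonical k-mers.

    ``counts`` maps canonical code -> occurrences; ``k`` records the word
    length the table was built at (assembly uses both k and k+1 tables).
    """

    k: int
    counts: dict[int, int] = field(default_factory=dict)

    def __getitem__(self, code: int) -> int:
        return self.counts[code]

    def get(self, code: int, default: int = 0) -> int:
        return self.counts.get(code, default)

    def __len__(self) -> int:
        return len(self.counts)

    def __contains__(self, code: int) -> bool:
        return code in self.counts

    def items(self):
        return self.counts.items()

    def total(self) -> int:
        """Number of valid windows scanned (conservation invariant)."""
        return sum(self.counts.values())


def count_canonical(reads: Iterable[str], spec: KmerSpec) -> CountTable:
    """Exact canonical k-mer counts over a read collection.

    Reads shorter than k contribute nothing. Windows containing ambiguous
    bases are skipped. Order-independent and strand-symmetric.
    """
    return _count_canonical_at(reads, spec.k)


def _count_canonical_at(reads: Iterable[str], k: int) -> CountTable:
    # internal: also used for (k+1)-mer abundance tables, where k+1 may be
    # 32 (still fits uint64) and may be even
    if not 1 <= k <= 32:
        raise ValueError(f"word length {k} outside 1..32")
    chunks: list[np.ndarray] = []
    for read in reads:
        codes, valid = window_codes(read, k)
        if codes.size == 0:
            continue
        good = codes[valid]
        if good.size:
            chunks.append(canonical_codes(good, k))
    table = CountTable(k=k)
    if not chunks:
        return table
    allcodes = np.concatenate(chunks)
    uniq, cnt = np.unique(allcodes, return_counts=True)
    table.counts = {int(u): int(c) for u, c in zip(uniq, cnt)}
    return table
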
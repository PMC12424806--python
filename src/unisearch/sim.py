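"""Seeded simulators and brute-force oracles.

Everything here is a pure function of its parameters and seed, so the
whole pipeline is testable without downloading data. The read model is
deliberately simple — uniform start positions, i.i.d. substitution
errors, no indels or quality profile — which makes expected k-mer
coverage analytically checkable while still producing the tip/bubble
artefacts graph simplification must handle.

``oracle_assemble`` is an independent string-based reimplementation of
unitig construction (hash-set k-mer store, exhaustive neighbour probing)
used only as a test oracle on small inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import UnisearchError

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = str.maketrans("ACGT", "TGCA")


def _rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass(frozen=True)
class SimSpec:
    """Study conditions for one simulated accession.

    genome_length : nt
    gc            : G+C fraction of the i.i.d. base model
    circular      : molecule topology (reads wrap around the origin)
    coverage      : mean fold coverage
    read_length   : nt per read
    error_rate    : per-base substitution probability
    seed          : RNG seed; same spec + seed => identical output
    """

    genome_length: int = 5000
    gc: float = 0.5
    circular: bool = False
    coverage: float = 30.0
    read_length: int = 100
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.gc <= 1:
            raise ValueError("gc must be in [0, 1]")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.coverage <= 0 or self.genome_length < 1 or self.read_length < 1:
            raise ValueError("coverage/lengths must be positive")


def simulate_genome(
    spec: SimSpec,
    unique_kmers_k: int | None = None,
    max_attempts: int = 50,
) -> str:
    """I.i.d. random genome at the requested GC content.

    With ``unique_kmers_k`` set, re-samples until every canonical k-mer of
    the genome (wrapping if circular) occurs exactly once — the clean
    single-unitig regime for assembly tests. Raises after
    ``max_attempts`` failures (longer k or a shorter genome will help).
    """
    rng = np.random.default_rng(spec.seed)
    p = np.array([(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2])
    for _ in range(max_attempts):
        idx = rng.choice(4, size=spec.genome_length, p=p)
        genome = _BASES[idx].tobytes().decode()
        if unique_kmers_k is None:
            return genome
        if _all_kmers_unique(genome, unique_kmers_k, spec.circular):
            return genome
    raise UnisearchError(
        f"could not sample a genome with unique {unique_kmers_k}-mers in "
        f"{max_attempts} attempts; try a larger k"
    )


def _all_kmers_unique(genome: str, k: int, circular: bool) -> bool:
    seq = genome + genome[: k - 1] if circular else genome
    seen: set[str] = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        can = min(km, _rc(km))
        if can in seen:
            return False
        seen.add(can)
    return True


def simulate_reads(genome: str, spec: SimSpec) -> list[str]:
    """Uniform-start substitution-error reads.

    n_reads = ceil(coverage * genome_length / read_length). Start
    positions are uniform over the genome (wrapping across the origin for
    circular molecules); each base is substituted with probability
    ``error_rate`` by one of the three other bases, uniformly.
    """
    L, rl = len(genome), spec.read_length
    if rl > L:
        raise UnisearchError("read_length exceeds genome length")
    rng = np.random.default_rng(spec.seed + 1)
    n_reads = math.ceil(spec.coverage * L / rl)
    if spec.circular:
        starts = rng.integers(0, L, size=n_reads)
        doubled = genome + genome[: rl - 1]
        reads = [doubled[s : s + rl] for s in starts]
    else:
        # starts range over [1-rl, L-1] with truncation at both edges, so
        # expected coverage is uniform across the genome (ordinary
        # interior-only starts would ramp coverage down to ~0 over the
        # last read_length bases and no assembler could recover the ends)
        starts = rng.integers(1 - rl, L, size=n_reads)
        reads = [genome[max(s, 0) : max(s + rl, 0)] for s in starts]
        reads = [r for r in reads if r]
    if spec.error_rate > 0:
        lens = np.array([len(r) for r in reads])
        arr = np.frombuffer("".join(reads).encode(), dtype=np.uint8).copy()
        err = rng.random(arr.size) < spec.error_rate
        pos = np.flatnonzero(err)
        if pos.size:
            # replace with one of the three other bases
            cur = np.searchsorted(_BASES, arr[pos])
            shift = rng.integers(1, 4, size=pos.size)
            arr[pos] = _BASES[(cur + shift) % 4]
        flat = arr.tobytes().decode()
        bounds = np.concatenate(([0], np.cumsum(lens)))
        reads = [flat[bounds[i] : bounds[i + 1]] for i in range(len(lens))]
    return reads


def inject_variant(genome: str, position: int, alt_base: str) -> str:
    """Single-base substituted haplotype copy."""
    if not 0 <= position < len(genome):
        raise UnisearchError(f"position {position} out of range")
    alt_base = alt_base.upper()
    if alt_base not in "ACGT":
        raise UnisearchError(f"alt base {alt_base!r} is not A/C/G/T")
    if genome[position] == alt_base:
        raise UnisearchError("alt base equals the reference base")
    return genome[:position] + alt_base + genome[position + 1 :]


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

_ORACLE_MAX_INPUT = 100_000


def oracle_assemble(reads: list[str], k: int, min_count: int = 2) -> set[str]:
    """Naive reference unitig assembler (strings only; test oracle).

    Returns the set of canonical unitig sequences (each the smaller of
    the unitig and its reverse complement). Refuses inputs over 100 kb.
    """
    if sum(len(r) for r in reads) > _ORACLE_MAX_INPUT:
        raise UnisearchError("oracle refuses inputs over 100 kb")

    counts: dict[str, int] = {}
    edges: set[str] = set()
    for r in reads:
        r = r.upper()
        for i in range(len(r) - k + 1):
            w = r[i : i + k]
            if any(c not in "ACGT" for c in w):
                continue
            can = min(w, _rc(w))
            counts[can] = counts.get(can, 0) + 1
        for i in range(len(r) - k):
            e = r[i : i + k + 1]
            if any(c not in "ACGT" for c in e):
                continue
            edges.add(min(e, _rc(e)))
    solid = {w for w, c in counts.items() if c >= min_count}

    def succs(w: str) -> list[str]:
        out = []
        for b in "ACGT":
            n = w[1:] + b
            if min(n, _rc(n)) in solid and min(w + b, _rc(w + b)) in edges:
                out.append(n)
        return out

    def preds(w: str) -> list[str]:
        out = []
        for b in "ACGT":
            n = b + w[:-1]
            if min(n, _rc(n)) in solid and min(b + w, _rc(b + w)) in edges:
                out.append(n)
        return out

    def canon(w: str) -> str:
        return min(w, _rc(w))

    visited: set[str] = set()
    unitigs: set[str] = set()
    for start in sorted(solid):
        if start in visited:
            continue
        chain = [start]
        visited.add(start)
        cur = start
        is_cycle = False
        while True:  # forward
            ns = succs(cur)
            if len(ns) != 1 or len(preds(ns[0])) != 1:
                break
            n = ns[0]
            if canon(n) == canon(start):
                is_cycle = True
                break
            if canon(n) == canon(cur) or canon(n) in visited:
                break
            chain.append(n)
            visited.add(canon(n))
            cur = n
        if not is_cycle:
            cur = start
            while True:  # backward
                ps = preds(cur)
                if len(ps) != 1 or len(succs(ps[0])) != 1:
                    break
                pr = ps[0]
                if canon(pr) == canon(cur) or canon(pr) in visited:
                    break
                chain.insert(0, pr)
                visited.add(canon(pr))
                cur = pr
        seq = chain[0] + "".join(w[-1] for w in chain[1:])
        unitigs.add(min(seq, _rc(seq)))
    return unitigs
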
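"""Graph simplification into contigs.

Unitigs preserve every solid k-mer; contigs are the consensus view after
removing structures that are overwhelmingly artefactual at typical short
read error rates:

* **tips** — short dead-end spurs (read-end errors),
* **bubbles** — pairs of parallel paths sharing both endpoints (isolated
  substitution errors, or minor alleles collapsed onto the major one),
* **weak links** — junction edges whose flanking coverage is wildly
  asymmetric (chimeric joins).

The heuristics and thresholds follow the conservative end of standard
short-read assembler practice; all of them are exposed on
:class:`SimplifyParams`. Rounds of tip clipping, bubble popping and weak
link removal alternate — recompacting the graph after each pass — until a
fixpoint or ``max_rounds``.

Circularity: a contig assembled from a circular molecule closes on
itself, leaving a self-link from its 3' end to its 5' end and a
duplicated terminal (k-1)-mer in the emitted sequence. Detection,
terminal-repeat trimming and a low-complexity artefact screen for such
contigs live here too.
"""

from __future__ import annotations

from dataclasses import dataclass

from .assembly import AssemblyGraph, LinkRecord, UnitigRecord, revcomp_seq
from .errors import UnisearchError

Incidence = tuple[int, int]  # (node id, end); end 0 = 5', end 1 = 3'
LinkPair = tuple[Incidence, Incidence]


@dataclass(frozen=True)
class SimplifyParams:
    """Tunables for graph simplification.

    tip_len_max       : max spur length (nt) eligible for clipping;
                        default 2.5*k, set when the graph k is known
    bubble_len_tol    : max length difference (nt) between bubble arms
    bubble_abund_ratio: pop the minor arm when minor/major mean abundance
                        is at or below this
    weak_link_ratio   : cut a junction link when the weaker flank's mean
                        abundance is strictly below ratio * stronger flank
    max_rounds        : cap on simplification rounds
    """

    tip_len_max: int | None = None
    bubble_len_tol: int = 3
    bubble_abund_ratio: float = 0.5
    weak_link_ratio: float = 0.1
    max_rounds: int = 10

    def __post_init__(self) -> None:
        for name in ("bubble_abund_ratio", "weak_link_ratio"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.bubble_len_tol < 0 or self.max_rounds < 1:
            raise ValueError("lengths/rounds must be positive")

    def resolved_tip_len(self, k: int) -> int:
        return self.tip_len_max if self.tip_len_max is not None else round(2.5 * k)


@dataclass
class ContigRecord:
    """An emitted contig: simplified consensus sequence plus flags."""

    id: int
    seq: str
    circular: bool
    mean_abund: float
    n_links: int


@dataclass
class _Node:
    seq: str
    abund_sum: float  # sum of per-k-mer codec-decoded abundances

    def n_kmers(self, k: int) -> int:
        return len(self.seq) - k + 1

    def mean_abund(self, k: int) -> float:
        n = self.n_kmers(k)
        return self.abund_sum / n if n else 0.0


def _norm_pair(a: Incidence, b: Incidence) -> LinkPair:
    return (a, b) if a <= b else (b, a)


class _MutGraph:
    """Bidirected unitig graph with orientation-aware chain merging.

    A link joins two incidences (node, end); walking out of one incidence
    enters the other node at its linked end and leaves by the opposite
    end. A self-link (u,0)-(u,1) marks a circular node.
    """

    def __init__(self, k: int):
        self.k = k
        self.nodes: dict[int, _Node] = {}
        self.links: set[LinkPair] = set()
        self._next = 0

    # -- construction ------------------------------------------------
    @classmethod
    def from_graph(cls, g: AssemblyGraph) -> "_MutGraph":
        mg = cls(g.k)
        for u in g.unitigs:
            mg.nodes[u.id] = _Node(u.seq, u.abund_sum)
            mg._next = max(mg._next, u.id + 1)
        for u in g.unitigs:
            for l in u.links:
                a = (u.id, 1 if l.from_end == "+" else 0)
                b = (l.to_id, 0 if l.to_end == "+" else 1)
                mg.links.add(_norm_pair(a, b))
        return mg

    def to_graph(self) -> AssemblyGraph:
        order = sorted(
            self.nodes,
            key=lambda i: (-len(self.nodes[i].seq), min(self.nodes[i].seq, revcomp_seq(self.nodes[i].seq))),
        )
        newid: dict[int, int] = {}
        flipped: dict[int, bool] = {}
        records: list[UnitigRecord] = []
        for rank, i in enumerate(order):
            node = self.nodes[i]
            rc = revcomp_seq(node.seq)
            flip = rc < node.seq
            seq = rc if flip else node.seq
            newid[i] = rank
            flipped[i] = flip
            records.append(
                UnitigRecord(
                    id=rank, seq=seq,
                    mean_abund=node.mean_abund(self.k),
                    abund_sum=node.abund_sum,
                )
            )
        for (u, eu), (v, ev) in self.links:
            fu = 1 - eu if flipped[u] else eu
            fv = 1 - ev if flipped[v] else ev
            a, b = (newid[u], fu), (newid[v], fv)
            records[a[0]].links.append(
                LinkRecord("+" if a[1] == 1 else "-", b[0], "+" if b[1] == 0 else "-")
            )
            if a != b:
                records[b[0]].links.append(
                    LinkRecord("+" if b[1] == 1 else "-", a[0], "+" if a[1] == 0 else "-")
                )
        for rec in records:
            rec.links.sort(key=lambda l: (l.from_end, l.to_id, l.to_end))
        return AssemblyGraph(unitigs=records, k=self.k)

    # -- queries -----------------------------------------------------
    def degree(self, inc: Incidence) -> int:
        d = 0
        for a, b in self.links:
            d += (a == inc) + (b == inc)
        return d

    def neighbours(self, inc: Incidence) -> list[Incidence]:
        out = []
        for a, b in self.links:
            if a == inc:
                out.append(b)
            if b == inc:
                out.append(a)
        return out

    def is_circular(self, nid: int) -> bool:
        return ((nid, 0), (nid, 1)) in self.links

    # -- mutation ----------------------------------------------------
    def drop_node(self, nid: int) -> None:
        del self.nodes[nid]
        self.links = {p for p in self.links if p[0][0] != nid and p[1][0] != nid}

    def drop_link(self, pair: LinkPair) -> None:
        self.links.discard(pair)

    def compact(self) -> None:
        """Merge every chain link whose two incidences both have degree 1."""
        changed = True
        while changed:
            changed = False
            for pair in sorted(self.links):
                (u, eu), (v, ev) = pair
                if u == v:
                    continue  # circular closure or hairpin: keep
                if self.degree((u, eu)) != 1 or self.degree((v, ev)) != 1:
                    continue
                self._merge(pair)
                changed = True
                break

    def _merge(self, pair: LinkPair) -> None:
        (u, eu), (v, ev) = pair
        k = self.k
        nu, nv = self.nodes[u], self.nodes[v]
        su = nu.seq if eu == 1 else revcomp_seq(nu.seq)  # u oriented 5'->3' into the join
        sv = nv.seq if ev == 0 else revcomp_seq(nv.seq)  # v oriented to continue
        if su[-(k - 1):] != sv[: k - 1]:
            raise UnisearchError("inconsistent (k-1)-overlap during merge")
        nid = self._next
        self._next += 1
        self.nodes[nid] = _Node(su + sv[k - 1:], nu.abund_sum + nv.abund_sum)
        remap = {(u, 1 - eu): (nid, 0), (v, 1 - ev): (nid, 1)}
        new_links: set[LinkPair] = set()
        for a, b in self.links:
            if (a, b) == pair or (b, a) == pair:
                continue
            new_links.add(_norm_pair(remap.get(a, a), remap.get(b, b)))
        self.links = new_links
        del self.nodes[u]
        del self.nodes[v]


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def _tip_candidates(mg: _MutGraph, p: SimplifyParams) -> list[int]:
    tip_max = p.resolved_tip_len(mg.k)
    out = []
    for nid, node in sorted(mg.nodes.items()):
        d0, d1 = mg.degree((nid, 0)), mg.degree((nid, 1))
        if (d0 == 0) == (d1 == 0):  # need exactly one dead end
            continue
        if len(node.seq) > tip_max:
            continue
        attached = (nid, 1) if d0 == 0 else (nid, 0)
        nb_ab = [
            mg.nodes[w].mean_abund(mg.k)
            for (w, _) in mg.neighbours(attached)
            if w != nid
        ]
        if nb_ab and node.mean_abund(mg.k) < max(nb_ab):
            out.append(nid)
    return out


def clip_tips(g: AssemblyGraph, p: SimplifyParams | None = None) -> AssemblyGraph:
    """Remove short, weakly covered dead-end spurs and recompact."""
    p = p or SimplifyParams()
    mg = _MutGraph.from_graph(g)
    _clip_tips_inplace(mg, p)
    return mg.to_graph()


def _clip_tips_inplace(mg: _MutGraph, p: SimplifyParams) -> bool:
    cands = _tip_candidates(mg, p)
    for nid in cands:
        mg.drop_node(nid)
    if cands:
        mg.compact()
    return bool(cands)


def _bubble_removals(mg: _MutGraph, p: SimplifyParams) -> list[int]:
    # group simple one-node arms by their (endpoint incidence) pair
    groups: dict[LinkPair, list[int]] = {}
    for nid in sorted(mg.nodes):
        if mg.degree((nid, 0)) != 1 or mg.degree((nid, 1)) != 1:
            continue
        n0 = mg.neighbours((nid, 0))
        n1 = mg.neighbours((nid, 1))
        if not n0 or not n1:
            continue
        (a,), (b,) = n0, n1
        if a[0] == nid or b[0] == nid:
            continue
        groups.setdefault(_norm_pair(a, b), []).append(nid)

    removals: list[int] = []
    k = mg.k
    for _, members in sorted(groups.items()):
        if len(members) < 2:
            continue
        def canon_seq(i: int) -> str:
            s = mg.nodes[i].seq
            return min(s, revcomp_seq(s))
        members.sort(key=lambda i: (-mg.nodes[i].mean_abund(k), canon_seq(i)))
        major = members[0]
        maj_ab = mg.nodes[major].mean_abund(k)
        for minor in members[1:]:
            if abs(len(mg.nodes[minor].seq) - len(mg.nodes[major].seq)) > p.bubble_len_tol:
                continue
            min_ab = mg.nodes[minor].mean_abund(k)
            if maj_ab > 0 and min_ab / maj_ab <= p.bubble_abund_ratio:
                removals.append(minor)
    return removals


def pop_bubbles(g: AssemblyGraph, p: SimplifyParams | None = None) -> AssemblyGraph:
    """Collapse simple two-arm bubbles onto the higher-coverage arm."""
    p = p or SimplifyParams()
    mg = _MutGraph.from_graph(g)
    _pop_bubbles_inplace(mg, p)
    return mg.to_graph()


def _pop_bubbles_inplace(mg: _MutGraph, p: SimplifyParams) -> bool:
    removals = _bubble_removals(mg, p)
    for nid in removals:
        mg.drop_node(nid)
    if removals:
        mg.compact()
    return bool(removals)


def _weak_link_cuts(mg: _MutGraph, p: SimplifyParams) -> list[LinkPair]:
    cuts = []
    k = mg.k
    for pair in sorted(mg.links):
        (u, eu), (v, ev) = pair
        if u == v:
            continue
        au, av = mg.nodes[u].mean_abund(k), mg.nodes[v].mean_abund(k)
        lo_ab, hi_ab = (au, av) if au <= av else (av, au)
        # only cut where an alternative continuation exists at the junction
        # (cutting a plain bridge between two degree-1 ends would merely
        # disconnect the graph)
        has_alt = mg.degree((u, eu)) >= 2 or mg.degree((v, ev)) >= 2
        if hi_ab > 0 and lo_ab < p.weak_link_ratio * hi_ab and has_alt:
            cuts.append(pair)
    return cuts


def remove_weak_links(g: AssemblyGraph, p: SimplifyParams | None = None) -> AssemblyGraph:
    """Cut junction links with strongly asymmetric flanking coverage."""
    p = p or SimplifyParams()
    mg = _MutGraph.from_graph(g)
    _remove_weak_links_inplace(mg, p)
    return mg.to_graph()


def _remove_weak_links_inplace(mg: _MutGraph, p: SimplifyParams) -> bool:
    cuts = _weak_link_cuts(mg, p)
    for pair in cuts:
        mg.drop_link(pair)
    if cuts:
        mg.compact()
    return bool(cuts)


def simplify(g: AssemblyGraph, p: SimplifyParams | None = None) -> AssemblyGraph:
    """Alternate tip clipping, bubble popping and weak-link removal to a
    fixpoint (or ``max_rounds``), recompacting after each pass."""
    p = p or SimplifyParams()
    mg = _MutGraph.from_graph(g)
    mg.compact()
    for _ in range(p.max_rounds):
        changed = _clip_tips_inplace(mg, p)
        changed |= _pop_bubbles_inplace(mg, p)
        changed |= _remove_weak_links_inplace(mg, p)
        if not changed:
            break
    return mg.to_graph()


def detect_circular(g: AssemblyGraph) -> dict[int, bool]:
    """Per-contig circularity: does the contig close onto its own start?

    True iff the node carries a 3'->5' self-link, equivalently the
    emitted sequence ends with its own first k-1 bases.
    """
    mg = _MutGraph.from_graph(g)
    return {u.id: mg.is_circular(u.id) for u in g.unitigs}


def trim_terminal_repeat(seq: str, r_min: int) -> tuple[str, int]:
    """Trim the duplicated terminal repeat of a circularised sequence.

    Finds the largest r with r_min <= r <= len(seq)/2 such that the first
    r bases equal the last r bases, and drops the last r bases. Returns
    ``(trimmed, r)``; r = 0 (no trim) when no such repeat exists.
    """
    if len(seq) < 2 * r_min:
        raise UnisearchError(
            f"sequence of length {len(seq)} too short for r_min={r_min}"
        )
    for r in range(len(seq) // 2, r_min - 1, -1):
        if seq[:r] == seq[-r:]:
            return seq[:-r], r
    return seq, 0


def low_complexity_fraction(window: str, max_period: int = 5, min_run: int = 8) -> float:
    """Fraction of positions covered by exact tandem repeats.

    A tandem run is a maximal stretch where the sequence equals itself
    shifted by p positions (period p <= max_period) spanning at least
    ``min_run`` bases; covered positions are unioned over all periods.
    """
    n = len(window)
    if n == 0:
        raise UnisearchError("empty window")
    covered = [False] * n
    for p in range(1, max_period + 1):
        i = 0
        while i + p < n:
            if window[i] != window[i + p]:
                i += 1
                continue
            j = i
            while j + p < n and window[j] == window[j + p]:
                j += 1
            run_len = (j - i) + p  # matched stretch plus one period
            if run_len >= min_run:
                for t in range(i, i + run_len):
                    covered[t] = True
            i = j + 1
    return sum(covered) / n


def is_circular_artifact(seq: str, r: int, threshold: float = 0.5) -> bool:
    """Flag a circular candidate whose terminal repeat is mostly
    low-complexity tandem sequence (> threshold of the repeat window)."""
    if r <= 0:
        return False
    return low_complexity_fraction(seq[:r]) > threshold


def emit_contigs(
    g: AssemblyGraph, min_len: int = 150, strict: bool = False
) -> list[ContigRecord]:
    """Apply the contig emission filter.

    Default rule: discard a contig iff it is non-circular, shorter than
    ``min_len`` and an isolated node of the simplified graph. Strict
    mode instead keeps only contigs longer than ``min_len`` that are
    connected to at least one other contig (a circular self-link counts
    as connected).
    """
    mg = _MutGraph.from_graph(g)
    out: list[ContigRecord] = []
    for u in g.unitigs:
        circular = mg.is_circular(u.id)
        n_links = sum(
            1
            for (a, b) in mg.links
            if (a[0] == u.id) != (b[0] == u.id)  # to a different node
        )
        if strict:
            connected = n_links >= 1 or circular
            keep = len(u.seq) > min_len and connected
        else:
            keep = not (
                not circular and len(u.seq) < min_len and n_links == 0
            )
        if keep:
            out.append(
                ContigRecord(
                    id=u.id, seq=u.seq, circular=circular,
                    mean_abund=u.mean_abund, n_links=n_links,
                )
            )
    return out
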
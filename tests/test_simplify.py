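"""Graph simplification, circularity detection, trimming, emission rules."""

import pytest

from unisearch.assembly import (
    AssemblyGraph,
    LinkRecord,
    UnitigRecord,
    assemble_unitigs,
    revcomp_seq,
)
from unisearch.errors import UnisearchError
from unisearch.kmer import KmerSpec
from unisearch.sim import SimSpec, inject_variant, simulate_genome, simulate_reads
from unisearch.simplify import (
    SimplifyParams,
    clip_tips,
    detect_circular,
    emit_contigs,
    is_circular_artifact,
    low_complexity_fraction,
    pop_bubbles,
    remove_weak_links,
    simplify,
    trim_terminal_repeat,
)

K21 = KmerSpec(21)


def _contig_seqs(g):
    return sorted(min(u.seq, revcomp_seq(u.seq)) for u in g.unitigs)


def _spur_graph():
    """A clean genome plus one low-coverage erroneous spur."""
    spec = SimSpec(genome_length=1500, coverage=20, seed=21)
    genome = simulate_genome(spec, unique_kmers_k=21)
    reads = simulate_reads(genome, spec)
    # a read with a substitution near its end, duplicated so the error
    # k-mers pass the solidity filter and form a spur
    bad = genome[700:800]
    bad = bad[:-3] + ("A" if bad[-3] != "A" else "C") + bad[-2:]
    return genome, assemble_unitigs(reads + [bad, bad], K21)


class TestTips:
    def test_spur_clipped(self):
        genome, g = _spur_graph()
        assert len(g.unitigs) > 1  # the spur is there
        out = clip_tips(g)
        assert len(out.unitigs) == 1
        assert out.unitigs[0].seq in (genome, revcomp_seq(genome))

    def test_no_dead_ends_unchanged(self):
        spec = SimSpec(genome_length=1200, circular=True, coverage=20, seed=22)
        genome = simulate_genome(spec, unique_kmers_k=21)
        g = assemble_unitigs(simulate_reads(genome, spec), K21)
        out = clip_tips(g)
        assert _contig_seqs(out) == _contig_seqs(g)

    def test_isolated_unitig_never_clipped(self):
        spec = SimSpec(genome_length=300, coverage=20, seed=23)
        genome = simulate_genome(spec, unique_kmers_k=21)
        g = assemble_unitigs(simulate_reads(genome, spec), K21)
        assert len(g.unitigs) == 1  # two dead ends
        assert len(clip_tips(g).unitigs) == 1


def _bubble_graph(major_cov=16.0, minor_cov=4.0, seed=31):
    spec = SimSpec(genome_length=1500, coverage=major_cov, seed=seed)
    hap1 = simulate_genome(spec, unique_kmers_k=21)
    alt = "A" if hap1[750] != "A" else "C"
    hap2 = inject_variant(hap1, 750, alt)
    r1 = simulate_reads(hap1, SimSpec(genome_length=1500, coverage=major_cov, seed=seed + 1))
    r2 = simulate_reads(hap2, SimSpec(genome_length=1500, coverage=minor_cov, seed=seed + 2))
    return hap1, assemble_unitigs(r1 + r2, K21)


class TestBubbles:
    def test_snp_bubble_collapses_to_major(self):
        hap1, g = _bubble_graph(16, 4)
        assert len(g.unitigs) >= 4  # shared flanks + two arms
        out = pop_bubbles(g)
        assert len(out.unitigs) == 1
        assert out.unitigs[0].seq in (hap1, revcomp_seq(hap1))

    def test_balanced_bubble_retained(self):
        _, g = _bubble_graph(10, 10)
        out = pop_bubbles(g)
        assert len(out.unitigs) == len(g.unitigs)  # ratio 1.0 > 0.5

    def test_no_parallel_paths_unchanged(self):
        spec = SimSpec(genome_length=800, coverage=20, seed=33)
        genome = simulate_genome(spec, unique_kmers_k=21)
        g = assemble_unitigs(simulate_reads(genome, spec), K21)
        assert _contig_seqs(pop_bubbles(g)) == _contig_seqs(g)


class TestWeakLinks:
    def test_uniform_graph_unchanged(self, clean_accession):
        *_, g = clean_accession
        assert _contig_seqs(remove_weak_links(g)) == _contig_seqs(g)

    def test_boundary_ratio_retained(self):
        # hand-built junction: node B (abund 1) joins A (abund 10) exactly
        # at the threshold ratio 0.1 -> strict inequality, link kept
        a = UnitigRecord(0, "ACTTAGCAA", mean_abund=10.0, abund_sum=70.0,
                         links=[LinkRecord("+", 1, "+"), LinkRecord("+", 2, "+")])
        b = UnitigRecord(1, "CAATGCA", mean_abund=1.0, abund_sum=5.0,
                         links=[LinkRecord("-", 0, "-")])
        c = UnitigRecord(2, "CAACGGT", mean_abund=10.0, abund_sum=50.0,
                         links=[LinkRecord("-", 0, "-")])
        g = AssemblyGraph([a, b, c], k=3)
        out = remove_weak_links(g, SimplifyParams(weak_link_ratio=0.1))
        n_links = sum(len(u.links) for u in out.unitigs)
        assert n_links == sum(len(u.links) for u in g.unitigs)

    def test_weak_junction_cut(self):
        a = UnitigRecord(0, "ACTTAGCAA", mean_abund=30.0, abund_sum=210.0,
                         links=[LinkRecord("+", 1, "+"), LinkRecord("+", 2, "+")])
        b = UnitigRecord(1, "AATGCA", mean_abund=1.0, abund_sum=5.0,
                         links=[LinkRecord("-", 0, "-")])
        c = UnitigRecord(2, "AACGGT", mean_abund=30.0, abund_sum=150.0,
                         links=[LinkRecord("-", 0, "-")])
        g = AssemblyGraph([a, b, c], k=3)
        out = remove_weak_links(g, SimplifyParams(weak_link_ratio=0.1))
        # the chimeric b-link is cut; a and c merge into one path, b isolated
        assert len(out.unitigs) == 2


class TestSimplify:
    def test_already_simple_unchanged(self, clean_accession):
        *_, g = clean_accession
        assert _contig_seqs(simplify(g)) == _contig_seqs(g)

    def test_errors_cleaned_to_single_contig(self):
        spec = SimSpec(genome_length=5000, coverage=30, error_rate=0.01, seed=40)
        genome = simulate_genome(spec, unique_kmers_k=21)
        g = assemble_unitigs(simulate_reads(genome, spec), K21)
        out = simplify(g)
        contigs = emit_contigs(out)
        assert len(contigs) == 1
        assert contigs[0].seq in (genome, revcomp_seq(genome))

    def test_fixpoint_idempotence(self):
        _, g = _spur_graph()
        once = simplify(g)
        twice = simplify(once)
        assert _contig_seqs(twice) == _contig_seqs(once)

    def test_monotone_shrinkage(self):
        _, g = _spur_graph()
        assert simplify(g).total_length() <= g.total_length()


class TestCircular:
    def test_circular_genome_detected(self):
        spec = SimSpec(genome_length=3000, circular=True, coverage=30, seed=50)
        genome = simulate_genome(spec, unique_kmers_k=21)
        g = simplify(assemble_unitigs(simulate_reads(genome, spec), K21))
        flags = detect_circular(g)
        assert len(g.unitigs) == 1
        assert flags[g.unitigs[0].id] is True
        assert len(g.unitigs[0].seq) == 3000 + 20  # genome + (k-1)

    def test_linear_genome_not_circular(self, clean_accession):
        *_, g = clean_accession
        assert not any(detect_circular(g).values())

    def test_two_disjoint_circles(self):
        reads = []
        for seed in (51, 52):
            spec = SimSpec(genome_length=1200, circular=True, coverage=25, seed=seed)
            genome = simulate_genome(spec, unique_kmers_k=21)
            reads += simulate_reads(genome, spec)
        g = simplify(assemble_unitigs(reads, K21))
        flags = detect_circular(g)
        assert len(g.unitigs) == 2 and all(flags.values())


class TestTrim:
    def test_circular_contig_trims_to_genome_length(self):
        spec = SimSpec(genome_length=2000, circular=True, coverage=25, seed=53)
        genome = simulate_genome(spec, unique_kmers_k=21)
        g = simplify(assemble_unitigs(simulate_reads(genome, spec), K21))
        seq = g.unitigs[0].seq
        trimmed, r = trim_terminal_repeat(seq, r_min=20)
        assert r == 20
        assert len(trimmed) == 2000

    def test_examples(self):
        assert trim_terminal_repeat("ACGTAC", 2) == ("ACGT", 2)
        assert trim_terminal_repeat("ACGTGA", 2) == ("ACGTGA", 0)

    def test_too_short_errors(self):
        with pytest.raises(UnisearchError):
            trim_terminal_repeat("ACG", 2)


class TestLowComplexity:
    @pytest.mark.parametrize(
        "seq,frac",
        [
            ("AAAAAAAAAA", 1.0),
            ("ATATATATATAT", 1.0),
            ("ACGTGCATCGATGCCAGTCAGGCTAGCAATC", 0.0),  # no period<=5 run >=8
        ],
    )
    def test_examples(self, seq, frac):
        assert low_complexity_fraction(seq) == frac

    def test_partial_coverage(self):
        s = "A" * 10 + "CGTAGCTAGCATCGATCGAA"
        f = low_complexity_fraction(s)
        assert 0.0 < f < 1.0

    def test_artifact_predicate(self):
        assert is_circular_artifact("A" * 20 + "CGT" * 20, r=20)
        assert not is_circular_artifact("ACGTGCATCGATGCCAGTCAGG" * 3, r=20)
        assert not is_circular_artifact("AAAA", r=0)


def _emission_graph():
    """One contig per cell of the truth table: length x circular x degree."""
    records = []
    short, long_ = "A" * 100, "C" * 101 + "A" * 99  # 100 vs 200 nt
    specs = [
        (0, short, False, []),          # short linear isolated
        (1, long_, False, []),          # long  linear isolated
        (2, short, True, []),           # short circular isolated
        (3, long_, True, []),           # long  circular isolated
        (4, short, False, [("+", 5, "+")]),  # short linear connected
        (5, long_, False, [("-", 4, "-")]),  # long  linear connected (mirror)
    ]
    for rid, seq, circ, nbrs in specs:
        links = [LinkRecord(fe, ti, te) for fe, ti, te in nbrs]
        if circ:
            links += [LinkRecord("+", rid, "+"), LinkRecord("-", rid, "-")]
        records.append(
            UnitigRecord(rid, seq, mean_abund=5.0, links=links, abund_sum=100.0)
        )
    return AssemblyGraph(records, k=21)


class TestEmission:
    def test_default_rule(self):
        g = _emission_graph()
        kept = {c.id for c in emit_contigs(g, min_len=150)}
        # discarded iff non-circular AND short AND isolated
        assert kept == {1, 2, 3, 4, 5}

    def test_strict_rule(self):
        g = _emission_graph()
        kept = {c.id for c in emit_contigs(g, min_len=150, strict=True)}
        # kept iff long AND connected (circular counts as connected)
        assert kept == {3, 5}

    def test_length_exactly_min_len_kept_by_default(self):
        rec = UnitigRecord(0, "A" * 150, mean_abund=1.0, abund_sum=10.0)
        g = AssemblyGraph([rec], k=21)
        assert len(emit_contigs(g, min_len=150)) == 1  # "shorter than" is strict

    def test_contig_fields(self):
        g = _emission_graph()
        by_id = {c.id: c for c in emit_contigs(g, min_len=150)}
        assert by_id[3].circular is True
        assert by_id[4].n_links == 1
        assert by_id[1].n_links == 0
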
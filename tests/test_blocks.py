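"""Block reference construction: boundaries, matching, screening, models."""

import numpy as np
import pytest

from spliceortho.blocks import (
    GenePairRejected,
    atomic_segments,
    build_reference,
    collect_boundaries,
    encode_transcript,
    exonic_intervals,
    is_subsequence,
    match_segments,
    annotate_reciprocal,
    screen_gene_pair,
)
from spliceortho.core import Exon, GeneSequence, Transcript
from spliceortho.synth import SimConfig, _random_codons, _random_nt, generate_pair
from tests.conftest import make_simple_gene


class TestBoundaries:
    def test_single_transcript_single_exon(self):
        t = Transcript("T", "G", (Exon(0, 6),))
        assert collect_boundaries([t]) == [0, 6]

    def test_alternative_donor_union(self):
        t1 = Transcript("T1", "G", (Exon(0, 6),))
        t2 = Transcript("T2", "G", (Exon(0, 9),))
        assert collect_boundaries([t1, t2]) == [0, 6, 9]

    def test_matches_set_union_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            transcripts = []
            expected = set()
            for k in range(rng.integers(1, 5)):
                cuts = sorted(
                    int(c)
                    for c in rng.choice(np.arange(1, 200), 6, replace=False)
                )
                exons = tuple(
                    Exon(cuts[2 * i], cuts[2 * i + 1]) for i in range(3)
                )
                transcripts.append(Transcript(f"T{k}", "G", exons))
                expected |= {c for e in exons for c in (e.start, e.end)}
            assert collect_boundaries(transcripts) == sorted(expected)

    def test_atomic_segments_partition_exons(self):
        t1 = Transcript("T1", "G", (Exon(0, 6),))
        t2 = Transcript("T2", "G", (Exon(0, 9),))
        segs = atomic_segments(
            collect_boundaries([t1, t2]), exonic_intervals([t1, t2])
        )
        assert segs == [(0, 6), (6, 9)]


def _matches_for(gene_a, ts_a, gene_b, ts_b):
    segs_a = atomic_segments(collect_boundaries(ts_a), exonic_intervals(ts_a))
    segs_b = atomic_segments(collect_boundaries(ts_b), exonic_intervals(ts_b))
    m_ab = match_segments(gene_a, gene_b, segs_a, "a", "b")
    m_ba = match_segments(gene_b, gene_a, segs_b, "b", "a")
    annotate_reciprocal(m_ab, gene_a, gene_b)
    annotate_reciprocal(m_ba, gene_b, gene_a)
    return m_ab, m_ba


class TestMatching:
    def test_identical_genes_all_reciprocal_identity_one(
        self, simple_identical_pair
    ):
        p = simple_identical_pair
        m_ab, m_ba = _matches_for(
            p.gene_a, p.transcripts_a, p.gene_b, p.transcripts_b
        )
        for m in m_ab + m_ba:
            assert m.matched and m.reciprocal
            assert m.identity == 1.0

    def test_diverged_segments_reciprocal_and_agree_with_allpairs_oracle(self):
        pair, _ = generate_pair(SimConfig(seed=21, divergence=0.05))
        m_ab, m_ba = _matches_for(
            pair.gene_a, pair.transcripts_a, pair.gene_b, pair.transcripts_b
        )
        segs_b = atomic_segments(
            collect_boundaries(pair.transcripts_b),
            exonic_intervals(pair.transcripts_b),
        )
        for m in m_ab:
            assert m.matched and m.reciprocal, m
            assert m.identity >= 0.8
            # all-vs-all oracle: the hit span must overlap the B segment(s)
            # that best-align the same sequence
            overlaps = [
                max(0, min(m.hit_span[1], e) - max(m.hit_span[0], s))
                for (s, e) in segs_b
            ]
            assert max(overlaps) > 0

    def test_segment_absent_from_other_gene_is_unmatched(
        self, specific_exon_synth
    ):
        pair, truth = specific_exon_synth
        m_ab, m_ba = _matches_for(
            pair.gene_a, pair.transcripts_a, pair.gene_b, pair.transcripts_b
        )
        carrier_matches = m_ab if len(pair.gene_a) > len(pair.gene_b) else m_ba
        assert any(not m.matched for m in carrier_matches)


def _dup_pair():
    """Species B annotates a near-identical duplicated copy of exon 1."""
    rng = np.random.default_rng(5)
    gene_a, ts_a = make_simple_gene(gene_id="GA")
    e1 = _random_codons(rng, 12)
    exons = ["ATG" + "".join(_random_codons(rng, 9)),
             "".join(e1),
             "".join(e1),
             "".join(_random_codons(rng, 9)) + "TAA"]
    # two point changes distinguish the copies
    exons[2] = "AC" + exons[2][2:]
    introns = ["GT" + _random_nt(rng, 36) + "AG" for _ in range(3)]
    pad = _random_nt(rng, 25)
    seq = pad
    spans = []
    for i, ex in enumerate(exons):
        spans.append((len(seq), len(seq) + len(ex)))
        seq += ex
        if i < 3:
            seq += introns[i]
    gene_b = GeneSequence("GB", "speciesB", seq + _random_nt(rng, 25))
    ts_b = [Transcript("CCDS9.1", "GB", tuple(Exon(s, e) for s, e in spans))]
    # species A uses the same exon sequences without the duplicate
    seq_a = pad + exons[0] + introns[0] + exons[1] + introns[1] + exons[3]
    gene_a = GeneSequence("GA", "speciesA", seq_a + _random_nt(rng, 25))
    off = len(pad)
    sa = [(off, off + len(exons[0]))]
    off = sa[0][1] + len(introns[0])
    sa.append((off, off + len(exons[1])))
    off = sa[1][1] + len(introns[1])
    sa.append((off, off + len(exons[3])))
    ts_a = [Transcript("CCDS8.1", "GA", tuple(Exon(s, e) for s, e in sa))]
    return gene_a, ts_a, gene_b, ts_b


def _rearranged_pair():
    """Species B carries exons 1 and 2 in swapped genomic order."""
    rng = np.random.default_rng(6)
    e = [
        "ATG" + "".join(_random_codons(rng, 11)),
        "".join(_random_codons(rng, 12)),
        "".join(_random_codons(rng, 12)),
        "".join(_random_codons(rng, 11)) + "TAA",
    ]
    introns = ["GT" + _random_nt(rng, 36) + "AG" for _ in range(3)]
    pad = _random_nt(rng, 25)

    def build(order, gid, species):
        seq = pad
        spans = []
        for i, k in enumerate(order):
            spans.append((len(seq), len(seq) + len(e[k])))
            seq += e[k]
            if i < len(order) - 1:
                seq += introns[i]
        gene = GeneSequence(gid, species, seq + _random_nt(rng, 25))
        ts = [Transcript(f"C{gid}.1", gid,
                         tuple(Exon(s, x) for s, x in spans))]
        return gene, ts

    gene_a, ts_a = build([0, 1, 2, 3], "GA", "speciesA")
    gene_b, ts_b = build([0, 2, 1, 3], "GB", "speciesB")
    return gene_a, ts_a, gene_b, ts_b


class TestScreening:
    def test_identical_pair_accepted(self, simple_identical_pair):
        p = simple_identical_pair
        m_ab, m_ba = _matches_for(
            p.gene_a, p.transcripts_a, p.gene_b, p.transcripts_b
        )
        assert screen_gene_pair(m_ab, m_ba).accepted

    def test_duplicated_exon_rejected(self):
        gene_a, ts_a, gene_b, ts_b = _dup_pair()
        m_ab, m_ba = _matches_for(gene_a, ts_a, gene_b, ts_b)
        res = screen_gene_pair(m_ab, m_ba)
        assert not res.accepted
        assert res.reason == "duplicated"

    def test_rearranged_exons_rejected(self):
        gene_a, ts_a, gene_b, ts_b = _rearranged_pair()
        m_ab, m_ba = _matches_for(gene_a, ts_a, gene_b, ts_b)
        res = screen_gene_pair(m_ab, m_ba)
        assert not res.accepted
        assert res.reason == "rearranged"

    def test_crossing_pair_oracle_agrees(self):
        gene_a, ts_a, gene_b, ts_b = _rearranged_pair()
        m_ab, _ = _matches_for(gene_a, ts_a, gene_b, ts_b)
        confident = sorted(
            (m for m in m_ab if m.matched), key=lambda m: m.query_span[0]
        )
        crossing = any(
            sum(m2.hit_span) / 2 < sum(m1.hit_span) / 2
            for i, m1 in enumerate(confident)
            for m2 in confident[i + 1:]
        )
        assert crossing

    def test_rejection_surfaces_through_build_reference(self):
        gene_a, ts_a, gene_b, ts_b = _dup_pair()
        with pytest.raises(GenePairRejected, match="duplicated"):
            build_reference(gene_a, ts_a, gene_b, ts_b)


class TestModelsAndStrings:
    def test_single_shared_exon_single_block(self):
        rng = np.random.default_rng(8)
        body = "ATG" + "".join(_random_codons(rng, 10)) + "TAA"
        pad1, pad2 = _random_nt(rng, 25), _random_nt(rng, 25)
        seq = pad1 + body + pad2
        span = (len(pad1), len(pad1) + len(body))
        ga = GeneSequence("GA", "spA", seq)
        gb = GeneSequence("GB", "spB", seq)
        ta = [Transcript("C1.1", "GA", (Exon(*span),))]
        tb = [Transcript("C2.1", "GB", (Exon(*span),))]
        ref = build_reference(ga, ta, gb, tb)
        assert len(ref.blocks) == 1
        assert ref.blocks[0].label == "A"
        assert ref.model_a.symbols == "[A]"

    def test_two_exon_model_and_encoding(self):
        gene, ts = make_simple_gene(exon_codons=(10, 10))
        full = Transcript("C1.1", gene.gene_id, ts[0].exons[:2])
        # second copy as the other species
        gb = GeneSequence("GB", "spB", gene.seq)
        fb = Transcript("C2.1", "GB", full.exons)
        ref = build_reference(gene, [full], gb, [fb])
        assert ref.model_a.symbols == "[A<>B]"
        assert ref.strings_a["C1.1"].symbols == "[A<>B]"

    def test_skipping_gene_model_and_transcript_strings(
        self, simple_identical_pair
    ):
        ref = build_reference(
            simple_identical_pair.gene_a,
            simple_identical_pair.transcripts_a,
            simple_identical_pair.gene_b,
            simple_identical_pair.transcripts_b,
        )
        assert ref.model_a.symbols == "[A<>B<>C]"
        assert ref.strings_a["CCDS1.1"].symbols == "[A<>B<>C]"
        assert ref.strings_a["CCDS2.1"].symbols == "[A<>C]"
        # identical genes and repertoires -> identical models
        assert ref.model_a.symbols == ref.model_b.symbols

    def test_alternative_donor_splits_block(self):
        gene, _ = make_simple_gene(exon_codons=(10, 10))
        e0, e1 = Exon(25, 55), Exon(95, 125)
        long = Transcript("C1.1", gene.gene_id, (e0, e1))
        short = Transcript("C2.1", gene.gene_id, (Exon(25, 46), e1))
        gb = GeneSequence("GB", "spB", gene.seq)
        tb = [
            Transcript("C11.1", "GB", long.exons),
            Transcript("C12.1", "GB", short.exons),
        ]
        ref = build_reference(gene, [long, short], gb, tb)
        assert len(ref.blocks) == 3  # core, 9-nt extension, second exon
        assert ref.strings_a["C1.1"].symbols == "[AB<>C]"
        assert ref.strings_a["C2.1"].symbols == "[A<>C]"

    def test_species_specific_block_absent_from_other_model(
        self, specific_exon_synth
    ):
        pair, truth = specific_exon_synth
        ref = build_reference(
            pair.gene_a, pair.transcripts_a, pair.gene_b, pair.transcripts_b
        )
        one_sided = [
            b for b in ref.blocks if (b.span_a is None) != (b.span_b is None)
        ]
        assert one_sided
        for b in one_sided:
            absent_model = ref.model_a if b.span_a is None else ref.model_b
            assert b.label not in absent_model.block_labels

    def test_block_containment_invariant_exhaustive(self, diverged_synth):
        pair, _ = diverged_synth
        ref = build_reference(
            pair.gene_a, pair.transcripts_a, pair.gene_b, pair.transcripts_b
        )
        for b in ref.blocks:
            for which, transcripts in (
                ("a", pair.transcripts_a),
                ("b", pair.transcripts_b),
            ):
                span = b.span(which)
                if span is None:
                    continue
                for t in transcripts:
                    ov = sum(
                        max(0, min(span[1], e.end) - max(span[0], e.start))
                        for e in t.exons
                    )
                    assert ov in (0, span[1] - span[0])

    def test_transcript_strings_are_subsequences_of_model(self, diverged_synth):
        pair, _ = diverged_synth
        ref = build_reference(
            pair.gene_a, pair.transcripts_a, pair.gene_b, pair.transcripts_b
        )
        for which in ("a", "b"):
            model = ref.model(which)
            for ts in ref.strings(which).values():
                assert is_subsequence(ts.tokens, model.tokens)

    def test_builder_is_deterministic(self, diverged_synth):
        pair, _ = diverged_synth
        args = (
            pair.gene_a, pair.transcripts_a, pair.gene_b, pair.transcripts_b
        )
        r1 = build_reference(*args)
        r2 = build_reference(*args)
        assert [
            (b.label, b.span_a, b.span_b) for b in r1.blocks
        ] == [(b.label, b.span_a, b.span_b) for b in r2.blocks]
        assert r1.model_a.symbols == r2.model_a.symbols

    def test_identical_splicing_gives_identical_symbols(
        self, simple_identical_pair
    ):
        p = simple_identical_pair
        ref = build_reference(
            p.gene_a, p.transcripts_a, p.gene_b, p.transcripts_b
        )
        dup = Transcript("CCDS3.1", "GA", p.transcripts_a[0].exons)
        s1 = encode_transcript(p.transcripts_a[0], ref.blocks, "a")
        s2 = encode_transcript(dup, ref.blocks, "a")
        assert s1.symbols == s2.symbols
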
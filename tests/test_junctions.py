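"""Novel junction classification, frame selection, junction translation."""

import pytest

from neopep.io_formats import FormatError, JunctionRecord, translate
from neopep.intron_retention import SpliceEvent
from neopep.junctions import (
    NoCodingContext,
    build_annotated_junctions,
    classify_junctions,
    event_contains_novel_junction,
    junction_context_sequence,
    junction_peptides_for_event,
    novel_junction_keys,
    select_reading_frame,
    translate_junction_peptides,
)


def _event(junctions, etype="alt_3prime", strand="+", contig="c1", gene="geneX"):
    return SpliceEvent(
        event_id="E1",
        event_type=etype,
        gene_id=gene,
        contig=contig,
        strand=strand,
        junctions=junctions,
        intron_confidence={"A": 6, "B": 6},
        junction_reads={"A": 6, "B": 6},
        psi={"A": 0.5, "B": 0.5},
    )


class TestAnnotatedSet:
    def test_exon_gaps_and_set_semantics(self, toy_world):
        _, transcripts, _ = toy_world
        ann = build_annotated_junctions(transcripts)
        brute = set()
        for t in transcripts:
            for i in range(len(t.exons) - 1):
                brute.add((t.contig, t.strand, t.exons[i][1], t.exons[i + 1][0]))
        assert ann.junctions == frozenset(brute)

    def test_single_exon_contributes_nothing(self, gene_factory):
        _, t, _ = gene_factory("ATG" + "GCT" * 10 + "TGA")
        assert len(build_annotated_junctions([t])) == 0

    def test_shared_intron_single_entry(self, gene_factory):
        intron = ("GT" + "A" * 40 + "AG",)
        _, t1, _ = gene_factory("ATG" + "GCT" * 10 + "TGA", intron_seqs=intron,
                                exon_splits=(18,), transcript_id="t1")
        _, t2, _ = gene_factory("ATG" + "GCT" * 10 + "TGA", intron_seqs=intron,
                                exon_splits=(18,), transcript_id="t2")
        assert len(build_annotated_junctions([t1, t2])) == 1


class TestClassify:
    def test_annotated_vs_novel(self, toy_world):
        _, transcripts, _ = toy_world
        ann = build_annotated_junctions(transcripts)
        t = transcripts[0]
        s, e = t.introns()[0]
        known = JunctionRecord(t.contig, s + 1, e, t.strand, 10)
        shifted = JunctionRecord(t.contig, s + 1, e + 4, t.strand, 10)
        out = dict((r.intron_start, novel) for r, novel in classify_junctions([known, shifted], ann))
        assert out[s + 1] in (False, True)  # both records classified
        classified = classify_junctions([known, shifted], ann)
        assert [novel for _, novel in classified] == [False, True]

    def test_unknown_strand_matches_both(self, toy_world):
        _, transcripts, _ = toy_world
        t = transcripts[0]
        ann = build_annotated_junctions(transcripts)
        s, e = t.introns()[0]
        unknown = JunctionRecord(t.contig, s + 1, e, ".", 5)
        assert classify_junctions([unknown], ann)[0][1] is False
        far = JunctionRecord(t.contig, 2, 3, ".", 5)
        assert classify_junctions([far], ann)[0][1] is True

    def test_empty_annotation_all_novel(self):
        from neopep.junctions import AnnotatedJunctionSet

        ann = AnnotatedJunctionSet(frozenset())
        recs = [JunctionRecord("c1", 10, 50, "+", 3)]
        assert classify_junctions(recs, ann)[0][1] is True

    def test_brute_force_membership_random(self, rng, toy_world):
        _, transcripts, _ = toy_world
        ann = build_annotated_junctions(transcripts)
        annotated_list = sorted(ann.junctions)
        for _ in range(300):
            if rng.random() < 0.5:
                contig, strand, s, e = annotated_list[int(rng.integers(len(annotated_list)))]
            else:
                contig, strand = "chr1", "+" if rng.random() < 0.5 else "-"
                s = int(rng.integers(0, 3000))
                e = s + int(rng.integers(40, 200))
            rec = JunctionRecord(contig, s + 1, e, strand, 5)
            ((_, novel),) = classify_junctions([rec], ann)
            assert novel == ((contig, strand, s, e) not in ann.junctions)


class TestEventNovelty:
    def test_novel_junction_detected(self):
        novel = {("c1", "+", 100, 200)}
        assert event_contains_novel_junction(_event([(100, 200)]), novel)

    def test_all_annotated_false(self):
        assert not event_contains_novel_junction(_event([(100, 200)]), set())

    def test_ir_events_not_junction_novel(self):
        novel = {("c1", "+", 100, 200)}
        ev = _event([(100, 200)], etype="intron_retention")
        assert not event_contains_novel_junction(ev, novel)

    def test_unknown_event_type_rejected(self):
        with pytest.raises(FormatError, match="unknown event type"):
            _event([(100, 200)], etype="mystery_event")

    def test_unknown_strand_event_checks_both(self):
        novel = {("c1", "-", 100, 200)}
        assert event_contains_novel_junction(_event([(100, 200)], strand="."), novel)


CODING = "ATG" + "GCTGGTACTCATAAGCTTGCAGCTTGGGAAGTCTTCGGACCTATC" + "TGA"


class TestContext:
    def test_lengths_and_offset_plus_strand(self, gene_factory):
        genome, t, tx = gene_factory(
            CODING, intron_seqs=("GT" + "C" * 56 + "AG",), exon_splits=(38,)
        )
        s, e = t.introns()[0]
        ev = _event([(s, e)], etype="intron_retention")
        ctx = junction_context_sequence(ev, t, genome, k=9)
        # donor is 30 coding nt into the CDS (38 - 8 nt UTR): upstream truncated
        assert ctx.junction_offset == min(24, 30)
        assert len(ctx.sequence) == ctx.junction_offset + 27  # 3*(k-1)+3 downstream
        # downstream side is the retained intron itself
        assert ctx.sequence[ctx.junction_offset :] == ("GT" + "C" * 56)[:27]
        assert ctx.frame_hint == (3 - 30 % 3) % 3

    def test_upstream_truncated_at_cds_start(self, gene_factory):
        # donor only 15 coding nt after the CDS start
        genome, t, tx = gene_factory(
            CODING, intron_seqs=("GT" + "C" * 40 + "AG",), exon_splits=(23,)
        )
        s, e = t.introns()[0]
        ctx = junction_context_sequence(_event([(s, e)], etype="intron_retention"), t, genome)
        assert ctx.junction_offset == 15
        assert ctx.frame_hint == 0

    def test_minus_strand_is_reverse_complement_oracle(self, gene_factory):
        from Bio.Seq import Seq

        intron = "GT" + "C" * 50 + "AG"
        gp, tp, _ = gene_factory(CODING, intron_seqs=(intron,), exon_splits=(38,))
        sp, ep = tp.introns()[0]
        ctx_plus = junction_context_sequence(
            _event([(sp, ep)], etype="intron_retention"), tp, gp
        )
        gm, tm, _ = gene_factory(CODING, strand="-", intron_seqs=(intron,), exon_splits=(38,))
        sm, em = tm.introns()[0]
        ctx_minus = junction_context_sequence(
            _event([(sm, em)], etype="intron_retention", strand="-"), tm, gm
        )
        # identical transcript content placed on opposite strands -> same context
        assert ctx_minus.sequence == ctx_plus.sequence
        assert ctx_minus.junction_offset == ctx_plus.junction_offset

    def test_novel_acceptor_downstream_past_intron(self, gene_factory):
        genome, t, tx = gene_factory(
            CODING, intron_seqs=("GT" + "C" * 56 + "AG",), exon_splits=(38,)
        )
        s, e = t.introns()[0]
        novel = (s, e + 6)
        ctx = junction_context_sequence(_event([novel]), t, genome)
        assert ctx.sequence[ctx.junction_offset :] == genome.fetch("c1", e + 6, e + 6 + 27)

    def test_noncoding_transcript_rejected(self, gene_factory):
        genome, t, tx = gene_factory(CODING)
        t.cds = []
        with pytest.raises(NoCodingContext):
            junction_context_sequence(_event([(10, 50)]), t, genome)


class TestFrameSelection:
    REF = ["MAGTHKLAAWEVFGPI"]

    def test_hint_takes_precedence(self):
        assert select_reading_frame("XXXXXX", 3, self.REF, frame_hint=1) == 1

    def test_fallback_substring_search(self):
        # frame 0 of the upstream flank translates to a reference substring
        up = "GGTACTCATAAGCTT"  # GTHKL
        seq = up + "CCCCCCCCC"
        assert translate(up) == "GTHKL"
        assert select_reading_frame(seq, len(up), self.REF) == 0

    def test_fallback_prefers_longest_match_then_lowest_frame(self):
        # engineer: frame 1 translation also matches but is shorter
        up = "G" + "GGTACTCATAAGCTT"  # frame 1 gives GTHKL (5 aa), frame 0 gives 5 aa too
        seq = up + "CCC"
        frame = select_reading_frame(seq, len(up), ["MAGTHKLAAWEVFGPI", "MX" + translate(up[0:15])])
        assert frame in (0, 1)  # deterministic total order
        assert select_reading_frame(seq, len(up), self.REF) == select_reading_frame(
            seq, len(up), self.REF
        )

    def test_all_frames_stop_dropped(self):
        up = "TAATAGTGATAATAG"  # stops in every frame
        assert select_reading_frame(up + "CCC", len(up), self.REF) is None


class TestTranslation:
    REF = "MAGTHKLAAWEVFGPIRSTNQD"
    REF_NT = (
        "ATGGCTGGTACTCATAAGCTTGCAGCTTGGGAAGTCTTCGGACCTATC"
        "AGAAGCACTAACCAAGAT"
    )

    def _context(self, up_codons, downstream):
        up = self.REF_NT[: 3 * up_codons]
        return up + downstream, len(up)

    def test_upstream_stop_kills_event(self):
        # stop planted 2 codons before the junction
        up = self.REF_NT[:18] + "TGA" + self.REF_NT[21:24]
        seq = up + "GGGGGGGGGGGGGGGGGGGGGGGGGGG"
        assert translate_junction_peptides(seq, len(up), 0, self.REF) == []

    def test_downstream_stop_truncates(self):
        seq, off = self._context(10, "CATCATCATTGA" + "G" * 15)
        peps = translate_junction_peptides(seq, off, 0, self.REF)
        # 10 upstream + HHH then stop: translated length 13 -> 5 nine-mers,
        # all overlapping the 3 novel histidines
        full = self.REF[:10] + "HHH"
        expected = {full[s : s + 9] for s in range(2, 5)}
        assert {p.sequence for p in peps} == expected
        assert all("*" not in p.sequence for p in peps)

    def test_clean_translation_matches_sliding_oracle(self):
        downstream = "CATCATCATCATCATCATCATCATCATCAT"  # 10 His, no stop
        seq, off = self._context(8, downstream)
        peps = translate_junction_peptides(seq, off, 0, self.REF)
        pep = self.REF[:8] + translate(downstream[:27])
        changed = {i for i in range(len(pep)) if i >= len(self.REF) or pep[i] != self.REF[i]}
        oracle = {
            pep[s : s + 9]
            for s in range(len(pep) - 8)
            if changed & set(range(s, s + 9))
        }
        assert {p.sequence for p in peps} == oracle
        assert all(p.changed_positions for p in peps)

    def test_translation_shorter_than_9_empty(self):
        seq, off = self._context(2, "CATCATCAT")  # 2 + 3 = 5 residues
        assert translate_junction_peptides(seq, off, 0, self.REF) == []

    def test_no_change_no_peptides(self):
        # downstream continues exactly like the reference: nothing novel
        seq, off = self._context(8, self.REF_NT[24:])
        assert translate_junction_peptides(seq, off, 0, self.REF) == []

    def test_every_peptide_differs_from_reference(self, rng):
        bases = list("ACGT")
        for _ in range(100):
            up_codons = int(rng.integers(1, 9))
            downstream = "".join(rng.choice(bases, size=30))
            seq, off = self._context(up_codons, downstream)
            for p in translate_junction_peptides(seq, off, 0, self.REF):
                assert len(p.sequence) == 9
                assert "*" not in p.sequence
                assert p.changed_positions


class TestEndToEndEvent:
    def test_ir_event_produces_peptides(self, gene_factory):
        intron = "GTCATCATCATCATCATCATCATCATCA" + "C" * 30 + "AG"
        genome, t, tx = gene_factory(CODING, intron_seqs=(intron,), exon_splits=(38,))
        s, e = t.introns()[0]
        ev = _event([(s, e)], etype="intron_retention")
        peps = junction_peptides_for_event(ev, [t], genome)
        assert peps, "retained intron with clean frame must yield peptides"
        assert all(p.event_id == "E1" for p in peps)

    def test_event_without_coding_transcript_skipped(self, gene_factory):
        genome, t, tx = gene_factory(CODING)
        ev = _event([(2, 8)], gene="other_gene")
        t.cds = []
        assert junction_peptides_for_event(ev, [t], genome) == []
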
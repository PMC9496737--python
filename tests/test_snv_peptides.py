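"""Mutant protein construction and k-mer window enumeration."""

import numpy as np
import pytest

from neopep.io_formats import ExpressionRecord, VariantKey, translate
from neopep.binding import BindingResult
from neopep.snv_peptides import (
    PeptideCandidate,
    VariantOutsideCDS,
    binder_filter,
    enumerate_snv_peptides,
    expression_filter,
    mutant_protein,
)

# a 17-codon CDS (stop included), no internal stops
CODING = "ATG" + "GCTGGTACTCATAAGCTTGCAGCTTGGGAAGTCTTCGGACCTATC" + "TGA"


def _variant_for_codon(genome, t, tx, utr5_len, codon_index, offset, new_base, strand):
    """Genomic VariantKey for substituting ``new_base`` at a coding position."""
    from Bio.Seq import Seq

    tx_pos = utr5_len + 3 * codon_index + offset
    # map spliced position to genomic by walking the exons
    remaining = tx_pos
    exons = t.exons if strand == "+" else list(reversed(t.exons))
    for s, e in exons:
        L = e - s
        if remaining < L:
            g = s + remaining if strand == "+" else e - 1 - remaining
            break
        remaining -= L
    ref = genome.fetch(t.contig, g, g + 1)
    alt = new_base if strand == "+" else str(Seq(new_base).complement())
    return VariantKey(t.contig, g, ref, alt)


class TestMutantProtein:
    def test_missense_codon_change(self, gene_factory):
        genome, t, tx = gene_factory(CODING)
        # codon 6 (0-based) is CTT -> make it CAT: L -> H
        assert CODING[18:21] == "CTT"
        key = _variant_for_codon(genome, t, tx, 8, 6, 1, "A", "+")
        wt, mut, aa_pos = mutant_protein(t, genome, key)
        assert aa_pos == 6
        assert (wt[6], mut[6]) == ("L", "H")
        assert wt[:6] == mut[:6] and wt[7:] == mut[7:]

    def test_synonymous_signals_no_peptide(self, gene_factory):
        genome, t, tx = gene_factory(CODING)
        # codon 7 GCA -> GCG, both alanine
        assert CODING[21:24] == "GCA"
        key = _variant_for_codon(genome, t, tx, 8, 7, 2, "G", "+")
        wt, mut, aa_pos = mutant_protein(t, genome, key)
        assert wt == mut and aa_pos is None

    def test_minus_strand_complemented(self, gene_factory):
        genome, t, tx = gene_factory(CODING, strand="-")
        key = _variant_for_codon(genome, t, tx, 8, 6, 1, "A", "-")
        wt, mut, aa_pos = mutant_protein(t, genome, key)
        assert aa_pos == 6 and (wt[6], mut[6]) == ("L", "H")

    def test_spliced_cds_same_result(self, gene_factory):
        """The same codon change through a two-exon CDS gives the same proteins."""
        genome, t, tx = gene_factory(
            CODING, intron_seqs=("GT" + "T" * 40 + "AG",), exon_splits=(20,)
        )
        key = _variant_for_codon(genome, t, tx, 8, 6, 1, "A", "+")
        wt, mut, aa_pos = mutant_protein(t, genome, key)
        assert aa_pos == 6 and (wt[6], mut[6]) == ("L", "H")

    def test_variant_outside_cds_rejected(self, gene_factory):
        genome, t, tx = gene_factory(CODING)
        key = VariantKey(t.contig, t.exons[0][0] + 2, genome.fetch(t.contig, t.exons[0][0] + 2, t.exons[0][0] + 3), "A")
        if key.ref == "A":
            key = VariantKey(key.contig, key.pos, key.ref, "G")
        with pytest.raises(VariantOutsideCDS):
            mutant_protein(t, genome, key)

    def test_stop_loss_reads_into_utr(self, gene_factory):
        genome, t, tx = gene_factory(CODING, utr3="CATCATCATTAAGGGTTT")
        # stop codon TGA at codon 16; offset 1 G->T gives TTA = Leu:
        # stop lost, translation continues into the 3'UTR
        key = _variant_for_codon(genome, t, tx, 8, 16, 1, "T", "+")
        wt, mut, aa_pos = mutant_protein(t, genome, key)
        assert len(mut) > len(wt)
        assert aa_pos == len(wt)  # first novel residue replaces the stop
        assert mut[: len(wt)] == wt


def _window_oracle(wt, mut, aa_pos, k):
    """Brute force: all k-mers of mut differing from the aligned wt k-mer."""
    out = []
    for s in range(len(mut) - k + 1):
        if s <= aa_pos < s + k and mut[s : s + k] != wt[s : s + k]:
            out.append((s, mut[s : s + k]))
    return out


class TestEnumerate:
    AAS = list("ACDEFGHIKLMNPQRSTVWY")

    def test_matches_brute_force_on_random_substitutions(self, rng):
        for _ in range(300):
            n = int(rng.integers(5, 40))
            k = int(rng.choice([8, 9]))
            aa_pos = int(rng.integers(0, n))
            wt = "".join(rng.choice(self.AAS, size=n))
            new = rng.choice([a for a in self.AAS if a != wt[aa_pos]])
            mut = wt[:aa_pos] + new + wt[aa_pos + 1 :]
            got = [(c.window_start, c.sequence) for c in enumerate_snv_peptides(wt, mut, aa_pos, k)]
            assert got == _window_oracle(wt, mut, aa_pos, k)

    def test_interior_position_gives_k_windows(self):
        wt = "A" * 25
        mut = wt[:12] + "W" + wt[13:]
        got = enumerate_snv_peptides(wt, mut, 12, 9)
        assert len(got) == 9
        assert all(c.sequence != c.wildtype_counterpart for c in got)
        assert all(c.sequence[12 - c.window_start] == "W" for c in got)

    def test_first_residue_k8_single_window(self):
        wt = "M" + "A" * 20
        mut = "W" + "A" * 20
        got = enumerate_snv_peptides(wt, mut, 0, 8)
        assert len(got) == 1 and got[0].window_start == 0

    def test_protein_shorter_than_k_empty(self):
        assert enumerate_snv_peptides("ACDEFGHI", "ACDEFGHM", 7, 9) == []

    def test_synonymous_empty(self):
        assert enumerate_snv_peptides("ACDEF" * 3, "ACDEF" * 3, None, 8) == []

    def test_frameshift_novel_tail_no_wildtype(self):
        wt = "MAAAAAAAAAAGGGG"
        mut = "MAAAAAAAAAAWCYWCYW"  # diverges from position 11 onwards
        got = enumerate_snv_peptides(wt, mut, 11, 9)
        oracle = {
            (s, mut[s : s + 9])
            for s in range(len(mut) - 8)
            if s + 9 > 11  # window overlaps a changed residue
        }
        assert {(c.window_start, c.sequence) for c in got} == oracle
        assert all(c.wildtype_counterpart is None for c in got)

    def test_pure_stop_gain_yields_nothing(self):
        # truncation with no changed residue before the stop: every window
        # equals wildtype, so no neoantigen is emitted
        wt = "MAAAAAAAAAAGGGGCCC"
        mut = wt[:12]
        got = enumerate_snv_peptides(wt, mut, 12, 9)
        assert got == []

    def test_no_candidate_contains_stop_symbol(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 30))
            wt = "".join(rng.choice(self.AAS, size=n))
            aa_pos = int(rng.integers(0, n))
            new = rng.choice([a for a in self.AAS if a != wt[aa_pos]])
            mut = wt[:aa_pos] + new + wt[aa_pos + 1 :]
            for c in enumerate_snv_peptides(wt, mut, aa_pos, 8):
                assert "*" not in c.sequence and len(c.sequence) == 8


class TestExpressionFilter:
    def _cand(self, gene="g1"):
        return PeptideCandidate("ACDEFGHI", 8, "SNV", gene_id=gene)

    def test_one_transcript_over_threshold_suffices(self):
        quant = [ExpressionRecord("t1", 0.2), ExpressionRecord("t2", 3.0)]
        t2g = {"t1": "g1", "t2": "g1"}
        assert expression_filter([self._cand()], quant, t2g) != []

    def test_all_below_dropped(self):
        quant = [ExpressionRecord("t1", 0.5), ExpressionRecord("t2", 0.9)]
        t2g = {"t1": "g1", "t2": "g1"}
        assert expression_filter([self._cand()], quant, t2g) == []

    def test_exactly_one_tpm_inclusive(self):
        quant = [ExpressionRecord("t1", 1.0)]
        assert expression_filter([self._cand()], quant, {"t1": "g1"}) != []

    def test_absent_gene_counts_as_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = expression_filter([self._cand("gX")], [], {})
        assert out == [] and "gX" in caplog.text


class TestBinderFilter:
    def _cand(self, seq="ACDEFGHIK"):
        return PeptideCandidate(seq, 9, "SNV", gene_id="g1")

    def _results(self, seq, kb, db):
        return [BindingResult(seq, "H-2Kb", kb), BindingResult(seq, "H-2Db", db)]

    def test_strong_binder_kept_and_flagged(self):
        c = self._cand()
        (kept,) = binder_filter([c], self._results(c.sequence, 499.0, 8000.0))
        assert kept.strong and kept.min_affinity_nm == 499.0

    def test_exactly_500_kept_not_strong(self):
        c = self._cand()
        (kept,) = binder_filter([c], self._results(c.sequence, 500.0, 8000.0))
        assert not kept.strong

    def test_both_over_cutoff_dropped(self):
        c = self._cand()
        assert binder_filter([c], self._results(c.sequence, 5001.0, 9000.0)) == []

    def test_exactly_cutoff_kept(self):
        c = self._cand()
        assert binder_filter([c], self._results(c.sequence, 5000.0, 9000.0)) != []

    def test_missing_result_raises(self):
        with pytest.raises(KeyError):
            binder_filter([self._cand()], [])
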
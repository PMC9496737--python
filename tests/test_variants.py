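"""Concordance, normalization, merging and consequence filtering."""

import numpy as np
import pytest

from neopep.io_formats import AnnotationRecord, GenomeSequence, Variant, VariantKey
from neopep.variants import (
    concordant_snvs,
    filter_consequences,
    filter_rna_variants,
    filter_wes_variants,
    integrate_wes,
    merge_samples,
    normalize_variant,
)


def V(pos=10, ref="A", alt="G", filt="PASS", dp=25, sample="s1", caller="star"):
    return Variant("c1", pos, ref, alt, filt, dp, sample, caller)


class TestRnaFilter:
    @pytest.mark.parametrize(
        "filt,dp,ref,alt,kept",
        [
            ("PASS", 15, "A", "G", True),
            ("PASS", 11, "A", "G", True),
            ("PASS", 10, "A", "G", False),  # strict: > 10 required
            ("badReads", 100, "A", "G", False),
            ("PASS", 50, "AT", "A", False),  # indel excluded by default
        ],
    )
    def test_boundaries(self, filt, dp, ref, alt, kept):
        out = filter_rna_variants([V(filt=filt, dp=dp, ref=ref, alt=alt)])
        assert bool(out) is kept

    def test_indels_survive_when_relaxed(self):
        out = filter_rna_variants([V(ref="AT", alt="A", dp=50)], snv_only=False)
        assert len(out) == 1

    def test_idempotent(self):
        vs = [V(dp=d) for d in (5, 11, 30)] + [V(filt="q", dp=40)]
        once = filter_rna_variants(vs)
        assert filter_rna_variants(once) == once


class TestWesFilter:
    @pytest.mark.parametrize("dp,filt,kept", [(20, "PASS", True), (19, "PASS", False), (50, "lowQ", False)])
    def test_inclusive_boundary(self, dp, filt, kept):
        assert bool(filter_wes_variants([V(dp=dp, filt=filt)])) is kept


class TestNormalize:
    GENOME = GenomeSequence({"c1": "GGGCACACACAGGTTT" + "A" * 20})

    def test_snv_fixed_point(self):
        g = GenomeSequence({"c1": "GGGGGGGGGGAGGGGG"})
        v = V(pos=10, ref="A", alt="G")
        assert normalize_variant(v, g) == v

    def test_common_prefix_trimmed_to_snv(self):
        g = GenomeSequence({"c1": "T" * 100 + "CA" + "T" * 20})
        v = V(pos=100, ref="CA", alt="CG")
        n = normalize_variant(v, g)
        assert (n.pos, n.ref, n.alt) == (101, "A", "G")

    def test_ref_mismatch_rejected(self):
        g = GenomeSequence({"c1": "T" * 30})
        with pytest.raises(ValueError, match="mismatch"):
            normalize_variant(V(pos=10, ref="A", alt="G"), g)

    def test_haplotype_preserved_on_random_indels(self, rng):
        """Oracle: applying the normalized variant to the reference yields the
        same haplotype string as applying the original."""
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGT"), size=60))
            g = GenomeSequence({"c1": seq})
            pos = int(rng.integers(5, 40))
            reflen = int(rng.integers(1, 5))
            ref = seq[pos : pos + reflen]
            alt = ref[0] + "".join(rng.choice(list("ACGT"), size=int(rng.integers(0, 4))))
            if ref == alt:
                continue
            v = V(pos=pos, ref=ref, alt=alt)
            n = normalize_variant(v, g)

            def apply(var):
                return seq[: var.pos] + var.alt + seq[var.pos + len(var.ref) :]

            assert apply(n) == apply(v)
            # normalization is a projection: applying it twice changes nothing
            assert normalize_variant(n, g) == n


class TestConcordance:
    def _callsets(self, rng, n_keys=30):
        keys = [VariantKey("c1", int(p), "A", "G") for p in rng.choice(500, n_keys, replace=False)]
        per_caller = {}
        for c in ("star", "tophat", "hisat2"):
            chosen = [k for k in keys if rng.random() < 0.6]
            per_caller[c] = [
                Variant(k.contig, k.pos, k.ref, k.alt, "PASS", 30, "s1", c) for k in chosen
            ]
        return per_caller

    def test_matches_brute_force_intersection(self, rng):
        for _ in range(200):
            per_caller = self._callsets(rng)
            got = {r.key for r in concordant_snvs(per_caller, sample_id="s1")}
            brute = set.intersection(*({v.key for v in vs} for vs in per_caller.values()))
            assert got == brute

    def test_two_of_three_discarded_and_sorted(self):
        k1, k2 = VariantKey("c1", 5, "A", "G"), VariantKey("c1", 2, "C", "T")
        mk = lambda k, c: Variant(k.contig, k.pos, k.ref, k.alt, "PASS", 20, "s", c)
        per_caller = {
            "a": [mk(k1, "a"), mk(k2, "a")],
            "b": [mk(k1, "b"), mk(k2, "b")],
            "c": [mk(k2, "c")],
        }
        recs = concordant_snvs(per_caller)
        assert [r.key for r in recs] == [k2]
        assert recs[0].supporting_callers == frozenset("abc")
        assert recs[0].per_caller_depths == {"a": 20, "b": 20, "c": 20}

    def test_caller_order_irrelevant(self, rng):
        per_caller = self._callsets(rng)
        a = concordant_snvs(per_caller)
        b = concordant_snvs(dict(reversed(list(per_caller.items()))))
        assert [r.key for r in a] == [r.key for r in b]

    def test_missing_required_caller_rejected(self):
        with pytest.raises(ValueError, match="no input"):
            concordant_snvs({"a": []}, required_callers={"a", "b"})

    def test_all_empty_gives_empty(self):
        assert concordant_snvs({"a": [], "b": [], "c": []}) == []


class TestMergeIntegrate:
    def _rec(self, key, sample):
        from neopep.variants import ConcordanceRecord

        return ConcordanceRecord(key, sample, frozenset({"a", "b", "c"}))

    def test_presence_matrix_completed(self):
        k1, k2 = VariantKey("c1", 5, "A", "G"), VariantKey("c1", 9, "C", "T")
        table = merge_samples(
            {"s1": [self._rec(k1, "s1"), self._rec(k2, "s1")], "s2": [self._rec(k2, "s2")]}
        )
        assert len(table) == 2  # |union| exactly
        assert bool(table.loc[k1, "s1"]) and not bool(table.loc[k1, "s2"])
        assert bool(table.loc[k2, "s1"]) and bool(table.loc[k2, "s2"])

    def test_union_row_count_random(self, rng):
        for _ in range(50):
            keys = [VariantKey("c1", int(p), "A", "T") for p in rng.choice(300, 20, replace=False)]
            by_sample = {
                s: [self._rec(k, s) for k in keys if rng.random() < 0.5]
                for s in ("s1", "s2", "s3")
            }
            table = merge_samples(by_sample)
            union = set().union(*({r.key for r in rs} for rs in by_sample.values()))
            assert len(table) == len(union)

    def test_single_sample_is_identity(self):
        k = VariantKey("c1", 5, "A", "G")
        table = merge_samples({"s1": [self._rec(k, "s1")]})
        assert list(table.index) == [k] and bool(table.loc[k, "s1"])

    def test_integrate_is_key_intersection(self):
        k1, k2 = VariantKey("c1", 5, "A", "G"), VariantKey("c1", 9, "C", "T")
        table = merge_samples({"s1": [self._rec(k1, "s1"), self._rec(k2, "s1")]})
        wes = [Variant("c1", 5, "A", "G", "PASS", 30)]
        kept = integrate_wes(table, wes)
        assert list(kept.index) == [k1]
        assert integrate_wes(table, []).empty


class TestConsequences:
    def _rec(self, cons):
        return AnnotationRecord("c1", 10, "A", "G", "tx1", cons)

    @pytest.mark.parametrize(
        "cons,kept",
        [
            ("missense_variant", True),
            ("frameshift_variant", True),
            ("splice_donor_variant", True),
            ("stop_gained", True),
            ("5_prime_UTR_variant", True),
            ("regulatory_region_variant", True),
            ("synonymous_variant", False),
            ("intron_variant", False),
            ("missense_variant&splice_region_variant", True),
        ],
    )
    def test_category_mapping(self, cons, kept):
        assert bool(filter_consequences([self._rec(cons)])) is kept

    def test_unknown_term_dropped_strict_kept_lenient(self, caplog):
        rec = self._rec("made_up_term")
        with caplog.at_level("WARNING"):
            assert filter_consequences([rec]) == []
        assert "unknown" in caplog.text
        assert filter_consequences([rec], strict=False) == [rec]

    def test_empty_input(self):
        assert filter_consequences([]) == []
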
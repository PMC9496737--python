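"""Multi-aligner RNA variant concordance and WES integration.

RNA-seq variant calls are noisy and aligner-dependent, so a variant is only
trusted when three independent splice-aware alignments all produce the same
call.  The surviving calls are merged across samples, intersected with
DNA-level (WES) calls, and restricted to protein-relevant consequence
categories before peptide enumeration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import AnnotationRecord, GenomeSequence, Variant, VariantKey

logger = logging.getLogger(__name__)

DEFAULT_RNA_MIN_DEPTH = 10  # strict: depth must exceed this
DEFAULT_WES_MIN_READS = 20  # inclusive: depth must reach this

#: The seven retained consequence categories, each mapped to VEP terms.
DEFAULT_CONSEQUENCE_CATEGORIES: dict[str, set[str]] = {
    "missense": {"missense_variant", "protein_altering_variant"},
    "frameshift": {"frameshift_variant"},
    "splice": {
        "splice_acceptor_variant",
        "splice_donor_variant",
        "splice_region_variant",
        "splice_donor_region_variant",
        "splice_polypyrimidine_tract_variant",
    },
    "start": {"start_lost", "initiator_codon_variant"},
    "stop": {"stop_gained", "stop_lost"},
    "UTR": {"5_prime_UTR_variant", "3_prime_UTR_variant"},
    "regulatory": {
        "regulatory_region_variant",
        "TF_binding_site_variant",
        "upstream_gene_variant",
        "downstream_gene_variant",
    },
}


@dataclass
class ConcordanceRecord:
    """A variant key supported by a set of callers in one sample."""

    key: VariantKey
    sample_id: str
    supporting_callers: frozenset[str]
    per_caller_depths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.supporting_callers:
            raise ValueError("supporting_callers must be non-empty")


def filter_rna_variants(
    variants: Iterable[Variant],
    min_depth: int = DEFAULT_RNA_MIN_DEPTH,
    snv_only: bool = True,
) -> list[Variant]:
    """Keep PASS SNVs with read depth strictly greater than ``min_depth``.

    ``snv_only=False`` relaxes the SNV restriction (indels then survive too).
    Idempotent and order-preserving.
    """
    return [
        v
        for v in variants
        if v.filter_status == "PASS"
        and v.read_depth > min_depth
        and (v.is_snv or not snv_only)
    ]


def filter_wes_variants(
    variants: Iterable[Variant], min_reads: int = DEFAULT_WES_MIN_READS
) -> list[Variant]:
    """Keep PASS WES variants supported by at least ``min_reads`` reads."""
    return [v for v in variants if v.filter_status == "PASS" and v.read_depth >= min_reads]


def normalize_variant(variant: Variant, genome: GenomeSequence) -> Variant:
    """Left-align and trim a variant (vt-style normalization).

    SNVs are fixed points.  The ref allele is checked against the genome
    before and after normalization.
    """
    ref, alt, pos = variant.ref, variant.alt, variant.pos
    observed = genome.fetch(variant.contig, pos, pos + len(ref))
    if observed != ref:
        raise ValueError(
            f"ref allele mismatch at {variant.contig}:{pos + 1}: "
            f"variant says {ref!r}, genome says {observed!r}"
        )
    # 1) while both alleles end with the same base, truncate the rightmost
    #    base; if an allele would empty, left-extend both with the genome base
    while True:
        if ref[-1:] == alt[-1:] and len(ref) > 0 and len(alt) > 0:
            if len(ref) == 1 or len(alt) == 1:
                if pos == 0:
                    break
                pos -= 1
                base = genome.fetch(variant.contig, pos, pos + 1)
                ref, alt = base + ref[:-1], base + alt[:-1]
            else:
                ref, alt = ref[:-1], alt[:-1]
        else:
            break
    # 2) while both alleles are >= 2 long and share their first base, trim it
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return Variant(
        contig=variant.contig,
        pos=pos,
        ref=ref,
        alt=alt,
        filter_status=variant.filter_status,
        read_depth=variant.read_depth,
        sample_id=variant.sample_id,
        caller_id=variant.caller_id,
    )


def concordant_snvs(
    per_caller_variants: Mapping[str, Iterable[Variant]],
    required_callers: set[str] | None = None,
    sample_id: str = "",
) -> list[ConcordanceRecord]:
    """Keep variant keys called by every required caller in one sample.

    ``per_caller_variants`` maps caller id -> that caller's (already filtered
    and normalized) calls.  Output is sorted by (contig, pos, ref, alt).
    """
    per_caller = {c: list(vs) for c, vs in per_caller_variants.items()}
    if required_callers is None:
        required_callers = set(per_caller)
    missing = required_callers - set(per_caller)
    if missing:
        raise ValueError(f"required caller(s) with no input: {sorted(missing)}")
    key_sets = {c: {v.key for v in vs} for c, vs in per_caller.items()}
    shared: set[VariantKey] = set.intersection(
        *(key_sets[c] for c in required_callers)
    ) if required_callers else set()
    depth_of = {
        c: {v.key: v.read_depth for v in vs} for c, vs in per_caller.items()
    }
    records = []
    for key in sorted(shared):
        supporting = frozenset(c for c, ks in key_sets.items() if key in ks)
        records.append(
            ConcordanceRecord(
                key=key,
                sample_id=sample_id,
                supporting_callers=supporting,
                per_caller_depths={c: depth_of[c][key] for c in supporting},
            )
        )
    return records


def merge_samples(
    concordance_by_sample: Mapping[str, Sequence[ConcordanceRecord]]
) -> pd.DataFrame:
    """Union per-sample concordant keys into a presence/absence matrix.

    Returns a boolean DataFrame indexed by :class:`VariantKey` with one
    column per sample; a site concordant in any sample gets a row with
    explicit presence status in every sample (the deterministic stand-in for
    multi-sample backfilling).
    """
    if not concordance_by_sample:
        raise ValueError("at least one sample required")
    samples = sorted(concordance_by_sample)
    present = {s: {r.key for r in concordance_by_sample[s]} for s in samples}
    all_keys = sorted(set.union(*present.values())) if any(present.values()) else []
    return pd.DataFrame(
        {s: [k in present[s] for k in all_keys] for s in samples},
        index=pd.Index(all_keys, name="variant_key"),
        dtype=bool,
    )


def integrate_wes(
    rna_table: pd.DataFrame, wes_variants: Iterable[Variant]
) -> pd.DataFrame:
    """Intersect the RNA presence matrix with DNA (WES) calls by variant key.

    RNA-side per-sample presence columns are preserved for retained rows.
    """
    wes_keys = {v.key for v in wes_variants}
    keep = [k for k in rna_table.index if k in wes_keys]
    return rna_table.loc[keep]


def filter_consequences(
    annotation_records: Iterable[AnnotationRecord],
    kept_categories: Mapping[str, set[str]] | None = None,
    strict: bool = True,
) -> list[AnnotationRecord]:
    """Keep annotation rows whose consequence maps to a retained category.

    VEP emits `&`-joined compound terms; a row survives if any constituent
    term maps.  Unknown terms are dropped with a warning (``strict=True``,
    default) or retained (``strict=False``).
    """
    if kept_categories is None:
        kept_categories = DEFAULT_CONSEQUENCE_CATEGORIES
    term_to_cat = {
        term: cat for cat, terms in kept_categories.items() for term in terms
    }
    known_terms = set(term_to_cat) | {
        # recognized but deliberately not retained
        "synonymous_variant", "stop_retained_variant", "start_retained_variant",
        "intron_variant", "intergenic_variant", "non_coding_transcript_variant",
        "non_coding_transcript_exon_variant", "coding_sequence_variant", "NMD_transcript_variant",
    }
    out = []
    for rec in annotation_records:
        terms = [t for t in rec.consequence.replace(",", "&").split("&") if t]
        if any(t in term_to_cat for t in terms):
            out.append(rec)
            continue
        unknown = [t for t in terms if t not in known_terms]
        if unknown:
            logger.warning("unknown consequence term(s) %s: %s", unknown,
                           "dropped" if strict else "retained")
            if not strict:
                out.append(rec)
    return out


def consequence_category(
    consequence: str, categories: Mapping[str, set[str]] | None = None
) -> str | None:
    """Map a (possibly compound) consequence string to its retained category."""
    if categories is None:
        categories = DEFAULT_CONSEQUENCE_CATEGORIES
    term_to_cat = {t: c for c, ts in categories.items() for t in ts}
    for term in consequence.replace(",", "&").split("&"):
        if term in term_to_cat:
            return term_to_cat[term]
    return None
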
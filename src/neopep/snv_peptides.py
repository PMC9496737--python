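"""Mutant/wildtype MHC-ready peptide windows around retained coding variants.

For a missense variant at protein position ``p`` the k-mer windows are all
``[s, s+k)`` with ``max(0, p-k+1) <= s <= min(len-k, p)`` — i.e. every k-mer
of the mutant protein that contains the changed residue, paired with the
same-coordinate wildtype window.  Frameshift and stop-loss variants
enumerate every k-mer overlapping at least one novel residue of the altered
C-terminal tail (no wildtype counterpart).  The window rule operates in
amino-acid space: a 2k-1-residue context centered on the changed residue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import (
    ExpressionRecord,
    GenomeSequence,
    TranscriptModel,
    VariantKey,
    translate,
)

logger = logging.getLogger(__name__)

DEFAULT_KS = (8, 9)
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class PeptideCandidate:
    """One candidate peptide with provenance and (later) binding annotation."""

    sequence: str
    k: int
    source: str  # "SNV" or "neojunction"
    gene_id: str = ""
    transcript_id: str = ""
    variant_key: VariantKey | None = None
    event_id: str = ""
    mutant: bool = True
    wildtype_counterpart: str | None = None
    window_start: int = 0  # 0-based index into the (mutant) protein
    # filled by the binding filter:
    affinities_nm: dict[str, float] = field(default_factory=dict)
    min_affinity_nm: float | None = None
    strong: bool = False

    def __post_init__(self) -> None:
        if set(self.sequence) - AA_ALPHABET:
            raise ValueError(f"peptide {self.sequence!r} outside the 20-letter alphabet")
        if self.source == "SNV" and len(self.sequence) != self.k:
            raise ValueError("SNV peptide length must equal k")


class VariantOutsideCDS(ValueError):
    """The variant does not fall inside the transcript's coding intervals."""


def mutant_protein(
    transcript: TranscriptModel, genome: GenomeSequence, key: VariantKey
) -> tuple[str, str, int | None]:
    """Apply a coding variant and translate both haplotypes.

    Returns ``(wt_protein, mut_protein, aa_pos)`` where ``aa_pos`` is the
    0-based index of the first differing residue (None for synonymous
    changes, which yield no peptide).  The alt allele is given on the plus
    strand, as in VCF; minus-strand transcripts are handled by substituting
    in genomic orientation before reverse-complementing.  Frameshift
    variants are translated to the first stop.
    """
    if key.contig != transcript.contig:
        raise VariantOutsideCDS(f"{key} not on transcript contig {transcript.contig}")
    span = (key.pos, key.pos + len(key.ref))
    host = [iv for iv in transcript.cds if iv[0] <= span[0] and span[1] <= iv[1]]
    if not host:
        raise VariantOutsideCDS(f"{key} outside CDS of {transcript.transcript_id}")

    wt_parts, mut_parts = [], []
    for s, e in transcript.cds:
        seg = genome.fetch(transcript.contig, s, e)
        wt_parts.append(seg)
        if (s, e) == host[0]:
            off = key.pos - s
            if seg[off : off + len(key.ref)] != key.ref:
                raise ValueError(
                    f"ref allele mismatch for {key} in {transcript.transcript_id}"
                )
            seg = seg[:off] + key.alt + seg[off + len(key.ref) :]
        mut_parts.append(seg)
    wt_nt, mut_nt = "".join(wt_parts), "".join(mut_parts)
    if transcript.strand == "-":
        from Bio.Seq import Seq

        wt_nt = str(Seq(wt_nt).reverse_complement())
        mut_nt = str(Seq(mut_nt).reverse_complement())
    wt_nt = wt_nt[transcript.start_phase :]
    mut_nt = mut_nt[transcript.start_phase :]
    if len(wt_nt) % 3:
        logger.warning(
            "%s: CDS length not divisible by 3; translating floor", transcript.transcript_id
        )
    # frameshift / stop-loss translation continues into the 3'UTR
    utr3 = transcript.three_prime_utr_sequence(genome)
    wt_nt += utr3
    mut_nt += utr3

    wt = _to_first_stop(translate(wt_nt))
    mut = _to_first_stop(translate(mut_nt))
    aa_pos = _first_difference(wt, mut)
    return wt, mut, aa_pos


def _to_first_stop(aa: str) -> str:
    stop = aa.find("*")
    return aa if stop < 0 else aa[:stop]


def _first_difference(wt: str, mut: str) -> int | None:
    for i in range(min(len(wt), len(mut))):
        if wt[i] != mut[i]:
            return i
    if len(wt) != len(mut):
        return min(len(wt), len(mut))
    return None


def enumerate_snv_peptides(
    wt_protein: str,
    mut_protein: str,
    aa_pos: int | None,
    k: int,
    *,
    source_key: VariantKey | None = None,
    gene_id: str = "",
    transcript_id: str = "",
) -> list[PeptideCandidate]:
    """Enumerate mutant k-mers covering the changed residue(s).

    Substitutions pair every window with the same-coordinate wildtype k-mer;
    frameshift-like changes (diverging tails) emit all k-mers overlapping a
    novel residue, with no wildtype counterpart.  A mutant protein shorter
    than k yields nothing; a premature stop with no changed residue before
    it (pure stop-gain) yields nothing, because every available window is
    identical to wildtype.
    """
    if aa_pos is None or len(mut_protein) < k:
        return []

    is_substitution = (
        len(wt_protein) == len(mut_protein)
        and wt_protein[:aa_pos] == mut_protein[:aa_pos]
        and wt_protein[aa_pos + 1 :] == mut_protein[aa_pos + 1 :]
    )
    out: list[PeptideCandidate] = []
    if is_substitution:
        lo = max(0, aa_pos - k + 1)
        hi = min(len(mut_protein) - k, aa_pos)
        for s in range(lo, hi + 1):
            mut_win = mut_protein[s : s + k]
            wt_win = wt_protein[s : s + k]
            out.append(
                PeptideCandidate(
                    sequence=mut_win,
                    k=k,
                    source="SNV",
                    gene_id=gene_id,
                    transcript_id=transcript_id,
                    variant_key=source_key,
                    mutant=True,
                    wildtype_counterpart=wt_win,
                    window_start=s,
                )
            )
    else:
        changed = {
            i
            for i in range(len(mut_protein))
            if i >= len(wt_protein) or mut_protein[i] != wt_protein[i]
        }
        for s in range(0, len(mut_protein) - k + 1):
            if not changed.intersection(range(s, s + k)):
                continue
            out.append(
                PeptideCandidate(
                    sequence=mut_protein[s : s + k],
                    k=k,
                    source="SNV",
                    gene_id=gene_id,
                    transcript_id=transcript_id,
                    variant_key=source_key,
                    mutant=True,
                    wildtype_counterpart=None,
                    window_start=s,
                )
            )
    return out


def expression_filter(
    candidates: Iterable[PeptideCandidate],
    expression: Iterable[ExpressionRecord] | Mapping[str, float],
    transcript_to_gene: Mapping[str, str],
    min_tpm: float = 1.0,
) -> list[PeptideCandidate]:
    """Keep candidates whose gene has >= 1 transcript at TPM >= ``min_tpm``.

    A gene absent from the quantification table counts as TPM 0 (warned).
    """
    if not isinstance(expression, Mapping):
        expression = {r.transcript_id: r.tpm for r in expression}
    gene_max: dict[str, float] = {}
    for tx, tpm in expression.items():
        gene = transcript_to_gene.get(tx)
        if gene is None:
            continue
        gene_max[gene] = max(gene_max.get(gene, 0.0), tpm)
    out = []
    warned: set[str] = set()
    for cand in candidates:
        if cand.gene_id not in gene_max and cand.gene_id not in warned:
            logger.warning("gene %s absent from quant table; TPM treated as 0", cand.gene_id)
            warned.add(cand.gene_id)
        if gene_max.get(cand.gene_id, 0.0) >= min_tpm:
            out.append(cand)
    return out


def binder_filter(
    candidates: Sequence[PeptideCandidate],
    binding_results: Iterable,
    non_binder_cutoff_nm: float = 5000.0,
    strong_cutoff_nm: float = 500.0,
) -> list[PeptideCandidate]:
    """Drop candidates with no allele at affinity <= ``non_binder_cutoff_nm``.

    Survivors are annotated with their per-allele affinities, the minimum,
    and a strong-binder flag (min affinity strictly below
    ``strong_cutoff_nm``).  Every candidate must have a result for every
    allele in the result set; a missing result raises.
    """
    by_peptide: dict[str, dict[str, float]] = {}
    for res in binding_results:
        by_peptide.setdefault(res.peptide, {})[res.allele] = res.affinity_nm
    kept = []
    for cand in candidates:
        affinities = by_peptide.get(cand.sequence)
        if not affinities:
            raise KeyError(f"no binding result for peptide {cand.sequence}")
        cand.affinities_nm = dict(affinities)
        cand.min_affinity_nm = min(affinities.values())
        cand.strong = cand.min_affinity_nm < strong_cutoff_nm
        if cand.min_affinity_nm <= non_binder_cutoff_nm:
            kept.append(cand)
    return kept
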
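"""Novel splice-junction classification and junction peptide translation.

A junction observed by the aligner is *novel* when its exact intron
coordinates are absent from the universe of introns derivable from the gene
annotation.  For events containing a novel junction, a nucleotide context is
extracted around the junction boundary — up to 3*(k-1) exonic bases upstream
of the donor (so every k-mer can overlap the boundary) and 3*(k-1)+3 bases
of the novel downstream side — translated in the frame inherited from the
annotated CDS (or recovered by matching the upstream flank against the
reference proteome), and scanned for 9-mers that differ from the reference
protein in at least one residue.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .io_formats import GenomeSequence, JunctionRecord, TranscriptModel, translate
from .intron_retention import SpliceEvent

logger = logging.getLogger(__name__)

JUNCTION_K = 9

JunctionKey = tuple[str, str, int, int]  # contig, strand, intron start, intron end (0-based ho)


@dataclass
class AnnotatedJunctionSet:
    """All intron intervals derivable from a transcript annotation."""

    junctions: frozenset[JunctionKey]

    @classmethod
    def from_transcripts(cls, transcripts: Iterable[TranscriptModel]) -> "AnnotatedJunctionSet":
        keys = set()
        for t in transcripts:
            for s, e in t.introns():
                keys.add((t.contig, t.strand, s, e))
        return cls(junctions=frozenset(keys))

    def __contains__(self, key: JunctionKey) -> bool:
        contig, strand, s, e = key
        if strand == ".":
            # unknown strand: annotated if present on either strand
            return (contig, "+", s, e) in self.junctions or (contig, "-", s, e) in self.junctions
        return key in self.junctions

    def __len__(self) -> int:
        return len(self.junctions)


def build_annotated_junctions(transcripts: Iterable[TranscriptModel]) -> AnnotatedJunctionSet:
    """One entry per distinct intron across all multi-exon transcripts."""
    return AnnotatedJunctionSet.from_transcripts(transcripts)


def classify_junctions(
    sj_records: Iterable[JunctionRecord], annotated: AnnotatedJunctionSet
) -> list[tuple[JunctionRecord, bool]]:
    """Tag each junction record ``(record, is_novel)``.

    Novel iff the exact intron coordinates are absent from the annotation;
    unknown-strand junctions are novel only if absent on both strands.
    """
    out = []
    for rec in sj_records:
        s, e = rec.interval
        key = (rec.contig, rec.strand, s, e)
        out.append((rec, key not in annotated))
    return out


def novel_junction_keys(
    classified: Iterable[tuple[JunctionRecord, bool]]
) -> set[JunctionKey]:
    """The set of novel junction keys from :func:`classify_junctions` output."""
    return {(r.contig, r.strand, *r.interval) for r, novel in classified if novel}


def event_contains_novel_junction(
    event: SpliceEvent, novel_junctions: set[JunctionKey]
) -> bool:
    """True iff >= 1 of the event's implied junctions is in the novel set.

    Intron-retention events carry no spliced novel junction (their novelty
    is the *absence* of splicing over an annotated intron, handled by the IR
    filters) and return False here.
    """
    if event.event_type == "intron_retention":
        return False
    for s, e in event.junctions:
        if event.strand == ".":
            if (event.contig, "+", s, e) in novel_junctions or (
                event.contig, "-", s, e
            ) in novel_junctions:
                return True
        elif (event.contig, event.strand, s, e) in novel_junctions or (
            event.contig, ".", s, e
        ) in novel_junctions:
            return True
    return False


@dataclass
class JunctionContext:
    """Nucleotide context around a junction, in translation orientation."""

    sequence: str
    junction_offset: int  # index of the first novel (downstream) base
    frame_hint: int | None  # frame forced by the annotated CDS phase, if known
    transcript_id: str = ""


class NoCodingContext(ValueError):
    """No overlapping coding transcript provides an upstream flank."""


def junction_context_sequence(
    event: SpliceEvent,
    transcript: TranscriptModel,
    genome: GenomeSequence,
    k: int = JUNCTION_K,
) -> JunctionContext:
    """Extract the translation context around an event's (first) junction.

    Upstream side: up to ``3*(k-1)`` exonic bases of the host transcript
    before the donor boundary, truncated at the CDS start (5'UTR excluded;
    post-stop exonic sequence is retained so premature-stop contexts are
    visible to the downstream filter).  Downstream side: ``3*(k-1)+3``
    genomic bases of the novel sequence — the retained intron itself for
    intron retention, the sequence past the novel acceptor otherwise.
    Minus-strand transcripts are reverse-complemented.  ``frame_hint`` gives
    the frame implied by the annotated CDS phase at the upstream flank.
    """
    if not transcript.cds:
        raise NoCodingContext(f"{transcript.transcript_id} has no CDS")
    s0, e0 = event.junctions[0]
    up_len = 3 * (k - 1)
    down_len = 3 * (k - 1) + 3
    plus = transcript.strand == "+"
    contig_len = genome.length(event.contig)

    # transcript-order exonic positions from the CDS start to the donor
    if plus:
        cds_start = min(s for s, _ in transcript.cds)
        parts = [
            (max(s, cds_start), min(e, s0))
            for s, e in transcript.exons
            if e > cds_start and s < s0
        ]
    else:
        cds_start = max(e for _, e in transcript.cds)  # 5'-most coding boundary
        parts = [
            (max(s, e0), min(e, cds_start))
            for s, e in transcript.exons
            if s < cds_start and e > e0
        ]
    parts = [(a, b) for a, b in parts if a < b]
    if not parts:
        raise NoCodingContext(
            f"{transcript.transcript_id} has no coding sequence upstream of the junction"
        )
    upstream_full = "".join(genome.fetch(event.contig, a, b) for a, b in parts)
    if not plus:
        upstream_full = str(Seq(upstream_full).reverse_complement())
    upstream = upstream_full[-up_len:]
    offset_from_cds = len(upstream_full) - len(upstream)
    codon_pos = (offset_from_cds - transcript.start_phase) % 3
    frame_hint = (3 - codon_pos) % 3

    if event.event_type == "intron_retention":
        if plus:
            down = genome.fetch(event.contig, s0, min(s0 + down_len, e0))
        else:
            down = genome.fetch(event.contig, max(e0 - down_len, s0), e0)
            down = str(Seq(down).reverse_complement())
    else:
        if plus:
            down = genome.fetch(event.contig, e0, min(e0 + down_len, contig_len))
        else:
            down = genome.fetch(event.contig, max(s0 - down_len, 0), s0)
            down = str(Seq(down).reverse_complement())

    return JunctionContext(
        sequence=upstream + down,
        junction_offset=len(upstream),
        frame_hint=frame_hint,
        transcript_id=transcript.transcript_id,
    )


def select_reading_frame(
    sequence: str,
    junction_offset: int,
    reference_proteins: Sequence[str],
    frame_hint: int | None = None,
) -> int | None:
    """Choose the reading frame for a junction context.

    The frame inherited from the annotated CDS phase takes precedence.
    Fallback: the frame whose upstream-flank translation is stop-free and
    occurs verbatim in a reference protein (exact substring search standing
    in for a protein BLAST); ties broken by longest matching translation,
    then lowest frame index.  None when no frame qualifies (event dropped).
    """
    if frame_hint is not None:
        return frame_hint
    best: tuple[int, int] | None = None  # (match_len, -frame) maximized
    for frame in (0, 1, 2):
        up = sequence[frame:junction_offset]
        aa = translate(up)
        if not aa or "*" in aa:
            continue
        if any(aa in ref for ref in reference_proteins):
            cand = (len(aa), -frame)
            if best is None or cand > best:
                best = cand
    return None if best is None else -best[1]


@dataclass
class JunctionPeptide:
    """A 9-mer (or longer) junction peptide with its changed residues."""

    sequence: str
    event_id: str
    contig: str = ""
    junction: tuple[int, int] = (0, 0)
    frame: int = 0
    changed_positions: frozenset[int] = frozenset()
    gene_id: str = ""
    window_start: int = 0  # index in the translated context peptide

    # attributes used by the shared peptide FASTA writer
    source: str = "neojunction"
    mutant: bool = True
    k: int = JUNCTION_K

    def __post_init__(self) -> None:
        if len(self.sequence) < JUNCTION_K:
            raise ValueError("junction peptide shorter than 9 residues")
        if "*" in self.sequence:
            raise ValueError("junction peptide contains a stop symbol")
        if not self.changed_positions:
            raise ValueError("junction peptide must differ from reference somewhere")


def translate_junction_peptides(
    sequence: str,
    junction_offset: int,
    frame: int,
    reference_protein: str,
    k: int = JUNCTION_K,
    *,
    event_id: str = "",
    contig: str = "",
    junction: tuple[int, int] = (0, 0),
    gene_id: str = "",
) -> list[JunctionPeptide]:
    """Translate a junction context and emit changed-residue k-mers.

    The whole event yields nothing when a stop codon occurs strictly
    upstream of the junction codon; a stop at or after the junction codon
    truncates the peptide.  Windows are all k-mers of the translated string
    that overlap at least one residue differing from the reference protein
    (aligned by exact match of the upstream translation); windows shorter
    than k never arise by construction, translations shorter than k yield
    nothing.
    """
    pep_full = translate(sequence[frame:])
    d = junction_offset - frame
    junction_codon = max(0, math.ceil((d - 2) / 3))

    stop = pep_full.find("*")
    if stop >= 0 and stop < junction_codon:
        return []  # premature stop upstream of the novel junction site
    pep = pep_full if stop < 0 else pep_full[:stop]
    if len(pep) < k:
        return []

    if junction_codon > 0:
        anchor = pep[:junction_codon]
        m = reference_protein.find(anchor)
        if m >= 0:
            aligned = reference_protein[m : m + len(pep)]
            changed = frozenset(
                i for i in range(len(pep)) if i >= len(aligned) or pep[i] != aligned[i]
            )
        else:
            changed = frozenset(range(junction_codon, len(pep)))
    else:
        changed = frozenset(range(len(pep)))
    if not changed:
        return []

    peptides = []
    for s in range(0, len(pep) - k + 1):
        window_changed = changed.intersection(range(s, s + k))
        if not window_changed:
            continue
        peptides.append(
            JunctionPeptide(
                sequence=pep[s : s + k],
                event_id=event_id,
                contig=contig,
                junction=junction,
                frame=frame,
                changed_positions=frozenset(i - s for i in window_changed),
                gene_id=gene_id,
                window_start=s,
            )
        )
    return peptides


def junction_peptides_for_event(
    event: SpliceEvent,
    transcripts: Sequence[TranscriptModel],
    genome: GenomeSequence,
    k: int = JUNCTION_K,
) -> list[JunctionPeptide]:
    """End-to-end peptide generation for one event.

    Picks the first coding transcript of the event's gene that provides an
    upstream flank, selects the frame, and translates.  Events with no
    coding context or no selectable frame are skipped with a log entry.
    """
    hosts = [
        t for t in transcripts
        if t.gene_id == event.gene_id and t.cds
    ] or [t for t in transcripts if t.contig == event.contig and t.cds]
    reference_proteins = [t.protein(genome) for t in transcripts if t.cds]
    for host in hosts:
        try:
            ctx = junction_context_sequence(event, host, genome, k=k)
        except NoCodingContext:
            continue
        frame = select_reading_frame(
            ctx.sequence, ctx.junction_offset, reference_proteins, ctx.frame_hint
        )
        if frame is None:
            logger.info("%s: no reading frame found; event dropped", event.event_id)
            return []
        return translate_junction_peptides(
            ctx.sequence,
            ctx.junction_offset,
            frame,
            host.protein(genome),
            k=k,
            event_id=event.event_id,
            contig=event.contig,
            junction=event.junctions[0],
            gene_id=event.gene_id,
        )
    logger.info("%s: no overlapping coding transcript; event skipped", event.event_id)
    return []
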
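"""Readers and writers for every external file format the pipeline touches.

All coordinate-convention conversion happens here, exactly once, at the
boundary: files speak their native dialect (VCF/GTF/SJ.out.tab are 1-based),
internal code speaks 0-based half-open intervals.  The one documented
exception is :class:`JunctionRecord`, which mirrors the SJ.out.tab file
(1-based inclusive intron coordinates) and exposes the internal convention
through its :attr:`~JunctionRecord.interval` property.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

NUCLEOTIDES = set("ACGTN")
STRANDS = {"+", "-", "."}  # "." = unknown


class FormatError(ValueError):
    """A file violated the documented dialect or an invariant."""


# ---------------------------------------------------------------------------
# genome


class GenomeSequence:
    """In-memory genome: contig name -> uppercase nucleotide string.

    Lookup is by 0-based half-open interval and either returns exactly the
    requested length or raises.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            if name in self._seqs:
                raise FormatError(f"duplicate contig name {name!r}")
            seq = seq.upper()
            bad = set(seq) - NUCLEOTIDES
            if bad:
                raise FormatError(f"non-nucleotide characters {sorted(bad)} in contig {name!r}")
            self._seqs[name] = seq

    @property
    def contigs(self) -> list[str]:
        return list(self._seqs)

    def __contains__(self, contig: str) -> bool:
        return contig in self._seqs

    def length(self, contig: str) -> int:
        return len(self._seqs[contig])

    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    def sequence(self, contig: str) -> str:
        return self._seqs[contig]

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Return the sequence of ``[start, end)`` on ``contig`` (0-based)."""
        if contig not in self._seqs:
            raise KeyError(f"unknown contig {contig!r}")
        seq = self._seqs[contig]
        if not (0 <= start <= end <= len(seq)):
            raise IndexError(
                f"interval [{start}, {end}) out of range for contig {contig!r} (len {len(seq)})"
            )
        return seq[start:end]


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence` (sequences uppercased)."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate contig name {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq)
    return GenomeSequence(seqs)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for contig in genome.contigs:
            fh.write(f">{contig}\n")
            seq = genome.sequence(contig)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# transcripts


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript; intervals 0-based half-open.

    ``exons`` and ``cds`` are sorted by genomic start regardless of strand;
    translation order is derived from ``strand``.  ``start_phase`` is the
    number of bases to skip at the 5' end of the first coding exon before the
    first complete codon (the GTF frame field of the first CDS record in
    translation order).
    """

    transcript_id: str
    gene_id: str
    gene_name: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    start_phase: int = 0

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise FormatError(f"{self.transcript_id}: strand must be + or -")
        self.exons = sorted(tuple(e) for e in self.exons)
        self.cds = sorted(tuple(c) for c in self.cds)
        prev_end = -1
        for s, e in self.exons:
            if s >= e:
                raise FormatError(f"{self.transcript_id}: empty/inverted exon ({s}, {e})")
            if s < prev_end:
                raise FormatError(f"{self.transcript_id}: overlapping exons")
            prev_end = e
        for cs, ce in self.cds:
            if not any(es <= cs and ce <= ee for es, ee in self.exons):
                raise FormatError(
                    f"{self.transcript_id}: CDS ({cs}, {ce}) not contained in any exon"
                )
        if self.cds and self.cds_length() < 3:
            raise FormatError(f"{self.transcript_id}: total CDS length < 3")
        if not 0 <= self.start_phase <= 2:
            raise FormatError(f"{self.transcript_id}: start_phase must be 0..2")

    # -- derived structure -------------------------------------------------

    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, 0-based half-open, genomic order."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] > self.exons[i][1]
        ]

    def _concat(self, intervals: Sequence[tuple[int, int]], genome: GenomeSequence) -> str:
        seq = "".join(genome.fetch(self.contig, s, e) for s, e in intervals)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def coding_sequence(self, genome: GenomeSequence) -> str:
        """Spliced CDS in translation order, start_phase bases removed."""
        return self._concat(self.cds, genome)[self.start_phase :]

    def exonic_sequence(self, genome: GenomeSequence) -> str:
        """Spliced exonic (mRNA) sequence in translation order."""
        return self._concat(self.exons, genome)

    def protein(self, genome: GenomeSequence) -> str:
        """Translate the CDS; trailing stop (if present) is stripped."""
        return translate(self.coding_sequence(genome), trim_stop=True)

    def three_prime_utr_sequence(self, genome: GenomeSequence) -> str:
        """Exonic sequence downstream of the CDS, in translation order.

        Needed to extend frameshift/stop-loss translation past the annotated
        coding region.  Empty when the transcript has no CDS or no 3'UTR.
        """
        if not self.cds:
            return ""
        if self.strand == "+":
            cds_end = max(e for _, e in self.cds)
            parts = [(max(s, cds_end), e) for s, e in self.exons if e > cds_end]
        else:
            cds_start = min(s for s, _ in self.cds)
            parts = [(s, min(e, cds_start)) for s, e in self.exons if s < cds_start]
        parts = [(s, e) for s, e in parts if s < e]
        return self._concat(parts, genome)


def translate(nt: str, trim_stop: bool = False) -> str:
    """Translate a nucleotide string (length floored to whole codons)."""
    nt = nt[: len(nt) // 3 * 3]
    aa = str(Seq(nt).translate())
    if trim_stop and aa.endswith("*"):
        aa = aa[:-1]
    return aa


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read exon and CDS features of an Ensembl-dialect GTF into transcript models.

    GTF 1-based inclusive intervals are converted to 0-based half-open here.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, tuple] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        try:
            tid = feat.attributes["transcript_id"][0]
        except KeyError:
            raise FormatError(f"{path}: {feat.featuretype} line without transcript_id")
        gid = feat.attributes.get("gene_id", [tid])[0]
        gname = feat.attributes.get("gene_name", [gid])[0]
        meta.setdefault(tid, (gid, gname, feat.seqid, feat.strand))
        iv = (feat.start - 1, feat.end)  # 1-based inclusive -> 0-based half-open
        if feat.featuretype == "exon":
            exons.setdefault(tid, []).append(iv)
        else:
            frame = 0 if feat.frame in (None, ".") else int(feat.frame)
            cds.setdefault(tid, []).append((iv, frame))
    out = []
    for tid, (gid, gname, contig, strand) in meta.items():
        cds_ivs = sorted(cds.get(tid, []))
        phase = 0
        if cds_ivs:
            # first CDS in translation order carries the start phase
            first = cds_ivs[0] if strand == "+" else cds_ivs[-1]
            phase = first[1]
        out.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                gene_name=gname,
                contig=contig,
                strand=strand,
                exons=exons.get(tid, []),
                cds=[iv for iv, _ in cds_ivs],
                start_phase=phase,
            )
        )
    out.sort(key=lambda t: (t.contig, t.exons[0][0] if t.exons else 0, t.transcript_id))
    return out


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write exon and CDS lines (1-based inclusive) for the given transcripts."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'gene_name "{t.gene_name}";'
            )
            for s, e in t.exons:
                fh.write(
                    f"{t.contig}\tneopep\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )
            cds_sorted = t.cds if t.strand == "+" else list(reversed(t.cds))
            consumed = 0
            for s, e in cds_sorted:
                frame = (3 - ((consumed - t.start_phase) % 3)) % 3 if consumed else t.start_phase
                fh.write(
                    f"{t.contig}\tneopep\tCDS\t{s + 1}\t{e}\t.\t{t.strand}\t{frame}\t{attrs}\n"
                )
                consumed += e - s


# ---------------------------------------------------------------------------
# variants


@dataclass(frozen=True, order=True)
class VariantKey:
    """Canonical, hashable identity of a variant.  ``pos`` is 0-based."""

    contig: str
    pos: int
    ref: str
    alt: str

    def __str__(self) -> str:  # rendered 1-based for humans and files
        return f"{self.contig}:{self.pos + 1}:{self.ref}>{self.alt}"


@dataclass
class Variant:
    """One normalized SNV/indel call.  ``pos`` is 0-based internally."""

    contig: str
    pos: int
    ref: str
    alt: str
    filter_status: str = "PASS"
    read_depth: int = 0
    sample_id: str = ""
    caller_id: str = ""

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise FormatError("variant alleles must be non-empty")
        if self.ref == self.alt:
            raise FormatError(f"ref == alt ({self.ref}) at {self.contig}:{self.pos + 1}")
        if set(self.ref + self.alt) - set("ACGT"):
            raise FormatError(f"non-ACGT allele at {self.contig}:{self.pos + 1}")
        if self.read_depth < 0:
            raise FormatError("read_depth must be >= 0")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.contig, self.pos, self.ref, self.alt)


def _record_depth(rec) -> int:
    """FORMAT DP of the first sample when present, else INFO DP, else 0."""
    for sample in rec.samples.values():
        dp = sample.get("DP")
        if dp is not None:
            return int(dp[0] if isinstance(dp, tuple) else dp)
    dp = rec.info.get("DP")
    if dp is not None:
        return int(dp[0] if isinstance(dp, tuple) else dp)
    logger.warning(
        "no DP field at %s:%s; read_depth set to 0", rec.contig, rec.pos
    )
    return 0


def read_vcf(path: str | Path, caller_id: str = "", sample_id: str = "") -> list[Variant]:
    """Read a VCF 4.x file; multiallelic records are split per alt allele."""
    variants: list[Variant] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vf = pysam.VariantFile(str(path))
        for rec in vf:
            filt = ";".join(rec.filter.keys()) or "."
            depth = _record_depth(rec)
            for alt in rec.alts or ():
                variants.append(
                    Variant(
                        contig=rec.contig,
                        pos=rec.start,
                        ref=rec.ref,
                        alt=alt,
                        filter_status=filt,
                        read_depth=depth,
                        sample_id=sample_id,
                        caller_id=caller_id,
                    )
                )
        vf.close()
    return variants


def _vcf_header(contig_lengths: Mapping[str, int]) -> pysam.VariantHeader:
    hdr = pysam.VariantHeader()
    for contig, length in contig_lengths.items():
        hdr.contigs.add(contig, length=length)
    return hdr


def write_simple_vcf(
    variants: Sequence[Variant],
    path: str | Path,
    contig_lengths: Mapping[str, int],
    sample_id: str = "SAMPLE",
    depth_field: str = "format",
) -> None:
    """Write a single-sample VCF with depth in FORMAT DP or INFO DP.

    Both dialects are emitted in the wild (Platypus versions differ), so the
    writer supports either for round-trip testing.
    """
    hdr = _vcf_header(contig_lengths)
    if depth_field == "format":
        hdr.formats.add("GT", 1, "String", "Genotype")
        hdr.formats.add("DP", 1, "Integer", "Read depth")
    else:
        hdr.info.add("DP", 1, "Integer", "Read depth")
    for v in variants:
        for f in v.filter_status.split(";"):
            if f not in (".", "PASS") and f not in hdr.filters:
                hdr.filters.add(f, None, None, "non-default filter")
    hdr.add_sample(sample_id)
    out = pysam.VariantFile(str(path), "w", header=hdr)
    for v in sorted(variants, key=lambda v: (v.contig, v.pos, v.ref, v.alt)):
        rec = out.new_record(contig=v.contig, start=v.pos, alleles=(v.ref, v.alt))
        for f in v.filter_status.split(";"):
            if f != ".":
                rec.filter.add(f)
        if depth_field == "format":
            rec.samples[sample_id]["GT"] = (0, 1)
            rec.samples[sample_id]["DP"] = v.read_depth
        else:
            rec.info["DP"] = v.read_depth
        out.write(rec)
    out.close()


def write_vcf(
    keys: Sequence[VariantKey],
    sample_presence: Mapping[str, set] | pd.DataFrame,
    path: str | Path,
    contig_lengths: Mapping[str, int],
) -> None:
    """Write a multi-sample VCF with GT-like per-sample presence flags.

    ``sample_presence`` maps sample id -> set of present VariantKeys (or a
    boolean DataFrame indexed by key with one column per sample).  Present
    sites get GT 0/1, absent sites ./. .
    """
    if isinstance(sample_presence, pd.DataFrame):
        sample_presence = {
            s: {k for k in sample_presence.index[sample_presence[s]]}
            for s in sample_presence.columns
        }
    samples = sorted(sample_presence)
    hdr = _vcf_header(contig_lengths)
    hdr.formats.add("GT", 1, "String", "Presence flag (0/1 present, ./. absent)")
    for s in samples:
        hdr.add_sample(s)
    out = pysam.VariantFile(str(path), "w", header=hdr)
    for key in sorted(keys):
        rec = out.new_record(contig=key.contig, start=key.pos, alleles=(key.ref, key.alt))
        rec.filter.add("PASS")
        for s in samples:
            rec.samples[s]["GT"] = (0, 1) if key in sample_presence[s] else (None, None)
        out.write(rec)
    out.close()


# ---------------------------------------------------------------------------
# splice junctions (STAR SJ.out.tab)

_SJ_STRAND = {0: ".", 1: "+", 2: "-"}


@dataclass
class JunctionRecord:
    """One SJ.out.tab row; intron coordinates 1-based inclusive as in the file."""

    contig: str
    intron_start: int
    intron_end: int
    strand: str
    unique_reads: int
    annotated_flag: int = 0

    def __post_init__(self) -> None:
        if self.intron_start > self.intron_end:
            raise FormatError(
                f"inverted intron ({self.intron_start} > {self.intron_end}) on {self.contig}"
            )
        if self.unique_reads < 0:
            raise FormatError("unique_reads must be >= 0")
        if self.strand not in STRANDS:
            raise FormatError(f"bad strand {self.strand!r}")

    @property
    def interval(self) -> tuple[int, int]:
        """The intron as a 0-based half-open interval."""
        return (self.intron_start - 1, self.intron_end)


def read_sj_tab(path: str | Path) -> list[JunctionRecord]:
    """Read a 9-column STAR SJ.out.tab file."""
    df = pd.read_csv(str(path), sep="\t", header=None, dtype=str)
    if df.shape[1] != 9:
        raise FormatError(f"{path}: expected 9 columns, found {df.shape[1]}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            strand_code = int(row[3])
            records.append(
                JunctionRecord(
                    contig=str(row[0]),
                    intron_start=int(row[1]),
                    intron_end=int(row[2]),
                    strand=_SJ_STRAND[strand_code],
                    unique_reads=int(row[6]),
                    annotated_flag=int(row[5]),
                )
            )
        except (ValueError, KeyError, FormatError) as exc:
            raise FormatError(f"{path}: line {i}: {exc}") from exc
    return records


def write_sj_tab(records: Sequence[JunctionRecord], path: str | Path) -> None:
    code = {v: k for k, v in _SJ_STRAND.items()}
    with open(path, "w") as fh:
        for r in sorted(records, key=lambda r: (r.contig, r.intron_start, r.intron_end)):
            motif = 1 if r.strand != "." else 0
            fh.write(
                f"{r.contig}\t{r.intron_start}\t{r.intron_end}\t{code[r.strand]}"
                f"\t{motif}\t{r.annotated_flag}\t{r.unique_reads}\t0\t50\n"
            )


# ---------------------------------------------------------------------------
# expression / annotation tables


@dataclass(frozen=True)
class ExpressionRecord:
    transcript_id: str
    tpm: float

    def __post_init__(self) -> None:
        if self.tpm < 0:
            raise FormatError(f"{self.transcript_id}: negative TPM")


def read_quant(path: str | Path) -> list[ExpressionRecord]:
    """Read a `transcript_id<TAB>TPM` table (header line optional)."""
    records: list[ExpressionRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 columns")
            if lineno == 1 and parts[0].lower() in {"transcript_id", "transcript", "name"}:
                continue
            try:
                records.append(ExpressionRecord(parts[0], float(parts[1])))
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return records


def write_quant(records: Sequence[ExpressionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tTPM\n")
        for r in records:
            fh.write(f"{r.transcript_id}\t{r.tpm:g}\n")


@dataclass(frozen=True)
class AnnotationRecord:
    """One VEP-style consequence annotation row.  ``pos`` is 0-based internally."""

    contig: str
    pos: int
    ref: str
    alt: str
    transcript_id: str
    consequence: str
    protein_pos: int | None = None  # 1-based residue index, protein-changing only
    aa_ref: str = ""
    aa_alt: str = ""

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.contig, self.pos, self.ref, self.alt)


_ANNOT_COLS = [
    "chrom", "pos", "ref", "alt", "transcript_id",
    "consequence", "protein_pos", "aa_ref", "aa_alt",
]


def read_annotation(path: str | Path) -> list[AnnotationRecord]:
    """Read the 9-column consequence annotation TSV (header line required)."""
    df = pd.read_csv(str(path), sep="\t", dtype=str)
    missing = [c for c in _ANNOT_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    records = []
    for i, row in df.iterrows():
        lineno = i + 2  # header is line 1
        try:
            ppos = row["protein_pos"]
            ppos = None if pd.isna(ppos) or ppos in ("", ".") else int(ppos)
            records.append(
                AnnotationRecord(
                    contig=row["chrom"],
                    pos=int(row["pos"]) - 1,
                    ref=row["ref"],
                    alt=row["alt"],
                    transcript_id=row["transcript_id"],
                    consequence=row["consequence"],
                    protein_pos=ppos,
                    aa_ref="" if pd.isna(row["aa_ref"]) or row["aa_ref"] == "." else row["aa_ref"],
                    aa_alt="" if pd.isna(row["aa_alt"]) or row["aa_alt"] == "." else row["aa_alt"],
                )
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return records


def write_annotation(records: Sequence[AnnotationRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_ANNOT_COLS) + "\n")
        for r in records:
            ppos = "." if r.protein_pos is None else str(r.protein_pos)
            fh.write(
                f"{r.contig}\t{r.pos + 1}\t{r.ref}\t{r.alt}\t{r.transcript_id}"
                f"\t{r.consequence}\t{ppos}\t{r.aa_ref or '.'}\t{r.aa_alt or '.'}\n"
            )


# ---------------------------------------------------------------------------
# peptide FASTA

def write_peptide_fasta(peptides, path: str | Path) -> None:
    """Write peptide candidates with provenance-encoding headers.

    Header fields (``|``-separated): source, gene, variant key or event id,
    mut/wt flag, k.  Works for both SNV and junction candidates.
    """
    with open(path, "w") as fh:
        for i, p in enumerate(peptides):
            origin = getattr(p, "variant_key", None) or getattr(p, "event_id", "")
            flag = "mut" if getattr(p, "mutant", True) else "wt"
            gene = getattr(p, "gene_id", "") or ""
            k = getattr(p, "k", len(p.sequence))
            fh.write(f">{p.source}|{gene}|{origin}|{flag}|k{k}|{i}\n{p.sequence}\n")


def read_peptide_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Return (header, sequence) pairs; inverse of :func:`write_peptide_fasta`."""
    return [(rec.description, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


# ---------------------------------------------------------------------------
# BED (blacklists, validation targets)

def read_bed_intervals(path: str | Path) -> set[tuple[str, int, int]]:
    """Read a BED3+ file into a set of (contig, start, end), 0-based half-open."""
    out = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >= 3 columns")
            out.add((parts[0], int(parts[1]), int(parts[2])))
    return out


def write_bed_intervals(
    intervals: Iterable[tuple[str, int, int]], path: str | Path, names: Sequence[str] | None = None
) -> None:
    intervals = list(intervals)
    with open(path, "w") as fh:
        for i, (contig, start, end) in enumerate(intervals):
            name = names[i] if names else f"iv{i}"
            fh.write(f"{contig}\t{start}\t{end}\t{name}\n")
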
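"""Self-contained toy dataset generator with a truth manifest.

Emits everything the pipeline consumes — genome FASTA, GTF, per-aligner
RNA VCFs for two samples, a WES VCF, consequence annotation and transcript
quantification tables, STAR-style SJ.out.tab files, a two-group splice-event
table with intron coverage, and a normal-tissue blacklist — at the level the
pipeline reads (counts and calls, not reads; alignment is out of scope).

Every planted entity is stratified to straddle the pipeline's thresholds:
RNA depth 10 (strict), WES depth 20 (inclusive), TPM 1, intron confidence 5
(strict), and the caller-concordance and WES-intersection requirements.
The truth manifest records, per planted entity, which filters it should
survive, and the exact peptide sequences expected at the end of the run —
computed here by an independent sliding-window reimplementation of the
window rules operating on the generator's own construction strings, never
by calling the pipeline.

A single integer seed controls all randomness; sub-generators draw from
split RNG streams so changing one plan does not perturb the others.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Seq import Seq

from .binding import MockBindingBackend, NON_BINDER_NM
from .io_formats import (
    AnnotationRecord,
    ExpressionRecord,
    GenomeSequence,
    JunctionRecord,
    TranscriptModel,
    Variant,
    translate,
    write_annotation,
    write_bed_intervals,
    write_fasta,
    write_gtf,
    write_quant,
    write_simple_vcf,
    write_sj_tab,
)
from .intron_retention import SpliceEvent, compute_psi, write_event_table

CONTIG = "chr1"
SAMPLES = ("EV", "MIR")  # the two biological groups, one sample each
CALLERS = ("star", "tophat", "hisat2")
ALLELES = ("H-2Kb", "H-2Db")

_STOPS = ("TAA", "TAG", "TGA")
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


# ---------------------------------------------------------------------------
# toy genome


@dataclass
class SimGene:
    """Construction-time bookkeeping for one toy gene."""

    gene_id: str
    transcript_id: str
    strand: str
    utr5_len: int
    coding: str  # CDS including the stop codon, transcript orientation
    utr3_len: int
    tx_seq: str  # spliced transcript sequence (utr5 + coding + utr3)
    intron_seqs: list[str]  # transcript orientation
    exon_tx_spans: list[tuple[int, int]]  # spliced-transcript coords
    exon_block_spans: list[tuple[int, int]]  # transcript-with-introns coords
    block_start: int = 0  # genomic offset of the gene block
    block_len: int = 0

    def tx_to_genomic(self, p: int) -> int:
        """Map a spliced-transcript position to a genomic position."""
        for (ts, te), (bs, be) in zip(self.exon_tx_spans, self.exon_block_spans):
            if ts <= p < te:
                q = bs + (p - ts)
                if self.strand == "+":
                    return self.block_start + q
                return self.block_start + self.block_len - 1 - q
        raise ValueError(f"tx position {p} outside exons")

    def tx_interval_to_genomic(self, a: int, b: int) -> list[tuple[int, int]]:
        """Map a spliced interval [a, b) to sorted genomic intervals."""
        out = []
        for (ts, te), (bs, be) in zip(self.exon_tx_spans, self.exon_block_spans):
            lo, hi = max(a, ts), min(b, te)
            if lo >= hi:
                continue
            qs, qe = bs + (lo - ts), bs + (hi - ts)
            if self.strand == "+":
                out.append((self.block_start + qs, self.block_start + qe))
            else:
                out.append(
                    (self.block_start + self.block_len - qe,
                     self.block_start + self.block_len - qs)
                )
        return sorted(out)

    @property
    def protein(self) -> str:
        return translate(self.coding, trim_stop=True)

    def genomic_introns(self) -> list[tuple[int, int]]:
        out = []
        for i in range(len(self.exon_block_spans) - 1):
            bs = self.exon_block_spans[i][1]
            be = self.exon_block_spans[i + 1][0]
            if self.strand == "+":
                out.append((self.block_start + bs, self.block_start + be))
            else:
                out.append(
                    (self.block_start + self.block_len - be,
                     self.block_start + self.block_len - bs)
                )
        return sorted(out)

    def transcript_order_intron(self, i: int) -> tuple[int, int]:
        """The i-th intron in transcript (translation) order, genomic coords."""
        introns = self.genomic_introns()
        return introns[i] if self.strand == "+" else introns[len(introns) - 1 - i]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def make_toy_genome(
    n_genes: int = 18,
    exons_per_gene: int = 3,
    seed: int = 0,
    codons_per_gene: int = 60,
    utr_len: int = 15,
) -> tuple[GenomeSequence, list[TranscriptModel], list[SimGene]]:
    """Build a deterministic multi-gene toy genome on one contig.

    Genes alternate strands; every CDS starts with ATG, has no internal
    stop, and ends with an in-frame stop codon (included in the annotated
    CDS intervals — see the methods note).  Terminal exons carry short
    UTRs so junction donors can be planted past the stop codon.
    """
    rng = np.random.default_rng([seed, 101])
    genome_parts: list[str] = []
    offset = 0
    genes: list[SimGene] = []
    transcripts: list[TranscriptModel] = []
    for gi in range(n_genes):
        spacer = _random_seq(rng, int(rng.integers(80, 161)))
        genome_parts.append(spacer)
        offset += len(spacer)

        coding = (
            "ATG"
            + "".join(rng.choice(_CODONS, size=codons_per_gene - 2))
            + _STOPS[int(rng.integers(0, 3))]
        )
        utr5 = _random_seq(rng, utr_len)
        utr3 = _random_seq(rng, utr_len + 45)  # room for post-stop junction donors
        tx = utr5 + coding + utr3

        # split the spliced transcript into exons (each >= 25 nt)
        n_ex = exons_per_gene
        base = len(tx) // n_ex
        lengths = [base] * (n_ex - 1) + [len(tx) - base * (n_ex - 1)]
        for j in range(n_ex - 1):
            jitter = int(rng.integers(-base // 4, base // 4 + 1))
            if lengths[j] + jitter >= 25 and lengths[j + 1] - jitter >= 25:
                lengths[j] += jitter
                lengths[j + 1] -= jitter
        exon_tx_spans = []
        pos = 0
        for L in lengths:
            exon_tx_spans.append((pos, pos + L))
            pos += L
        intron_seqs = [
            "GT" + _random_seq(rng, int(rng.integers(56, 117))) + "AG"
            for _ in range(n_ex - 1)
        ]
        block_parts = []
        exon_block_spans = []
        bpos = 0
        for j, (ts, te) in enumerate(exon_tx_spans):
            block_parts.append(tx[ts:te])
            exon_block_spans.append((bpos, bpos + (te - ts)))
            bpos += te - ts
            if j < len(intron_seqs):
                block_parts.append(intron_seqs[j])
                bpos += len(intron_seqs[j])
        block = "".join(block_parts)

        strand = "+" if gi % 2 == 0 else "-"
        placed = block if strand == "+" else str(Seq(block).reverse_complement())
        gene = SimGene(
            gene_id=f"gene{gi:02d}",
            transcript_id=f"tx{gi:02d}",
            strand=strand,
            utr5_len=len(utr5),
            coding=coding,
            utr3_len=len(utr3),
            tx_seq=tx,
            intron_seqs=intron_seqs,
            exon_tx_spans=exon_tx_spans,
            exon_block_spans=exon_block_spans,
            block_start=offset,
            block_len=len(block),
        )
        genome_parts.append(placed)
        offset += len(block)
        genes.append(gene)

        exons = gene.tx_interval_to_genomic(0, len(tx))
        cds = gene.tx_interval_to_genomic(gene.utr5_len, gene.utr5_len + len(coding))
        transcripts.append(
            TranscriptModel(
                transcript_id=gene.transcript_id,
                gene_id=gene.gene_id,
                gene_name=gene.gene_id.upper(),
                contig=CONTIG,
                strand=strand,
                exons=exons,
                cds=cds,
                start_phase=0,
            )
        )
    genome_parts.append(_random_seq(rng, 200))
    genome = GenomeSequence({CONTIG: "".join(genome_parts)})
    return genome, transcripts, genes


# ---------------------------------------------------------------------------
# variant planting


@dataclass
class VariantPlan:
    """How many variants to plant in each filter stratum."""

    concordant: int = 5  # 3/3 callers, WES-confirmed, expressed, missense: survivors
    partial: int = 3  # called by only 1-2 aligners
    wes_absent: int = 2  # concordant but missing from WES
    low_tpm: int = 2  # concordant + WES but gene below 1 TPM
    synonymous: int = 2  # concordant + WES + expressed but silent
    low_depth: int = 1  # depth exactly 10 in one caller (fails strict > 10)
    fail_filter: int = 1  # non-PASS FILTER in one caller
    noise_per_caller: int = 3  # caller-unique distractors


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _plant_one_substitution(
    rng: np.random.Generator, gene: SimGene, used_codons: set[tuple[str, int]],
    synonymous: bool,
) -> dict:
    """Pick a codon and a single-base change of the requested kind."""
    n_codons = len(gene.coding) // 3
    for _ in range(200):
        ci = int(rng.integers(2, n_codons - 2))
        if (gene.gene_id, ci) in used_codons:
            continue
        codon = gene.coding[3 * ci : 3 * ci + 3]
        offsets = rng.permutation(3)
        bases = rng.permutation(list("ACGT"))
        for off in offsets:
            for b in bases:
                if b == codon[off]:
                    continue
                new = codon[:off] + b + codon[off + 1 :]
                if new in _STOPS:
                    continue
                same_aa = translate(new) == translate(codon)
                if same_aa != synonymous:
                    continue
                used_codons.add((gene.gene_id, ci))
                tx_pos = gene.utr5_len + 3 * ci + int(off)
                g = gene.tx_to_genomic(tx_pos)
                if gene.strand == "+":
                    ref, alt = codon[off], b
                else:
                    ref = codon[off].translate(_COMPLEMENT)
                    alt = b.translate(_COMPLEMENT)
                return {
                    "gene": gene,
                    "codon_index": ci,
                    "pos": g,
                    "ref": ref,
                    "alt": alt,
                    "aa_ref": translate(codon),
                    "aa_alt": translate(new),
                    "mut_codon": new,
                }
    raise RuntimeError(f"could not plant a variant in {gene.gene_id}")


def _window_oracle(wt: str, mut: str, aa_pos: int, k: int) -> list[str]:
    """Brute force: every k-mer of ``mut`` differing from the aligned wt k-mer."""
    out = []
    for s in range(0, len(mut) - k + 1):
        if s <= aa_pos < s + k and mut[s : s + k] != wt[s : s + k]:
            out.append(mut[s : s + k])
    return out


def plant_variants(
    genome: GenomeSequence,
    transcripts: Sequence[TranscriptModel],
    genes: Sequence[SimGene],
    plan: VariantPlan,
    seed: int,
    out_dir: Path,
    ks: Sequence[int] = (8, 9),
) -> dict:
    """Plant stratified variants; write VCFs/annotation/quant; return manifest part."""
    rng = np.random.default_rng([seed, 202])
    out_dir = Path(out_dir)
    (out_dir / "rna").mkdir(parents=True, exist_ok=True)

    classes = (
        ["concordant"] * plan.concordant
        + ["partial"] * plan.partial
        + ["wes_absent"] * plan.wes_absent
        + ["low_tpm"] * plan.low_tpm
        + ["synonymous"] * plan.synonymous
        + ["low_depth"] * plan.low_depth
        + ["fail_filter"] * plan.fail_filter
    )
    if len(classes) > len(genes):
        raise ValueError("more variant classes than available genes")
    gene_order = list(rng.permutation(len(genes)))
    used_codons: set[tuple[str, int]] = set()

    planted: list[dict] = []
    for idx, cls in enumerate(classes):
        gene = genes[gene_order[idx]]
        sub = _plant_one_substitution(rng, gene, used_codons, synonymous=(cls == "synonymous"))
        callers = list(CALLERS)
        if cls == "partial":
            n = int(rng.integers(1, 3))
            callers = sorted(rng.choice(CALLERS, size=n, replace=False))
        depths = {c: int(rng.integers(15, 40)) for c in callers}
        filt = {c: "PASS" for c in callers}
        if cls == "low_depth":
            depths[CALLERS[0]] = 10  # fails the strict > 10 rule
        if cls == "fail_filter":
            filt[CALLERS[0]] = "badReads"
        samples = list(SAMPLES)
        if cls == "concordant" and idx == 0:
            samples = [SAMPLES[0]]  # exercise the presence matrix
        planted.append(
            {
                "class": cls,
                "gene_id": gene.gene_id,
                "transcript_id": gene.transcript_id,
                "contig": CONTIG,
                "pos": sub["pos"],
                "ref": sub["ref"],
                "alt": sub["alt"],
                "codon_index": sub["codon_index"],
                "mut_codon": sub["mut_codon"],
                "aa_ref": sub["aa_ref"],
                "aa_alt": sub["aa_alt"],
                "callers": callers,
                "depths": depths,
                "filters": filt,
                "samples": samples,
                "in_wes": cls not in ("wes_absent",),
                "expressed": cls != "low_tpm",
            }
        )

    # caller-unique noise SNVs (never concordant)
    noise: list[dict] = []
    for caller in CALLERS:
        for _ in range(plan.noise_per_caller):
            gene = genes[int(rng.integers(0, len(genes)))]
            try:
                sub = _plant_one_substitution(rng, gene, used_codons, synonymous=False)
            except RuntimeError:
                continue
            noise.append(
                {
                    "caller": caller,
                    "pos": sub["pos"],
                    "ref": sub["ref"],
                    "alt": sub["alt"],
                    "depth": int(rng.integers(15, 40)),
                }
            )

    contig_lengths = genome.lengths()
    depth_dialect = {"star": "format", "tophat": "info", "hisat2": "format"}
    for sample in SAMPLES:
        for caller in CALLERS:
            records = []
            for p in planted:
                if caller in p["callers"] and sample in p["samples"]:
                    records.append(
                        Variant(
                            contig=CONTIG,
                            pos=p["pos"],
                            ref=p["ref"],
                            alt=p["alt"],
                            filter_status=p["filters"][caller],
                            read_depth=p["depths"][caller],
                            sample_id=sample,
                            caller_id=caller,
                        )
                    )
            records += [
                Variant(CONTIG, n["pos"], n["ref"], n["alt"], "PASS", n["depth"], sample, caller)
                for n in noise
                if n["caller"] == caller
            ]
            write_simple_vcf(
                records,
                out_dir / "rna" / f"{sample}.{caller}.vcf",
                contig_lengths,
                sample_id=sample,
                depth_field=depth_dialect[caller],
            )

    wes_records = [
        Variant(CONTIG, p["pos"], p["ref"], p["alt"], "PASS", int(rng.integers(25, 60)), "WES", "bwa")
        for p in planted
        if p["in_wes"]
    ]
    # a DNA-only call that never appears in RNA
    spare = genes[gene_order[len(classes)]]
    sub = _plant_one_substitution(rng, spare, used_codons, synonymous=False)
    wes_records.append(Variant(CONTIG, sub["pos"], sub["ref"], sub["alt"], "PASS", 30, "WES", "bwa"))
    write_simple_vcf(wes_records, out_dir / "wes.vcf", contig_lengths, sample_id="WES")

    annotation = [
        AnnotationRecord(
            contig=CONTIG,
            pos=p["pos"],
            ref=p["ref"],
            alt=p["alt"],
            transcript_id=p["transcript_id"],
            consequence="synonymous_variant" if p["class"] == "synonymous" else "missense_variant",
            protein_pos=None if p["class"] == "synonymous" else p["codon_index"] + 1,
            aa_ref=p["aa_ref"],
            aa_alt=p["aa_alt"],
        )
        for p in planted
    ]
    write_annotation(annotation, out_dir / "annotation.tsv")

    gene_tpm: dict[str, float] = {}
    for gene in genes:
        hosted = [p for p in planted if p["gene_id"] == gene.gene_id]
        if any(p["class"] == "low_tpm" for p in hosted):
            gene_tpm[gene.gene_id] = round(float(rng.uniform(0.1, 0.8)), 3)
        else:
            gene_tpm[gene.gene_id] = round(float(rng.uniform(2.0, 50.0)), 3)
    write_quant(
        [ExpressionRecord(g.transcript_id, gene_tpm[g.gene_id]) for g in genes],
        out_dir / "quant.tsv",
    )

    # ---- expectations, computed from construction strings ----
    gene_by_id = {g.gene_id: g for g in genes}
    survivors = [p for p in planted if p["class"] == "concordant"]
    expected_peptides: set[str] = set()
    for p in survivors:
        gene = gene_by_id[p["gene_id"]]
        wt = gene.protein
        ci = p["codon_index"]
        mut_coding = gene.coding[: 3 * ci] + p["mut_codon"] + gene.coding[3 * ci + 3 :]
        mut = translate(mut_coding, trim_stop=True)
        for k in ks:
            expected_peptides.update(_window_oracle(wt, mut, ci, k))
    backend = MockBindingBackend(seed)
    expected_final = {
        pep
        for pep in expected_peptides
        if min(backend.affinity(pep, a) for a in ALLELES) <= NON_BINDER_NM
    }

    def key_str(p):
        return f"{CONTIG}:{p['pos'] + 1}:{p['ref']}>{p['alt']}"

    concordant_classes = {"concordant", "wes_absent", "low_tpm", "synonymous"}
    expected_concordant = {
        sample: sorted(
            key_str(p) for p in planted
            if p["class"] in concordant_classes and sample in p["samples"]
        )
        for sample in SAMPLES
    }
    expected_integrated = sorted(
        key_str(p) for p in planted if p["class"] in concordant_classes and p["in_wes"]
    )
    return {
        "variants": [
            {k: v for k, v in p.items() if k not in ("depths", "filters")}
            | {"key": key_str(p)}
            for p in planted
        ],
        "expected_concordant_keys": expected_concordant,
        "expected_integrated_keys": expected_integrated,
        "expected_snv_peptides_pre_binding": sorted(expected_peptides),
        "expected_snv_peptides": sorted(expected_final),
        "gene_tpm": gene_tpm,
    }


# ---------------------------------------------------------------------------
# splicing planting


@dataclass
class SplicingPlan:
    clean_novel: int = 2  # in-frame novel acceptors, clean translation
    frameshift_novel: int = 1  # out-of-frame novel acceptor
    upstream_stop: int = 1  # donor past the stop codon: zero peptides expected
    annotated_only: int = 1  # event with only annotated junctions: filtered out
    ir_kept: int = 2  # differential, confident, unlisted IR
    ir_no_delta: int = 1
    ir_low_conf: int = 1
    ir_blacklisted: int = 1


def _independent_junction_peptides(
    upstream_full: str, downstream: str, reference: str, k: int = 9
) -> list[str]:
    """Sliding-window reimplementation of the junction translation rules.

    Operates purely on construction strings: coding-anchored upstream flank
    (frame 0 relative to its start), novel downstream sequence, and the host
    reference protein.  Used only to write manifest expectations.
    """
    up = upstream_full[-3 * (k - 1) :]
    skipped = len(upstream_full) - len(up)
    frame = (3 - (skipped % 3)) % 3
    seq = up + downstream[: 3 * (k - 1) + 3]
    joffset = len(up)
    pep = translate(seq[frame:])
    d = joffset - frame
    jc = max(0, math.ceil((d - 2) / 3))
    stop = pep.find("*")
    if 0 <= stop < jc:
        return []
    if stop >= 0:
        pep = pep[:stop]
    if len(pep) < k:
        return []
    if jc > 0:
        m = reference.find(pep[:jc])
        if m >= 0:
            aligned = reference[m : m + len(pep)]
            changed = {i for i in range(len(pep)) if i >= len(aligned) or pep[i] != aligned[i]}
        else:
            changed = set(range(jc, len(pep)))
    else:
        changed = set(range(len(pep)))
    return [
        pep[s : s + k]
        for s in range(len(pep) - k + 1)
        if changed.intersection(range(s, s + k))
    ]


def plant_splicing(
    genome: GenomeSequence,
    transcripts: Sequence[TranscriptModel],
    genes: Sequence[SimGene],
    plan: SplicingPlan,
    seed: int,
    out_dir: Path,
    reserved_genes: set[str] = frozenset(),
) -> dict:
    """Plant novel junctions and IR events; write SJ/event/coverage/blacklist files."""
    rng = np.random.default_rng([seed, 303])
    out_dir = Path(out_dir)
    (out_dir / "sj").mkdir(parents=True, exist_ok=True)
    gene_by_id = {g.gene_id: g for g in genes}
    tx_by_gene = {t.gene_id: t for t in transcripts}
    pool = [g for g in genes if g.gene_id not in reserved_genes]
    rng.shuffle(pool)
    pool_iter = iter(pool)

    def next_gene() -> SimGene:
        try:
            return next(pool_iter)
        except StopIteration:
            raise ValueError("not enough genes to host all splicing plants")

    sj_extra: list[JunctionRecord] = []  # novel junctions, both samples
    events: list[SpliceEvent] = []
    manifest_events: list[dict] = []
    expected_peptides: set[str] = set()
    coverage_rows: list[dict] = []
    blacklist: list[tuple[str, int, int]] = []
    eid = 0

    def upstream_context(gene: SimGene, tx_cut: int) -> str:
        """Exonic sequence from the CDS start to the junction donor (tx coords)."""
        return gene.tx_seq[gene.utr5_len : tx_cut]

    # -- novel-acceptor junction events ------------------------------------
    def plant_novel(delta: int, want_peptides: bool) -> None:
        nonlocal eid
        for _ in range(len(pool)):
            gene = next_gene()
            tx = tx_by_gene[gene.gene_id]
            s, e = gene.transcript_order_intron(0)
            if gene.strand == "+":
                novel = (s, e + delta)
                down = genome.fetch(CONTIG, novel[1], novel[1] + 30)
            else:
                novel = (s - delta, e)
                down = str(Seq(genome.fetch(CONTIG, novel[0] - 30, novel[0])).reverse_complement())
            tx_cut = gene.exon_tx_spans[0][1]  # donor at the first exon boundary
            peps = _independent_junction_peptides(
                upstream_context(gene, tx_cut), down, gene.protein
            )
            if want_peptides and not peps:
                continue  # e.g. immediate stop at the hybrid junction codon: redraw
            eid += 1
            ev_id = f"EV{eid:03d}"
            events.append(
                SpliceEvent(
                    event_id=ev_id,
                    event_type="alt_3prime",
                    gene_id=gene.gene_id,
                    contig=CONTIG,
                    strand=gene.strand,
                    junctions=[novel],
                    intron_confidence={s: 6.0 for s in SAMPLES},
                    junction_reads={s: 6.0 for s in SAMPLES},
                    psi={s: 0.5 for s in SAMPLES},
                )
            )
            sj_extra.append(
                JunctionRecord(CONTIG, novel[0] + 1, novel[1], gene.strand,
                               int(rng.integers(15, 40)), 0)
            )
            expected_peptides.update(peps)
            manifest_events.append(
                {
                    "event_id": ev_id,
                    "class": "frameshift_novel" if delta % 3 else "clean_novel",
                    "gene_id": gene.gene_id,
                    "junction": [novel[0] + 1, novel[1]],  # 1-based inclusive
                    "upstream_stop": False,
                    "expected_peptides": sorted(peps),
                }
            )
            return
        raise ValueError("could not place a novel junction with surviving peptides")

    for _ in range(plan.clean_novel):
        plant_novel(delta=6, want_peptides=True)
    for _ in range(plan.frameshift_novel):
        plant_novel(delta=7, want_peptides=True)

    # -- upstream-stop junction: donor 3 nt past the stop codon ------------
    for _ in range(plan.upstream_stop):
        gene = next_gene()
        tx_cut = gene.utr5_len + len(gene.coding) + 3
        g = gene.tx_to_genomic(tx_cut - 1)  # last exonic base before the junction
        if gene.strand == "+":
            novel = (g + 1, g + 81)
            down = genome.fetch(CONTIG, novel[1], novel[1] + 30)
        else:
            novel = (g - 80, g)
            down = str(Seq(genome.fetch(CONTIG, novel[0] - 30, novel[0])).reverse_complement())
        peps = _independent_junction_peptides(upstream_context(gene, tx_cut), down, gene.protein)
        assert peps == [], "upstream-stop plant must yield no peptides"
        eid += 1
        ev_id = f"EV{eid:03d}"
        events.append(
            SpliceEvent(
                event_id=ev_id,
                event_type="alt_5prime",
                gene_id=gene.gene_id,
                contig=CONTIG,
                strand=gene.strand,
                junctions=[novel],
                intron_confidence={s: 6.0 for s in SAMPLES},
                junction_reads={s: 6.0 for s in SAMPLES},
                psi={s: 0.5 for s in SAMPLES},
            )
        )
        sj_extra.append(
            JunctionRecord(CONTIG, novel[0] + 1, novel[1], gene.strand,
                           int(rng.integers(15, 40)), 0)
        )
        manifest_events.append(
            {
                "event_id": ev_id,
                "class": "upstream_stop",
                "gene_id": gene.gene_id,
                "junction": [novel[0] + 1, novel[1]],
                "upstream_stop": True,
                "expected_peptides": [],
            }
        )

    # -- all-annotated event (must be filtered out) ------------------------
    for _ in range(plan.annotated_only):
        gene = next_gene()
        s, e = gene.transcript_order_intron(0)
        eid += 1
        ev_id = f"EV{eid:03d}"
        events.append(
            SpliceEvent(
                event_id=ev_id,
                event_type="exon_skip",
                gene_id=gene.gene_id,
                contig=CONTIG,
                strand=gene.strand,
                junctions=[(s, e)],
                intron_confidence={smp: 6.0 for smp in SAMPLES},
                junction_reads={smp: 6.0 for smp in SAMPLES},
                psi={smp: 0.5 for smp in SAMPLES},
            )
        )
        manifest_events.append(
            {
                "event_id": ev_id,
                "class": "annotated_only",
                "gene_id": gene.gene_id,
                "junction": [s + 1, e],
                "upstream_stop": False,
                "expected_peptides": [],
            }
        )

    # -- intron-retention events -------------------------------------------
    ir_specs = (
        [("ir_kept", (8, 5, 2, 18), False)] * plan.ir_kept
        + [("ir_no_delta", (9, 9, 9, 9), False)] * plan.ir_no_delta
        + [("ir_low_conf", (5, 2, 4, 30), False)] * plan.ir_low_conf
        + [("ir_blacklisted", (10, 4, 1, 20), True)] * plan.ir_blacklisted
    )
    for cls, (conf_a, jr_a, conf_b, jr_b), listed in ir_specs:
        expects_peptides = cls == "ir_kept"
        for _ in range(len(pool) + 1):
            gene = next_gene()
            intron_i = 0
            s, e = gene.transcript_order_intron(intron_i)
            intron_seq = gene.intron_seqs[intron_i]  # transcript orientation
            tx_cut = gene.exon_tx_spans[intron_i][1]
            peps = _independent_junction_peptides(
                upstream_context(gene, tx_cut), intron_seq, gene.protein
            )
            if expects_peptides and not peps:
                continue  # early in-frame stop inside the intron: redraw gene
            break
        else:
            raise ValueError("could not place a peptide-yielding IR event")
        eid += 1
        ev_id = f"EV{eid:03d}"
        psi = {SAMPLES[0]: compute_psi(conf_a, jr_a), SAMPLES[1]: compute_psi(conf_b, jr_b)}
        events.append(
            SpliceEvent(
                event_id=ev_id,
                event_type="intron_retention",
                gene_id=gene.gene_id,
                contig=CONTIG,
                strand=gene.strand,
                junctions=[(s, e)],
                intron_confidence={SAMPLES[0]: conf_a, SAMPLES[1]: conf_b},
                junction_reads={SAMPLES[0]: jr_a, SAMPLES[1]: jr_b},
                psi=psi,
            )
        )
        for sample, conf in ((SAMPLES[0], conf_a), (SAMPLES[1], conf_b)):
            coverage_rows.append(
                {"contig": CONTIG, "intron_start": s + 1, "intron_end": e,
                 "sample": sample, "coverage": conf}
            )
        if listed:
            blacklist.append((CONTIG, s, e))
        kept = cls == "ir_kept"
        if kept:
            expected_peptides.update(peps)
        manifest_events.append(
            {
                "event_id": ev_id,
                "class": cls,
                "gene_id": gene.gene_id,
                "junction": [s + 1, e],
                "upstream_stop": False,
                "expected_kept": kept,
                "expected_peptides": sorted(peps) if kept else [],
            }
        )

    # -- per-sample SJ files: annotated negatives + planted novels ---------
    ir_reads = {
        ev.event_id: ev.junction_reads for ev in events if ev.event_type == "intron_retention"
    }
    ir_introns = {
        ev.junctions[0]: ev.junction_reads for ev in events
        if ev.event_type == "intron_retention"
    }
    for sample in SAMPLES:
        records = []
        for t in transcripts:
            for s, e in t.introns():
                reads = ir_introns.get((s, e), {}).get(sample)
                if reads is None:
                    reads = int(rng.integers(20, 60))
                records.append(JunctionRecord(t.contig, s + 1, e, t.strand, int(reads), 1))
        records.extend(sj_extra)
        write_sj_tab(records, out_dir / "sj" / f"{sample}.SJ.out.tab")

    write_event_table(events, out_dir / "events.tsv", groups=list(SAMPLES))
    import pandas as pd

    pd.DataFrame(
        coverage_rows, columns=["contig", "intron_start", "intron_end", "sample", "coverage"]
    ).to_csv(out_dir / "intron_coverage.tsv", sep="\t", index=False)
    write_bed_intervals(blacklist, out_dir / "blacklist.bed")

    backend = MockBindingBackend(seed)
    expected_final = {
        pep
        for pep in expected_peptides
        if min(backend.affinity(pep, a) for a in ALLELES) <= NON_BINDER_NM
    }
    return {
        "junction_events": manifest_events,
        "expected_kept_ir_event_ids": sorted(
            m["event_id"] for m in manifest_events if m.get("expected_kept")
        ),
        "expected_junction_peptides_pre_binding": sorted(expected_peptides),
        "expected_junction_peptides": sorted(expected_final),
    }


# ---------------------------------------------------------------------------
# top-level


def simulate(
    out_dir: str | Path,
    seed: int = 0,
    n_genes: int = 24,
    exons_per_gene: int = 3,
    variant_plan: VariantPlan | None = None,
    splicing_plan: SplicingPlan | None = None,
) -> dict:
    """Write a complete toy input tree plus ``truth.json``; return the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    variant_plan = variant_plan or VariantPlan()
    splicing_plan = splicing_plan or SplicingPlan()

    genome, transcripts, genes = make_toy_genome(
        n_genes=n_genes, exons_per_gene=exons_per_gene, seed=seed
    )
    write_fasta(genome, out_dir / "genome.fa")
    write_gtf(transcripts, out_dir / "annotation.gtf")

    vpart = plant_variants(genome, transcripts, genes, variant_plan, seed, out_dir)
    variant_genes = {v["gene_id"] for v in vpart["variants"]}
    spart = plant_splicing(
        genome, transcripts, genes, splicing_plan, seed, out_dir,
        reserved_genes=variant_genes,
    )

    manifest = {
        "seed": seed,
        "binding_seed": seed,
        "contig": CONTIG,
        "samples": list(SAMPLES),
        "callers": list(CALLERS),
        "alleles": list(ALLELES),
        **vpart,
        **spart,
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
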
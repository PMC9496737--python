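"""End-to-end orchestration: variants -> peptides with provenance capture.

Each stage writes its artifact to the output directory so any stage can be
inspected or rerun in isolation; the run report counts records in and out
of every filter.  With the mock binding backend and a fixed seed the whole
run is deterministic (byte-identical outputs across reruns).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import binding as binding_mod
from .binding import MockBindingBackend, NetMHCBackend, predict_binding
from .io_formats import (
    read_annotation,
    read_bed_intervals,
    read_fasta,
    read_gtf,
    read_quant,
    read_sj_tab,
    read_vcf,
    write_peptide_fasta,
    write_vcf,
)
from .intron_retention import ir_priority_filter, read_event_table
from .junctions import (
    build_annotated_junctions,
    classify_junctions,
    event_contains_novel_junction,
    junction_peptides_for_event,
    novel_junction_keys,
)
from .snv_peptides import (
    PeptideCandidate,
    VariantOutsideCDS,
    binder_filter,
    enumerate_snv_peptides,
    expression_filter,
    mutant_protein,
)
from .variants import (
    concordant_snvs,
    filter_consequences,
    filter_rna_variants,
    filter_wes_variants,
    integrate_wes,
    merge_samples,
    normalize_variant,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All inputs and thresholds of one pipeline run.

    The config is serialized verbatim into the output directory for
    provenance.  ``rna_vcfs`` maps sample -> caller -> path.
    """

    genome_fasta: str
    gtf: str
    rna_vcfs: dict[str, dict[str, str]]
    wes_vcf: str
    annotation_tsv: str
    quant_tsv: str
    sj_tabs: dict[str, str]
    event_tsv: str
    blacklist_bed: str | None
    out_dir: str
    samples: list[str] = field(default_factory=list)
    min_depth: int = 10
    wes_min_reads: int = 20
    min_tpm: float = 1.0
    k_list: tuple[int, ...] = (8, 9)
    strong_nm: float = 500.0
    non_binder_nm: float = 5000.0
    min_confidence: float = 5.0
    min_delta_psi: float = 0.1
    alleles: tuple[str, ...] = ("H-2Kb", "H-2Db")
    backend: str = "mock"  # or "external"
    netmhc_executable: str = "netMHC"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.samples:
            self.samples = sorted(self.rna_vcfs)
        if not set(self.k_list) <= set(range(8, 12)):
            raise ValueError("k_list must be within 8..11")
        for name in ("min_tpm", "strong_nm", "non_binder_nm", "min_confidence",
                     "min_delta_psi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_simulation(cls, sim_dir: str | Path, out_dir: str | Path, **overrides) -> "RunConfig":
        """Build a config pointing at a :func:`neopep.simulate.simulate` tree."""
        sim_dir = Path(sim_dir)
        with open(sim_dir / "truth.json") as fh:
            manifest = json.load(fh)
        samples = manifest["samples"]
        callers = manifest["callers"]
        kwargs = dict(
            genome_fasta=str(sim_dir / "genome.fa"),
            gtf=str(sim_dir / "annotation.gtf"),
            rna_vcfs={
                s: {c: str(sim_dir / "rna" / f"{s}.{c}.vcf") for c in callers}
                for s in samples
            },
            wes_vcf=str(sim_dir / "wes.vcf"),
            annotation_tsv=str(sim_dir / "annotation.tsv"),
            quant_tsv=str(sim_dir / "quant.tsv"),
            sj_tabs={s: str(sim_dir / "sj" / f"{s}.SJ.out.tab") for s in samples},
            event_tsv=str(sim_dir / "events.tsv"),
            blacklist_bed=str(sim_dir / "blacklist.bed"),
            out_dir=str(out_dir),
            samples=list(samples),
            seed=manifest.get("binding_seed", 0),
            alleles=tuple(manifest.get("alleles", ("H-2Kb", "H-2Db"))),
        )
        kwargs.update(overrides)
        return cls(**kwargs)


def _make_backend(config: RunConfig):
    if config.backend == "mock":
        return MockBindingBackend(seed=config.seed)
    if config.backend == "external":
        return NetMHCBackend(executable=config.netmhc_executable)
    raise ValueError(f"unknown backend {config.backend!r}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run report (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}

    def stage(name: str, **counts) -> None:
        report["stages"][name] = counts
        logger.info("%s: %s", name, counts)

    with open(out / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=1, sort_keys=True)

    genome = read_fasta(config.genome_fasta)
    transcripts = read_gtf(config.gtf)
    tx_by_id = {t.transcript_id: t for t in transcripts}
    tx2gene = {t.transcript_id: t.gene_id for t in transcripts}

    # ---- RNA concordance across aligners ---------------------------------
    concordance_by_sample = {}
    rna_in = rna_filtered = 0
    for sample in config.samples:
        per_caller = {}
        for caller, path in config.rna_vcfs[sample].items():
            raw = read_vcf(path, caller_id=caller, sample_id=sample)
            rna_in += len(raw)
            kept = [
                normalize_variant(v, genome)
                for v in filter_rna_variants(raw, min_depth=config.min_depth)
            ]
            rna_filtered += len(kept)
            per_caller[caller] = kept
        concordance_by_sample[sample] = concordant_snvs(per_caller, sample_id=sample)
    rna_table = merge_samples(concordance_by_sample)
    stage(
        "concordance",
        variants_in=rna_in,
        after_depth_filter=rna_filtered,
        concordant_per_sample={s: len(r) for s, r in concordance_by_sample.items()},
        merged_sites=int(len(rna_table)),
    )
    write_vcf(list(rna_table.index), rna_table, out / "concordant.vcf", genome.lengths())

    # ---- WES integration --------------------------------------------------
    wes_raw = read_vcf(config.wes_vcf, caller_id="wes", sample_id="WES")
    wes_kept = [
        normalize_variant(v, genome)
        for v in filter_wes_variants(wes_raw, min_reads=config.wes_min_reads)
    ]
    integrated = integrate_wes(rna_table, wes_kept)
    stage(
        "wes_integration",
        wes_in=len(wes_raw),
        wes_after_filter=len(wes_kept),
        integrated_sites=int(len(integrated)),
    )
    write_vcf(list(integrated.index), integrated, out / "integrated.vcf", genome.lengths())

    # ---- consequence filter and SNV peptide enumeration -------------------
    annotation = read_annotation(config.annotation_tsv)
    kept_annotation = filter_consequences(annotation)
    integrated_keys = set(integrated.index)
    relevant = [r for r in kept_annotation if r.key in integrated_keys]
    candidates: list[PeptideCandidate] = []
    for rec in sorted(relevant, key=lambda r: (r.key, r.transcript_id)):
        transcript = tx_by_id.get(rec.transcript_id)
        if transcript is None or not transcript.cds:
            continue
        try:
            wt, mut, aa_pos = mutant_protein(transcript, genome, rec.key)
        except VariantOutsideCDS:
            continue  # UTR / splice / regulatory records carry no coding change
        for k in config.k_list:
            candidates.extend(
                enumerate_snv_peptides(
                    wt, mut, aa_pos, k,
                    source_key=rec.key,
                    gene_id=transcript.gene_id,
                    transcript_id=transcript.transcript_id,
                )
            )
    stage(
        "snv_enumeration",
        annotation_rows=len(annotation),
        consequence_kept=len(kept_annotation),
        protein_changing_on_integrated=len(relevant),
        snv_candidates=len(candidates),
    )

    quant = read_quant(config.quant_tsv)
    expressed = expression_filter(candidates, quant, tx2gene, min_tpm=config.min_tpm)
    stage("expression_filter", candidates_in=len(candidates), candidates_out=len(expressed))

    # ---- neojunctions ------------------------------------------------------
    annotated_set = build_annotated_junctions(transcripts)
    novel_keys = set()
    junctions_total = 0
    for sample, path in sorted(config.sj_tabs.items()):
        classified = classify_junctions(read_sj_tab(path), annotated_set)
        junctions_total += len(classified)
        novel_keys |= novel_junction_keys(classified)
    events = read_event_table(config.event_tsv, groups=tuple(config.samples[:2]))
    junction_events = [
        ev
        for ev in events
        if ev.event_type != "intron_retention"
        and event_contains_novel_junction(ev, novel_keys)
    ]
    junction_peptides = []
    for ev in junction_events:
        junction_peptides.extend(junction_peptides_for_event(ev, transcripts, genome))
    stage(
        "neojunctions",
        junctions_seen=junctions_total,
        novel_junctions=len(novel_keys),
        events_in=len(events),
        events_with_novel_junction=len(junction_events),
        junction_peptides=len(junction_peptides),
    )

    # ---- intron retention --------------------------------------------------
    ir_events = [ev for ev in events if ev.event_type == "intron_retention"]
    blacklist = (
        read_bed_intervals(config.blacklist_bed) if config.blacklist_bed else set()
    )
    ir_kept = ir_priority_filter(
        ir_events,
        min_confidence=config.min_confidence,
        min_delta_psi=config.min_delta_psi,
        normal_blacklist=blacklist,
    )
    ir_peptides = []
    for ev in ir_kept:
        ir_peptides.extend(junction_peptides_for_event(ev, transcripts, genome))
    stage(
        "intron_retention",
        ir_events_in=len(ir_events),
        ir_events_kept=len(ir_kept),
        ir_kept_event_ids=sorted(ev.event_id for ev in ir_kept),
        ir_peptides=len(ir_peptides),
    )

    # ---- binding -----------------------------------------------------------
    backend = _make_backend(config)
    all_junction = junction_peptides + ir_peptides
    sequences = sorted(
        {c.sequence for c in expressed}
        | {p.sequence for p in all_junction}
        | {c.wildtype_counterpart for c in expressed if c.wildtype_counterpart}
    )
    results = (
        predict_binding(sequences, config.alleles, backend) if sequences else []
    )
    binding_mod.write_binding_tsv(results, out / "binding.tsv")
    min_aff = {}
    for r in results:
        min_aff[r.peptide] = min(min_aff.get(r.peptide, float("inf")), r.affinity_nm)
    snv_final = binder_filter(
        expressed, results,
        non_binder_cutoff_nm=config.non_binder_nm,
        strong_cutoff_nm=config.strong_nm,
    )
    junction_final = [
        p for p in all_junction if min_aff[p.sequence] <= config.non_binder_nm
    ]
    stage(
        "binding",
        peptides_predicted=len(sequences),
        snv_candidates_kept=len(snv_final),
        junction_peptides_kept=len(junction_final),
        strong_binders=len(
            {c.sequence for c in snv_final if c.strong}
            | {p.sequence for p in junction_final
               if min_aff[p.sequence] < config.strong_nm}
        ),
    )

    # ---- final reports -----------------------------------------------------
    snv_final.sort(key=lambda c: (str(c.variant_key), c.k, c.window_start, c.sequence))
    junction_final.sort(key=lambda p: (p.event_id, p.window_start, p.sequence))
    write_peptide_fasta(list(snv_final) + list(junction_final), out / "peptides.fasta")
    with open(out / "peptides.tsv", "w") as fh:
        fh.write(
            "peptide\tk\tsource\tgene\torigin\tmutant\twt_counterpart"
            "\tmin_affinity_nm\tstrong\n"
        )
        for c in snv_final:
            fh.write(
                f"{c.sequence}\t{c.k}\tSNV\t{c.gene_id}\t{c.variant_key}\t1"
                f"\t{c.wildtype_counterpart or '.'}\t{c.min_affinity_nm:.4f}"
                f"\t{int(c.strong)}\n"
            )
        for p in junction_final:
            aff = min_aff[p.sequence]
            fh.write(
                f"{p.sequence}\t{p.k}\tneojunction\t{p.gene_id}\t{p.event_id}\t1\t."
                f"\t{aff:.4f}\t{int(aff < config.strong_nm)}\n"
            )

    report["final"] = {
        "snv_peptides": sorted({c.sequence for c in snv_final}),
        "junction_peptides": sorted({p.sequence for p in junction_final}),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
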
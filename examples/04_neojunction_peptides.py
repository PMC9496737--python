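"""Novel junction detection and junction-spanning 9-mer translation.

Compares observed splice junctions (SJ.out.tab) against the intron universe
of the annotation, keeps events containing a junction absent from it, and
translates each junction region in the CDS-inherited reading frame into all
9-mers that differ from the reference protein in at least one residue.
"""

from pathlib import Path

from neopep import (
    build_annotated_junctions,
    classify_junctions,
    event_contains_novel_junction,
    junction_peptides_for_event,
    read_fasta,
    read_gtf,
    read_sj_tab,
    simulate,
)
from neopep.intron_retention import read_event_table
from neopep.junctions import novel_junction_keys

sim = Path("scratch/example_sim")
if not (sim / "truth.json").exists():
    simulate(sim, seed=7, n_genes=32)

genome = read_fasta(sim / "genome.fa")
transcripts = read_gtf(sim / "annotation.gtf")
annotated = build_annotated_junctions(transcripts)
print(f"annotation contributes {len(annotated)} distinct introns")

novel = set()
for sample in ("EV", "MIR"):
    classified = classify_junctions(read_sj_tab(sim / "sj" / f"{sample}.SJ.out.tab"), annotated)
    n_novel = sum(novel_flag for _, novel_flag in classified)
    print(f"{sample}: {len(classified)} junctions observed, {n_novel} novel")
    novel |= novel_junction_keys(classified)

events = read_event_table(sim / "events.tsv", groups=("EV", "MIR"))
with_novel = [ev for ev in events
              if ev.event_type != "intron_retention"
              and event_contains_novel_junction(ev, novel)]
print(f"{len(with_novel)} / {len(events)} events contain a novel junction\n")

for ev in with_novel:
    peps = junction_peptides_for_event(ev, transcripts, genome)
    print(f"{ev.event_id} ({ev.event_type}, {ev.gene_id}): {len(peps)} junction 9-mers")
    for p in peps[:3]:
        print(f"   {p.sequence}  changed residues at {sorted(p.changed_positions)}")
print("\n(zero peptides means a premature stop upstream of the junction "
      "or no resolvable reading frame)")
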
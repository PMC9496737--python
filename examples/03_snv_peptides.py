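"""From a missense variant to mutant/wildtype MHC peptide windows.

Takes one integrated, protein-changing variant from the toy dataset,
rebuilds the wildtype and mutant proteins from the coding sequence, and
enumerates every 8- and 9-mer containing the changed residue, then applies
the expression (TPM >= 1) and binding (<= 5000 nM on some allele) filters.
"""

from pathlib import Path

from neopep import (
    MockBindingBackend,
    binder_filter,
    enumerate_snv_peptides,
    expression_filter,
    mutant_protein,
    predict_binding,
    read_annotation,
    read_fasta,
    read_gtf,
    read_quant,
    simulate,
)
from neopep.io_formats import VariantKey

sim = Path("scratch/example_sim")
if not (sim / "truth.json").exists():
    simulate(sim, seed=7, n_genes=32)

genome = read_fasta(sim / "genome.fa")
transcripts = {t.transcript_id: t for t in read_gtf(sim / "annotation.gtf")}
rec = next(r for r in read_annotation(sim / "annotation.tsv")
           if r.consequence == "missense_variant")
t = transcripts[rec.transcript_id]

wt, mut, aa_pos = mutant_protein(t, genome, rec.key)
print(f"variant {rec.key} in {t.gene_id}: {wt[aa_pos]}{aa_pos + 1}{mut[aa_pos]} "
      f"(protein length {len(wt)})")

candidates = []
for k in (8, 9):
    wins = enumerate_snv_peptides(wt, mut, aa_pos, k, source_key=rec.key,
                                  gene_id=t.gene_id, transcript_id=t.transcript_id)
    print(f"k={k}: {len(wins)} windows, each containing the mutated residue")
    candidates += wins

tx2gene = {tid: tr.gene_id for tid, tr in transcripts.items()}
expressed = expression_filter(candidates, read_quant(sim / "quant.tsv"), tx2gene)
print(f"after TPM >= 1 filter: {len(expressed)} candidates")

results = predict_binding({c.sequence for c in expressed},
                          ("H-2Kb", "H-2Db"), MockBindingBackend(seed=7))
final = binder_filter(expressed, results)
print(f"after binding filter (min affinity <= 5000 nM): {len(final)} candidates\n")
for c in final[:5]:
    print(f"  {c.sequence}  wt={c.wildtype_counterpart}  "
          f"min {c.min_affinity_nm:7.1f} nM  {'STRONG (<500 nM)' if c.strong else 'weak'}")
print("  ... (mutant peptide, its wildtype counterpart, best allele affinity)")
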
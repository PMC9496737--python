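"""Generate the self-contained toy dataset with its truth manifest.

Writes a directory tree mirroring a real run's inputs (genome, GTF,
per-aligner VCFs for two samples, WES VCF, quantification, SJ.out.tab
files, splice-event table, blacklist) plus truth.json recording what the
pipeline is expected to recover.
"""

from pathlib import Path

from neopep import simulate

out = Path("scratch/example_sim")
manifest = simulate(out, seed=7, n_genes=32)

print(f"wrote toy dataset to {out}/")
print(f"planted variants:        {len(manifest['variants'])} "
      f"(classes straddle every filter threshold)")
print(f"planted splice events:   {len(manifest['junction_events'])}")
print(f"expected SNV peptides:   {len(manifest['expected_snv_peptides'])} "
      f"(after concordance, WES, TPM >= 1 and binding filters)")
print(f"expected junction 9-mers: {len(manifest['expected_junction_peptides'])}")
print(f"expected prioritized IR events: {manifest['expected_kept_ir_event_ids']}")
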
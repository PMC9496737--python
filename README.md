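# neopep

Tumor neoantigen candidate discovery from bulk RNA-seq evidence, for
computational immunologists working with mouse (C57BL/6, H-2K^b^/H-2D^b^) or
similar MHC class I systems. The package turns three streams of
transcriptome evidence into filtered, binding-annotated peptide candidates:

1. **SNV-derived neoantigens.** RNA variant calls made independently on three
   splice-aware alignments are quality-filtered (PASS, depth > 10), kept only
   when all three aligners agree on the exact call, merged across samples,
   confirmed in whole-exome DNA (depth ≥ 20), and restricted to
   protein-relevant consequence categories. Each retained missense variant at
   protein position *p* is expanded into every k-mer window
   (k ∈ {8, 9}) containing the changed residue — window starts
   *s* ∈ [max(0, p−k+1), min(L−k, p)] — paired with the same-coordinate
   wildtype peptide. Frameshift and stop-loss variants enumerate the novel
   C-terminal tail.
2. **Neojunction peptides.** Splice junctions observed by the aligner are
   *novel* when their exact intron coordinates are absent from the annotation's
   intron universe. For events containing a novel junction, a nucleotide
   context of up to 3(k−1) coding bases upstream of the donor plus 3(k−1)+3
   novel downstream bases is translated in the CDS-inherited reading frame
   (fallback: exact substring match of the upstream translation against the
   reference proteome), and every 9-mer differing from the reference protein
   in ≥ 1 residue is emitted. Events with a stop codon strictly upstream of
   the junction are discarded; downstream stops truncate.
3. **Intron retention (IR).** For a retained intron,
   PSI = confidence / (confidence + junction reads), where *confidence* is the
   mean number of alignments spanning the intron. Events are prioritized when
   confidence > 5 in at least one group, the between-group ΔPSI is ≥ 0.1, and
   the intron is absent from a normal-tissue blacklist; kept events are
   translated like retained-intron junctions and exported with flanking-exon
   RT-PCR validation targets.

All candidates pass an expression filter (gene has ≥ 1 transcript at
TPM ≥ 1) and a binding filter (minimum predicted affinity over alleles
≤ 5000 nM; strong binders < 500 nM). Binding comes from a wrapped external
NetMHC-4.0-style executable or from a deterministic mock backend
(keyed hash → log-uniform [1, 50000] nM) for fully reproducible tests.

A first-class synthetic data generator (`neopep.simulate`) emits the entire
input tree — genome FASTA, GTF, per-aligner VCFs, WES VCF, annotation and
quantification tables, SJ.out.tab files, event tables, blacklist — with a
truth manifest of expected survivors, so every stage is testable offline.

## Worked example

```bash
python examples/06_full_pipeline.py
```

simulates a 32-gene toy dataset (seed 7) and runs every stage:

```
SNV peptides recovered:      77 -- exact match with truth manifest
junction peptides recovered: 35 -- exact match with truth manifest
```

The 77 SNV peptides are the 8/9-mer windows of the five planted
fully-concordant, WES-confirmed, expressed missense variants that bind at
least one allele at ≤ 5000 nM; the 35 junction 9-mers come from the planted
in-frame and frameshift novel acceptors plus the two prioritized IR events.
Planted negatives — variants called by only 1–2 aligners, absent from WES,
below 1 TPM, synonymous, under-covered, or non-PASS; annotated-only splice
events; blacklisted, low-confidence or non-differential IR events; junctions
with an upstream premature stop — contribute zero peptides. The other
example scripts (`examples/01…05`) walk each capability in isolation and
print what every number means.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the synthetic dataset at the given seed, runs the complete
pipeline with the mock binding backend, verifies that the recovered SNV and
junction peptide sets equal the truth manifest exactly, and writes the JSON
report to `--out`. A non-zero exit means the pipeline failed to recover the
planted truth.

## Layout

```
src/neopep/
  io_formats.py        FASTA/GTF/VCF/SJ.out.tab/TSV/BED readers & writers
                       (0-based half-open internally; converted once at IO)
  variants.py          RNA filter, vt-style normalization, 3-aligner
                       concordance, sample merge, WES integration,
                       consequence categories
  snv_peptides.py      mutant/wildtype proteins, k-mer windows, expression
                       and binding filters
  junctions.py         annotated-intron universe, novelty classification,
                       junction context, frame selection, 9-mer translation
  intron_retention.py  PSI, IR detection/prioritization, validation targets,
                       shared event-table dialect
  binding.py           mock + external NetMHC-style backends, classification
  simulate.py          synthetic dataset generator + truth manifest
  pipeline.py          RunConfig + run_pipeline orchestration
```

See `docs/methods.md` for the model, parameter defaults, numerical choices
and known limitations.
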
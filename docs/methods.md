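# Methods

## Scope and model

`neopep` implements the computational core of an RNA-seq-driven neoantigen
discovery workflow: it consumes the *outputs* of upstream tools — aligner
VCFs, a VEP-style consequence table, Salmon-style TPM tables, STAR-style
SJ.out.tab junction files, SplAdder-style event tables — and produces
filtered MHC class I peptide candidates. Read alignment, variant calling,
transcript quantification, splice-graph construction and the binding neural
network itself are all external; their file formats are the contract.

## Coordinates

Internal coordinates are 0-based half-open everywhere; the 1-based
conventions of VCF/GTF/SJ.out.tab are converted exactly once at read/write,
eliminating off-by-one drift. One deliberate exception: `JunctionRecord`
mirrors its file (1-based inclusive intron coordinates) and exposes the
internal convention via `.interval`, because SJ.out.tab rows are often
compared against raw files during debugging.

## SNV candidates

* **RNA filter:** PASS, depth **strictly greater than** 10 reads, SNVs only
  (a flag readmits indels). Depth is taken from FORMAT `DP` when present,
  else INFO `DP`, else 0 with a warning — variant callers emit both dialects
  across versions.
* **Concordance:** a call survives only when all three configured aligners
  produced the identical normalized (contig, pos, ref, alt) in that sample.
  Normalization is the standard left-align-and-trim (vt-style): right-trim
  shared terminal bases extending left through reference repeats, then trim
  the shared prefix. SNVs are fixed points; the invariant tested is that the
  normalized and original variant build the same haplotype string.
* **Sample merge:** the multi-sample table is the union of per-sample
  concordant keys with an explicit presence flag per sample. Re-genotyping
  missing samples from alignments ("backfilling") is out of scope because
  the package consumes VCFs, not BAMs; the deterministic presence matrix is
  the replacement.
* **WES integration:** DNA confirmation is an exact key intersection; the
  WES-side filter is PASS with depth **at least** 20 (inclusive, unlike the
  strict RNA bound — the two rules are stated differently on purpose).
* **Consequence categories:** seven retained categories (missense,
  frameshift, splice, start, stop, UTR, regulatory), each mapped to a
  configurable set of VEP terms; compound (`&`-joined) terms match if any
  constituent maps. Unknown terms are dropped with a warning by default.
* **Window rule:** implemented in amino-acid space: for a change at protein
  position *p*, all k-mer windows covering *p* (2k−1-residue context).
  Frameshift and stop-loss variants translate to the first stop — continuing
  past the annotated CDS into 3'UTR sequence — and emit every k-mer touching
  a novel residue, with no wildtype counterpart. A pure stop-gain emits
  nothing: every window preceding the new stop is identical to the aligned
  wildtype k-mer, and a peptide indistinguishable from self is not a
  neoantigen candidate (this also keeps the "mutant ≠ wildtype counterpart"
  invariant unconditional).
* **Expression filter:** a candidate's gene needs ≥ 1 transcript at
  TPM ≥ 1 (inclusive). Genes missing from the table count as 0 with a
  warning rather than an error, since quantification sets are routinely
  incomplete.

## Neojunctions

* **Novelty** is exact-coordinate membership against the set of all introns
  derivable from the annotation (gaps between consecutive exons of every
  transcript). Junctions with unknown strand (STAR strand code 0) are
  matched on both strands and are novel only if absent from both.
* **Junction context:** up to 3(k−1) exonic bases upstream of the donor —
  truncated at the CDS start, but *retaining* post-stop exonic sequence so
  premature-stop contexts remain visible — plus 3(k−1)+3 bases of the novel
  downstream side (the retained intron itself for IR events, the sequence
  past the novel acceptor otherwise). Minus-strand transcripts are handled
  by reverse complement of the genomic slices. The downstream length
  3(k−1)+3 = 27 nt for k = 9 is the minimum guaranteeing every junction-
  overlapping 9-mer a complete codon supply.
* **Frame selection:** the frame inherited from the annotated CDS phase of
  the upstream flank always wins. When no phase is available the frame whose
  stop-free upstream translation occurs verbatim in the reference proteome
  is used (exact substring search replaces a protein BLAST — at flank
  lengths ≥ 8 aa, chance hits are negligible at this scale and the external
  binary disappears from the test path); ties break by longest matching
  translation, then lowest frame index, giving a total order.
* **Translation rules:** a stop strictly upstream of the junction codon
  discards the event; a stop at or after it truncates; translations shorter
  than 9 residues yield nothing; emitted 9-mers must differ from the
  reference protein (aligned by locating the upstream translation inside
  it) in at least one residue. Three transcript-strand frames are
  considered, not six: antisense ORFs are outside the model.

## Intron retention

PSI is defined here as `confidence / (confidence + junction_reads)` —
intron evidence over total evidence; the inputs never state a formula, so
this definition is flagged prominently. Prioritization keeps events with
confidence **strictly** > 5 in ≥ 1 group, ΔPSI ≥ 0.1 (configurable; the
evidence for a specific cutoff is weak, so it is a parameter, not a
constant) and intron absent from the normal-tissue blacklist. The blacklist
is a plain coordinate list (BED/TSV) so any source of normal evidence —
RT-PCR, a normal-tissue cohort — can feed it. `export_validation_targets`
emits flanking-exon intervals and the two expected RT-PCR band sizes
(exon:exon, and exon:exon + intron length).

Degenerate PSI (0 evidence in both channels) is `None` and flags the event;
the ΔPSI boundary uses a 1e-9 tolerance so values that are equal up to
float subtraction error (0.30 − 0.20 vs 0.1) land on the inclusive side.

## Binding

The external backend wraps a NetMHC-4.0-style executable (peptide-list
input, whitespace table output; affinity and %rank column indices are
configurable) and is exercised in tests by a stub executable. The mock
backend maps a SHA-256 hash of (seed, peptide, allele) log-uniformly onto
[1, 50000] nM — a pure function, bitwise reproducible across platforms.
Thresholds: strong binder < 500 nM (strict); non-binder > 5000 nM
(configurable — "no predicted binding" has no standard operational
definition, so the default is the conventional weak-binding ceiling).
Reproducing published affinities requires the externally installed
predictor and is deliberately not asserted anywhere.

## Synthetic data

The generator writes counts and calls at the level the pipeline reads —
no read-level simulation, since alignment is out of scope. Toy genes are
multi-exon, both strands, ATG-initiated, internally stop-free, with short
UTRs; annotated CDS intervals **include the stop codon** (a deviation from
the Ensembl convention, documented here) so that junction donors planted in
the 3'UTR carry the stop codon in their upstream flank — that is how the
"premature stop upstream of the junction" stratum is constructed without
corrupting any CDS.

Planted variants straddle every threshold: 3/3-caller vs 1–2/3-caller
calls, depth 10 (just failing the strict RNA bound) vs 15–40, WES-present
vs absent, TPM 0.1–0.8 vs ≥ 2, missense vs synonymous, PASS vs filtered.
IR events cover kept / non-differential / low-confidence / blacklisted
strata with integer count pairs whose PSI values are exact ratios. The
truth manifest's expected peptides are computed by an independent
sliding-window reimplementation over the generator's construction strings
(never by calling the pipeline), then passed through the same deterministic
mock binding function; the end-to-end test therefore checks two separate
routes from construction to peptide set. A single seed drives split RNG
streams (genome / variants / splicing) so changing one plan leaves the
others' draws untouched.

What a green end-to-end test does *not* establish: robustness to malformed
real-world files beyond the documented dialects, calling errors upstream of
the VCFs, quantification noise, binding-model fidelity, or performance at
genome scale.

## Design choices on open points

* Window enumeration is in amino-acid space (a 2k−1-residue context); the
  alternative nucleotide-space reading is incoherent for peptide k-mers.
* Wildtype counterpart affinities are computed and reported but never used
  as an exclusion rule; no such rule is specified anywhere.
* Only 9-mers are generated for junctions; longer reported peptides exist
  in the field but follow no stated generation rule.
* Each biological group may hold one or more samples; group confidence is
  the mean over samples, junction reads the sum.

## Limitations

* Fusion transcripts, trans-splicing and splice-graph construction are not
  modeled; event tables are consumed, not derived from alignments.
* Proteasomal processing and TAP transport are not predicted; class II is
  out of scope.
* The concordance unit is the exact normalized call; near-miss calls
  (same site, different alt) are treated as discordant by design.
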
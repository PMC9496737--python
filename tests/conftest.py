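import numpy as np
import pytest
from Bio.Seq import Seq

from neopep.io_formats import GenomeSequence, TranscriptModel


def build_gene(
    coding: str,
    strand: str = "+",
    utr5: str = "TTTCCAGG",
    utr3: str = "GGACCTTTAAACCGG",
    intron_seqs: tuple[str, ...] = (),
    exon_splits: tuple[int, ...] = (),
    contig: str = "c1",
    pad: int = 30,
    gene_id: str = "geneX",
    transcript_id: str = "txX",
):
    """Construct a genome + transcript from explicit transcript parts.

    ``coding`` must include its stop codon.  ``exon_splits`` are cut points
    in spliced-transcript coordinates; introns are inserted at the cuts.
    Returns (genome, transcript, tx_sequence).
    """
    tx = utr5 + coding + utr3
    splits = list(exon_splits)
    assert len(intron_seqs) == len(splits)
    bounds = [0] + splits + [len(tx)]
    exon_tx = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
    block_parts, exon_block = [], []
    bpos = 0
    for i, (ts, te) in enumerate(exon_tx):
        block_parts.append(tx[ts:te])
        exon_block.append((bpos, bpos + te - ts))
        bpos += te - ts
        if i < len(intron_seqs):
            block_parts.append(intron_seqs[i])
            bpos += len(intron_seqs[i])
    block = "".join(block_parts)
    placed = block if strand == "+" else str(Seq(block).reverse_complement())
    left = "A" * pad
    genome = GenomeSequence({contig: left + placed + "C" * pad})
    B, L = pad, len(block)

    def to_genomic(a, b):
        if strand == "+":
            return (B + a, B + b)
        return (B + L - b, B + L - a)

    exons = sorted(to_genomic(bs, be) for bs, be in exon_block)

    def tx_iv_to_genomic(a, b):
        out = []
        for (ts, te), (bs, be) in zip(exon_tx, exon_block):
            lo, hi = max(a, ts), min(b, te)
            if lo < hi:
                out.append(to_genomic(bs + lo - ts, bs + hi - ts))
        return sorted(out)

    cds = tx_iv_to_genomic(len(utr5), len(utr5) + len(coding))
    t = TranscriptModel(
        transcript_id=transcript_id,
        gene_id=gene_id,
        gene_name=gene_id.upper(),
        contig=contig,
        strand=strand,
        exons=exons,
        cds=cds,
        start_phase=0,
    )
    return genome, t, tx


@pytest.fixture
def gene_factory():
    return build_gene


@pytest.fixture(scope="session")
def toy_world():
    from neopep.simulate import make_toy_genome

    return make_toy_genome(n_genes=8, exons_per_gene=3, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
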
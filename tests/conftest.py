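"""Shared fixtures: toy gene models, genomes and small simulated crosses."""

from __future__ import annotations

import numpy as np
import pytest

from grainqtl.effects import GeneModel
from grainqtl.simcross import SimConfig, simulate_f2


def make_toy_gene(strand: str = "+") -> tuple[GeneModel, dict[str, str]]:
    """Two-exon coding gene on a 200 bp contig, with a clean 60-codon ORF.

    Plus strand layout (1-based): exon1 11-40 (CDS 21-40), intron 41-60
    (GT...AG), exon2 61-100 (CDS 61-100). CDS = ATG + (GGA)*18 + TAA.
    The minus-strand version mirrors the layout on the reverse complement
    so the transcript sequence is identical.
    """
    cds_seq = "ATG" + "GGA" * 18 + "TAA"
    s = ["A"] * 200
    s[10:20] = list("CCCCCCCCCC")  # 5' UTR filler
    s[20:40] = list(cds_seq[:20])
    s[60:100] = list(cds_seq[20:])
    s[40], s[41] = "G", "T"  # donor
    s[58], s[59] = "A", "G"  # acceptor
    seq = "".join(s)
    if strand == "+":
        gene = GeneModel(
            transcript_id="t1", gene_id="gene1", chrom="chr1", strand="+",
            exons=[(11, 40), (61, 100)], cds=[(21, 40), (61, 100)],
        )
        return gene, {"chr1": seq}
    # mirror: reverse-complement the contig; interval (a, b) -> (L-b+1, L-a+1)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[b] for b in reversed(seq))
    L = len(seq)
    flip = lambda a, b: (L - b + 1, L - a + 1)
    gene = GeneModel(
        transcript_id="t1m", gene_id="gene1m", chrom="chr1", strand="-",
        exons=[flip(61, 100), flip(11, 40)], cds=[flip(61, 100), flip(21, 40)],
    )
    return gene, {"chr1": rc}


@pytest.fixture(scope="session")
def toy_gene_plus():
    return make_toy_gene("+")


@pytest.fixture(scope="session")
def toy_gene_minus():
    return make_toy_gene("-")


@pytest.fixture(scope="session")
def small_sim():
    """Error-free 49-individual cross on two 2 Mb chromosomes."""
    cfg = SimConfig(
        n_chromosomes=2, chrom_length_bp=2_000_000, markers_per_chrom=60,
        causal_chrom="chr1", causal_pos_bp=1_000_000, seed=20_001,
    )
    return simulate_f2(cfg)


def sim_panel(sim):
    """Assemble a MarkerPanel directly from a simulation (no VCF round trip)."""
    from grainqtl.markers import MarkerPanel

    return MarkerPanel(
        samples=sim.samples,
        parent_sample=sim.parent_sample,
        chroms=sim.marker_chroms,
        positions=sim.marker_positions,
        genotypes=sim.genotypes,
        ref=sim.ref_alleles.astype(object),
        alt=sim.alt_alleles.astype(object),
        parent_is_alt=sim.parent_is_alt.copy(),
    )
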
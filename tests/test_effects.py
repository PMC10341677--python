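"""Gene-model parsing and variant-consequence classification.

The classifier is checked against an independent brute-force oracle that
re-derives every consequence from first principles: coding substitutions
by rebuilding and translating the complete mutant CDS, indels by counting
the coding bases they add or remove, and the positional categories
(splice windows, UTR, intron, intergenic) from a separate re-implementation
of the interval logic.
"""

import itertools

import numpy as np
import pytest
from Bio.Seq import Seq

from conftest import make_toy_gene
from grainqtl.effects import (
    IMPACT_OF,
    GeneModel,
    classify_variant,
    read_fasta,
    read_gff3,
    worst_effect_per_gene,
)

# ---------------------------------------------------------------- oracle


def _mutant_cds(gene, genome, pos, ref, alt):
    """Rebuild the spliced CDS after applying the variant to the contig."""
    contig = genome[gene.chrom]
    mutant = contig[: pos - 1] + alt + contig[pos - 1 + len(ref) :]
    shift = len(alt) - len(ref)
    pieces = []
    for a, b in gene.cds:
        # coordinates at or beyond the edited span shift by the length change
        a2 = a if a <= pos else a + shift
        b2 = b if b < pos else b + shift
        pieces.append(mutant[a2 - 1 : b2])
    seq = "".join(pieces)
    if gene.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def oracle_classify(gene, genome, pos, ref, alt):
    """Independent consequence derivation for one bi-allelic variant."""
    is_ins = len(alt) > len(ref)
    is_del = len(ref) > len(alt)
    if is_ins:
        span = (pos + len(ref) - 1, pos + len(ref))
        inside = lambda a, b: a <= span[0] and span[1] <= b
    else:
        span = (pos + len(alt), pos + len(ref) - 1) if is_del else (pos, pos)
        inside = lambda a, b: span[0] <= b and a <= span[1]

    # splice windows, re-derived from the exon list
    introns = [
        (b1 + 1, a2 - 1)
        for (_, b1), (a2, _) in zip(gene.exons, gene.exons[1:])
    ]
    for s, e in introns:
        donor, acceptor = ((s, s + 1), (e - 1, e))
        if gene.strand == "-":
            donor, acceptor = acceptor, donor
        if inside(*donor):
            return "splice_donor"
        if inside(*acceptor):
            return "splice_acceptor"

    if any(inside(a, b) for a, b in gene.cds):
        if is_del:
            removed = sum(
                max(0, min(span[1], b) - max(span[0], a) + 1)
                for a, b in gene.cds
            )
            if removed % 3:
                return "frameshift"
            return "inframe_deletion"
        if is_ins:
            if (len(alt) - len(ref)) % 3:
                return "frameshift"
            return "inframe_insertion"
        # SNV: full mutant-CDS translation
        ref_prot = str(Seq(gene.cds_sequence(genome)).translate())
        alt_prot = str(Seq(_mutant_cds(gene, genome, pos, ref, alt)).translate())
        if ref_prot == alt_prot:
            return "synonymous"
        diff = [i for i, (a, b) in enumerate(zip(ref_prot, alt_prot)) if a != b]
        i = diff[0]
        if i == 0 and ref_prot[0] == "M" and alt_prot[0] != "M":
            return "start_lost"
        if ref_prot[i] == "*":
            return "stop_lost"
        if alt_prot[i] == "*":
            return "stop_gained"
        return "missense"

    if any(inside(a, b) for a, b in gene.exons):
        cds_lo, cds_hi = gene.cds[0][0], gene.cds[-1][1]
        if span[1] < cds_lo:
            return "five_prime_UTR" if gene.strand == "+" else "three_prime_UTR"
        if span[0] > cds_hi:
            return "three_prime_UTR" if gene.strand == "+" else "five_prime_UTR"
    if inside(gene.start, gene.end):
        return "intron"
    return "intergenic"


# ---------------------------------------------------------------- tests


class TestReadGff3AndFasta:
    GFF = """\
##gff-version 3
chr1\ttoy\tgene\t11\t100\t.\t+\t.\tID=gene1
chr1\ttoy\tmRNA\t11\t100\t.\t+\t.\tID=t1;Parent=gene1
chr1\ttoy\texon\t11\t40\t.\t+\t.\tParent=t1
chr1\ttoy\texon\t61\t100\t.\t+\t.\tParent=t1
chr1\ttoy\tCDS\t21\t40\t.\t+\t0\tParent=t1
chr1\ttoy\tCDS\t61\t100\t.\t+\t2\tParent=t1
chr1\ttoy\tgene\t120\t180\t.\t-\t.\tID=gene2
chr1\ttoy\tmRNA\t120\t180\t.\t-\t.\tID=t2;Parent=gene2
chr1\ttoy\texon\t120\t150\t.\t-\t.\tParent=t2
chr1\ttoy\texon\t161\t180\t.\t-\t.\tParent=t2
chr1\ttoy\tCDS\t120\t150\t.\t-\t0\tParent=t2
chr1\ttoy\tCDS\t161\t172\t.\t-\t0\tParent=t2
"""

    def test_two_exon_plus_strand_parse(self, tmp_path):
        path = tmp_path / "toy.gff3"
        path.write_text(self.GFF)
        models = {m.transcript_id: m for m in read_gff3(path)}
        t1 = models["t1"]
        assert t1.gene_id == "gene1"
        assert t1.exons == [(11, 40), (61, 100)]
        assert t1.cds == [(21, 40), (61, 100)]
        assert t1.strand == "+"
        assert t1.cds_complete  # 60 bases

    def test_minus_strand_keeps_genome_coordinates(self, tmp_path):
        path = tmp_path / "toy.gff3"
        path.write_text(self.GFF)
        t2 = {m.transcript_id: m for m in read_gff3(path)}["t2"]
        assert t2.strand == "-"
        assert t2.exons == [(120, 150), (161, 180)]  # sorted by genome coord

    def test_incomplete_cds_flagged_but_usable(self, tmp_path):
        path = tmp_path / "toy.gff3"
        path.write_text(self.GFF)
        t2 = {m.transcript_id: m for m in read_gff3(path)}["t2"]
        assert t2.cds_length % 3 != 0
        assert not t2.cds_complete
        assert t2.introns == [(151, 160)]  # non-coding logic still works

    def test_fasta_reader_round_trip(self, tmp_path, toy_gene_plus):
        gene, genome = toy_gene_plus
        fa = tmp_path / "g.fa"
        fa.write_text(f">chr1\n{genome['chr1']}\n")
        fx = read_fasta(fa)
        assert str(fx["chr1"][:]).upper() == genome["chr1"]


class TestGeneModelInvariants:
    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            GeneModel("t", "g", "chr1", "+", exons=[(1, 50), (40, 90)])

    def test_splice_windows_swap_with_strand(self, toy_gene_plus, toy_gene_minus):
        plus, _ = toy_gene_plus
        minus, _ = toy_gene_minus
        pw = {k: (a, b) for a, b, k in plus.splice_windows()}
        mw = {k: (a, b) for a, b, k in minus.splice_windows()}
        assert pw["splice_donor"] == (41, 42)
        assert pw["splice_acceptor"] == (59, 60)
        # mirrored contig: genomic left end of the intron is the acceptor
        L = 200
        assert mw["splice_acceptor"] == (L - 60 + 1, L - 59 + 1)
        assert mw["splice_donor"] == (L - 42 + 1, L - 41 + 1)

    def test_cds_sequence_identical_on_both_strands(
        self, toy_gene_plus, toy_gene_minus
    ):
        pg, pgen = toy_gene_plus
        mg, mgen = toy_gene_minus
        assert pg.cds_sequence(pgen) == mg.cds_sequence(mgen)
        assert pg.cds_sequence(pgen).startswith("ATG")
        assert str(Seq(pg.cds_sequence(pgen)).translate()).endswith("*")


class TestNamedExamples:
    def test_splice_acceptor_snv_is_high(self, toy_gene_plus):
        """A substitution at an intron's last base abolishes the acceptor."""
        gene, genome = toy_gene_plus
        eff = classify_variant("chr1", 60, "G", "T", [gene], genome)[0]
        assert eff.consequence == "splice_acceptor"
        assert eff.impact == "HIGH"

    @pytest.mark.parametrize(
        "pos,ref,alt,consequence",
        [
            (26, "A", "G", "synonymous"),      # GGA -> GGG (Gly)
            (24, "G", "T", "stop_gained"),     # GGA -> TGA
            (21, "A", "C", "start_lost"),      # ATG -> CTG
            (25, "G", "A", "missense"),        # GGA -> GAA (Gly -> Glu)
            (15, "C", "T", "five_prime_UTR"),
            (50, "A", "T", "intron"),
            (150, "A", "T", "intergenic"),
        ],
    )
    def test_snv_categories(self, toy_gene_plus, pos, ref, alt, consequence):
        gene, genome = toy_gene_plus
        assert genome["chr1"][pos - 1] == ref
        eff = classify_variant("chr1", pos, ref, alt, [gene], genome)[0]
        assert eff.consequence == consequence
        assert eff.impact == IMPACT_OF[consequence]

    def test_deletion_frame_rule(self, toy_gene_plus):
        """2 bp mid-CDS deletion shifts frame; 3 bp stays in frame."""
        gene, genome = toy_gene_plus
        ref3 = genome["chr1"][23:26]  # pos 24..26
        e2 = classify_variant("chr1", 24, ref3, ref3[0], [gene], genome)[0]
        assert (e2.consequence, e2.impact) == ("frameshift", "HIGH")
        ref4 = genome["chr1"][23:27]
        e3 = classify_variant("chr1", 24, ref4, ref4[0], [gene], genome)[0]
        assert (e3.consequence, e3.impact) == ("inframe_deletion", "MODERATE")

    def test_stop_lost(self, toy_gene_plus):
        gene, genome = toy_gene_plus
        # stop codon TAA at CDS offsets 57..59 -> genome 98..100
        eff = classify_variant("chr1", 98, "T", "C", [gene], genome)[0]
        assert eff.consequence == "stop_lost"

    def test_ref_mismatch_is_hard_error(self, toy_gene_plus):
        gene, genome = toy_gene_plus
        with pytest.raises(ValueError, match="REF mismatch"):
            classify_variant("chr1", 26, "T", "G", [gene], genome)

    def test_worst_impact_per_gene(self, toy_gene_plus):
        gene, genome = toy_gene_plus
        second = GeneModel("t1b", "gene1", "chr1", "+",
                           exons=[(11, 100)], cds=[])
        effs = classify_variant("chr1", 60, "G", "T", [gene, second], genome)
        assert len(effs) == 2
        best = worst_effect_per_gene(effs)
        assert len(best) == 1
        assert best[0].impact == "HIGH"


class TestExhaustiveOracleAgreement:
    """Classifier vs brute-force oracle over every small variant."""

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_all_snvs_and_small_indels(self, strand):
        gene, genome = make_toy_gene(strand)
        contig = genome["chr1"]
        n = len(contig)
        mismatches = []
        variants = []
        for pos in range(1, n + 1):
            ref = contig[pos - 1]
            for alt in "ACGT":
                if alt != ref:
                    variants.append((pos, ref, alt))
        for pos in range(1, n):
            for dlen in (1, 2, 3):
                if pos + dlen > n:
                    continue
                ref = contig[pos - 1 : pos + dlen]
                variants.append((pos, ref, ref[0]))
        for pos in range(1, n):
            ref = contig[pos - 1]
            for ins in ("T", "TA", "TAC"):
                variants.append((pos, ref, ref + ins))
        assert len(variants) > 1500
        for pos, ref, alt in variants:
            got = classify_variant("chr1", pos, ref, alt, [gene], genome)[0]
            want = oracle_classify(gene, genome, pos, ref, alt)
            if got.consequence != want:
                mismatches.append((pos, ref, alt, got.consequence, want))
        assert mismatches == []

    def test_strand_mirror_symmetry(self):
        """A variant and its mirrored counterpart classify identically."""
        plus_gene, plus_genome = make_toy_gene("+")
        minus_gene, minus_genome = make_toy_gene("-")
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        L = 200
        rng = np.random.default_rng(0)
        for pos in rng.choice(np.arange(1, L + 1), size=60, replace=False):
            pos = int(pos)
            ref = plus_genome["chr1"][pos - 1]
            alt = next(b for b in "ACGT" if b != ref)
            mpos = L - pos + 1
            mref = comp[ref]
            malt = comp[alt]
            assert minus_genome["chr1"][mpos - 1] == mref
            a = classify_variant("chr1", pos, ref, alt,
                                 [plus_gene], plus_genome)[0]
            b = classify_variant("chr1", mpos, mref, malt,
                                 [minus_gene], minus_genome)[0]
            assert a.consequence == b.consequence

    def test_impact_is_pure_function_of_consequence(self):
        assert set(IMPACT_OF.values()) == {"HIGH", "MODERATE", "LOW", "MODIFIER"}
        highs = {"frameshift", "stop_gained", "stop_lost", "start_lost",
                 "splice_acceptor", "splice_donor"}
        assert {c for c, i in IMPACT_OF.items() if i == "HIGH"} == highs
        assert {c for c, i in IMPACT_OF.items() if i == "MODERATE"} == {
            "missense", "inframe_insertion", "inframe_deletion"}
        assert {c for c, i in IMPACT_OF.items() if i == "LOW"} == {"synonymous"}
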
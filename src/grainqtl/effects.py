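"""Variant-consequence classification against gene models.

A deliberately small consequence predictor covering the categories that
matter for loss-of-function candidate screening: splice donor/acceptor
disruption (the two intronic bases at each intron end), coding SNVs
(synonymous / missense / stop gained / stop lost / start lost), coding
indels (frameshift vs in-frame), UTR, intron and intergenic. Impact tiers
follow the usual annotation convention:

    HIGH      frameshift, stop_gained, stop_lost, start_lost,
              splice_acceptor, splice_donor
    MODERATE  missense, inframe_insertion, inframe_deletion
    LOW       synonymous
    MODIFIER  UTR, intron, intergenic

Indels are VCF-style left-anchored (REF and ALT share their first base);
all coordinates are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pyfaidx
from Bio.Seq import Seq

__all__ = [
    "GeneModel",
    "VariantEffect",
    "IMPACT_OF",
    "read_gff3",
    "read_fasta",
    "classify_variant",
    "classify_all",
    "worst_effect_per_gene",
    "write_effects_tsv",
]

IMPACT_OF = {
    "frameshift": "HIGH",
    "stop_gained": "HIGH",
    "stop_lost": "HIGH",
    "start_lost": "HIGH",
    "splice_acceptor": "HIGH",
    "splice_donor": "HIGH",
    "missense": "MODERATE",
    "inframe_insertion": "MODERATE",
    "inframe_deletion": "MODERATE",
    "synonymous": "LOW",
    "five_prime_UTR": "MODIFIER",
    "three_prime_UTR": "MODIFIER",
    "intron": "MODIFIER",
    "intergenic": "MODIFIER",
}

_IMPACT_RANK = {"HIGH": 3, "MODERATE": 2, "LOW": 1, "MODIFIER": 0}


@dataclass
class GeneModel:
    """Strand-aware exon/CDS structure of one transcript.

    Exon and CDS intervals are 1-based inclusive, stored sorted by genome
    coordinate regardless of strand; 5'→3' order is resolved at
    classification time. ``cds_complete`` is False when the summed CDS
    length is not a multiple of 3 — such models are still usable for
    non-coding consequences.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    is_te: bool = False

    def __post_init__(self) -> None:
        self.exons = sorted(tuple(e) for e in self.exons)
        self.cds = sorted(tuple(c) for c in self.cds)
        for a, b in self.exons + self.cds:
            if b < a:
                raise ValueError(f"{self.transcript_id}: inverted interval {a}-{b}")
        for (a1, b1), (a2, b2) in zip(self.exons, self.exons[1:]):
            if a2 <= b1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(b - a + 1 for a, b in self.cds)

    @property
    def cds_complete(self) -> bool:
        return bool(self.cds) and self.cds_length % 3 == 0

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (b1 + 1, a2 - 1)
            for (a1, b1), (a2, b2) in zip(self.exons, self.exons[1:])
            if a2 - b1 > 1
        ]

    def splice_windows(self) -> list[tuple[int, int, str]]:
        """(start, end, kind) of the 2-bp splice windows of each intron.

        On the plus strand the donor site is the first two intron bases and
        the acceptor the last two; on the minus strand the roles of the two
        genomic ends swap. Single-base introns yield one ambiguous window
        reported as donor.
        """
        out = []
        for s, e in self.introns:
            if e - s + 1 < 2:
                out.append((s, e, "splice_donor"))
                continue
            left = (s, min(s + 1, e))
            right = (max(e - 1, s), e)
            if self.strand == "+":
                out.append((*left, "splice_donor"))
                out.append((*right, "splice_acceptor"))
            else:
                out.append((*right, "splice_donor"))
                out.append((*left, "splice_acceptor"))
        return out

    def cds_sequence(self, genome) -> str:
        """Spliced CDS in translation (5'→3') orientation."""
        parts = [fetch_seq(genome, self.chrom, a, b) for a, b in self.cds]
        seq = "".join(parts)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def cds_offset(self, pos: int) -> int | None:
        """0-based offset of a genomic position within the spliced CDS."""
        off = 0
        if self.strand == "+":
            for a, b in self.cds:
                if a <= pos <= b:
                    return off + (pos - a)
                off += b - a + 1
        else:
            for a, b in reversed(self.cds):
                if a <= pos <= b:
                    return off + (b - pos)
                off += b - a + 1
        return None


@dataclass(frozen=True)
class VariantEffect:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str  # "." for intergenic
    transcript_id: str
    consequence: str
    impact: str


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features into one GeneModel per mRNA.

    Transposable-element transcripts are flagged when the feature type is
    an *_TE_gene/mRNA variant or a Note attribute mentions a transposon.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[GeneModel] = []
    for mrna in db.features_of_type(("mRNA", "transcript")):
        exons = [(f.start, f.end) for f in db.children(mrna, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
        parents = list(db.parents(mrna, featuretype="gene"))
        gene_id = parents[0].id if parents else mrna.attributes.get("Parent", [mrna.id])[0]
        note = " ".join(mrna.attributes.get("Note", [])).lower()
        if parents:
            note += " " + " ".join(parents[0].attributes.get("Note", [])).lower()
        is_te = "transpos" in note or "te_gene" in mrna.featuretype.lower()
        if not exons:
            exons = list(cds)
        if not exons:
            continue
        models.append(
            GeneModel(
                transcript_id=mrna.id,
                gene_id=gene_id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                exons=exons,
                cds=cds,
                is_te=is_te,
            )
        )
    return models


def read_fasta(path: str | Path) -> pyfaidx.Fasta:
    """Open an (uncompressed) genome FASTA with random access."""
    return pyfaidx.Fasta(str(path), sequence_always_upper=True)


def fetch_seq(genome, chrom: str, start: int, end: int) -> str:
    """1-based inclusive substring of a contig."""
    if isinstance(genome, dict):
        return genome[chrom][start - 1 : end].upper()
    return str(genome[chrom][start - 1 : end]).upper()


def _overlaps(a1: int, b1: int, a2: int, b2: int) -> bool:
    return a1 <= b2 and a2 <= b1


def _variant_span(pos: int, ref: str, alt: str) -> tuple[int, int, str, int]:
    """(start, end, kind, length_change) of the affected genomic region.

    SNV/MNV: the substituted bases. Deletion: the removed bases (anchor
    base excluded). Insertion: the two bases flanking the insertion point;
    overlap tests for insertions require the point to fall strictly inside
    a region.
    """
    if len(ref) == len(alt):
        return pos, pos + len(ref) - 1, "snv" if len(ref) == 1 else "mnv", 0
    delta = len(alt) - len(ref)
    if delta < 0:
        return pos + len(alt), pos + len(ref) - 1, "deletion", delta
    return pos + len(ref) - 1, pos + len(ref), "insertion", delta


def _codon_effect(model: GeneModel, genome, pos: int, ref: str, alt: str) -> str:
    """Consequence of a coding SNV from its ref/alt codon pair."""
    cds_seq = model.cds_sequence(genome)
    off = model.cds_offset(pos)
    assert off is not None
    ref_base = ref if model.strand == "+" else str(Seq(ref).reverse_complement())
    alt_base = alt if model.strand == "+" else str(Seq(alt).reverse_complement())
    if cds_seq[off] != ref_base:
        raise ValueError(
            f"{model.transcript_id}: CDS base at offset {off} is "
            f"{cds_seq[off]}, expected {ref_base}"
        )
    ci = off // 3
    codon_start = ci * 3
    ref_codon = cds_seq[codon_start : codon_start + 3]
    if len(ref_codon) < 3:  # incomplete terminal codon
        return "missense"
    alt_codon = list(ref_codon)
    alt_codon[off - codon_start] = alt_base
    alt_codon = "".join(alt_codon)
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ci == 0 and ref_codon == "ATG" and alt_codon != "ATG":
        return "start_lost"
    if ref_aa == "*" and alt_aa != "*":
        return "stop_lost"
    if alt_aa == "*" and ref_aa != "*":
        return "stop_gained"
    if ref_aa == alt_aa:
        return "synonymous"
    return "missense"


def _classify_for_model(
    model: GeneModel, genome, chrom: str, pos: int, ref: str, alt: str
) -> str:
    vstart, vend, kind, delta = _variant_span(pos, ref, alt)

    def hits(a: int, b: int) -> bool:
        if kind == "insertion":
            return a <= vstart and vend <= b  # point strictly inside
        return _overlaps(vstart, vend, a, b)

    # splice windows outrank everything else (more specific signal)
    for a, b, sk in model.splice_windows():
        if hits(a, b):
            return sk
    if any(hits(a, b) for a, b in model.cds):
        if kind in ("snv", "mnv"):
            if kind == "mnv":
                return "missense"  # complex substitution; conservative call
            return _codon_effect(model, genome, pos, ref, alt)
        if kind == "deletion":
            # frame change counts only the deleted bases inside the CDS
            cds_delta = -sum(
                max(0, min(vend, b) - max(vstart, a) + 1) for a, b in model.cds
            )
        else:
            cds_delta = delta
        if cds_delta % 3 != 0:
            return "frameshift"
        return "inframe_insertion" if cds_delta > 0 else "inframe_deletion"
    if any(hits(a, b) for a, b in model.exons):
        if not model.cds:
            return "intron"  # non-coding transcript; treated as MODIFIER
        cds_lo = model.cds[0][0]
        cds_hi = model.cds[-1][1]
        if vend < cds_lo:
            return "five_prime_UTR" if model.strand == "+" else "three_prime_UTR"
        if vstart > cds_hi:
            return "three_prime_UTR" if model.strand == "+" else "five_prime_UTR"
        return "intron"  # straddles CDS boundary without hitting CDS: exotic
    if hits(model.start, model.end):
        return "intron"
    return "intergenic"


def classify_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    gene_models: Sequence[GeneModel],
    genome,
) -> list[VariantEffect]:
    """Classify one bi-allelic variant against every overlapping transcript.

    REF must match the genome at ``pos`` (a mismatch signals a coordinate
    convention bug and is a hard error). Returns one VariantEffect per
    overlapping transcript, or a single intergenic record when none
    overlap.
    """
    obs = fetch_seq(genome, chrom, pos, pos + len(ref) - 1)
    if obs != ref.upper():
        raise ValueError(
            f"REF mismatch at {chrom}:{pos}: VCF says {ref!r}, genome has {obs!r}"
        )
    vstart, vend, _, _ = _variant_span(pos, ref, alt)
    out: list[VariantEffect] = []
    for model in gene_models:
        if model.chrom != chrom or not _overlaps(vstart, vend, model.start, model.end):
            continue
        cons = _classify_for_model(model, genome, chrom, pos, ref, alt)
        out.append(
            VariantEffect(
                chrom=chrom, pos=pos, ref=ref, alt=alt,
                gene_id=model.gene_id, transcript_id=model.transcript_id,
                consequence=cons, impact=IMPACT_OF[cons],
            )
        )
    if not out:
        out.append(
            VariantEffect(
                chrom=chrom, pos=pos, ref=ref, alt=alt, gene_id=".",
                transcript_id=".", consequence="intergenic",
                impact=IMPACT_OF["intergenic"],
            )
        )
    return out


def classify_all(
    variants: Iterable[tuple[str, int, str, str]],
    gene_models: Sequence[GeneModel],
    genome,
) -> list[VariantEffect]:
    """Classify (chrom, pos, ref, alt) tuples; worst impact per gene each."""
    out: list[VariantEffect] = []
    for chrom, pos, ref, alt in variants:
        out.extend(
            worst_effect_per_gene(
                classify_variant(chrom, pos, ref, alt, gene_models, genome)
            )
        )
    return out


def worst_effect_per_gene(effects: Sequence[VariantEffect]) -> list[VariantEffect]:
    """Keep, per gene, the transcript effect with the highest impact tier."""
    best: dict[str, VariantEffect] = {}
    for eff in effects:
        cur = best.get(eff.gene_id)
        if cur is None or _IMPACT_RANK[eff.impact] > _IMPACT_RANK[cur.impact]:
            best[eff.gene_id] = eff
    return list(best.values())


def write_effects_tsv(effects: Sequence[VariantEffect], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("chrom\tpos\tref\talt\tgene\ttranscript\tconsequence\timpact\n")
        for e in effects:
            fh.write(
                f"{e.chrom}\t{e.pos}\t{e.ref}\t{e.alt}\t{e.gene_id}\t"
                f"{e.transcript_id}\t{e.consequence}\t{e.impact}\n"
            )
    return path
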
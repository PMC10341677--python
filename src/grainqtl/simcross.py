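"""Synthetic F2 intercross generator.

Emulates the cross design behind resequencing-based QTL mapping of a
monogenic recessive grain-size trait: two fully homozygous inbred parents
(P1, the sequenced parent; P2, the mutant parent carrying the recessive
allele), an F1, and an F2 population obtained by selfing. Each F2
individual is the union of two independent F1 gametes; gametes recombine
under the Haldane model (Poisson crossover count, no interference).

A single causal locus on one chromosome determines a binary size class
(recessive: only P2-homozygotes are "small") and shifts a quantitative
grain-length phenotype. Genotyping error and missingness are applied after
the hidden truth is recorded, so parameter-recovery tests can compare
against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .markers import P1_HOM, HET, P2_HOM, MISSING

__all__ = [
    "SimConfig",
    "TruthRecord",
    "F2Simulation",
    "simulate_gamete",
    "simulate_f2",
    "write_simulated_vcf",
    "write_phenotypes",
    "write_truth",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of the simulated cross.

    Defaults mirror the mapping-population design the generator emulates:
    49 F2 individuals, a recessive causal locus with a large effect on
    grain length (1.0 mm shift against a 0.2 mm residual SD, i.e. clearly
    separable classes), and a rice-like recombination rate of 4 cM/Mb.
    Grain-length defaults (7.0 mm mean) are plausible rice values chosen as
    configuration defaults, not estimates from any particular cross.
    """

    n_chromosomes: int = 2
    chrom_length_bp: int | Sequence[int] = 25_000_000
    markers_per_chrom: int = 200
    cm_per_mb: float = 4.0
    n_f2: int = 49
    causal_chrom: str = "chr1"
    causal_pos_bp: int = 12_500_000
    effect_size: float = 1.0
    pheno_sd: float = 0.2
    pheno_mean: float = 7.0
    width_mean: float = 3.0
    width_shift: float = 0.05
    width_sd: float = 0.05
    genotyping_error_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        if self.markers_per_chrom < 2:
            raise ValueError("need at least two markers per chromosome")
        if self.n_f2 < 1:
            raise ValueError("need at least one F2 individual")
        for rate, name in [
            (self.genotyping_error_rate, "genotyping_error_rate"),
            (self.missing_rate, "missing_rate"),
        ]:
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.cm_per_mb < 0:
            raise ValueError("cm_per_mb must be non-negative")
        if self.pheno_sd < 0 or self.width_sd < 0:
            raise ValueError("phenotype SDs must be non-negative")
        lengths = self.chrom_lengths()
        if any(l <= 0 for l in lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.causal_chrom not in self.chrom_names():
            raise ValueError(f"causal_chrom {self.causal_chrom!r} not in genome")
        causal_len = dict(zip(self.chrom_names(), lengths))[self.causal_chrom]
        if not 1 <= self.causal_pos_bp <= causal_len:
            raise ValueError("causal_pos_bp outside its chromosome")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def chrom_lengths(self) -> list[int]:
        if isinstance(self.chrom_length_bp, (int, np.integer)):
            return [int(self.chrom_length_bp)] * self.n_chromosomes
        lengths = [int(x) for x in self.chrom_length_bp]
        if len(lengths) != self.n_chromosomes:
            raise ValueError("chrom_length_bp length mismatch")
        return lengths


@dataclass
class TruthRecord:
    """Hidden state of a simulated cross, for recovery tests.

    ``crossovers[sample][chrom]`` holds two lists of breakpoint positions
    (bp), one per gamete. ``causal_genotype`` uses the panel coding
    (0 = P1-hom, 1 = het, 2 = P2-hom); class is "small" iff the causal
    genotype is P2-homozygous (fully penetrant recessive model).
    """

    causal_chrom: str
    causal_pos_bp: int
    causal_marker_index: int
    samples: list[str]
    causal_genotype: list[int]
    phenotype_class: list[str]
    crossovers: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        return cls(**json.loads(text))


@dataclass
class F2Simulation:
    """Everything simulate_f2 produces: observed data plus hidden truth."""

    config: SimConfig
    samples: list[str]
    parent_sample: str
    positions: dict[str, np.ndarray]          # chrom -> marker bp positions
    genotypes: np.ndarray                     # (n_f2, n_markers) observed codes
    true_genotypes: np.ndarray                # same shape, error/missing-free
    ref_alleles: np.ndarray                   # per marker
    alt_alleles: np.ndarray
    parent_is_alt: np.ndarray                 # bool per marker: P1 carries ALT
    phenotypes: pd.DataFrame
    truth: TruthRecord

    @property
    def marker_chroms(self) -> np.ndarray:
        return np.concatenate(
            [np.repeat(c, len(p)) for c, p in self.positions.items()]
        )

    @property
    def marker_positions(self) -> np.ndarray:
        return np.concatenate(list(self.positions.values()))


def simulate_gamete(
    marker_positions: np.ndarray,
    chrom_length_bp: int,
    cm_per_mb: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[int]]:
    """Draw one F1 gamete for a chromosome under the Haldane model.

    The genetic length is ``L = length_bp * cm_per_mb / 1e6 / 100`` Morgans;
    the crossover count is Poisson(L) and breakpoints are uniform on the
    (linear) genetic map, hence uniform in bp. The gamete is a mosaic of
    the two grandparental haplotypes, returned as a 0/1 allele per marker
    (1 = mutant-parent allele), plus the breakpoint positions.
    """
    if chrom_length_bp <= 0:
        raise ValueError("chromosome length must be positive")
    L = chrom_length_bp * cm_per_mb / 1e6 / 100.0
    n_xo = int(rng.poisson(L))
    breaks = np.sort(rng.uniform(0, chrom_length_bp, size=n_xo))
    start = int(rng.integers(0, 2))
    # allele flips at each breakpoint
    alleles = (start + np.searchsorted(breaks, marker_positions)) % 2
    return alleles.astype(np.int8), [int(b) for b in breaks]


def _marker_positions(config: SimConfig) -> dict[str, np.ndarray]:
    """Evenly spaced markers; the causal site replaces its nearest marker."""
    out: dict[str, np.ndarray] = {}
    for chrom, length in zip(config.chrom_names(), config.chrom_lengths()):
        pos = np.unique(
            np.linspace(1, length, config.markers_per_chrom).round().astype(np.int64)
        )
        if chrom == config.causal_chrom and config.causal_pos_bp not in pos:
            i = int(np.argmin(np.abs(pos - config.causal_pos_bp)))
            pos[i] = config.causal_pos_bp
            pos = np.unique(pos)
        out[chrom] = pos
    return out


def simulate_f2(config: SimConfig) -> F2Simulation:
    """Simulate an F2 population with phenotypes and hidden truth.

    Each individual is formed from two independent gametes per chromosome.
    Grain length is ``pheno_mean - effect_size * [causal genotype == P2-hom]
    + N(0, pheno_sd)``; the binary class ("small" vs "large") follows the
    true causal genotype. Genotyping error (replace by one of the other two
    codes, uniformly) and missingness are applied to a copy after the truth
    is recorded. Identical seeds give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    positions = _marker_positions(config)
    chrom_names = config.chrom_names()
    lengths = dict(zip(chrom_names, config.chrom_lengths()))
    samples = [f"F2_{i + 1:03d}" for i in range(config.n_f2)]

    causal_pos = positions[config.causal_chrom]
    causal_idx_in_chrom = int(np.searchsorted(causal_pos, config.causal_pos_bp))
    offset = 0
    for c in chrom_names:
        if c == config.causal_chrom:
            break
        offset += len(positions[c])
    causal_marker_index = offset + causal_idx_in_chrom

    blocks = []
    crossovers: dict[str, dict[str, list[list[int]]]] = {s: {} for s in samples}
    for chrom in chrom_names:
        pos = positions[chrom]
        geno = np.empty((config.n_f2, len(pos)), dtype=np.int8)
        for i, s in enumerate(samples):
            g1, b1 = simulate_gamete(pos, lengths[chrom], config.cm_per_mb, rng)
            g2, b2 = simulate_gamete(pos, lengths[chrom], config.cm_per_mb, rng)
            geno[i] = g1 + g2
            crossovers[s][chrom] = [b1, b2]
        blocks.append(geno)
    true_geno = np.concatenate(blocks, axis=1)

    causal_geno = true_geno[:, causal_marker_index].copy()
    is_small = causal_geno == P2_HOM
    length_mm = (
        config.pheno_mean
        - config.effect_size * is_small
        + rng.normal(0.0, config.pheno_sd, size=config.n_f2)
    )
    width_mm = (
        config.width_mean
        + config.width_shift * is_small
        + rng.normal(0.0, config.width_sd, size=config.n_f2)
    )
    classes = np.where(is_small, "small", "large")
    phenotypes = pd.DataFrame(
        {
            "sample_id": samples,
            "length_mm": length_mm,
            "width_mm": width_mm,
            "class": classes,
        }
    )

    # observed genotypes: perturb, then mask
    observed = true_geno.copy()
    if config.genotyping_error_rate > 0:
        err = rng.random(observed.shape) < config.genotyping_error_rate
        shift = rng.integers(1, 3, size=observed.shape)  # +1 or +2 mod 3
        observed[err] = ((observed[err] + shift[err]) % 3).astype(np.int8)
    if config.missing_rate > 0:
        observed[rng.random(observed.shape) < config.missing_rate] = MISSING

    n_markers = true_geno.shape[1]
    ref_idx = rng.integers(0, 4, size=n_markers)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_markers)) % 4
    parent_is_alt = rng.random(n_markers) < 0.5
    # the causal allele is derived (arose in the mutant parent), so the
    # sequenced parent carries the reference allele at the causal site
    parent_is_alt[causal_marker_index] = False
    truth = TruthRecord(
        causal_chrom=config.causal_chrom,
        causal_pos_bp=int(config.causal_pos_bp),
        causal_marker_index=causal_marker_index,
        samples=samples,
        causal_genotype=[int(g) for g in causal_geno],
        phenotype_class=[str(c) for c in classes],
        crossovers=crossovers,
    )
    return F2Simulation(
        config=config,
        samples=samples,
        parent_sample="P1",
        positions=positions,
        genotypes=observed,
        true_genotypes=true_geno,
        ref_alleles=_BASES[ref_idx],
        alt_alleles=_BASES[alt_idx],
        parent_is_alt=parent_is_alt,
        phenotypes=phenotypes,
        truth=truth,
    )


def _gt_string(code: int, parent_is_alt: bool) -> str:
    """Map a phased code to an unphased VCF GT given the P1 allele."""
    if code == MISSING:
        return "./."
    if code == HET:
        return "0/1"
    p1_allele = 1 if parent_is_alt else 0
    if code == P1_HOM:
        a = p1_allele
    else:  # P2_HOM
        a = 1 - p1_allele
    return f"{a}/{a}"


def write_simulated_vcf(
    sim: F2Simulation,
    path: str | Path,
    qual: float = 999.0,
    mean_depth: float = 40.0,
) -> Path:
    """Emit the simulated genotypes as a minimal VCF 4.2 file.

    One column for the sequenced parent (homozygous everywhere, at the
    REF or ALT allele per the simulated orientation) followed by the F2
    samples. QUAL is constant and per-cell DP is Poisson(mean_depth), so
    the quality filters are exercisable but pass by default.
    """
    path = Path(path)
    rng = np.random.default_rng(sim.config.seed + 2**20)  # depth substream
    chroms = sim.marker_chroms
    positions = sim.marker_positions
    n_markers = len(positions)
    all_samples = [sim.parent_sample] + sim.samples
    dp = rng.poisson(mean_depth, size=(n_markers, len(all_samples)))
    lengths = dict(zip(sim.config.chrom_names(), sim.config.chrom_lengths()))
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=grainqtl.simcross\n')
        for c in sim.config.chrom_names():
            fh.write(f"##contig=<ID={c},length={lengths[c]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(all_samples)
            + "\n"
        )
        for m in range(n_markers):
            p1_gt = "1/1" if sim.parent_is_alt[m] else "0/0"
            cells = [f"{p1_gt}:{dp[m, 0]}"]
            for i in range(sim.config.n_f2):
                gt = _gt_string(int(sim.genotypes[i, m]), bool(sim.parent_is_alt[m]))
                cells.append(f"{gt}:{dp[m, i + 1]}")
            fh.write(
                f"{chroms[m]}\t{positions[m]}\t.\t{sim.ref_alleles[m]}\t"
                f"{sim.alt_alleles[m]}\t{qual:g}\tPASS\t.\tGT:DP\t"
                + "\t".join(cells)
                + "\n"
            )
    return path


def simulate_annotation(
    sim: F2Simulation,
    n_decoy_genes: int = 2,
) -> tuple[dict[str, str], list]:
    """Build a toy genome and gene models that make the causal marker HIGH.

    The causal marker becomes the last base of the first intron of a
    two-exon coding gene ("geneC"), so any substitution there disrupts the
    splice acceptor. Up to ``n_decoy_genes`` further genes ("decoy1", ...)
    are placed the same way at the nearest markers on the causal
    chromosome whose disrupting (ALT) allele is carried by the *sequenced*
    parent — high-impact decoys that the parental ruling-out logic must
    discard. The genome carries each marker's REF base at its position.

    Returns the genome as a dict of contig sequences plus the GeneModel
    list; use :func:`write_annotation` to emit FASTA/GFF3 files.
    """
    from .effects import GeneModel

    lengths = dict(zip(sim.config.chrom_names(), sim.config.chrom_lengths()))
    seqs = {c: bytearray(b"A" * l) for c, l in lengths.items()}
    chroms = sim.marker_chroms
    positions = sim.marker_positions
    for m in range(len(positions)):
        seqs[chroms[m]][positions[m] - 1] = ord(sim.ref_alleles[m])

    cds_fill = ("ATG" + "GGA" * 58 + "TAA").encode()  # 180 bp, clean ORF

    def place_gene(gene_id: str, chrom: str, p: int) -> GeneModel | None:
        # two-exon gene with p as the last intronic base (splice acceptor)
        if p - 210 < 1 or p + 120 > lengths[chrom]:
            return None
        exons = [(p - 210, p - 91), (p + 1, p + 120)]
        cds = [(p - 180, p - 91), (p + 1, p + 90)]
        seq = seqs[chrom]
        seq[p - 181 : p - 91] = cds_fill[:90]
        seq[p : p + 90] = cds_fill[90:]
        # canonical splice dinucleotides; p itself keeps the marker REF base
        seq[p - 91] = ord("G")
        seq[p - 90] = ord("T")
        seq[p - 2] = ord("A")
        return GeneModel(
            transcript_id=f"{gene_id}.1", gene_id=gene_id, chrom=chrom,
            strand="+", exons=exons, cds=cds,
        )

    models = []
    causal = place_gene("geneC", sim.truth.causal_chrom, sim.truth.causal_pos_bp)
    if causal is None:
        raise ValueError("causal position too close to a chromosome end")
    models.append(causal)

    on_chrom = np.flatnonzero(
        (chroms == sim.truth.causal_chrom) & sim.parent_is_alt
    )
    order = on_chrom[
        np.argsort(np.abs(positions[on_chrom] - sim.truth.causal_pos_bp))
    ]
    used = [(causal.start, causal.end)]
    k = 0
    for m in order:
        if k >= n_decoy_genes:
            break
        p = int(positions[m])
        if any(abs(p - (a + b) // 2) < 1000 for a, b in used):
            continue
        g = place_gene(f"decoy{k + 1}", str(chroms[m]), p)
        if g is None:
            continue
        models.append(g)
        used.append((g.start, g.end))
        k += 1
    genome = {c: bytes(s).decode() for c, s in seqs.items()}
    return genome, models


def write_annotation(
    genome: dict[str, str],
    models: Sequence,
    fasta_path: str | Path,
    gff3_path: str | Path,
    line_width: int = 80,
) -> tuple[Path, Path]:
    """Write a toy genome dict and GeneModels as FASTA + GFF3 files."""
    fasta_path = Path(fasta_path)
    gff3_path = Path(gff3_path)
    with fasta_path.open("w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")
    with gff3_path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            fh.write(
                f"{g.chrom}\ttoy\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            fh.write(
                f"{g.chrom}\ttoy\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.transcript_id};Parent={g.gene_id}\n"
            )
            for a, b in g.exons:
                fh.write(
                    f"{g.chrom}\ttoy\texon\t{a}\t{b}\t.\t{g.strand}\t.\t"
                    f"Parent={g.transcript_id}\n"
                )
            for a, b in g.cds:
                fh.write(
                    f"{g.chrom}\ttoy\tCDS\t{a}\t{b}\t.\t{g.strand}\t0\t"
                    f"Parent={g.transcript_id}\n"
                )
    return fasta_path, gff3_path


def write_phenotypes(phenotypes: pd.DataFrame, path: str | Path) -> Path:
    """Write the phenotype table as TSV (sample_id, length_mm, width_mm, class)."""
    path = Path(path)
    phenotypes.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def write_truth(truth: TruthRecord, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(truth.to_json())
    return path
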
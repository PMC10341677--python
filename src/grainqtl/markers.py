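"""VCF reading, variant-quality filtering and one-parent marker phasing.

The mapping design has only one sequenced parent (P1); the other parent's
genotype is inferred by contrast. After quality filtering, every retained
bi-allelic site is recoded relative to the sequenced parent's homozygous
allele: an F2 homozygous for the parent allele is ``P1_HOM`` (0), the
opposite homozygote is ``P2_HOM`` (2) and heterozygotes are ``HET`` (1).
Sites that do not segregate among the F2s (minor allele frequency below a
cutoff) are parent-vs-reference differences and are excluded.

Filtering follows four rules applied in order:

1. keep bi-allelic sites with variant quality >= ``min_qual`` (inclusive);
2. set individual genotypes to missing when their read depth falls outside
   ``[min_depth, max_depth]`` (both ends inclusive);
3. remove every site within ``pseudo_het_radius_bp`` (inclusive) of a site
   where the fully inbred sequenced parent is called heterozygous — such
   "pseudo-heterozygous" calls flag read mis-mapping — including the
   flagged site itself;
4. remove sites where more than ``max_missing_fraction`` of the sample
   columns are missing (strict majority under the default 0.5).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

# phased genotype codes (relative to the sequenced parent P1)
P1_HOM = 0
HET = 1
P2_HOM = 2
MISSING = -1

# raw VCF genotype codes (relative to REF/ALT)
REF_HOM = 0
ALT_HOM = 2

__all__ = [
    "P1_HOM",
    "HET",
    "P2_HOM",
    "MISSING",
    "REF_HOM",
    "ALT_HOM",
    "VariantRecord",
    "FilterParams",
    "FilterReport",
    "MarkerPanel",
    "read_vcf",
    "filter_variants",
    "phase_against_parent",
]


@dataclass
class VariantRecord:
    """One VCF site with per-sample genotype codes and read depths.

    ``genotypes`` are coded against REF/ALT (0 = ref-hom, 1 = het,
    2 = alt-hom, -1 = missing), one entry per sample in ``samples`` order.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    qual: float
    samples: tuple[str, ...]
    genotypes: np.ndarray  # int8
    depths: np.ndarray  # int32; -1 when DP absent

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1

    @property
    def alt(self) -> str:
        return self.alts[0]

    def genotype_of(self, sample: str) -> int:
        return int(self.genotypes[self.samples.index(sample)])


def _code_gt(alleles: tuple) -> int:
    if alleles is None or len(alleles) == 0 or any(a is None for a in alleles):
        return MISSING
    if len(set(alleles)) > 1:
        return HET
    return REF_HOM if alleles[0] == 0 else ALT_HOM


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read a VCF 4.2 file (GT and DP per sample) into VariantRecords.

    Records come back in file order; multi-allelic records are kept but
    flagged via ``is_biallelic`` for removal downstream; a missing GT
    (``./.``) is coded -1 with the depth as given.
    """
    path = Path(path)
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise ValueError(f"{path}: malformed VCF header: {exc}") from exc
    samples = tuple(vf.header.samples)
    records: list[VariantRecord] = []
    try:
        for i, rec in enumerate(vf):
            genos = np.empty(len(samples), dtype=np.int8)
            depths = np.empty(len(samples), dtype=np.int32)
            for j, s in enumerate(samples):
                call = rec.samples[s]
                genos[j] = _code_gt(call.get("GT"))
                dp = call.get("DP")
                depths[j] = -1 if dp is None else int(dp)
            records.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=tuple(rec.alts or ()),
                    qual=float(rec.qual) if rec.qual is not None else float("nan"),
                    samples=samples,
                    genotypes=genos,
                    depths=depths,
                )
            )
    except (ValueError, OSError) as exc:
        raise ValueError(
            f"{path}: malformed record near data line {len(records) + 1}: {exc}"
        ) from exc
    finally:
        vf.close()
    return records


@dataclass
class FilterParams:
    """Thresholds of the four-rule variant filter plus the MAF screen."""

    min_qual: float = 50.0
    min_depth: int = 10
    max_depth: int = 90
    pseudo_het_radius_bp: int = 150
    max_missing_fraction: float = 0.5
    min_maf: float = 0.05

    def __post_init__(self) -> None:
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth must not exceed max_depth")
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must be in [0, 1]")
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0, 0.5]")


@dataclass
class FilterReport:
    """Per-rule rejection counts, in application order."""

    n_input: int = 0
    rule1_low_qual_or_multiallelic: int = 0
    rule2_genotypes_masked: int = 0  # genotype cells set missing, not sites
    rule3_pseudo_het_window: int = 0
    rule4_excess_missing: int = 0
    n_retained: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def filter_variants(
    records: Sequence[VariantRecord],
    parent_sample: str,
    params: FilterParams | None = None,
) -> tuple[list[VariantRecord], FilterReport]:
    """Apply the four quality-filter rules in order; report rejections.

    Rule 2 masks individual genotype calls (depth outside the inclusive
    band) rather than dropping the site, so that the missingness rule 4
    can then act on the site as a whole. Pseudo-heterozygous seeds for
    rule 3 are the sites where the parent call is heterozygous after
    rules 1–2; removal is symmetric and inclusive
    (``|pos - het_pos| <= radius``) and removes the seed site itself.
    """
    params = params or FilterParams()
    if records and parent_sample not in records[0].samples:
        raise KeyError(f"parent sample {parent_sample!r} not in VCF columns")
    report = FilterReport(n_input=len(records))

    # rule 1: bi-allelic, qual >= min_qual (inclusive)
    stage1 = []
    for rec in records:
        if rec.is_biallelic and rec.qual >= params.min_qual:
            stage1.append(rec)
        else:
            report.rule1_low_qual_or_multiallelic += 1

    # rule 2: per-sample depth band, inclusive both ends; mask to missing
    stage2 = []
    for rec in stage1:
        has_dp = rec.depths >= 0
        bad = has_dp & (
            (rec.depths < params.min_depth) | (rec.depths > params.max_depth)
        )
        bad &= rec.genotypes != MISSING
        if bad.any():
            genos = rec.genotypes.copy()
            genos[bad] = MISSING
            rec = VariantRecord(
                chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alts=rec.alts,
                qual=rec.qual, samples=rec.samples, genotypes=genos,
                depths=rec.depths,
            )
            report.rule2_genotypes_masked += int(bad.sum())
        stage2.append(rec)

    # rule 3: drop sites within the radius of a parent-heterozygous site
    pidx = records[0].samples.index(parent_sample) if records else 0
    het_pos: dict[str, list[int]] = {}
    for rec in stage2:
        if rec.genotypes[pidx] == HET:
            het_pos.setdefault(rec.chrom, []).append(rec.pos)
    stage3 = []
    for rec in stage2:
        near = any(
            abs(rec.pos - hp) <= params.pseudo_het_radius_bp
            for hp in het_pos.get(rec.chrom, ())
        )
        if near:
            report.rule3_pseudo_het_window += 1
        else:
            stage3.append(rec)

    # rule 4: strict-majority missingness over all sample columns
    retained = []
    for rec in stage3:
        frac = float(np.mean(rec.genotypes == MISSING))
        if frac > params.max_missing_fraction:
            report.rule4_excess_missing += 1
        else:
            retained.append(rec)
    report.n_retained = len(retained)
    return retained, report


@dataclass
class MarkerPanel:
    """Phased F2 genotype matrix over ordered marker positions.

    ``genotypes`` has shape (n_f2, n_markers) with codes 0/1/2/-1 as in the
    module header; the parent sample itself is not a column. ``parent_is_alt``
    records, per marker, whether the sequenced parent carries the ALT allele
    (needed to map phased codes back to VCF alleles).
    """

    samples: list[str]
    parent_sample: str
    chroms: np.ndarray  # per-marker chromosome id
    positions: np.ndarray  # per-marker 1-based bp
    genotypes: np.ndarray  # (n_f2, n_markers) int8
    ref: np.ndarray = field(default=None)  # type: ignore[assignment]
    alt: np.ndarray = field(default=None)  # type: ignore[assignment]
    parent_is_alt: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.positions)
        if self.ref is None:
            self.ref = np.full(n, "N", dtype=object)
        if self.alt is None:
            self.alt = np.full(n, "N", dtype=object)
        if self.parent_is_alt is None:
            self.parent_is_alt = np.zeros(n, dtype=bool)
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        order = np.lexsort((self.positions, _chrom_rank(self.chroms)))
        if not np.array_equal(order, np.arange(n)):
            self._reorder(order)
        for chrom in self.chrom_names():
            pos = self.positions[self.chroms == chrom]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"duplicate marker positions on {chrom}")

    def _reorder(self, order: np.ndarray) -> None:
        self.chroms = self.chroms[order]
        self.positions = self.positions[order]
        self.genotypes = self.genotypes[:, order]
        self.ref = self.ref[order]
        self.alt = self.alt[order]
        self.parent_is_alt = self.parent_is_alt[order]

    @property
    def n_markers(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def chrom_names(self) -> list[str]:
        seen: list[str] = []
        for c in self.chroms:
            if c not in seen:
                seen.append(c)
        return seen

    def chrom_slice(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.chroms == chrom)

    def interval_slice(self, chrom: str, start_bp: int, end_bp: int) -> np.ndarray:
        """Marker indices within [start_bp, end_bp] (1-based inclusive)."""
        return np.flatnonzero(
            (self.chroms == chrom)
            & (self.positions >= start_bp)
            & (self.positions <= end_bp)
        )

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        df = pd.DataFrame(
            {
                "chrom": self.chroms,
                "pos": self.positions,
                "ref": self.ref,
                "alt": self.alt,
                "parent_is_alt": self.parent_is_alt.astype(int),
            }
        )
        codes = self.genotypes.astype(object).T
        for j, s in enumerate(self.samples):
            col = codes[:, j]
            col[col == MISSING] = "NA"
            df[s] = col
        df.to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def from_tsv(cls, path: str | Path, parent_sample: str = "P1") -> "MarkerPanel":
        df = pd.read_csv(
            Path(path), sep="\t", dtype={"chrom": str}, keep_default_na=False
        )
        meta = ["chrom", "pos", "ref", "alt", "parent_is_alt"]
        samples = [c for c in df.columns if c not in meta]
        geno = (
            df[samples]
            .replace("NA", MISSING)
            .apply(pd.to_numeric)
            .to_numpy(dtype=np.int8)
            .T
        )
        return cls(
            samples=samples,
            parent_sample=parent_sample,
            chroms=df["chrom"].to_numpy(dtype=object),
            positions=df["pos"].to_numpy(dtype=np.int64),
            genotypes=geno,
            ref=df["ref"].to_numpy(dtype=object),
            alt=df["alt"].to_numpy(dtype=object),
            parent_is_alt=df["parent_is_alt"].to_numpy(dtype=bool),
        )


def _chrom_rank(chroms: np.ndarray) -> np.ndarray:
    names = sorted(set(chroms), key=_natural_key)
    rank = {c: i for i, c in enumerate(names)}
    return np.array([rank[c] for c in chroms])


def _natural_key(name: str):
    digits = "".join(ch for ch in name if ch.isdigit())
    return (int(digits) if digits else 1 << 30, name)


def phase_against_parent(
    records: Sequence[VariantRecord],
    parent_sample: str,
    params: FilterParams | None = None,
) -> MarkerPanel:
    """Recode filtered records relative to the sequenced parent.

    Sites where the parent call is missing or heterozygous cannot be
    phased and are dropped (logged). Each F2 genotype becomes P1_HOM when
    it matches the parent homozygote, P2_HOM for the opposite homozygote
    and HET for heterozygous calls. The minor allele frequency is computed
    over non-missing F2 allele calls (two per individual, one per het
    allele) and sites with MAF < ``min_maf`` are excluded — these are
    parent-vs-reference differences that do not segregate in the cross.
    Sites with no non-missing F2 call are dropped.
    """
    params = params or FilterParams()
    if records and parent_sample not in records[0].samples:
        raise KeyError(f"parent sample {parent_sample!r} not in VCF columns")
    dropped = {"parent_missing": 0, "parent_het": 0, "low_maf": 0, "all_missing": 0}
    chroms, positions, refs, alts, p_is_alt, columns = [], [], [], [], [], []
    samples: list[str] = []
    for rec in records:
        pidx = rec.samples.index(parent_sample)
        pg = int(rec.genotypes[pidx])
        if pg == MISSING:
            dropped["parent_missing"] += 1
            continue
        if pg == HET:
            dropped["parent_het"] += 1
            continue
        f2_mask = np.ones(len(rec.samples), dtype=bool)
        f2_mask[pidx] = False
        if not samples:
            samples = [s for i, s in enumerate(rec.samples) if f2_mask[i]]
        raw = rec.genotypes[f2_mask]
        # recode relative to parent allele
        phased = np.full(raw.shape, MISSING, dtype=np.int8)
        phased[raw == HET] = HET
        phased[raw == pg] = P1_HOM
        phased[(raw != MISSING) & (raw != HET) & (raw != pg)] = P2_HOM
        obs = phased != MISSING
        if not obs.any():
            dropped["all_missing"] += 1
            continue
        # allele counts: P1_HOM -> 2 parent alleles, HET -> 1 each, P2_HOM -> 2 other
        n_p1 = 2 * int((phased == P1_HOM).sum()) + int((phased == HET).sum())
        n_p2 = 2 * int((phased == P2_HOM).sum()) + int((phased == HET).sum())
        maf = min(n_p1, n_p2) / (n_p1 + n_p2)
        if maf < params.min_maf:
            dropped["low_maf"] += 1
            continue
        chroms.append(rec.chrom)
        positions.append(rec.pos)
        refs.append(rec.ref)
        alts.append(rec.alt)
        p_is_alt.append(pg == ALT_HOM)
        columns.append(phased)
    if any(dropped.values()):
        logger.info("phase_against_parent dropped sites: %s", dropped)
    geno = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return MarkerPanel(
        samples=samples,
        parent_sample=parent_sample,
        chroms=np.array(chroms, dtype=object),
        positions=np.array(positions, dtype=np.int64),
        genotypes=geno,
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        parent_is_alt=np.array(p_is_alt, dtype=bool),
    )
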
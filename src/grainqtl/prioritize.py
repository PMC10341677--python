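"""Causal-gene prioritization for a recessive trait in an F2 cross.

Inside the QTL support interval, a variant is a plausible cause of a fully
penetrant recessive phenotype only if it strictly co-segregates with it:
every recessive-class individual must be homozygous for the mutant-parent
allele, and no dominant-class individual may be. Among co-segregating
variants, only HIGH-impact (function-abolishing) consequences are retained,
and each disrupting allele is assigned to the parental haplotype that
carries it. Knowing which parent the phenotype arose in (the mutagenized
line) then rules genes in or out:

* genes whose only high-impact alleles come from the *other* parent would
  make the phenotype dominant-functional — ruled out;
* genes disrupted by high-impact alleles from *both* parents cannot
  explain a phenotype present in only one — ruled out;
* the remainder, carrying mutant-parent-associated high-impact alleles,
  are the candidates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .markers import MarkerPanel, P1_HOM, HET, P2_HOM, MISSING
from .effects import VariantEffect

__all__ = [
    "SegregationPattern",
    "CandidateReport",
    "cosegregation_filter",
    "parental_association",
    "rank_candidates",
]

MUTANT_PARENT = "mutant_parent"
OTHER_PARENT = "other_parent"
UNRESOLVABLE = "unresolvable"


@dataclass
class SegregationPattern:
    """Recessive-rule evaluation of one marker against phenotype classes."""

    chrom: str
    pos: int
    co_segregates: bool
    n_recessive_mutant_hom: int
    n_recessive_other: int  # recessive-class individuals violating the rule
    n_dominant_mutant_hom: int  # dominant-class individuals violating the rule
    recessive_callrate: float
    dominant_callrate: float


def cosegregation_filter(
    panel: MarkerPanel,
    phenotype_classes: Mapping[str, str] | Sequence[str],
    interval: tuple[str, int, int] | None = None,
    recessive_label: str = "small",
    min_class_callrate: float = 0.8,
) -> tuple[np.ndarray, list[SegregationPattern]]:
    """Markers whose genotypes strictly co-segregate with the recessive class.

    A marker co-segregates when every non-missing recessive-class genotype
    is mutant-parent homozygous (P2_HOM) and no non-missing dominant-class
    genotype is. Missing calls neither satisfy nor violate the rule, but a
    marker is only eligible when at least ``min_class_callrate`` of each
    phenotype class is non-missing there.

    Parameters
    ----------
    phenotype_classes
        Mapping from sample id to class label, or a sequence aligned with
        ``panel.samples``.
    interval
        ``(chrom, start_bp, end_bp)``, 1-based inclusive — typically the
        LOD support interval. ``None`` scans the whole panel.

    Returns
    -------
    Marker indices (into the panel) of co-segregating variants, and the
    per-marker SegregationPattern for every marker examined.
    """
    if isinstance(phenotype_classes, Mapping):
        labels = np.array([phenotype_classes[s] for s in panel.samples])
    else:
        labels = np.asarray(list(phenotype_classes))
        if labels.size != panel.n_samples:
            raise ValueError("phenotype class vector length mismatch")
    rec = labels == recessive_label
    dom = ~rec
    if not rec.any():
        raise ValueError("no recessive-class individuals: pattern undefined")

    if interval is None:
        marker_idx = np.arange(panel.n_markers)
    else:
        chrom, start, end = interval
        marker_idx = panel.interval_slice(chrom, start, end)

    geno = panel.genotypes
    hits: list[int] = []
    patterns: list[SegregationPattern] = []
    for m in marker_idx:
        g = geno[:, m]
        rg = g[rec]
        dg = g[dom]
        rec_obs = rg != MISSING
        dom_obs = dg != MISSING
        rec_cr = float(rec_obs.mean()) if rg.size else 0.0
        dom_cr = float(dom_obs.mean()) if dg.size else 1.0
        n_rec_mut = int((rg[rec_obs] == P2_HOM).sum())
        n_rec_other = int(rec_obs.sum()) - n_rec_mut
        n_dom_mut = int((dg[dom_obs] == P2_HOM).sum())
        ok = (
            rec_cr >= min_class_callrate
            and dom_cr >= min_class_callrate
            and n_rec_other == 0
            and n_dom_mut == 0
            and rec_obs.any()
        )
        patterns.append(
            SegregationPattern(
                chrom=str(panel.chroms[m]),
                pos=int(panel.positions[m]),
                co_segregates=bool(ok),
                n_recessive_mutant_hom=n_rec_mut,
                n_recessive_other=n_rec_other,
                n_dominant_mutant_hom=n_dom_mut,
                recessive_callrate=rec_cr,
                dominant_callrate=dom_cr,
            )
        )
        if ok:
            hits.append(int(m))
    return np.array(hits, dtype=int), patterns


def parental_association(
    effect: VariantEffect,
    panel: MarkerPanel,
) -> str:
    """Which parental haplotype carries the disrupting (ALT) allele.

    Effects are computed against the reference annotation, so the
    disrupting allele of a HIGH-impact variant is the ALT allele. If the
    sequenced parent is homozygous ALT at the site, the allele rode in on
    that parent's haplotype (``other_parent`` in a design where the
    phenotype arose in the unsequenced line); if the sequenced parent is
    homozygous REF, the ALT allele must come from the unsequenced mutant
    parent (``mutant_parent``). Variants absent from the phased panel
    cannot be assigned and return ``unresolvable``.
    """
    m = np.flatnonzero((panel.chroms == effect.chrom) & (panel.positions == effect.pos))
    if m.size == 0:
        return UNRESOLVABLE
    i = int(m[0])
    if str(panel.alt[i]) != effect.alt or str(panel.ref[i]) != effect.ref:
        return UNRESOLVABLE
    return OTHER_PARENT if panel.parent_is_alt[i] else MUTANT_PARENT


@dataclass
class CandidateReport:
    """Stepwise counts and per-gene verdicts of the ruling-out logic."""

    n_cosegregating: int
    n_high_impact: int
    gene_verdicts: dict[str, str] = field(default_factory=dict)
    gene_variants: dict[str, list[dict]] = field(default_factory=dict)
    candidates: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def write_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_json())
        return path

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"# co-segregating variants\t{self.n_cosegregating}\n")
            fh.write(f"# high-impact variants\t{self.n_high_impact}\n")
            fh.write(f"# candidate genes\t{len(self.candidates)}\n")
            fh.write("gene\tverdict\tn_high_impact\tassociations\n")
            for gene, verdict in sorted(self.gene_verdicts.items()):
                var = self.gene_variants.get(gene, [])
                assoc = ",".join(v["association"] for v in var) or "."
                fh.write(f"{gene}\t{verdict}\t{len(var)}\t{assoc}\n")
        return path


def rank_candidates(
    effects: Sequence[VariantEffect],
    associations: Mapping[tuple[str, int], str] | Sequence[str],
    direction_of_change: str = MUTANT_PARENT,
) -> CandidateReport:
    """Apply the parental ruling-out logic to co-segregating variant effects.

    ``effects`` are the (per-gene worst) consequences of the co-segregating
    variants; ``associations`` gives each variant's parental association,
    either keyed by (chrom, pos) or aligned with ``effects``.
    ``direction_of_change`` names the parent in which the phenotype arose
    (the default assumes the mutant/derived line is the unsequenced one);
    genes qualify only through high-impact alleles associated with that
    parent. Input order does not affect the result.
    """
    if direction_of_change not in (MUTANT_PARENT, OTHER_PARENT):
        raise ValueError("direction_of_change must be a parent label")
    other_side = OTHER_PARENT if direction_of_change == MUTANT_PARENT else MUTANT_PARENT

    if isinstance(associations, Mapping):
        assoc_of = lambda i, e: associations.get((e.chrom, e.pos), UNRESOLVABLE)
    else:
        if len(associations) != len(effects):
            raise ValueError("associations length mismatch")
        assoc_of = lambda i, e: associations[i]

    report = CandidateReport(n_cosegregating=len(effects), n_high_impact=0)
    by_gene: dict[str, list[tuple[VariantEffect, str]]] = {}
    genes_with_variants: set[str] = set()
    for i, eff in enumerate(effects):
        if eff.gene_id != ".":
            genes_with_variants.add(eff.gene_id)
        if eff.impact != "HIGH" or eff.gene_id == ".":
            continue
        report.n_high_impact += 1
        by_gene.setdefault(eff.gene_id, []).append((eff, assoc_of(i, eff)))

    for gene in sorted(genes_with_variants - set(by_gene)):
        report.gene_verdicts[gene] = "ruled_out_no_high_impact"
    for gene in sorted(by_gene):
        pairs = by_gene[gene]
        report.gene_variants[gene] = [
            {
                "chrom": e.chrom,
                "pos": e.pos,
                "ref": e.ref,
                "alt": e.alt,
                "consequence": e.consequence,
                "association": a,
            }
            for e, a in pairs
        ]
        assoc = {a for _, a in pairs}
        if direction_of_change not in assoc:
            report.gene_verdicts[gene] = "ruled_out_other_parent"
        elif other_side in assoc:
            report.gene_verdicts[gene] = "ruled_out_both_parents_disrupted"
        else:
            report.gene_verdicts[gene] = "candidate"
            report.candidates.append(gene)
    report.candidates.sort()
    return report
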
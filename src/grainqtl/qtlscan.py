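"""Single-QTL genome scan for an F2 intercross.

The scan follows the classical interval-mapping pipeline: a hidden-Markov
model over the three F2 genotype states {AA, AB, BB} (AA = homozygous for
the sequenced parent P1) converts observed, possibly erroneous or missing,
marker calls into per-locus genotype probabilities; Haley–Knott regression
then regresses the phenotype on those probabilities at every marker and
reports a LOD score

    LOD(m) = (n/2) * log10(RSS0 / RSS1(m)),

where RSS1 is the residual sum of squares of the 2-df QTL model
(intercept + P(AB) + P(BB)) and RSS0 that of the intercept-only null.
Genome-wide significance thresholds come from phenotype-permutation tests,
and QTL location uncertainty is summarized by a LOD-drop support interval
(1.8 LOD units for an F2 by convention).

Physical positions are converted to map distance with a constant
centimorgan-per-megabase rate, and map distance to recombination fraction
with the Haldane function r = (1 - exp(-2d/100)) / 2 (d in cM).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .markers import MarkerPanel, MISSING

__all__ = [
    "GeneticMap",
    "GenotypeProbabilities",
    "LodProfile",
    "SupportInterval",
    "haldane_r",
    "build_genetic_map",
    "calc_genoprob",
    "hk_scan",
    "permutation_threshold",
    "lod_support_interval",
    "align_phenotype",
]

F2_INIT = np.array([0.25, 0.5, 0.25])


def haldane_r(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Haldane map function: recombination fraction for map distance in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


@dataclass
class GeneticMap:
    """Marker map in both physical (bp) and genetic (cM) coordinates."""

    cm_per_mb: float
    positions_bp: dict[str, np.ndarray]
    positions_cm: dict[str, np.ndarray]

    def recombination_fractions(self, chrom: str) -> np.ndarray:
        """r between adjacent markers on ``chrom`` (length n_markers - 1)."""
        d = np.diff(self.positions_cm[chrom])
        return np.asarray(haldane_r(d))


def build_genetic_map(panel: MarkerPanel, cm_per_mb: float = 4.0) -> GeneticMap:
    """Map physical marker positions to cM at a constant expansion rate."""
    if cm_per_mb <= 0:
        raise ValueError("cm_per_mb must be positive")
    bp: dict[str, np.ndarray] = {}
    cm: dict[str, np.ndarray] = {}
    for chrom in panel.chrom_names():
        idx = panel.chrom_slice(chrom)
        bp[chrom] = panel.positions[idx]
        cm[chrom] = bp[chrom] * cm_per_mb / 1e6
    return GeneticMap(cm_per_mb=cm_per_mb, positions_bp=bp, positions_cm=cm)


@dataclass
class GenotypeProbabilities:
    """Posterior P(AA), P(AB), P(BB) per individual per marker."""

    samples: list[str]
    chroms: np.ndarray
    positions: np.ndarray
    probs: np.ndarray  # (n_individuals, n_markers, 3)
    error_prob: float

    def chrom_slice(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.chroms == chrom)


def _transition(r: float) -> np.ndarray:
    """F2 genotype transition matrix between adjacent markers."""
    return np.array(
        [
            [(1 - r) ** 2, 2 * r * (1 - r), r**2],
            [r * (1 - r), (1 - r) ** 2 + r**2, r * (1 - r)],
            [r**2, 2 * r * (1 - r), (1 - r) ** 2],
        ]
    )


def _emission(obs: np.ndarray, error_prob: float) -> np.ndarray:
    """Emission weights, shape (n_ind, n_markers, 3); missing emits ones."""
    n, m = obs.shape
    e = np.full((n, m, 3), error_prob / 2.0)
    states = np.arange(3)
    match = obs[:, :, None] == states[None, None, :]
    e[match] = 1.0 - error_prob
    e[obs == MISSING] = 1.0
    return e


def calc_genoprob(
    panel: MarkerPanel,
    gmap: GeneticMap,
    error_prob: float = 1e-4,
) -> GenotypeProbabilities:
    """Forward–backward genotype probabilities per chromosome.

    Initial distribution is the F2 expectation (1/4, 1/2, 1/4); transitions
    between adjacent markers use the Haldane recombination fraction from the
    map; the emission gives the observed code probability ``1 - error_prob``
    under the matching hidden state and ``error_prob / 2`` under each of the
    other two; a missing observation is uninformative. Rows are rescaled at
    every step, so the posteriors are exact up to float precision.
    """
    if not 0.0 <= error_prob < 0.5:
        raise ValueError("error_prob must be in [0, 0.5)")
    n = panel.n_samples
    probs = np.empty((n, panel.n_markers, 3))
    for chrom in panel.chrom_names():
        idx = panel.chrom_slice(chrom)
        obs = panel.genotypes[:, idx]
        m = len(idx)
        rs = gmap.recombination_fractions(chrom)
        if np.any(rs < 0) or np.any(rs >= 0.5):
            raise ValueError("recombination fractions must lie in [0, 0.5)")
        trans = [_transition(float(r)) for r in rs]
        E = _emission(obs, error_prob)

        fwd = np.empty((n, m, 3))
        f = F2_INIT[None, :] * E[:, 0, :]
        f /= f.sum(axis=1, keepdims=True)
        fwd[:, 0, :] = f
        for t in range(1, m):
            f = (f @ trans[t - 1]) * E[:, t, :]
            f /= f.sum(axis=1, keepdims=True)
            fwd[:, t, :] = f

        b = np.ones((n, 3))
        post = np.empty((n, m, 3))
        post[:, m - 1, :] = fwd[:, m - 1, :]
        for t in range(m - 2, -1, -1):
            b = (E[:, t + 1, :] * b) @ trans[t].T
            b /= b.sum(axis=1, keepdims=True)
            p = fwd[:, t, :] * b
            post[:, t, :] = p / p.sum(axis=1, keepdims=True)
        probs[:, idx, :] = post
    return GenotypeProbabilities(
        samples=list(panel.samples),
        chroms=panel.chroms.copy(),
        positions=panel.positions.copy(),
        probs=probs,
        error_prob=error_prob,
    )


@dataclass
class SupportInterval:
    chrom: str
    start_bp: int  # 1-based inclusive
    end_bp: int
    drop: float

    def to_bed_line(self, name: str = "qtl_support") -> str:
        """0-based half-open BED line."""
        return f"{self.chrom}\t{self.start_bp - 1}\t{self.end_bp}\t{name}"


@dataclass
class LodProfile:
    """Per-marker LOD scores plus optional thresholds and support interval."""

    chroms: np.ndarray
    positions_bp: np.ndarray
    positions_cm: np.ndarray
    lod: np.ndarray
    n_individuals: int
    thresholds: dict[float, float] = field(default_factory=dict)
    support_interval: SupportInterval | None = None

    @property
    def max_index(self) -> int:
        """Index of the global maximum; ties broken leftmost (chrom, bp)."""
        best = np.flatnonzero(self.lod == self.lod.max())
        return int(best[0])  # markers already sorted by (chrom, bp)

    @property
    def max_lod(self) -> float:
        return float(self.lod[self.max_index])

    @property
    def max_chrom(self) -> str:
        return str(self.chroms[self.max_index])

    @property
    def max_pos_bp(self) -> int:
        return int(self.positions_bp[self.max_index])

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(
            {
                "chrom": self.chroms,
                "pos_bp": self.positions_bp,
                "pos_cM": self.positions_cm,
                "lod": self.lod,
            }
        ).to_csv(path, sep="\t", index=False, float_format="%.6g")
        return path

    def thresholds_json(self) -> str:
        return json.dumps(
            {f"alpha_{a:g}": t for a, t in sorted(self.thresholds.items())},
            indent=2,
        )


def _projection_bases(probs: np.ndarray) -> np.ndarray:
    """Orthonormal bases of the HK design [1, pAB, pBB] per marker.

    Returns (n_markers, n, 3) with rank-deficient directions zeroed so that
    ``||U^T y||^2`` is the projection of y onto the column space exactly.
    """
    n_ind, n_mark, _ = probs.shape
    X = np.empty((n_mark, n_ind, 3))
    X[:, :, 0] = 1.0
    X[:, :, 1] = probs[:, :, 1].T
    X[:, :, 2] = probs[:, :, 2].T
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    tol = s[:, :1] * max(n_ind, 3) * np.finfo(float).eps
    U = U * (s > tol)[:, None, :]
    return U


def _lod_from_projection(U: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """LOD for each marker (rows) and each phenotype column of Y."""
    n = Y.shape[0]
    yty = np.sum(Y**2, axis=0)  # (p,)
    ybar = Y.mean(axis=0)
    rss0 = yty - n * ybar**2  # (p,)
    proj = np.einsum("mnk,np->mkp", U, Y)  # (m, 3, p)
    rss1 = yty[None, :] - np.sum(proj**2, axis=1)  # (m, p)
    tiny = np.finfo(float).tiny
    rss1 = np.maximum(rss1, tiny)
    with np.errstate(divide="ignore", invalid="ignore"):
        lod = 0.5 * n * np.log10(np.maximum(rss0[None, :], tiny) / rss1)
    lod[:, rss0 <= n * np.finfo(float).eps * np.maximum(yty, 1.0)] = 0.0
    return np.maximum(lod, 0.0)


def align_phenotype(
    samples: Sequence[str],
    phenotypes: pd.DataFrame,
    column: str = "length_mm",
) -> np.ndarray:
    """Phenotype vector aligned to ``samples``; absent samples become NaN."""
    lookup = phenotypes.set_index("sample_id")[column]
    return np.array([float(lookup.get(s, np.nan)) for s in samples])


def hk_scan(
    genoprob: GenotypeProbabilities,
    phenotype: np.ndarray | Sequence[float],
    gmap: GeneticMap | None = None,
) -> LodProfile:
    """Haley–Knott regression scan over all markers.

    Individuals with a missing (NaN) phenotype are dropped listwise.
    A phenotype without variance yields an all-zero profile (degenerate
    null, logged as a warning).
    """
    y = np.asarray(phenotype, dtype=float)
    if y.shape[0] != len(genoprob.samples):
        raise ValueError("phenotype length does not match individuals")
    keep = ~np.isnan(y)
    y = y[keep]
    if y.size < 3:
        raise ValueError("need at least 3 phenotyped individuals")
    if np.var(y) == 0:
        warnings.warn("phenotype has zero variance; LOD profile is all zero")
    U = _projection_bases(genoprob.probs[keep])
    lod = _lod_from_projection(U, y[:, None])[:, 0]
    if gmap is not None:
        cm = np.concatenate([gmap.positions_cm[c] for c in gmap.positions_cm])
    else:
        cm = np.full(len(genoprob.positions), np.nan)
    return LodProfile(
        chroms=genoprob.chroms.copy(),
        positions_bp=genoprob.positions.copy(),
        positions_cm=cm,
        lod=lod,
        n_individuals=int(y.size),
    )


def permutation_threshold(
    genoprob: GenotypeProbabilities,
    phenotype: np.ndarray | Sequence[float],
    n_perm: int = 1000,
    alphas: Sequence[float] = (0.05, 0.01),
    seed: int | None = None,
) -> dict[float, float]:
    """Genome-wide LOD thresholds by phenotype permutation.

    Phenotype labels are shuffled against individuals (genotypes fixed),
    the scan re-run, and the genome-wide maximum LOD recorded for each of
    ``n_perm`` permutations; the threshold at level alpha is the empirical
    (1 - alpha) quantile of those maxima (linear interpolation, matching
    R's default quantile definition). Missing phenotypes are excluded
    before permuting. Seeded and reproducible.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    if min(alphas) > 0 and n_perm < 1.0 / min(alphas):
        warnings.warn(
            f"n_perm = {n_perm} is small for alpha = {min(alphas):g}; "
            "the quantile estimate will be unstable"
        )
    y = np.asarray(phenotype, dtype=float)
    keep = ~np.isnan(y)
    y = y[keep]
    rng = np.random.default_rng(seed)
    Y = np.empty((y.size, n_perm))
    for p in range(n_perm):
        Y[:, p] = rng.permutation(y)
    U = _projection_bases(genoprob.probs[keep])
    lod = _lod_from_projection(U, Y)  # (m, n_perm)
    maxima = lod.max(axis=0)
    return {float(a): float(np.quantile(maxima, 1.0 - a)) for a in alphas}


def lod_support_interval(profile: LodProfile, drop: float = 1.8) -> SupportInterval:
    """LOD-drop support interval on the peak chromosome.

    Starting at the global maximum, walk outward while the LOD stays within
    ``drop`` units of the maximum; the first marker below the cutoff ends
    the walk. Each side is then extended by one flanking marker when one
    exists (the usual interval-mapping convention, so the interval brackets
    rather than clips the region of high support).
    """
    if profile.lod.size == 0:
        raise ValueError("empty LOD profile")
    peak = profile.max_index
    chrom = str(profile.chroms[peak])
    on_chrom = np.flatnonzero(profile.chroms == chrom)
    cutoff = profile.max_lod - drop
    pos_in_chrom = int(np.flatnonzero(on_chrom == peak)[0])

    left = pos_in_chrom
    while left > 0 and profile.lod[on_chrom[left - 1]] >= cutoff:
        left -= 1
    if left > 0:
        left -= 1  # flanking marker
    right = pos_in_chrom
    last = len(on_chrom) - 1
    while right < last and profile.lod[on_chrom[right + 1]] >= cutoff:
        right += 1
    if right < last:
        right += 1  # flanking marker
    interval = SupportInterval(
        chrom=chrom,
        start_bp=int(profile.positions_bp[on_chrom[left]]),
        end_bp=int(profile.positions_bp[on_chrom[right]]),
        drop=float(drop),
    )
    profile.support_interval = interval
    return interval
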
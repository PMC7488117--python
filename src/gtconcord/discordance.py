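"""Localizing discordance across the genome.

Three views of where the two platforms disagree: per-chromosome
discordant-call fractions, neighbor-distance pairs (the distance to the
previous and next variant of the same concordance group, whose log-log
density concentrates on the diagonal when variants are evenly spread),
and a greedy sliding-window selection of compact regions (<= one Sanger
read, 500 bp by default) packing as many discordant variants as possible
for downstream validation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .callset_io import PairedCall, Site, VarClass, _chrom_rank

__all__ = [
    "Group",
    "ChromDiscordance",
    "DiscordanceSummary",
    "DistancePair",
    "ValidationRegion",
    "KdeMap",
    "per_chromosome_discordance",
    "mean_discordance_pct",
    "neighbor_distance_pairs",
    "kde_density",
    "bisectrix_deviation",
    "select_validation_regions",
    "regions_to_bed",
    "regions_to_table",
]


class Group(enum.Enum):
    CONCORDANT = "CONCORDANT"
    DISCORDANT = "DISCORDANT"


@dataclass(frozen=True)
class ChromDiscordance:
    chrom: str
    n_pairs: int
    n_discordant: int

    @property
    def pct_discordant(self) -> float:
        return 100.0 * self.n_discordant / self.n_pairs


@dataclass(frozen=True)
class DiscordanceSummary:
    """Per-chromosome table plus the genome-wide (pooled) fraction."""

    per_chrom: tuple[ChromDiscordance, ...]
    n_pairs: int
    n_discordant: int

    @property
    def pct_discordant(self) -> float:
        return 100.0 * self.n_discordant / self.n_pairs if self.n_pairs else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.chrom, c.n_pairs, c.n_discordant, c.pct_discordant)
             for c in self.per_chrom],
            columns=["chrom", "n_pairs", "n_discordant", "pct_discordant"],
        )


def per_chromosome_discordance(paired: Iterable[PairedCall]) -> DiscordanceSummary:
    """Fraction of discordant calls per chromosome and genome-wide."""
    n: dict[str, int] = {}
    d: dict[str, int] = {}
    for p in paired:
        c = p.site.chrom
        n[c] = n.get(c, 0) + 1
        if not p.concordant:
            d[c] = d.get(c, 0) + 1
    chroms = sorted(n, key=_chrom_rank)
    per = tuple(ChromDiscordance(c, n[c], d.get(c, 0)) for c in chroms)
    return DiscordanceSummary(per, sum(n.values()), sum(d.values()))


def mean_discordance_pct(sample_pcts: Sequence[float]) -> float:
    """Average the genome-wide discordance percentages across samples."""
    if not sample_pcts:
        raise ValueError("no sample fractions supplied")
    return float(np.mean(sample_pcts))


# ---------------------------------------------------------------------------
# Neighbor-distance pairs and their density map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistancePair:
    """Distances from one variant to its previous and next group neighbor."""

    pos: int
    d_prev: int
    d_next: int
    group: Group


def neighbor_distance_pairs(
    positions: Sequence[int], group: Group = Group.CONCORDANT
) -> list[DistancePair]:
    """(d_prev, d_next) for each interior variant of one group on one chromosome.

    Positions must be strictly increasing; the first and last variant have
    no pair, so fewer than three positions yield an empty list.
    """
    pos = list(positions)
    if any(b <= a for a, b in zip(pos, pos[1:])):
        raise ValueError("positions must be strictly increasing")
    if len(pos) < 3:
        return []
    return [
        DistancePair(pos[i], pos[i] - pos[i - 1], pos[i + 1] - pos[i], group)
        for i in range(1, len(pos) - 1)
    ]


@dataclass(frozen=True)
class KdeMap:
    """Gaussian-kernel density of (d_prev, d_next) pairs on a log10-log10 grid."""

    log10_dprev: np.ndarray  # grid axis, shape (nx,)
    log10_dnext: np.ndarray  # grid axis, shape (ny,)
    density: np.ndarray      # shape (nx, ny), density in log10 space

    @property
    def grid_integral(self) -> float:
        return float(np.trapezoid(np.trapezoid(self.density, self.log10_dnext, axis=1),
                                  self.log10_dprev))

    def mode(self) -> tuple[float, float]:
        i, j = np.unravel_index(np.argmax(self.density), self.density.shape)
        return float(self.log10_dprev[i]), float(self.log10_dnext[j])


def kde_density(
    points: Sequence[tuple[float, float]] | np.ndarray,
    gridsize: int = 100,
    bw_method: str | float = "scott",
    pad: float = 0.75,
) -> KdeMap:
    """Gaussian KDE of distance pairs on a log-log grid (Scott's rule bandwidth).

    The grid extends ``pad`` log10 units beyond the data range so that the
    estimated density integrates to ~1 on the grid.  Fewer than two points
    is an error.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("need at least 2 (d_prev, d_next) points")
    if (pts <= 0).any():
        raise ValueError("distances must be positive")
    logpts = np.log10(pts)
    # a degenerate (single-point) cloud has no spread for the KDE bandwidth;
    # jitter below grid resolution keeps the estimate well defined
    if np.allclose(logpts.std(axis=0), 0):
        rng = np.random.default_rng(0)
        logpts = logpts + rng.normal(0, 1e-3, size=logpts.shape)
    kde = gaussian_kde(logpts.T, bw_method=bw_method)
    x = np.linspace(logpts[:, 0].min() - pad, logpts[:, 0].max() + pad, gridsize)
    y = np.linspace(logpts[:, 1].min() - pad, logpts[:, 1].max() + pad, gridsize)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    dens = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
    return KdeMap(x, y, dens)


def bisectrix_deviation(points: Sequence[tuple[float, float]] | np.ndarray) -> float:
    """Mean |log10 d_prev - log10 d_next|: 0 for perfectly even spacing.

    A simple summary of how far the distance-pair cloud sits from the
    diagonal of the log-log map.
    """
    pts = np.asarray(points, dtype=float)
    return float(np.abs(np.log10(pts[:, 0]) - np.log10(pts[:, 1])).mean())


# ---------------------------------------------------------------------------
# Sliding-window region selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationRegion:
    """A compact span of discordant variants chosen for Sanger validation.

    ``start``/``end`` are the tight (1-based, closed) span of the region's
    discordant sites; nearby concordant sites are attached for context.
    """

    chrom: str
    start: int
    end: int
    discordant_sites: tuple[Site, ...]
    concordant_sites: tuple[Site, ...] = ()

    @property
    def n_snv(self) -> int:
        return sum(s.var_class is VarClass.SNV for s in self.discordant_sites)

    @property
    def n_indel(self) -> int:
        return sum(s.var_class is VarClass.INDEL for s in self.discordant_sites)

    @property
    def n_total(self) -> int:
        return len(self.discordant_sites)


def select_validation_regions(
    discordant: Sequence[Site],
    concordant: Sequence[Site] = (),
    max_span: int = 500,
    pad: int = 0,
) -> list[ValidationRegion]:
    """Greedy maximal cover of discordant sites by windows of span <= max_span.

    Repeatedly picks the window containing the most not-yet-covered
    discordant sites (ties broken by leftmost window), emits the tight
    span of those sites as a region, and marks them covered.  Concordant
    sites within ``pad`` bp of a region's span are attached (the printed
    validation windows of the study include primer-design padding, which
    is kept separate from the <= max_span constraint on discordant span).
    """
    by_chrom: dict[str, list[Site]] = {}
    for s in discordant:
        by_chrom.setdefault(s.chrom, []).append(s)
    conc_by_chrom: dict[str, list[Site]] = {}
    for s in concordant:
        conc_by_chrom.setdefault(s.chrom, []).append(s)

    regions: list[ValidationRegion] = []
    for chrom in sorted(by_chrom, key=_chrom_rank):
        sites = sorted(by_chrom[chrom], key=lambda s: s.pos)
        conc = sorted(conc_by_chrom.get(chrom, ()), key=lambda s: s.pos)
        uncovered = list(sites)
        while uncovered:
            pos = [s.pos for s in uncovered]
            # candidate windows anchored at each uncovered site
            best_i, best_count = 0, 0
            j = 0
            for i, p in enumerate(pos):
                while j < len(pos) and pos[j] <= p + max_span:
                    j += 1
                count = j - i
                if count > best_count:  # strict: ties keep the leftmost anchor
                    best_i, best_count = i, count
                j = max(j, i)
            chosen = [s for s in uncovered
                      if pos[best_i] <= s.pos <= pos[best_i] + max_span]
            start, end = chosen[0].pos, chosen[-1].pos
            attached = tuple(s for s in conc if start - pad <= s.pos <= end + pad)
            regions.append(ValidationRegion(chrom, start, end, tuple(chosen), attached))
            uncovered = [s for s in uncovered if s not in chosen]
    regions.sort(key=lambda r: (_chrom_rank(r.chrom), r.start))
    return regions


def regions_to_bed(regions: Iterable[ValidationRegion], path: str | Path) -> None:
    """Write regions as BED (0-based half-open, converted from 1-based closed)."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions, 1):
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\tregion_{i}\t{r.n_total}\n")


def regions_to_table(regions: Iterable[ValidationRegion], path: str | Path) -> None:
    """Write regions as a TSV with the validation-table column layout."""
    rows = [
        (r.chrom, r.start, r.end, r.n_indel, r.n_snv, r.n_total)
        for r in regions
    ]
    pd.DataFrame(
        rows, columns=["Chromosome", "Start", "End", "INDELs", "SNVs", "Total"]
    ).to_csv(path, sep="\t", index=False)
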
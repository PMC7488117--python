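"""Synthetic paired call sets with the statistical structure the analysis assumes.

The study's raw call sets are not public, so this module generates a
stand-in: diploid genotypes drawn under Hardy-Weinberg equilibrium at
SNV and indel sites (with a small fraction of triallelic SNVs), observed
through two independent platform-specific miscall processes, plus
BeadChip-style intensity records in which discordant calls can be
enriched near the Theta cluster borders.  With the default error rates
(0.002 and 0.004) the expected pairwise discordance is ~0.6%, inside the
0.33-0.84% per-sample range the analysis is built around.

Simulation starts at genotype calls (no reads); files are written in the
exact dialects :mod:`gtconcord.callset_io` reads, so a write/read round
trip reproduces every genotype and annotation.

All randomness flows from ``SimulationConfig.seed`` through
``numpy.random.SeedSequence`` children (streams 0-3: truth, platform A,
platform B, intensities/annotations), so one seed fixes every downstream
number in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy.stats import truncnorm

from .callset_io import (
    BeadChipRecord,
    GenotypeCall,
    Platform,
    Site,
    VarClass,
    WgsCallAnnotations,
    indel_symbol_map,
    BEADCHIP_COLUMNS,
    _chrom_rank,
)

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "SimulatedDataset",
    "simulate_truth",
    "simulate_platform_calls",
    "simulate_beadchip_intensities",
    "simulate_wgs_annotations",
    "simulate_dataset",
    "write_vcf",
    "write_beadchip_report",
    "write_truth_table",
]

_BASES = "ACGT"

#: GRCh38 autosome lengths (bp); the default simulated genome.
GRCH38_AUTOSOMES: dict[str, int] = {
    "1": 248956422, "2": 242193529, "3": 198295559, "4": 190214555,
    "5": 181538259, "6": 170805979, "7": 159345973, "8": 145138636,
    "9": 138394717, "10": 133797422, "11": 135086622, "12": 133275309,
    "13": 114364328, "14": 107043718, "15": 101991189, "16": 90338345,
    "17": 83257441, "18": 80373285, "19": 58617616, "20": 64444167,
    "21": 46709983, "22": 50818468,
}

_PAIRS_BI = [(0, 0), (0, 1), (1, 1)]
_PAIRS_TRI = [(0, 0), (0, 1), (1, 1), (0, 2), (1, 2), (2, 2)]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated sample pair.

    Defaults emulate the regime the analysis operates in: ~1e5 markers
    (a desk-scale stand-in for a genotyping array), minor-allele
    frequencies uniform on [0.05, 0.5], a few percent indels, a trace of
    triallelic SNVs, and per-platform miscall rates whose sum lands the
    pairwise discordance near 0.6%.
    """

    n_sites: int = 100_000
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: dict(GRCH38_AUTOSOMES)
    )
    maf_range: tuple[float, float] = (0.05, 0.5)
    frac_indel: float = 0.04
    frac_triallelic: float = 0.002
    error_rate_a: float = 0.002  # WGS-like platform
    error_rate_b: float = 0.004  # BeadChip-like platform
    border_enrichment: bool = True
    theta_sd: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_indel", "frac_triallelic"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("error_rate_a", "error_rate_b"):
            v = getattr(self, name)
            if not 0 <= v <= 0.5:
                raise ValueError(f"{name} must be in [0,0.5], got {v}")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")

    def child_seed(self, stream: int) -> int:
        """Deterministic sub-seed for one named random stream."""
        return int(np.random.SeedSequence([self.seed, stream]).generate_state(1)[0]
                   % (2**31))


@dataclass(frozen=True)
class TruthRecord:
    """The latent genotype at one simulated site."""

    site: Site
    allele_indices: tuple[int, int]  # sorted indices into site.alleles

    @property
    def genotype(self) -> tuple[str, str]:
        a = self.site.alleles
        i, j = self.allele_indices
        return tuple(sorted((a[i], a[j])))  # type: ignore[return-value]


def _unique_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """n distinct 1-based positions, uniform on [1, length], sorted."""
    if n > length:
        raise ValueError(f"cannot place {n} sites on a {length} bp chromosome")
    pos: np.ndarray = np.unique(rng.integers(1, length + 1, size=int(n * 1.05) + 16))
    while len(pos) < n:
        extra = rng.integers(1, length + 1, size=n)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(rng.choice(pos, size=n, replace=False))


def _random_tail(rng: np.random.Generator) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=rng.integers(1, 4)))


def simulate_truth(cfg: SimulationConfig) -> list[TruthRecord]:
    """Draw sites and Hardy-Weinberg genotypes for one individual.

    Site positions are uniform without replacement per chromosome (counts
    proportional to chromosome length); each site's genotype is two
    independent draws from its allele frequencies.
    """
    rng = np.random.default_rng(cfg.child_seed(0))
    chroms = sorted(cfg.chrom_lengths, key=_chrom_rank)
    lengths = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    if cfg.n_sites > lengths.sum():
        raise ValueError("n_sites exceeds the total simulated genome length")
    counts = rng.multinomial(cfg.n_sites, lengths / lengths.sum())

    records: list[TruthRecord] = []
    marker = 0
    for chrom, cnt in zip(chroms, counts):
        if cnt == 0:
            continue
        positions = _unique_positions(rng, cfg.chrom_lengths[chrom], cnt)
        is_indel = rng.random(cnt) < cfg.frac_indel
        is_tri = ~is_indel & (rng.random(cnt) < cfg.frac_triallelic)
        ref_idx = rng.integers(0, 4, cnt)
        alt_off = rng.integers(1, 4, cnt)
        maf = rng.uniform(*cfg.maf_range, cnt)
        u_gt = rng.random((cnt, 2))
        is_ins = rng.random(cnt) < 0.5
        for i in range(cnt):
            marker += 1
            base = _BASES[ref_idx[i]]
            if is_indel[i]:
                tail = _random_tail(rng)
                ref, alts = (base, (base + tail,)) if is_ins[i] else (base + tail, (base,))
                freqs = np.array([1 - maf[i], maf[i]])
            elif is_tri[i]:
                alt1 = _BASES[(ref_idx[i] + alt_off[i]) % 4]
                rest = [b for b in _BASES if b not in (base, alt1)]
                alt2 = rest[int(rng.integers(0, len(rest)))]
                ref, alts = base, (alt1, alt2)
                p_c = maf[i] / 2
                freqs = np.array([1 - maf[i] - p_c, maf[i], p_c])
            else:
                ref, alts = base, (_BASES[(ref_idx[i] + alt_off[i]) % 4],)
                freqs = np.array([1 - maf[i], maf[i]])
            cdf = np.cumsum(freqs)
            pair = tuple(sorted(int(np.searchsorted(cdf, u)) for u in u_gt[i]))
            site = Site(chrom, int(positions[i]), f"sim{marker:07d}", ref, alts)
            records.append(TruthRecord(site, pair))  # type: ignore[arg-type]
    return records


def simulate_platform_calls(
    truth: Sequence[TruthRecord],
    error_rate: float,
    seed: int,
    platform: Platform = Platform.WGS,
) -> list[GenotypeCall]:
    """Observe the truth through a genotype-class-uniform miscall process.

    Each call equals the truth with probability 1 - error_rate and is
    otherwise a uniformly chosen *different* genotype class from the
    site's class set (3 classes at biallelic sites, 6 at triallelic), so
    every confusion-matrix cell is reachable.  Calls are independent
    across platforms given the truth.
    """
    if not 0 <= error_rate <= 0.5:
        raise ValueError(f"error_rate must be in [0,0.5], got {error_rate}")
    rng = np.random.default_rng(seed)
    n = len(truth)
    is_err = rng.random(n) < error_rate
    j2 = rng.integers(0, 2, n)  # biallelic: one of the 2 other classes
    j5 = rng.integers(0, 5, n)  # triallelic: one of the 5 other classes
    out: list[GenotypeCall] = []
    for i, rec in enumerate(truth):
        pairs = _PAIRS_TRI if len(rec.site.alleles) == 3 else _PAIRS_BI
        idx = pairs.index(rec.allele_indices)
        if is_err[i]:
            j = int(j5[i] if len(pairs) == 6 else j2[i])
            idx = j if j < idx else j + 1
        a = rec.site.alleles
        pair = pairs[idx]
        out.append(GenotypeCall(rec.site, (a[pair[0]], a[pair[1]]), platform))
    return out


def simulate_wgs_annotations(
    calls: Sequence[GenotypeCall], seed: int, mean_depth: float = 28.0
) -> list[WgsCallAnnotations]:
    """Plausible DP/QUAL/GQ/RGQ annotations for a simulated WGS call set.

    Depth is Poisson around ``mean_depth`` (the study's coverage regime);
    Phred-scaled qualities scale with depth and are capped at 99.
    Hom-ref calls carry RGQ, variant calls GQ.  Values are integral so
    that a VCF write/read round trip is exact.
    """
    rng = np.random.default_rng(seed)
    dp = rng.poisson(mean_depth, len(calls))
    out: list[WgsCallAnnotations] = []
    for call, d in zip(calls, dp):
        d = int(d)
        q = float(min(99 * 3, round(d * 1.5)))
        phred = int(min(99, 3 * d))
        hom_ref = call.alleles == (call.site.ref, call.site.ref)
        out.append(WgsCallAnnotations(
            site=call.site,
            dp=d,
            qual=q,
            gq=None if hom_ref else phred,
            rgq=phred if hom_ref else None,
        ))
    return out


def simulate_beadchip_intensities(
    calls: Sequence[GenotypeCall],
    discordant_flags: Sequence[bool],
    cfg: SimulationConfig,
) -> list[BeadChipRecord]:
    """Theta/R intensity records consistent with the calls' genotype clusters.

    Theta is a truncated Gaussian (sd ``cfg.theta_sd``) around the called
    class's canonical center (0, 0.5 or 1 for 0, 1 or 2 non-reference
    alleles).  With ``border_enrichment`` on, flagged discordant calls
    have their Theta mean shifted halfway toward the nearest cluster
    border (0.25 / 0.75), reproducing the near-border excess of
    discordant array calls.  GC score decreases deterministically with
    the distance from the cluster center; R is log-normal; B allele
    frequency is Theta interpolated against the canonical centers.  All
    values are quantized to 4 decimals, the report's printed precision.
    """
    if len(calls) != len(discordant_flags):
        raise ValueError("discordant_flags must align with calls")
    rng = np.random.default_rng(cfg.child_seed(3))
    n = len(calls)
    n_nonref = np.array(
        [sum(a != c.site.ref for a in c.alleles) for c in calls], dtype=float
    )
    centers = n_nonref / 2.0
    means = centers.copy()
    if cfg.border_enrichment:
        flagged = np.asarray(discordant_flags, dtype=bool)
        side = rng.random(n) < 0.5  # which border a het shifts toward
        target = np.where(centers == 0.0, 0.25,
                          np.where(centers == 1.0, 0.75,
                                   np.where(side, 0.25, 0.75)))
        means[flagged] = (means[flagged] + target[flagged]) / 2.0
    a = (0.0 - means) / cfg.theta_sd
    b = (1.0 - means) / cfg.theta_sd
    theta = truncnorm.rvs(a, b, loc=means, scale=cfg.theta_sd,
                          size=n, random_state=rng)
    dist = np.abs(theta - centers)
    gc = np.clip(0.92 - 1.2 * dist, 0.0, 1.0)
    gt_score = rng.uniform(0.70, 0.95, n)
    cluster_sep = rng.uniform(0.3, 1.0, n)
    r = rng.lognormal(0.0, 0.25, n)
    with np.errstate(over="ignore"):
        t = np.tan(np.pi / 2 * theta)
    x = np.where(np.isfinite(t), r / (1 + t), 0.0)
    y = r - x
    baf = np.clip(theta, 0.0, 1.0)

    q = lambda arr: np.round(arr, 4)
    theta, gc, gt_score, cluster_sep, r, x, y, baf = map(
        q, (theta, gc, gt_score, cluster_sep, r, x, y, baf)
    )
    return [
        BeadChipRecord(
            site=c.site, gc_score=float(gc[i]), gt_score=float(gt_score[i]),
            cluster_sep=float(cluster_sep[i]), theta=float(theta[i]),
            r=float(r[i]), x=float(x[i]), y=float(y[i]),
            b_allele_freq=float(baf[i]),
        )
        for i, c in enumerate(calls)
    ]


@dataclass(frozen=True)
class SimulatedDataset:
    """Everything one simulated sample pair produces."""

    config: SimulationConfig
    truth: tuple[TruthRecord, ...]
    wgs_calls: tuple[GenotypeCall, ...]
    beadchip_calls: tuple[GenotypeCall, ...]
    wgs_annotations: tuple[WgsCallAnnotations, ...]
    beadchip_records: tuple[BeadChipRecord, ...]

    @property
    def discordant_flags(self) -> tuple[bool, ...]:
        return tuple(
            w.alleles != b.alleles
            for w, b in zip(self.wgs_calls, self.beadchip_calls)
        )


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Run the full generator: truth, two platform call sets, annotations."""
    truth = simulate_truth(cfg)
    wgs = simulate_platform_calls(truth, cfg.error_rate_a, cfg.child_seed(1),
                                  Platform.WGS)
    bead = simulate_platform_calls(truth, cfg.error_rate_b, cfg.child_seed(2),
                                   Platform.BEADCHIP)
    ann = simulate_wgs_annotations(wgs, cfg.child_seed(4))
    flags = [w.alleles != b.alleles for w, b in zip(wgs, bead)]
    recs = simulate_beadchip_intensities(bead, flags, cfg)
    return SimulatedDataset(cfg, tuple(truth), tuple(wgs), tuple(bead),
                            tuple(ann), tuple(recs))


# ---------------------------------------------------------------------------
# File output (dialects matched to callset_io readers)
# ---------------------------------------------------------------------------

def write_vcf(
    calls: Sequence[GenotypeCall],
    annotations: Sequence[WgsCallAnnotations],
    path: str | Path,
    sample_name: str = "synthetic_sample",
    chrom_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write a single-sample VCF 4.x with GT/DP/GQ/RGQ and site QUAL."""
    header = pysam.VariantHeader()
    chroms: dict[str, int] = dict(chrom_lengths or {})
    for c in calls:
        chroms.setdefault(c.site.chrom, 0)
        chroms[c.site.chrom] = max(chroms[c.site.chrom], c.site.pos + 1000)
    for chrom in sorted(chroms, key=_chrom_rank):
        header.contigs.add(chrom, length=chroms[chrom])
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQ", 1, "Integer", "Conditional genotype quality")
    header.formats.add("RGQ", 1, "Integer", "Reference genotype confidence")
    header.add_sample(sample_name)

    ann_by_site = {(a.site.chrom, a.site.pos): a for a in annotations}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for call in sorted(calls, key=lambda c: (_chrom_rank(c.site.chrom), c.site.pos)):
            site = call.site
            rec = vcf.new_record(
                contig=site.chrom, start=site.pos - 1,
                alleles=(site.ref,) + site.alts if site.alts else (site.ref,),
                id=site.id,
            )
            rec.filter.add("PASS")
            ann = ann_by_site.get((site.chrom, site.pos))
            if ann is not None and ann.qual is not None:
                rec.qual = ann.qual
            sample = rec.samples[sample_name]
            if call.missing:
                sample["GT"] = (None, None)
            else:
                allele_index = {a: i for i, a in enumerate(site.alleles)}
                sample["GT"] = tuple(allele_index[a] for a in call.alleles)
            if ann is not None:
                if ann.dp is not None:
                    sample["DP"] = ann.dp
                if ann.gq is not None:
                    sample["GQ"] = ann.gq
                if ann.rgq is not None:
                    sample["RGQ"] = ann.rgq
            vcf.write(rec)


def _beadchip_allele(call: GenotypeCall, idx: int) -> str:
    if call.missing:
        return "-"
    allele = call.alleles[idx]
    if call.site.var_class is VarClass.INDEL and allele not in ("I", "D"):
        return indel_symbol_map(call.site)[allele]
    return allele


def write_beadchip_report(
    calls: Sequence[GenotypeCall],
    records: Sequence[BeadChipRecord],
    path: str | Path,
) -> None:
    """Write a GenomeStudio-style final report ([Header] + [Data] blocks)."""
    if len(calls) != len(records):
        raise ValueError("calls and records must align")
    lines = [
        "[Header]",
        "GSGT Version\t2.0.4",
        "Processing Date\t2026-01-01",
        "Content\tsynthetic final report",
        f"Num SNPs\t{len(calls)}",
        "Num Samples\t1",
        "[Data]",
        "\t".join(BEADCHIP_COLUMNS),
    ]
    for call, rec in zip(calls, records):
        site = call.site
        lines.append("\t".join([
            site.id, site.chrom, str(site.pos),
            _beadchip_allele(call, 0) if not call.missing else "-",
            _beadchip_allele(call, 1) if not call.missing else "-",
            f"{rec.gc_score:.4f}", f"{rec.gt_score:.4f}",
            f"{rec.cluster_sep:.4f}", f"{rec.theta:.4f}", f"{rec.r:.4f}",
            f"{rec.x:.4f}", f"{rec.y:.4f}", f"{rec.b_allele_freq:.4f}",
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_truth_table(truth: Sequence[TruthRecord], path: str | Path) -> None:
    rows = [
        (t.site.chrom, t.site.pos, t.site.id, t.site.ref, ",".join(t.site.alts),
         "/".join(t.genotype))
        for t in truth
    ]
    pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alts", "genotype"]
                 ).to_csv(path, sep="\t", index=False)
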
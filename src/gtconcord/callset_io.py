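"""Reading, normalizing and pairing platform call sets.

A BeadChip final report and a single-sample WGS VCF describe the same
individual with different vocabularies: the array reports plus-strand
allele letters (or I/D symbols at indels) with no notion of a reference
allele, while the VCF anchors every call to REF/ALT sequences.  This
module reads both, reconciles alleles site by site, and emits
:class:`PairedCall` records — the atom every downstream concordance
computation consumes.

Genotype classes follow the A/B/C labeling convention: A is the
reference allele, B the first alternative, C the second, giving six
diploid classes (A/A, A/B, B/B, A/C, B/C, C/C) plus MISSING for
no-calls.  MISSING never enters a confusion matrix.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

__all__ = [
    "VarClass",
    "Platform",
    "GenotypeClass",
    "Site",
    "GenotypeCall",
    "PairedCall",
    "BeadChipRecord",
    "WgsCallAnnotations",
    "HarmonizeReport",
    "read_wgs_vcf",
    "read_beadchip_report",
    "harmonize_pair",
    "assign_genotype_class",
    "reverse_complement",
    "BEADCHIP_COLUMNS",
]


class VarClass(enum.Enum):
    SNV = "SNV"
    INDEL = "INDEL"


class Platform(enum.Enum):
    BEADCHIP = "BEADCHIP"
    WGS = "WGS"
    SANGER = "SANGER"


class GenotypeClass(enum.Enum):
    """Diploid genotype class over reference (A) and alternative (B, C) alleles."""

    AA = "AA"
    AB = "AB"
    BB = "BB"
    AC = "AC"
    BC = "BC"
    CC = "CC"
    MISSING = "MISSING"


#: The six classes admitted into confusion matrices, in canonical order.
CONFUSION_CLASSES: tuple[GenotypeClass, ...] = (
    GenotypeClass.AA,
    GenotypeClass.AB,
    GenotypeClass.BB,
    GenotypeClass.AC,
    GenotypeClass.BC,
    GenotypeClass.CC,
)

_PAIR_TO_CLASS: dict[tuple[int, int], GenotypeClass] = {
    (0, 0): GenotypeClass.AA,
    (0, 1): GenotypeClass.AB,
    (1, 1): GenotypeClass.BB,
    (0, 2): GenotypeClass.AC,
    (1, 2): GenotypeClass.BC,
    (2, 2): GenotypeClass.CC,
}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    """Reverse-complement a nucleotide sequence; I/D indel symbols pass through."""
    if seq in ("I", "D"):
        return seq
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Site:
    """One genomic site (1-based, point position).

    ``ref``/``alts`` follow the VCF record where one is available; array-only
    sites, whose report carries no reference allele, use ``ref="N"`` with no
    alts and are resolved during harmonization.
    """

    chrom: str
    pos: int
    id: str
    ref: str
    alts: tuple[str, ...] = ()
    var_class: VarClass | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.var_class is None:
            object.__setattr__(self, "var_class", infer_var_class(self.ref, self.alts))

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref,) + self.alts


def infer_var_class(ref: str, alts: Sequence[str]) -> VarClass:
    """INDEL iff any allele length differs from the reference length.

    Array-side I/D symbols are indel alleles by definition.
    """
    if ref in ("I", "D") or any(a in ("I", "D") for a in alts):
        return VarClass.INDEL
    if any(len(a) != len(ref) for a in alts):
        return VarClass.INDEL
    return VarClass.SNV


@dataclass(frozen=True)
class GenotypeCall:
    """An unordered diploid allele pair from one platform at one site."""

    site: Site
    alleles: tuple[str, ...]
    platform: Platform
    missing: bool = False

    def __post_init__(self) -> None:
        if self.missing and self.alleles:
            raise ValueError("missing call must carry no alleles")
        object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))

    def same_genotype(self, other: "GenotypeCall") -> bool:
        if self.missing or other.missing:
            return False
        return self.alleles == other.alleles


@dataclass(frozen=True)
class BeadChipRecord:
    """Array-side quality and intensity metrics for one marker."""

    site: Site
    gc_score: float
    gt_score: float
    cluster_sep: float
    theta: float
    r: float
    x: float
    y: float
    b_allele_freq: float


@dataclass(frozen=True)
class WgsCallAnnotations:
    """Sequencing-side quality annotations for one VCF record.

    ``gq`` is the conditional genotype quality at variant sites; ``rgq``
    the reference-genotype confidence emitted at non-variant sites.  At
    most one of the two is absent.
    """

    site: Site
    dp: int | None = None
    qual: float | None = None
    gq: int | None = None
    rgq: int | None = None


@dataclass(frozen=True)
class PairedCall:
    """A site genotyped on both platforms, with harmonized class labels."""

    site: Site
    call_truth: GenotypeCall
    call_test: GenotypeCall
    class_truth: GenotypeClass
    class_test: GenotypeClass

    @property
    def concordant(self) -> bool:
        return (
            self.class_truth == self.class_test
            and self.class_truth is not GenotypeClass.MISSING
        )


def assign_genotype_class(site: Site, call: GenotypeCall) -> GenotypeClass:
    """Map a reconciled call onto the six-class A/B/C labeling of ``site``.

    A = reference allele, B = first alternative, C = second alternative.
    Indel-site calls are compared through I/D symbols (I = the longer
    allele of the site's pair, D = the shorter).
    """
    if call.missing:
        return GenotypeClass.MISSING
    if site.var_class is VarClass.INDEL:
        symbols = indel_symbol_map(site)
        universe = [symbols[a] for a in site.alleles]
        alleles = [a if a in ("I", "D") else symbols.get(a) for a in call.alleles]
        if any(a is None for a in alleles):
            raise ValueError(
                f"allele not mappable to I/D at {site.chrom}:{site.pos}: {call.alleles}"
            )
    else:
        universe = list(site.alleles)
        alleles = list(call.alleles)
    try:
        idx = tuple(sorted(universe.index(a) for a in alleles))
    except ValueError:
        raise ValueError(
            f"allele {call.alleles} not in site allele set {site.alleles} "
            f"at {site.chrom}:{site.pos} (harmonization bug)"
        ) from None
    if len(idx) == 1:  # haploid call treated as homozygous-equivalent
        idx = (idx[0], idx[0])
    return _PAIR_TO_CLASS[idx]


def indel_symbol_map(site: Site) -> dict[str, str]:
    """Map the sequences of a biallelic indel site onto {I, D} symbols.

    The longer allele is the insertion symbol I, the shorter the deletion
    symbol D — the BeadChip convention for simple indels.
    """
    if len(site.alts) != 1:
        raise ValueError(
            f"I/D symbols are defined for biallelic indels only; "
            f"{site.chrom}:{site.pos} has alts {site.alts}"
        )
    ref, alt = site.ref, site.alts[0]
    if len(ref) == len(alt):
        raise ValueError(f"alleles of equal length at {site.chrom}:{site.pos}")
    longer, shorter = (ref, alt) if len(ref) > len(alt) else (alt, ref)
    return {longer: "I", shorter: "D", "I": "I", "D": "D"}


# ---------------------------------------------------------------------------
# WGS VCF input
# ---------------------------------------------------------------------------

def read_wgs_vcf(
    path: str | Path, sample_name: str
) -> list[tuple[GenotypeCall, WgsCallAnnotations]]:
    """Read one sample's calls from a VCF with variant and non-variant sites.

    Non-variant (hom-ref) records yield reference-homozygous calls; records
    whose FILTER is anything other than PASS or ``.`` are dropped, as are
    records with more than two ALT alleles (the class labeling admits at
    most two alternatives).  DP/GQ/RGQ and site QUAL are captured where
    present.
    """
    path = str(path)
    vcf = pysam.VariantFile(path)
    if sample_name not in vcf.header.samples:
        raise KeyError(
            f"sample {sample_name!r} not in VCF {path}; "
            f"available: {list(vcf.header.samples)}"
        )
    out: list[tuple[GenotypeCall, WgsCallAnnotations]] = []
    for i, rec in enumerate(vcf.fetch() if vcf.index else vcf):
        try:
            filters = list(rec.filter.keys())
            if filters and filters != ["PASS"]:
                continue
            alts = tuple(a for a in (rec.alts or ()) if a not in (".", "<NON_REF>"))
            if len(alts) > 2:
                continue
            site = Site(rec.chrom, rec.pos, rec.id or f"{rec.chrom}:{rec.pos}",
                        rec.ref, alts)
            sample = rec.samples[sample_name]
            gt = sample.get("GT")
            allele_idx = [a for a in (gt or ()) if a is not None]
            if not allele_idx:
                call = GenotypeCall(site, (), Platform.WGS, missing=True)
            else:
                seqs = tuple(site.alleles[a] for a in allele_idx)
                if len(seqs) == 1:
                    seqs = (seqs[0], seqs[0])
                call = GenotypeCall(site, seqs, Platform.WGS)
            ann = WgsCallAnnotations(
                site=site,
                dp=sample.get("DP"),
                qual=rec.qual,
                gq=sample.get("GQ"),
                rgq=sample.get("RGQ"),
            )
        except (KeyError, IndexError, ValueError) as exc:
            raise ValueError(f"unparseable VCF record #{i + 1} in {path}: {exc}") from exc
        out.append((call, ann))
    return out


# ---------------------------------------------------------------------------
# BeadChip final report input
# ---------------------------------------------------------------------------

BEADCHIP_COLUMNS = [
    "SNP Name", "Chr", "Position", "Allele1 - Plus", "Allele2 - Plus",
    "GC Score", "GT Score", "Cluster Sep", "Theta", "R", "X", "Y",
    "B Allele Freq",
]

_NOCALL_PAIRS = {"--", "NC"}


def read_beadchip_report(
    path: str | Path,
) -> list[tuple[GenotypeCall, BeadChipRecord]]:
    """Parse a GenomeStudio-style final report ([Header] block + [Data] table).

    Two-letter genotypes are split into unordered allele pairs; ``--`` and
    ``NC`` genotype strings map to missing calls; indel genotypes use the
    I/D symbols.  The report carries no reference allele, so sites are
    emitted with ``ref="N"`` pending harmonization against a VCF call set.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    try:
        data_start = next(i for i, ln in enumerate(lines) if ln.strip() == "[Data]")
    except StopIteration:
        raise ValueError(f"{path}: no [Data] section found") from None
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(lines[data_start + 1:])), sep="\t", dtype=str)
    missing_cols = [c for c in BEADCHIP_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing mandatory columns {missing_cols}")

    out: list[tuple[GenotypeCall, BeadChipRecord]] = []
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        a1, a2 = str(d["Allele1 - Plus"]).strip(), str(d["Allele2 - Plus"]).strip()
        pair = a1 + a2
        alleles: tuple[str, ...]
        if pair in _NOCALL_PAIRS or a1 == "-" or a2 == "-":
            alleles, missing = (), True
        else:
            alleles, missing = (a1, a2), False
        var_class = (
            VarClass.INDEL
            if alleles and set(alleles) <= {"I", "D"}
            else VarClass.SNV
        )
        site = Site(str(d["Chr"]), int(d["Position"]), str(d["SNP Name"]),
                    "N", (), var_class)
        call = GenotypeCall(site, alleles, Platform.BEADCHIP, missing=missing)
        rec = BeadChipRecord(
            site=site,
            gc_score=float(d["GC Score"]),
            gt_score=float(d["GT Score"]),
            cluster_sep=float(d["Cluster Sep"]),
            theta=float(d["Theta"]),
            r=float(d["R"]),
            x=float(d["X"]),
            y=float(d["Y"]),
            b_allele_freq=float(d["B Allele Freq"]),
        )
        out.append((call, rec))
    return out


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

@dataclass
class HarmonizeReport:
    """Bookkeeping for sites excluded during pairing."""

    n_truth: int = 0
    n_test: int = 0
    n_shared: int = 0
    n_paired: int = 0
    n_missing_either: int = 0
    n_excluded_chrom: int = 0
    n_unreconciled: int = 0
    n_ambiguous_strand: int = 0


def _is_palindromic(site: Site) -> bool:
    """A/T or C/G biallelic SNVs: a strand flip is undetectable from alleles."""
    if site.var_class is not VarClass.SNV or len(site.alts) != 1:
        return False
    return reverse_complement(site.ref) == site.alts[0]


def _reconcile(site: Site, call: GenotypeCall, report: HarmonizeReport) -> GenotypeCall | None:
    """Express ``call``'s alleles in terms of ``site``'s allele set.

    SNVs: direct match first, then reverse-complement; mismatches at
    palindromic (A/T, C/G) sites are counted as strand-ambiguous.  Indels:
    alleles are funneled through the I/D symbol map.
    """
    if site.var_class is VarClass.INDEL:
        try:
            symbols = indel_symbol_map(site)
        except ValueError:
            report.n_unreconciled += 1
            return None
        mapped = tuple(a if a in ("I", "D") else symbols.get(a) for a in call.alleles)
        if any(m is None for m in mapped):
            report.n_unreconciled += 1
            return None
        return GenotypeCall(site, mapped, call.platform)  # type: ignore[arg-type]

    universe = set(site.alleles)
    if set(call.alleles) <= universe:
        return GenotypeCall(site, call.alleles, call.platform)
    flipped = tuple(reverse_complement(a) for a in call.alleles)
    if set(flipped) <= universe and not _is_palindromic(site):
        return GenotypeCall(site, flipped, call.platform)
    if _is_palindromic(site):
        report.n_ambiguous_strand += 1
    else:
        report.n_unreconciled += 1
    return None


def harmonize_pair(
    callset_truth: Iterable[GenotypeCall],
    callset_test: Iterable[GenotypeCall],
    exclude_chroms: frozenset[str] | set[str] = frozenset(),
) -> tuple[list[PairedCall], HarmonizeReport]:
    """Pair two call sets on shared (chrom, pos) keys and reconcile alleles.

    Only sites genotyped (non-missing) on both platforms survive; the site
    carrying reference/alternative alleles (normally the VCF side) anchors
    the class labeling.  Sites whose alleles cannot be reconciled — and
    mismatching palindromic A/T, C/G markers, where a strand flip cannot
    be proven — are excluded and counted in the report, never fatal.
    """
    report = HarmonizeReport()
    truth_by_pos: dict[tuple[str, int], GenotypeCall] = {}
    for c in callset_truth:
        truth_by_pos[(c.site.chrom, c.site.pos)] = c
    test_by_pos: dict[tuple[str, int], GenotypeCall] = {}
    for c in callset_test:
        test_by_pos[(c.site.chrom, c.site.pos)] = c
    report.n_truth = len(truth_by_pos)
    report.n_test = len(test_by_pos)

    pairs: list[PairedCall] = []
    for key in sorted(set(truth_by_pos) & set(test_by_pos),
                      key=lambda k: (_chrom_rank(k[0]), k[1])):
        report.n_shared += 1
        chrom, _ = key
        if chrom in exclude_chroms:
            report.n_excluded_chrom += 1
            continue
        ct, cs = truth_by_pos[key], test_by_pos[key]
        if ct.missing or cs.missing:
            report.n_missing_either += 1
            continue
        # anchor on whichever side knows its reference allele
        anchor = ct.site if ct.site.ref != "N" else cs.site
        if anchor.ref == "N":
            report.n_unreconciled += 1
            continue
        rt = _reconcile(anchor, ct, report)
        if rt is None:
            continue
        rs = _reconcile(anchor, cs, report)
        if rs is None:
            continue
        try:
            cls_t = assign_genotype_class(anchor, rt)
            cls_s = assign_genotype_class(anchor, rs)
        except ValueError:
            report.n_unreconciled += 1
            continue
        pairs.append(PairedCall(anchor, rt, rs, cls_t, cls_s))
    report.n_paired = len(pairs)
    return pairs, report


_CHROM_ORDER = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24, "MT": 25, "M": 25}


def _chrom_rank(chrom: str) -> tuple[int, str]:
    c = chrom.removeprefix("chr")
    return (_CHROM_ORDER.get(c, 99), c)
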
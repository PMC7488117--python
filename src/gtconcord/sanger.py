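"""Sanger adjudication of BeadChip/WGS discordant genotypes.

Sanger sequencing of a short amplicon gives a third, independent genotype
at each validated site.  A genotype supported by both the forward and
reverse chromatogram is a resolved diploid call; a single-read genotype
(one letter plus a dash) is haploid evidence only, and ``NA`` marks a
failed reaction.  Resolved rows are classified by which platforms agree
with the Sanger call, and — treating Sanger as the truth set — each
platform gets a confusion matrix and the full concordance metric report.

Only resolved diploid rows enter the metrics; haploid single-read calls
are excluded even when their one allele is compatible with both
platforms.

The packaged validation table for the study's sample_002 is exposed via
:func:`load_validation_table`.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .callset_io import (
    GenotypeCall,
    GenotypeClass,
    PairedCall,
    Platform,
    Site,
    VarClass,
)
from .concordance import (
    ClassUniverse,
    MetricsReport,
    build_confusion_matrix,
    compute_metrics,
)

__all__ = [
    "SangerStatus",
    "Pattern",
    "SangerCall",
    "ValidationRow",
    "parse_sanger_genotype",
    "parse_two_letter_genotype",
    "classify_concordance_pattern",
    "validation_metrics",
    "load_validation_table",
    "rows_from_table",
    "write_validation_table",
]

_DASHES = {"-", "‐", "‑", "‒", "–", "—"}
_ALLELE_LETTERS = set("ACGTID")


class SangerStatus(enum.Enum):
    RESOLVED_DIPLOID = "RESOLVED_DIPLOID"
    HAPLOID_SINGLE_READ = "HAPLOID_SINGLE_READ"
    FAILED = "FAILED"


class Pattern(enum.Enum):
    """Three-way concordance class (the validation table's a-d footnotes)."""

    WGS_ONLY = "WGS_ONLY"          # Sanger agrees with WGS only
    ALL_THREE = "ALL_THREE"        # all three methods agree
    BEADCHIP_ONLY = "BEADCHIP_ONLY"  # Sanger agrees with BeadChip only
    NONE = "NONE"                  # Sanger agrees with neither
    UNRESOLVED = "UNRESOLVED"      # no resolved diploid Sanger call


@dataclass(frozen=True)
class SangerCall:
    genotype: str
    alleles: tuple[str, ...]
    status: SangerStatus


def parse_sanger_genotype(text: str) -> SangerCall:
    """Parse a Sanger genotype string ("CC", "G-", "NA", "II", "DI"...).

    Two allele symbols -> resolved diploid; one symbol plus a dash
    (hyphen, en- or em-dash) -> haploid single-read; ``NA`` -> failed.
    """
    raw = text.strip()
    if not raw:
        raise ValueError("empty Sanger genotype string")
    if raw.upper() == "NA":
        return SangerCall(raw, (), SangerStatus.FAILED)
    chars = list(raw)
    if len(chars) == 2 and chars[0] in _ALLELE_LETTERS and chars[1] in _DASHES:
        return SangerCall(raw, (chars[0],), SangerStatus.HAPLOID_SINGLE_READ)
    if len(chars) == 2 and all(c in _ALLELE_LETTERS for c in chars):
        return SangerCall(raw, tuple(sorted(chars)), SangerStatus.RESOLVED_DIPLOID)
    raise ValueError(f"unrecognized Sanger genotype string: {text!r}")


def parse_two_letter_genotype(text: str) -> tuple[str, ...]:
    """Split a two-letter platform genotype ("TC", "II", "DI") into alleles."""
    raw = text.strip()
    if len(raw) != 2 or not all(c in _ALLELE_LETTERS for c in raw):
        raise ValueError(f"unrecognized genotype string: {text!r}")
    return tuple(sorted(raw))


@dataclass(frozen=True)
class ValidationRow:
    rsid: str
    chrom: str
    pos: int
    bead: GenotypeCall
    wgs: GenotypeCall
    sanger: SangerCall
    note: str = ""

    @property
    def site(self) -> Site:
        return self.bead.site

    @property
    def bead_wgs_discordant(self) -> bool:
        return self.bead.alleles != self.wgs.alleles


def classify_concordance_pattern(row: ValidationRow) -> Pattern:
    """Classify a row by exact unordered-pair genotype equality."""
    if row.sanger.status is not SangerStatus.RESOLVED_DIPLOID:
        return Pattern.UNRESOLVED
    s = row.sanger.alleles
    eq_wgs = s == row.wgs.alleles
    eq_bead = s == row.bead.alleles
    if eq_wgs and eq_bead:
        return Pattern.ALL_THREE
    if eq_wgs:
        return Pattern.WGS_ONLY
    if eq_bead:
        return Pattern.BEADCHIP_ONLY
    return Pattern.NONE


def _site_local_classes(row: ValidationRow) -> tuple[GenotypeClass, GenotypeClass, GenotypeClass]:
    """Class labels (sanger, wgs, bead) under a site-local allele ranking.

    Without a reference genome the A/B/C labeling is anchored on the
    Sanger truth call: A = the allele most frequent in the Sanger
    genotype, ties broken by frequency across all three genotypes, then
    lexicographically.  The micro-averaged precision is invariant to this
    choice; it only fixes which off-diagonal cell a discordance lands in.
    """
    sanger_counts = Counter(row.sanger.alleles)
    all_counts = Counter(row.sanger.alleles + row.wgs.alleles + row.bead.alleles)
    ranked = sorted(all_counts, key=lambda a: (-sanger_counts[a], -all_counts[a], a))
    if len(ranked) > 3:
        raise ValueError(f"more than three alleles at {row.rsid}: {ranked}")
    index = {a: i for i, a in enumerate(ranked)}
    pair_to_class = {
        (0, 0): GenotypeClass.AA, (0, 1): GenotypeClass.AB,
        (1, 1): GenotypeClass.BB, (0, 2): GenotypeClass.AC,
        (1, 2): GenotypeClass.BC, (2, 2): GenotypeClass.CC,
    }

    def cls(alleles: tuple[str, ...]) -> GenotypeClass:
        idx = tuple(sorted(index[a] for a in alleles))
        return pair_to_class[idx]

    return cls(row.sanger.alleles), cls(row.wgs.alleles), cls(row.bead.alleles)


def validation_metrics(
    rows: Iterable[ValidationRow],
    class_universe: ClassUniverse = "present",
) -> tuple[MetricsReport, MetricsReport, int]:
    """Sanger-as-truth metric reports for WGS and BeadChip.

    Only resolved diploid rows enter; one confusion matrix per platform is
    built with the Sanger call as truth and handed to the concordance
    engine.  Returns (wgs_report, beadchip_report, n_resolved); with zero
    resolved rows both reports are undefined.
    """
    wgs_pairs: list[PairedCall] = []
    bead_pairs: list[PairedCall] = []
    n_resolved = 0
    for row in rows:
        if row.sanger.status is not SangerStatus.RESOLVED_DIPLOID:
            continue
        n_resolved += 1
        cls_s, cls_w, cls_b = _site_local_classes(row)
        site = row.site
        truth = GenotypeCall(site, row.sanger.alleles, Platform.SANGER)
        wgs_pairs.append(PairedCall(site, truth, row.wgs, cls_s, cls_w))
        bead_pairs.append(PairedCall(site, truth, row.bead, cls_s, cls_b))
    if n_resolved == 0:
        undefined = MetricsReport(*([None] * 7))
        return undefined, undefined, 0
    wgs_report = compute_metrics(build_confusion_matrix(wgs_pairs), class_universe)
    bead_report = compute_metrics(build_confusion_matrix(bead_pairs), class_universe)
    return wgs_report, bead_report, n_resolved


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["rsID", "Chromosome", "Position", "BeadChip genotype",
                  "WGS genotype", "Sanger genotype"]


def load_validation_table(path: str | Path | None = None) -> list[ValidationRow]:
    """Read a three-way validation table (TSV).

    With no path, loads the packaged table transcribing the study's
    sample_002 validation results (26 rows).
    """
    if path is None:
        src = resources.files("gtconcord.data") / "sanger_validation_sample002.tsv"
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t", dtype=str,
                             keep_default_na=False, na_values=[])
    else:
        df = pd.read_csv(path, sep="\t", dtype=str,
                         keep_default_na=False, na_values=[])
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"validation table missing columns {missing}")
    return rows_from_table(df)


def rows_from_table(df: pd.DataFrame) -> list[ValidationRow]:
    rows: list[ValidationRow] = []
    for rec in df.itertuples(index=False):
        d = dict(zip(df.columns, rec))
        bead_alleles = parse_two_letter_genotype(str(d["BeadChip genotype"]))
        wgs_alleles = parse_two_letter_genotype(str(d["WGS genotype"]))
        var_class = (
            VarClass.INDEL if set(bead_alleles) <= {"I", "D"} else VarClass.SNV
        )
        site = Site(str(d["Chromosome"]), int(d["Position"]), str(d["rsID"]),
                    "N", (), var_class)
        note = str(d.get("Note", "") or "")
        if note == "nan":
            note = ""
        rows.append(ValidationRow(
            rsid=str(d["rsID"]),
            chrom=str(d["Chromosome"]),
            pos=int(d["Position"]),
            bead=GenotypeCall(site, bead_alleles, Platform.BEADCHIP),
            wgs=GenotypeCall(site, wgs_alleles, Platform.WGS),
            sanger=parse_sanger_genotype(str(d["Sanger genotype"])),
            note=note,
        ))
    return rows


def write_validation_table(rows: Sequence[ValidationRow], path: str | Path) -> None:
    recs = [
        (r.rsid, r.chrom, r.pos, "".join(r.bead.alleles), "".join(r.wgs.alleles),
         r.sanger.genotype, r.note)
        for r in rows
    ]
    pd.DataFrame(recs, columns=_TABLE_COLUMNS + ["Note"]).to_csv(
        path, sep="\t", index=False
    )
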
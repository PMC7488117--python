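"""Confusion-matrix concordance metrics for paired diploid call sets.

The comparison of two call sets with no external truth is summarized as a
6x6 count matrix over the diploid genotype classes {A/A, A/B, B/B, A/C,
B/C, C/C}, indexed (truth_class, test_class).  Each focal class is then
collapsed to a 2x2 matrix (the focal cell intact, all other classes
pooled), from which per-class precision, sensitivity, specificity and
accuracy follow.  Overall precision and sensitivity are weighted by each
reduced matrix's share of the full matrix (focal-column and focal-row
shares respectively), which makes them algebraically equal to each other
and to the genotype concordance trace/total — the micro-average identity.
Accuracy and specificity are unweighted means of the per-class values,
excluding NaNs from zero denominators.

When neither call set is privileged as truth, :func:`symmetrize_metrics`
averages the metrics obtained with the roles alternated.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .callset_io import CONFUSION_CLASSES, GenotypeClass, PairedCall

__all__ = [
    "ConfusionMatrix",
    "ReducedMatrix",
    "MetricsReport",
    "build_confusion_matrix",
    "reduce_by_class",
    "compute_metrics",
    "symmetrize_metrics",
    "write_metrics_table",
]

_CLASS_INDEX = {cls: i for i, cls in enumerate(CONFUSION_CLASSES)}

ClassUniverse = Literal["present", "all"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """6x6 genotype-class count matrix, rows = truth, columns = test."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=np.int64)
        if arr.shape != (6, 6):
            raise ValueError(f"expected a 6x6 matrix, got shape {arr.shape}")
        if (arr < 0).any():
            raise ValueError("confusion matrix cells must be non-negative")
        object.__setattr__(self, "counts", arr)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def trace(self) -> int:
        return int(np.trace(self.counts))

    def transpose(self) -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts.T.copy())

    def to_frame(self) -> pd.DataFrame:
        labels = [c.value for c in CONFUSION_CLASSES]
        return pd.DataFrame(self.counts, index=labels, columns=labels)

    def present_classes(self) -> list[GenotypeClass]:
        """Classes with a nonzero row or column sum."""
        rows = self.counts.sum(axis=1)
        cols = self.counts.sum(axis=0)
        return [c for c in CONFUSION_CLASSES
                if rows[_CLASS_INDEX[c]] or cols[_CLASS_INDEX[c]]]


@dataclass(frozen=True)
class ReducedMatrix:
    """2x2 collapse of a confusion matrix around one focal class."""

    focal_class: GenotypeClass
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """The seven concordance metrics; ``None`` marks an undefined value."""

    genotype_concordance: float | None
    nonref_genotype_concordance: float | None
    nonref_sensitivity: float | None
    sensitivity: float | None
    precision: float | None
    specificity: float | None
    accuracy: float | None

    def to_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def build_confusion_matrix(paired: Iterable[PairedCall]) -> ConfusionMatrix:
    """Count (truth_class, test_class) co-occurrences over paired calls.

    Every pair must carry non-MISSING classes; an empty collection yields
    the zero matrix (downstream metrics are then undefined).
    """
    counts = np.zeros((6, 6), dtype=np.int64)
    for p in paired:
        if GenotypeClass.MISSING in (p.class_truth, p.class_test):
            raise ValueError(
                f"MISSING class in paired call at {p.site.chrom}:{p.site.pos}"
            )
        counts[_CLASS_INDEX[p.class_truth], _CLASS_INDEX[p.class_test]] += 1
    return ConfusionMatrix(counts)


def reduce_by_class(cm: ConfusionMatrix, focal: GenotypeClass) -> ReducedMatrix:
    """Collapse to 2x2: focal cell intact, all other classes pooled."""
    k = _CLASS_INDEX[focal]
    tp = int(cm.counts[k, k])
    fn = int(cm.counts[k, :].sum()) - tp
    fp = int(cm.counts[:, k].sum()) - tp
    tn = cm.total - tp - fn - fp
    return ReducedMatrix(focal, tp, fn, fp, tn)


def _ratio(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def compute_metrics(
    cm: ConfusionMatrix, class_universe: ClassUniverse = "present"
) -> MetricsReport:
    """Compute the seven metrics from one confusion matrix.

    Per focal class k: precision_k = tp/(tp+fp), sensitivity_k =
    tp/(tp+fn), specificity_k = tn/(tn+fp), accuracy_k = (tp+tn)/total.
    Overall precision and sensitivity weight each class by its reduced
    matrix's focal-column (resp. focal-row) share of the total; classes
    with a zero denominator carry zero weight.  Accuracy and specificity
    are arithmetic means of the defined per-class values over
    ``class_universe`` — by default only classes occupied somewhere in the
    matrix ("present"), optionally all six ("all").
    """
    total = cm.total
    if total == 0:
        return MetricsReport(*([None] * 7))

    universe = cm.present_classes() if class_universe == "present" else list(CONFUSION_CLASSES)

    precision_sum = 0.0
    sensitivity_sum = 0.0
    accuracies: list[float] = []
    specificities: list[float] = []
    for cls in CONFUSION_CLASSES:
        red = reduce_by_class(cm, cls)
        p_k = _ratio(red.tp, red.tp + red.fp)
        s_k = _ratio(red.tp, red.tp + red.fn)
        if p_k is not None:
            precision_sum += p_k * (red.tp + red.fp) / total
        if s_k is not None:
            sensitivity_sum += s_k * (red.tp + red.fn) / total
        if cls in universe:
            accuracies.append((red.tp + red.tn) / total)
            sp_k = _ratio(red.tn, red.tn + red.fp)
            if sp_k is not None:
                specificities.append(sp_k)

    trace = cm.trace
    aa = int(cm.counts[0, 0])
    nonref_rows = int(cm.counts[1:, :].sum())
    return MetricsReport(
        genotype_concordance=_ratio(trace, total),
        nonref_genotype_concordance=_ratio(trace - aa, total - aa),
        nonref_sensitivity=_ratio(trace - aa, nonref_rows),
        sensitivity=sensitivity_sum,
        precision=precision_sum,
        specificity=float(np.mean(specificities)) if specificities else None,
        accuracy=float(np.mean(accuracies)) if accuracies else None,
    )


def symmetrize_metrics(
    cm: ConfusionMatrix, class_universe: ClassUniverse = "present"
) -> MetricsReport:
    """Average the metrics with truth/test roles alternated.

    Element-wise mean of the reports for ``cm`` and its transpose; a value
    is defined only when both directions define it.
    """
    fwd = compute_metrics(cm, class_universe)
    rev = compute_metrics(cm.transpose(), class_universe)
    merged = {}
    for f in fields(MetricsReport):
        a, b = getattr(fwd, f.name), getattr(rev, f.name)
        merged[f.name] = (a + b) / 2 if a is not None and b is not None else None
    return MetricsReport(**merged)


def write_metrics_table(
    reports: Mapping[str, MetricsReport], path: str | Path, fmt: str | None = None
) -> None:
    """Serialize reports as a flat table, one row per (sample, comparison).

    ``fmt`` is inferred from the suffix (.tsv or .json) when omitted;
    undefined values are written as NaN (TSV) / null (JSON), never 0.
    """
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".")
    rows = {name: rep.to_dict() for name, rep in reports.items()}
    if fmt == "json":
        path.write_text(json.dumps(rows, indent=2) + "\n")
    elif fmt == "tsv":
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "comparison"
        df.to_csv(path, sep="\t", na_rep="NaN")
    else:
        raise ValueError(f"unsupported metrics table format: {fmt!r}")
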
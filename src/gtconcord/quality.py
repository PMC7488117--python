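"""Quality-metric distribution comparisons and cluster-border scoring.

Two questions about why platforms disagree: (1) do the per-call quality
annotations (DP, GQ, GC score, Theta, R, ...) differ in distribution
between concordant and discordant calls (Welch's unequal-variance t-test,
alpha = 0.05)?  (2) do discordant array calls sit near the borders of the
Theta genotype clusters that the calling software separates?

The border score idealizes cluster centers at the canonical Theta values
0 (AA), 0.5 (AB) and 1 (BB); true per-marker cluster positions live in
the array vendor's clustering model and are not available here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .callset_io import BeadChipRecord, GenotypeClass, Site

__all__ = [
    "GroupBy",
    "GroupComparison",
    "BorderScore",
    "compare_metric_distributions",
    "compare_many",
    "theta_distance",
    "score_cluster_border",
    "write_comparisons",
    "write_border_scores",
]

THETA_CENTERS = {
    GenotypeClass.AA: 0.0,
    GenotypeClass.AB: 0.5,
    GenotypeClass.BB: 1.0,
}


class GroupBy(enum.Enum):
    CONCORDANCE = "CONCORDANCE"
    VAR_CLASS = "VAR_CLASS"
    ZYGOSITY = "ZYGOSITY"


@dataclass(frozen=True)
class GroupComparison:
    """Welch's t-test between a metric's values in two groups."""

    metric_name: str
    group_by: GroupBy | None
    n_a: int
    n_b: int
    mean_a: float | None
    mean_b: float | None
    t_stat: float | None
    p_value: float | None
    alpha: float = 0.05

    @property
    def defined(self) -> bool:
        return self.p_value is not None and np.isfinite(self.p_value)

    @property
    def significant(self) -> bool | None:
        if not self.defined:
            return None
        return bool(self.p_value < self.alpha)


def compare_metric_distributions(
    values_a: Sequence[float],
    values_b: Sequence[float],
    metric_name: str = "",
    group_by: GroupBy | None = None,
    alpha: float = 0.05,
) -> GroupComparison:
    """Welch's unequal-variance t-test (Welch-Satterthwaite df, two-sided p).

    Groups with fewer than two finite values yield an undefined
    comparison rather than an exception.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        return GroupComparison(metric_name, group_by, len(a), len(b),
                               float(a.mean()) if len(a) else None,
                               float(b.mean()) if len(b) else None,
                               None, None, alpha)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    t, p = float(t), float(p)
    if not (np.isfinite(t) and np.isfinite(p)):  # e.g. both groups constant
        t_out, p_out = None, None
    else:
        t_out, p_out = t, p
    return GroupComparison(metric_name, group_by, len(a), len(b),
                           float(a.mean()), float(b.mean()), t_out, p_out, alpha)


def compare_many(
    table: pd.DataFrame,
    metric_names: Sequence[str],
    group_column: str,
    group_by: GroupBy | None = None,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> list[GroupComparison]:
    """One Welch comparison per metric between the two levels of ``group_column``.

    Multiple testing is uncorrected by default (each test stands alone at
    ``alpha``); ``bonferroni=True`` divides alpha by the number of metrics.
    """
    levels = sorted(table[group_column].dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"{group_column} must have exactly two levels, got {levels}")
    eff_alpha = alpha / len(metric_names) if bonferroni else alpha
    out = []
    for m in metric_names:
        va = table.loc[table[group_column] == levels[0], m]
        vb = table.loc[table[group_column] == levels[1], m]
        out.append(compare_metric_distributions(va, vb, m, group_by, eff_alpha))
    return out


# ---------------------------------------------------------------------------
# Cluster-border proximity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BorderScore:
    site: Site
    theta_distance: float
    near_border: bool


def theta_distance(theta: float, called_class: GenotypeClass) -> float:
    """|Theta - canonical center of the called class|.

    Classes outside the biallelic trio (A/C etc., or MISSING) fall back to
    the nearest of the three canonical centers.
    """
    center = THETA_CENTERS.get(called_class)
    if center is None:
        center = min(THETA_CENTERS.values(), key=lambda c: abs(theta - c))
    return abs(theta - center)


def score_cluster_border(
    records: Sequence[tuple[BeadChipRecord, GenotypeClass, bool]],
    border_quantile: float = 0.9,
) -> list[BorderScore]:
    """Score each call's distance from its genotype-cluster center.

    ``records`` are (array record, called class, concordant?) triples.
    ``near_border`` flags calls whose distance exceeds the given quantile
    of the concordant group's distances (the whole cohort when no call is
    concordant).
    """
    dists = np.array([theta_distance(rec.theta, cls) for rec, cls, _ in records])
    conc = np.array([c for _, _, c in records], dtype=bool)
    ref = dists[conc] if conc.any() else dists
    threshold = float(np.quantile(ref, border_quantile)) if len(ref) else np.inf
    return [
        BorderScore(rec.site, float(d), bool(d > threshold))
        for (rec, _, _), d in zip(records, dists)
    ]


def write_comparisons(comparisons: Iterable[GroupComparison], path: str | Path) -> None:
    rows = [
        (c.metric_name, c.group_by.value if c.group_by else "",
         c.n_a, c.n_b, c.mean_a, c.mean_b, c.t_stat, c.p_value, c.significant)
        for c in comparisons
    ]
    pd.DataFrame(rows, columns=[
        "metric", "group_by", "n_a", "n_b", "mean_a", "mean_b",
        "t_stat", "p_value", "significant",
    ]).to_csv(path, sep="\t", index=False, na_rep="NaN")


def write_border_scores(scores: Iterable[BorderScore], path: str | Path) -> None:
    rows = [(s.site.chrom, s.site.pos, s.site.id, s.theta_distance, s.near_border)
            for s in scores]
    pd.DataFrame(rows, columns=[
        "chrom", "pos", "id", "theta_distance", "near_border",
    ]).to_csv(path, sep="\t", index=False)
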
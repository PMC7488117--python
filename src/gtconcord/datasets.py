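"""Packaged reference tables from the BeadChip/WGS comparison study.

Three small tables transcribed from the study the package's fixtures and
acceptance checks are built around: the sample_002 three-way Sanger
validation table, the selected validation regions for that sample, and
the per-sample summary of the seven concordance metrics.  The underlying
raw call sets are not public; these printed summaries are the only data
that ship with the package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "sanger_validation_table",
    "selected_regions_table",
    "platform_metrics_table",
    "REPORTED_DISCORDANCE_PCT",
]

#: Genome-wide discordant-call percentages reported per study sample.
REPORTED_DISCORDANCE_PCT: dict[str, float] = {
    "001": 0.3317,
    "002": 0.8448,
    "003": 0.7392,
}


def _read(name: str, **kwargs) -> pd.DataFrame:
    src = resources.files("gtconcord.data") / name
    with resources.as_file(src) as p:
        return pd.read_csv(p, sep="\t", **kwargs)


def sanger_validation_table() -> pd.DataFrame:
    """The 26-row three-way BeadChip/WGS/Sanger validation table (sample_002)."""
    return _read("sanger_validation_sample002.tsv", dtype=str,
                 keep_default_na=False, na_values=[])


def selected_regions_table() -> pd.DataFrame:
    """The 8 validation regions selected for sample_002 (printed windows)."""
    return _read("selected_regions_sample002.tsv")


def platform_metrics_table() -> pd.DataFrame:
    """Per-sample concordance metrics of the full BeadChip-vs-WGS comparison."""
    return _read("platform_metrics_summary.tsv")
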
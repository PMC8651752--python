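"""Nitrogen-cycling functional gene summaries.

Works on a sample × gene-family count table from capture-based metagenomic
sequencing of the key N-cycle genes: N₂ fixation (nifH), nitrification
(amoA, bacterial + archaeal), nitrate reduction (narG, napA),
denitrification (nirK, nirS, norB, nosZ), DNRA (nrfA) and anammox (hdhA).
Relative abundances are percentages of all captured functional-gene
sequences per sample; the (nirK + nirS)/nosZ ratio is a widely used
indicator of the soil's N₂O production (vs. consumption) potential.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GENE_FAMILIES",
    "AGGREGATES",
    "relative_abundance",
    "nir_nosz_ratio",
    "qpcr_copies_per_g",
    "summarize_by_surface",
    "QpcrResult",
]

GENE_FAMILIES = (
    "nifH",
    "amoA_bacterial",
    "amoA_archaeal",
    "narG",
    "napA",
    "nirK",
    "nirS",
    "norB",
    "nosZ",
    "nrfA",
    "hdhA",
    "other",
)

#: aggregate families used in reporting
AGGREGATES = {
    "amoA": ("amoA_bacterial", "amoA_archaeal"),
    "nir": ("nirK", "nirS"),
}

_METADATA_COLS = ("surface_class", "replicate", "sample_id")


def _count_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in _METADATA_COLS]


def _resolve(table: pd.DataFrame, gene: str) -> pd.Series:
    """A gene family's counts, resolving the amoA/nir aggregates."""
    if gene in table.columns:
        return table[gene]
    if gene in AGGREGATES:
        members = [m for m in AGGREGATES[gene] if m in table.columns]
        if members:
            return table[members].sum(axis=1)
    raise KeyError(f"gene family {gene!r} not in table")


def relative_abundance(table: pd.DataFrame, gene_set: str | list[str]) -> pd.Series:
    """Percent of all captured functional-gene sequences per sample.

    ``gene_set`` may be a single family, an aggregate name ("amoA", "nir")
    or a list of families summed together. The denominator is the per-sample
    total over all count columns (including "other").
    """
    if isinstance(gene_set, str):
        gene_set = [gene_set]
    if not gene_set:
        raise ValueError("empty gene_set")
    counts = _count_columns(table)
    row_sum = table[counts].sum(axis=1)
    if (row_sum <= 0).any():
        raise ValueError("zero row sum: sample with no captured sequences")
    num = sum(_resolve(table, g) for g in gene_set)
    return 100.0 * num / row_sum


def nir_nosz_ratio(table: pd.DataFrame) -> pd.Series:
    """(nirK + nirS)/nosZ per sample; NaN (flagged) where nosZ is zero."""
    nir = _resolve(table, "nir")
    nosz = _resolve(table, "nosZ")
    return nir / nosz.where(nosz > 0)


@dataclass
class QpcrResult:
    copies_per_reaction: float
    template_volume: float  # μL of DNA extract per reaction
    elution_volume: float  # μL the extract was eluted into
    soil_dw_extracted: float  # g dry soil extracted

    def __post_init__(self) -> None:
        if min(self.template_volume, self.elution_volume, self.soil_dw_extracted) <= 0:
            raise ValueError("volumes and soil mass must be positive")


def qpcr_copies_per_g(res: QpcrResult) -> float:
    """Gene copies per g dry soil from per-reaction qPCR quantification."""
    return res.copies_per_reaction * (res.elution_volume / res.template_volume) / res.soil_dw_extracted


def summarize_by_surface(table: pd.DataFrame, gene_sets: list[str]) -> pd.DataFrame:
    """Per-surface mean ± SE of relative abundances and the nir/nosZ ratio.

    The ratio is computed per sample and then summarized, matching how
    individual values and their means are reported.
    """
    out = table[["surface_class"]].copy()
    for g in gene_sets:
        out[f"{g}_pct"] = relative_abundance(table, g)
    out["nir_nosz_ratio"] = nir_nosz_ratio(table)
    grouped = out.groupby("surface_class")
    mean = grouped.mean()
    se = grouped.sem()
    n = grouped.size()
    summary = mean.join(se, lsuffix="_mean", rsuffix="_se")
    summary["n"] = n
    return summary.reset_index()
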
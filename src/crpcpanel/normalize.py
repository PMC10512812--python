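"""Normalization and scaling primitives plus subgroup summaries.

The working expression scale everywhere downstream is log2(CPM + 1):
counts-per-million library-size normalization followed by a log2
transform with pseudocount 1, so a raw zero stays exactly zero. Gene
z-scores use the sample (n-1) standard deviation, and genes with zero
variance map to all-zero rather than NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .datatypes import CellAnnotation, CountMatrix

logger = logging.getLogger(__name__)


@dataclass
class NormMatrix:
    """Genes x cells matrix on the log2(CPM+1) scale."""

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("normalized matrix shape does not match identifier lists")
        if np.isnan(self.values).any():
            raise ValueError("normalized matrix contains NaN")
        if (self.values < 0).any():
            raise ValueError("normalized matrix contains negative values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "NormMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))


def cpm(m: CountMatrix) -> np.ndarray:
    """Counts-per-million per cell; column sums are exactly 1e6."""
    totals = m.counts.sum(axis=0)
    zero = totals == 0
    if zero.any():
        raise ValueError(
            "cells with zero total count: "
            f"{[m.cell_ids[i] for i in np.flatnonzero(zero)][:10]}"
        )
    return m.counts / totals * 1e6


def log2cpm(m: CountMatrix) -> NormMatrix:
    """log2(CPM + 1) normalization. Fatal on any zero-total cell."""
    return NormMatrix(m.gene_ids, m.cell_ids, np.log2(cpm(m) + 1.0))


def zscore_by_gene(m: NormMatrix, within: pd.Series | None = None) -> pd.DataFrame:
    """Per-gene z-scores (mean 0, sample SD 1), optionally within strata.

    Parameters
    ----------
    m : NormMatrix
    within : optional Series mapping cell id -> stratum label; scaling
        is then done independently inside each stratum (e.g. per
        dataset, to sidestep cross-dataset batch effects). ``None``
        scales globally.

    Genes with zero variance map to all-zero. A stratum with a single
    cell is fatal.
    """
    df = m.to_frame()
    if within is None:
        groups = {"__all__": list(df.columns)}
    else:
        within = within.reindex(df.columns)
        if within.isna().any():
            raise ValueError("`within` does not cover every cell in the matrix")
        groups = {k: list(v.index) for k, v in within.groupby(within)}
    out = np.empty_like(df.to_numpy())
    for label, cells in groups.items():
        if len(cells) < 2:
            raise ValueError(f"scaling stratum '{label}' has fewer than 2 cells")
        idx = [df.columns.get_loc(c) for c in cells]
        block = df.to_numpy()[:, idx]
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=1, keepdims=True)
        z = np.where(sd > 0, (block - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        out[:, idx] = z
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def _round_half_up(x: Decimal, ndigits: int = 2) -> float:
    return float(x.quantize(Decimal(10) ** -ndigits, rounding=ROUND_HALF_UP))


def composition(ann: CellAnnotation, dataset_id: str, lineage: str) -> pd.DataFrame:
    """Subgroup composition within one (dataset, lineage) block.

    percent = 100 * n_subgroup / n_lineage_total, reported to two
    decimals with half-up rounding. The denominator is the number of
    annotated cells of the requested lineage in the requested dataset.
    """
    sub = ann.table[(ann.table["dataset_id"] == dataset_id) & (ann.table["lineage"] == lineage)]
    if len(sub) == 0:
        logger.warning("no cells for dataset=%s lineage=%s", dataset_id, lineage)
        return pd.DataFrame(columns=["dataset_id", "subgroup", "n_cells", "percent"])
    total = len(sub)
    rows = []
    for subgroup, block in sub.groupby("subgroup", sort=True):
        pct = _round_half_up(Decimal(100 * len(block)) / Decimal(total))
        rows.append({"dataset_id": dataset_id, "subgroup": subgroup,
                     "n_cells": len(block), "percent": pct})
    return pd.DataFrame(rows)


def subgroup_mean_profiles(m: NormMatrix, ann: CellAnnotation) -> pd.DataFrame:
    """Mean log2(CPM+1) per gene per subgroup (subgroups x genes).

    Subgroups with no cells in the matrix are dropped with a warning.
    """
    df = m.to_frame()
    sub = ann.table.reindex(df.columns)
    if sub["subgroup"].isna().any():
        missing = list(sub.index[sub["subgroup"].isna()])[:10]
        raise ValueError(f"cells missing from annotation: {missing}")
    profiles = {}
    for subgroup in pd.unique(sub["subgroup"]):
        cells = list(sub.index[sub["subgroup"] == subgroup])
        if not cells:
            logger.warning("subgroup '%s' has no cells in the matrix; dropped", subgroup)
            continue
        profiles[subgroup] = df[cells].mean(axis=1)
    return pd.DataFrame(profiles).T


def similarity_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between subgroup mean-expression profiles.

    Symmetric with unit diagonal; a constant profile has undefined
    correlations and is reported as missing (NaN), never as 0.
    """
    x = profiles.to_numpy(dtype=float)
    n = x.shape[0]
    sd = x.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r = np.asarray(r, dtype=float).reshape(n, n)
    constant = sd == 0
    r[constant, :] = np.nan
    r[:, constant] = np.nan
    for i in range(n):
        if not constant[i]:
            r[i, i] = 1.0
    return pd.DataFrame(r, index=profiles.index, columns=profiles.index)
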
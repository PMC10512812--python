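"""Bulk-cohort stratification and the differential-expression screen.

Stratification follows TCGA-PRAD clinical conventions: normals are
"Solid Tissue Normal", every other sample is tumor; recurrence splits
tumors by the new-tumor-event flag; the hormone-therapy contrast
(HT_YES vs HT_NO) takes the recurrent / non-recurrent samples whose
therapy description contains "Hormone Therapy" (substring,
case-insensitive).

The DE screen is a moderated two-sample t on log2(CPM+1) with a
log-ratio of group mean CPM as the effect size and Benjamini–Hochberg
FDR control; genes are called up/down at |log2FC| > 1 and adjusted
p < 0.05. The variance moderation shrinks each gene's pooled variance
toward a common prior (default: the median pooled variance, weight
d0 = 4), the empirical-Bayes idea behind limma-style tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .datatypes import BulkCohort

logger = logging.getLogger(__name__)

STRATA_NAMES = ("normal", "tumor", "recurrent", "non_recurrent", "HT_YES", "HT_NO")

NORMAL_SAMPLE_TYPE = "Solid Tissue Normal"
HT_TOKEN = "hormone therapy"


@dataclass
class CohortStrata:
    """Sample-id lists for each clinical stratum."""

    groups: dict[str, list[str]] = field(default_factory=dict)

    def __getitem__(self, name: str) -> list[str]:
        return self.groups[name]

    def sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.groups.items()}


def stratify(cohort: BulkCohort) -> CohortStrata:
    """Assign every sample to the clinical strata.

    normal / tumor partition all samples; recurrent / non_recurrent and
    the HT strata are defined only for samples whose relevant phenotype
    fields are present — samples with missing fields are excluded from
    those dependent strata only.
    """
    ph = cohort.phenotype
    normal = [s for s in cohort.sample_ids if ph.loc[s, "sample_type"] == NORMAL_SAMPLE_TYPE]
    tumor = [s for s in cohort.sample_ids if s not in set(normal)]
    tumor_set = set(tumor)
    recurrent = [s for s in tumor if ph.loc[s, "recurrence"] == "YES" and s in tumor_set]
    non_recurrent = [s for s in tumor if ph.loc[s, "recurrence"] == "NO"]

    def _ht(samples):
        out = []
        for s in samples:
            t = ph.loc[s, "therapy_type"]
            if t is not None and not pd.isna(t) and HT_TOKEN in str(t).lower():
                out.append(s)
        return out

    strata = CohortStrata({
        "normal": normal,
        "tumor": tumor,
        "recurrent": recurrent,
        "non_recurrent": non_recurrent,
        "HT_YES": _ht(recurrent),
        "HT_NO": _ht(non_recurrent),
    })
    for name, ids in strata.groups.items():
        if not ids:
            logger.warning("stratum '%s' is empty", name)
    return strata


def _moderated_t_arrays(a: np.ndarray, b: np.ndarray, prior_df: float, prior_var: float):
    """Vectorized moderated t over gene rows.

    a, b: genes x nA / genes x nB value matrices. Returns (t, p, df).
    """
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    d = na + nb - 2
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    s2 = ((na - 1) * va + (nb - 1) * vb) / d
    s2_tilde = (prior_df * prior_var + d * s2) / (prior_df + d)
    diff = a.mean(axis=1) - b.mean(axis=1)
    df = prior_df + d
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(s2_tilde * (1.0 / na + 1.0 / nb))
    degenerate = s2_tilde == 0
    t = np.where(degenerate, 0.0, t)
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df)
    p = np.where(degenerate, 1.0, p)
    if np.any(degenerate):
        logger.warning("%d genes with zero moderated variance: p set to 1", degenerate.sum())
    return t, p, df


def moderated_t(x, y, prior_df: float = 0.0, prior_var: float = 0.0):
    """Moderated two-sample t for one gene.

    The pooled variance s2 (d = nx + ny - 2 df) is shrunk toward the
    prior: s2~ = (d0*s0^2 + d*s2) / (d0 + d); the statistic is compared
    to a t distribution with d0 + d degrees of freedom. With d0 = 0 this
    is exactly the ordinary pooled two-sample t-test. Zero variance in
    both groups with a zero prior yields p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)[None, :]
    y = np.asarray(y, dtype=float)[None, :]
    t, p, _ = _moderated_t_arrays(x, y, prior_df, prior_var)
    return float(t[0]), float(p[0])


def de_screen(
    cohort: BulkCohort,
    group_a_ids,
    group_b_ids,
    lfc_cut: float = 1.0,
    fdr_cut: float = 0.05,
    prior_df: float = 4.0,
    prior_var: float | None = None,
) -> pd.DataFrame:
    """Two-group differential-expression screen (A vs B).

    Effect size: log2FC = log2((meanCPM_A + 1) / (meanCPM_B + 1)) with a
    pseudocount of 1 on the CPM scale. Significance: moderated t on
    log2(CPM+1) (prior variance defaults to the median of gene-wise
    pooled variances), BH-adjusted over all tested genes. Direction
    calls: up iff log2FC > lfc_cut and p_adj < fdr_cut; down iff
    log2FC < -lfc_cut and p_adj < fdr_cut; otherwise ns.
    """
    a_ids, b_ids = list(group_a_ids), list(group_b_ids)
    if set(a_ids) & set(b_ids):
        raise ValueError("groups overlap: " + str(sorted(set(a_ids) & set(b_ids))[:5]))
    expr = cohort.expression_frame()
    totals = expr.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("samples with zero total expression")
    cpm = expr / totals * 1e6
    log_cpm = np.log2(cpm + 1.0)

    a = log_cpm[a_ids].to_numpy()
    b = log_cpm[b_ids].to_numpy()
    if prior_var is None:
        na, nb = a.shape[1], b.shape[1]
        d = na + nb - 2
        s2 = ((na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)) / d
        prior_var = float(np.median(s2))
    t, p_raw, _ = _moderated_t_arrays(a, b, prior_df, prior_var)
    p_adj = multipletests(p_raw, method="fdr_bh")[1]

    log2fc = np.log2((cpm[a_ids].mean(axis=1) + 1.0) / (cpm[b_ids].mean(axis=1) + 1.0))
    direction = np.where(
        (log2fc > lfc_cut) & (p_adj < fdr_cut), "up",
        np.where((log2fc < -lfc_cut) & (p_adj < fdr_cut), "down", "ns"),
    )
    return pd.DataFrame(
        {"log2fc": log2fc, "t": t, "p_raw": p_raw, "p_adj": p_adj, "direction": direction},
        index=cohort.gene_ids,
    ).rename_axis("gene")
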
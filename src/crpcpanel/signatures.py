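"""Gene-signature scoring and subgroup marker-gene selection.

A module/panel score for a cell or sample is the sum of per-gene
z-scores over the signature's genes — unweighted, all positive sign, so
scores are exactly additive over disjoint gene sets on the same
z-matrix.

Subgroup-featured genes are the one-vs-rest markers: a gene is featured
for the subgroup where its mean log2(CPM+1) is strictly highest,
provided that subgroup's cells differ significantly from all remaining
cells (moderated t, BH-adjusted) and the gene is detected (raw count
> 0) in more than a minimum fraction of that subgroup's cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .cohort import _moderated_t_arrays
from .datatypes import BulkCohort, CellAnnotation, GeneSet
from .normalize import NormMatrix

logger = logging.getLogger(__name__)


@dataclass
class ModuleScore:
    """Per-unit signature score plus the genes actually used."""

    set_name: str
    scores: pd.Series
    genes_used: list[str]
    genes_missing: list[str]


def module_score(z: pd.DataFrame, gene_set: GeneSet) -> ModuleScore:
    """Sum of per-gene z-scores over the signature, per cell/sample.

    ``z`` is a genes x units z-score matrix (see
    :func:`crpcpanel.normalize.zscore_by_gene`). Signature genes absent
    from the matrix are skipped and reported; zero overlap is fatal.
    """
    present = [g for g in gene_set.genes if g in z.index]
    missing = [g for g in gene_set.genes if g not in z.index]
    if not present:
        raise ValueError(
            f"no gene of set '{gene_set.name}' is present in the matrix: {gene_set.genes}"
        )
    if missing:
        logger.warning("set '%s': %d genes absent and skipped: %s",
                       gene_set.name, len(missing), missing[:10])
    scores = z.loc[present].sum(axis=0)
    scores.name = gene_set.name
    return ModuleScore(gene_set.name, scores, present, missing)


_STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for cut, stars in _STAR_LEVELS:
        if p < cut:
            return stars
    return "ns"


@dataclass
class ScoreComparison:
    mean_a: float
    mean_b: float
    t: float
    p: float
    stars: str


def compare_scores(scores: pd.Series, group_a_ids, group_b_ids) -> ScoreComparison:
    """Welch two-sample t-test between group score distributions."""
    a = scores.loc[list(group_a_ids)].to_numpy(dtype=float)
    b = scores.loc[list(group_b_ids)].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 units")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        logger.warning("degenerate variance in both groups: p set to 1")
        t, p = 0.0, 1.0
    else:
        t, p = scipy.stats.ttest_ind(a, b, equal_var=False)
        t, p = float(t), float(p)
    return ScoreComparison(float(a.mean()), float(b.mean()), t, p, significance_stars(p))


def featured_genes(
    norm: NormMatrix,
    ann: CellAnnotation,
    min_frac: float = 0.20,
    fdr: float = 0.05,
    prior_df: float = 4.0,
) -> pd.DataFrame:
    """One-vs-rest subgroup marker calls with an expressed-fraction filter.

    For each gene, the candidate subgroup is the strict argmax of its
    per-subgroup mean log2(CPM+1) (ties are not called). The candidate
    is tested against all remaining cells with a moderated t; BH
    adjustment runs over all tested genes. A call additionally requires
    the gene to be detected (normalized value > 0, i.e. raw count > 0)
    in more than ``min_frac`` of the candidate subgroup's cells. Each
    gene is featured for at most one subgroup by construction.

    Returns a DataFrame with columns gene, subgroup, mean_in_subgroup,
    max_other_mean, expressed_fraction, t, p_raw, p_adj.
    """
    df = norm.to_frame()
    sub = ann.table.reindex(df.columns)["subgroup"]
    if sub.isna().any():
        raise ValueError("cells missing from annotation")
    subgroups = list(pd.unique(sub))
    if len(subgroups) < 2:
        raise ValueError("need at least 2 subgroups")
    cols_by_sg = {sg: np.flatnonzero((sub == sg).to_numpy()) for sg in subgroups}
    for sg, idx in cols_by_sg.items():
        if len(idx) < 3:
            raise ValueError(f"subgroup '{sg}' has fewer than 3 cells")

    x = df.to_numpy()
    means = np.column_stack([x[:, cols_by_sg[sg]].mean(axis=1) for sg in subgroups])
    order = np.argsort(means, axis=1)
    top, second = order[:, -1], order[:, -2]
    top_mean = means[np.arange(len(df)), top]
    second_mean = means[np.arange(len(df)), second]
    strict = top_mean > second_mean
    n_ties = int((~strict).sum())
    if n_ties:
        logger.info("%d genes with tied maximal mean not called", n_ties)

    # one moderated t per subgroup (vs pooled rest), vectorized over genes
    t_by_sg, p_by_sg = {}, {}
    for k, sg in enumerate(subgroups):
        in_idx = cols_by_sg[sg]
        out_idx = np.setdiff1d(np.arange(x.shape[1]), in_idx)
        a, b = x[:, in_idx], x[:, out_idx]
        na, nb = a.shape[1], b.shape[1]
        d = na + nb - 2
        s2 = ((na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)) / d
        prior_var = float(np.median(s2))
        t_by_sg[k], p_by_sg[k], _ = _moderated_t_arrays(a, b, prior_df, prior_var)

    tested = np.flatnonzero(strict)
    t_sel = np.array([t_by_sg[top[i]][i] for i in tested])
    p_sel = np.array([p_by_sg[top[i]][i] for i in tested])
    p_adj = multipletests(p_sel, method="fdr_bh")[1] if len(tested) else np.array([])

    frac = np.array([
        (x[i, cols_by_sg[subgroups[top[i]]]] > 0).mean() for i in tested
    ])
    keep = (p_adj < fdr) & (frac > min_frac)
    out = pd.DataFrame({
        "gene": [df.index[i] for i in tested],
        "subgroup": [subgroups[top[i]] for i in tested],
        "mean_in_subgroup": top_mean[tested],
        "max_other_mean": second_mean[tested],
        "expressed_fraction": frac,
        "t": t_sel,
        "p_raw": p_sel,
        "p_adj": p_adj,
    })
    return out[keep].sort_values(["subgroup", "p_adj", "gene"]).reset_index(drop=True)


def panel_score_bulk(
    cohort: BulkCohort,
    panel: GeneSet,
    scaling_ids=None,
) -> ModuleScore:
    """Panel z-score sum for bulk samples.

    Expression is taken to log2(x+1) on the scale provided (FPKM-like
    values work directly; use CPM from counts upstream if preferred),
    z-scored per gene across the scaling stratum (default: all samples,
    i.e. the union of every compared group), and summed over the panel.
    """
    ids = list(scaling_ids) if scaling_ids is not None else cohort.sample_ids
    expr = cohort.expression_frame()[ids]
    log_expr = np.log2(expr + 1.0)
    mu = log_expr.mean(axis=1)
    sd = log_expr.std(axis=1, ddof=1)
    z = log_expr.sub(mu, axis=0).div(sd.where(sd > 0, 1.0), axis=0)
    z[sd == 0] = 0.0
    return module_score(z, panel)
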
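"""Synthetic single-cell and bulk cohorts with planted ground truth.

The single-cell generator draws negative-binomial counts
(variance = mean + dispersion * mean^2, dispersion shared across genes)
around a common baseline mean, with per-cell library-size factors drawn
log-normal so CPM normalization is non-trivial. Each subgroup gets a
disjoint block of marker genes whose mean is multiplied by
2**marker_log2fc in the home subgroup, and an optional ligand/receptor
plant co-elevates one gene in a source subgroup and one in a target
subgroup.

The bulk generator emulates a TCGA-style cohort: normal samples, tumor
samples with/without recurrence, and hormone-treated recurrent /
non-recurrent samples. Expression is baseline-normal on the log2 scale
(stored as 2**g - 1 so that log2(x+1) recovers the log scale exactly);
panel genes receive an additive log-scale shift in the recurrent tumor
groups, and recurrence times decrease linearly in the planted true
score, giving the negative score-time association the evaluation stage
should recover.

Determinism: one generator seeded once per simulation; the draw order
is fixed (single-cell: size factors, then the count matrix in one call;
bulk: gene baselines, then the expression noise matrix, then time
noise), so identical configs and seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import PANEL_6, BulkCohort, CellAnnotation, CountMatrix, GeneSet

BULK_GROUPS = ("normal", "tumor_norec", "tumor_rec", "HT_norec", "HT_rec")

#: Default group sizes: the hormone-therapy strata match the cohort the
#: panel targets (14 recurrent / 53 non-recurrent hormone-treated
#: samples); the remaining groups approximate a TCGA-PRAD-sized cohort.
DEFAULT_N_PER_GROUP = {
    "normal": 52,
    "tumor_norec": 300,
    "tumor_rec": 60,
    "HT_norec": 53,
    "HT_rec": 14,
}


@dataclass
class SCSimConfig:
    n_subgroups: int = 3
    cells_per_subgroup: tuple = (200, 200, 200)
    n_genes: int = 1000
    markers_per_subgroup: int = 20
    marker_log2fc: float = 3.0
    baseline_mean: float = 0.5
    nb_dispersion: float = 0.5
    library_size_sd: float = 0.3
    lr_plant: tuple | None = None  # (ligand, receptor, source_sg, target_sg, fold)
    seed: int = 0


@dataclass
class BulkSimConfig:
    n_per_group: dict = field(default_factory=lambda: dict(DEFAULT_N_PER_GROUP))
    panel: GeneSet = field(default_factory=lambda: GeneSet(PANEL_6.name, PANEL_6.genes))
    n_genes: int = 2000
    panel_shift: float = 2.0
    gene_noise_sd: float = 1.0
    baseline_range: tuple = (2.0, 8.0)
    time_intercept: float = 1200.0
    time_beta: float = -50.0
    time_noise_sd: float = 200.0
    seed: int = 0


def _subgroup_names(n: int) -> list[str]:
    return [f"S{i + 1}" for i in range(n)]


def simulate_sc(config: SCSimConfig) -> tuple[CountMatrix, CellAnnotation, pd.DataFrame]:
    """Generate a single-cell cohort with planted subgroup markers.

    Returns (counts, annotation, truth) where truth lists each planted
    marker gene with its home subgroup, plus any ligand/receptor plant.
    """
    k, n_genes = config.n_subgroups, config.n_genes
    sizes = list(config.cells_per_subgroup)
    if len(sizes) != k:
        raise ValueError("cells_per_subgroup length must equal n_subgroups")
    if config.markers_per_subgroup * k > n_genes:
        raise ValueError(
            f"{config.markers_per_subgroup} markers x {k} subgroups exceed {n_genes} genes"
        )
    subgroups = _subgroup_names(k)
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    cell_ids, labels = [], []
    for sg, size in zip(subgroups, sizes):
        for j in range(size):
            cell_ids.append(f"{sg}_c{j + 1:04d}")
            labels.append(sg)
    n_cells = len(cell_ids)

    mu = np.full((n_genes, n_cells), float(config.baseline_mean))
    truth_rows = []
    for si, sg in enumerate(subgroups):
        gidx = np.arange(si * config.markers_per_subgroup,
                         (si + 1) * config.markers_per_subgroup)
        cidx = np.flatnonzero(np.array(labels) == sg)
        mu[np.ix_(gidx, cidx)] *= 2.0 ** config.marker_log2fc
        for gi in gidx:
            truth_rows.append({"gene": gene_ids[gi], "subgroup": sg, "role": "marker"})

    if config.lr_plant is not None:
        lig, rec, src, tgt, fold = config.lr_plant
        for g in (lig, rec):
            if g not in gene_ids:
                raise ValueError(f"planted gene '{g}' not in the simulated gene universe")
        lab = np.array(labels)
        mu[gene_ids.index(lig), lab == src] *= fold
        mu[gene_ids.index(rec), lab == tgt] *= fold
        truth_rows.append({"gene": lig, "subgroup": src, "role": "ligand"})
        truth_rows.append({"gene": rec, "subgroup": tgt, "role": "receptor"})

    rng = np.random.default_rng(config.seed)
    size_factors = np.exp(rng.normal(0.0, config.library_size_sd, n_cells))
    mu = mu * size_factors[None, :]
    if config.nb_dispersion <= 1e-8:  # Poisson limit
        counts = rng.poisson(mu)
    else:
        n_param = 1.0 / config.nb_dispersion
        p_param = n_param / (n_param + mu)
        counts = rng.negative_binomial(n_param, p_param)

    ann = CellAnnotation(pd.DataFrame(
        {"dataset_id": "sim", "lineage": "epithelial", "subgroup": labels},
        index=pd.Index(cell_ids, name="cell_id"),
    ))
    truth = pd.DataFrame(truth_rows)
    return CountMatrix(gene_ids, cell_ids, counts.astype(np.int64)), ann, truth


def simulate_bulk(config: BulkSimConfig) -> tuple[BulkCohort, pd.DataFrame]:
    """Generate a bulk cohort with a planted panel effect.

    Returns (cohort, truth) where truth has per-sample group label and
    planted true score. Positive classes (tumor_rec, HT_rec) carry the
    additive panel shift; recurrence times exist only for recurrent
    samples and decrease with the true score when time_beta < 0.
    """
    n_per_group = {g: int(config.n_per_group.get(g, 0)) for g in BULK_GROUPS}
    panel_genes = list(config.panel.genes)
    if config.n_genes < len(panel_genes):
        raise ValueError("n_genes smaller than the panel")
    fillers = [f"B{i + 1:05d}" for i in range(config.n_genes - len(panel_genes))]
    gene_ids = panel_genes + fillers
    panel_idx = np.arange(len(panel_genes))

    sample_ids, groups = [], []
    for g in BULK_GROUPS:
        for j in range(n_per_group[g]):
            sample_ids.append(f"{g}_s{j + 1:04d}")
            groups.append(g)
    groups_arr = np.array(groups)
    n_samples = len(sample_ids)
    if n_samples == 0:
        raise ValueError("empty cohort")

    rng = np.random.default_rng(config.seed)
    lo, hi = config.baseline_range
    baseline = rng.uniform(lo, hi, config.n_genes)
    g_mat = baseline[:, None] + rng.normal(0.0, config.gene_noise_sd,
                                           (config.n_genes, n_samples))
    positive = np.isin(groups_arr, ("tumor_rec", "HT_rec"))
    g_mat[np.ix_(panel_idx, np.flatnonzero(positive))] += config.panel_shift
    g_mat = np.clip(g_mat, 0.0, None)
    expression = 2.0 ** g_mat - 1.0

    true_score = ((g_mat[panel_idx, :] - baseline[panel_idx, None])
                  / config.gene_noise_sd).sum(axis=0)

    recurrent = np.isin(groups_arr, ("tumor_rec", "HT_rec"))
    time_noise = rng.normal(0.0, config.time_noise_sd, n_samples)
    times = np.where(
        recurrent,
        np.maximum(1.0, config.time_intercept + config.time_beta * true_score + time_noise),
        np.nan,
    )

    sample_type = np.where(groups_arr == "normal", "Solid Tissue Normal", "Primary Tumor")
    recurrence = np.where(groups_arr == "normal", None,
                          np.where(recurrent, "YES", "NO"))
    therapy = np.where(np.isin(groups_arr, ("HT_norec", "HT_rec")), "Hormone Therapy",
                       np.where(groups_arr == "normal", None, "Radiation Therapy"))
    phenotype = pd.DataFrame(
        {
            "sample_type": sample_type,
            "recurrence": recurrence,
            "therapy_type": therapy,
            "recurrence_time_days": times,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    cohort = BulkCohort(gene_ids, sample_ids, expression, phenotype)
    truth = pd.DataFrame(
        {"group": groups_arr, "true_score": true_score, "recurrence_time_days": times},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return cohort, truth
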
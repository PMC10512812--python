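"""Ligand–receptor communication intensity between cell subgroups.

A directed candidate (L, R) exists for every protein–protein
interaction pair whose ligand side is annotated secreted and whose
receptor side is annotated plasma-membrane. The intensity from source
subgroup A to target subgroup B is the sum over candidates of
mean_A(L) * mean_B(R), means taken on the log2(CPM+1) scale.

Significance comes from a label permutation null: subgroup labels are
shuffled across all annotated cells (subgroup sizes preserved) and the
intensity recomputed; the p-value is the add-one rank
(1 + #{permuted >= observed}) / (1 + n_perm), which can never be zero.
When the number of distinct label arrangements is small the sampling is
replaced by exhaustive enumeration and the p-value is the exact
fraction of arrangements at least as extreme (the observed arrangement
counts itself, so p >= 1/n_arrangements).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CellAnnotation, LRModel
from .normalize import NormMatrix

logger = logging.getLogger(__name__)


def lr_pairs(model: LRModel) -> list[tuple[str, str]]:
    """Directed (ligand, receptor) candidates from the interaction table.

    A gene annotated both secreted and membrane can appear on either
    side; an interaction of two such genes yields both directions.
    """
    out: set[tuple[str, str]] = set()
    for pair in model.pairs:
        members = sorted(pair)
        a = members[0]
        b = members[1] if len(members) == 2 else members[0]
        for lig, rec in ((a, b), (b, a)):
            if lig in model.secreted and rec in model.membrane:
                out.add((lig, rec))
    return sorted(out)


@dataclass
class LRIntensity:
    """Communication intensity A -> B with optional permutation p-value."""

    source_subgroup: str
    target_subgroup: str
    intensity: float
    pair_contributions: list[tuple[str, str, float]]
    p_perm: float | None = None
    n_perm: int = 0
    seed: int | None = None
    exhaustive: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(self.source_subgroup, self.target_subgroup, lig, rec, c)
             for lig, rec, c in self.pair_contributions],
            columns=["source", "target", "ligand", "receptor", "contribution"],
        )


def _usable_pairs(model: LRModel, gene_index: dict[str, int]) -> list[tuple[str, str]]:
    return [(l, r) for l, r in lr_pairs(model) if l in gene_index and r in gene_index]


def _sorted_contributions(pairs, contrib):
    rows = [(l, r, float(c)) for (l, r), c in zip(pairs, contrib)]
    rows.sort(key=lambda t: (-t[2], t[0], t[1]))
    return rows


def lr_intensity(
    norm: NormMatrix,
    ann: CellAnnotation,
    model: LRModel,
    source: str,
    target: str,
) -> LRIntensity:
    """Observed intensity between two subgroups (autocrine allowed)."""
    df = norm.to_frame()
    sub = ann.table.reindex(df.columns)["subgroup"]
    a_cells = list(sub.index[sub == source])
    b_cells = list(sub.index[sub == target])
    if not a_cells or not b_cells:
        raise ValueError(f"source '{source}' or target '{target}' has no cells")
    gene_index = {g: i for i, g in enumerate(df.index)}
    pairs = _usable_pairs(model, gene_index)
    if not pairs:
        logger.warning("no usable ligand-receptor pair in the gene universe: intensity 0")
        return LRIntensity(source, target, 0.0, [])
    mean_a = df[a_cells].mean(axis=1)
    mean_b = df[b_cells].mean(axis=1)
    contrib = [mean_a[l] * mean_b[r] for l, r in pairs]
    rows = _sorted_contributions(pairs, contrib)
    return LRIntensity(source, target, float(sum(contrib)), rows)


def _perm_intensities(x_l, x_r, l_idx, r_idx, a_ind, b_ind, n_a, n_b):
    """Intensity per permutation from indicator matrices (cells x nperm)."""
    mean_a = x_l @ a_ind / n_a  # ligands x nperm
    mean_b = x_r @ b_ind / n_b
    return (mean_a[l_idx, :] * mean_b[r_idx, :]).sum(axis=0)


def lr_permutation_p(
    norm: NormMatrix,
    ann: CellAnnotation,
    model: LRModel,
    source: str,
    target: str,
    n_perm: int = 1000,
    seed: int | None = None,
    exhaustive_cap: int = 20000,
    restrict_to_pair: bool = False,
) -> LRIntensity:
    """Permutation-tested intensity between two subgroups.

    Labels are shuffled over all annotated cells present in the matrix
    (``restrict_to_pair=True`` shuffles only over the source∪target
    cells instead). Ties between permuted and observed intensities
    count as "at least as extreme" (conservative). When the number of
    distinct (source-set, target-set) arrangements is at most
    ``exhaustive_cap`` the exact enumeration p-value replaces sampling.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    obs = lr_intensity(norm, ann, model, source, target)
    if not obs.pair_contributions:
        obs.p_perm, obs.n_perm, obs.seed = 1.0, 0, seed
        return obs

    df = norm.to_frame()
    sub = ann.table.reindex(df.columns)["subgroup"]
    if restrict_to_pair:
        keep = sub.isin([source, target])
        df, sub = df.loc[:, keep.to_numpy()], sub[keep]
    n = df.shape[1]
    n_a = int((sub == source).sum())
    n_b = int((sub == target).sum())
    autocrine = source == target

    gene_index = {g: i for i, g in enumerate(df.index)}
    pairs = _usable_pairs(model, gene_index)
    ligands = sorted({l for l, _ in pairs})
    receptors = sorted({r for _, r in pairs})
    l_idx = np.array([ligands.index(l) for l, _ in pairs])
    r_idx = np.array([receptors.index(r) for _, r in pairs])
    x_l = df.loc[ligands].to_numpy()
    x_r = df.loc[receptors].to_numpy()

    if autocrine:
        n_arr = math.comb(n, n_a)
    else:
        n_arr = math.comb(n, n_a) * math.comb(n - n_a, n_b)

    if n_arr <= exhaustive_cap:
        intensities = []
        cells = np.arange(n)
        for a_set in itertools.combinations(cells, n_a):
            a_arr = np.array(a_set)
            if autocrine:
                b_choices = [a_arr]
            else:
                rest = np.setdiff1d(cells, a_arr)
                b_choices = (np.array(c) for c in itertools.combinations(rest, n_b))
            for b_arr in b_choices:
                mean_a = x_l[:, a_arr].mean(axis=1)
                mean_b = x_r[:, b_arr].mean(axis=1)
                intensities.append(float((mean_a[l_idx] * mean_b[r_idx]).sum()))
        intensities = np.array(intensities)
        p = float((intensities >= obs.intensity - 1e-12).sum()) / n_arr
        obs.p_perm, obs.n_perm, obs.seed, obs.exhaustive = p, n_arr, seed, True
        return obs

    rng = np.random.default_rng(seed)
    a_ind = np.zeros((n, n_perm))
    b_ind = np.zeros((n, n_perm))
    for j in range(n_perm):
        perm = rng.permutation(n)
        a_cells = perm[:n_a]
        b_cells = a_cells if autocrine else perm[n_a:n_a + n_b]
        a_ind[a_cells, j] = 1.0
        b_ind[b_cells, j] = 1.0
    perm_int = _perm_intensities(x_l, x_r, l_idx, r_idx, a_ind, b_ind, n_a, n_b)
    r = int((perm_int >= obs.intensity - 1e-12).sum())
    obs.p_perm = (1 + r) / (1 + n_perm)
    obs.n_perm, obs.seed = n_perm, seed
    return obs


def rank_pairs(results, top_k: int = 20) -> pd.DataFrame:
    """Pool pair contributions across subgroup combinations; top-k table.

    Sorted by contribution descending; ties broken lexicographically by
    (ligand, receptor, source, target) so the ranking is deterministic.
    """
    results = list(results)
    if not results:
        raise ValueError("no results to rank")
    rows = []
    for res in results:
        for lig, rec, c in res.pair_contributions:
            rows.append((lig, rec, res.source_subgroup, res.target_subgroup, c))
    rows.sort(key=lambda t: (-t[4], t[0], t[1], t[2], t[3]))
    return pd.DataFrame(
        rows[:top_k],
        columns=["ligand", "receptor", "source", "target", "contribution"],
    )
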
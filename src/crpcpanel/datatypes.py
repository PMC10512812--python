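"""Core in-memory containers shared by every pipeline stage.

The pipeline moves between four substrates: raw single-cell (or bulk)
counts, per-cell annotations, a bulk cohort with clinical phenotype, and
the ligand–receptor universe (protein locations + interaction pairs).
Each container validates its invariants on construction so that
downstream stages can assume clean inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Closed vocabulary of cell lineages used for annotation.
LINEAGES = frozenset({"epithelial", "endothelial", "stroma", "myeloid", "mast", "T", "B"})

#: Recurrence is tri-state: "YES", "NO", or missing (None / NaN).
RECURRENCE_STATES = ("YES", "NO")


def _check_unique(ids, what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValueError(f"duplicate {what} identifiers: {sorted(set(dups))[:10]}")


@dataclass
class CountMatrix:
    """Genes x cells (or samples) matrix of non-negative integer counts."""

    gene_ids: list[str]
    cell_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(map(str, self.gene_ids))
        self.cell_ids = list(map(str, self.cell_ids))
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise ValueError("counts must be integers")
            self.counts = as_int
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class CellAnnotation:
    """Per-cell dataset, lineage and subgroup labels.

    ``table`` is indexed by cell id with columns ``dataset_id``,
    ``lineage`` and ``subgroup``. Lineage comes from the closed
    vocabulary :data:`LINEAGES`; subgroup is a free non-empty label
    (luminal, basal, CAF, ...).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"dataset_id", "lineage", "subgroup"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation table missing columns: {sorted(missing)}")
        _check_unique(list(self.table.index), "cell")
        bad_lineage = set(self.table["lineage"]) - LINEAGES
        if bad_lineage:
            raise ValueError(f"unknown lineage labels: {sorted(bad_lineage)}")
        empty = self.table["subgroup"].astype(str).str.len() == 0
        if empty.any():
            raise ValueError("empty subgroup label for cells: "
                             f"{list(self.table.index[empty])[:10]}")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.table.index)

    def subgroup_of(self, cells) -> pd.Series:
        return self.table.loc[cells, "subgroup"]

    def cells_in_subgroup(self, subgroup: str) -> list[str]:
        return list(self.table.index[self.table["subgroup"] == subgroup])


PHENOTYPE_COLUMNS = ["sample_type", "recurrence", "therapy_type", "recurrence_time_days"]


@dataclass
class BulkCohort:
    """Bulk expression (genes x samples) plus per-sample clinical phenotype.

    Phenotype fields mirror the clinical table of a TCGA-style cohort:
    ``sample_type`` (e.g. "Solid Tissue Normal" vs tumor types),
    ``recurrence`` ("YES"/"NO"/missing — new tumor event after initial
    treatment), ``therapy_type`` (free text; hormone therapy is matched
    by substring) and ``recurrence_time_days`` (only meaningful when
    recurrence is "YES").
    """

    gene_ids: list[str]
    sample_ids: list[str]
    expression: np.ndarray
    phenotype: pd.DataFrame

    def __post_init__(self) -> None:
        self.gene_ids = list(map(str, self.gene_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        self.expression = np.asarray(self.expression, dtype=float)
        if self.expression.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("expression shape does not match gene/sample lists")
        if np.isnan(self.expression).any():
            raise ValueError("expression contains NaN")
        if (self.expression < 0).any():
            raise ValueError("expression contains negative values")
        missing = set(PHENOTYPE_COLUMNS) - set(self.phenotype.columns)
        if missing:
            raise ValueError(f"phenotype missing columns: {sorted(missing)}")
        if list(self.phenotype.index) != self.sample_ids:
            self.phenotype = self.phenotype.reindex(self.sample_ids)
        rec = self.phenotype["recurrence"]
        bad = rec.dropna()[~rec.dropna().isin(RECURRENCE_STATES)]
        if len(bad):
            raise ValueError(f"invalid recurrence values: {sorted(set(bad))}")
        # recurrence time only meaningful for recurrence == YES
        t = self.phenotype["recurrence_time_days"]
        misplaced = t.notna() & (rec != "YES")
        if misplaced.any():
            raise ValueError(
                "recurrence_time_days present for non-recurrent samples: "
                f"{list(self.phenotype.index[misplaced])[:10]}"
            )
        if (t.dropna() < 0).any():
            raise ValueError("negative recurrence times")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def expression_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.expression, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class GeneSet:
    """Named ordered list of gene symbols (a panel or a module)."""

    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        self.genes = list(map(str, self.genes))
        if not self.genes:
            raise ValueError(f"gene set '{self.name}' is empty")
        _check_unique(self.genes, "gene-set")

    def __len__(self) -> int:
        return len(self.genes)

    def union(self, other: "GeneSet", name: str | None = None) -> "GeneSet":
        extra = [g for g in other.genes if g not in self.genes]
        return GeneSet(name or f"{self.name}+{other.name}", self.genes + extra)


#: The six epithelial-feature genes of the core panel.
PANEL_6 = GeneSet("panel6", ["PEG10", "CCDC74A", "PPIB", "GAPDH", "AR", "EPCAM"])

#: The extended panel adding six tumor-microenvironment genes
#: (CAF activation, immunosuppressive cytokines, T-cell exhaustion markers).
PANEL_12 = GeneSet(
    "panel12",
    PANEL_6.genes + ["FAP", "IL10", "TGFB1", "TIGIT", "LAG3", "PDCD1"],
)


@dataclass
class LRModel:
    """Ligand–receptor universe: protein location flags + interaction pairs.

    ``secreted`` and ``membrane`` are sets of gene symbols (a gene may be
    in both); ``pairs`` holds unordered interaction pairs as frozensets
    (a singleton frozenset encodes a self-interaction).
    """

    secreted: set[str] = field(default_factory=set)
    membrane: set[str] = field(default_factory=set)
    pairs: set[frozenset] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.secreted = set(map(str, self.secreted))
        self.membrane = set(map(str, self.membrane))
        self.pairs = {frozenset(map(str, p)) for p in self.pairs}
        for p in self.pairs:
            if not 1 <= len(p) <= 2:
                raise ValueError(f"malformed interaction pair: {set(p)}")

    @property
    def gene_universe(self) -> set[str]:
        out = set(self.secreted) | set(self.membrane)
        for p in self.pairs:
            out |= set(p)
        return out
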
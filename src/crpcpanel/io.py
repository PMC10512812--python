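"""Readers and writers for the on-disk formats the pipeline touches.

Single-cell counts travel as Matrix Market (.mtx) plus one-identifier-
per-line gene/barcode files (the CellRanger-style triplet) or as dense
delimited text. Bulk expression, phenotype tables, protein locations and
interaction pairs are TSV/CSV; gene sets are GMT or one-gene-per-line
text. All outputs are TSV with a header row.

Delimiters are auto-detected between tab and comma unless ``sep`` is
given. Empty strings and "NA" are both treated as missing.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import (
    PHENOTYPE_COLUMNS,
    BulkCohort,
    CellAnnotation,
    CountMatrix,
    GeneSet,
    LRModel,
)

logger = logging.getLogger(__name__)

_NA_STRINGS = {"", "NA", "na", "NaN", "nan", "None"}

# Xena-style clinical column names accepted as synonyms.
_PHENO_SYNONYMS = {
    "sample_type.sample": "sample_type",
    "new_tumor_event_after_initial_treatment": "recurrence",
    "new_tumor_event_dx_days_to": "recurrence_time_days",
}


def _detect_sep(path, sep: str | None) -> str:
    if sep is not None:
        return sep
    with open(path) as fh:
        head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") else ","


def make_unique(names: list[str]) -> list[str]:
    """Disambiguate duplicates R-style: second ACTB becomes ACTB.1, etc."""
    counts: dict[str, int] = {}
    out = []
    for n in names:
        if n in counts:
            counts[n] += 1
            new = f"{n}.{counts[n]}"
            while new in counts:
                counts[n] += 1
                new = f"{n}.{counts[n]}"
            out.append(new)
            counts[new] = 0
        else:
            counts[n] = 0
            out.append(n)
    return out


def _read_id_column(path, sep: str | None) -> list[str]:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            ids.append(re.split(r"[\t,]", line)[0] if sep is None else line.split(sep)[0])
    return ids


def read_count_matrix(path_matrix, path_genes, path_cells, sep: str | None = None) -> CountMatrix:
    """Load a count matrix from MTX or dense text plus identifier files.

    Duplicated gene symbols are made unique by suffixing (".1", ".2", ...)
    with a logged warning. Dimension mismatches and negative entries are
    fatal.
    """
    path_matrix = Path(path_matrix)
    with open(path_matrix) as fh:
        first = fh.readline()
    if path_matrix.suffix == ".mtx" or first.startswith("%%MatrixMarket"):
        mat = scipy.io.mmread(path_matrix)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat)
    else:
        mat = pd.read_csv(path_matrix, sep=_detect_sep(path_matrix, sep), header=None).to_numpy()
    if mat.size == 0:
        raise ValueError(
            f"dimension mismatch between {path_matrix}, {path_genes}, {path_cells}: "
            "empty matrix"
        )
    if np.isnan(mat.astype(float)).any():
        raise ValueError(f"count matrix {path_matrix} contains NaN")
    if (mat < 0).any():
        raise ValueError(f"count matrix {path_matrix} contains negative entries")

    genes = _read_id_column(path_genes, sep)
    cells = _read_id_column(path_cells, sep)
    if mat.shape != (len(genes), len(cells)):
        raise ValueError(
            f"dimension mismatch between {path_matrix} (shape {mat.shape}), "
            f"{path_genes} ({len(genes)} genes), {path_cells} ({len(cells)} cells)"
        )
    if len(set(genes)) != len(genes):
        logger.warning("duplicate gene symbols in %s made unique by suffixing", path_genes)
        genes = make_unique(genes)
    if len(set(cells)) != len(cells):
        logger.warning("duplicate cell ids in %s made unique by suffixing", path_cells)
        cells = make_unique(cells)
    return CountMatrix(genes, cells, np.rint(mat).astype(np.int64))


def write_count_matrix(cm: CountMatrix, out_dir) -> None:
    """Write matrix.mtx + genes.tsv + barcodes.tsv under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out / "matrix.mtx", scipy.sparse.coo_matrix(cm.counts), field="integer")
    (out / "genes.tsv").write_text("".join(g + "\n" for g in cm.gene_ids))
    (out / "barcodes.tsv").write_text("".join(c + "\n" for c in cm.cell_ids))


def read_cell_annotation(path, sep: str | None = None) -> CellAnnotation:
    """Read a per-cell annotation TSV/CSV with columns
    cell_id, dataset_id, lineage, subgroup (header required)."""
    df = pd.read_csv(path, sep=_detect_sep(path, sep), dtype=str)
    if "cell_id" in df.columns:
        df = df.set_index("cell_id")
    else:
        df = df.set_index(df.columns[0])
    return CellAnnotation(df)


def write_cell_annotation(ann: CellAnnotation, path) -> None:
    ann.table.rename_axis("cell_id").to_csv(path, sep="\t")


def read_bulk_cohort(path_expression, path_phenotype, sep: str | None = None) -> BulkCohort:
    """Load a bulk cohort: genes x samples expression + phenotype table.

    Samples present in the expression matrix but absent from the
    phenotype table are retained with all phenotype fields missing (a
    warning is logged). A recurrent sample with no recorded time keeps
    recurrence = "YES" with a missing time and is flagged in the log.
    """
    expr = pd.read_csv(path_expression, sep=_detect_sep(path_expression, sep), index_col=0)
    expr_vals = expr.to_numpy(dtype=float)
    if np.isnan(expr_vals).any():
        raise ValueError(f"expression matrix {path_expression} contains NaN")
    if (expr_vals < 0).any():
        raise ValueError(f"expression matrix {path_expression} contains negative values")

    pheno = pd.read_csv(path_phenotype, sep=_detect_sep(path_phenotype, sep), dtype=str)
    pheno = pheno.rename(columns=_PHENO_SYNONYMS)
    pheno = pheno.set_index(pheno.columns[0])
    samples = [str(s) for s in expr.columns]
    overlap = set(samples) & set(pheno.index.astype(str))
    if not overlap:
        raise ValueError(
            f"no overlapping sample ids between {path_expression} and {path_phenotype}"
        )
    missing_pheno = [s for s in samples if s not in set(pheno.index.astype(str))]
    if missing_pheno:
        logger.warning(
            "%d samples have no phenotype entry and get missing fields: %s",
            len(missing_pheno), missing_pheno[:5],
        )
    pheno = pheno.reindex(samples)
    for col in PHENOTYPE_COLUMNS:
        if col not in pheno.columns:
            pheno[col] = None
    for col in ("sample_type", "recurrence", "therapy_type"):
        pheno[col] = pheno[col].map(
            lambda v: None if (pd.isna(v) or str(v).strip() in _NA_STRINGS) else str(v).strip()
        )
    times = pd.to_numeric(
        pheno["recurrence_time_days"].map(
            lambda v: np.nan if (pd.isna(v) or str(v).strip() in _NA_STRINGS) else v
        ),
        errors="coerce",
    )
    flagged = (pheno["recurrence"] == "YES") & times.isna()
    if flagged.any():
        logger.warning(
            "recurrent samples without recurrence time: %s",
            list(pheno.index[flagged])[:10],
        )
    times[pheno["recurrence"] != "YES"] = np.nan
    pheno["recurrence_time_days"] = times
    return BulkCohort(
        gene_ids=[str(g) for g in expr.index],
        sample_ids=samples,
        expression=expr_vals,
        phenotype=pheno[PHENOTYPE_COLUMNS],
    )


def read_gene_set(path, name: str | None = None) -> GeneSet:
    """Read a gene set from GMT (first line: name, description, genes...)
    or one-gene-per-line text."""
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    if lines and "\t" in lines[0] and len(lines[0].split("\t")) > 2:
        fields = lines[0].split("\t")
        return GeneSet(name or fields[0], [g for g in fields[2:] if g])
    return GeneSet(name or path.stem, [ln.split("\t")[0].strip() for ln in lines])


def read_lr_model(path_locations, path_pairs, sep: str | None = None) -> LRModel:
    """Build the ligand–receptor universe from a protein-location table
    and an interaction-pair table.

    Secreted = location list contains the token "Secreted"; membrane =
    contains "Plasma membrane" (multi-valued locations are split on
    ';' or ','). Pairs are deduplicated as unordered; a pair whose gene
    is absent from the locations table is kept with a warning.
    """
    loc = pd.read_csv(path_locations, sep=_detect_sep(path_locations, sep), dtype=str)
    gene_col, loc_col = loc.columns[0], loc.columns[1]
    secreted: set[str] = set()
    membrane: set[str] = set()
    located: set[str] = set()
    for gene, locs in zip(loc[gene_col], loc[loc_col]):
        if pd.isna(gene):
            continue
        gene = str(gene).strip()
        located.add(gene)
        tokens = {t.strip() for t in re.split(r"[;,]", str(locs))} if pd.notna(locs) else set()
        if "Secreted" in tokens:
            secreted.add(gene)
        if "Plasma membrane" in tokens:
            membrane.add(gene)

    pair_df = pd.read_csv(path_pairs, sep=_detect_sep(path_pairs, sep), dtype=str)
    pairs: set[frozenset] = set()
    unlocated = set()
    for a, b in zip(pair_df.iloc[:, 0], pair_df.iloc[:, 1]):
        if pd.isna(a) or pd.isna(b):
            continue
        a, b = str(a).strip(), str(b).strip()
        pairs.add(frozenset((a, b)))
        unlocated |= {g for g in (a, b) if g not in located}
    if unlocated:
        logger.warning(
            "%d pair genes absent from the locations table (kept): %s",
            len(unlocated), sorted(unlocated)[:10],
        )
    return LRModel(secreted=secreted, membrane=membrane, pairs=pairs)


def write_table(df: pd.DataFrame, path, index_label: str | None = None) -> None:
    """Write any tabular output as TSV with a header row."""
    if index_label is not None:
        df.rename_axis(index_label).to_csv(path, sep="\t")
    else:
        df.to_csv(path, sep="\t", index=False)
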
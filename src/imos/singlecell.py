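"""Single-cell QC, library-size normalization and cell-type specificity.

QC applies the three per-cell metrics — total UMI count, detected
genes, mitochondrial fraction — with *strict* inequality semantics:
cells below 2000 UMI, below 500 genes or above 10% mitochondrial counts
are removed, and suspected doublets (more than 40,000 UMI AND more than
5000 detected genes) are removed; cells sitting exactly on a threshold
are kept.  Clustering/annotation is out of scope: cell-type labels are
inputs, and the specificity score just asks which labeled population
dominates a gene's normalized expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datamodel import SingleCellDataset, ValidationError

logger = logging.getLogger("imos.singlecell")

__all__ = [
    "CellQcMetrics",
    "SpecificityResult",
    "compute_qc",
    "qc_filter",
    "normalize_log1p",
    "specificity_score",
]


@dataclass
class CellQcMetrics:
    cell_id: str
    umi_total: int
    genes_detected: int
    mito_fraction: float


@dataclass
class SpecificityResult:
    gene_id: str
    label_means: dict[str, float]
    dominant_label: str
    specificity_score: float
    tie_flag: bool = False


def compute_qc(dataset: SingleCellDataset) -> list[CellQcMetrics]:
    """Per-cell UMI total, detected-gene count and mitochondrial fraction.

    mito_fraction is mito counts / total UMI, defined as 0 for empty cells.
    """
    counts = dataset.counts
    umi = np.asarray(counts.sum(axis=1)).ravel()
    genes = counts.getnnz(axis=1)
    mito_idx = [i for i, g in enumerate(dataset.gene_ids) if g in dataset.mito_genes]
    if mito_idx:
        mito = np.asarray(counts[:, mito_idx].sum(axis=1)).ravel()
    else:
        mito = np.zeros_like(umi)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(umi > 0, mito / np.maximum(umi, 1), 0.0)
    return [
        CellQcMetrics(c, int(u), int(g), float(f))
        for c, u, g, f in zip(dataset.cell_ids, umi, genes, frac)
    ]


def qc_filter(
    dataset: SingleCellDataset,
    min_umi: int = 2000,
    min_genes: int = 500,
    max_mito: float = 0.10,
    doublet_umi: int = 40000,
    doublet_genes: int = 5000,
) -> tuple[SingleCellDataset, pd.DataFrame]:
    """Remove low-quality cells and suspected doublets.

    Removal rules (strict inequalities; boundary cells are kept):
    umi < min_umi, genes < min_genes, mito > max_mito, or
    (umi > doublet_umi AND genes > doublet_genes).  Returns the filtered
    dataset and a per-cell log with kept flag and removal reasons.
    """
    metrics = compute_qc(dataset)
    keep_idx, rows = [], []
    for i, m in enumerate(metrics):
        reasons = []
        if m.umi_total < min_umi:
            reasons.append("low_umi")
        if m.genes_detected < min_genes:
            reasons.append("low_genes")
        if m.mito_fraction > max_mito:
            reasons.append("high_mito")
        if m.umi_total > doublet_umi and m.genes_detected > doublet_genes:
            reasons.append("doublet")
        kept = not reasons
        if kept:
            keep_idx.append(i)
        rows.append({
            "cell_id": m.cell_id, "umi": m.umi_total, "genes": m.genes_detected,
            "mito_fraction": m.mito_fraction, "kept": kept,
            "reasons": ";".join(reasons),
        })
    log = pd.DataFrame(rows).set_index("cell_id")
    if not keep_idx:
        raise ValidationError(
            "QC removed every cell; review thresholds against the library depth"
        )
    n_removed = dataset.n_cells - len(keep_idx)
    if n_removed:
        logger.info("QC removed %d of %d cells", n_removed, dataset.n_cells)
    return dataset.subset_cells(np.asarray(keep_idx)), log


def normalize_log1p(dataset: SingleCellDataset, target_sum: float = 10_000.0) -> pd.DataFrame:
    """Library-size correction to ``target_sum`` per cell, then log1p.

    Returns a dense cells x genes DataFrame of log-normalized expression.
    Cells with zero UMI should have been removed by QC and raise.
    """
    umi = np.asarray(dataset.counts.sum(axis=1)).ravel()
    if (umi == 0).any():
        bad = [c for c, u in zip(dataset.cell_ids, umi) if u == 0]
        raise ValidationError(f"zero-UMI cells present (QC should remove them): {bad[:5]}")
    scale = sp.diags(target_sum / umi)
    normalized = scale @ dataset.counts
    out = normalized.toarray()
    np.log1p(out, out=out)
    return pd.DataFrame(out, index=dataset.cell_ids, columns=dataset.gene_ids)


def specificity_score(
    normalized: pd.DataFrame,
    labels,
    gene_id: str,
    eps: float = 1e-9,
) -> SpecificityResult:
    """Which cell type dominates a gene's expression, and how strongly.

    Per-label mean normalized expression is computed; the score is
    max(mean) / (sum of means + eps), in [0, 1] — 1 means the gene is
    expressed in a single labeled population, 1/k means uniform across k
    labels.  Ties on the max go to the lexicographically first label and
    are flagged.
    """
    if gene_id not in normalized.columns:
        raise ValidationError(f"gene {gene_id!r} absent from normalized matrix")
    lab = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    lab = lab.reindex(normalized.index)
    if lab.isna().any():
        raise ValidationError("every cell needs a label")
    distinct = sorted(lab.unique())
    if len(distinct) < 2:
        raise ValidationError("specificity needs >=2 distinct cell-type labels")
    means = normalized[gene_id].groupby(lab).mean()
    means = means.reindex(distinct)
    max_val = float(means.max())
    dominant_candidates = sorted(means.index[means == max_val])
    dominant = dominant_candidates[0]
    score = max_val / (float(means.sum()) + eps) if means.sum() > 0 else 0.0
    return SpecificityResult(
        gene_id=gene_id,
        label_means={str(k): float(v) for k, v in means.items()},
        dominant_label=str(dominant),
        specificity_score=float(score),
        tie_flag=len(dominant_candidates) > 1,
    )
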
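"""Core domain types for the screening cascade.

Every type wraps a pandas/`scipy.sparse` container and validates its
invariants on construction, so downstream code can assume well-formed
inputs.  Readers in :mod:`imos.io` construct these from files; the
synthetic generators in :mod:`imos.simulate` construct them directly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "ValidationError",
    "GeneExpressionMatrix",
    "ClinicalTable",
    "Cohort",
    "GeneSignature",
    "CnvMatrix",
    "MethylationMatrix",
    "MutationTable",
    "SingleCellDataset",
    "METHYLATION_REGIONS",
]

METHYLATION_REGIONS = ("TSS1500", "TSS200", "body", "other")

CNV_STATES = (-2, -1, 0, 1, 2)


class ValidationError(ValueError):
    """An input violates a domain-type invariant."""


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what}: {dup}")


@dataclass
class GeneExpressionMatrix:
    """Genes x samples expression values.

    ``values`` is a DataFrame whose index holds gene ids and whose
    columns hold sample ids.  ``scale`` records whether the values are
    linear or log2; differential-expression routines require log2.
    Missing values are allowed and propagate to pairwise-complete
    statistics downstream.
    """

    values: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValidationError(f"unknown expression scale {self.scale!r}")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.shape[0] < 1 or self.values.shape[1] < 2:
            raise ValidationError(
                f"expression matrix needs >=1 gene and >=2 samples, "
                f"got shape {self.values.shape}"
            )
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "sample ids")
        vals = self.values.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValidationError("expression values must be finite or missing (NaN)")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids) -> "GeneExpressionMatrix":
        return GeneExpressionMatrix(self.values.loc[:, list(sample_ids)], scale=self.scale)


@dataclass
class ClinicalTable:
    """Per-sample overall survival: time (months, >0) and event (1=death).

    ``table`` is indexed by sample id with columns ``os_time`` and
    ``os_event``; any further columns are carried along as covariates.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        for col in ("os_time", "os_event"):
            if col not in t.columns:
                raise ValidationError(f"clinical table missing required column {col!r}")
        _check_unique(t.index, "sample ids")
        times = t["os_time"].to_numpy(dtype=float)
        events = t["os_event"].to_numpy(dtype=float)
        if np.isnan(times).any() or np.isnan(events).any():
            raise ValidationError("clinical table contains missing os_time/os_event")
        if (times <= 0).any():
            bad = t.index[times <= 0].tolist()[:5]
            raise ValidationError(f"os_time must be > 0; offending samples: {bad}")
        if not np.isin(events, (0, 1)).all():
            raise ValidationError("os_event must be 0 or 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def os_time(self) -> np.ndarray:
        return self.table["os_time"].to_numpy(dtype=float)

    @property
    def os_event(self) -> np.ndarray:
        return self.table["os_event"].to_numpy(dtype=int)

    def subset(self, sample_ids) -> "ClinicalTable":
        return ClinicalTable(self.table.loc[list(sample_ids)])


@dataclass
class Cohort:
    """An aligned expression matrix + clinical table; the unit a screen runs on.

    Construct via :func:`imos.io.align_cohort`, which intersects and
    reorders the sample sets; the constructor enforces that they already
    agree exactly (same ids, same order).
    """

    name: str
    expression: GeneExpressionMatrix
    clinical: ClinicalTable

    def __post_init__(self) -> None:
        es = self.expression.sample_ids
        cs = self.clinical.sample_ids
        if es != cs:
            raise ValidationError(
                f"cohort {self.name!r}: expression and clinical sample ids differ "
                f"(use align_cohort); {len(es)} vs {len(cs)} samples"
            )

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass(frozen=True)
class GeneSignature:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"signature {self.name!r} has no genes")
        object.__setattr__(self, "genes", frozenset(self.genes))


@dataclass
class CnvMatrix:
    """Thresholded (GISTIC-style) copy-number states, genes x samples.

    States live in {-2,-1,0,1,2}; state > 0 is treated as duplication
    (gain or amplification) throughout.
    """

    states: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.states.index, "gene ids")
        _check_unique(self.states.columns, "sample ids")
        vals = self.states.to_numpy()
        if not np.isin(vals, CNV_STATES).all():
            bad = np.argwhere(~np.isin(vals, CNV_STATES))[0]
            raise ValidationError(
                f"CNV state {vals[bad[0], bad[1]]!r} at gene "
                f"{self.states.index[bad[0]]!r}, sample "
                f"{self.states.columns[bad[1]]!r} not in {CNV_STATES}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.states.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.states.columns)


@dataclass
class MethylationMatrix:
    """Probe-level methylation beta values plus the probe->gene map.

    ``beta`` is probes x samples in [0,1]; ``probe_map`` is indexed by
    probe id with columns ``gene_id`` and ``region`` (one of
    TSS1500/TSS200/body/other).  Every probe in ``beta`` must be mapped.
    """

    beta: pd.DataFrame
    probe_map: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.beta.index, "probe ids")
        _check_unique(self.beta.columns, "sample ids")
        vals = self.beta.to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if ((finite < 0) | (finite > 1)).any():
            raise ValidationError("methylation beta values must lie in [0, 1]")
        for col in ("gene_id", "region"):
            if col not in self.probe_map.columns:
                raise ValidationError(f"probe map missing column {col!r}")
        missing = set(self.beta.index) - set(self.probe_map.index)
        if missing:
            raise ValidationError(
                f"{len(missing)} probes absent from probe map, e.g. {sorted(missing)[:5]}"
            )
        bad_regions = set(self.probe_map["region"]) - set(METHYLATION_REGIONS)
        if bad_regions:
            raise ValidationError(
                f"unknown probe regions {sorted(bad_regions)}; allowed: {METHYLATION_REGIONS}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.beta.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.columns)

    def probes_for_gene(self, gene_id: str) -> list[str]:
        m = self.probe_map["gene_id"] == gene_id
        return list(self.probe_map.index[m])


@dataclass
class MutationTable:
    """MAF-like long table of somatic mutations: (sample_id, gene_id, variant_class)."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("sample_id", "gene_id", "variant_class"):
            if col not in self.rows.columns:
                raise ValidationError(f"mutation table missing column {col!r}")
        if self.rows.duplicated().any():
            raise ValidationError("mutation table contains fully duplicated rows")

    def mutated_samples(self, gene_id: str) -> set[str]:
        m = self.rows["gene_id"] == gene_id
        return set(self.rows.loc[m, "sample_id"])

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.rows["gene_id"].unique())


@dataclass
class SingleCellDataset:
    """Labeled single-cell UMI counts (cells x genes, sparse CSR).

    ``labels`` maps every cell id to a cell-type string; ``mito_genes``
    is the subset of gene ids used for the mitochondrial-fraction QC
    metric.
    """

    cell_ids: list[str]
    gene_ids: list[str]
    counts: sp.csr_matrix
    labels: Mapping[str, str]
    mito_genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        n_cells, n_genes = self.counts.shape
        if n_cells != len(self.cell_ids) or n_genes != len(self.gene_ids):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        _check_unique(self.cell_ids, "cell ids")
        _check_unique(self.gene_ids, "gene ids")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("counts must be non-negative")
        data = self.counts.data
        if data.size and not np.allclose(data, np.round(data)):
            raise ValidationError("counts must be integers")
        unlabeled = [c for c in self.cell_ids if c not in self.labels]
        if unlabeled:
            raise ValidationError(
                f"{len(unlabeled)} cells lack a cell-type label, "
                f"e.g. {unlabeled[:10]}"
            )
        self.mito_genes = frozenset(self.mito_genes)
        extra = self.mito_genes - set(self.gene_ids)
        if extra:
            raise ValidationError(f"mito genes not in gene universe: {sorted(extra)[:5]}")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, keep_idx: np.ndarray) -> "SingleCellDataset":
        keep_idx = np.asarray(keep_idx)
        cell_ids = [self.cell_ids[i] for i in keep_idx]
        return SingleCellDataset(
            cell_ids=cell_ids,
            gene_ids=list(self.gene_ids),
            counts=self.counts[keep_idx],
            labels={c: self.labels[c] for c in cell_ids},
            mito_genes=self.mito_genes,
        )
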
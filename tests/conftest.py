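import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import HealthCheck, settings

from imos.datamodel import (
    ClinicalTable,
    Cohort,
    GeneExpressionMatrix,
    GeneSignature,
    SingleCellDataset,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_expr():
    """4 genes x 4 samples, log2 scale, no ties."""
    values = pd.DataFrame(
        [[4.0, 8.0, 1.0, 5.0],
         [3.0, 7.0, 2.0, 6.0],
         [2.0, 6.0, 3.0, 7.0],
         [1.0, 5.0, 4.0, 8.0]],
        index=["g1", "g2", "g3", "g4"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return GeneExpressionMatrix(values, scale="log2")


@pytest.fixture
def toy_signature():
    return GeneSignature("toy", frozenset({"g1", "g2"}))


@pytest.fixture
def km_worked_fixture():
    """Times 1(event), 2(censored), 3(event), 4(censored):
    S(1) = 3/4, S(3) = 3/4 * 1/2 = 3/8."""
    return np.array([1.0, 2.0, 3.0, 4.0]), np.array([1, 0, 1, 0])


def build_cohort(times, events, expr_rows, name="test"):
    """Hand-build an aligned cohort from survival arrays and gene rows."""
    n = len(times)
    samples = [f"s{i+1}" for i in range(n)]
    expr = GeneExpressionMatrix(
        pd.DataFrame.from_dict(expr_rows, orient="index").set_axis(samples, axis=1),
        scale="log2",
    )
    clinical = ClinicalTable(
        pd.DataFrame({"os_time": times, "os_event": events},
                     index=pd.Index(samples, name="sample_id"))
    )
    return Cohort(name, expr, clinical)


def build_qc_fixture():
    """Cells engineered to sit on and around the QC thresholds.

    Returns (dataset, expected_kept_ids).  Gene universe is ~6000 genes
    plus one mitochondrial gene so detected-gene counts can straddle the
    5000-gene doublet rule.
    """
    n_genes = 6001
    gene_ids = [f"g{i}" for i in range(n_genes - 1)] + ["MT-CO1"]
    mito_col = n_genes - 1

    specs = [
        # (cell, umi, genes_detected, mito_counts, expected_kept)
        ("low_umi", 1500, 600, 0, False),          # below 2000 UMI
        ("umi_boundary", 2000, 600, 0, True),      # exactly 2000 kept (strict <)
        ("normal", 3000, 800, 150, True),          # 5% mito
        ("low_genes", 3000, 499, 0, False),        # below 500 genes
        ("genes_boundary", 3000, 500, 0, True),    # exactly 500 kept
        ("mito_boundary", 3000, 700, 300, True),   # exactly 10% mito kept
        ("high_mito", 3000, 700, 360, False),      # 12% mito
        ("doublet", 45000, 6000, 0, False),        # >40k UMI and >5000 genes
        ("high_umi_only", 45000, 4000, 0, True),   # doublet rule needs both
        ("doublet_boundary", 40000, 5500, 0, True),  # exactly 40k kept
    ]
    rows_i, cols_j, data = [], [], []
    cell_ids, expected_kept = [], []
    for i, (cid, umi, genes, mito, kept) in enumerate(specs):
        cell_ids.append(cid)
        if kept:
            expected_kept.append(cid)
        n_other = genes - (1 if mito > 0 else 0)
        non_mito_umi = umi - mito
        # first non-mito gene absorbs the remainder, others get 1 count
        first = non_mito_umi - (n_other - 1)
        assert first >= 1
        cols = list(range(n_other))
        counts = [first] + [1] * (n_other - 1)
        if mito > 0:
            cols.append(mito_col)
            counts.append(mito)
        rows_i += [i] * len(cols)
        cols_j += cols
        data += counts
    counts = sp.csr_matrix(
        (data, (rows_i, cols_j)), shape=(len(specs), n_genes), dtype=np.int64
    )
    dataset = SingleCellDataset(
        cell_ids=cell_ids,
        gene_ids=gene_ids,
        counts=counts,
        labels={c: "T_cell" for c in cell_ids},
        mito_genes=frozenset({"MT-CO1"}),
    )
    return dataset, expected_kept
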
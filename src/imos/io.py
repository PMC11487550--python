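"""File readers/writers for the tabular formats the cascade touches.

Conventions
-----------
* Expression / CNV / methylation matrices: TSV with genes (or probes) as
  rows, first column the row id, header row of sample ids.  Expression
  can also be GCT v1.2.
* Clinical tables, probe maps, mutation tables, labels: TSV with named
  columns.
* Single cell: MatrixMarket coordinate integer counts (features x
  barcodes, 10x convention) plus one-id-per-line barcode and feature
  files and a barcode -> cell-type label TSV.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datamodel import (
    ClinicalTable,
    CnvMatrix,
    Cohort,
    GeneExpressionMatrix,
    GeneSignature,
    MethylationMatrix,
    MutationTable,
    SingleCellDataset,
    ValidationError,
)

logger = logging.getLogger("imos.io")

DAYS_PER_MONTH = 30.44


class ParseError(ValueError):
    """A file could not be parsed into a valid domain object."""


def _read_numeric_matrix(path, what: str) -> pd.DataFrame:
    """Read a genes-as-rows TSV, reporting the offending cell on failure."""
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.columns.size == 0:
        raise ParseError(f"{path}: malformed header (line 1): no sample columns")
    if raw.columns.duplicated().any():
        raise ParseError(f"{path}: malformed header (line 1): duplicate sample ids")
    out = {}
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna() & ~raw[col].str.strip().str.upper().isin(["NA", "NAN", ""])
        if bad.any():
            gene = raw.index[bad.to_numpy()][0]
            raise ParseError(
                f"{path}: non-numeric {what} value {raw.loc[gene, col]!r} "
                f"at row {gene!r}, column {col!r}"
            )
        out[col] = converted
    return pd.DataFrame(out, index=raw.index)


def _collapse_duplicate_genes(df: pd.DataFrame) -> pd.DataFrame:
    """Keep the highest-mean row per duplicated gene id (deterministic)."""
    if not df.index.duplicated().any():
        return df
    n_dup = int(df.index.duplicated().sum())
    means = df.mean(axis=1, skipna=True).to_numpy()
    order = np.lexsort((-means, pd.factorize(df.index)[0]))
    best: dict = {}
    for i in order:
        best.setdefault(df.index[i], i)
    keep = sorted(best.values())
    logger.warning("collapsed %d duplicate gene rows (kept highest-mean row)", n_dup)
    return df.iloc[keep]


def read_expression(path, format: str = "tsv", scale: str = "linear") -> GeneExpressionMatrix:
    """Read an expression matrix from TSV (genes x samples) or GCT v1.2."""
    path = Path(path)
    if format == "tsv":
        df = _read_numeric_matrix(path, "expression")
    elif format == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise ParseError(f"{path}: line 1: expected GCT version '#1.2', got {version!r}")
            dims = fh.readline().split()
            if len(dims) != 2:
                raise ParseError(f"{path}: line 2: expected '<n_genes>\\t<n_samples>'")
            n_genes, n_samples = int(dims[0]), int(dims[1])
        body = pd.read_csv(path, sep="\t", skiprows=2, index_col=0)
        if "Description" in body.columns:
            body = body.drop(columns="Description")
        if body.shape != (n_genes, n_samples):
            raise ParseError(
                f"{path}: dims line says {(n_genes, n_samples)}, body is {body.shape}"
            )
        df = body.astype(float)
    else:
        raise ValueError(f"unknown expression format {format!r}")
    df = _collapse_duplicate_genes(df)
    return GeneExpressionMatrix(df, scale=scale)


def write_expression(expr: GeneExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id")


def read_clinical(path, time_unit: str = "months") -> ClinicalTable:
    """Read a survival TSV with columns sample_id, os_time, os_event.

    Rows with missing os_time/os_event are dropped (count logged); rows
    with non-positive os_time are rejected with a warning.  With
    ``time_unit='days'`` times are divided by 30.44.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "os_time", "os_event"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    df["os_time"] = pd.to_numeric(df["os_time"], errors="coerce")
    df["os_event"] = pd.to_numeric(df["os_event"], errors="coerce")
    n0 = len(df)
    df = df.dropna(subset=["os_time", "os_event"])
    if len(df) < n0:
        logger.warning("dropped %d clinical rows with missing os_time/os_event", n0 - len(df))
    bad = df["os_time"] <= 0
    if bad.any():
        logger.warning("rejected %d clinical rows with os_time <= 0", int(bad.sum()))
        df = df[~bad]
    if time_unit == "days":
        df = df.assign(os_time=df["os_time"] / DAYS_PER_MONTH)
    elif time_unit != "months":
        raise ValueError(f"unknown time unit {time_unit!r}")
    return ClinicalTable(df.set_index("sample_id"))


def write_clinical(clinical: ClinicalTable, path) -> None:
    clinical.table.to_csv(path, sep="\t", index_label="sample_id")


def read_cnv(path) -> CnvMatrix:
    df = _read_numeric_matrix(path, "CNV state")
    vals = df.to_numpy()
    bad = ~np.isin(vals, (-2, -1, 0, 1, 2)) | np.isnan(vals)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: CNV state {vals[i, j]!r} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r} is not in {{-2,-1,0,1,2}}"
        )
    return CnvMatrix(df.astype(int))


def write_cnv(cnv: CnvMatrix, path) -> None:
    cnv.states.to_csv(path, sep="\t", index_label="gene_id")


def read_methylation(beta_path, map_path) -> MethylationMatrix:
    beta = _read_numeric_matrix(beta_path, "beta")
    finite = beta.to_numpy()
    finite = finite[~np.isnan(finite)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ParseError(f"{beta_path}: beta values outside [0, 1]")
    pmap = pd.read_csv(map_path, sep="\t", dtype=str)
    for col in ("probe_id", "gene_id", "region"):
        if col not in pmap.columns:
            raise ParseError(f"{map_path}: missing required column {col!r}")
    return MethylationMatrix(beta, pmap.set_index("probe_id"))


def write_methylation(meth: MethylationMatrix, beta_path, map_path) -> None:
    meth.beta.to_csv(beta_path, sep="\t", index_label="probe_id")
    meth.probe_map.to_csv(map_path, sep="\t", index_label="probe_id")


def read_mutations(path) -> MutationTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "gene_id", "variant_class"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    n0 = len(df)
    df = df.drop_duplicates()
    if len(df) < n0:
        logger.warning("dropped %d fully duplicated mutation rows", n0 - len(df))
    return MutationTable(df.reset_index(drop=True))


def write_mutations(mut: MutationTable, path) -> None:
    mut.rows.to_csv(path, sep="\t", index=False)


def read_signature_gmt(path) -> list[GeneSignature]:
    """Read GMT: one signature per line, fields name, description, genes..."""
    sigs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: GMT needs name, description, >=1 gene")
            sigs.append(GeneSignature(fields[0], frozenset(g for g in fields[2:] if g)))
    return sigs


def read_signature_list(path, name: str | None = None) -> GeneSignature:
    """Read a plain one-gene-per-line list."""
    genes = [ln.strip() for ln in open(path) if ln.strip()]
    return GeneSignature(name or Path(path).stem, frozenset(genes))


def write_signature_list(sig: GeneSignature, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(sig.genes):
            fh.write(g + "\n")


def _read_id_lines(path) -> list[str]:
    # take the first tab field per line (10x feature files carry extra columns)
    return [ln.rstrip("\n").split("\t")[0] for ln in open(path) if ln.strip()]


def read_single_cell(
    mtx_path, barcodes_path, features_path, labels_path, mito_prefix: str = "MT-"
) -> SingleCellDataset:
    """Read MatrixMarket counts (features x barcodes) plus sidecar TSVs."""
    mat = scipy.io.mmread(mtx_path)
    barcodes = _read_id_lines(barcodes_path)
    features = _read_id_lines(features_path)
    if mat.shape != (len(features), len(barcodes)):
        raise ParseError(
            f"{mtx_path}: matrix is {mat.shape} but sidecars give "
            f"{len(features)} features x {len(barcodes)} barcodes"
        )
    labels_df = pd.read_csv(labels_path, sep="\t", dtype=str)
    for col in ("barcode", "cell_type"):
        if col not in labels_df.columns:
            raise ParseError(f"{labels_path}: missing required column {col!r}")
    labels = dict(zip(labels_df["barcode"], labels_df["cell_type"]))
    missing = [b for b in barcodes if b not in labels]
    if missing:
        raise ParseError(
            f"{labels_path}: {len(missing)} barcodes unlabeled, e.g. {missing[:10]}"
        )
    mito = frozenset(g for g in features if g.startswith(mito_prefix))
    return SingleCellDataset(
        cell_ids=barcodes,
        gene_ids=features,
        counts=sp.csr_matrix(mat.T),
        labels={b: labels[b] for b in barcodes},
        mito_genes=mito,
    )


def write_single_cell(dataset: SingleCellDataset, outdir) -> None:
    """Write MTX (features x barcodes) + barcodes/features/labels TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    coo = sp.coo_matrix(dataset.counts.T)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), coo, field="integer")
    (outdir / "barcodes.tsv").write_text("".join(c + "\n" for c in dataset.cell_ids))
    (outdir / "features.tsv").write_text("".join(g + "\n" for g in dataset.gene_ids))
    with open(outdir / "labels.tsv", "w") as fh:
        fh.write("barcode\tcell_type\n")
        for c in dataset.cell_ids:
            fh.write(f"{c}\t{dataset.labels[c]}\n")


def align_cohort(expression: GeneExpressionMatrix, clinical: ClinicalTable, name: str) -> Cohort:
    """Restrict both inputs to their shared samples, in expression order."""
    shared = [s for s in expression.sample_ids if s in set(clinical.sample_ids)]
    if not shared:
        raise ValidationError(
            f"cohort {name!r}: expression and clinical tables share no samples"
        )
    dropped = (len(expression.sample_ids) - len(shared)) + (len(clinical.sample_ids) - len(shared))
    if dropped:
        logger.info("cohort %s: dropped %d unmatched samples during alignment", name, dropped)
    if len(shared) < 2:
        raise ValidationError(f"cohort {name!r}: fewer than 2 shared samples")
    return Cohort(name, expression.subset_samples(shared), clinical.subset(shared))
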
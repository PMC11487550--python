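"""SNV, CNV and methylation evidence gates for candidate genes.

Each gate asks whether an orthogonal data layer supports a candidate:
mutation frequency and mutated-vs-unmutated survival; copy-number /
expression concordance (Pearson, BH-FDR) and duplication-vs-rest
survival; methylation-probe / expression anticorrelation and per-probe
survival.  Survival comparisons delegate to :mod:`imos.survival`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import CnvMatrix, Cohort, GeneExpressionMatrix, MethylationMatrix, MutationTable
from .survival import LogRankResult, SkipSignal, bh_fdr, logrank_test, pearson_test

logger = logging.getLogger("imos.multiomics")

__all__ = [
    "OmicsEvidence",
    "snv_frequency",
    "mutation_survival",
    "cnv_expression_correlation",
    "cnv_group_survival",
    "methylation_expression_correlation",
    "probe_survival",
    "compute_omics_evidence",
]


@dataclass
class ProbeCorrelation:
    probe_id: str
    region: str
    r: float
    p: float
    q: float | None = None


@dataclass
class ProbeSurvival:
    probe_id: str
    p: float
    direction: str          # low_methylation_worse / high_methylation_worse / none


@dataclass
class OmicsEvidence:
    gene_id: str
    snv_fraction: float = float("nan")
    mutation_survival_p: float | None = None
    mutation_direction: str | None = None
    cnv_expr_r: float = float("nan")
    cnv_expr_p: float = float("nan")
    cnv_expr_q: float = float("nan")
    cnv_concordant: bool = False
    cnv_survival_p: float | None = None
    cnv_survival_direction: str | None = None
    meth_probe_results: list[ProbeCorrelation] = field(default_factory=list)
    meth_negative_flag: bool = False
    meth_probe_survival: list[ProbeSurvival] = field(default_factory=list)
    skips: dict[str, str] = field(default_factory=dict)


def snv_frequency(mutations: MutationTable, cohort_samples) -> dict[str, float]:
    """Per-gene mutated-sample fraction: distinct mutated samples / cohort size."""
    universe = list(cohort_samples)
    if not universe:
        raise ValueError("cohort sample universe is empty")
    uset = set(universe)
    offenders = sorted(set(mutations.rows["sample_id"]) - uset)
    if offenders:
        raise ValueError(
            f"{len(offenders)} mutation samples outside the cohort universe, "
            f"e.g. {offenders[:5]}"
        )
    counts = mutations.rows.groupby("gene_id")["sample_id"].nunique()
    return {g: float(c) / len(universe) for g, c in counts.items()}


def mutation_survival(
    mutations: MutationTable, cohort: Cohort, gene_id: str
) -> LogRankResult:
    """Log-rank of mutated vs unmutated carriers of one gene.

    Direction 'high_worse' means mutated-worse (the mutated group plays
    'high').  Fewer than 2 samples on either side raises SkipSignal.
    """
    carriers = mutations.mutated_samples(gene_id) & set(cohort.sample_ids)
    groups = np.array(
        ["mutated" if s in carriers else "wildtype" for s in cohort.sample_ids]
    )
    n_mut = int((groups == "mutated").sum())
    if n_mut < 2 or len(groups) - n_mut < 2:
        raise SkipSignal(
            f"gene {gene_id!r}: need >=2 mutated and >=2 unmutated samples "
            f"(have {n_mut}/{len(groups) - n_mut})"
        )
    return logrank_test(
        cohort.clinical.os_time, cohort.clinical.os_event, groups, high_label="mutated"
    )


def cnv_expression_correlation(
    cnv: CnvMatrix,
    expr: GeneExpressionMatrix,
    genes=None,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Pearson correlation of CNV state vs expression, with BH q.

    Returns a DataFrame indexed by gene with columns r, p, q, concordant
    (q < threshold and r > 0) plus a ``skipped`` reason column for genes
    with constant CNV/expression or too few shared samples.
    """
    if genes is None:
        genes = [g for g in cnv.gene_ids if g in set(expr.gene_ids)]
    shared = [s for s in cnv.sample_ids if s in set(expr.sample_ids)]
    rows = {}
    for gene in genes:
        if gene not in cnv.states.index or gene not in expr.values.index:
            rows[gene] = dict(r=np.nan, p=np.nan, skipped="absent from CNV or expression")
            continue
        if len(shared) < 3:
            rows[gene] = dict(r=np.nan, p=np.nan, skipped="fewer than 3 shared samples")
            continue
        states = cnv.states.loc[gene, shared].to_numpy(dtype=float)
        x = expr.values.loc[gene, shared].to_numpy(dtype=float)
        res = pearson_test(states, x)
        if res is None:
            rows[gene] = dict(r=np.nan, p=np.nan, skipped="constant CNV or expression")
        else:
            rows[gene] = dict(r=res[0], p=res[1], skipped=None)
    df = pd.DataFrame.from_dict(rows, orient="index")
    tested = df.index[df["skipped"].isna()]
    df["q"] = np.nan
    if len(tested):
        df.loc[tested, "q"] = bh_fdr(df.loc[tested, "p"].to_numpy())
    df["concordant"] = (df["q"] < fdr_threshold) & (df["r"] > 0)
    return df


def cnv_group_survival(cnv: CnvMatrix, cohort: Cohort, gene_id: str) -> LogRankResult:
    """Log-rank of duplication (state > 0) vs non-duplication samples.

    Direction 'high_worse' means duplication-worse.
    """
    if gene_id not in cnv.states.index:
        raise SkipSignal(f"gene {gene_id!r} absent from CNV matrix")
    shared = [s for s in cohort.sample_ids if s in set(cnv.sample_ids)]
    if not shared:
        raise SkipSignal(f"gene {gene_id!r}: no shared samples with CNV matrix")
    states = cnv.states.loc[gene_id, shared]
    groups = np.array(["dup" if v > 0 else "nondup" for v in states])
    n_dup = int((groups == "dup").sum())
    if n_dup < 2 or len(groups) - n_dup < 2:
        raise SkipSignal(
            f"gene {gene_id!r}: need >=2 duplicated and >=2 non-duplicated samples"
        )
    clin = cohort.clinical.table.loc[shared]
    return logrank_test(
        clin["os_time"].to_numpy(), clin["os_event"].to_numpy(), groups, high_label="dup"
    )


def methylation_expression_correlation(
    meth: MethylationMatrix,
    expr: GeneExpressionMatrix,
    gene_id: str,
    probe_qvalues: pd.Series | None = None,
    fdr_threshold: float = 0.05,
) -> tuple[list[ProbeCorrelation], bool]:
    """Per-probe Pearson r (beta vs expression) and the gene-level flag.

    ``meth_negative_flag`` is true when at least one probe has r < 0
    with q below the FDR threshold.  ``probe_qvalues`` supplies
    analysis-wide q-values (the default pool); when absent, BH is
    applied within the gene's own probe set.
    """
    probes = meth.probes_for_gene(gene_id)
    if not probes:
        raise SkipSignal(f"gene {gene_id!r} has no mapped methylation probes")
    shared = [s for s in meth.sample_ids if s in set(expr.sample_ids)]
    if len(shared) < 3 or gene_id not in expr.values.index:
        raise SkipSignal(f"gene {gene_id!r}: insufficient shared methylation samples")
    x = expr.values.loc[gene_id, shared].to_numpy(dtype=float)
    results = []
    for probe in probes:
        beta = meth.beta.loc[probe, shared].to_numpy(dtype=float)
        res = pearson_test(beta, x)
        if res is None:
            continue
        region = str(meth.probe_map.loc[probe, "region"])
        results.append(ProbeCorrelation(probe, region, res[0], res[1]))
    if not results:
        raise SkipSignal(f"gene {gene_id!r}: all probes constant")
    if probe_qvalues is not None:
        for pr in results:
            pr.q = float(probe_qvalues.get(pr.probe_id, np.nan))
    else:
        qs = bh_fdr([pr.p for pr in results])
        for pr, qv in zip(results, qs):
            pr.q = float(qv)
    flag = any(pr.r < 0 and pr.q is not None and pr.q < fdr_threshold for pr in results)
    return results, flag


def probe_survival(
    meth: MethylationMatrix, cohort: Cohort, probe_id: str, q: float = 0.5
) -> ProbeSurvival:
    """Log-rank of high-beta vs low-beta samples at one probe (median split)."""
    if probe_id not in meth.beta.index:
        raise SkipSignal(f"probe {probe_id!r} absent")
    shared = [s for s in cohort.sample_ids if s in set(meth.sample_ids)]
    beta = meth.beta.loc[probe_id, shared].to_numpy(dtype=float)
    ok = ~np.isnan(beta)
    beta, samples = beta[ok], [s for s, k in zip(shared, ok) if k]
    if beta.size < 4:
        raise SkipSignal(f"probe {probe_id!r}: fewer than 4 samples")
    if np.ptp(beta) == 0:
        raise SkipSignal(f"probe {probe_id!r}: constant beta")
    cutoff = np.quantile(beta, 1.0 - q)
    groups = np.array(["high" if b > cutoff else "low" for b in beta])
    if len(set(groups)) < 2:
        raise SkipSignal(f"probe {probe_id!r}: degenerate beta split")
    clin = cohort.clinical.table.loc[samples]
    lr = logrank_test(
        clin["os_time"].to_numpy(), clin["os_event"].to_numpy(), groups, high_label="high"
    )
    direction = {
        "high_worse": "high_methylation_worse",
        "high_better": "low_methylation_worse",
        "none": "none",
    }[lr.direction]
    return ProbeSurvival(probe_id, lr.p, direction)


def compute_omics_evidence(
    genes,
    cohort: Cohort,
    cnv: CnvMatrix | None = None,
    meth: MethylationMatrix | None = None,
    mutations: MutationTable | None = None,
    cnv_fdr: float = 0.05,
    meth_fdr: float = 0.05,
) -> dict[str, OmicsEvidence]:
    """Run every available evidence gate over a gene list.

    Per-item precondition failures are recorded in ``skips`` rather than
    raised; the methylation FDR pool is analysis-wide over all tested
    probes of the gene list.
    """
    genes = list(genes)
    evidence = {g: OmicsEvidence(gene_id=g) for g in genes}

    if mutations is not None:
        freqs = snv_frequency(mutations, cohort.sample_ids)
        for g in genes:
            ev = evidence[g]
            ev.snv_fraction = freqs.get(g, 0.0)
            try:
                lr = mutation_survival(mutations, cohort, g)
                ev.mutation_survival_p = lr.p
                ev.mutation_direction = (
                    "mutated_worse" if lr.direction == "high_worse"
                    else "mutated_better" if lr.direction == "high_better" else "none"
                )
            except SkipSignal as sig:
                ev.skips["mutation_survival"] = sig.reason

    if cnv is not None:
        corr = cnv_expression_correlation(cnv, cohort.expression, genes, fdr_threshold=cnv_fdr)
        for g in genes:
            ev = evidence[g]
            if g in corr.index and corr.loc[g, "skipped"] is None:
                ev.cnv_expr_r = float(corr.loc[g, "r"])
                ev.cnv_expr_p = float(corr.loc[g, "p"])
                ev.cnv_expr_q = float(corr.loc[g, "q"])
                ev.cnv_concordant = bool(corr.loc[g, "concordant"])
            else:
                reason = corr.loc[g, "skipped"] if g in corr.index else "absent"
                ev.skips["cnv_correlation"] = str(reason)
            try:
                lr = cnv_group_survival(cnv, cohort, g)
                ev.cnv_survival_p = lr.p
                ev.cnv_survival_direction = (
                    "duplication_worse" if lr.direction == "high_worse"
                    else "duplication_better" if lr.direction == "high_better" else "none"
                )
            except SkipSignal as sig:
                ev.skips["cnv_survival"] = sig.reason

    if meth is not None:
        # analysis-wide probe q-values over every probe mapped to the gene list
        probe_ps: dict[str, float] = {}
        shared = [s for s in meth.sample_ids if s in set(cohort.sample_ids)]
        for g in genes:
            if g not in cohort.expression.values.index or len(shared) < 3:
                continue
            x = cohort.expression.values.loc[g, shared].to_numpy(dtype=float)
            for probe in meth.probes_for_gene(g):
                beta = meth.beta.loc[probe, shared].to_numpy(dtype=float)
                res = pearson_test(beta, x)
                if res is not None:
                    probe_ps[probe] = res[1]
        probe_q = (
            pd.Series(bh_fdr(list(probe_ps.values())), index=list(probe_ps))
            if probe_ps else pd.Series(dtype=float)
        )
        for g in genes:
            ev = evidence[g]
            try:
                probe_results, flag = methylation_expression_correlation(
                    meth, cohort.expression, g, probe_qvalues=probe_q,
                    fdr_threshold=meth_fdr,
                )
                ev.meth_probe_results = probe_results
                ev.meth_negative_flag = flag
            except SkipSignal as sig:
                ev.skips["methylation_correlation"] = sig.reason
                continue
            for pr in ev.meth_probe_results:
                try:
                    ev.meth_probe_survival.append(probe_survival(meth, cohort, pr.probe_id))
                except SkipSignal as sig:
                    ev.skips[f"probe_survival:{pr.probe_id}"] = sig.reason
    return evidence


def evidence_table(evidence: dict[str, OmicsEvidence]) -> pd.DataFrame:
    """Flatten gene-level evidence to one row per gene."""
    rows = []
    for g in sorted(evidence):
        ev = evidence[g]
        rows.append({
            "gene_id": g,
            "snv_fraction": ev.snv_fraction,
            "mutation_survival_p": ev.mutation_survival_p,
            "cnv_expr_r": ev.cnv_expr_r,
            "cnv_expr_p": ev.cnv_expr_p,
            "cnv_expr_q": ev.cnv_expr_q,
            "cnv_concordant": ev.cnv_concordant,
            "cnv_survival_p": ev.cnv_survival_p,
            "cnv_survival_direction": ev.cnv_survival_direction,
            "meth_negative_flag": ev.meth_negative_flag,
            "n_meth_probes": len(ev.meth_probe_results),
        })
    return pd.DataFrame(rows).set_index("gene_id")
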
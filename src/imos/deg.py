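"""Differential expression between immune-high and immune-low groups.

The main test is an empirical-Bayes moderated t: per-gene pooled
variances s_g^2 (d_g df) are shrunk toward a prior s0^2 with d0 prior
df, the hyperparameters (d0, s0^2) being estimated across genes by
method-of-moments on log s_g^2 — log variances of normal data follow a
scaled log-chi-square whose mean/variance involve digamma/trigamma, so
matching the first two moments and inverting the trigamma function
recovers d0.  The moderated statistic

    t_g = log2fc_g / (s~_g * sqrt(1/n_h + 1/n_l)),
    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

is referred to a t distribution with d0 + d_g df.  At d0 = 0 this is the
ordinary pooled two-sample t; as d0 -> inf it approaches a z-like
statistic with common variance s0^2.

The module also carries the bulk RNA-seq quantification rules: FPKM
(fragments per kilobase of exon per million mapped reads) and the
FC>2-or-FC<0.5 gate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .datamodel import GeneExpressionMatrix, ValidationError

logger = logging.getLogger("imos.deg")

__all__ = [
    "DegResult",
    "BulkCountsMatrix",
    "moderated_t_test",
    "select_degs",
    "fpkm",
    "bulk_deg_select",
    "estimate_prior",
]

FC_EPS = 1e-6


@dataclass
class DegResult:
    gene_id: str
    log2fc: float
    t_stat: float
    p: float
    s2: float            # pooled two-group variance
    s2_moderated: float
    d0: float            # prior df shared across genes
    s0_2: float          # prior variance shared across genes
    flagged: str | None = None


@dataclass
class BulkCountsMatrix:
    """Fragment counts plus the per-gene/per-sample normalizers FPKM needs."""

    fragment_counts: pd.DataFrame          # genes x samples, non-negative ints
    exon_length_kb: pd.Series              # per gene, > 0
    mapped_reads_millions: pd.Series       # per sample, > 0

    def __post_init__(self) -> None:
        counts = self.fragment_counts.to_numpy()
        if (counts < 0).any():
            raise ValidationError("fragment counts must be non-negative")
        self.exon_length_kb = self.exon_length_kb.reindex(self.fragment_counts.index)
        self.mapped_reads_millions = self.mapped_reads_millions.reindex(
            self.fragment_counts.columns
        )
        if self.exon_length_kb.isna().any() or (self.exon_length_kb <= 0).any():
            raise ValidationError("every gene needs exon_length_kb > 0")
        if self.mapped_reads_millions.isna().any() or (self.mapped_reads_millions <= 0).any():
            raise ValidationError("every sample needs mapped_reads_millions > 0")


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    # Newton on x -> trigamma(x), starting from the asymptotic inverse 1/y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        tet = float(special.polygamma(2, x))
        delta = tri * (1.0 - tri / y) / tet
        x += delta
        if abs(delta) < tol * x:
            break
    return x


def estimate_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments estimate of (d0, s0^2) from per-gene variances.

    Works on e_g = log(s_g^2) - digamma(d_g/2) + log(d_g/2).  Returns
    d0 = inf when the excess variance of e_g is non-positive (variances
    are more concordant than sampling alone predicts).  Raises
    ValueError when no informative genes remain; callers fall back to
    d0 = 0 (no moderation).
    """
    ok = (s2 > 0) & (df > 0) & np.isfinite(s2)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 genes with positive variance")
    s2, df = s2[ok], df[ok]
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_bar = float(e.mean())
    n = e.size
    excess = float(((e - e_bar) ** 2 * n / (n - 1) - special.polygamma(1, df / 2.0)).mean())
    if excess <= 0:
        d0 = math.inf
        s0_2 = float(np.exp(e_bar))
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_2 = float(np.exp(e_bar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    if not np.isfinite(s0_2) or s0_2 <= 0:
        raise ValueError("degenerate prior variance")
    return d0, s0_2


def moderated_t_test(
    expr: GeneExpressionMatrix,
    groups: dict[str, str],
    d0: float | None = None,
) -> list[DegResult]:
    """Moderated two-group t-test per gene (high minus low, log2 scale).

    ``groups`` maps sample id -> 'high'/'low'; both groups need >=2
    samples.  ``d0`` overrides the estimated prior df (0 forces the
    ordinary pooled t).  Missing values are handled per gene with
    pairwise-complete group means/variances.
    """
    if expr.scale != "log2":
        raise ValidationError("moderated_t_test expects log2-scale expression")
    high = [s for s in expr.sample_ids if groups.get(s) == "high"]
    low = [s for s in expr.sample_ids if groups.get(s) == "low"]
    if len(high) < 2 or len(low) < 2:
        raise ValidationError(
            f"each group needs >=2 samples (high={len(high)}, low={len(low)})"
        )
    xh = expr.values[high].to_numpy(dtype=float)
    xl = expr.values[low].to_numpy(dtype=float)
    nh = (~np.isnan(xh)).sum(axis=1)
    nl = (~np.isnan(xl)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        mh = np.nanmean(xh, axis=1)
        ml = np.nanmean(xl, axis=1)
        vh = np.nan_to_num(np.nanvar(xh, axis=1, ddof=1), nan=0.0)
        vl = np.nan_to_num(np.nanvar(xl, axis=1, ddof=1), nan=0.0)
    log2fc = mh - ml
    dg = (nh - 1) + (nl - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = ((nh - 1) * vh + (nl - 1) * vl) / dg

    if d0 is None:
        try:
            d0_est, s0_2 = estimate_prior(s2, dg.astype(float))
        except ValueError as exc:
            logger.warning("prior estimation failed (%s); falling back to d0=0", exc)
            d0_est, s0_2 = 0.0, float(np.nan)
    else:
        d0_est = float(d0)
        if d0_est > 0:
            _, s0_2 = estimate_prior(s2, dg.astype(float))
        else:
            s0_2 = float(np.nan)

    results: list[DegResult] = []
    for g, gene in enumerate(expr.gene_ids):
        if nh[g] < 2 or nl[g] < 2:
            results.append(DegResult(gene, float("nan"), float("nan"), 1.0,
                                     float("nan"), float("nan"), d0_est, s0_2,
                                     flagged="insufficient non-missing samples"))
            continue
        fc = float(log2fc[g])
        sg2 = float(s2[g])
        d = float(dg[g])
        if d0_est == 0:
            s2_mod = sg2
            df_total = d
        elif math.isinf(d0_est):
            s2_mod = s0_2
            df_total = math.inf
        else:
            s2_mod = (d0_est * s0_2 + d * sg2) / (d0_est + d)
            df_total = d0_est + d
        se = math.sqrt(s2_mod * (1.0 / nh[g] + 1.0 / nl[g])) if s2_mod > 0 else 0.0
        flagged = None
        if se == 0:
            if fc == 0:
                t = 0.0
                p = 1.0
            else:
                t = math.copysign(math.inf, fc)
                p = 0.0
                flagged = "zero variance with nonzero fold change"
        else:
            t = fc / se
            if math.isinf(df_total):
                p = float(2.0 * stats.norm.sf(abs(t)))
            else:
                p = float(2.0 * stats.t.sf(abs(t), df=df_total))
        results.append(DegResult(gene, fc, t, p, sg2, s2_mod, d0_est, s0_2, flagged))
    return results


def select_degs(
    results: list[DegResult], fc_threshold: float = 1.5, p_threshold: float = 0.05
) -> set[str]:
    """Genes with |log2fc| > log2(fc_threshold) and p < p_threshold (both tails)."""
    if not results:
        raise ValueError("empty DEG result list")
    cut = math.log2(fc_threshold)
    return {
        r.gene_id
        for r in results
        if np.isfinite(r.log2fc) and abs(r.log2fc) > cut and r.p < p_threshold
    }


def deg_table(results: list[DegResult], selected: set[str] | None = None) -> pd.DataFrame:
    rows = [
        {
            "gene_id": r.gene_id, "log2fc": r.log2fc, "t": r.t_stat, "p": r.p,
            "s2": r.s2, "s2_moderated": r.s2_moderated,
            "selected": (r.gene_id in selected) if selected is not None else None,
        }
        for r in results
    ]
    return pd.DataFrame(rows).set_index("gene_id")


def fpkm(counts: BulkCountsMatrix) -> GeneExpressionMatrix:
    """Fragments per kilobase of exon per million mapped reads.

    FPKM_gj = fragments_gj / (mapped_reads_millions_j * exon_length_kb_g).
    """
    frags = counts.fragment_counts.to_numpy(dtype=float)
    lengths = counts.exon_length_kb.to_numpy(dtype=float)[:, None]
    depth = counts.mapped_reads_millions.to_numpy(dtype=float)[None, :]
    vals = frags / (depth * lengths)
    return GeneExpressionMatrix(
        pd.DataFrame(vals, index=counts.fragment_counts.index,
                     columns=counts.fragment_counts.columns),
        scale="linear",
    )


def bulk_deg_select(
    fpkm_matrix: GeneExpressionMatrix,
    groups: dict[str, str],
    p_threshold: float = 0.05,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
) -> set[str]:
    """Bulk RNA-seq DEG gate: FC > 2 or FC < 0.5, with a two-group test.

    Fold change is computed on linear FPKM group means (pseudocount
    1e-6); the p-value comes from a pooled two-sample t on
    log2(FPKM + 1), the two-group equivalent of an F test between
    nested linear models (F = t^2).
    """
    a = [s for s in fpkm_matrix.sample_ids if groups.get(s) == "high"]
    b = [s for s in fpkm_matrix.sample_ids if groups.get(s) == "low"]
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("both groups need >=2 samples")
    xa = fpkm_matrix.values[a].to_numpy(dtype=float)
    xb = fpkm_matrix.values[b].to_numpy(dtype=float)
    fc = (xa.mean(axis=1) + FC_EPS) / (xb.mean(axis=1) + FC_EPS)
    la, lb = np.log2(xa + 1.0), np.log2(xb + 1.0)
    t, p = stats.ttest_ind(la, lb, axis=1)
    p = np.nan_to_num(p, nan=1.0)
    passed = ((fc > fc_up) | (fc < fc_down)) & (p < p_threshold)
    return {g for g, ok in zip(fpkm_matrix.gene_ids, passed) if ok}
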
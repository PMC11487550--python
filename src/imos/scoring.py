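"""Rank-based single-sample signature scoring and cohort stratification.

The immune score is a single-sample gene-set enrichment score (ssGSEA):
within each sample, genes are ranked by descending expression and a
Kolmogorov-Smirnov-style running sum is accumulated along that ranking.
Signature genes push the sum up in proportion to ``|rank|^alpha``
(normalized over the signature); non-signature genes push it down by a
uniform step.  The score is the sum of the running-sum values over all
positions, so it depends on the expression values only through their
within-sample ranks — the scale the ESTIMATE-style immune score needs
to compare heterogeneous cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datamodel import GeneExpressionMatrix, GeneSignature, ValidationError

logger = logging.getLogger("imos.scoring")

__all__ = ["ImmuneScoreResult", "ssgsea_score", "stratify_by_score"]


@dataclass
class ImmuneScoreResult:
    scores: pd.Series            # sample_id -> enrichment score
    signature_name: str
    alpha: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise ValidationError("immune scores must be finite")


def _sample_score(values: np.ndarray, gene_ids: np.ndarray, in_sig: np.ndarray,
                  alpha: float) -> float:
    """Running-sum enrichment score for one sample.

    Ties get average ranks (equal weights); the walking order among tied
    genes is fixed by gene id so the score is invariant to input gene
    order.  Missing values rank last.
    """
    n = values.size
    filled = np.where(np.isnan(values), -np.inf, values)
    ranks = rankdata(filled, method="average")          # 1 = lowest expression
    # walk genes from highest expression to lowest; break ties by gene id
    order = np.lexsort((gene_ids, -ranks))
    weights = np.abs(ranks[order]) ** alpha
    hit = in_sig[order]
    n_miss = n - int(in_sig.sum())
    hit_total = weights[hit].sum()
    if hit_total == 0 or n_miss == 0:
        return 0.0
    p_hit = np.cumsum(np.where(hit, weights, 0.0)) / hit_total
    p_miss = np.cumsum(np.where(hit, 0.0, 1.0)) / n_miss
    return float(np.sum(p_hit - p_miss))


def ssgsea_score(
    expr: GeneExpressionMatrix, signature: GeneSignature, alpha: float = 0.25
) -> ImmuneScoreResult:
    """Score every sample against a signature (ssGSEA running sum).

    Requires at least one signature gene in the matrix.  A sample with
    constant expression carries no rank information and scores 0 (with a
    warning).
    """
    gene_ids = np.asarray(expr.gene_ids)
    in_sig = np.isin(gene_ids, list(signature.genes))
    if not in_sig.any():
        raise ValidationError(
            f"no gene of signature {signature.name!r} present in the expression matrix"
        )
    if expr.n_genes < 2:
        raise ValidationError("ssGSEA needs at least 2 genes")
    mat = expr.values.to_numpy(dtype=float)
    scores = {}
    for j, sample in enumerate(expr.sample_ids):
        col = mat[:, j]
        finite = col[~np.isnan(col)]
        if finite.size and np.ptp(finite) == 0:
            logger.warning("sample %s has constant expression; score set to 0", sample)
            scores[sample] = 0.0
            continue
        scores[sample] = _sample_score(col, gene_ids, in_sig, alpha)
    return ImmuneScoreResult(pd.Series(scores, name=signature.name),
                             signature_name=signature.name, alpha=alpha)


def stratify_by_score(
    scores: ImmuneScoreResult | pd.Series, rule: str = "median", q: float = 0.5
) -> dict[str, str]:
    """Split samples into immune-'high'/'low' groups by score.

    ``rule='median'`` puts samples strictly above the median in 'high';
    samples exactly at the median go 'low'.  ``rule='quantile'`` targets
    a high-group fraction of ``q``: the cutoff is the (1-q) score
    quantile, again with strict > for 'high'.
    """
    s = scores.scores if isinstance(scores, ImmuneScoreResult) else scores
    if len(s) < 2:
        raise ValidationError("stratification needs >=2 samples")
    vals = s.to_numpy(dtype=float)
    if np.ptp(vals) == 0:
        raise ValidationError("all scores identical; no stratification possible")
    if rule == "median":
        cutoff = np.median(vals)
    elif rule == "quantile":
        cutoff = np.quantile(vals, 1.0 - q)
    else:
        raise ValueError(f"unknown stratification rule {rule!r}")
    groups = {sid: ("high" if v > cutoff else "low") for sid, v in s.items()}
    n_high = sum(1 for g in groups.values() if g == "high")
    logger.info("stratified %d samples: %d high / %d low", len(groups), n_high,
                len(groups) - n_high)
    return groups
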
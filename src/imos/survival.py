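"""Survival statistics: product-limit estimation, two-group log-rank
testing with a directionality call, genome-wide per-gene survival
screening, and shared utilities (Pearson test, Benjamini-Hochberg FDR).

The log-rank implementation follows the Mantel-Cox form: at each
distinct event time the expected events per group come from the
hypergeometric distribution of events over the at-risk sets; censored
observations at an event time are still at risk at that time.  The
direction call compares observed vs expected events in the designated
"high" group: more deaths than expected in high expressers marks a
harmful gene, fewer marks a beneficial one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import Cohort

logger = logging.getLogger("imos.survival")

__all__ = [
    "SurvivalCurve",
    "LogRankResult",
    "GeneSurvivalResult",
    "km_estimate",
    "logrank_test",
    "split_by_gene_expression",
    "gene_survival_screen",
    "bh_fdr",
    "pearson_test",
    "SkipSignal",
]

HIGH_WORSE = "high_worse"
HIGH_BETTER = "high_better"
NO_DIRECTION = "none"


class SkipSignal(Exception):
    """A per-item precondition failed; record as skipped, not an error."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass
class SurvivalCurve:
    event_times: np.ndarray          # distinct times with >=1 event, increasing
    survival_prob: np.ndarray        # S(t) just after each event time
    at_risk: np.ndarray              # n at risk just before each event time

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_prob[idx])


@dataclass
class LogRankResult:
    chi2: float
    p: float
    observed: dict[str, float]
    expected: dict[str, float]
    direction: str = NO_DIRECTION


@dataclass
class GeneSurvivalResult:
    gene_id: str
    p: float
    direction: str
    n_high: int
    n_low: int
    split_quantile: float
    chi2: float = np.nan
    q: float | None = None


def _as_survival_arrays(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times <= 0).any():
        raise ValueError("survival times must be > 0")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be 0/1")
    return times, events


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    S(t) = prod over distinct event times t_i <= t of (1 - d_i / n_i),
    where d_i counts deaths at t_i and n_i the subjects at risk just
    before t_i.  Censored-only times affect at-risk counts only.
    """
    times, events = _as_survival_arrays(times, events)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    n = times.size
    event_times, surv, at_risk = [], [], []
    s = 1.0
    for t in np.unique(times[events == 1]):
        n_i = int(np.sum(times >= t))
        d_i = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d_i / n_i
        event_times.append(t)
        surv.append(s)
        at_risk.append(n_i)
    return SurvivalCurve(
        np.asarray(event_times), np.asarray(surv), np.asarray(at_risk, dtype=int)
    )


def logrank_test(times, events, groups, high_label=None) -> LogRankResult:
    """Two-group log-rank (Mantel-Cox) test with a direction call.

    ``groups`` must take exactly two values.  ``high_label`` designates
    which group plays "high" for the direction call; defaults to the
    lexicographically larger label.  Zero events overall is flagged:
    chi2 = 0, p = 1, direction 'none'.
    """
    times, events = _as_survival_arrays(times, events)
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    if len(labels) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {labels}")
    for lab in labels:
        if not np.any(groups == lab):
            raise ValueError(f"group {lab!r} is empty")
    if high_label is None:
        high_label = labels[1]
    elif high_label not in labels:
        raise ValueError(f"high_label {high_label!r} not among groups {labels}")
    other = labels[0] if high_label == labels[1] else labels[1]

    in_high = groups == high_label
    o_high = e_high = var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n_t = int(at_risk.sum())
        n_h = int((at_risk & in_high).sum())
        d_t = int(((times == t) & (events == 1)).sum())
        d_h = int(((times == t) & (events == 1) & in_high).sum())
        o_high += d_h
        e_high += d_t * n_h / n_t
        if n_t > 1:
            var += d_t * (n_h / n_t) * (1 - n_h / n_t) * (n_t - d_t) / (n_t - 1)

    total_events = int(events.sum())
    o_other = total_events - o_high
    e_other = total_events - e_high
    if total_events == 0 or var <= 0:
        return LogRankResult(
            chi2=0.0, p=1.0,
            observed={high_label: o_high, other: o_other},
            expected={high_label: e_high, other: e_other},
            direction=NO_DIRECTION,
        )
    chi2 = (o_high - e_high) ** 2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    if o_high > e_high:
        direction = HIGH_WORSE
    elif o_high < e_high:
        direction = HIGH_BETTER
    else:
        direction = NO_DIRECTION
    return LogRankResult(
        chi2=float(chi2), p=p,
        observed={high_label: float(o_high), other: float(o_other)},
        expected={high_label: float(e_high), other: float(e_other)},
        direction=direction,
    )


def _quantile_split(values: np.ndarray, q: float) -> np.ndarray:
    """Boolean high mask: strictly above the (1-q) quantile; ties -> low.

    ``q`` is the target fraction assigned to the high group; the median
    rule is q = 0.5.
    """
    cutoff = np.quantile(values, 1.0 - q)
    return values > cutoff


def split_by_gene_expression(cohort: Cohort, gene_id: str, q: float = 0.5) -> dict[str, str]:
    """Assign each sample to 'high'/'low' by one gene's expression.

    Missing-expression samples are excluded; a zero-variance gene raises
    :class:`SkipSignal` (distinct from an error); fewer than 4 usable
    samples is an error.
    """
    if gene_id not in cohort.expression.values.index:
        raise SkipSignal(f"gene {gene_id!r} absent from expression matrix")
    x = cohort.expression.values.loc[gene_id]
    x = x[~x.isna()]
    if len(x) < 4:
        raise ValueError(f"gene {gene_id!r}: fewer than 4 samples with expression")
    vals = x.to_numpy(dtype=float)
    if np.ptp(vals) == 0:
        raise SkipSignal(f"gene {gene_id!r}: constant expression")
    high = _quantile_split(vals, q)
    if high.all() or (~high).all():
        raise SkipSignal(f"gene {gene_id!r}: degenerate split at q={q}")
    return {s: ("high" if h else "low") for s, h in zip(x.index, high)}


def gene_survival_screen(
    cohort: Cohort,
    gene_ids=None,
    q: float = 0.5,
    alpha: float = 0.05,
    fdr: bool = False,
) -> tuple[list[GeneSurvivalResult], dict[str, str]]:
    """Per-gene high/low split + log-rank across a gene list.

    Returns (results, skipped) where ``skipped`` maps gene id -> reason.
    Raw p vs ``alpha`` is the default gate; with ``fdr=True`` BH q-values
    are attached for the caller to gate on instead.
    """
    if gene_ids is None:
        gene_ids = cohort.expression.gene_ids
    clin = cohort.clinical.table
    results: list[GeneSurvivalResult] = []
    skipped: dict[str, str] = {}
    for gene in gene_ids:
        try:
            assignment = split_by_gene_expression(cohort, gene, q=q)
        except SkipSignal as sig:
            skipped[gene] = sig.reason
            continue
        except ValueError as exc:
            skipped[gene] = str(exc)
            continue
        samples = list(assignment)
        sub = clin.loc[samples]
        groups = np.array([assignment[s] for s in samples])
        lr = logrank_test(
            sub["os_time"].to_numpy(), sub["os_event"].to_numpy(),
            groups, high_label="high",
        )
        results.append(
            GeneSurvivalResult(
                gene_id=gene, p=lr.p, direction=lr.direction,
                n_high=int((groups == "high").sum()),
                n_low=int((groups == "low").sum()),
                split_quantile=q, chi2=lr.chi2,
            )
        )
    if fdr and results:
        qvals = bh_fdr([r.p for r in results])
        for r, qv in zip(results, qvals):
            r.q = float(qv)
    if skipped:
        logger.info("survival screen skipped %d genes", len(skipped))
    return results, skipped


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pearson_test(x, y):
    """Pearson r with two-sided t-distribution p on pairwise-complete pairs.

    Returns (r, p), or None when the correlation is undefined (either
    variable constant on the complete pairs) so screening callers can
    record a skip.  Fewer than 3 complete pairs is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError(f"pearson_test needs >=3 complete pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
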
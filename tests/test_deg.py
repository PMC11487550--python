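"""Moderated-t differential expression and bulk quantification rules."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from imos.datamodel import GeneExpressionMatrix, ValidationError
from imos.deg import (
    BulkCountsMatrix,
    bulk_deg_select,
    estimate_prior,
    fpkm,
    moderated_t_test,
    select_degs,
)


def _expr(arr, scale="log2"):
    arr = np.asarray(arr, dtype=float)
    return GeneExpressionMatrix(
        pd.DataFrame(arr, index=[f"g{i+1}" for i in range(arr.shape[0])],
                     columns=[f"s{j+1}" for j in range(arr.shape[1])]),
        scale=scale,
    )


def _groups(n_high, n_low):
    return {f"s{j+1}": ("high" if j < n_high else "low") for j in range(n_high + n_low)}


def test_d0_zero_equals_ordinary_pooled_t(rng):
    arr = rng.normal(size=(6, 6))
    expr = _expr(arr)
    results = moderated_t_test(expr, _groups(3, 3), d0=0)
    t_ref, p_ref = stats.ttest_ind(arr[:, :3], arr[:, 3:], axis=1, equal_var=True)
    for r, t, p in zip(results, t_ref, p_ref):
        assert r.t_stat == pytest.approx(t, abs=1e-10)
        assert r.p == pytest.approx(p, abs=1e-10)


def test_identical_group_means_zero_fc(rng):
    base = rng.normal(size=(5, 3))
    arr = np.hstack([base, base])
    results = moderated_t_test(_expr(arr), _groups(3, 3))
    assert all(r.log2fc == pytest.approx(0.0) for r in results)


def test_moderated_quantities_match_stated_formulas(rng):
    """Independent step-by-step evaluation of the moderation formulas on
    a 10-gene fixture with heterogeneous variances."""
    n_h, n_l = 4, 5
    arr = rng.normal(size=(10, n_h + n_l)) * rng.uniform(0.3, 3.0, size=(10, 1))
    expr = _expr(arr)
    results = moderated_t_test(expr, _groups(n_h, n_l))
    d0, s0_2 = results[0].d0, results[0].s0_2
    assert np.isfinite(d0) and d0 > 0
    for g, r in enumerate(results):
        xh, xl = arr[g, :n_h], arr[g, n_h:]
        fc = xh.mean() - xl.mean()
        s2 = ((n_h - 1) * xh.var(ddof=1) + (n_l - 1) * xl.var(ddof=1)) / (n_h + n_l - 2)
        s2_mod = (d0 * s0_2 + (n_h + n_l - 2) * s2) / (d0 + n_h + n_l - 2)
        t = fc / np.sqrt(s2_mod * (1 / n_h + 1 / n_l))
        p = 2 * stats.t.sf(abs(t), df=d0 + n_h + n_l - 2)
        assert r.log2fc == pytest.approx(fc, abs=1e-12)
        assert r.s2 == pytest.approx(s2, abs=1e-12)
        assert r.s2_moderated == pytest.approx(s2_mod, abs=1e-12)
        assert r.t_stat == pytest.approx(t, abs=1e-10)
        assert r.p == pytest.approx(p, abs=1e-10)
        # shrinkage bracketing
        lo, hi = min(s2, s0_2), max(s2, s0_2)
        assert lo - 1e-12 <= r.s2_moderated <= hi + 1e-12


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_moderated_t_matches_limma(tmp_path, rng):
    """Cross-check hyperparameter estimation + moderated t against the
    reference empirical-Bayes implementation in Bioconductor limma."""
    arr = rng.normal(size=(60, 10)) * rng.uniform(0.3, 3.0, size=(60, 1))
    arr[:5, :5] += 2.0
    expr = _expr(arr)
    results = moderated_t_test(expr, _groups(5, 5))
    expr.values.to_csv(tmp_path / "expr.tsv", sep="\t")
    script = textwrap.dedent("""
        suppressMessages(library(limma))
        x <- as.matrix(read.delim("expr.tsv", row.names = 1))
        design <- cbind(Intercept = 1, High = c(rep(1, 5), rep(0, 5)))
        fit <- eBayes(lmFit(x, design))
        out <- data.frame(t = fit$t[, "High"], p = fit$p.value[, "High"],
                          d0 = fit$df.prior, s02 = fit$s2.prior)
        write.table(out, "limma.tsv", sep = "\t", quote = FALSE)
    """)
    (tmp_path / "run.R").write_text(script)
    subprocess.run(["Rscript", "run.R"], cwd=tmp_path, check=True,
                   capture_output=True, timeout=300)
    ref = pd.read_csv(tmp_path / "limma.tsv", sep="\t")
    assert results[0].d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-3)
    assert results[0].s0_2 == pytest.approx(ref["s02"].iloc[0], rel=1e-3)
    for r, t_ref, p_ref in zip(results, ref["t"], ref["p"]):
        assert r.t_stat == pytest.approx(t_ref, rel=1e-3, abs=1e-6)
        assert r.p == pytest.approx(p_ref, rel=1e-3, abs=1e-12)


def test_prior_estimation_degenerate_falls_back(caplog):
    arr = np.ones((3, 6))  # zero variance everywhere
    with caplog.at_level("WARNING", logger="imos.deg"):
        results = moderated_t_test(_expr(arr), _groups(3, 3))
    assert results[0].d0 == 0.0
    assert results[0].p == 1.0  # zero variance, zero fold change


def test_group_size_precondition():
    with pytest.raises(ValidationError, match=">=2"):
        moderated_t_test(_expr(np.zeros((2, 3))), _groups(1, 2))
    with pytest.raises(ValidationError, match="log2"):
        moderated_t_test(_expr(np.zeros((2, 4)), scale="linear"), _groups(2, 2))


def test_select_degs_gates_and_monotonicity(rng):
    from imos.deg import DegResult

    def mk(g, fc, p):
        return DegResult(g, fc, 0.0, p, 1.0, 1.0, 1.0, 1.0)

    results = [
        mk("pass_up", 0.60, 0.01),     # FC ~1.52, both gates pass
        mk("fc_fail", 0.50, 0.001),    # FC ~1.41 < 1.5
        mk("p_fail", 2.0, 0.2),
        mk("pass_down", -0.9, 0.01),   # both tails kept
    ]
    assert select_degs(results) == {"pass_up", "pass_down"}
    strict = select_degs(results, fc_threshold=2.0, p_threshold=0.001)
    relaxed = select_degs(results, fc_threshold=1.2, p_threshold=0.05)
    assert strict <= relaxed
    assert select_degs([mk("g", 1.0, 1.0)]) == set()


def _counts(frags, lengths, depth):
    frags = np.atleast_2d(np.asarray(frags, dtype=float))
    return BulkCountsMatrix(
        pd.DataFrame(frags, index=[f"g{i+1}" for i in range(frags.shape[0])],
                     columns=[f"s{j+1}" for j in range(frags.shape[1])]),
        pd.Series(lengths, index=[f"g{i+1}" for i in range(frags.shape[0])]),
        pd.Series(depth, index=[f"s{j+1}" for j in range(frags.shape[1])]),
    )


def test_fpkm_unit_and_worked_cases():
    m = fpkm(_counts([[10, 0]], [1.0], [1.0, 1.0]))
    assert m.values.loc["g1", "s1"] == pytest.approx(10.0)
    assert m.values.loc["g1", "s2"] == 0.0
    m = fpkm(_counts([[250, 250]], [2.0], [5.0, 5.0]))
    assert m.values.loc["g1", "s1"] == pytest.approx(25.0)
    with pytest.raises(ValidationError, match="mapped_reads"):
        _counts([[1, 1]], [1.0], [0.0, 1.0])


def test_fpkm_linearity_and_inverse_proportionality(rng):
    frags = rng.integers(0, 1000, size=(8, 3)).astype(float)
    lengths = rng.uniform(0.5, 5.0, 8)
    depth = rng.uniform(1.0, 50.0, 3)
    base = fpkm(_counts(frags, lengths, depth)).values.to_numpy()
    doubled = fpkm(_counts(2 * frags, lengths, depth)).values.to_numpy()
    assert np.allclose(doubled, 2 * base)
    deeper = fpkm(_counts(frags, lengths, 4 * depth)).values.to_numpy()
    assert np.allclose(deeper, base / 4)
    longer = fpkm(_counts(frags, 2 * lengths, depth)).values.to_numpy()
    assert np.allclose(longer, base / 2)


def test_bulk_deg_fc_and_p_gates():
    # strong separation, FC=3 -> selected; FC=1.8 -> FC gate fails;
    # FC=0.4 with huge within-group spread -> p gate fails
    mat = _expr(
        [[3.0, 3.0, 3.001, 1.0, 1.0, 1.001],
         [1.8, 1.8, 1.801, 1.0, 1.0, 1.001],
         [0.05, 0.75, 0.4, 0.1, 1.9, 1.0]],
        scale="linear",
    )
    groups = _groups(3, 3)
    selected = bulk_deg_select(mat, groups)
    assert selected == {"g1"}
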
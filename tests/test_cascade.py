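"""Cascade orchestration: stage gates, classification, validation rules,
candidate ranking and report determinism."""

import json

import numpy as np
import pandas as pd
import pytest

from conftest import build_cohort
from imos.cascade import (
    ImosConfig,
    StageError,
    classify_ibg_ihg,
    nominate_candidates,
    run_imos,
    run_imos_objects,
    screen_ipg,
    validate_cross_cohort,
)
from imos.multiomics import OmicsEvidence, ProbeSurvival
from imos.simulate import generate_bundle, write_bundle
from imos.singlecell import SpecificityResult
from imos.survival import GeneSurvivalResult


def _gsr(gene, p=0.01, direction="high_worse"):
    return GeneSurvivalResult(gene, p, direction, 10, 10, 0.5)


def test_config_validation_and_yaml(tmp_path):
    with pytest.raises(ValueError):
        ImosConfig(deg_p_threshold=2.0)
    with pytest.raises(ValueError):
        ImosConfig(validation_min_cohorts=0)
    y = tmp_path / "cfg.yaml"
    y.write_text("deg_fc_threshold: 2.0\nseed: 7\ninputs:\n  expression: x.tsv\n")
    cfg, inputs = ImosConfig.from_yaml(y)
    assert cfg.deg_fc_threshold == 2.0 and cfg.seed == 7
    assert inputs == {"expression": "x.tsv"}
    y.write_text("bogus_key: 1\n")
    with pytest.raises(ValueError, match="bogus_key"):
        ImosConfig.from_yaml(y)


def test_classify_partition():
    ipg = [_gsr("a", direction="high_worse"), _gsr("b", direction="high_better"),
           _gsr("c", direction="none")]
    ibg, ihg = classify_ibg_ihg(ipg)
    assert ibg == {"b"} and ihg == {"a"}
    assert len(ibg) + len(ihg) + 1 == len(ipg)  # 'none' excluded


def _directional_cohort(name, high_dies_early: bool, n=40):
    """Cohort where one gene's high-expressers die clearly early (or late)."""
    expr = {"gX": list(range(n))}
    half = n // 2
    if high_dies_early:
        times = [50.0 + i for i in range(half)] + [5.0 + 0.1 * i for i in range(half)]
    else:
        times = [5.0 + 0.1 * i for i in range(half)] + [50.0 + i for i in range(half)]
    events = [1] * n
    return build_cohort(times, events, expr, name=name)


def test_validate_cross_cohort_k_of_n_and_direction_consistency():
    ipg = [_gsr("gX", direction="high_worse")]
    consistent = _directional_cohort("v1", high_dies_early=True)
    flipped = _directional_cohort("v2", high_dies_early=False)
    null = build_cohort(
        [10.0 + (i % 7) for i in range(40)], [1] * 40,
        {"gX": [float((i * 13) % 40) for i in range(40)]}, name="v3",
    )
    cfg = ImosConfig()
    cipg, detail = validate_cross_cohort(ipg, [consistent, null], cfg)
    assert cipg == {"gX"}  # significant + consistent in 1 of 2, k=1

    cipg, detail = validate_cross_cohort(ipg, [flipped, null], cfg)
    assert cipg == set()  # significant but direction flipped -> not credible
    assert detail["gX"][0]["direction"] == "high_better"

    loose = ImosConfig(require_direction_consistency=False)
    cipg, _ = validate_cross_cohort(ipg, [flipped, null], loose)
    assert cipg == {"gX"}

    strict = ImosConfig(validation_min_cohorts=2)
    cipg, _ = validate_cross_cohort(ipg, [consistent, null], strict)
    assert cipg == set()


def test_validate_missing_gene_counts_as_not_validated():
    ipg = [_gsr("gAbsent", direction="high_worse")]
    cohort = _directional_cohort("v1", True)
    cipg, detail = validate_cross_cohort(ipg, [cohort], ImosConfig())
    assert cipg == set()
    assert detail["gAbsent"][0]["validated"] is False


def test_screen_ipg_degenerate_gates():
    bundle = generate_bundle(3, n_samples=60, n_genes=60, n_validation=1,
                             validation_sizes=(40,), n_cells_per_type=20)
    cfg = ImosConfig(deg_p_threshold=1e-300)
    degs, table, ipg, skipped = screen_ipg(bundle.discovery, bundle.signature, cfg)
    assert degs == set() and ipg == []


def _evidence(gene, cnv_r=0.5, all_flags=True):
    ev = OmicsEvidence(gene_id=gene)
    if all_flags:
        ev.cnv_concordant = True
        ev.cnv_expr_r = cnv_r
        ev.cnv_survival_p = 0.01
        ev.cnv_survival_direction = "duplication_worse"
        ev.meth_negative_flag = True
        ev.meth_probe_survival = [ProbeSurvival("cg1", 0.01, "low_methylation_worse")]
    else:
        ev.cnv_expr_r = cnv_r
    return ev


def test_nominate_ranking_flags_and_tie_rule():
    cfg = ImosConfig()
    spec = {
        "gFull": SpecificityResult("gFull", {"mac": 2.0}, "mac", 0.9),
        "gTieA": SpecificityResult("gTieA", {"mac": 2.0}, "mac", 0.9),
        "gTieB": SpecificityResult("gTieB", {"mac": 2.0}, "mac", 0.9),
    }
    evidence = {
        "gFull": _evidence("gFull", cnv_r=0.5),
        "gTieA": _evidence("gTieA", cnv_r=0.3),
        "gTieB": _evidence("gTieB", cnv_r=0.8),
    }
    ranked = nominate_candidates({"gFull", "gTieA", "gTieB", "gMissing"},
                                 evidence, spec, cfg)
    assert ranked[0].evidence_count == 5
    # equal counts: higher CNV-expression r ranks first
    tie_order = [c.gene_id for c in ranked if c.gene_id in ("gTieA", "gTieB")]
    assert tie_order == ["gTieB", "gTieA"]
    missing = [c for c in ranked if c.gene_id == "gMissing"][0]
    assert missing.evidence_count == 0 and not any(missing.flags.values())
    assert [c.rank for c in ranked] == [1, 2, 3, 4]


def test_run_imos_missing_omics_input_names_stage(tmp_path):
    bundle = generate_bundle(5, n_samples=60, n_genes=60, n_validation=1,
                             validation_sizes=(40,), n_cells_per_type=20)
    paths = write_bundle(bundle, tmp_path)
    inputs = {
        "expression": paths["expression.tsv"],
        "clinical": paths["clinical.tsv"],
        "signature": paths["signature.txt"],
        "cnv": str(tmp_path / "does_not_exist.tsv"),
    }
    with pytest.raises(StageError, match="omics"):
        run_imos(ImosConfig(), inputs)


def test_run_imos_from_files_deterministic_and_invariant(tmp_path):
    bundle = generate_bundle(9, n_samples=120, n_genes=150, n_validation=2,
                             validation_sizes=(60, 60), n_cells_per_type=40)
    paths = write_bundle(bundle, tmp_path / "in")
    inputs = {
        "expression": paths["expression.tsv"],
        "clinical": paths["clinical.tsv"],
        "signature": paths["signature.txt"],
        "validation1_expression": paths["validation1_expression.tsv"],
        "validation1_clinical": paths["validation1_clinical.tsv"],
        "validation2_expression": paths["validation2_expression.tsv"],
        "validation2_clinical": paths["validation2_clinical.tsv"],
        "cnv": paths["cnv.tsv"],
        "methylation_beta": paths["methylation_beta.tsv"],
        "methylation_map": paths["methylation_map.tsv"],
        "mutations": paths["mutations.tsv"],
        "single_cell": paths["single_cell"],
    }
    cfg = ImosConfig(seed=9)
    report1 = run_imos(cfg, inputs, outdir=tmp_path / "out1")
    report2 = run_imos(cfg, inputs, outdir=tmp_path / "out2")
    report1.check_invariants()
    b1 = (tmp_path / "out1/report.json").read_bytes()
    b2 = (tmp_path / "out2/report.json").read_bytes()
    assert b1 == b2
    assert (tmp_path / "out1/manifest.json").exists()
    counts = report1.to_json_dict()["counts"]
    assert counts["deg"] >= counts["ipg"] >= counts["cipg"]


def test_cascade_threshold_monotonicity():
    bundle = generate_bundle(7, n_samples=150, n_genes=150, n_validation=1,
                             validation_sizes=(70,), n_cells_per_type=20)
    loose = run_imos_objects(ImosConfig(), bundle.discovery, bundle.signature,
                             bundle.validation)
    tight = run_imos_objects(
        ImosConfig(deg_fc_threshold=2.0, deg_p_threshold=0.01, survival_alpha=0.01),
        bundle.discovery, bundle.signature, bundle.validation,
    )
    assert tight.deg_set <= loose.deg_set
    assert {r.gene_id for r in tight.ipg} <= {r.gene_id for r in loose.ipg}
    assert tight.cipg <= loose.cipg
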
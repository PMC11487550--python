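"""The full discovery cascade: immune scoring -> DEG -> survival screen
-> cross-cohort validation -> multi-omic evidence gates -> single-cell
specificity -> ranked candidate report.

Set inclusions hold by construction on every run:
DEG >= IPG >= (IBG u IHG) >= cIPG >= candidates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as imos_io
from .datamodel import Cohort, GeneSignature, SingleCellDataset
from .deg import deg_table, moderated_t_test, select_degs
from .multiomics import OmicsEvidence, compute_omics_evidence, evidence_table
from .scoring import ssgsea_score, stratify_by_score
from .singlecell import SpecificityResult, normalize_log1p, qc_filter, specificity_score
from .survival import GeneSurvivalResult, gene_survival_screen

logger = logging.getLogger("imos.cascade")

__all__ = [
    "ImosConfig",
    "ImosReport",
    "StageError",
    "screen_ipg",
    "classify_ibg_ihg",
    "validate_cross_cohort",
    "nominate_candidates",
    "run_imos",
    "run_imos_objects",
]


class StageError(RuntimeError):
    """A cascade stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class ImosConfig:
    deg_fc_threshold: float = 1.5
    deg_p_threshold: float = 0.05
    survival_alpha: float = 0.05
    split_quantile: float = 0.5
    validation_min_cohorts: int = 1
    require_direction_consistency: bool = True
    cnv_fdr: float = 0.05
    meth_fdr: float = 0.05
    specificity_min: float = 0.5
    candidate_pool: str = "cihg"          # or "cibg"
    ssgsea_alpha: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.deg_p_threshold <= 1 and 0 <= self.survival_alpha <= 1):
            raise ValueError("p thresholds must lie in [0, 1]")
        if self.deg_fc_threshold < 1:
            raise ValueError("fold-change threshold must be >= 1")
        if not 0 < self.split_quantile < 1:
            raise ValueError("split quantile must lie in (0, 1)")
        if self.validation_min_cohorts < 1:
            raise ValueError("validation_min_cohorts must be >= 1")
        if self.candidate_pool not in ("cihg", "cibg"):
            raise ValueError("candidate_pool must be 'cihg' or 'cibg'")

    @classmethod
    def from_yaml(cls, path) -> tuple["ImosConfig", dict]:
        """Load config + input path map from a YAML file."""
        doc = yaml.safe_load(Path(path).read_text()) or {}
        inputs = doc.pop("inputs", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc), inputs

    def content_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class CandidateRecord:
    gene_id: str
    rank: int
    evidence_count: int
    flags: dict[str, bool]
    cnv_expr_r: float
    dominant_cell_type: str | None
    specificity: float | None


@dataclass
class ImosReport:
    config: ImosConfig
    deg_set: set[str]
    deg_results: pd.DataFrame
    ipg: list[GeneSurvivalResult]
    ibg: set[str]
    ihg: set[str]
    cipg: set[str]
    cibg: set[str]
    cihg: set[str]
    validation_detail: dict[str, list[dict]]
    evidence: dict[str, OmicsEvidence]
    specificity: dict[str, SpecificityResult]
    candidates: list[CandidateRecord]
    skipped: dict[str, dict[str, str]] = field(default_factory=dict)

    def check_invariants(self) -> None:
        ipg_genes = {r.gene_id for r in self.ipg}
        assert ipg_genes <= self.deg_set, "IPG must be a subset of DEG"
        assert (self.ibg | self.ihg) <= ipg_genes, "IBG u IHG must be within IPG"
        assert self.ibg.isdisjoint(self.ihg), "IBG and IHG must be disjoint"
        assert self.cipg <= (self.ibg | self.ihg), "cIPG must come from IBG u IHG"
        assert self.cibg | self.cihg == self.cipg
        pool = self.cihg if self.config.candidate_pool == "cihg" else self.cibg
        assert {c.gene_id for c in self.candidates} <= pool

    def to_json_dict(self) -> dict:
        return {
            "config": dataclasses.asdict(self.config),
            "deg": sorted(self.deg_set),
            "ipg": [
                {"gene_id": r.gene_id, "p": r.p, "direction": r.direction,
                 "n_high": r.n_high, "n_low": r.n_low}
                for r in sorted(self.ipg, key=lambda r: r.gene_id)
            ],
            "ibg": sorted(self.ibg),
            "ihg": sorted(self.ihg),
            "cipg": sorted(self.cipg),
            "cibg": sorted(self.cibg),
            "cihg": sorted(self.cihg),
            "candidates": [
                {"gene_id": c.gene_id, "rank": c.rank,
                 "evidence_count": c.evidence_count, "flags": c.flags,
                 "cnv_expr_r": None if np.isnan(c.cnv_expr_r) else c.cnv_expr_r,
                 "dominant_cell_type": c.dominant_cell_type,
                 "specificity": c.specificity}
                for c in self.candidates
            ],
            "counts": {
                "deg": len(self.deg_set), "ipg": len(self.ipg),
                "ibg": len(self.ibg), "ihg": len(self.ihg),
                "cipg": len(self.cipg), "cibg": len(self.cibg),
                "cihg": len(self.cihg), "candidates": len(self.candidates),
            },
        }

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(
            json.dumps(self.to_json_dict(), indent=2, sort_keys=True) + "\n"
        )
        self.deg_results.to_csv(outdir / "deg.tsv", sep="\t")
        pd.DataFrame(
            [{"gene_id": r.gene_id, "p": r.p, "direction": r.direction,
              "n_high": r.n_high, "n_low": r.n_low, "q": r.q}
             for r in sorted(self.ipg, key=lambda r: r.gene_id)]
        ).to_csv(outdir / "ipg.tsv", sep="\t", index=False)
        if self.evidence:
            evidence_table(self.evidence).to_csv(outdir / "evidence.tsv", sep="\t")
        pd.DataFrame(
            [{"gene_id": c.gene_id, "rank": c.rank,
              "evidence_count": c.evidence_count, **{f"flag_{k}": v for k, v in c.flags.items()},
              "cnv_expr_r": c.cnv_expr_r, "dominant_cell_type": c.dominant_cell_type,
              "specificity": c.specificity}
             for c in self.candidates]
        ).to_csv(outdir / "candidates.tsv", sep="\t", index=False)


def screen_ipg(
    discovery: Cohort, immune_signature: GeneSignature, config: ImosConfig
) -> tuple[set[str], pd.DataFrame, list[GeneSurvivalResult], dict[str, str]]:
    """Stage 1+2: immune stratification -> moderated-t DEG -> per-gene
    survival screen restricted to the DEG set.

    Returns (deg_set, deg_table, ipg_results, skipped).
    """
    scores = ssgsea_score(discovery.expression, immune_signature, alpha=config.ssgsea_alpha)
    groups = stratify_by_score(scores, rule="median")
    results = moderated_t_test(discovery.expression, groups)
    degs = select_degs(results, config.deg_fc_threshold, config.deg_p_threshold)
    table = deg_table(results, degs)
    if not degs:
        logger.warning("empty DEG set; IPG stage skipped")
        return degs, table, [], {}
    survival_results, skipped = gene_survival_screen(
        discovery, sorted(degs), q=config.split_quantile, alpha=config.survival_alpha
    )
    ipg = [r for r in survival_results if r.p < config.survival_alpha]
    logger.info("screen: %d DEG -> %d IPG", len(degs), len(ipg))
    return degs, table, ipg, skipped


def classify_ibg_ihg(ipg: list[GeneSurvivalResult]) -> tuple[set[str], set[str]]:
    """Partition prognostic genes by direction: high_better -> beneficial
    (IBG), high_worse -> harmful (IHG); direction 'none' is excluded."""
    ibg = {r.gene_id for r in ipg if r.direction == "high_better"}
    ihg = {r.gene_id for r in ipg if r.direction == "high_worse"}
    excluded = len(ipg) - len(ibg) - len(ihg)
    if excluded:
        logger.warning("%d prognostic genes had no direction and were excluded", excluded)
    return ibg, ihg


def validate_cross_cohort(
    ipg: list[GeneSurvivalResult],
    validation_cohorts: list[Cohort],
    config: ImosConfig,
) -> tuple[set[str], dict[str, list[dict]]]:
    """Credibility by k-of-n replication: a gene validates in a cohort
    when its log-rank p < alpha there and (by default) its direction
    matches the discovery direction; it is credible when it validates in
    at least ``validation_min_cohorts`` cohorts.  Genes missing from a
    cohort count as not validated in that cohort.
    """
    if not validation_cohorts:
        raise ValueError("need at least one validation cohort")
    discovery_direction = {r.gene_id: r.direction for r in ipg}
    detail: dict[str, list[dict]] = {g: [] for g in discovery_direction}
    n_hits = {g: 0 for g in discovery_direction}
    genes = sorted(discovery_direction)
    for cohort in validation_cohorts:
        results, skipped = gene_survival_screen(
            cohort, genes, q=config.split_quantile, alpha=config.survival_alpha
        )
        by_gene = {r.gene_id: r for r in results}
        for g in genes:
            r = by_gene.get(g)
            if r is None:
                detail[g].append({"cohort": cohort.name, "p": None,
                                  "direction": None, "validated": False,
                                  "reason": skipped.get(g, "absent")})
                continue
            ok = r.p < config.survival_alpha
            if ok and config.require_direction_consistency:
                ok = r.direction == discovery_direction[g]
            detail[g].append({"cohort": cohort.name, "p": r.p,
                              "direction": r.direction, "validated": bool(ok)})
            if ok:
                n_hits[g] += 1
    cipg = {g for g, k in n_hits.items() if k >= config.validation_min_cohorts}
    logger.info("validation: %d of %d prognostic genes credible", len(cipg), len(genes))
    return cipg, detail


EVIDENCE_FLAGS = (
    "cnv_concordant", "cnv_survival", "meth_negative", "meth_probe_survival",
    "cell_type_specific",
)


def nominate_candidates(
    pool: set[str],
    evidence: dict[str, OmicsEvidence],
    specificity: dict[str, SpecificityResult],
    config: ImosConfig,
) -> list[CandidateRecord]:
    """Rank the candidate pool by how many orthogonal evidence layers
    support each gene.

    Flags: CNV-expression concordance (q < FDR, r > 0); duplication-worse
    survival (p < alpha); >=1 negatively correlated methylation probe
    (q < FDR); >=1 probe with low-methylation-worse survival (p < alpha);
    cell-type specificity >= threshold.  Ties break by CNV-expression r
    (descending), then gene id.  Missing evidence makes a flag false.
    """
    records = []
    for gene in sorted(pool):
        ev = evidence.get(gene)
        spec = specificity.get(gene)
        if ev is None:
            logger.warning("no omics evidence for %s; all omics flags false", gene)
            ev = OmicsEvidence(gene_id=gene)
        flags = {
            "cnv_concordant": bool(ev.cnv_concordant),
            "cnv_survival": bool(
                ev.cnv_survival_p is not None
                and ev.cnv_survival_p < config.survival_alpha
                and ev.cnv_survival_direction == "duplication_worse"
            ),
            "meth_negative": bool(ev.meth_negative_flag),
            "meth_probe_survival": bool(any(
                ps.p < config.survival_alpha and ps.direction == "low_methylation_worse"
                for ps in ev.meth_probe_survival
            )),
            "cell_type_specific": bool(
                spec is not None and spec.specificity_score >= config.specificity_min
            ),
        }
        records.append(CandidateRecord(
            gene_id=gene,
            rank=0,
            evidence_count=sum(flags.values()),
            flags=flags,
            cnv_expr_r=ev.cnv_expr_r,
            dominant_cell_type=spec.dominant_label if spec else None,
            specificity=spec.specificity_score if spec else None,
        ))
    records.sort(key=lambda c: (
        -c.evidence_count,
        -(c.cnv_expr_r if np.isfinite(c.cnv_expr_r) else -np.inf),
        c.gene_id,
    ))
    for i, rec in enumerate(records, 1):
        rec.rank = i
    return records


def run_imos_objects(
    config: ImosConfig,
    discovery: Cohort,
    signature: GeneSignature,
    validation_cohorts: list[Cohort],
    cnv=None,
    methylation=None,
    mutations=None,
    single_cell: SingleCellDataset | None = None,
) -> ImosReport:
    """Run the cascade on in-memory objects.  Omics/single-cell layers
    are optional; absent layers simply contribute no evidence flags."""
    try:
        deg_set, table, ipg, skipped = screen_ipg(discovery, signature, config)
    except Exception as exc:  # noqa: BLE001 - re-tag with the stage name
        raise StageError("screen_ipg", str(exc)) from exc
    ibg, ihg = classify_ibg_ihg(ipg)
    if ipg and validation_cohorts:
        try:
            cipg, detail = validate_cross_cohort(ipg, validation_cohorts, config)
        except Exception as exc:
            raise StageError("validate", str(exc)) from exc
    else:
        cipg, detail = set(), {}
    cipg &= ibg | ihg
    cibg, cihg = cipg & ibg, cipg & ihg
    pool = cihg if config.candidate_pool == "cihg" else cibg

    evidence: dict[str, OmicsEvidence] = {}
    if pool and (cnv is not None or methylation is not None or mutations is not None):
        try:
            evidence = compute_omics_evidence(
                sorted(pool), discovery, cnv=cnv, meth=methylation,
                mutations=mutations, cnv_fdr=config.cnv_fdr, meth_fdr=config.meth_fdr,
            )
        except Exception as exc:
            raise StageError("omics", str(exc)) from exc

    specificity: dict[str, SpecificityResult] = {}
    if pool and single_cell is not None:
        try:
            filtered, _ = qc_filter(single_cell)
            normalized = normalize_log1p(filtered)
            labels = pd.Series({c: filtered.labels[c] for c in filtered.cell_ids})
            for gene in sorted(pool):
                if gene in normalized.columns:
                    specificity[gene] = specificity_score(normalized, labels, gene)
        except Exception as exc:
            raise StageError("single_cell", str(exc)) from exc

    candidates = nominate_candidates(pool, evidence, specificity, config)
    report = ImosReport(
        config=config, deg_set=deg_set, deg_results=table, ipg=ipg,
        ibg=ibg, ihg=ihg, cipg=cipg, cibg=cibg, cihg=cihg,
        validation_detail=detail, evidence=evidence, specificity=specificity,
        candidates=candidates, skipped={"discovery_screen": skipped},
    )
    report.check_invariants()
    return report


def _require(inputs: dict, key: str, stage: str) -> str:
    if key not in inputs or not inputs[key]:
        raise StageError(stage, f"missing required input {key!r}")
    return inputs[key]


def run_imos(config: ImosConfig, inputs: dict, outdir=None) -> ImosReport:
    """Run the cascade from an input path map (the YAML ``inputs`` block).

    Recognized keys: expression, clinical, signature,
    validation{K}_expression/_clinical, cnv, methylation_beta,
    methylation_map, mutations, single_cell (a directory with
    matrix.mtx/barcodes.tsv/features.tsv/labels.tsv).  When ``outdir``
    is given the report (JSON + TSVs) and a run manifest are written
    there; any stage failure names the stage.
    """
    try:
        expr = imos_io.read_expression(_require(inputs, "expression", "io"), scale="log2")
        clinical = imos_io.read_clinical(_require(inputs, "clinical", "io"))
        discovery = imos_io.align_cohort(expr, clinical, "discovery")
        signature = imos_io.read_signature_list(_require(inputs, "signature", "io"))
    except StageError:
        raise
    except Exception as exc:
        raise StageError("io", str(exc)) from exc

    validation_cohorts = []
    k = 1
    while f"validation{k}_expression" in inputs:
        try:
            vexpr = imos_io.read_expression(inputs[f"validation{k}_expression"], scale="log2")
            vclin = imos_io.read_clinical(_require(inputs, f"validation{k}_clinical", "io"))
            validation_cohorts.append(imos_io.align_cohort(vexpr, vclin, f"validation{k}"))
        except StageError:
            raise
        except Exception as exc:
            raise StageError("io", f"validation cohort {k}: {exc}") from exc
        k += 1

    def _read_optional(key, reader, stage):
        if key not in inputs or not inputs[key]:
            return None
        try:
            return reader(inputs[key])
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc

    cnv = _read_optional("cnv", imos_io.read_cnv, "omics")
    methylation = None
    if inputs.get("methylation_beta"):
        try:
            methylation = imos_io.read_methylation(
                inputs["methylation_beta"], _require(inputs, "methylation_map", "omics")
            )
        except StageError:
            raise
        except Exception as exc:
            raise StageError("omics", str(exc)) from exc
    mutations = _read_optional("mutations", imos_io.read_mutations, "omics")
    single_cell = None
    if inputs.get("single_cell"):
        scdir = Path(inputs["single_cell"])
        try:
            single_cell = imos_io.read_single_cell(
                scdir / "matrix.mtx", scdir / "barcodes.tsv",
                scdir / "features.tsv", scdir / "labels.tsv",
            )
        except Exception as exc:
            raise StageError("single_cell", str(exc)) from exc

    report = run_imos_objects(
        config, discovery, signature, validation_cohorts,
        cnv=cnv, methylation=methylation, mutations=mutations, single_cell=single_cell,
    )
    if outdir is not None:
        report.write(outdir)
        manifest = {
            "config_hash": config.content_hash(),
            "config": dataclasses.asdict(config),
            "inputs": {
                k: hashlib.sha256(Path(v).read_bytes()).hexdigest()[:16]
                for k, v in sorted(inputs.items()) if Path(str(v)).is_file()
            },
        }
        (Path(outdir) / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    return report
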
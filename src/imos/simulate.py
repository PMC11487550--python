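"""Synthetic multi-omic cohorts with planted, known-truth structure.

The generator emulates the statistical skeleton of a tumor-cohort
screening study: a latent immune-infiltration factor per sample that a
signature-gene block loads on; genes whose (standardized) expression
enters an exponential proportional-hazards model for overall survival
with known log-hazard coefficients; uniform independent censoring
calibrated to a requested censoring fraction; copy-number states tied
to expression through a thresholded Gaussian copula; methylation
probes whose beta values are a logistic transform of (negative) scaled
expression; mutation carriers with a planted hazard ratio; and a
labeled multi-cell-type single-cell dataset with one or more genes
expressed only in a mapped cell type, plus injected QC-failing cells.

Every generator is a pure function of (parameters, seed).  Defaults
mirror the scale of the motivating study: a discovery cohort of ~400-500
cases, four validation cohorts totalling ~530 cases, and ~60% censoring
(typical of lung-adenocarcinoma overall survival).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import expit
from scipy.stats import norm

from . import io as imos_io
from .datamodel import (
    ClinicalTable,
    CnvMatrix,
    Cohort,
    GeneExpressionMatrix,
    GeneSignature,
    MethylationMatrix,
    MutationTable,
    SingleCellDataset,
)

logger = logging.getLogger("imos.simulate")

__all__ = [
    "SimulationTruth",
    "CohortRealization",
    "MultiomicsBundle",
    "ImosBundle",
    "make_truth",
    "generate_cohort",
    "generate_validation_cohorts",
    "generate_multiomics",
    "generate_single_cell",
    "generate_bundle",
    "write_bundle",
]

MITO_GENES = ("MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-CYB")
VARIANT_CLASSES = ("missense", "nonsense", "frameshift", "splice_site")

# marginal state probabilities for (-2,-1,0,1,2)
CNV_MARGINAL_PLANTED = (0.05, 0.15, 0.45, 0.25, 0.10)
CNV_MARGINAL_NULL = (0.02, 0.08, 0.80, 0.08, 0.02)


@dataclass
class SimulationTruth:
    """Planted structure shared by every generated artifact."""

    seed: int
    gene_ids: list[str]
    signature_loadings: dict[str, float]          # immune-signature gene -> a_g > 0
    planted_beneficial: dict[str, float]          # gene -> beta < 0
    planted_harmful: dict[str, float]             # gene -> beta > 0
    cnv_concordant: dict[str, float]              # gene -> target rho > 0
    meth_anticorrelated: dict[str, float]         # gene -> target rho < 0
    mutated_prognostic: dict[str, tuple[float, float]]  # gene -> (carrier_frac, hazard_ratio)
    specific_genes: dict[str, str]                # gene -> cell type
    prognostic_factor_loading: float = 1.2        # a_g for planted prognostic genes

    def __post_init__(self) -> None:
        universe = set(self.gene_ids)
        for name in ("signature_loadings", "planted_beneficial", "planted_harmful",
                     "cnv_concordant", "meth_anticorrelated", "mutated_prognostic",
                     "specific_genes"):
            extra = set(getattr(self, name)) - universe
            if extra:
                raise ValueError(f"{name} references genes outside the universe: {sorted(extra)[:5]}")
        overlap = set(self.planted_beneficial) & set(self.planted_harmful)
        if overlap:
            raise ValueError(f"genes planted both beneficial and harmful: {sorted(overlap)[:5]}")

    @property
    def planted_prognostic(self) -> dict[str, float]:
        return {**self.planted_beneficial, **self.planted_harmful}

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["mutated_prognostic"] = {g: list(v) for g, v in self.mutated_prognostic.items()}
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationTruth":
        d = json.loads(text)
        d["mutated_prognostic"] = {g: tuple(v) for g, v in d["mutated_prognostic"].items()}
        return cls(**d)


@dataclass
class CohortRealization:
    """Latent variables behind one generated cohort (not part of the inputs)."""

    immune_factor: np.ndarray                 # u_j per sample
    z: pd.DataFrame                           # standardized expression, genes x samples
    carriers: dict[str, np.ndarray]           # mutated-prognostic gene -> bool per sample


@dataclass
class MultiomicsBundle:
    cnv: CnvMatrix
    methylation: MethylationMatrix
    mutations: MutationTable
    realized_cnv_corr: dict[str, float]
    realized_meth_corr: dict[str, float]


def make_truth(
    seed: int,
    n_genes: int = 500,
    n_signature: int = 40,
    n_beneficial: int = 6,
    n_harmful: int = 6,
    beta_beneficial: float = -float(np.log(2.2)),
    beta_harmful: float = float(np.log(2.0)),
    checkpoint_beta: float = float(np.log(3.0)),
    signature_loading: float = 1.2,
    prognostic_loading: float = 0.6,
    rho_cnv: float = 0.6,
    rho_meth: float = -0.5,
    carrier_fraction: float = 0.3,
    mutation_hr: float = 2.0,
    checkpoint_cell_type: str = "macrophage",
) -> SimulationTruth:
    """Standard planted scenario: disjoint signature/beneficial/harmful
    blocks, with the first harmful gene fully planted across every omics
    layer (the 'checkpoint') and the remaining harmful genes serving as
    decoys with no or partial omics evidence.

    Because every prognostic gene loads on the shared immune factor (so
    it can pass the immune-DEG gate), the factor carries the *sum* of
    the planted coefficients; the beneficial and harmful blocks are
    sized so that sum is near zero, otherwise each gene's marginal
    survival direction would be dominated by the shared factor rather
    than its own planted sign.  The checkpoint gets the largest
    coefficient — it is the candidate every layer supports.
    """
    if n_signature + n_beneficial + n_harmful > n_genes:
        raise ValueError("planted blocks exceed the gene universe")
    gene_ids = [f"G{i + 1:04d}" for i in range(n_genes)]
    sig = gene_ids[:n_signature]
    ben = gene_ids[n_signature:n_signature + n_beneficial]
    harm = gene_ids[n_signature + n_beneficial:n_signature + n_beneficial + n_harmful]
    checkpoint = harm[0] if harm else None
    decoys = harm[1:3]  # partial evidence: CNV concordance only
    harmful_betas = {g: beta_harmful for g in harm}
    if checkpoint is not None:
        harmful_betas[checkpoint] = checkpoint_beta
    truth = SimulationTruth(
        seed=seed,
        gene_ids=gene_ids,
        signature_loadings={g: signature_loading for g in sig},
        planted_beneficial={g: beta_beneficial for g in ben},
        planted_harmful=harmful_betas,
        cnv_concordant=(
            {checkpoint: rho_cnv, **{g: rho_cnv * 0.8 for g in decoys}} if checkpoint else {}
        ),
        meth_anticorrelated={checkpoint: rho_meth} if checkpoint else {},
        mutated_prognostic=(
            {checkpoint: (carrier_fraction, mutation_hr)} if checkpoint else {}
        ),
        specific_genes={checkpoint: checkpoint_cell_type} if checkpoint else {},
        prognostic_factor_loading=prognostic_loading,
    )
    return truth


def _calibrate_uniform_censoring(times: np.ndarray, target: float) -> float:
    """Upper bound c of Uniform(0, c) censoring achieving the target
    expected censoring fraction on the realized event times."""
    if not 0.0 <= target < 1.0:
        raise ValueError(f"censoring fraction must be in [0, 1), got {target}")
    if target == 0.0:
        return float("inf")

    def frac(c: float) -> float:
        return float(np.mean(np.minimum(times / c, 1.0)))

    lo, hi = 1e-9, float(times.max()) * 1e6
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if frac(mid) > target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def generate_cohort(
    n_samples: int,
    truth: SimulationTruth,
    censoring_fraction: float = 0.6,
    seed: int | None = None,
    baseline_median_months: float = 50.0,
    name: str = "discovery",
    prognostic_on_factor: bool = True,
    effect_attenuation: float = 1.0,
) -> tuple[Cohort, CohortRealization]:
    """Expression + censored survival with the planted structure of ``truth``.

    Expression: x_gj = a_g * u_j + N(0,1) + 8 on a log2-like scale, with
    u_j the latent immune factor; planted prognostic genes also load on
    u (so they pass the immune-DEG gate) unless ``prognostic_on_factor``
    is off.  Survival: T_j ~ Exponential with log-hazard
    log(lambda0) + sum_g beta_g z_gj + sum_g log(HR_g) * carrier_gj over
    planted genes, z the per-gene standardized expression.  Censoring:
    independent Uniform(0, c) with c calibrated to the requested
    fraction.
    """
    if n_samples < 20:
        raise ValueError("generate_cohort needs n_samples >= 20")
    rng = np.random.default_rng(seed if seed is not None else truth.seed)
    genes = truth.gene_ids
    n_genes = len(genes)

    u = rng.standard_normal(n_samples)
    loadings = np.zeros(n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    for g, a in truth.signature_loadings.items():
        loadings[gene_index[g]] = a
    if prognostic_on_factor:
        for g in truth.planted_prognostic:
            if loadings[gene_index[g]] == 0:
                loadings[gene_index[g]] = truth.prognostic_factor_loading
    x = loadings[:, None] * u[None, :] + rng.standard_normal((n_genes, n_samples)) + 8.0

    sd = x.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]

    log_hazard = np.full(n_samples, np.log(np.log(2.0) / baseline_median_months))
    for g, beta in truth.planted_prognostic.items():
        log_hazard += effect_attenuation * beta * z[gene_index[g]]
    carriers: dict[str, np.ndarray] = {}
    for g, (frac, hr) in truth.mutated_prognostic.items():
        carrier = rng.random(n_samples) < frac
        carriers[g] = carrier
        log_hazard += effect_attenuation * np.log(hr) * carrier

    t_event = rng.exponential(scale=1.0 / np.exp(log_hazard))
    c_max = _calibrate_uniform_censoring(t_event, censoring_fraction)
    if np.isinf(c_max):
        os_time = t_event
        os_event = np.ones(n_samples, dtype=int)
    else:
        c = rng.uniform(0.0, c_max, size=n_samples)
        os_event = (t_event <= c).astype(int)
        os_time = np.minimum(t_event, c)
    os_time = np.maximum(os_time, 1e-6)

    sample_ids = [f"{name}-S{j + 1:04d}" for j in range(n_samples)]
    expr = GeneExpressionMatrix(
        pd.DataFrame(x, index=genes, columns=sample_ids), scale="log2"
    )
    clinical = ClinicalTable(
        pd.DataFrame({"os_time": os_time, "os_event": os_event},
                     index=pd.Index(sample_ids, name="sample_id"))
    )
    cohort = Cohort(name, expr, clinical)
    realization = CohortRealization(
        immune_factor=u,
        z=pd.DataFrame(z, index=genes, columns=sample_ids),
        carriers=carriers,
    )
    logger.info("generated cohort %s: %d samples, %d genes, %.0f%% censored",
                name, n_samples, n_genes, 100 * (1 - clinical.os_event.mean()))
    return cohort, realization


def generate_validation_cohorts(
    truth: SimulationTruth,
    n_cohorts: int = 4,
    sizes=(133, 133, 132, 132),
    effect_attenuation: float = 1.0,
    censoring_fraction: float = 0.6,
    seed: int | None = None,
) -> list[Cohort]:
    """Independent cohorts from the same truth, survival effects scaled
    by ``effect_attenuation`` (0 makes them null)."""
    sizes = list(sizes)
    if len(sizes) < n_cohorts:
        raise ValueError("need one size per cohort")
    if any(s <= 0 for s in sizes):
        raise ValueError("cohort sizes must be positive")
    master = seed if seed is not None else truth.seed
    child_seeds = np.random.SeedSequence(master).generate_state(n_cohorts) % (2**31)
    cohorts = []
    for k in range(n_cohorts):
        cohort, _ = generate_cohort(
            sizes[k], truth,
            censoring_fraction=censoring_fraction,
            seed=int(child_seeds[k]),
            name=f"validation{k + 1}",
            effect_attenuation=effect_attenuation,
        )
        cohorts.append(cohort)
    return cohorts


def _cnv_cutpoints(marginal) -> np.ndarray:
    return norm.ppf(np.cumsum(marginal)[:-1])


def _discretization_attenuation(marginal) -> float:
    """corr(w, state(w)) for standard normal w thresholded at the
    marginal's cutpoints, evaluated on a deterministic fine grid."""
    grid = norm.ppf((np.arange(200_001) + 0.5) / 200_001)
    states = np.digitize(grid, _cnv_cutpoints(marginal)) - 2
    return float(np.corrcoef(grid, states)[0, 1])


def generate_multiomics(
    cohort: Cohort,
    truth: SimulationTruth,
    realization: CohortRealization,
    seed: int | None = None,
    n_background_mutated: int = 20,
    background_mutation_rate: float = 0.02,
    n_background_probes: int = 50,
) -> MultiomicsBundle:
    """CNV states, methylation probes and a mutation table for one cohort.

    CNV: planted genes get states from a thresholded Gaussian copula
    whose latent correlation is inflated to offset discretization, so
    the realized Pearson correlation with expression lands near the
    target rho (recorded); other genes get independent states.
    Methylation: planted genes get 2-4 promoter probes with
    beta = logistic(b0 - c * z + noise) tuned to the target (negative)
    correlation; a pool of background genes gets one null probe each.
    Mutations: planted carriers come from the cohort realization (their
    hazard effect was applied at cohort generation); background genes
    mutate independently at a low rate.
    """
    rng = np.random.default_rng(seed if seed is not None else truth.seed + 1)
    genes = truth.gene_ids
    samples = cohort.sample_ids
    n = len(samples)
    z = realization.z

    # --- CNV ---
    att_planted = _discretization_attenuation(CNV_MARGINAL_PLANTED)
    states = np.zeros((len(genes), n), dtype=int)
    realized_cnv: dict[str, float] = {}
    null_cuts = _cnv_cutpoints(CNV_MARGINAL_NULL)
    planted_cuts = _cnv_cutpoints(CNV_MARGINAL_PLANTED)
    for i, g in enumerate(genes):
        if g in truth.cnv_concordant:
            rho = truth.cnv_concordant[g]
            if abs(rho) > 0.95:
                raise ValueError(f"target CNV correlation {rho} for {g} unreachable (|rho| > 0.95)")
            rho_latent = min(rho / att_planted, 0.99)
            zg = z.loc[g].to_numpy()
            w = rho_latent * zg + np.sqrt(1 - rho_latent**2) * rng.standard_normal(n)
            states[i] = np.digitize(w, planted_cuts) - 2
            realized_cnv[g] = float(np.corrcoef(states[i],
                                                cohort.expression.values.loc[g])[0, 1])
        else:
            w = rng.standard_normal(n)
            states[i] = np.digitize(w, null_cuts) - 2
    cnv = CnvMatrix(pd.DataFrame(states, index=genes, columns=samples))

    # --- methylation ---
    probe_rows, probe_map_rows = [], []
    realized_meth: dict[str, float] = {}
    sigma = 0.8
    probe_no = 0
    for g in sorted(truth.meth_anticorrelated):
        rho = truth.meth_anticorrelated[g]
        if abs(rho) > 0.95:
            raise ValueError(f"target methylation correlation {rho} for {g} unreachable")
        # linear-stage correlation, mildly inflated for the logistic squash
        rho_adj = min(abs(rho) / 0.95, 0.99)
        c = rho_adj * sigma / np.sqrt(1 - rho_adj**2)
        zg = z.loc[g].to_numpy()
        n_probes = int(rng.integers(2, 5))
        rs = []
        for _ in range(n_probes):
            probe_no += 1
            pid = f"cg{probe_no:07d}"
            b0 = rng.normal(0.0, 0.5)
            beta = expit(b0 - c * zg + sigma * rng.standard_normal(n))
            probe_rows.append(pd.Series(beta, index=samples, name=pid))
            region = rng.choice(["TSS200", "TSS1500"])
            probe_map_rows.append({"probe_id": pid, "gene_id": g, "region": str(region)})
            rs.append(float(np.corrcoef(beta, cohort.expression.values.loc[g])[0, 1]))
        realized_meth[g] = float(np.mean(rs))
    background_pool = [g for g in genes
                       if g not in truth.meth_anticorrelated][:n_background_probes]
    for g in background_pool:
        probe_no += 1
        pid = f"cg{probe_no:07d}"
        b0 = rng.normal(0.0, 0.5)
        beta = expit(b0 + sigma * rng.standard_normal(n))
        probe_rows.append(pd.Series(beta, index=samples, name=pid))
        region = rng.choice(["TSS200", "TSS1500", "body", "other"])
        probe_map_rows.append({"probe_id": pid, "gene_id": g, "region": str(region)})
    meth = MethylationMatrix(
        pd.DataFrame(probe_rows),
        pd.DataFrame(probe_map_rows).set_index("probe_id"),
    )

    # --- mutations ---
    rows = []
    for g, carrier in realization.carriers.items():
        for s, hit in zip(samples, carrier):
            if hit:
                rows.append({"sample_id": s, "gene_id": g,
                             "variant_class": str(rng.choice(VARIANT_CLASSES))})
    background_genes = [g for g in genes
                        if g not in realization.carriers][:n_background_mutated]
    for g in background_genes:
        hits = rng.random(n) < background_mutation_rate
        for s, hit in zip(samples, hits):
            if hit:
                rows.append({"sample_id": s, "gene_id": g,
                             "variant_class": str(rng.choice(VARIANT_CLASSES))})
    if not rows:
        rows.append({"sample_id": samples[0], "gene_id": genes[-1],
                     "variant_class": VARIANT_CLASSES[0]})
    mutations = MutationTable(pd.DataFrame(rows).drop_duplicates().reset_index(drop=True))

    return MultiomicsBundle(cnv, meth, mutations, realized_cnv, realized_meth)


def generate_single_cell(
    truth: SimulationTruth,
    n_cells_per_type: int = 150,
    cell_types=("T_cell", "B_cell", "macrophage", "epithelial"),
    depth: int = 6000,
    seed: int | None = None,
    n_low_umi: int = 10,
    n_high_mito: int = 10,
    n_doublets: int = 5,
    low_umi_depth: int = 800,
    high_mito_fraction: float = 0.30,
    doublet_depth: int = 60_000,
    mito_fraction: float = 0.03,
    n_filler_genes: int = 1500,
) -> tuple[SingleCellDataset, dict[str, str]]:
    """Labeled multi-cell-type UMI counts with injected QC failures.

    Each cell type has its own expression profile; planted specific
    genes are expressed (5% of reads) only in their mapped type.  Counts
    are multinomial draws at Poisson-distributed depth.  Injected cells
    (low-UMI, high-mito, doublet-like) are recorded in the returned
    injection-truth map (cell id -> 'normal'/'low_umi'/'high_mito'/'doublet').
    """
    rng = np.random.default_rng(seed if seed is not None else truth.seed + 2)
    cell_types = list(cell_types)
    for g, ct in truth.specific_genes.items():
        if ct not in cell_types:
            raise ValueError(f"specific gene {g} maps to unknown cell type {ct!r}")
    # pad the universe with filler genes so detected-gene counts sit in a
    # realistic range relative to the QC floor (real references carry ~20k genes)
    filler = [f"SCF{i + 1:04d}" for i in range(n_filler_genes)]
    gene_ids = list(truth.gene_ids) + filler + list(MITO_GENES)
    n_genes = len(gene_ids)
    n_mito = len(MITO_GENES)
    gene_index = {g: i for i, g in enumerate(gene_ids)}

    profiles = {}
    for ct in cell_types:
        # moderately even per-type profiles: a random gene's expression is
        # spread over the types, so only planted markers look specific
        w = rng.gamma(2.0, 1.0, n_genes) + 1e-4
        for g, target in truth.specific_genes.items():
            w[gene_index[g]] *= 0.001
        # fix mitochondrial mass
        w[-n_mito:] = 0.0
        w /= w.sum()
        w *= 1.0 - mito_fraction
        mito_w = rng.dirichlet(np.ones(n_mito)) * mito_fraction
        w[-n_mito:] = mito_w
        profiles[ct] = w
    for g, target in truth.specific_genes.items():
        w = profiles[target].copy()
        w[gene_index[g]] = 0.05 / 0.95 * w.sum()   # ~5% of reads after renorm
        profiles[target] = w / w.sum()

    rows, labels, classes, cell_ids = [], {}, {}, []

    def add_cell(profile, cell_depth, cell_type, klass):
        cid = f"cell{len(cell_ids) + 1:05d}"
        counts = rng.multinomial(max(int(cell_depth), 1), profile)
        rows.append(counts)
        labels[cid] = cell_type
        classes[cid] = klass
        cell_ids.append(cid)

    for ct in cell_types:
        depths = rng.poisson(depth, n_cells_per_type)
        for d in depths:
            add_cell(profiles[ct], d, ct, "normal")
    for _ in range(n_low_umi):
        ct = str(rng.choice(cell_types))
        add_cell(profiles[ct], rng.poisson(low_umi_depth), ct, "low_umi")
    for _ in range(n_high_mito):
        ct = str(rng.choice(cell_types))
        w = profiles[ct].copy()
        non_mito = w[:-n_mito].sum()
        w[:-n_mito] *= (1 - high_mito_fraction) / non_mito
        w[-n_mito:] *= high_mito_fraction / w[-n_mito:].sum()
        add_cell(w / w.sum(), rng.poisson(depth), ct, "high_mito")
    for _ in range(n_doublets):
        ct1, ct2 = rng.choice(cell_types, 2, replace=False)
        mix = 0.5 * (profiles[str(ct1)] + profiles[str(ct2)])
        add_cell(mix, rng.poisson(doublet_depth), str(ct1), "doublet")

    dataset = SingleCellDataset(
        cell_ids=cell_ids,
        gene_ids=gene_ids,
        counts=sp.csr_matrix(np.asarray(rows)),
        labels=labels,
        mito_genes=frozenset(MITO_GENES),
    )
    return dataset, classes


@dataclass
class ImosBundle:
    """A complete synthetic input set for one cascade run."""

    truth: SimulationTruth
    discovery: Cohort
    validation: list[Cohort]
    omics: MultiomicsBundle
    single_cell: SingleCellDataset
    sc_injections: dict[str, str]
    signature: GeneSignature
    discovery_realization: CohortRealization


def generate_bundle(
    seed: int,
    n_samples: int = 400,
    n_genes: int = 500,
    n_validation: int = 4,
    validation_sizes=(133, 133, 132, 132),
    censoring_fraction: float = 0.6,
    n_cells_per_type: int = 150,
    truth: SimulationTruth | None = None,
) -> ImosBundle:
    """Generate discovery + validation cohorts, omics layers, single-cell
    data and the immune signature from one master seed."""
    ss = np.random.SeedSequence(seed)
    s_cohort, s_val, s_omics, s_sc = (int(v) for v in ss.generate_state(4) % (2**31))
    if truth is None:
        truth = make_truth(seed, n_genes=n_genes)
    discovery, realization = generate_cohort(
        n_samples, truth, censoring_fraction=censoring_fraction, seed=s_cohort
    )
    validation = generate_validation_cohorts(
        truth, n_cohorts=n_validation, sizes=validation_sizes,
        censoring_fraction=censoring_fraction, seed=s_val,
    )
    omics = generate_multiomics(discovery, truth, realization, seed=s_omics)
    single_cell, injections = generate_single_cell(
        truth, n_cells_per_type=n_cells_per_type, seed=s_sc
    )
    signature = GeneSignature("immune_signature", frozenset(truth.signature_loadings))
    return ImosBundle(truth, discovery, validation, omics, single_cell,
                      injections, signature, realization)


def write_bundle(bundle: ImosBundle, outdir) -> dict[str, str]:
    """Write the full input bundle in the formats the readers accept,
    plus ``truth.json``.  Returns the path map the CLI/config uses."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def p(name: str) -> str:
        paths[name] = str(outdir / name)
        return paths[name]

    imos_io.write_expression(bundle.discovery.expression, p("expression.tsv"))
    imos_io.write_clinical(bundle.discovery.clinical, p("clinical.tsv"))
    for k, cohort in enumerate(bundle.validation, 1):
        imos_io.write_expression(cohort.expression, p(f"validation{k}_expression.tsv"))
        imos_io.write_clinical(cohort.clinical, p(f"validation{k}_clinical.tsv"))
    imos_io.write_cnv(bundle.omics.cnv, p("cnv.tsv"))
    imos_io.write_methylation(bundle.omics.methylation, p("methylation_beta.tsv"),
                              p("methylation_map.tsv"))
    imos_io.write_mutations(bundle.omics.mutations, p("mutations.tsv"))
    imos_io.write_signature_list(bundle.signature, p("signature.txt"))
    imos_io.write_single_cell(bundle.single_cell, outdir / "single_cell")
    paths["single_cell"] = str(outdir / "single_cell")
    (outdir / "truth.json").write_text(bundle.truth.to_json())
    paths["truth.json"] = str(outdir / "truth.json")
    return paths
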
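"""The full discovery cascade on a synthetic bundle with known truth.

Generates a discovery cohort, four validation cohorts, multi-omic layers
and labeled single-cell data with one fully-planted checkpoint gene,
runs every stage, and prints the ranked candidate table.
"""

from imos.cascade import ImosConfig, run_imos_objects
from imos.simulate import generate_bundle

bundle = generate_bundle(seed=1)
report = run_imos_objects(
    ImosConfig(seed=1), bundle.discovery, bundle.signature, bundle.validation,
    cnv=bundle.omics.cnv, methylation=bundle.omics.methylation,
    mutations=bundle.omics.mutations, single_cell=bundle.single_cell,
)

c = report.to_json_dict()["counts"]
print(f"DEG {c['deg']} -> IPG {c['ipg']} -> IBG/IHG {c['ibg']}/{c['ihg']} "
      f"-> cIPG {c['cipg']} (cIBG {c['cibg']} / cIHG {c['cihg']}) "
      f"-> candidates {c['candidates']}")
checkpoint = sorted(bundle.truth.meth_anticorrelated)[0]
print(f"planted checkpoint: {checkpoint}")
for cand in report.candidates:
    mark = " <- planted" if cand.gene_id == checkpoint else ""
    print(f"  rank {cand.rank}: {cand.gene_id}  evidence {cand.evidence_count}/5  "
          f"cell type {cand.dominant_cell_type}{mark}")
# Every set shrinks monotonically along the cascade, and the fully-planted
# checkpoint should sit at rank 1 with all five evidence flags set.
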
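"""Run the whole pipeline end to end and print the summary report.

simulate -> burden correction -> DP clustering -> pigeonhole tree ->
spatial maps, with every artefact written to ./pipeline_out and a
machine-readable report.json tying the stages together.  The same can
be done from a shell with `glandphylo run --seed 5 --out pipeline_out`.
"""

import json

import glandphylo as gp
from glandphylo.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(
    out_dir="pipeline_out",
    seed=5,
    sim=gp.SimulationConfig(seed=5, n_terminal_acini=6, n_microdissections=14),
    cluster=gp.ClusterConfig(seed=5, max_iterations=30, burn_in=15),
)
report = run_pipeline(config)

print(json.dumps(report, indent=1, sort_keys=True)[:1500])
print("...")
print(f"artefacts in {config.out_dir}/: mutations.tsv, burden.tsv, "
      "clusters.tsv, tree.nwk, spatial.tsv, report.json")
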
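"""One-call orchestration: simulate, score, compare, enrich, survive, select.

Writes the full report bundle (TSV tables, KM plots, manifest) to
./immunocyt_out. The same run is available from the shell as
`immunocyt run --simulate 371 --seed 0 --outdir immunocyt_out`.
"""

import json

from immunocyt import PipelineConfig, default_config, run_pipeline

config = PipelineConfig(
    outdir="immunocyt_out",
    seed=0,
    simulate=default_config(n_samples=371, seed=0),
    gsea_n_permutations=500,
)
manifest = run_pipeline(config)

print("completed stages:", ", ".join(manifest["stages"]))
print("group sizes:", manifest["group_sizes"])
print("outputs:")
for name, path in sorted(manifest["outputs"].items()):
    print(f"  {name:18s} -> immunocyt_out/{path}")
print(json.dumps({"config_hash": manifest["config_hash"], "seed": manifest["seed"]}))
print(
    "\nEvery table is reproducible from the manifest's config hash and seed; "
    "rerunning with the same configuration yields byte-identical TSVs."
)
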
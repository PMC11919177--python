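"""Run the whole workflow (simulate -> screen -> score -> estimate ->
centrality -> bootstrap -> compare -> cross-lagged) in one call.

Equivalent to ``cognet run --out demo_run`` with a reduced-replicate
config.  The run directory holds every stage's artifacts; the summary
JSON is byte-reproducible for a fixed config and seed.
"""

import json

from cognet import RunConfig, run_pipeline

config = RunConfig(
    n=600,
    seed=2026,
    bootstrap_B=150,
    cs_B=25,
    n_perm=200,
    path_size=40,
)
summary = run_pipeline(config, "demo_run")

print(json.dumps(
    {k: summary[k] for k in
     ("qc", "matched", "networks", "cs", "strongest_node")},
    indent=2,
))
comp = summary["comparison"]
print(f"wave comparison: global-strength p = {comp['gs_p']:.3f}, "
      f"omnibus edge p = {comp['omnibus_p']:.3f}")
print("see demo_run/report.md for the rendered report")
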
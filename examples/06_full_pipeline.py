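"""Seeded end-to-end run: simulate -> preprocess -> decode -> stats -> report.

A minimal two-subject configuration exercises every stage and writes a results
bundle (HDF5 maps, CSV behavior, JSON statistics, manifest) plus heat-map
figures.  The same config and seed always reproduce identical numbers.
"""

import json

from seqdecode import RunConfig, report, run_pipeline

cfg = RunConfig(seed=5, out_dir="scratch/example_run", n_subjects=2, n_blocks=6,
                codes=("element", "within_chunk_position"),
                n_freqs=8, n_iterations=1, window_step=50, n_permutations=200)
paths = run_pipeline(cfg)
print("bundle files:", json.dumps(paths, indent=2))

stats = json.loads(open(paths["stats"]).read())
print("\nbehavioral boundary contrast:",
      json.dumps(stats["behavior"].get("rt:pos1_vs_23", {}), indent=2))

out = report(cfg.out_dir)
print("\nreport figures:", *out["figures"], sep="\n  ")
print("Each heat map shows decoding accuracy over frequency x time, with"
      " white outlines around cluster-significant regions when present.")
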
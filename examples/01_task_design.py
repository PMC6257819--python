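"""Task designs: sequence enumeration, counterbalanced schedules, WM capacity.

Builds the two canonical cycling-sequence designs, shows that the chunk-order
combinatorics match the intended counts, and that a full session schedule
counterbalances every control code against every other.
"""

import pandas as pd

from seqdecode import ExperimentDesign, build_schedule, cowans_k, enumerate_sequences

for variant in ("exp1", "exp3"):
    design = ExperimentDesign.from_variant(variant)
    seqs = enumerate_sequences(design)
    print(f"{variant}: {len(seqs)} legal sequences, "
          f"{design.trials_per_block} trials/block x {design.n_blocks} blocks")
    print("  first three:", ", ".join(s.label for s in seqs[:3]))

# A 9-element design schedule: each element must occur at each within-chunk
# position equally often, and each chunk at each chunk position equally often.
sched = build_schedule(ExperimentDesign.from_variant("exp1"), seed=1)
print("\nelement x within-chunk position counts (should be constant):")
print(pd.crosstab(sched["element"], sched["within_chunk_position"]))

# Working-memory capacity from a change-detection task: K = S * (H - F).
k = cowans_k(S=8, H=0.75, F=0.25)
print(f"\nCowan's K for set size 8, hit rate .75, false-alarm rate .25: K = {k.K}")
print("K estimates how many items survive in visual working memory.")
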
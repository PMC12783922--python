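"""Simulate a complete six-sample study and score every pipeline stage.

The generator plants the ground truth (cluster structure, lineages,
lifestyles, AMG kinds, active fraction, environment associations); the
report shows how well each stage recovers it.
"""

import json

from viroflow import ScenarioConfig, run_pipeline, simulate

cfg = ScenarioConfig(seed=1, n_votus=60)
scn = simulate(cfg)
print(f"simulated {len(scn.sequences)} contigs in "
      f"{scn.truth['clusters']['cluster_id'].nunique()} planted clusters, "
      f"{cfg.n_samples} samples\n")

result = run_pipeline(scn)
print(json.dumps(result.report, indent=2, sort_keys=True))
print("\nEach block scores one stage against the planted truth: "
      "an ARI of 1.0 means the 95/85 clustering recovered every vOTU, "
      "and 'planted_recovered' counts the injected virus-host-NH4_N "
      "associations found by the correlation screen.")
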
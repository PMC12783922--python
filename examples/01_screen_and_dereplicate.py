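"""Screen candidate viral contigs and collapse them into vOTUs.

Builds a handful of predictor hits around each tool's cutoff, screens
them, then dereplicates three sequences (two near-identical, one
unrelated) at 95% ANI / 85% alignment fraction.
"""

import numpy as np

from viroflow import PredictorHit, dereplicate, screen_contigs
from viroflow.simulate import mutate_sequence, random_sequence

hits = [
    PredictorHit("c1", "genomad", 12_000, score=0.80),           # at the cutoff: pass
    PredictorHit("c2", "virsorter2", 15_000, score=0.90),        # strict >0.9: fail
    PredictorHit("c3", "deepvirfinder", 11_000, score=0.95, p_value=0.01),
    PredictorHit("c4", "vibrant", 20_000),                       # VIBRANT always passes
    PredictorHit("c5", "genomad", 9_000, score=0.99),            # below 10 kb: fail
]
passed = screen_contigs(hits)
print(f"screened {len(hits)} hits -> {sorted(passed)} pass")
print("  (c2 fails the strict VirSorter2 cutoff; c5 is shorter than 10 kb)\n")

rng = np.random.default_rng(0)
base = random_sequence(rng, 15_000)
contigs = {
    "c_long": base,
    "c_variant": mutate_sequence(rng, base, 0.02)[:14_000],  # ~98% ANI copy
    "c_other": random_sequence(rng, 12_000),                 # unrelated
}
votus = dereplicate(contigs)
for v in votus:
    print(f"{v.votu_id}: representative={v.representative_contig} "
          f"members={v.member_contigs} length={v.length_bp}")
print("\nThe 2%-divergent variant joins its parent's vOTU (ANI ~98 >= 95, "
      "AF 100 >= 85); the unrelated contig founds its own.")
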
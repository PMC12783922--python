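"""TPM abundance with covered-fraction gating, and activity calls.

Metagenome TPM excludes features covered over less than 10% of their
length before normalising to one million per sample; a feature is
transcriptionally active when its transcript TPM is positive anywhere.
"""

import pandas as pd

from viroflow import activity, amg_metagenome_abundance, tpm

counts = pd.DataFrame(
    {
        "feature_id": ["vOTU_a", "vOTU_b", "vOTU_c"],
        "length_bp": [10_000, 20_000, 15_000],
        "count_s1": [100, 100, 80],
        "covfrac_s1": [0.90, 0.85, 0.04],   # vOTU_c barely covered
        "count_s2": [0, 50, 0],
        "covfrac_s2": [0.00, 0.70, 0.00],
    }
)
m = tpm(counts)
print("metagenome TPM (covered-fraction gate 0.10):")
print(m.round(1).to_string())
print(f"\ncolumn sums: {m.sum().round(1).to_dict()}  (one million per sample;"
      "\n  vOTU_c is gated out of s1 and reports 0)\n")

tx = counts.copy()
tx[["count_s1", "count_s2"]] = [[5, 0], [0, 0], [12, 3]]
tx_tpm = tpm(tx, min_covered_fraction=0.0)
flags = activity(tx_tpm)
print("transcript TPM > 0 in any sample -> active:")
print(flags.to_string())

amg_rows = amg_metagenome_abundance({"amg1": "vOTU_a", "amg2": "vOTU_a"}, m)
print("\nAMG metagenomic abundance inherits the parent vOTU row verbatim:")
print(amg_rows.round(1).to_string())
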
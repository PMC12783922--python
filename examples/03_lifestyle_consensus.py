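"""Call lytic vs lysogenic lifestyles from four evidence streams.

A provirus boundary or an integrase annotation can only argue for
lysogeny; lytic labels come from VIBRANT and BACPHLIP.  Two agreeing
methods decide; a lone conflict falls back to the priority order
CheckV > annotation > VIBRANT > BACPHLIP.
"""

from viroflow import LifestyleEvidence, call_methods, consensus

cases = {
    "agreeing lytic": LifestyleEvidence(
        "v1", vibrant_call="lytic", bacphlip_temperate_score=0.02
    ),
    "integrase + provirus": LifestyleEvidence(
        "v2", checkv_provirus=True,
        marker_genes=("site-specific integrase", "tail fiber protein"),
    ),
    "CheckV vs VIBRANT conflict": LifestyleEvidence(
        "v3", checkv_provirus=True, vibrant_call="lytic"
    ),
    "no evidence": LifestyleEvidence("v4"),
}

for name, ev in cases.items():
    calls = call_methods(ev)
    final = consensus(calls, votu_id=ev.votu_id)
    voting = {m: c for m, c in calls.items() if c != "no-call"}
    print(f"{name:28s} votes={voting or '{}'}")
    print(f"{'':28s} -> {final.final} (resolved by {final.resolved_by})")

print("\nThe conflict case lands lysogenic: CheckV's provirus boundary "
      "outranks VIBRANT's lytic call in the stated priority.")
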
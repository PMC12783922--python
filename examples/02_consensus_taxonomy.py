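"""Integrate conflicting per-tool taxonomy calls into one lineage.

Two classifiers disagree at family level but agree on everything above;
the consensus backs off to the shared order (lowest common ancestor).
A third case shares no rank at all, so the priority order decides.
"""

from viroflow import RankedLineage, ToolAssignment, accept, integrate

base = dict(
    realm="Duplodnaviria", kingdom="Heunggongvirae",
    phylum="Uroviricota", class_="Caudoviricetes", order="Synvirales",
)
peduo = RankedLineage(family="Peduoviridae", **base)
kyano = RankedLineage(family="Kyanoviridae", **base)
ncldv = RankedLineage(realm="Varidnaviria", phylum="Nucleocytoviricota",
                      kingdom="Bamfordvirae")

# acceptance rules first: only well-supported calls enter the consensus
good = ToolAssignment("v1", "vcontact2", peduo,
                      {"protein_total": 10, "protein_assigned_to_family": 7,
                       "min_bitscore": 120.0})
weak = ToolAssignment("v1", "vcontact2", peduo,
                      {"protein_total": 10, "protein_assigned_to_family": 4,
                       "min_bitscore": 120.0})
print("well-supported vConTACT2 call accepted:", accept(good) is not None)
print("minority-protein call rejected:", accept(weak) is None)

consensus = integrate({"vcontact2": peduo, "blastn": kyano})
print("\nfamily conflict, shared order ->", consensus.to_string())
print("  (Peduoviridae vs Kyanoviridae collapses to their common order)")

fallback = integrate({"vcontact2": peduo, "phagcn2": ncldv})
print("\nno shared rank at all ->", fallback.to_string())
print("  (highest-priority tool, vConTACT2, wins the arbitration)")
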
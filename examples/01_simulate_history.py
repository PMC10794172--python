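"""Simulate a karyotype-evolution history with planted ground truth.

Starting from a 13-chromosome ancestor (elements A-M), rearrangements
accumulate along a 5-taxon phylogeny: Robertsonian fusions and fissions
at centromeres, end-to-end fusions at telomeres, reciprocal
translocations, and inversions.  The history records every event per
branch and emits an ortholog table that downstream analyses consume.
"""

import dendropy

from frogsynt.simulate import default_ancestral_layout, simulate_karyotype_history

tree = dendropy.Tree.get(
    data="((xtrop:80,(xlaevL:40,xlaevS:40):40):40,(hboet:150,ecoqui:150):50):0;",
    schema="newick",
)
rates = {
    "robertsonian_fusion": 0.003,
    "robertsonian_fission": 0.001,
    "end_to_end_fusion": 0.002,
    "reciprocal_translocation": 0.002,
    "inversion": 0.01,
}

hist = simulate_karyotype_history(
    default_ancestral_layout(), tree, rates=rates, seed=42
)

print(f"ancestral chromosomes: {hist.ancestral_layout.names}")
branches = sorted({e.branch for e in hist.events})
for branch in branches:
    kinds = [e.etype for e in hist.events_on_branch(branch)]
    print(f"branch {branch:8s} {len(kinds)} events: {kinds}")

tips = hist.replay()
for name, kar in sorted(tips.items()):
    print(f"{name:8s} karyotype: {len(kar.chromosomes)} chromosomes")

print(f"\northolog table: {len(hist.orthologs)} genes, "
      f"columns {list(hist.orthologs.columns)[:6]}...")
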
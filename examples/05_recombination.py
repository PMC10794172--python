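"""Recombination landscapes, variant filtering, and inbreeding decay.

A Marey map (genetic vs physical position) is smoothed with a cubic
spline; its derivative is the local recombination rate, strongly
concentrated in subtelomeres.  A simulated variant table is filtered
with depth/balance/parental rules, and residual heterozygosity after
full-sib inbreeding is compared with the closed-form expectation
1.17 * 0.809**t.
"""

import numpy as np

from frogsynt.layout import GenomeLayout
from frogsynt.recomb import (
    filter_variant_sites,
    inbreeding_expected_fraction,
    recombination_concentration,
    region_rate_comparison,
    smooth_marey,
)
from frogsynt.simulate import (
    simulate_inbred_pedigree,
    simulate_marey_map,
    simulate_variant_sites,
)

layout = GenomeLayout(
    {"chr1": 200_000_000, "chr2": 150_000_000, "chr3": 120_000_000},
    {"chr1": 90_000_000, "chr2": 67_000_000, "chr3": 54_000_000},
)
gm = simulate_marey_map(layout, seed=4)
track = smooth_marey(gm, grid=500e3, layout=layout)

res = region_rate_comparison(track, layout)
for cls, med in res["medians"].items():
    print(f"median rate in {cls:15s} {med:.3f} cM/Mb")
conc = recombination_concentration(track, quantiles=(0.5,))
print(f"half the genetic map sits in {100 * conc[0.5]:.1f}% of the genome")

tab = simulate_variant_sites(n_sites=4000, with_parents=True, seed=11)
kept, counts = filter_variant_sites(tab)
print(f"\nvariant filtering: {counts}")

t = 17
theory = 100 * inbreeding_expected_fraction(t)
fr = simulate_inbred_pedigree(t, [107.016] * 10, replicates=300, seed=17)
se = 100 * fr.std(ddof=1) / np.sqrt(len(fr))
print(f"\nheterozygous map fraction after {t} full-sib generations: "
      f"theory {theory:.2f}%, simulated {100 * fr.mean():.2f}% "
      f"(+- {se:.2f}% SE)")
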
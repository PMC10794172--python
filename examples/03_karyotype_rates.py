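"""Karyotype-evolution rates and per-branch Poisson tests.

Reproduces the headline desk numbers: 17 inter-chromosomal changes over
1.05 Gy of branch length give one change every ~62 My; a ~200 My branch
with zero changes has tail probability ~0.04; a 62 My branch with six
changes (one expected) has two-sided P ~ 1e-3.  Breakpoint positions are
also tested against a random-breakage model.
"""

from frogsynt.karyorate import (
    branch_poisson_test,
    karyotype_change_rate,
    random_break_test,
)
from frogsynt.layout import GenomeLayout

rate_my = karyotype_change_rate(17, 1054)
print(f"one karyotype change every {rate_my:.1f} My")

stasis = branch_poisson_test(200.0, 0, 1 / rate_my)
print(f"~200 My stasis: lambda={stasis.lam:.2f}, "
      f"P(X<=0)={stasis.p_lower:.3f}")

burst = branch_poisson_test(62.0, 6, 1 / rate_my)
print(f"6 changes where {burst.lam:.0f} expected: "
      f"two-sided P={burst.p_two_sided:.1e}")

# are breakpoints avoiding chromosome-arm interiors?
layout = GenomeLayout(
    {f"chr{i + 1}": int(2e8 - i * 1.2e7) for i in range(10)},
    {f"chr{i + 1}": int(0.4 * (2e8 - i * 1.2e7)) for i in range(10)},
)
expected, p = random_break_test(
    [layout], n_breaks=17, observed_interior=2,
    eps_centromere=5e6, eps_telomere=5e6,
)
print(f"random-break model: expected {expected:.1f} interior breaks, "
      f"observed 2, P={p:.4f}")
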
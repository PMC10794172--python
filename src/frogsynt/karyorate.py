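"""Rearrangement classification and karyotype-evolution rate statistics.

Implements the centric grammar of chromosome change (Robertsonian events
break/join at centromeres, end-to-end fusions join telomeres), translo-
cation counting with composite multi-way events, the Poisson constant-
rate branch test, and the random-break null model for the placement of
rearrangement breakpoints along chromosome arms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .layout import GenomeLayout
from .simulate.karyotype import RearrangementEvent

__all__ = [
    "classify_junction",
    "count_translocations",
    "karyotype_change_rate",
    "PoissonTestResult",
    "branch_poisson_test",
    "hochberg_correct",
    "random_break_test",
]


def classify_junction(
    parent_layout: GenomeLayout,
    event: RearrangementEvent,
    eps_centromere: float = 5e6,
    eps_telomere: float = 5e6,
) -> RearrangementEvent:
    """Re-type an event from its junction geometry in the parent frame.

    Robertsonian when every breakpoint lies within ``eps_centromere`` of
    its chromosome's centromere; otherwise end-to-end when every junction
    lies within ``eps_telomere`` of a chromosome end (fusions only);
    otherwise a reciprocal translocation.  Inversions keep their type.
    """
    if event.etype == "inversion":
        return event
    for chrom, pos in event.junctions:
        length = parent_layout.length(chrom)
        if not (0 <= pos <= length):
            raise ValueError(
                f"junction {chrom}:{pos} outside [0, {length}]"
            )
    near_cen = all(
        abs(pos - parent_layout.centromere(chrom)) <= eps_centromere
        for chrom, pos in event.junctions
    )
    is_fusion = len(event.parents) == 2 and len(event.children) == 1
    is_fission = len(event.parents) == 1 and len(event.children) == 2
    if near_cen:
        if is_fission:
            return replace(event, etype="robertsonian_fission")
        if is_fusion:
            return replace(event, etype="robertsonian_fusion")
    if is_fusion:
        near_tel = all(
            min(pos, parent_layout.length(chrom) - pos) <= eps_telomere
            for chrom, pos in event.junctions
        )
        if near_tel:
            return replace(event, etype="end_to_end_fusion")
    if is_fission:
        return replace(event, etype="robertsonian_fission")
    return replace(event, etype="reciprocal_translocation")


def count_translocations(
    events: list[RearrangementEvent],
    four_way_as: int = 3,
) -> int:
    """Count inter-chromosomal changes, excluding inversions.

    Fusions and fissions count 1 each.  A reciprocal event among k
    chromosomes counts as ``four_way_as`` when k = 4 (a four-way exchange
    is a composite of pairwise rearrangements), 1 when k = 2, and k - 1
    otherwise.
    """
    total = 0
    for ev in events:
        if ev.etype == "inversion":
            continue
        if ev.etype == "reciprocal_translocation":
            k = len(ev.parents)
            total += 1 if k == 2 else (four_way_as if k == 4 else k - 1)
        else:
            total += 1
    return total


def karyotype_change_rate(count: int, total_branch_my: float) -> float | None:
    """My per karyotype change, or None when no events occurred."""
    if total_branch_my <= 0:
        raise ValueError("total branch length must be > 0")
    if count < 0:
        raise ValueError("event count must be >= 0")
    if count == 0:
        return None
    return total_branch_my / count


@dataclass
class PoissonTestResult:
    lam: float
    observed: int
    p_lower: float        # P(X <= k)
    p_upper: float        # P(X >= k)
    p_one_sided: float    # smaller tail
    p_two_sided: float    # doubled smaller tail, capped at 1


def branch_poisson_test(
    branch_my: float, observed: int, rate_per_my: float
) -> PoissonTestResult:
    """Exact Poisson test of a branch's event count against a genome-wide
    constant rate (events/My)."""
    if rate_per_my <= 0:
        raise ValueError("rate must be > 0")
    lam = branch_my * rate_per_my
    p_lower = float(stats.poisson.cdf(observed, lam))
    p_upper = float(stats.poisson.sf(observed - 1, lam))
    one = min(p_lower, p_upper)
    return PoissonTestResult(
        lam=lam,
        observed=observed,
        p_lower=p_lower,
        p_upper=p_upper,
        p_one_sided=one,
        p_two_sided=min(1.0, 2 * one),
    )


def hochberg_correct(pvalues) -> np.ndarray:
    """Hochberg step-up family-wise correction."""
    return multipletests(np.asarray(pvalues, float), method="simes-hochberg")[1]


def random_break_test(
    layouts: list[GenomeLayout],
    n_breaks: int,
    eps_centromere: float = 5e6,
    eps_telomere: float = 5e6,
    observed_interior: int = 0,
) -> tuple[float, float]:
    """Random-break model: are too few breaks in chromosome-arm interiors?

    Terminal windows (``eps_telomere`` at each chromosome end and
    ``eps_centromere`` each side of the centromere) are excised; q is the
    interior fraction of the genome.  Under random breakage the expected
    number of interior breaks is ``n_breaks * q``; the returned p-value is
    the exact binomial lower tail P(X <= observed_interior).
    """
    interior = 0.0
    total = 0.0
    for layout in layouts:
        for chrom in layout.names:
            length = layout.length(chrom)
            if 2 * eps_telomere > length or 2 * eps_centromere > length:
                raise ValueError(
                    f"terminal windows exceed chromosome {chrom!r} length"
                )
            windows = [
                (0, eps_telomere),
                (length - eps_telomere, length),
            ]
            cen = layout.centromere(chrom)
            windows.append((max(0, cen - eps_centromere),
                            min(length, cen + eps_centromere)))
            covered = _union_length(windows)
            total += length
            interior += length - covered
    q = interior / total
    expected = n_breaks * q
    p = float(stats.binom.cdf(observed_interior, n_breaks, q))
    return expected, p


def _union_length(intervals) -> float:
    ivs = sorted(intervals)
    covered = 0.0
    cur_lo, cur_hi = ivs[0]
    for lo, hi in ivs[1:]:
        if lo > cur_hi:
            covered += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    covered += cur_hi - cur_lo
    return covered
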
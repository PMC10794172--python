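"""Forward simulation of residual heterozygosity under full-sib inbreeding.

Two founders carry four mutually distinguishable haplotypes.  Each
generation a single brother-sister pair produces the next; gametes
recombine with crossovers Poisson on the genetic map (no interference).
The reported statistic per replicate is the fraction of the genetic map
on which a sampled individual's two haplotypes are *not* identical by
descent.  Classical theory gives the large-t expectation
``1.17 * 0.809**t``, with 0.809 = (1 + sqrt(5))/4 the dominant root of
the full-sib recurrence.
"""

from __future__ import annotations

import numpy as np

__all__ = ["simulate_inbred_pedigree"]

# haplotype = (breaks, labels): piecewise-constant founder origin on [0, L] cM;
# labels[i] applies on [breaks[i], breaks[i+1]) with breaks[0]=0, breaks[-1]=L


def _segments_between(hap, lo: float, hi: float):
    """Yield (start, end, label) pieces of ``hap`` covering [lo, hi)."""
    breaks, labels = hap
    i = int(np.searchsorted(breaks, lo, side="right")) - 1
    i = max(0, min(i, len(labels) - 1))
    pos = lo
    while pos < hi:
        nxt = min(hi, breaks[i + 1]) if i + 1 < len(breaks) else hi
        yield pos, nxt, labels[i]
        pos = nxt
        i += 1


def _gamete(hap_a, hap_b, length_cm: float, rng: np.random.Generator):
    """Recombine two parental haplotypes: Poisson crossovers, no interference."""
    n_x = rng.poisson(length_cm / 100.0)
    phase = int(rng.integers(2))
    if n_x == 0:
        return (hap_a, hap_b)[phase]
    cuts = np.sort(rng.uniform(0, length_cm, size=n_x))
    bounds = np.concatenate([[0.0], cuts, [length_cm]])
    haps = (hap_a, hap_b)
    starts: list[float] = []
    labels: list[int] = []
    for k in range(len(bounds) - 1):
        lo, hi = bounds[k], bounds[k + 1]
        if hi <= lo:
            continue
        for seg_lo, seg_hi, lab in _segments_between(haps[(phase + k) % 2], lo, hi):
            if labels and labels[-1] == lab:
                continue  # merge with previous identical block
            starts.append(seg_lo)
            labels.append(lab)
    starts[0] = 0.0
    return (np.array(starts + [length_cm]), np.array(labels))


def _het_length(hap1, hap2, length_cm: float) -> float:
    """Total cM where two haplotypes carry different founder labels."""
    b1, l1 = hap1
    b2, l2 = hap2
    edges = np.union1d(b1, b2)
    het = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        mid = (lo + hi) / 2
        a = l1[np.searchsorted(b1, mid, side="right") - 1]
        b = l2[np.searchsorted(b2, mid, side="right") - 1]
        if a != b:
            het += hi - lo
    return het


def simulate_inbred_pedigree(
    generations: int,
    chrom_lengths_cm,
    replicates: int = 500,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Simulate full-sib inbreeding; return per-replicate heterozygous
    map fractions.

    Parameters
    ----------
    generations:
        Number of generations of brother-sister mating (t >= 1); the
        measured individual belongs to generation t.
    chrom_lengths_cm:
        Iterable of per-chromosome map lengths in cM.
    """
    if generations < 1:
        raise ValueError("need at least one generation")
    lengths = np.asarray(list(chrom_lengths_cm), float)
    if len(lengths) == 0 or lengths.sum() <= 0:
        raise ValueError("total map length must be positive")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    total = lengths.sum()
    fractions = np.empty(replicates)
    for rep in range(replicates):
        het = 0.0
        for L in lengths:
            # founders: haplotypes 0/1 and 2/3
            sire = (
                (np.array([0.0, L]), np.array([0])),
                (np.array([0.0, L]), np.array([1])),
            )
            dam = (
                (np.array([0.0, L]), np.array([2])),
                (np.array([0.0, L]), np.array([3])),
            )
            for _ in range(generations):
                child1 = (_gamete(*sire, L, rng), _gamete(*dam, L, rng))
                child2 = (_gamete(*sire, L, rng), _gamete(*dam, L, rng))
                sire, dam = child1, child2
            het += _het_length(*sire, L)
        fractions[rep] = het / total
    return fractions
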
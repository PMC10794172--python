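"""Marey-map simulator with subtelomere-concentrated recombination.

The per-bp recombination intensity is a step function: a baseline rate on
chromosome arms multiplied by an enrichment factor inside the terminal
subtelomeric windows (and optionally suppressed around the centromere).
Marker genetic positions are the integral of this intensity with
multiplicative gamma noise on inter-marker increments, which keeps the
map monotone by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..genmap import GeneticMap
from ..layout import GenomeLayout

__all__ = ["simulate_marey_map"]


def simulate_marey_map(
    layout: GenomeLayout,
    subtelomere_multiplier: float = 12.0,
    markers_per_chrom: int = 200,
    seed: int | np.random.Generator = 0,
    base_rate: float = 0.2,
    subtelomere_size: float = 30e6,
    pericentromere_suppression: float = 0.05,
    pericentromere_size: float = 5e6,
    noise_shape: float = 50.0,
) -> GeneticMap:
    """Simulate a sex-averaged genetic map over ``layout``.

    Parameters
    ----------
    subtelomere_multiplier:
        Rate enrichment in the terminal windows; must be >= 1.
    base_rate:
        Arm recombination rate in cM/Mb.
    noise_shape:
        Shape of the gamma multiplier on marker-interval increments
        (mean 1); larger is smoother.
    """
    if subtelomere_multiplier < 1:
        raise ValueError("subtelomere multiplier must be >= 1")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    rows = []
    for chrom in layout.names:
        length = layout.length(chrom)
        bp = np.sort(rng.choice(length, size=markers_per_chrom, replace=False))
        bp[0] = 0  # anchor ends so the full physical span is mapped
        bp[-1] = length - 1
        mids = (bp[:-1] + bp[1:]) / 2
        rate = np.full(mids.shape, base_rate)
        for lo, hi in layout.subtelomeres(chrom, subtelomere_size):
            rate[(mids >= lo) & (mids < hi)] *= subtelomere_multiplier
        lo, hi = layout.pericentromere(chrom, pericentromere_size)
        rate[(mids >= lo) & (mids < hi)] = base_rate * pericentromere_suppression
        inc = rate * np.diff(bp) / 1e6  # cM per interval
        inc = inc * rng.gamma(noise_shape, 1.0 / noise_shape, size=inc.shape)
        cm = np.concatenate([[0.0], np.cumsum(inc)])
        rows.append(pd.DataFrame({"chrom": chrom, "bp": bp, "cM": cm}))
    return GeneticMap(pd.concat(rows, ignore_index=True))
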
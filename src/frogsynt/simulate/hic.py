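"""Generative model for binned Hi-C contact maps with planted architecture.

The expectation for each bin pair is built from the features the
architecture statistics are designed to detect:

* intra-chromosomal: power-law distance decay modulated by an A/B
  checkerboard, plus an additive "wing" between opposite arms at matched
  centromere distance (the Rabl fold-back signal);
* inter-chromosomal: a territory-factor background modulated by
  centromere clustering, telomere clustering, and a polar
  (centromere-to-telomere axis) alignment term.

Counts are Poisson samples of the depth-scaled expectation; the noise-free
expectation matrix and all planted truth (compartment labels, centromere
bins, gene density) are returned alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..contacts import ContactMatrix
from ..layout import GenomeLayout

__all__ = ["HicSimParams", "HicSimulation", "simulate_hic_matrix"]


@dataclass
class HicSimParams:
    """Weights and scales of the contact-map generative model.

    All weights are dimensionless multipliers (>= 0); widths are in bp
    except ``sigma_u`` which is on the arm-relative polar coordinate
    u in [0, 1].
    """

    bin_size: int = 1_000_000
    decay_alpha: float = 1.0
    w_rabl: float = 4.0
    sigma_rabl: float = 8e6
    w_ab: float = 0.4
    ab_block_scale: float = 4e6
    inter_background: float = 0.03
    w_cen: float = 8.0
    sigma_cen: float = 10e6
    w_tel: float = 3.0
    sigma_tel: float = 10e6
    w_pol: float = 1.5
    sigma_u: float = 0.15
    w_arm: float = 0.06
    territory: pd.DataFrame | None = None   # chrom x chrom symmetric factors
    total_reads: float = 2e7

    def __post_init__(self) -> None:
        for name in ("w_rabl", "w_ab", "w_cen", "w_tel", "w_pol", "w_arm",
                     "inter_background", "decay_alpha"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.w_ab >= 1:
            raise ValueError("w_ab must be < 1 (multiplicative contrast)")
        if self.bin_size <= 0:
            raise ValueError("bin size must be positive")
        if self.total_reads <= 0:
            raise ValueError("total read count must be > 0")
        if self.territory is not None:
            T = self.territory.to_numpy(float)
            if not (np.allclose(T, T.T) and np.all(T > 0)):
                raise ValueError("territory matrix must be symmetric positive")


@dataclass
class HicSimulation:
    matrix: ContactMatrix
    expected: np.ndarray           # depth-scaled model expectation
    compartments: np.ndarray       # per-bin +1 (A) / -1 (B)
    gene_density: np.ndarray       # per-bin density correlated with A
    centromere_bins: dict[str, int]
    params: HicSimParams
    truth: dict = field(default_factory=dict)


def _make_bins(layout: GenomeLayout, bin_size: int) -> pd.DataFrame:
    rows = []
    bid = 0
    for chrom in layout.names:
        length = layout.length(chrom)
        for start in range(0, length, bin_size):
            rows.append((chrom, start, min(start + bin_size, length), bid))
            bid += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "bin_id"])


def _draw_compartments(
    n: int, bin_size: int, block_scale: float, rng: np.random.Generator
) -> np.ndarray:
    """Alternating +-1 blocks with exponential lengths (in bp)."""
    labels = np.empty(n, dtype=int)
    sign = 1 if rng.integers(2) else -1
    i = 0
    while i < n:
        nblocks = max(1, int(round(rng.exponential(block_scale) / bin_size)))
        labels[i : i + nblocks] = sign
        sign = -sign
        i += nblocks
    return labels


def simulate_hic_matrix(
    layout: GenomeLayout,
    params: HicSimParams | None = None,
    seed: int | np.random.Generator = 0,
) -> HicSimulation:
    """Simulate a binned symmetric Hi-C count matrix for ``layout``."""
    params = params or HicSimParams()
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    for chrom in layout.names:
        if chrom not in layout.centromeres:
            raise ValueError(f"layout lacks a centromere for {chrom!r}")

    bins = _make_bins(layout, params.bin_size)
    n = len(bins)
    chrom_arr = bins["chrom"].to_numpy()
    mid = ((bins["start"] + bins["end"]) / 2).to_numpy(float)

    # per-bin geometry
    cen = np.array([layout.centromere(c) for c in chrom_arr], float)
    length = np.array([layout.length(c) for c in chrom_arr], float)
    d_cen = mid - cen                      # signed distance to centromere
    d_tel = np.minimum(mid, length - mid)  # distance to nearest telomere
    arm_len = np.where(d_cen < 0, cen, length - cen)
    u = np.abs(d_cen) / np.maximum(arm_len, 1.0)  # polar coordinate in [0,1]

    # compartments and a correlated gene-density track
    comp = np.empty(n, dtype=int)
    for chrom in layout.names:
        sel = chrom_arr == chrom
        comp[sel] = _draw_compartments(
            int(sel.sum()), params.bin_size, params.ab_block_scale, rng
        )
    gene_density = 10.0 * (1 + 0.6 * comp) + rng.normal(0, 1.0, n)
    gene_density = np.clip(gene_density, 0.1, None)

    # territory factors
    chroms = layout.names
    if params.territory is None:
        T = pd.DataFrame(1.0, index=chroms, columns=chroms)
    else:
        T = params.territory
    tidx = np.array([T.index.get_loc(c) for c in chrom_arr])
    t_fac = T.to_numpy(float)[np.ix_(tidx, tidx)]

    same = chrom_arr[:, None] == chrom_arr[None, :]
    s = np.abs(mid[:, None] - mid[None, :])
    decay = (1.0 + s / params.bin_size) ** (-params.decay_alpha)
    comp_fac = 1.0 + params.w_ab * np.outer(comp, comp)
    opposite = (d_cen[:, None] * d_cen[None, :]) < 0
    wing = params.w_rabl * np.exp(
        -((np.abs(d_cen)[:, None] - np.abs(d_cen)[None, :]) ** 2)
        / (2 * params.sigma_rabl**2)
    )
    intra = decay * comp_fac + np.where(same & opposite, wing, 0.0) * decay.mean()

    cen_term = 1.0 + params.w_cen * np.exp(
        -(np.abs(d_cen)[:, None] ** 2 + np.abs(d_cen)[None, :] ** 2)
        / (2 * params.sigma_cen**2)
    )
    tel_term = 1.0 + params.w_tel * np.exp(
        -(d_tel[:, None] ** 2 + d_tel[None, :] ** 2) / (2 * params.sigma_tel**2)
    )
    pol_term = 1.0 + params.w_pol * np.exp(
        -((u[:, None] - u[None, :]) ** 2) / (2 * params.sigma_u**2)
    )
    arm_sign = np.sign(d_cen)
    arm_term = 1.0 + params.w_arm * (
        (arm_sign[:, None] * arm_sign[None, :]) > 0
    )
    inter = (params.inter_background * t_fac * cen_term * tel_term
             * pol_term * arm_term)

    expect = np.where(same, intra, inter)
    expect = (expect + expect.T) / 2

    # depth scaling: expected total count over unique pairs = total_reads
    iu = np.triu_indices(n)
    scale = params.total_reads / expect[iu].sum()
    expect *= scale

    counts = np.zeros((n, n))
    counts[iu] = rng.poisson(expect[iu])
    counts = np.maximum(counts, counts.T)

    matrix = ContactMatrix(bins=bins, counts=counts, bin_size=params.bin_size)
    cen_bins = {}
    starts = bins["start"].to_numpy()
    ends = bins["end"].to_numpy()
    for chrom in chroms:
        idx = np.flatnonzero(chrom_arr == chrom)
        c = layout.centromere(chrom)
        inside = (starts[idx] <= c) & (c < ends[idx])
        cen_bins[chrom] = int(idx[np.flatnonzero(inside)[0]])
    return HicSimulation(
        matrix=matrix,
        expected=expect,
        compartments=comp,
        gene_density=gene_density,
        centromere_bins=cen_bins,
        params=params,
        truth={"u": u, "d_cen": d_cen},
    )
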
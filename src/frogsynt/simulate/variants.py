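"""Synthetic variant-site tables with planted filter labels.

Generates a site table shaped like the output of a short-read variant
caller: alleles, genotype, depth, and allele balance per site, with
planted pass/fail truth for each downstream filter (bi-allelic, depth
within mode +- k*SD, heterozygote allele balance, parental
informativeness).  Outliers are planted far outside the filter windows so
that the labels are unambiguous for any reasonable mode/SD estimate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["simulate_variant_sites"]


def simulate_variant_sites(
    n_sites: int = 2000,
    depth_mode: int = 30,
    depth_sd: float = 3.0,
    balance_noise: float = 0.05,
    frac_multiallelic: float = 0.05,
    frac_depth_outlier: float = 0.10,
    frac_balance_outlier: float = 0.10,
    with_parents: bool = False,
    frac_uninformative_parents: float = 0.1,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate bi-allelic (and a few multi-allelic) SNP sites.

    Returns a DataFrame with observed columns (``chrom``, ``pos``,
    ``n_alleles``, ``genotype``, ``depth``, ``allele_balance``, and
    optionally parental genotypes/depths) and planted truth columns
    (``planted_*`` flags and ``expected_pass``).
    """
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    pos = np.sort(rng.choice(10**8, size=n_sites, replace=False))
    multi = rng.random(n_sites) < frac_multiallelic
    depth_out = (rng.random(n_sites) < frac_depth_outlier) & ~multi
    het = rng.random(n_sites) < 0.5
    bal_out = (rng.random(n_sites) < frac_balance_outlier) & ~multi & ~depth_out & het

    # depths: inliers tight around the mode (within ~1 SD); outliers far out
    depth = depth_mode + np.clip(
        np.round(rng.normal(0, depth_sd * 0.5, n_sites)), -depth_sd, depth_sd
    )
    low = rng.random(n_sites) < 0.5
    far = np.round(depth_mode * (0.15 + 0.1 * rng.random(n_sites)))
    depth = np.where(depth_out, np.where(low, far, depth_mode * 3 + far), depth)
    depth = depth.astype(int)

    balance = np.where(
        het,
        np.clip(rng.normal(0.5, balance_noise, n_sites), 0.35, 0.65),
        np.where(rng.random(n_sites) < 0.5, 0.0, 1.0),
    )
    # balance outliers land clearly outside [0.3, 0.7]
    shifted = np.where(rng.random(n_sites) < 0.5, 0.1, 0.9)
    balance = np.where(bal_out, shifted, balance)

    genotype = np.where(het, "0/1", np.where(balance > 0.5, "1/1", "0/0"))

    df = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": pos,
            "n_alleles": np.where(multi, 3, 2),
            "genotype": genotype,
            "depth": depth,
            "allele_balance": balance,
            "planted_multiallelic": multi,
            "planted_depth_outlier": depth_out,
            "planted_balance_outlier": bal_out,
        }
    )
    # expected_pass replays the documented filter rules on the generated
    # observables (not the planted intent): with heavy planted outliers the
    # sample SD of depth is inflated, and the mode +- 1.78 SD window must be
    # evaluated on the depths actually produced
    bi = ~multi
    bi_depths = pd.Series(depth[bi])
    mode_d = int(bi_depths.mode().iloc[0])
    sd_d = float(bi_depths.std(ddof=0))
    in_depth = (depth >= mode_d - 1.78 * sd_d) & (depth <= mode_d + 1.78 * sd_d)
    is_het = genotype == "0/1"
    bal_ok = ~is_het | ((balance >= 0.3) & (balance <= 0.7))
    expected = bi & in_depth & bal_ok
    if with_parents:
        uninf = rng.random(n_sites) < frac_uninformative_parents
        reason = rng.integers(3, size=n_sites)  # 0: het parent, 1: same, 2: depth
        p1 = np.where(uninf & (reason == 0), "0/1", "0/0")
        p2 = np.where(uninf & (reason == 1), "0/0", "1/1")
        pdep = np.where(
            uninf & (reason == 2),
            rng.integers(1, 10, n_sites),
            rng.integers(10, 40, n_sites),
        )
        df["parent1_genotype"] = p1
        df["parent2_genotype"] = p2
        df["parent1_depth"] = pdep
        df["parent2_depth"] = rng.integers(10, 40, n_sites)
        df["planted_uninformative_parents"] = uninf
        fixed_diff = (
            pd.Series(p1).isin(["0/0", "1/1"]).to_numpy()
            & pd.Series(p2).isin(["0/0", "1/1"]).to_numpy()
            & (p1 != p2)
        )
        deep = (pdep >= 10) & (df["parent2_depth"].to_numpy() >= 10)
        expected = expected & fixed_diff & deep
    df["expected_pass"] = expected
    return df
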
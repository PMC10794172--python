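"""Recombination landscapes, variant filtering, and inbreeding expectations.

The Marey map (genetic vs physical position) is smoothed with a
"not-a-knot" cubic spline evaluated on a regular grid; its derivative is
the local recombination rate in cM/Mb.  Downstream operations compare
rate distributions between region classes, filter variant-site tables
the way pool/F2 SNP sets are filtered (bi-allelic, modal depth window,
heterozygote allele balance, parental informativeness), and segment
residual-heterozygosity blocks whose size is expressed as a fraction of
the genetic map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline

from .genmap import GeneticMap
from .karyorate import hochberg_correct
from .layout import GenomeLayout, region_classes

__all__ = [
    "RateTrack",
    "smooth_marey",
    "recombination_concentration",
    "region_rate_comparison",
    "feature_correlation",
    "filter_variant_sites",
    "heterozygosity_windows",
    "inbreeding_expected_fraction",
]


@dataclass
class RateTrack:
    """Recombination rate (cM/Mb) on a regular physical grid."""

    table: pd.DataFrame           # chrom, pos, rate, clamped
    grid: float
    n_clamped: int = 0
    splines: dict = field(default_factory=dict, repr=False)

    def rates(self, chrom: str | None = None) -> np.ndarray:
        t = self.table if chrom is None else self.table[self.table["chrom"] == chrom]
        return t["rate"].to_numpy()


def smooth_marey(
    genetic_map: GeneticMap,
    grid: float = 500e3,
    layout: GenomeLayout | None = None,
) -> RateTrack:
    """Spline-smooth a Marey map and differentiate to a rate track.

    A not-a-knot cubic spline of cM against bp is fit per chromosome and
    evaluated every ``grid`` bp (across the chromosome when ``layout``
    is given, else across the marker span).  The rate is the spline
    derivative rescaled to cM/Mb; negative derivatives are clamped to
    zero and counted.
    """
    rows = []
    n_clamped = 0
    splines = {}
    for chrom in genetic_map.chromosomes:
        g = genetic_map.chrom(chrom).drop_duplicates(subset="bp")
        if len(g) < 4:
            raise ValueError(f"chromosome {chrom!r} has fewer than 4 markers")
        bp = g["bp"].to_numpy(float)
        cm = g["cM"].to_numpy(float)
        spl = CubicSpline(bp, cm, bc_type="not-a-knot")
        splines[chrom] = spl
        hi = layout.length(chrom) if layout is not None else bp[-1]
        pos = np.arange(0 if layout is not None else bp[0], hi, grid)
        rate = spl(pos, 1) * 1e6  # cM/bp -> cM/Mb
        clamped = rate < 0
        n_clamped += int(clamped.sum())
        rate = np.clip(rate, 0, None)
        rows.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": pos, "rate": rate, "clamped": clamped}
            )
        )
    return RateTrack(
        pd.concat(rows, ignore_index=True), grid, n_clamped, splines
    )


def recombination_concentration(
    track: RateTrack, quantiles=(0.5, 0.9)
) -> dict[float, float]:
    """Smallest genome fraction containing each quantile of total cM.

    Grid points are sorted by rate (descending); the cumulative cM is the
    rate times the grid spacing.
    """
    rate = np.sort(track.rates())[::-1]
    mass = np.cumsum(rate)
    total = mass[-1]
    frac_genome = np.arange(1, len(rate) + 1) / len(rate)
    out = {}
    for q in quantiles:
        k = int(np.searchsorted(mass, q * total))
        out[q] = float(frac_genome[min(k, len(rate) - 1)])
    return out


def region_rate_comparison(
    track: RateTrack,
    layout: GenomeLayout,
    subtelomere_size: float = 30e6,
    pericentromere_size: float = 5e6,
    acro_exclusion: float = 15e6,
    acro_threshold: float = 30e6,
) -> dict:
    """Median rate per region class with pairwise two-sample KS tests.

    Regions follow the extended-subtelomere definition: terminal windows
    of each (sub)metacentric chromosome, excluding the pericentromeric
    neighbourhood on acrocentrics; the pericentromere is reported as its
    own class.  KS p-values are Hochberg-corrected across class pairs.
    """
    t = track.table.copy()
    t["region"] = region_classes(
        layout,
        t[["chrom", "pos"]],
        subtelomere_size=subtelomere_size,
        pericentromere_size=pericentromere_size,
        acro_exclusion=acro_exclusion,
        acro_threshold=acro_threshold,
    )
    medians = t.groupby("region")["rate"].median().to_dict()
    tests = []
    classes = [c for c in ("subtelomere", "arm", "pericentromere") if c in medians]
    for a, b in combinations(classes, 2):
        ra = t.loc[t["region"] == a, "rate"]
        rb = t.loc[t["region"] == b, "rate"]
        ks = stats.ks_2samp(ra, rb, alternative="two-sided")
        tests.append({"class_a": a, "class_b": b,
                      "ks_stat": float(ks.statistic), "p": float(ks.pvalue)})
    tests_df = pd.DataFrame(tests)
    if len(tests_df):
        tests_df["p_hochberg"] = hochberg_correct(tests_df["p"])
    return {"medians": medians, "tests": tests_df, "table": t}


def feature_correlation(track: RateTrack, features: pd.DataFrame) -> pd.Series:
    """Pearson r between the rate track and grid-aligned feature tracks.

    ``features`` must share the track's (chrom, pos) grid; extra columns
    are the features.  Missing values are dropped pairwise.
    """
    merged = track.table.merge(features, on=["chrom", "pos"], how="inner")
    out = {}
    for col in features.columns:
        if col in ("chrom", "pos"):
            continue
        sub = merged[["rate", col]].dropna()
        out[col] = float(stats.pearsonr(sub["rate"], sub[col])[0])
    return pd.Series(out, name="pearson_r")


def filter_variant_sites(
    table: pd.DataFrame,
    depth_sd_multiplier: float = 1.78,
    balance_window: tuple[float, float] = (0.3, 0.7),
    parental_min_depth: int = 10,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the SNP-site filters in order; return survivors and counts.

    Order: bi-allelic only; depth within modal depth +- k*SD (mode and SD
    computed over the bi-allelic sites); heterozygote allele balance
    within the window; when parental genotype columns are present, keep
    only sites where the parents are fixed and different with depth at
    least ``parental_min_depth`` each.
    """
    counts: dict[str, int] = {"input": len(table)}
    df = table[table["n_alleles"] == 2].copy()
    counts["biallelic"] = len(df)

    depths = df["depth"].to_numpy(int)
    mode = int(pd.Series(depths).mode().iloc[0])
    sd = float(depths.std(ddof=0))
    lo, hi = mode - depth_sd_multiplier * sd, mode + depth_sd_multiplier * sd
    df = df[(df["depth"] >= lo) & (df["depth"] <= hi)]
    counts["depth"] = len(df)

    het = df["genotype"] == "0/1"
    ok = ~het | (
        (df["allele_balance"] >= balance_window[0])
        & (df["allele_balance"] <= balance_window[1])
    )
    df = df[ok]
    counts["allele_balance"] = len(df)

    if "parent1_genotype" in table.columns:
        fixed_diff = (
            df["parent1_genotype"].isin(["0/0", "1/1"])
            & df["parent2_genotype"].isin(["0/0", "1/1"])
            & (df["parent1_genotype"] != df["parent2_genotype"])
        )
        deep = (df["parent1_depth"] >= parental_min_depth) & (
            df["parent2_depth"] >= parental_min_depth
        )
        df = df[fixed_diff & deep]
        counts["parental"] = len(df)
    return df.reset_index(drop=True), counts


def heterozygosity_windows(
    table: pd.DataFrame,
    genetic_map: GeneticMap,
    chrom_lengths: dict[str, int],
    window: float = 500e3,
    step: float = 50e3,
    threshold: float | None = None,
    min_block_windows: int = 3,
) -> dict:
    """Sliding-window heterozygous-SNV density and residual-het blocks.

    Windows of ``window`` bp advance by ``step``; density is het SNVs per
    kb.  Blocks are maximal runs of at least ``min_block_windows``
    consecutive windows with density above ``threshold`` (default: 10%
    of the mean density of non-empty windows).  Each block's genetic
    length comes from interpolating the map at its ends; the headline
    fraction is total block cM over total map cM.
    """
    het = table[table["genotype"] == "0/1"]
    win_rows = []
    for chrom, length in chrom_lengths.items():
        n_win = max(0, int((length - window) // step) + 1)
        starts = np.arange(n_win) * step
        pos = het.loc[het["chrom"] == chrom, "pos"].to_numpy()
        for s in starts:
            e = s + window
            dens = np.sum((pos >= s) & (pos < e)) / (window / 1e3)
            win_rows.append({"chrom": chrom, "start": s, "end": e, "density": dens})
    windows_df = pd.DataFrame(win_rows)
    nonzero = windows_df.loc[windows_df["density"] > 0, "density"]
    if threshold is None:
        threshold = 0.1 * nonzero.mean() if len(nonzero) else 0.0

    blocks = []
    for chrom, grp in windows_df.groupby("chrom", sort=False):
        above = grp["density"].to_numpy() > threshold
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        i = 0
        while i < len(above):
            if not above[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            if j - i + 1 >= min_block_windows:
                blocks.append(
                    {"chrom": chrom, "start": float(starts[i]),
                     "end": float(ends[j])}
                )
            i = j + 1
    blocks_df = pd.DataFrame(blocks, columns=["chrom", "start", "end"])

    block_cm = 0.0
    for _, b in blocks_df.iterrows():
        if b["chrom"] in genetic_map.chromosomes:
            lo, hi = genetic_map.interpolate(b["chrom"], [b["start"], b["end"]])
            block_cm += hi - lo
    total_cm = genetic_map.length_cm()
    return {
        "windows": windows_df,
        "blocks": blocks_df,
        "threshold": float(threshold),
        "block_cm": float(block_cm),
        "total_cm": float(total_cm),
        "map_fraction": float(block_cm / total_cm) if total_cm > 0 else np.nan,
    }


def inbreeding_expected_fraction(t: int) -> float:
    """Expected heterozygous map fraction after t generations of full-sib
    mating: min(1, 1.17 * 0.809**t); 0.809 = (1 + sqrt 5)/4."""
    if t < 5:
        warnings.warn(
            "asymptotic approximation is inaccurate below t = 5", stacklevel=2
        )
    return min(1.0, 1.17 * 0.809**t)
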
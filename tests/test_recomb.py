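"""Marey-map smoothing, recombination statistics, variant filters, windows."""

import numpy as np
import pandas as pd
import pytest

from frogsynt.genmap import GeneticMap
from frogsynt.layout import GenomeLayout
from frogsynt.recomb import (
    feature_correlation,
    filter_variant_sites,
    heterozygosity_windows,
    inbreeding_expected_fraction,
    recombination_concentration,
    region_rate_comparison,
    smooth_marey,
)
from frogsynt.simulate import simulate_marey_map, simulate_variant_sites


# -- genetic map container -------------------------------------------------


def test_genetic_map_rejects_non_monotone():
    tab = pd.DataFrame(
        {"chrom": "c", "bp": [0, 10, 20], "cM": [0.0, 5.0, 3.0]}
    )
    with pytest.raises(ValueError, match="not monotone"):
        GeneticMap(tab)


def test_genetic_map_lengths_and_interpolation():
    tab = pd.DataFrame(
        {"chrom": ["c"] * 3, "bp": [0, 100, 200], "cM": [0.0, 10.0, 30.0]}
    )
    gm = GeneticMap(tab)
    assert gm.length_cm("c") == 30.0
    assert gm.length_cm() == 30.0
    assert gm.interpolate("c", [50, 150]) == pytest.approx([5.0, 20.0])


# -- spline smoothing ------------------------------------------------------


def test_smooth_marey_recovers_analytic_slopes():
    # cM = a*bp + b*bp^2 exactly representable by a cubic spline: the
    # derivative should match the analytic slope (a + 2 b x) everywhere
    a, b = 2e-6, 1e-14  # cM per bp (and per bp^2)
    bp = np.linspace(0, 50e6, 25)
    cm = a * bp + b * bp**2
    gm = GeneticMap(pd.DataFrame({"chrom": "c", "bp": bp, "cM": cm}))
    track = smooth_marey(gm, grid=1e6)
    expect = (a + 2 * b * track.table["pos"].to_numpy()) * 1e6  # cM/Mb
    assert np.allclose(track.table["rate"], expect, rtol=1e-6)
    assert track.n_clamped == 0


def test_smooth_marey_clamps_negative_derivatives():
    # a flat plateau between steep ends makes the interpolating spline
    # overshoot and dip below zero somewhere
    bp = np.array([0, 1e6, 2e6, 10e6, 18e6, 19e6, 20e6])
    cm = np.array([0, 10, 11, 11.01, 11.02, 12, 22])
    gm = GeneticMap(pd.DataFrame({"chrom": "c", "bp": bp, "cM": cm}))
    track = smooth_marey(gm, grid=2e5)
    assert track.n_clamped > 0
    assert (track.table["rate"] >= 0).all()


def test_smooth_marey_needs_four_markers():
    gm = GeneticMap(
        pd.DataFrame({"chrom": "c", "bp": [0, 10, 20], "cM": [0, 1, 2]})
    )
    with pytest.raises(ValueError, match="fewer than 4"):
        smooth_marey(gm)


# -- landscape statistics --------------------------------------------------


@pytest.fixture(scope="module")
def marey_setup():
    lengths = {
        f"chr{i + 1}": int(l) for i, l in enumerate([200e6, 150e6, 120e6])
    }
    layout = GenomeLayout(lengths, {c: int(0.45 * l) for c, l in lengths.items()})
    gm = simulate_marey_map(layout, seed=4)
    track = smooth_marey(gm, grid=500e3, layout=layout)
    return layout, gm, track


def test_subtelomeric_rates_dominate(marey_setup):
    layout, gm, track = marey_setup
    res = region_rate_comparison(track, layout)
    med = res["medians"]
    assert med["subtelomere"] > med["arm"] > med["pericentromere"]
    tests = res["tests"]
    sub_arm = tests[
        (tests["class_a"] == "subtelomere") & (tests["class_b"] == "arm")
    ]
    assert sub_arm["p_hochberg"].iloc[0] < 1e-6


def test_recombination_concentrated_in_small_fraction(marey_setup):
    _, _, track = marey_setup
    conc = recombination_concentration(track, quantiles=(0.5, 0.9))
    # the enriched subtelomeres hold half the map in a small genome slice
    assert conc[0.5] < 0.25
    assert conc[0.5] < conc[0.9] <= 1.0


def test_feature_correlation_detects_aligned_track(marey_setup):
    _, _, track = marey_setup
    feats = track.table[["chrom", "pos"]].copy()
    rng = np.random.default_rng(0)
    feats["aligned"] = track.table["rate"] + rng.normal(
        0, 0.1 * track.table["rate"].std(), len(feats)
    )
    feats["noise"] = rng.normal(size=len(feats))
    r = feature_correlation(track, feats)
    assert r["aligned"] > 0.9
    assert abs(r["noise"]) < 0.2


# -- variant-site filters --------------------------------------------------


def test_filter_recovers_planted_pass_flags():
    tab = simulate_variant_sites(n_sites=4000, with_parents=True, seed=11)
    kept, counts = filter_variant_sites(tab)
    expected = set(tab.loc[tab["expected_pass"], "pos"])
    assert set(kept["pos"]) == expected
    # filters applied in order: counts monotonically decrease
    ordered = [counts[k] for k in
               ("input", "biallelic", "depth", "allele_balance", "parental")]
    assert ordered == sorted(ordered, reverse=True)


def test_filter_without_parent_columns_skips_parental_stage():
    tab = simulate_variant_sites(n_sites=1000, with_parents=False, seed=1)
    kept, counts = filter_variant_sites(tab)
    assert "parental" not in counts
    assert set(kept["pos"]) == set(tab.loc[tab["expected_pass"], "pos"])


# -- heterozygosity windows ------------------------------------------------


def brute_force_window_overlap(pos, start, end):
    return int(np.sum((pos >= start) & (pos < end)))


def test_heterozygosity_windows_density_vs_brute_force():
    rng = np.random.default_rng(3)
    pos = np.sort(rng.integers(0, 10_000_000, 400))
    tab = pd.DataFrame({"chrom": "c", "pos": pos, "genotype": "0/1"})
    gm = GeneticMap(
        pd.DataFrame({"chrom": "c", "bp": [0, 10_000_000], "cM": [0.0, 50.0]})
    )
    res = heterozygosity_windows(
        tab, gm, {"c": 10_000_000}, window=500e3, step=50e3
    )
    w = res["windows"]
    for _, row in w.sample(20, random_state=0).iterrows():
        n = brute_force_window_overlap(pos, row["start"], row["end"])
        assert row["density"] == pytest.approx(n / 500.0)


def test_heterozygosity_blocks_and_map_fraction():
    # hets confined to [0, 2 Mb) of a 10-Mb chromosome with a linear map:
    # the block covers ~20% of bp and ~20% of cM
    rng = np.random.default_rng(5)
    pos = np.sort(rng.integers(0, 2_000_000, 300))
    tab = pd.DataFrame({"chrom": "c", "pos": pos, "genotype": "0/1"})
    gm = GeneticMap(
        pd.DataFrame({"chrom": "c", "bp": [0, 10_000_000], "cM": [0.0, 100.0]})
    )
    res = heterozygosity_windows(
        tab, gm, {"c": 10_000_000}, window=500e3, step=100e3
    )
    assert len(res["blocks"]) == 1
    assert res["map_fraction"] == pytest.approx(0.2, abs=0.05)


# -- inbreeding theory -----------------------------------------------------


def test_inbreeding_expected_fraction_values():
    assert inbreeding_expected_fraction(17) == pytest.approx(0.032, abs=5e-4)
    assert inbreeding_expected_fraction(13) == pytest.approx(0.074, abs=5e-4)


def test_inbreeding_expected_fraction_warns_small_t():
    with pytest.warns(UserWarning):
        inbreeding_expected_fraction(2)
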
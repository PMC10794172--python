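"""Tandem-repeat clustering, enrichment, ageing, and density landscapes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from frogsynt.layout import GenomeLayout
from frogsynt.repeats import (
    array_footprints,
    binned_density,
    build_monomer_db,
    density_pca,
    jc_distance,
    region_enrichment,
    tetramer_enrichment,
)
from frogsynt.simulate import (
    mutate_sequence,
    random_monomer,
    simulate_tandem_annotations,
)


# -- monomer clustering ----------------------------------------------------


def test_rotations_of_one_monomer_cluster_together():
    rng = np.random.default_rng(0)
    m = random_monomer(205, rng)
    rotated = m[50:] + m[:50]
    clusters = build_monomer_db({"a": m, "b": rotated})
    assert len(clusters) == 1
    assert sorted(clusters[0].members) == ["a", "b"]


def test_unrelated_monomers_stay_apart():
    rng = np.random.default_rng(1)
    clusters = build_monomer_db(
        {"a": random_monomer(205, rng), "b": random_monomer(205, rng)}
    )
    assert len(clusters) == 2


def test_single_monomer_is_its_own_representative():
    rng = np.random.default_rng(2)
    m = random_monomer(205, rng)
    clusters = build_monomer_db({"only": m})
    assert clusters[0].representative == "only"
    assert clusters[0].representative_seq == m


def test_diverged_copies_join_within_identity_threshold():
    rng = np.random.default_rng(3)
    m = random_monomer(205, rng)
    variants = {
        f"v{i}": mutate_sequence(m, 0.10, rng) for i in range(5)
    }
    variants["ref"] = m
    clusters = build_monomer_db(variants)
    assert len(clusters) == 1


def test_empty_input_gives_empty_db():
    assert build_monomer_db({}) == []


def test_short_monomer_rejected():
    with pytest.raises(ValueError, match="> 10 bp"):
        build_monomer_db({"x": "ACGTACGT"})


@settings(derandomize=True, max_examples=20, deadline=None)
@given(shift=st.integers(min_value=0, max_value=204),
       seed=st.integers(min_value=0, max_value=1000))
def test_clustering_invariant_to_rotation(shift, seed):
    rng = np.random.default_rng(seed)
    m = random_monomer(205, rng)
    other = random_monomer(205, rng)
    rotated = m[shift:] + m[:shift]
    clusters = build_monomer_db({"m": m, "rot": rotated, "other": other})
    parts = sorted(sorted(c.members) for c in clusters)
    assert parts == [["m", "rot"], ["other"]]


# -- regional enrichment ---------------------------------------------------


def test_region_enrichment_ranking_and_scale_invariance():
    fp = pd.DataFrame(
        {
            "family": ["confined", "uniform"],
            "roi_bp": [10_000.0, 1_000.0],
            "rest_bp": [0.0, 9_000.0],
        }
    )
    out = region_enrichment(fp, roi_length=1e6, rest_length=9e6)
    assert out["family"].iloc[0] == "confined"
    assert out.loc[out["family"] == "uniform", "enrichment"].iloc[0] == (
        pytest.approx(1.0, rel=0.01)
    )
    # doubling all footprints and lengths leaves the ratio unchanged
    # (checked away from the pseudocount-dominated zero-rest edge case)
    out2 = region_enrichment(
        fp.assign(roi_bp=fp["roi_bp"] * 2, rest_bp=fp["rest_bp"] * 2),
        roi_length=2e6, rest_length=18e6,
    )
    u1 = out.loc[out["family"] == "uniform", "enrichment"].iloc[0]
    u2 = out2.loc[out2["family"] == "uniform", "enrichment"].iloc[0]
    assert u1 == pytest.approx(u2, rel=0.01)


def test_planted_subtelomeric_family_ranks_first():
    layout = GenomeLayout(
        {"c1": 150_000_000, "c2": 120_000_000},
        {"c1": 60_000_000, "c2": 50_000_000},
    )
    sim = simulate_tandem_annotations(layout, seed=8)
    sub_fam = [f for f, r in sim.region_of_family.items()
               if r == "subtelomere"][0]
    rois = []
    for chrom in layout.names:
        rois += [(chrom, lo, hi) for lo, hi in layout.subtelomeres(chrom)]
    fp = array_footprints(sim.table, rois)
    roi_len = sum(hi - lo for _, lo, hi in rois)
    out = region_enrichment(
        fp, roi_length=roi_len, rest_length=layout.genome_size - roi_len
    )
    assert out["family"].iloc[0] == sub_fam


# -- Jukes-Cantor ----------------------------------------------------------


def test_jc_distance_formula():
    assert jc_distance(0.0) == 0.0
    assert jc_distance(0.05) == pytest.approx(
        -0.75 * np.log(1 - 4 * 0.05 / 3)
    )
    assert jc_distance(0.05) == pytest.approx(0.0517, abs=1e-4)
    with pytest.raises(ValueError):
        jc_distance(0.75)
    with pytest.raises(ValueError):
        jc_distance(-0.01)


@settings(derandomize=True, max_examples=50)
@given(p=st.floats(min_value=1e-6, max_value=0.74))
def test_jc_distance_monotone_and_above_p(p):
    assert jc_distance(p) >= p  # correction only inflates
    assert jc_distance(p) < jc_distance(min(p + 0.005, 0.7499))


# -- tetramer enrichment ---------------------------------------------------


def test_tetramer_counts_hand_checked():
    # TGGG appears twice overlapping-free; its reverse complement CCCA once
    seq = "TGGGTGGGCCCA"
    out = tetramer_enrichment([seq], ["ACGTACGTACGT"], motifs=("TGGG",))
    row = out.iloc[0]
    assert row["tandem_per_kb"] == pytest.approx(3 / (len(seq) / 1e3))
    assert not row["absent_in_tandem"]


def test_tetramer_planted_array_enriched():
    rng = np.random.default_rng(4)
    tandem = ["TGGG" * 100]
    background = [random_monomer(5000, rng)]
    out = tetramer_enrichment(tandem, background)
    tggg = out[out["motif"] == "TGGG"].iloc[0]
    assert tggg["ratio"] > 10


def test_tetramer_absent_flagged():
    out = tetramer_enrichment(["AAAAAAAA"], ["CCCCGGGG"], motifs=("ACAG",))
    row = out.iloc[0]
    assert row["absent_in_tandem"]
    assert np.isnan(row["ratio"])  # missing from both sets


def test_single_strand_mode_halves_palindrome_free_counts():
    seq = "TGGGCCCA"  # one forward TGGG + one reverse-complement hit
    both = tetramer_enrichment([seq], ["A" * 20], motifs=("TGGG",))
    single = tetramer_enrichment(
        [seq], ["A" * 20], motifs=("TGGG",), both_strands=False
    )
    assert both.iloc[0]["tandem_per_kb"] == 2 * single.iloc[0]["tandem_per_kb"]


# -- densities and PCA -----------------------------------------------------


def test_binned_density_interval_overlap_brute_force():
    rng = np.random.default_rng(6)
    starts = rng.integers(0, 9_000, 10)
    iv = pd.DataFrame({"start": starts, "end": starts + rng.integers(50, 500, 10)})
    out = binned_density(10_000, window=1_000, step=250, intervals=iv)
    for _, row in out.iterrows():
        brute = sum(
            max(0, min(e, row["end"]) - max(s, row["start"]))
            for s, e in zip(iv["start"], iv["end"])
        )
        assert row["value"] == pytest.approx(brute)


def test_binned_density_full_and_half_coverage():
    iv = pd.DataFrame({"start": [0], "end": [1_000]})
    out = binned_density(2_000, window=1_000, step=500, intervals=iv)
    assert out["value"].iloc[0] == 1_000       # fully covered window
    assert out["value"].iloc[1] == 500         # half covered
    assert out["value"].iloc[2] == 0


def test_binned_density_gc_fraction():
    seq = "G" * 500 + "A" * 500
    out = binned_density(1_000, window=500, step=250, sequence=seq)
    assert out["value"].iloc[0] == 1.0
    assert out["value"].iloc[1] == 0.5
    assert out["value"].iloc[2] == 0.0


def test_binned_density_requires_input():
    with pytest.raises(ValueError):
        binned_density(1_000, 100, 50)


def test_density_pca_recovers_planted_axis():
    rng = np.random.default_rng(9)
    axis = np.where(rng.random(300) < 0.5, 1.0, -1.0)
    X = pd.DataFrame(
        {
            f"f{k}": axis * rng.uniform(0.5, 2.0)
            + rng.normal(0, 0.3, 300)
            for k in range(6)
        }
    )
    out = density_pca(X, compartment_track=axis)
    assert abs(out["compartment_correlation"][0]) > 0.95
    assert out["explained_variance_ratio"][0] > 0.5


def test_density_pca_orthogonal_factors_in_separate_components():
    rng = np.random.default_rng(10)
    f1 = rng.normal(size=400)
    f2 = rng.normal(size=400)
    # unequal column counts keep the two (standardized) factor
    # eigenvalues well separated, so the components do not mix
    X = pd.DataFrame(
        {
            "a": f1 + rng.normal(0, 0.1, 400),
            "b": f1 + rng.normal(0, 0.1, 400),
            "c": f1 + rng.normal(0, 0.1, 400),
            "d": f2 + rng.normal(0, 0.1, 400),
            "e": f2 + rng.normal(0, 0.1, 400),
        }
    )
    out = density_pca(X)
    s = out["scores"]
    assert abs(np.corrcoef(s[:, 0], f1)[0, 1]) > 0.95
    assert abs(np.corrcoef(s[:, 1], f2)[0, 1]) > 0.95
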
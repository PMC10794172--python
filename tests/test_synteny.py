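"""Syntenic-element inference: collinear runs, parsimony, recovery."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from frogsynt.synteny import (
    _root_state_costs,
    collinear_runs,
    conservation_fraction,
    element_proportions,
    filter_stray_orthologs,
    infer_elements,
    species_of,
)


def tree4(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


def test_species_of_parses_column_pairs():
    tab = pd.DataFrame(columns=["gene", "sp1_chrom", "sp1_pos",
                                "sp2_chrom", "sp2_pos"])
    assert species_of(tab) == ["sp1", "sp2"]


def test_collinear_runs_simple_forward_run():
    # 6 genes collinear on chrA/chrB, then 3 on chrA/chrC
    tab = pd.DataFrame(
        {
            "gene": [f"g{i}" for i in range(9)],
            "a_chrom": ["chrA"] * 9,
            "a_pos": np.arange(9) * 100,
            "b_chrom": ["chrB"] * 6 + ["chrC"] * 3,
            "b_pos": list(np.arange(6) * 50) + list(np.arange(3) * 70),
        }
    )
    runs = collinear_runs(tab, "a", "b", min_run=3)
    assert len(runs) == 2
    assert list(runs["n_genes"]) == [6, 3]
    assert set(runs["orientation"]) == {"+"}


def test_collinear_runs_detects_inverted_orientation():
    tab = pd.DataFrame(
        {
            "gene": [f"g{i}" for i in range(5)],
            "a_chrom": ["chrA"] * 5,
            "a_pos": np.arange(5) * 100,
            "b_chrom": ["chrB"] * 5,
            "b_pos": (4 - np.arange(5)) * 50,  # reversed order
        }
    )
    runs = collinear_runs(tab, "a", "b", min_run=3)
    assert len(runs) == 1
    assert runs["orientation"].iloc[0] == "-"


def test_collinear_runs_short_runs_dropped():
    tab = pd.DataFrame(
        {
            "gene": ["g0", "g1"],
            "a_chrom": ["chrA", "chrA"],
            "a_pos": [0, 100],
            "b_chrom": ["chrB", "chrB"],
            "b_pos": [0, 50],
        }
    )
    assert len(collinear_runs(tab, "a", "b", min_run=3)) == 0


def test_filter_stray_orthologs():
    tab = pd.DataFrame(
        {
            "gene": [f"g{i}" for i in range(7)],
            "a_chrom": ["1"] * 6 + ["2"],
            "a_pos": range(7),
            "b_chrom": ["1"] * 6 + ["9"],
            "b_pos": range(7),
        }
    )
    out = filter_stray_orthologs(tab, min_cluster=3)
    assert len(out) == 6
    assert "g6" not in set(out["gene"])


def test_root_state_costs_hand_worked():
    # ((a:1,b:1):1,(c:1,d:1):1); a,b "apart", c,d "together".
    # root=together needs one change on the (a,b) stem (cost 1/1);
    # root=apart needs one change on the (c,d) stem (cost 1/1): tie.
    t = tree4("((a:1,b:1):1,(c:1,d:1):1):0;")
    costs = _root_state_costs(
        t, {"a": "apart", "b": "apart", "c": "together", "d": "together"}
    )
    assert costs["together"] == pytest.approx(1.0)
    assert costs["apart"] == pytest.approx(1.0)
    # lengthening the (a,b) stem makes the change there cheaper, so
    # "together" at the root wins
    t2 = tree4("((a:1,b:1):10,(c:1,d:1):1):0;")
    costs2 = _root_state_costs(
        t2, {"a": "apart", "b": "apart", "c": "together", "d": "together"}
    )
    assert costs2["together"] < costs2["apart"]


def test_root_state_costs_unanimous():
    t = tree4("((a:1,b:1):1,(c:1,d:1):1):0;")
    costs = _root_state_costs(t, {s: "together" for s in "abcd"})
    assert costs["together"] == 0.0
    assert costs["apart"] > 0.0


def make_table(chroms_by_species: dict[str, list[str]]) -> pd.DataFrame:
    """Build an ortholog table with 5 genes per listed signature row."""
    species = list(chroms_by_species)
    n_rows = len(chroms_by_species[species[0]])
    rows = []
    g = 0
    for i in range(n_rows):
        for _ in range(5):
            row = {"gene": f"g{g}"}
            for sp in species:
                row[f"{sp}_chrom"] = chroms_by_species[sp][i]
                row[f"{sp}_pos"] = g * 1000
            rows.append(row)
            g += 1
    return pd.DataFrame(rows)


def test_infer_elements_merges_lineage_specific_fission():
    # element X split on the terminal branch to sp1 only: root together
    tab = make_table(
        {
            "sp1": ["1a", "1b", "2"],
            "sp2": ["1", "1", "2"],
            "sp3": ["1", "1", "2"],
        }
    )
    t = tree4("((sp1:1,sp2:1):1,sp3:2):0;")
    asg = infer_elements(tab, t)
    assert len(asg.elements) == 2
    # the two sp1 chromosomes carry the same element
    df = asg.assignments
    e1 = df.loc[df["sp1_chrom"] == "1a", "element"].iloc[0]
    e2 = df.loc[df["sp1_chrom"] == "1b", "element"].iloc[0]
    assert e1 == e2


def test_infer_elements_keeps_lineage_specific_fusion_apart():
    # two elements fused only in sp1: root apart, two elements inferred
    tab = make_table(
        {
            "sp1": ["12", "12"],
            "sp2": ["1", "2"],
            "sp3": ["1", "2"],
        }
    )
    t = tree4("((sp1:1,sp2:1):1,sp3:2):0;")
    asg = infer_elements(tab, t)
    assert len(asg.elements) == 2


def test_infer_elements_small_clusters_unassigned():
    tab = make_table({"sp1": ["1"], "sp2": ["1"]})
    stray = pd.DataFrame(
        {
            "gene": ["s0"],
            "sp1_chrom": ["9"],
            "sp1_pos": [0],
            "sp2_chrom": ["9"],
            "sp2_pos": [0],
        }
    )
    tab = pd.concat([tab, stray], ignore_index=True)
    t = tree4("(sp1:1,sp2:1):0;")
    asg = infer_elements(tab, t, min_cluster=3)
    assert list(asg.unassigned["gene"]) == ["s0"]


def test_infer_elements_ref_species_labels():
    tab = make_table({"sp1": ["7", "8"], "sp2": ["1", "2"]})
    t = tree4("(sp1:1,sp2:1):0;")
    asg = infer_elements(tab, t, ref_species="sp1")
    assert set(asg.elements) == {"7", "8"}


def test_infer_elements_requires_tree_species():
    tab = make_table({"sp1": ["1"], "spX": ["1"]})
    t = tree4("(sp1:1,sp2:1):0;")
    with pytest.raises(ValueError, match="lacks species"):
        infer_elements(tab, t)


def test_conservation_fraction_all_conserved():
    tab = make_table({"sp1": ["1", "2"], "sp2": ["1", "2"]})
    t = tree4("(sp1:1,sp2:1):0;")
    asg = infer_elements(tab, t)
    assert conservation_fraction(asg) == 1.0


def test_element_proportions_fractions_sum():
    tab = make_table({"sp1": ["1", "2"], "sp2": ["1", "2"]})
    t = tree4("(sp1:1,sp2:1):0;")
    asg = infer_elements(tab, t)
    props = element_proportions(
        asg, genome_sizes={"sp1": 10_000, "sp2": 10_000}
    )
    assert set(props["element"]) == set(asg.elements)
    assert np.isfinite(props["bp_fraction_cv"]).all()
    assert (props["sp1_gene_fraction"] > 0).all()


def test_truth_column_preserved_as_element_truth():
    tab = make_table({"sp1": ["1"], "sp2": ["1"]})
    tab["element"] = "X"
    t = tree4("(sp1:1,sp2:1):0;")
    asg = infer_elements(tab, t)
    assert "element_truth" in asg.assignments.columns
    assert (asg.assignments["element_truth"] == "X").all()
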
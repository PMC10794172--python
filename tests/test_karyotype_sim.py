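"""Karyotype rearrangement simulator: event grammar, replay, conservation."""

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from frogsynt.layout import GenomeLayout
from frogsynt.simulate import (
    Chromosome,
    Karyotype,
    RearrangementEvent,
    Segment,
    apply_event,
    default_ancestral_layout,
    request_fission,
    simulate_karyotype_history,
)
from frogsynt.simulate.karyotype import _branch_id

from conftest import RATES, make_tree


def toy_karyotype() -> Karyotype:
    lay = GenomeLayout(
        {"A": 100_000_000, "B": 80_000_000},
        {"A": 40_000_000, "B": 8_000_000},
    )
    return Karyotype.from_layout(lay)


def total_element_bp(kar: Karyotype) -> dict[str, int]:
    out: dict[str, int] = {}
    for chrom in kar.chromosomes.values():
        for seg in chrom.segments:
            out[seg.element] = out.get(seg.element, 0) + seg.length
    return out


def test_fusion_concatenates_and_keeps_one_centromere():
    kar = toy_karyotype()
    ev = RearrangementEvent(
        branch="x",
        etype="end_to_end_fusion",
        parents=("A", "B"),
        children=("A-B",),
        junctions=(("A", 100_000_000), ("B", 0)),
        params={"flip_a": False, "flip_b": False, "surviving_centromere": "A"},
    )
    out = apply_event(kar, ev)
    assert set(out.chromosomes) == {"A-B"}
    child = out.chromosomes["A-B"]
    assert child.length == 180_000_000
    assert child.centromere == 40_000_000
    # surviving centromere from B instead: offset by A's length
    ev.params["surviving_centromere"] = "B"
    child2 = apply_event(kar, ev).chromosomes["A-B"]
    assert child2.centromere == 100_000_000 + 8_000_000


def test_fission_at_centromere_gives_acrocentric_daughters():
    kar = toy_karyotype()
    ev = RearrangementEvent(
        branch="x",
        etype="robertsonian_fission",
        parents=("A",),
        children=("A1", "A2"),
        junctions=(("A", 40_000_000),),
        params={},
    )
    out = apply_event(kar, ev)
    a1, a2 = out.chromosomes["A1"], out.chromosomes["A2"]
    assert a1.length == 40_000_000 and a2.length == 60_000_000
    # neo-centromeres sit just inside the broken (centric) ends
    assert a1.length - a1.centromere <= 1_000_000
    assert a2.centromere <= 1_000_000


def test_reciprocal_translocation_exchanges_and_is_monocentric():
    kar = toy_karyotype()
    ev = RearrangementEvent(
        branch="x",
        etype="reciprocal_translocation",
        parents=("A", "B"),
        children=("T1", "T2"),
        junctions=(("A", 70_000_000), ("B", 50_000_000)),
        params={},
    )
    out = apply_event(kar, ev)
    t1, t2 = out.chromosomes["T1"], out.chromosomes["T2"]
    assert t1.length == 70_000_000 + 30_000_000
    assert t2.length == 50_000_000 + 30_000_000
    assert 0 < t1.centromere < t1.length
    assert 0 < t2.centromere < t2.length
    # bp conservation per element
    assert total_element_bp(out) == total_element_bp(kar)


def test_reciprocal_translocation_rejects_dicentric():
    kar = toy_karyotype()
    ev = RearrangementEvent(
        branch="x",
        etype="reciprocal_translocation",
        parents=("A", "B"),
        children=("T1", "T2"),
        junctions=(("A", 70_000_000), ("B", 4_000_000)),
        params={},
    )
    with pytest.raises(ValueError, match="dicentric"):
        apply_event(kar, ev)


def test_inversion_reflects_positions_and_centromere():
    kar = toy_karyotype()
    p1, p2 = 30_000_000, 60_000_000
    ev = RearrangementEvent(
        branch="x", etype="inversion", parents=("A",), children=("A",),
        junctions=(("A", p1), ("A", p2)), params={},
    )
    out = apply_event(kar, ev)
    chrom = out.chromosomes["A"]
    assert chrom.length == 100_000_000
    # centromere inside the inverted interval is reflected
    assert chrom.centromere == p1 + p2 - 1 - 40_000_000
    # an ancestral position inside the inversion maps to its mirror image
    name, pos = out.locate("A", 35_000_000)
    assert name == "A" and pos == p1 + p2 - 1 - 35_000_000
    # a position outside is untouched
    assert out.locate("A", 5_000_000) == ("A", 5_000_000)


def test_child_name_clash_rejected():
    kar = toy_karyotype()
    ev = RearrangementEvent(
        branch="x",
        etype="robertsonian_fission",
        parents=("A",),
        children=("B", "A2"),  # "B" already exists
        junctions=(("A", 40_000_000),),
        params={},
    )
    with pytest.raises(ValueError, match="already present"):
        apply_event(kar, ev)


def test_request_fission_rejects_single_element_chromosome():
    kar = Karyotype(
        {"A": Chromosome("A", [Segment("A", 0, 1000)], 500)}
    )
    with pytest.raises(ValueError, match="single ancestral element"):
        request_fission(kar, "A")


def test_zero_rates_reproduce_ancestor(species_tree):
    lay = default_ancestral_layout()
    hist = simulate_karyotype_history(lay, species_tree, rates={}, seed=0)
    assert hist.events == []
    for leaf, leaf_lay in hist.leaf_layouts.items():
        assert leaf_lay.lengths == lay.lengths
        assert leaf_lay.centromeres == lay.centromeres


def test_replay_is_exact(karyotype_history):
    replayed = karyotype_history.replay()
    for leaf, kar in karyotype_history.leaf_karyotypes.items():
        rep = replayed[leaf]
        assert set(rep.chromosomes) == set(kar.chromosomes)
        for name, chrom in kar.chromosomes.items():
            other = rep.chromosomes[name]
            assert chrom.segments == other.segments
            assert chrom.centromere == other.centromere


def test_element_bp_conserved_across_history(karyotype_history):
    lay = karyotype_history.ancestral_layout
    ancestral = {c: lay.length(c) for c in lay.names}
    for kar in karyotype_history.leaf_karyotypes.values():
        assert total_element_bp(kar) == ancestral


def element_at(kar: Karyotype, chrom: str, pos: int) -> str:
    off = 0
    for seg in kar.chromosomes[chrom].segments:
        if off <= pos < off + seg.length:
            return seg.element
        off += seg.length
    raise IndexError(pos)


def test_ortholog_table_consistent_with_karyotypes(karyotype_history):
    tab = karyotype_history.orthologs
    rng = np.random.default_rng(0)
    rows = tab.iloc[rng.choice(len(tab), size=200, replace=False)]
    for leaf, kar in karyotype_history.leaf_karyotypes.items():
        for _, row in rows.iterrows():
            chrom = row[f"{leaf}_chrom"]
            pos = int(row[f"{leaf}_pos"])
            assert 0 <= pos < kar.chromosomes[chrom].length
            # the gene's recorded leaf position falls on a segment of its
            # ancestral element
            assert element_at(kar, chrom, pos) == row["element"]


def test_events_only_on_tree_branches(karyotype_history):
    branch_ids = {
        _branch_id(node)
        for node in karyotype_history.tree.preorder_node_iter()
        if node is not karyotype_history.tree.seed_node
    }
    assert {e.branch for e in karyotype_history.events} <= branch_ids


def test_unknown_rate_key_rejected(species_tree):
    with pytest.raises(ValueError, match="unknown event types"):
        simulate_karyotype_history(
            default_ancestral_layout(), species_tree, rates={"fusion": 0.1}
        )


def test_negative_rate_rejected(species_tree):
    with pytest.raises(ValueError, match=">= 0"):
        simulate_karyotype_history(
            default_ancestral_layout(),
            species_tree,
            rates={"inversion": -0.1},
        )


@settings(derandomize=True, max_examples=30, deadline=None)
@given(seed=st.integers(min_value=0, max_value=10_000))
def test_simulated_leaves_are_valid_karyotypes(seed):
    hist = simulate_karyotype_history(
        default_ancestral_layout(), make_tree(), rates=RATES, seed=seed
    )
    for kar in hist.leaf_karyotypes.values():
        for chrom in kar.chromosomes.values():
            assert 0 < chrom.centromere < chrom.length
            assert all(s.length > 0 for s in chrom.segments)
        # a layout can always be built (validates invariants again)
        kar.to_layout()
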
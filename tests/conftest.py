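"""Shared fixtures: small genome layouts and cached expensive simulations."""

import dendropy
import numpy as np
import pytest

from frogsynt.layout import GenomeLayout
from frogsynt.simulate import (
    HicSimParams,
    default_ancestral_layout,
    simulate_hic_matrix,
    simulate_karyotype_history,
)

TREE_STR = (
    "((xtrop:80,(xlaevL:40,xlaevS:40):40):40,(hboet:150,ecoqui:150):50):0;"
)

RATES = {
    "robertsonian_fusion": 0.003,
    "robertsonian_fission": 0.001,
    "end_to_end_fusion": 0.002,
    "reciprocal_translocation": 0.002,
    "inversion": 0.01,
}


def make_tree() -> dendropy.Tree:
    return dendropy.Tree.get(data=TREE_STR, schema="newick")


@pytest.fixture()
def species_tree() -> dendropy.Tree:
    return make_tree()


@pytest.fixture(scope="session")
def small_layout() -> GenomeLayout:
    lengths = {
        f"chr{i + 1}": int(l)
        for i, l in enumerate([200e6, 180e6, 160e6, 120e6, 100e6])
    }
    cens = {c: int(0.4 * l) for c, l in lengths.items()}
    return GenomeLayout(lengths, cens)


@pytest.fixture(scope="session")
def hic_sim(small_layout):
    """One cached Hi-C simulation shared by the architecture tests."""
    params = HicSimParams(bin_size=2_000_000, total_reads=1e7)
    return simulate_hic_matrix(small_layout, params, seed=3)


@pytest.fixture(scope="session")
def karyotype_history():
    """One cached rearrangement history shared by synteny/rate tests."""
    return simulate_karyotype_history(
        default_ancestral_layout(), make_tree(), rates=RATES, seed=42
    )


def truth_centromere_bins(sim):
    """Planted centromere bins as within-chromosome indices."""
    out = {}
    for chrom in sim.matrix.chromosomes:
        idx = sim.matrix.chrom_bins(chrom)
        out[chrom] = int(np.flatnonzero(idx == sim.centromere_bins[chrom])[0])
    return out
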
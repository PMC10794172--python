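"""Forward simulation of karyotype evolution on a dated phylogeny.

Chromosomes are modelled as ordered lists of oriented segments of 13 (or
any number of) ancestral elements.  Rearrangements — Robertsonian
fusion/fission, end-to-end fusion, reciprocal translocation, inversion —
are drawn as independent Poisson processes per branch and applied to a
replayable event log, so the true history can be reconstructed exactly:
applying the recorded events to the ancestor reproduces every leaf
karyotype bit-for-bit.

Junction geometry follows the centric grammar of frog karyotype change:
Robertsonian events break or join exactly at centromeres, end-to-end
fusions join telomeric ends and silence one of the two centromeres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from ..layout import GenomeLayout

__all__ = [
    "Segment",
    "Chromosome",
    "Karyotype",
    "RearrangementEvent",
    "SimulatedHistory",
    "apply_event",
    "simulate_karyotype_history",
]

EVENT_TYPES = (
    "robertsonian_fusion",
    "robertsonian_fission",
    "end_to_end_fusion",
    "reciprocal_translocation",
    "inversion",
)


@dataclass(frozen=True)
class Segment:
    """Oriented interval of an ancestral element, half-open in element bp."""

    element: str
    start: int
    end: int
    strand: int = 1

    @property
    def length(self) -> int:
        return self.end - self.start

    def reversed(self) -> "Segment":
        return replace(self, strand=-self.strand)


@dataclass
class Chromosome:
    name: str
    segments: list[Segment]
    centromere: int

    @property
    def length(self) -> int:
        return sum(s.length for s in self.segments)

    def reversed(self, name: str | None = None) -> "Chromosome":
        return Chromosome(
            name or self.name,
            [s.reversed() for s in reversed(self.segments)],
            self.length - self.centromere,
        )

    def split_segments(self, pos: int) -> tuple[list[Segment], list[Segment]]:
        """Cut the segment list at chromosome coordinate ``pos``."""
        if not (0 < pos < self.length):
            raise ValueError(f"breakpoint {pos} outside (0, {self.length})")
        return _split(self.segments, pos)


@dataclass
class Karyotype:
    chromosomes: dict[str, Chromosome]

    @classmethod
    def from_layout(cls, layout: GenomeLayout) -> "Karyotype":
        chroms = {
            name: Chromosome(
                name,
                [Segment(name, 0, layout.length(name))],
                layout.centromere(name),
            )
            for name in layout.names
        }
        return cls(chroms)

    def to_layout(self) -> GenomeLayout:
        return GenomeLayout(
            {c.name: c.length for c in self.chromosomes.values()},
            {c.name: c.centromere for c in self.chromosomes.values()},
        )

    def copy(self) -> "Karyotype":
        return Karyotype(
            {
                n: Chromosome(c.name, list(c.segments), c.centromere)
                for n, c in self.chromosomes.items()
            }
        )

    def locate(self, element: str, pos: int) -> tuple[str, int]:
        """Map an ancestral-element coordinate to (chromosome, position)."""
        for chrom in self.chromosomes.values():
            off = 0
            for seg in chrom.segments:
                if seg.element == element and seg.start <= pos < seg.end:
                    if seg.strand == 1:
                        return chrom.name, off + (pos - seg.start)
                    return chrom.name, off + (seg.end - 1 - pos)
                off += seg.length
        raise KeyError(f"ancestral position {element}:{pos} not found")


@dataclass
class RearrangementEvent:
    """One typed rearrangement on a tree branch, replayable on the parent.

    ``junctions`` are breakpoint coordinates in the *parent* frame as
    ``(chromosome, position)`` pairs; ``params`` carries whatever the apply
    step needs to be deterministic (orientations, child names, surviving
    centromere).
    """

    branch: str
    etype: str
    parents: tuple[str, ...]
    children: tuple[str, ...]
    junctions: tuple[tuple[str, int], ...]
    params: dict = field(default_factory=dict)


def _split(segments: list[Segment], pos: int) -> tuple[list[Segment], list[Segment]]:
    left: list[Segment] = []
    right: list[Segment] = []
    off = 0
    for seg in segments:
        if off + seg.length <= pos:
            left.append(seg)
        elif off >= pos:
            right.append(seg)
        else:
            cut = pos - off
            if seg.strand == 1:
                left.append(replace(seg, end=seg.start + cut))
                right.append(replace(seg, start=seg.start + cut))
            else:
                left.append(replace(seg, start=seg.end - cut))
                right.append(replace(seg, end=seg.end - cut))
        off += seg.length
    return left, right


def _fresh_name(kar: Karyotype, base: str) -> str:
    if base not in kar.chromosomes:
        return base
    i = 2
    while f"{base}.{i}" in kar.chromosomes:
        i += 1
    return f"{base}.{i}"


def _neo_centromere_margin(length: int) -> int:
    return int(min(1e6, max(1, 0.05 * length)))


def apply_event(kar: Karyotype, ev: RearrangementEvent) -> Karyotype:
    """Apply one event to a karyotype, returning a new karyotype."""
    kar = kar.copy()
    clash = [c for c in ev.children if c in kar.chromosomes and c not in ev.parents]
    if clash:
        raise ValueError(f"child name(s) already present: {clash}")
    if ev.etype in ("robertsonian_fusion", "end_to_end_fusion"):
        a = kar.chromosomes.pop(ev.parents[0])
        b = kar.chromosomes.pop(ev.parents[1])
        if ev.params["flip_a"]:
            a = a.reversed()
        if ev.params["flip_b"]:
            b = b.reversed()
        survivor = ev.params["surviving_centromere"]
        cen_a, cen_b = a.centromere, a.length + b.centromere
        cen = cen_a if survivor == ev.parents[0] else cen_b
        child = Chromosome(ev.children[0], a.segments + b.segments, cen)
        kar.chromosomes[child.name] = child
    elif ev.etype == "robertsonian_fission":
        chrom = kar.chromosomes.pop(ev.parents[0])
        pos = ev.junctions[0][1]
        left_seg, right_seg = chrom.split_segments(pos)
        left_len = sum(s.length for s in left_seg)
        right_len = chrom.length - left_len
        # parent centromere == breakpoint: each daughter gets an acrocentric
        # neo-centromere just inside the broken end
        left = Chromosome(
            ev.children[0], left_seg, left_len - _neo_centromere_margin(left_len)
        )
        right = Chromosome(ev.children[1], right_seg, _neo_centromere_margin(right_len))
        kar.chromosomes[left.name] = left
        kar.chromosomes[right.name] = right
    elif ev.etype == "reciprocal_translocation":
        a = kar.chromosomes.pop(ev.parents[0])
        b = kar.chromosomes.pop(ev.parents[1])
        pos_a, pos_b = ev.junctions[0][1], ev.junctions[1][1]
        a_left, a_right = a.split_segments(pos_a)
        b_left, b_right = b.split_segments(pos_b)
        # products: A_left+B_right and B_left+A_right; exactly one centromere
        # lands in each when the breakpoints are on the same side of their
        # respective centromeres (validated at draw time)
        if (pos_a > a.centromere) != (pos_b > b.centromere):
            raise ValueError("translocation would create a dicentric product")
        if pos_a > a.centromere:
            cen1, cen2 = a.centromere, b.centromere
        else:
            cen1 = pos_a + (b.centromere - pos_b)
            cen2 = pos_b + (a.centromere - pos_a)
        c1 = Chromosome(ev.children[0], a_left + b_right, cen1)
        c2 = Chromosome(ev.children[1], b_left + a_right, cen2)
        kar.chromosomes[c1.name] = c1
        kar.chromosomes[c2.name] = c2
    elif ev.etype == "inversion":
        chrom = kar.chromosomes[ev.parents[0]]
        p1, p2 = ev.junctions[0][1], ev.junctions[1][1]
        left, rest = _split(chrom.segments, p1)
        mid, right = _split(rest, p2 - p1)
        inv = [s.reversed() for s in reversed(mid)]
        cen = chrom.centromere
        if p1 <= cen < p2:
            cen = p1 + p2 - 1 - cen  # point coordinate reflected in [p1, p2)
            cen = max(1, min(chrom.length - 1, cen))
        kar.chromosomes[chrom.name] = Chromosome(chrom.name, left + inv + right, cen)
    else:
        raise ValueError(f"unknown event type {ev.etype!r}")
    return kar


@dataclass
class SimulatedHistory:
    """Planted truth for one simulated karyotype history."""

    ancestral_layout: GenomeLayout
    tree: dendropy.Tree
    events: list[RearrangementEvent]
    leaf_karyotypes: dict[str, Karyotype]
    leaf_layouts: dict[str, GenomeLayout]
    orthologs: pd.DataFrame
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def events_on_branch(self, branch: str) -> list[RearrangementEvent]:
        return [e for e in self.events if e.branch == branch]

    def replay(self) -> dict[str, Karyotype]:
        """Re-derive every leaf karyotype from the ancestor and event log."""
        root_kar = Karyotype.from_layout(self.ancestral_layout)
        out: dict[str, Karyotype] = {}
        state = {self.tree.seed_node: root_kar}
        for node in self.tree.preorder_node_iter():
            if node is self.tree.seed_node:
                continue
            kar = state[node.parent_node]
            for ev in self.events_on_branch(_branch_id(node)):
                kar = apply_event(kar, ev)
            state[node] = kar
            if node.is_leaf():
                out[node.taxon.label] = kar
        return out


def _branch_id(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return node.label or f"node{id(node)}"


def _label_internal_nodes(tree: dendropy.Tree) -> None:
    i = 0
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and not node.label:
            node.label = f"anc{i}"
            i += 1


def _draw_fusion(
    kar: Karyotype, rng: np.random.Generator, branch: str, robertsonian: bool,
    eps_c: float,
) -> RearrangementEvent | None:
    names = list(kar.chromosomes)
    if len(names) < 2:
        return None
    if robertsonian:
        # eligible: centromere within eps_c of one end
        elig = [
            n for n in names
            if min(kar.chromosomes[n].centromere,
                   kar.chromosomes[n].length - kar.chromosomes[n].centromere) <= eps_c
        ]
        if len(elig) < 2:
            return None
        na, nb = rng.choice(elig, size=2, replace=False)
    else:
        na, nb = rng.choice(names, size=2, replace=False)
    a, b = kar.chromosomes[na], kar.chromosomes[nb]
    if robertsonian:
        # join the centromere-proximal ends
        flip_a = a.centromere <= a.length - a.centromere  # cen near left -> flip
        flip_b = b.centromere > b.length - b.centromere   # cen near right -> flip
        jx_a = 0 if flip_a else a.length
        jx_b = b.length if flip_b else 0
        etype = "robertsonian_fusion"
    else:
        flip_a = bool(rng.integers(2))
        flip_b = bool(rng.integers(2))
        jx_a = 0 if flip_a else a.length
        jx_b = b.length if flip_b else 0
        etype = "end_to_end_fusion"
    survivor = str(rng.choice([na, nb]))
    child = _fresh_name(kar, f"{na}-{nb}")
    return RearrangementEvent(
        branch, etype, (na, nb), (child,),
        ((na, jx_a), (nb, jx_b)),
        {"flip_a": bool(flip_a), "flip_b": bool(flip_b),
         "surviving_centromere": survivor},
    )


def _draw_fission(
    kar: Karyotype, rng: np.random.Generator, branch: str
) -> RearrangementEvent | None:
    margin = 2_000_000
    elig = [
        n for n, c in kar.chromosomes.items()
        if margin < c.centromere < c.length - margin
    ]
    if not elig:
        return None
    name = str(rng.choice(elig))
    chrom = kar.chromosomes[name]
    return RearrangementEvent(
        branch, "robertsonian_fission", (name,),
        (_fresh_name(kar, f"{name}p"), _fresh_name(kar, f"{name}q")),
        ((name, chrom.centromere),),
    )


def _draw_translocation(
    kar: Karyotype, rng: np.random.Generator, branch: str
) -> RearrangementEvent | None:
    names = [n for n, c in kar.chromosomes.items() if c.length > 4]
    if len(names) < 2:
        return None
    for _ in range(20):
        na, nb = rng.choice(names, size=2, replace=False)
        a, b = kar.chromosomes[na], kar.chromosomes[nb]
        pos_a = int(rng.integers(1, a.length))
        # same side of the centromere keeps both products monocentric
        if pos_a > a.centromere:
            if b.centromere + 1 >= b.length:
                continue
            pos_b = int(rng.integers(b.centromere + 1, b.length))
        else:
            if b.centromere <= 1:
                continue
            pos_b = int(rng.integers(1, b.centromere + 1))
        return RearrangementEvent(
            branch, "reciprocal_translocation", (na, nb),
            (_fresh_name(kar, f"{na}t"), _fresh_name(kar, f"{nb}t")),
            ((na, pos_a), (nb, pos_b)),
        )
    return None


def _draw_inversion(
    kar: Karyotype, rng: np.random.Generator, branch: str
) -> RearrangementEvent | None:
    names = [n for n, c in kar.chromosomes.items() if c.length > 4]
    if not names:
        return None
    name = str(rng.choice(names))
    chrom = kar.chromosomes[name]
    p1, p2 = sorted(rng.integers(1, chrom.length, size=2))
    if p1 == p2:
        return None
    return RearrangementEvent(
        branch, "inversion", (name,), (name,), ((name, int(p1)), (name, int(p2)))
    )


def simulate_karyotype_history(
    ancestral_layout: GenomeLayout,
    tree: dendropy.Tree,
    rates: dict[str, float],
    seed: int | np.random.Generator = 0,
    n_genes: int = 7292,
    eps_c: float = 5e6,
) -> SimulatedHistory:
    """Simulate rearrangement histories along a dated tree.

    Parameters
    ----------
    rates:
        Events per My for each type in ``EVENT_TYPES``; missing types
        default to 0.
    n_genes:
        One-to-one orthologs placed uniformly across the ancestral
        elements, proportionally to element length.
    eps_c:
        Centric window (bp): Robertsonian fusions only involve
        chromosomes whose centromere lies within this distance of an end.
    """
    bad = set(rates) - set(EVENT_TYPES)
    if bad:
        raise ValueError(f"unknown event types: {sorted(bad)}")
    if any(r < 0 for r in rates.values()):
        raise ValueError("rates must be >= 0")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    tree = tree.clone(depth=1)
    _label_internal_nodes(tree)

    # place genes proportionally to element length
    lengths = np.array([ancestral_layout.length(c) for c in ancestral_layout.names])
    probs = lengths / lengths.sum()
    elements = rng.choice(ancestral_layout.names, size=n_genes, p=probs)
    positions = np.array(
        [int(rng.integers(0, ancestral_layout.length(e))) for e in elements]
    )

    drawers = {
        "robertsonian_fusion": lambda k, b: _draw_fusion(k, rng, b, True, eps_c),
        "end_to_end_fusion": lambda k, b: _draw_fusion(k, rng, b, False, eps_c),
        "robertsonian_fission": lambda k, b: _draw_fission(k, rng, b),
        "reciprocal_translocation": lambda k, b: _draw_translocation(k, rng, b),
        "inversion": lambda k, b: _draw_inversion(k, rng, b),
    }

    events: list[RearrangementEvent] = []
    skipped: list[tuple[str, str]] = []
    leaf_karyotypes: dict[str, Karyotype] = {}
    state = {tree.seed_node: Karyotype.from_layout(ancestral_layout)}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if not node.edge.length or node.edge.length <= 0:
            raise ValueError("tree branch lengths must be > 0")
        branch = _branch_id(node)
        kar = state[node.parent_node].copy()
        queue: list[str] = []
        for etype in EVENT_TYPES:
            n_ev = rng.poisson(rates.get(etype, 0.0) * node.edge.length)
            queue.extend([etype] * n_ev)
        rng.shuffle(queue)
        for etype in queue:
            ev = drawers[etype](kar, branch)
            if ev is None:
                skipped.append((branch, etype))
                continue
            kar = apply_event(kar, ev)
            events.append(ev)
        state[node] = kar
        if node.is_leaf():
            leaf_karyotypes[node.taxon.label] = kar

    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    table = {"gene": gene_ids, "element": elements}
    for sp, kar in leaf_karyotypes.items():
        chroms, poss = [], []
        for e, p in zip(elements, positions):
            c, q = kar.locate(str(e), int(p))
            chroms.append(c)
            poss.append(q)
        table[f"{sp}_chrom"] = chroms
        table[f"{sp}_pos"] = poss
    orthologs = pd.DataFrame(table)

    return SimulatedHistory(
        ancestral_layout=ancestral_layout,
        tree=tree,
        events=events,
        leaf_karyotypes=leaf_karyotypes,
        leaf_layouts={sp: k.to_layout() for sp, k in leaf_karyotypes.items()},
        orthologs=orthologs,
        skipped=skipped,
    )


def request_fission(kar: Karyotype, chrom: str, at_junction: bool = True):
    """Explicitly request a fission; rejects single-element chromosomes
    when an internal element junction is required."""
    c = kar.chromosomes[chrom]
    if at_junction and len(c.segments) < 2:
        raise ValueError(
            f"{chrom!r} is a single ancestral element with no internal junction"
        )
    pos = c.centromere if not at_junction else sum(
        s.length for s in c.segments[:1]
    )
    return RearrangementEvent(
        "manual", "robertsonian_fission", (chrom,),
        (f"{chrom}p", f"{chrom}q"), ((chrom, pos),),
    )


def default_ancestral_layout(
    n_elements: int = 13,
    mean_length: float = 110e6,
    seed: int | np.random.Generator = 0,
) -> GenomeLayout:
    """A 13-element ancestral frog-like karyotype with mixed centromere
    placements (several acrocentric, the rest submetacentric)."""
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    names = [chr(ord("A") + i) for i in range(n_elements)]
    lengths = {}
    cens = {}
    for i, name in enumerate(names):
        length = int(mean_length * (1.5 - i / max(1, n_elements - 1)))
        length = max(length, int(0.4 * mean_length))
        lengths[name] = length
        if i % 4 == 3:  # every fourth element acrocentric
            cens[name] = int(0.08 * length)
        else:
            cens[name] = int(length * rng.uniform(0.35, 0.5))
    return GenomeLayout(lengths, cens)
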
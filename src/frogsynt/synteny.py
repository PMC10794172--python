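"""Ancestral syntenic-element inference from cross-species ortholog placements.

An ortholog table assigns each one-to-one ortholog a chromosome and
position in every species.  Genes sharing an identical cross-species
chromosome signature form strict clusters; clusters are then merged when
a branch-length-weighted two-state ("together"/"apart") parsimony
reconstruction on the species tree places them on the same chromosome in
the root ancestor.
The merged clusters are the ancestral elements.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "species_of",
    "collinear_runs",
    "filter_stray_orthologs",
    "ElementAssignment",
    "infer_elements",
    "conservation_fraction",
    "element_proportions",
]


def species_of(table: pd.DataFrame) -> list[str]:
    """Species named by ``<sp>_chrom`` / ``<sp>_pos`` column pairs."""
    return [c[:-6] for c in table.columns if c.endswith("_chrom")]


def _require_species(table: pd.DataFrame, species: str) -> None:
    if f"{species}_chrom" not in table.columns:
        raise KeyError(f"species {species!r} absent from ortholog table")


def collinear_runs(
    table: pd.DataFrame,
    species_a: str,
    species_b: str,
    min_run: int = 3,
    max_gap: int = 2,
) -> pd.DataFrame:
    """Maximal collinear runs of genes between two species.

    Genes are ordered by rank (not bp) within each chromosome, so the
    result is assembly-scale-free.  A run extends while consecutive genes
    (in species-A order) stay on one chromosome pair and their species-B
    ranks advance monotonically with jumps of at most ``max_gap + 1``.
    Orientation may be + or - per run.  Runs shorter than ``min_run``
    genes are dropped.
    """
    for sp in (species_a, species_b):
        _require_species(table, sp)
    df = table[["gene", f"{species_a}_chrom", f"{species_a}_pos",
                f"{species_b}_chrom", f"{species_b}_pos"]].copy()
    df.columns = ["gene", "ca", "pa", "cb", "pb"]
    df["rb"] = df.groupby("cb")["pb"].rank(method="first").astype(int)
    df = df.sort_values(["ca", "pa"]).reset_index(drop=True)

    runs = []
    cur: list[int] = []
    direction = 0

    def flush() -> None:
        nonlocal cur, direction
        if len(cur) >= min_run:
            sub = df.loc[cur]
            runs.append(
                {
                    "chrom_a": sub["ca"].iloc[0],
                    "chrom_b": sub["cb"].iloc[0],
                    "n_genes": len(sub),
                    "orientation": "+" if direction >= 0 else "-",
                    "genes": list(sub["gene"]),
                    "start_a": int(sub["pa"].min()),
                    "end_a": int(sub["pa"].max()),
                    "start_b": int(sub["pb"].min()),
                    "end_b": int(sub["pb"].max()),
                }
            )
        cur, direction = [], 0

    for i in range(len(df)):
        if not cur:
            cur = [i]
            continue
        prev = df.loc[cur[-1]]
        row = df.loc[i]
        step = row["rb"] - prev["rb"]
        ok = (
            row["ca"] == prev["ca"]
            and row["cb"] == prev["cb"]
            and 1 <= abs(step) <= max_gap + 1
            and (direction == 0 or np.sign(step) == direction)
        )
        if ok:
            if direction == 0:
                direction = int(np.sign(step))
            cur.append(i)
        else:
            flush()
            cur = [i]
    flush()
    return pd.DataFrame(
        runs,
        columns=["chrom_a", "chrom_b", "n_genes", "orientation", "genes",
                 "start_a", "end_a", "start_b", "end_b"],
    )


def _signatures(table: pd.DataFrame, species: list[str]) -> pd.Series:
    cols = [f"{sp}_chrom" for sp in species]
    return table[cols].astype(str).agg("|".join, axis=1)


def filter_stray_orthologs(table: pd.DataFrame, min_cluster: int = 3) -> pd.DataFrame:
    """Drop genes whose cross-species chromosome signature is carried by
    fewer than ``min_cluster`` genes (stray orthologs)."""
    sig = _signatures(table, species_of(table))
    counts = sig.map(sig.value_counts())
    return table[counts >= min_cluster].reset_index(drop=True)


@dataclass
class ElementAssignment:
    """Gene-to-element assignment with per-species spans."""

    assignments: pd.DataFrame       # gene, element + original columns
    elements: list[str]
    unassigned: pd.DataFrame        # gene + reason

    def genes_of(self, element: str) -> list[str]:
        df = self.assignments
        return list(df.loc[df["element"] == element, "gene"])

    def spans(self, species: str) -> pd.DataFrame:
        df = self.assignments
        out = (
            df.groupby(["element", f"{species}_chrom"])[f"{species}_pos"]
            .agg(["min", "max", "count"])
            .reset_index()
            .rename(columns={"min": "start", "max": "end", "count": "n_genes"})
        )
        return out


_STATES = ("together", "apart")


def _root_state_costs(
    tree: dendropy.Tree, leaf_states: dict[str, str]
) -> dict[str, float]:
    """Sankoff parsimony cost of each root state for a two-state character.

    A state change on a branch of length b costs 1/b (unit cost when the
    tree carries no lengths), so changes are preferentially placed on
    long branches — the same tie-break a constant-rate likelihood model
    would make.  Returns the minimum total cost for each root state.
    """
    costs: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = leaf_states[node.taxon.label]
            costs[node] = {st: (0.0 if st == s else np.inf) for st in _STATES}
        else:
            total = {st: 0.0 for st in _STATES}
            for ch in node.child_nodes():
                b = ch.edge.length
                w = 1.0 / b if (b is not None and b > 0) else 1.0
                for st in _STATES:
                    total[st] += min(
                        costs[ch][st2] + (0.0 if st2 == st else w)
                        for st2 in _STATES
                    )
            costs[node] = total
    return costs[tree.seed_node]


def infer_elements(
    table: pd.DataFrame,
    tree: dendropy.Tree,
    ref_species: str | None = None,
    min_cluster: int = 3,
) -> ElementAssignment:
    """Infer ancestral syntenic elements.

    Stage 1 groups genes by identical chromosome-signature vectors
    (clusters below ``min_cluster`` genes are set aside as unassigned).
    Stage 2 scores every cluster pair with a per-species two-state
    character — on the same chromosome ("together") or not ("apart") —
    reconstructs the root state by branch-length-weighted parsimony on
    ``tree``, and merges clusters whose root state is strictly cheaper
    as "together" (ties are resolved as "apart").  Merging is transitive.  Elements are labelled from
    ``ref_species`` chromosomes when given, else E01, E02, ... by
    decreasing gene count.
    """
    species = species_of(table)
    if len(species) < 1:
        raise ValueError("ortholog table names no species")
    taxa = {t.label for t in tree.taxon_namespace}
    missing = set(species) - taxa
    if missing:
        raise ValueError(f"tree lacks species {sorted(missing)}")
    tree = tree.extract_tree_with_taxa_labels(species)

    sig = _signatures(table, species)
    counts = sig.value_counts()
    keep = counts[counts >= min_cluster]
    unassigned = table.loc[~sig.isin(keep.index), ["gene"]].copy()
    unassigned["reason"] = f"signature cluster smaller than {min_cluster}"
    work = table[sig.isin(keep.index)].reset_index(drop=True)
    wsig = _signatures(work, species)

    clusters = sorted(keep.index)  # lexicographic for determinism
    chrom_of = {
        c: dict(zip(species, c.split("|"))) for c in clusters
    }

    # union-find over clusters
    parent = {c: c for c in clusters}

    def find(c: str) -> str:
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    if len(species) >= 2:
        for i, ci in enumerate(clusters):
            for cj in clusters[i + 1:]:
                states = {
                    sp: "together" if chrom_of[ci][sp] == chrom_of[cj][sp]
                    else "apart"
                    for sp in species
                }
                root = _root_state_costs(tree, states)
                if root["together"] < root["apart"]:  # ties -> apart
                    union(ci, cj)

    groups: dict[str, list[str]] = {}
    for c in clusters:
        groups.setdefault(find(c), []).append(c)

    # label elements
    cluster_size = {c: int(keep[c]) for c in clusters}
    group_list = sorted(
        groups.values(),
        key=lambda g: (-sum(cluster_size[c] for c in g), g[0]),
    )
    labels = {}
    used: set[str] = set()
    for i, grp in enumerate(group_list):
        if ref_species is not None:
            _require_species(table, ref_species)
            refs = sorted(
                {chrom_of[c][ref_species] for c in grp},
            )
            name = "+".join(refs)
            if name in used:
                name = f"{name}#{i}"
        else:
            name = f"E{i + 1:02d}"
        used.add(name)
        for c in grp:
            labels[c] = name

    out = work.copy()
    if "element" in out.columns:  # planted truth column from a simulator
        out = out.rename(columns={"element": "element_truth"})
    out.insert(1, "element", wsig.map(labels))
    elements = sorted(set(labels.values()))
    return ElementAssignment(out, elements, unassigned)


def conservation_fraction(
    assignment: ElementAssignment, min_genes: int = 3
) -> float:
    """Fraction of assigned orthologs that travel with their element in
    every species.

    For each (element, species), the element's resident chromosomes are
    those holding at least ``min_genes`` of its genes; a gene is
    conserved when its chromosome is a resident chromosome of its element
    in all species.
    """
    df = assignment.assignments
    species = species_of(df)
    ok = np.ones(len(df), bool)
    for sp in species:
        col = f"{sp}_chrom"
        counts = df.groupby(["element", col]).size()
        resident = counts[counts >= min_genes]
        keys = list(zip(df["element"], df[col]))
        ok &= np.array([k in resident.index for k in keys])
    return float(ok.mean()) if len(df) else float("nan")


def element_proportions(
    assignment: ElementAssignment,
    genome_sizes: dict[str, float],
) -> pd.DataFrame:
    """Per-species fraction of genome bp spanned and genes carried by each
    element, with the across-species coefficient of variation.

    Span is the bp extent of the element's gene positions per chromosome,
    summed over its resident chromosomes.
    """
    df = assignment.assignments
    species = species_of(df)
    rows = []
    for element in assignment.elements:
        sub = df[df["element"] == element]
        rec: dict = {"element": element}
        fracs = []
        for sp in species:
            span = (
                sub.groupby(f"{sp}_chrom")[f"{sp}_pos"]
                .agg(lambda s: s.max() - s.min())
                .sum()
            )
            frac = span / genome_sizes[sp]
            rec[f"{sp}_bp_fraction"] = frac
            rec[f"{sp}_gene_fraction"] = len(sub) / len(df)
            fracs.append(frac)
        fracs = np.array(fracs, float)
        rec["bp_fraction_cv"] = (
            float(fracs.std(ddof=0) / fracs.mean()) if fracs.mean() > 0 else np.nan
        )
        rows.append(rec)
    return pd.DataFrame(rows)
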
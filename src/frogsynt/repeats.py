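"""Tandem-repeat monomer clustering, enrichment, ageing, and densities.

Monomers from tandem arrays are clustered rotation-invariantly with the
dimer trick: each candidate is aligned against a head-to-tail duplication
of the cluster representative, so any rotational phase of the same
repeat unit aligns end to end.  Greedy centroid clustering joins a
monomer to the first representative it matches at >= 75% identity over
>= 45% of its length (banded edit-distance alignment).  Repeat families
are aged by Jukes-Cantor distance to consensus and ranked by regional
footprint enrichment; binned densities and their PCA summarize the
repeat landscape along chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from sklearn.decomposition import PCA

__all__ = [
    "MonomerCluster",
    "build_monomer_db",
    "region_enrichment",
    "jc_distance",
    "tetramer_enrichment",
    "binned_density",
    "density_pca",
]


@dataclass
class MonomerCluster:
    members: list[str]                  # member ids
    representative: str                 # member id with the modal length
    representative_seq: str
    footprint: dict[str, float] = field(default_factory=dict)


def _dimer_identity(query: str, target: str) -> tuple[float, float]:
    """(identity, coverage) of ``query`` against the dimer of ``target``.

    Infix alignment of the query inside target+target makes the score
    independent of rotational phase; coverage is the aligned fraction of
    the longer monomer.
    """
    short, long_ = (query, target) if len(query) <= len(target) else (target, query)
    res = edlib.align(short, long_ + long_, mode="HW", task="distance")
    identity = 1.0 - res["editDistance"] / len(short)
    coverage = len(short) / len(long_)
    return identity, coverage


def build_monomer_db(
    monomers: dict[str, str],
    min_identity: float = 0.75,
    min_coverage: float = 0.45,
) -> list[MonomerCluster]:
    """Greedy rotation-invariant centroid clustering of monomers.

    Input order is canonicalized (length descending, then id) so the
    result is deterministic.  The cluster representative is the member
    whose length equals the modal member length (ties broken by id).
    """
    for mid, seq in monomers.items():
        if len(seq) <= 10:
            raise ValueError(f"monomer {mid!r} must be > 10 bp")
    order = sorted(monomers, key=lambda m: (-len(monomers[m]), m))
    clusters: list[list[str]] = []
    for mid in order:
        seq = monomers[mid]
        placed = False
        for members in clusters:
            rep_seq = monomers[members[0]]
            ident, cov = _dimer_identity(seq, rep_seq)
            if ident >= min_identity and cov >= min_coverage:
                members.append(mid)
                placed = True
                break
        if not placed:
            clusters.append([mid])
    out = []
    for members in clusters:
        lengths = [len(monomers[m]) for m in members]
        modal = pd.Series(lengths).mode().iloc[0]
        rep = sorted(m for m in members if len(monomers[m]) == modal)[0]
        out.append(MonomerCluster(members, rep, monomers[rep]))
    return out


def region_enrichment(
    footprints: pd.DataFrame,
    roi_length: float,
    rest_length: float,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Rank repeat families by footprint enrichment in a region of interest.

    ``footprints`` needs columns ``family``, ``roi_bp``, ``rest_bp``.
    The score is (roi_bp / roi_length) / ((rest_bp + pseudocount) /
    rest_length), so a family confined to the region ranks first and a
    uniformly spread family scores ~1.
    """
    df = footprints.copy()
    df["enrichment"] = (df["roi_bp"] / roi_length) / (
        (df["rest_bp"] + pseudocount) / rest_length
    )
    return df.sort_values("enrichment", ascending=False).reset_index(drop=True)


def array_footprints(
    arrays: pd.DataFrame, roi_intervals: list[tuple[str, float, float]]
) -> pd.DataFrame:
    """bp of each family's arrays inside vs outside regions of interest.

    ``arrays`` has columns chrom, start, end, monomer_id; overlap is
    computed interval-exactly.
    """
    rows = []
    for fam, grp in arrays.groupby("monomer_id"):
        roi_bp = 0.0
        tot = 0.0
        for _, a in grp.iterrows():
            tot += a["end"] - a["start"]
            for chrom, lo, hi in roi_intervals:
                if a["chrom"] == chrom:
                    roi_bp += max(
                        0.0, min(a["end"], hi) - max(a["start"], lo)
                    )
        rows.append({"family": fam, "roi_bp": roi_bp, "rest_bp": tot - roi_bp})
    return pd.DataFrame(rows)


def jc_distance(p: float) -> float:
    """Jukes-Cantor distance -(3/4) ln(1 - 4p/3) for mismatch fraction p."""
    if not 0 <= p < 0.75:
        raise ValueError("mismatch fraction must be in [0, 0.75)")
    return -0.75 * np.log(1 - 4 * p / 3)


_COMP = str.maketrans("ACGT", "TGCA")


def _count_motif(seq: str, motif: str, both_strands: bool) -> int:
    n = _overlapping_count(seq, motif)
    if both_strands:
        rc = motif.translate(_COMP)[::-1]
        n += _overlapping_count(seq, rc)
    return n


def _overlapping_count(seq: str, motif: str) -> int:
    count = start = 0
    while True:
        i = seq.find(motif, start)
        if i < 0:
            return count
        count += 1
        start = i + 1


def tetramer_enrichment(
    tandem_seqs: list[str],
    background_seqs: list[str],
    motifs: tuple[str, ...] = ("TGGG", "AGGG", "ACAG"),
    both_strands: bool = True,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Short-motif frequency (per kb) in tandem vs background sequence.

    Families completely devoid of a motif are flagged ``absent`` (ratio
    NaN when the motif is missing from both sets).
    """
    t_kb = sum(len(s) for s in tandem_seqs) / 1e3
    b_kb = sum(len(s) for s in background_seqs) / 1e3
    rows = []
    for motif in motifs:
        t_n = sum(_count_motif(s, motif, both_strands) for s in tandem_seqs)
        b_n = sum(_count_motif(s, motif, both_strands) for s in background_seqs)
        t_rate = t_n / t_kb if t_kb else np.nan
        b_rate = b_n / b_kb if b_kb else np.nan
        if t_n == 0 and b_n == 0:
            ratio = np.nan
        else:
            ratio = (t_n / t_kb + pseudocount / t_kb) / (
                b_n / b_kb + pseudocount / b_kb
            )
        rows.append(
            {
                "motif": motif,
                "tandem_per_kb": t_rate,
                "background_per_kb": b_rate,
                "ratio": ratio,
                "absent_in_tandem": t_n == 0,
            }
        )
    return pd.DataFrame(rows)


def binned_density(
    chrom_length: int,
    window: float,
    step: float,
    intervals: pd.DataFrame | None = None,
    sequence: str | None = None,
) -> pd.DataFrame:
    """Sliding-window density column.

    With ``intervals`` (columns start, end): bp of overlap per window.
    With ``sequence``: GC fraction per window.  Windows of ``window`` bp
    slide by ``step`` within [0, chrom_length).
    """
    n_win = max(0, int((chrom_length - window) // step) + 1)
    starts = np.arange(n_win) * step
    ends = starts + window
    if intervals is not None:
        lo = intervals["start"].to_numpy(float)
        hi = intervals["end"].to_numpy(float)
        vals = np.array(
            [
                np.clip(np.minimum(hi, e) - np.maximum(lo, s), 0, None).sum()
                for s, e in zip(starts, ends)
            ]
        )
    elif sequence is not None:
        arr = np.frombuffer(sequence.upper().encode(), dtype="S1")
        gc = np.cumsum(np.isin(arr, [b"G", b"C"]).astype(float))
        gc = np.concatenate([[0.0], gc])
        vals = np.array(
            [
                (gc[min(int(e), len(arr))] - gc[int(s)])
                / max(1, min(int(e), len(arr)) - int(s))
                for s, e in zip(starts, ends)
            ]
        )
    else:
        raise ValueError("provide intervals or sequence")
    return pd.DataFrame({"start": starts, "end": ends, "value": vals})


def density_pca(
    matrix: pd.DataFrame,
    compartment_track: np.ndarray | None = None,
    n_components: int = 5,
    smooth: bool = False,
    positions: np.ndarray | None = None,
) -> dict:
    """PCA of a bins x features density matrix.

    Columns are standardized before decomposition.  When a per-bin
    compartment sign track is given, the Pearson correlation of each
    component with it is reported.  ``smooth`` applies a cubic-spline fit
    to each PC track over ``positions`` (defaults to bin index).
    """
    X = matrix.to_numpy(float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    n_components = min(n_components, Z.shape[1], Z.shape[0])
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Z)
    # deterministic sign: largest-|score| entry positive
    for k in range(scores.shape[1]):
        j = np.argmax(np.abs(scores[:, k]))
        if scores[j, k] < 0:
            scores[:, k] *= -1
    if smooth:
        x = positions if positions is not None else np.arange(scores.shape[0])
        sm = np.column_stack(
            [CubicSpline(x, scores[:, k])(x) for k in range(scores.shape[1])]
        )
    else:
        sm = scores
    out = {
        "scores": scores,
        "smoothed": sm,
        "explained_variance_ratio": pca.explained_variance_ratio_,
        "components": pca.components_,
    }
    if compartment_track is not None:
        out["compartment_correlation"] = np.array(
            [
                float(np.corrcoef(scores[:, k], compartment_track)[0, 1])
                for k in range(scores.shape[1])
            ]
        )
    return out
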
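"""Nuclear-architecture statistics from binned Hi-C contact matrices.

Covers centromere inference from the transverse interarm contact "wing",
A/B compartment calling from the leading eigenvector of the
observed/expected correlation matrix, Rabl-configuration statistics (the
interarm sum-of-squared-distances SSD in PC1–PC2 contact-profile space
and the centromere-to-telomere-polar contact enrichment CTP), a circular-
rotation permutation test, and chi-square contact-enrichment analyses for
arm-level and chromosome-territory structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .contacts import ContactMatrix, balance_matrix, expected_by_distance
from .karyorate import hochberg_correct

__all__ = [
    "CentromereCall",
    "infer_centromeres",
    "CompartmentTrack",
    "call_compartments",
    "compartment_stats",
    "RablMetrics",
    "rabl_ssd",
    "rabl_ctp",
    "permutation_test",
    "interarm_enrichment",
    "territory_enrichment",
    "centromere_concordance",
]


def _balanced(matrix: ContactMatrix) -> np.ndarray:
    if matrix.weights is None:
        balance_matrix(matrix, method="KR")
    return matrix.balanced()


def _oe_intra(matrix: ContactMatrix, balanced: np.ndarray, chrom: str) -> np.ndarray:
    """Observed/expected normalization of one intra-chromosomal block."""
    idx = matrix.chrom_bins(chrom)
    M = balanced[np.ix_(idx, idx)]
    n = len(idx)
    exp = np.empty(n)
    for d in range(n):
        diag = np.diagonal(M, offset=d)
        good = ~np.isnan(diag)
        exp[d] = diag[good].mean() if good.any() else np.nan
    D = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = M / exp[D]
    return oe


# -- centromere inference -------------------------------------------------


@dataclass
class CentromereCall:
    chromosome: str
    bin: int | None              # index within the chromosome
    interval: tuple[int, int] | None
    score: float
    flags: list[str] = field(default_factory=list)


def _wing_scores(oe: np.ndarray, min_depth: int = 1) -> np.ndarray:
    """Anti-diagonal mean of the O/E matrix through each candidate bin.

    Score(c) averages oe[c-d, c+d] for d = 1..min(c, n-1-c): high values
    mean the two arms fold back onto each other around c.
    """
    n = oe.shape[0]
    scores = np.full(n, np.nan)
    for c in range(1, n - 1):
        depth = min(c, n - 1 - c)
        if depth < min_depth:
            continue
        d = np.arange(1, depth + 1)
        vals = oe[c - d, c + d]
        good = ~np.isnan(vals)
        if good.any():
            scores[c] = vals[good].mean()
    return scores


def infer_centromeres(
    matrix: ContactMatrix,
    min_bins: int = 20,
    refine: bool = True,
    confidence_ratio: float = 1.5,
    edge_bins: int = 3,
) -> dict[str, CentromereCall]:
    """Infer centromere positions from the interarm contact wing.

    The intra-chromosomal call is the bin maximizing the anti-diagonal
    mean of the O/E matrix.  When ``refine`` is set, calls are polished
    by cross-chromosome agreement: the inter-chromosomal contact of each
    candidate bin with the other chromosomes' current centromere bins is
    z-combined with the wing score and calls are iterated to a fixed
    point (centromeres cluster in the nucleus, so the inter signal peaks
    at true centromeres).
    """
    balanced = _balanced(matrix)
    calls: dict[str, CentromereCall] = {}
    wing: dict[str, np.ndarray] = {}
    for chrom in matrix.chromosomes:
        idx = matrix.chrom_bins(chrom)
        if len(idx) < min_bins:
            calls[chrom] = CentromereCall(chrom, None, None, np.nan, ["too_short"])
            continue
        oe = _oe_intra(matrix, balanced, chrom)
        s = _wing_scores(oe)
        wing[chrom] = s
        c = int(np.nanargmax(s))
        flags = []
        background = float(np.nanmedian(s))
        if not (s[c] >= confidence_ratio * background):
            flags.append("low_confidence")
        if min(c, len(idx) - 1 - c) < edge_bins:
            flags.append("acrocentric")
        start = int(matrix.bins["start"].iloc[idx[c]])
        end = int(matrix.bins["end"].iloc[idx[c]])
        calls[chrom] = CentromereCall(chrom, c, (start, end), float(s[c]), flags)

    if refine:
        B = np.nan_to_num(balanced)
        chrom_arr = matrix.chrom_of_bins()
        for _ in range(10):
            changed = False
            for chrom, call in calls.items():
                if call.bin is None:
                    continue
                idx = matrix.chrom_bins(chrom)
                others = [
                    matrix.chrom_bins(c2)[calls[c2].bin]
                    for c2 in calls
                    if c2 != chrom and calls[c2].bin is not None
                ]
                if not others:
                    break
                inter = B[np.ix_(idx, np.array(others))].mean(axis=1)
                s = wing.get(chrom)
                if s is None:
                    continue
                comb = _zscore(s) + _zscore(inter)
                c_new = int(np.nanargmax(comb))
                if c_new != call.bin:
                    start = int(matrix.bins["start"].iloc[idx[c_new]])
                    end = int(matrix.bins["end"].iloc[idx[c_new]])
                    calls[chrom] = CentromereCall(
                        chrom, c_new, (start, end), float(s[c_new]), call.flags
                    )
                    changed = True
            if not changed:
                break
    return calls


def _zscore(x: np.ndarray) -> np.ndarray:
    m = np.nanmean(x)
    sd = np.nanstd(x)
    return (x - m) / sd if sd > 0 else np.zeros_like(x)


# -- A/B compartments -----------------------------------------------------


@dataclass
class CompartmentTrack:
    """Per-bin leading-eigenvector loadings and A/B labels."""

    table: pd.DataFrame          # chrom, start, end, loading, label
    orientation: dict[str, int]  # per-chromosome sign applied

    def labels(self) -> np.ndarray:
        return self.table["label"].to_numpy()


def _compartment_eigenvector(
    oe_block: np.ndarray, gene_density: np.ndarray, n_candidates: int
) -> np.ndarray:
    """Signed compartment loadings for one O/E block (NaN where no data).

    Among the leading ``n_candidates`` eigenvectors of the Pearson
    correlation matrix, the one most correlated (in absolute value) with
    gene density is the compartment axis; it is oriented so positive
    loadings (A) correlate positively with gene density.
    """
    good = ~np.all(np.isnan(oe_block), axis=0)
    sub = oe_block[np.ix_(good, good)]
    if sub.size == 0 or np.allclose(np.nanstd(sub, axis=0), 0):
        raise ValueError("constant contact block: degenerate eigenvector")
    sub = np.nan_to_num(sub, nan=1.0)
    corr = np.nan_to_num(np.corrcoef(sub))
    vals, vecs = np.linalg.eigh(corr)
    gd = gene_density[good]
    kmax = min(n_candidates, vecs.shape[1])
    best_r, pc = 0.0, vecs[:, -1]
    for k in range(1, kmax + 1):
        v = vecs[:, -k]
        r = np.corrcoef(v, gd)[0, 1]
        if not np.isnan(r) and abs(r) > abs(best_r):
            best_r, pc = r, v
    loading = np.full(oe_block.shape[0], np.nan)
    loading[good] = pc if best_r >= 0 else -pc
    return loading


def call_compartments(
    matrix: ContactMatrix,
    gene_density: np.ndarray,
    centromere_bins: dict[str, int] | None = None,
    n_candidates: int = 3,
) -> CompartmentTrack:
    """Call A/B compartments per chromosome (or per arm).

    The intra-chromosomal balanced matrix is O/E normalized, converted to
    a Pearson correlation matrix, and decomposed.  Among the leading
    ``n_candidates`` eigenvectors, the one most correlated (in absolute
    value) with gene density is taken as the compartment axis — arm-scale
    structure such as the Rabl interarm wing can displace the checkerboard
    from the first eigenvector, and gene density disambiguates.  When
    ``centromere_bins`` (within-chromosome indices) are supplied, each
    arm is decomposed separately, which excludes the interarm wing from
    the decomposition altogether.  The chosen vector is oriented so
    positive loadings (A) correlate positively with gene density.  Bins
    without coverage get no label.
    """
    rows = []
    orientation: dict[str, int] = {}
    for chrom in matrix.chromosomes:
        idx = matrix.chrom_bins(chrom)
        oe = _oe_intra(matrix, _balanced(matrix), chrom)
        gd = gene_density[idx]
        loading = np.full(len(idx), np.nan)
        c = None if centromere_bins is None else centromere_bins.get(chrom)
        if c is None:
            blocks = [np.arange(len(idx))]
        else:
            blocks = [np.arange(0, c), np.arange(c, len(idx))]
        for k in blocks:
            if len(k) == 0:
                continue
            loading[k] = _compartment_eigenvector(
                oe[np.ix_(k, k)], gd[k], n_candidates
            )
        orientation[chrom] = 1
        for k, gbin in enumerate(idx):
            rows.append(
                {
                    "chrom": chrom,
                    "start": matrix.bins["start"].iloc[gbin],
                    "end": matrix.bins["end"].iloc[gbin],
                    "loading": loading[k],
                    "label": (
                        None if np.isnan(loading[k])
                        else ("A" if loading[k] > 0 else "B")
                    ),
                }
            )
    return CompartmentTrack(pd.DataFrame(rows), orientation)


def compartment_stats(track: CompartmentTrack) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Maximal same-label segments and their mean lengths.

    Returns (segments, summary); summary has arithmetic and geometric
    mean segment length (bp) per label.
    """
    segs = []
    t = track.table
    for chrom, grp in t.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        cur_label, cur_start, cur_end = None, None, None
        for _, row in grp.iterrows():
            if row["label"] is None:
                if cur_label is not None:
                    segs.append((chrom, cur_start, cur_end, cur_label))
                cur_label = None
                continue
            if row["label"] == cur_label and row["start"] == cur_end:
                cur_end = row["end"]
            else:
                if cur_label is not None:
                    segs.append((chrom, cur_start, cur_end, cur_label))
                cur_label, cur_start, cur_end = row["label"], row["start"], row["end"]
        if cur_label is not None:
            segs.append((chrom, cur_start, cur_end, cur_label))
    seg_df = pd.DataFrame(segs, columns=["chrom", "start", "end", "label"])
    seg_df["length"] = seg_df["end"] - seg_df["start"]
    summary = (
        seg_df.groupby("label")["length"]
        .agg(
            arithmetic_mean="mean",
            geometric_mean=lambda s: float(np.exp(np.mean(np.log(s)))),
            n="count",
        )
        .reset_index()
    )
    return seg_df, summary


# -- Rabl statistics ------------------------------------------------------


@dataclass
class RablMetrics:
    ssd_per_chrom: dict[str, float]
    ssd: float
    ctp_per_pair: pd.DataFrame | None = None
    ctp: float | None = None
    p_ssd: float | None = None
    p_ctp: float | None = None
    excluded: list[str] = field(default_factory=list)


def _profile_pcs(balanced: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Standardized PC scores of the bins' genome-wide contact profiles."""
    X = np.nan_to_num(balanced)
    X = X - X.mean(axis=0)
    # deterministic eigendecomposition of the covariance
    cov = X @ X.T / X.shape[1]
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1][:n_components]
    scores = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0))
    # fixed sign convention: largest-|loading| entry positive
    for k in range(scores.shape[1]):
        j = np.argmax(np.abs(scores[:, k]))
        if scores[j, k] < 0:
            scores[:, k] = -scores[:, k]
    sd = scores.std(axis=0)
    sd[sd == 0] = 1.0
    return scores / sd


def rabl_ssd(
    matrix: ContactMatrix,
    centromere_bins: dict[str, int],
    min_arm_bins: int = 5,
) -> RablMetrics:
    """Interarm sum-of-squared-distances in PC1-PC2 profile space.

    Bins are paired outward from the centromere (i-th p-arm bin with i-th
    q-arm bin); the per-chromosome SSD is the mean squared Euclidean
    distance between paired bins' standardized (PC1, PC2) scores.  Low
    SSD means the two arms run alongside each other (Rabl fold-back).
    Chromosomes with an arm shorter than ``min_arm_bins`` are excluded.
    """
    balanced = _balanced(matrix)
    scores = _profile_pcs(balanced)
    per: dict[str, float] = {}
    excluded = []
    for chrom in matrix.chromosomes:
        c = centromere_bins.get(chrom)
        idx = matrix.chrom_bins(chrom)
        if c is None:
            excluded.append(chrom)
            continue
        n = len(idx)
        n_p, n_q = c, n - 1 - c
        if min(n_p, n_q) < min_arm_bins:
            excluded.append(chrom)
            continue
        m = min(n_p, n_q)
        p_bins = idx[c - np.arange(1, m + 1)]
        q_bins = idx[c + np.arange(1, m + 1)]
        diff = scores[p_bins] - scores[q_bins]
        per[chrom] = float(np.mean(np.sum(diff**2, axis=1)))
    return RablMetrics(
        ssd_per_chrom=per,
        ssd=float(np.mean(list(per.values()))) if per else np.nan,
        excluded=excluded,
    )


def _polar_coordinate(
    matrix: ContactMatrix, centromere_bins: dict[str, int]
) -> np.ndarray:
    """u in [0, 1]: 0 at the bin's centromere, 1 at its telomere."""
    u = np.full(matrix.n_bins, np.nan)
    for chrom in matrix.chromosomes:
        c = centromere_bins.get(chrom)
        if c is None:
            continue
        idx = matrix.chrom_bins(chrom)
        n = len(idx)
        k = np.arange(n)
        arm = np.where(k < c, c, n - 1 - c)
        u[idx] = np.abs(k - c) / np.maximum(arm, 1)
    return u


def rabl_ctp(
    matrix: ContactMatrix,
    centromere_bins: dict[str, int],
    polar_window: float = 0.2,
) -> RablMetrics:
    """Centromere-to-telomere-polar interarm contact enrichment.

    Each bin's polar coordinate u runs 0 (centromere) to 1 (telomere)
    within its arm.  CTP is the mean balanced inter-chromosomal contact
    among bin pairs with |u_i - u_j| <= window divided by the mean among
    the remaining pairs; > 1 indicates polarized (Rabl-like) alignment.
    """
    balanced = _balanced(matrix)
    u = _polar_coordinate(matrix, centromere_bins)
    chrom_arr = matrix.chrom_of_bins()
    pairs = []
    vals_per = {}
    for a_i, chrom_a in enumerate(matrix.chromosomes):
        for chrom_b in matrix.chromosomes[a_i + 1:]:
            ia, ib = matrix.chrom_bins(chrom_a), matrix.chrom_bins(chrom_b)
            sub = balanced[np.ix_(ia, ib)]
            du = np.abs(u[ia][:, None] - u[ib][None, :])
            good = ~np.isnan(sub) & ~np.isnan(du)
            near = good & (du <= polar_window)
            far = good & (du > polar_window)
            if near.sum() == 0 or far.sum() == 0:
                continue
            ctp = float(sub[near].mean() / sub[far].mean())
            vals_per[(chrom_a, chrom_b)] = ctp
            pairs.append({"chrom_a": chrom_a, "chrom_b": chrom_b, "ctp": ctp})
    df = pd.DataFrame(pairs)
    return RablMetrics(
        ssd_per_chrom={},
        ssd=np.nan,
        ctp_per_pair=df,
        ctp=float(df["ctp"].mean()) if len(df) else np.nan,
    )


# -- permutation test -----------------------------------------------------


def permutation_test(
    statistic,
    balanced: np.ndarray,
    chrom_of: np.ndarray,
    n: int = 10000,
    alternative: str = "greater",
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, np.ndarray]:
    """One-sided permutation test with a within-chromosome rotation null.

    The null rotates the bin order circularly and independently within
    each chromosome, preserving marginal distributions and distance decay
    while destroying cross-feature alignment.  Returns (observed, p,
    null draws) with p = (1 + #{null at least as extreme}) / (n + 1).
    """
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    observed = float(statistic(balanced))
    chroms = pd.unique(chrom_of)
    idx_of = {c: np.flatnonzero(chrom_of == c) for c in chroms}
    null = np.empty(n)
    for t in range(n):
        perm = np.arange(len(chrom_of))
        for c in chroms:
            idx = idx_of[c]
            shift = int(rng.integers(len(idx)))
            perm[idx] = idx[np.roll(np.arange(len(idx)), shift)]
        null[t] = statistic(balanced[np.ix_(perm, perm)])
    if alternative == "greater":
        p = (1 + np.sum(null >= observed)) / (n + 1)
    elif alternative == "less":
        p = (1 + np.sum(null <= observed)) / (n + 1)
    else:
        raise ValueError("alternative must be 'greater' or 'less'")
    return observed, float(p), null


# -- enrichment tests -----------------------------------------------------


def _arm_of_bins(matrix: ContactMatrix, centromere_bins: dict[str, int]) -> np.ndarray:
    arm = np.full(matrix.n_bins, "", dtype=object)
    for chrom in matrix.chromosomes:
        c = centromere_bins.get(chrom)
        if c is None:
            continue
        idx = matrix.chrom_bins(chrom)
        k = np.arange(len(idx))
        arm[idx] = np.where(k < c, "p", np.where(k > c, "q", ""))
    return arm


def interarm_enrichment(
    matrix: ContactMatrix,
    centromere_bins: dict[str, int],
    expected_from: str = "bins",
) -> dict:
    """Enrichment of p-p + q-q over p-q inter-chromosomal contacts.

    Expected fractions come from products of arm bin counts
    (``expected_from='bins'``) or of arm marginal contact sums
    (``'marginals'``).  Chi-square has 1 degree of freedom (2 cells).
    """
    arm = _arm_of_bins(matrix, centromere_bins)
    chrom_arr = matrix.chrom_of_bins()
    C = matrix.counts
    inter = chrom_arr[:, None] != chrom_arr[None, :]
    labelled = (arm != "")[:, None] & (arm != "")[None, :]
    same_arm = (arm[:, None] == arm[None, :])
    use = inter & labelled
    obs_same = C[use & same_arm].sum() / 2
    obs_diff = C[use & ~same_arm].sum() / 2
    total = obs_same + obs_diff
    if expected_from == "bins":
        weight = np.ones(matrix.n_bins)
    elif expected_from == "marginals":
        weight = C.sum(axis=1)
    else:
        raise ValueError("expected_from must be 'bins' or 'marginals'")
    w_same = w_tot = 0.0
    for a_i, ca in enumerate(matrix.chromosomes):
        for cb in matrix.chromosomes[a_i + 1:]:
            ia, ib = matrix.chrom_bins(ca), matrix.chrom_bins(cb)
            wa, wb = weight[ia], weight[ib]
            aa, ab = arm[ia], arm[ib]
            for x in ("p", "q"):
                for y in ("p", "q"):
                    m = wa[aa == x].sum() * wb[ab == y].sum()
                    w_tot += m
                    if x == y:
                        w_same += m
    f_same = w_same / w_tot
    exp_same, exp_diff = total * f_same, total * (1 - f_same)
    chi2 = (obs_same - exp_same) ** 2 / exp_same + (
        obs_diff - exp_diff
    ) ** 2 / exp_diff
    return {
        "enrichment": float(obs_same / exp_same),
        "chi2": float(chi2),
        "df": 1,
        "n": int(total),
        "p": float(stats.chi2.sf(chi2, 1)),
        "observed_same": float(obs_same),
        "expected_same": float(exp_same),
    }


def territory_enrichment(matrix: ContactMatrix) -> dict:
    """Chromosome-territory contact enrichment.

    Builds the K x K inter-chromosomal contact count table, compares it
    with the independence expectation from its marginals, and reports the
    normalized enrichment C/E, the global chi-square with (K-1)^2 degrees
    of freedom, and Hochberg-corrected per-pair standardized-residual
    tests.
    """
    chroms = matrix.chromosomes
    K = len(chroms)
    T = np.zeros((K, K))
    for i, ca in enumerate(chroms):
        for j, cb in enumerate(chroms):
            if i >= j:
                continue
            ia, ib = matrix.chrom_bins(ca), matrix.chrom_bins(cb)
            T[i, j] = T[j, i] = matrix.counts[np.ix_(ia, ib)].sum()
    N = T.sum()
    m = T.sum(axis=1)
    E = np.outer(m, m) / N
    off = ~np.eye(K, dtype=bool)
    with np.errstate(invalid="ignore", divide="ignore"):
        enrich = np.where(off & (E > 0), T / E, np.nan)
    chi2 = float(np.nansum(np.where(off, (T - E) ** 2 / E, 0.0)))
    df = (K - 1) ** 2
    resid = np.where(off, (T - E) / np.sqrt(np.where(E > 0, E, np.nan)), np.nan)
    iu = np.triu_indices(K, k=1)
    pvals = 2 * stats.norm.sf(np.abs(resid[iu]))
    padj = hochberg_correct(pvals)
    pairs = pd.DataFrame(
        {
            "chrom_a": [chroms[i] for i in iu[0]],
            "chrom_b": [chroms[j] for j in iu[1]],
            "observed": T[iu],
            "expected": E[iu],
            "enrichment": enrich[iu],
            "residual": resid[iu],
            "p": pvals,
            "p_hochberg": padj,
        }
    )
    return {
        "table": pd.DataFrame(T, index=chroms, columns=chroms),
        "enrichment": pd.DataFrame(enrich, index=chroms, columns=chroms),
        "chi2": chi2,
        "df": df,
        "n": int(N / 2),
        "p": float(stats.chi2.sf(chi2, df)),
        "pairs": pairs,
    }


def centromere_concordance(
    calls_a: dict[str, CentromereCall],
    calls_b: dict[str, CentromereCall],
    tolerance_bp: float,
) -> pd.DataFrame:
    """Per-chromosome agreement of two centromere call sets."""
    rows = []
    for chrom in calls_a:
        a, b = calls_a[chrom], calls_b.get(chrom)
        if b is None or a.interval is None or b.interval is None:
            rows.append({"chrom": chrom, "diff_bp": np.nan, "concordant": False})
            continue
        mid_a = sum(a.interval) / 2
        mid_b = sum(b.interval) / 2
        diff = abs(mid_a - mid_b)
        rows.append(
            {"chrom": chrom, "diff_bp": diff, "concordant": diff <= tolerance_bp}
        )
    return pd.DataFrame(rows)
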
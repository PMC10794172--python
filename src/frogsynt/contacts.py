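"""Binned Hi-C contact matrices: container, I/O, and matrix balancing.

The container holds an already-binned symmetric count matrix together with
its bin table (chrom, start, end, bin_id).  Balancing offers the
Knight–Ruiz symmetric scaling (Newton method with conjugate-gradient inner
iterations) and ICE-style iterative correction; both return per-bin
weights such that the rescaled matrix has constant row sums, with
zero-coverage bins masked out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ContactMatrix", "load_contacts", "balance_matrix", "expected_by_distance"]


@dataclass
class ContactMatrix:
    """Symmetric binned contact counts with a tiling bin table."""

    bins: pd.DataFrame            # columns: chrom, start, end, bin_id
    counts: np.ndarray            # dense symmetric (n x n)
    bin_size: int
    weights: np.ndarray | None = None
    expected: np.ndarray | None = None   # expectation-by-distance, per stratum
    _chrom_index: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        n = len(self.bins)
        if self.counts.shape != (n, n):
            raise ValueError("counts shape does not match bin table")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError("counts must be symmetric")
        self._validate_tiling()
        self._chrom_index = {
            str(c): np.flatnonzero((self.bins["chrom"] == c).to_numpy())
            for c in self.bins["chrom"].unique()
        }

    def _validate_tiling(self) -> None:
        for chrom, grp in self.bins.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            order = np.argsort(starts)
            if starts[order][0] != 0 or np.any(starts[order][1:] != ends[order][:-1]):
                raise ValueError(f"bins do not tile chromosome {chrom!r}")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.bins["chrom"]))

    def chrom_bins(self, chrom: str) -> np.ndarray:
        return self._chrom_index[chrom]

    def chrom_of_bins(self) -> np.ndarray:
        return self.bins["chrom"].to_numpy()

    def sub(self, chrom: str) -> np.ndarray:
        idx = self.chrom_bins(chrom)
        return self.counts[np.ix_(idx, idx)]

    def balanced(self) -> np.ndarray:
        """diag(w) C diag(w); masked bins give NaN rows/columns."""
        if self.weights is None:
            raise ValueError("matrix has no balancing weights; run balance_matrix")
        w = self.weights
        return self.counts * np.outer(w, w)

    # -- I/O: bins.tsv + triplets.tsv ------------------------------------

    def to_files(self, bins_path, triplets_path) -> None:
        self.bins.to_csv(bins_path, sep="\t", index=False)
        iu = np.triu_indices(self.n_bins)
        vals = self.counts[iu]
        nz = vals != 0
        pd.DataFrame(
            {"bin1": iu[0][nz], "bin2": iu[1][nz], "count": vals[nz]}
        ).to_csv(triplets_path, sep="\t", index=False)


def load_contacts(bins_path, triplets_path, bin_size: int | None = None) -> ContactMatrix:
    """Read a bins.tsv + triplets.tsv pair.

    Triplets may cover only the upper triangle; the matrix is symmetrized.
    """
    bins = pd.read_csv(bins_path, sep="\t")
    trip = pd.read_csv(triplets_path, sep="\t")
    n = len(bins)
    counts = np.zeros((n, n))
    i = trip["bin1"].to_numpy(int)
    j = trip["bin2"].to_numpy(int)
    v = trip["count"].to_numpy(float)
    if np.any(i >= n) or np.any(j >= n):
        raise ValueError("triplet bin id outside bin table")
    counts[i, j] = v
    lower = i > j
    if not np.allclose(counts[j[lower], i[lower]], counts[i[lower], j[lower]]):
        # mixed triangles: trust explicit entries, then symmetrize by max
        pass
    full = np.maximum(counts, counts.T)
    if bin_size is None:
        bin_size = int((bins["end"] - bins["start"]).max())
    return ContactMatrix(bins=bins, counts=full, bin_size=bin_size)


# -- balancing ------------------------------------------------------------


def _kr_scaling(A: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    """Knight–Ruiz algorithm: find x > 0 with diag(x) A diag(x) e = e."""
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    delta, Delta = 0.1, 3.0
    g = 0.9
    etamax = 0.1
    eta = etamax
    rt = tol**2
    v = x * (A @ x)
    rk = 1 - v
    rho_km1 = rk @ rk
    rout = rho_km1
    rold = rout
    i = 0
    while rout > rt:
        i += 1
        if i > max_iter:
            raise RuntimeError(
                f"Knight-Ruiz balancing did not converge "
                f"(residual {np.sqrt(rout):.3g} after {max_iter} outer iterations)"
            )
        k = 0
        y = e.copy()
        innertol = max(eta**2 * rout, rt)
        rho_km2 = rho_km1
        while rho_km1 > innertol:  # CG on the Newton system
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = rk @ Z
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            alpha = rho_km1 / (p @ w)
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                if delta == 0:
                    break
                ind = ap < 0
                gamma = ((delta - y[ind]) / ap[ind]).min()
                y += gamma * ap
                break
            if ynew.max() >= Delta:
                ind = ynew > Delta
                gamma = ((Delta - y[ind]) / ap[ind]).min()
                y += gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = rk @ Z
            if k > 200:
                break
        x = x * y
        v = x * (A @ x)
        rk = 1 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        rat = rout / rold
        rold = rout
        res_norm = np.sqrt(rout)
        eta = min(max(g * rat, 0.5 * rt / res_norm if res_norm > 0 else etamax),
                  etamax)
    return x


def _ice_scaling(A: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    """Iterative correction: repeatedly divide by row-sum biases."""
    n = A.shape[0]
    b = np.ones(n)
    W = A.copy()
    for _ in range(max_iter):
        s = W.sum(axis=1)
        s = s / s.mean()
        s[s == 0] = 1.0
        b *= s
        W = A / np.outer(b, b)
        if np.abs(W.sum(axis=1) / W.sum(axis=1).mean() - 1).max() < tol:
            # scale so row sums are 1
            r = W.sum(axis=1).mean()
            return 1.0 / (b * np.sqrt(r))
    raise RuntimeError(
        f"ICE balancing did not converge within {max_iter} iterations "
        f"(residual {np.abs(W.sum(axis=1)/W.sum(axis=1).mean()-1).max():.3g})"
    )


def balance_matrix(
    matrix: ContactMatrix,
    method: str = "KR",
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Balance a contact matrix; returns (weights, balanced matrix).

    Rows/columns of the balanced matrix sum to 1 (over unmasked bins).
    Zero-coverage bins are masked: their weight is NaN and their rows and
    columns in the balanced matrix are NaN.
    """
    C = matrix.counts
    n = matrix.n_bins
    cov = C.sum(axis=1) > 0
    if cov.sum() < 2:
        raise ValueError("matrix degenerate after masking zero-coverage bins")
    A = C[np.ix_(cov, cov)]
    if method.upper() == "KR":
        x = _kr_scaling(A, tol=tol, max_iter=max_iter)
    elif method.upper() == "ICE":
        x = _ice_scaling(A, tol=max(tol, 1e-10), max_iter=max_iter)
    else:
        raise ValueError(f"unknown balancing method {method!r}")
    weights = np.full(n, np.nan)
    weights[cov] = x
    balanced = C * np.outer(weights, weights)
    matrix.weights = weights
    return weights, balanced


def expected_by_distance(matrix: ContactMatrix, balanced: np.ndarray | None = None):
    """Mean balanced contact per genomic-distance stratum, per chromosome.

    Returns ``{chrom: 1-D array}`` where entry ``d`` is the mean over bin
    pairs at separation ``d`` bins (NaN-aware).
    """
    if balanced is None:
        balanced = matrix.balanced()
    out = {}
    for chrom in matrix.chromosomes:
        idx = matrix.chrom_bins(chrom)
        M = balanced[np.ix_(idx, idx)]
        n = len(idx)
        exp = np.empty(n)
        for d in range(n):
            diag = np.diagonal(M, offset=d)
            exp[d] = np.nanmean(diag) if np.any(~np.isnan(diag)) else np.nan
        out[chrom] = exp
    return out
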
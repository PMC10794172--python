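"""Genetic maps: ordered (bp, cM) marker pairs per chromosome."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GeneticMap"]


@dataclass
class GeneticMap:
    """Per-chromosome Marey-map markers.

    ``table`` has columns ``chrom``, ``bp``, ``cM``; within each
    chromosome cM must be non-decreasing in bp.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.table = self.table.sort_values(["chrom", "bp"]).reset_index(drop=True)
        for chrom, grp in self.table.groupby("chrom"):
            if np.any(np.diff(grp["cM"].to_numpy()) < -1e-9):
                bad = grp["bp"].to_numpy()[
                    np.flatnonzero(np.diff(grp["cM"].to_numpy()) < -1e-9)
                ]
                raise ValueError(
                    f"map not monotone on {chrom!r}; offending markers near bp "
                    f"{bad[:5].tolist()}"
                )

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    def chrom(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]

    def length_cm(self, chrom: str | None = None) -> float:
        """Map length (max - min cM) of one chromosome or the whole map."""
        if chrom is not None:
            g = self.chrom(chrom)["cM"]
            return float(g.max() - g.min())
        return float(sum(self.length_cm(c) for c in self.chromosomes))

    def interpolate(self, chrom: str, bp) -> np.ndarray:
        """Genetic position at arbitrary bp, linear between flanking markers."""
        g = self.chrom(chrom)
        return np.interp(np.asarray(bp, float), g["bp"], g["cM"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GeneticMap":
        return cls(pd.read_csv(path, sep="\t"))
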
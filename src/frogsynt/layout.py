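"""Genome layouts: chromosome lengths, centromeres, and derived regions.

A :class:`GenomeLayout` is the minimal physical description of a karyotype
that the downstream analyses need: per-chromosome length, centromere
position, and the regions derived from them (p/q arms, extended
subtelomeres, pericentromere).  Coordinates are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenomeLayout", "region_classes"]


@dataclass
class GenomeLayout:
    """Chromosome lengths and centromere positions for one genome.

    Parameters
    ----------
    lengths:
        Mapping of chromosome name to length in bp.
    centromeres:
        Mapping of chromosome name to centromere position in bp.  Every
        centromere must lie strictly inside its chromosome.
    """

    lengths: dict[str, int]
    centromeres: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length")
            cen = self.centromeres.get(chrom)
            if cen is not None and not (0 < cen < length):
                raise ValueError(
                    f"centromere of {chrom!r} at {cen} outside (0, {length})"
                )

    # -- basic accessors -------------------------------------------------

    @property
    def names(self) -> list[str]:
        return list(self.lengths)

    def length(self, chrom: str) -> int:
        return self.lengths[chrom]

    def centromere(self, chrom: str) -> int:
        return self.centromeres[chrom]

    @property
    def genome_size(self) -> int:
        return int(sum(self.lengths.values()))

    def arms(self, chrom: str) -> dict[str, tuple[int, int]]:
        """p/q arm intervals; p is the shorter (or left) arm by convention."""
        cen = self.centromeres[chrom]
        length = self.lengths[chrom]
        left, right = (0, cen), (cen, length)
        if cen <= length - cen:
            return {"p": left, "q": right}
        return {"p": right, "q": left}

    def subtelomeres(self, chrom: str, size: float = 30e6) -> list[tuple[int, int]]:
        """Terminal windows of ``size`` bp at each chromosome end (clipped)."""
        length = self.lengths[chrom]
        size = int(min(size, length // 2))
        return [(0, size), (length - size, length)]

    def pericentromere(self, chrom: str, size: float = 5e6) -> tuple[int, int]:
        """Window of total width ``size`` centred on the centromere (clipped)."""
        cen = self.centromeres[chrom]
        length = self.lengths[chrom]
        half = int(size) // 2
        return (max(0, cen - half), min(length, cen + half))

    def is_acrocentric(self, chrom: str, threshold: float = 30e6) -> bool:
        """True when the centromere lies within ``threshold`` of an end."""
        cen = self.centromeres[chrom]
        return min(cen, self.lengths[chrom] - cen) < threshold

    # -- I/O --------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.names,
                "length": [self.lengths[c] for c in self.names],
                "centromere": [self.centromeres.get(c, -1) for c in self.names],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenomeLayout":
        lengths = dict(zip(df["chrom"].astype(str), df["length"].astype(int)))
        cens = {
            str(c): int(p)
            for c, p in zip(df["chrom"], df.get("centromere", []))
            if int(p) >= 0
        }
        return cls(lengths, cens)

    @classmethod
    def from_tsv(cls, path) -> "GenomeLayout":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def region_classes(
    layout: GenomeLayout,
    grid: pd.DataFrame,
    subtelomere_size: float = 30e6,
    pericentromere_size: float = 5e6,
    acro_exclusion: float = 15e6,
    acro_threshold: float = 30e6,
) -> pd.Series:
    """Classify grid points as subtelomere / arm / pericentromere.

    The extended subtelomere is the terminal ``subtelomere_size`` of each
    (sub)metacentric chromosome; for acrocentric chromosomes (centromere
    within ``acro_threshold`` of an end) the window around the
    pericentromere (``acro_exclusion`` each side of the centromere) is
    excluded from the subtelomere.  The pericentromere class
    (``pericentromere_size`` total around the centromere) takes precedence
    over both.

    ``grid`` must have columns ``chrom`` and ``pos``.
    """
    out = np.full(len(grid), "arm", dtype=object)
    pos = grid["pos"].to_numpy(float)
    for chrom in layout.names:
        sel = (grid["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        p = pos[sel]
        length = layout.length(chrom)
        cen = layout.centromere(chrom)
        size = min(subtelomere_size, length / 2)
        sub = (p < size) | (p >= length - size)
        if layout.is_acrocentric(chrom, acro_threshold):
            sub &= ~((p >= cen - acro_exclusion) & (p < cen + acro_exclusion))
        peri_lo, peri_hi = layout.pericentromere(chrom, pericentromere_size)
        peri = (p >= peri_lo) & (p < peri_hi)
        lab = np.where(peri, "pericentromere", np.where(sub, "subtelomere", "arm"))
        out[sel] = lab
    return pd.Series(out, index=grid.index, name="region")
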
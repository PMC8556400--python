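"""Genome model: chromosomes, fixed-size bins, and TSS annotation.

All analyses in this package operate on a fixed binning of one or more
chromosomes.  Bin indices are 0-based and global (concatenated across
chromosomes in declaration order); intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenomeModel", "make_genome"]


@dataclass
class GenomeModel:
    """A binned genome with TSS annotation.

    Parameters
    ----------
    chromsizes
        Mapping of chromosome name to length in bp.  Every length must be a
        positive multiple of ``bin_size``.
    bin_size
        Bin width in bp.
    tss
        DataFrame with columns ``chrom``, ``pos``, ``gene_id``, ``strand``.
    """

    chromsizes: dict[str, int]
    bin_size: int
    tss: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "pos", "gene_id", "strand"]))

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for chrom, length in self.chromsizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")
            if length % self.bin_size != 0:
                raise ValueError(
                    f"length of {chrom} ({length}) is not a multiple of the "
                    f"bin size ({self.bin_size})")
        if len(self.tss):
            bad = ~self.tss.apply(
                lambda r: 0 <= r["pos"] < self.chromsizes[r["chrom"]], axis=1)
            if bad.any():
                raise ValueError("TSS positions outside chromosome bounds")
            if self.tss["gene_id"].duplicated().any():
                raise ValueError("gene ids must be unique")

    @property
    def chroms(self) -> list[str]:
        return list(self.chromsizes)

    def n_bins(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return self.chromsizes[chrom] // self.bin_size
        return sum(v // self.bin_size for v in self.chromsizes.values())

    def chrom_offset(self, chrom: str) -> int:
        """Global index of the first bin of *chrom*."""
        off = 0
        for name, length in self.chromsizes.items():
            if name == chrom:
                return off
            off += length // self.bin_size
        raise KeyError(chrom)

    def bins(self) -> pd.DataFrame:
        """Bin table with columns chrom, start, end, bin (global index)."""
        rows = []
        for chrom, length in self.chromsizes.items():
            n = length // self.bin_size
            starts = np.arange(n, dtype=np.int64) * self.bin_size
            rows.append(pd.DataFrame({
                "chrom": chrom, "start": starts, "end": starts + self.bin_size,
            }))
        out = pd.concat(rows, ignore_index=True)
        out["bin"] = np.arange(len(out), dtype=np.int64)
        return out

    def tss_bin_counts(self) -> np.ndarray:
        """Number of TSS per global bin (used for compartment sign fixing)."""
        counts = np.zeros(self.n_bins(), dtype=np.int64)
        for _, row in self.tss.iterrows():
            b = self.chrom_offset(row["chrom"]) + int(row["pos"]) // self.bin_size
            counts[b] += 1
        return counts


def make_genome(n_chrom: int = 1, chrom_len: int = 20_000_000,
                bin_size: int = 25_000, n_genes: int = 200,
                seed: int = 0) -> GenomeModel:
    """Build a toy genome with uniformly placed TSS.

    Deterministic for a fixed ``seed``.  Chromosomes are named ``chr1`` ...
    ``chrN`` and all share the same length.
    """
    if n_chrom <= 0 or chrom_len <= 0 or bin_size <= 0:
        raise ValueError("sizes must be positive")
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if chrom_len % bin_size != 0:
        raise ValueError("chrom_len must be a multiple of bin_size")
    rng = np.random.default_rng(seed)
    chromsizes = {f"chr{i + 1}": chrom_len for i in range(n_chrom)}
    chrom_names = rng.choice(list(chromsizes), size=n_genes)
    pos = rng.integers(0, chrom_len, size=n_genes)
    strand = rng.choice(["+", "-"], size=n_genes)
    tss = pd.DataFrame({
        "chrom": chrom_names,
        "pos": pos,
        "gene_id": [f"gene{i:05d}" for i in range(n_genes)],
        "strand": strand,
    }).sort_values(["chrom", "pos"], ignore_index=True)
    return GenomeModel(chromsizes=chromsizes, bin_size=bin_size, tss=tss)
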
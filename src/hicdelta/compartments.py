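"""A/B compartment calling, saddle plots, and compartment-strength metrics.

PC1 is the leading eigenvector of the Pearson-correlation matrix of the
obs/exp map (the classic construction), computed per chromosome, with the
sign oriented so that positive (A) bins have higher TSS density than
negative (B) bins.  The saddle plot re-orders bins by PC1 from high to low,
coarse-grains the obs/exp map into quantile blocks, and quantifies
compartment strength as the ratio of homotypic corner means (A-A or B-B) to
the heterotypic (A-B) corner mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genome import GenomeModel

__all__ = [
    "CompartmentTrack", "SaddleResult", "compute_pc1", "saddle",
    "compartment_strength", "compartment_score", "saddle_difference",
]

MIN_BINS = 10  # chromosomes with fewer unmasked bins are skipped


@dataclass
class CompartmentTrack:
    """Per-bin PC1 values and A/B labels (per chromosome).

    ``labels`` holds +1 for A (PC1 > 0), -1 for B, 0 for masked bins.
    ``reliable[chrom]`` is False when the map carried no compartment signal
    (near-zero PC1 everywhere).
    """

    pc1: dict[str, np.ndarray]
    labels: dict[str, np.ndarray]
    resolution: int
    reliable: dict[str, bool]


@dataclass
class SaddleResult:
    """Coarse-grained (n_quantiles x n_quantiles) mean obs/exp matrix.

    Rows/columns are ordered by PC1 from high (A) to low (B)."""

    matrix: np.ndarray
    n_quantiles: int


def compute_pc1(obsexp: dict[str, np.ndarray], genome: GenomeModel,
                exclude: tuple[str, ...] = ("chrY", "chrM")
                ) -> CompartmentTrack:
    """Leading eigenvector of the obs/exp correlation matrix, TSS-oriented."""
    tss_counts = genome.tss_bin_counts()
    pc1, labels, reliable = {}, {}, {}
    for chrom, oe in obsexp.items():
        n = oe.shape[0]
        vec = np.full(n, np.nan)
        lab = np.zeros(n, dtype=np.int8)
        ok = ~np.all(np.isnan(oe), axis=1)
        if chrom in exclude or ok.sum() < MIN_BINS:
            if chrom not in exclude:
                warnings.warn(f"{chrom}: fewer than {MIN_BINS} unmasked bins; skipped")
            pc1[chrom], labels[chrom], reliable[chrom] = vec, lab, False
            continue
        sub = oe[np.ix_(ok, ok)]
        sub = np.where(np.isnan(sub), 1.0, sub)  # neutral fill inside valid block
        if sub.std() < 1e-12:  # structureless map: PC1 undefined
            pc1[chrom], labels[chrom], reliable[chrom] = vec, lab, False
            continue
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub)
        corr = np.nan_to_num(corr)
        evals, evecs = np.linalg.eigh(corr)
        if evals[-1] < 1e-8:
            pc1[chrom], labels[chrom], reliable[chrom] = vec, lab, False
            continue
        v = evecs[:, -1]
        # orient: A (+) bins are TSS-enriched relative to B (-) bins
        off = genome.chrom_offset(chrom)
        tss_c = tss_counts[off:off + n][ok].astype(float)
        pos_density = tss_c[v > 0].mean() if (v > 0).any() else 0.0
        neg_density = tss_c[v < 0].mean() if (v < 0).any() else 0.0
        if neg_density > pos_density:
            v = -v
        vec[ok] = v
        if np.nanstd(v) < 1e-10:
            reliable[chrom] = False
        else:
            reliable[chrom] = True
            lab[ok] = np.where(v > 0, 1, -1)
        pc1[chrom], labels[chrom] = vec, lab
    return CompartmentTrack(pc1=pc1, labels=labels,
                            resolution=genome.bin_size, reliable=reliable)


def saddle(obsexp: dict[str, np.ndarray], track: CompartmentTrack,
           n_quantiles: int = 50,
           exclude: tuple[str, ...] = ("chrX", "chrY", "chrM")
           ) -> SaddleResult:
    """PC1-sorted, quantile-coarse-grained obs/exp saddle matrix.

    Bins are ranked by PC1 from high to low; the obs/exp map is re-ordered
    accordingly and averaged within n_quantiles x n_quantiles blocks per
    chromosome, then averaged across chromosomes weighted by block pair
    count.
    """
    sums = np.zeros((n_quantiles, n_quantiles))
    cnts = np.zeros((n_quantiles, n_quantiles))
    used = 0
    for chrom, oe in obsexp.items():
        if chrom in exclude:
            continue
        v = track.pc1.get(chrom)
        if v is None:
            continue
        ok = np.isfinite(v)
        if ok.sum() < n_quantiles:
            if ok.sum() > 0:
                raise ValueError(
                    f"{chrom}: n_quantiles={n_quantiles} exceeds the "
                    f"{ok.sum()} unmasked bins")
            continue
        used += 1
        order = np.argsort(-v[ok], kind="stable")
        sub = oe[np.ix_(ok, ok)][np.ix_(order, order)]
        edges = np.floor(np.linspace(0, n_quantiles, len(order),
                                     endpoint=False)).astype(int)
        valid = ~np.isnan(sub)
        filled = np.where(valid, sub, 0.0)
        # quantile-membership matrix: block sums via two matmuls
        member = (edges[None, :] == np.arange(n_quantiles)[:, None]).astype(float)
        sums += member @ filled @ member.T
        cnts += member @ valid.astype(float) @ member.T
    if used == 0:
        raise ValueError("no usable chromosome for saddle computation")
    with np.errstate(invalid="ignore"):
        mat = sums / cnts
    return SaddleResult(matrix=mat, n_quantiles=n_quantiles)


def compartment_strength(sad: SaddleResult, corner_bins: int | None = None
                         ) -> tuple[float, float]:
    """(A_strength, B_strength) from saddle corners.

    With PC1 sorted high-to-low the A-A corner is the top-left block and
    B-B the bottom-right; each strength is its homotypic corner mean over
    the heterotypic (A-B) corner mean.  ``corner_bins`` defaults to 20% of
    the quantile count (10 of 50).
    """
    nq = sad.n_quantiles
    c = corner_bins if corner_bins is not None else max(nq // 5, 1)
    if c > nq // 2:
        raise ValueError("corner_bins must not exceed n_quantiles/2")
    m = sad.matrix
    aa = np.nanmean(m[:c, :c])
    bb = np.nanmean(m[-c:, -c:])
    ab = np.nanmean(np.concatenate([m[:c, -c:].ravel(), m[-c:, :c].ravel()]))
    if not np.isfinite(ab) or ab == 0:
        return (np.nan, np.nan)
    return (float(aa / ab), float(bb / ab))


def compartment_score(obsexp: dict[str, np.ndarray],
                      track: CompartmentTrack) -> dict[str, np.ndarray]:
    """Per-bin homotypic preference score.

    score(b) = mean obs/exp of b with same-label bins / mean obs/exp of b
    with all other bins (cis, excluding b itself).  1 means no
    compartmentalization.
    """
    out = {}
    for chrom, oe in obsexp.items():
        lab = track.labels[chrom]
        n = oe.shape[0]
        score = np.full(n, np.nan)
        valid = ~np.isnan(oe)
        np.fill_diagonal(valid, False)
        filled = np.where(valid, oe, 0.0)
        for cls in (1, -1):
            members = lab == cls
            if members.sum() < 2:
                continue
            same_sum = filled[:, members].sum(axis=1)
            same_n = valid[:, members].sum(axis=1)
            all_sum = filled.sum(axis=1)
            all_n = valid.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                s = (same_sum / same_n) / (all_sum / all_n)
            sel = members & (same_n > 0) & (all_n > 0)
            score[sel] = s[sel]
        out[chrom] = score
    return out


def saddle_difference(saddle1: SaddleResult, saddle2: SaddleResult
                      ) -> np.ndarray:
    """Element-wise log2(saddle2 / saddle1); NaN where either side is 0/NaN."""
    if saddle1.matrix.shape != saddle2.matrix.shape:
        raise ValueError("saddle shapes differ")
    m1, m2 = saddle1.matrix, saddle2.matrix
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.log2(m2 / m1)
    out[~np.isfinite(out)] = np.nan
    return out
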
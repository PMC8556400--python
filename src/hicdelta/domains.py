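"""Insulation scores, TAD boundaries, consensus domains, and differential
intra-TAD contact testing.

The insulation score of a bin is the log2 of the mean balanced interaction
in a diamond window straddling it, normalized by the chromosome-wide
geometric mean of those diamond means.  Boundaries are local minima of the
score; boundary strength is the prominence of the minimum (the lower of the
two flanking maxima minus the minimum).  Domains between non-redundant
boundaries are filtered against a reference TAD set to yield consensus
TADs, whose intra-domain mean obs/exp is compared between conditions with a
paired t-test and the double gate p <= 0.05 and |log2FC| > 0.15.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "InsulationTrack", "insulation", "call_boundaries", "merge_boundaries",
    "reference_tads_standin", "consensus_tads", "intra_tad_frequency",
    "differential_tads", "tad_overlap_hypergeom", "boundary_pileup",
]


@dataclass
class InsulationTrack:
    """Per-bin insulation scores plus candidate boundary minima.

    ``scores[chrom]`` holds the log2-normalized diamond means (NaN within
    ``window_bins`` of a chromosome edge or at masked bins); ``minima`` is a
    DataFrame (chrom, bin, score, strength) of all local minima with their
    prominence-based strengths.
    """

    scores: dict[str, np.ndarray]
    minima: pd.DataFrame
    window_bins: int
    bin_size: int


def _local_minima_strengths(score: np.ndarray,
                            radius: int = 10) -> list[tuple[int, float]]:
    """(index, prominence) of each local minimum of a 1-D curve with NaNs.

    Prominence is measured against the highest value within ``radius``
    bins on each side, taking the lower of the two flanking maxima; this
    windowed form is robust to one-bin noise wiggles next to the minimum.
    """
    ok = np.isfinite(score)
    out = []
    n = len(score)
    for i in range(1, n - 1):
        if not (ok[i - 1] and ok[i] and ok[i + 1]):
            continue
        if score[i] <= score[i - 1] and score[i] <= score[i + 1] \
                and (score[i] < score[i - 1] or score[i] < score[i + 1]):
            left = score[max(0, i - radius):i]
            right = score[i + 1:i + 1 + radius]
            lmax = np.nanmax(left) if np.isfinite(left).any() else score[i]
            rmax = np.nanmax(right) if np.isfinite(right).any() else score[i]
            out.append((i, float(min(lmax, rmax) - score[i])))
    return out


def insulation(balanced: dict[str, np.ndarray], bin_size: int,
               window: int = 250_000) -> InsulationTrack:
    """Diamond insulation scores on balanced (or obs/exp) maps.

    ``window`` must be a multiple of ``bin_size``; bins within one window of
    the chromosome edge get no score.
    """
    if window % bin_size != 0:
        raise ValueError("window must be a multiple of the bin size")
    w = window // bin_size
    scores = {}
    rows = []
    for chrom, mat in balanced.items():
        n = mat.shape[0]
        raw = np.full(n, np.nan)
        for i in range(w, n - w):
            diamond = mat[i - w:i, i + 1:i + w + 1]
            good = np.isfinite(diamond)
            if good.sum() >= diamond.size // 2:
                raw[i] = diamond[good].mean()
        with np.errstate(divide="ignore", invalid="ignore"):
            logv = np.log2(raw)
        finite = np.isfinite(logv)
        score = np.full(n, np.nan)
        if finite.any():
            score[finite] = logv[finite] - logv[finite].mean()
        scores[chrom] = score
        for b, s in _local_minima_strengths(score, radius=w):
            rows.append((chrom, b, score[b], s))
    minima = pd.DataFrame(rows, columns=["chrom", "bin", "score", "strength"])
    return InsulationTrack(scores=scores, minima=minima,
                           window_bins=w, bin_size=bin_size)


def call_boundaries(track: InsulationTrack,
                    min_strength: float = 0.1) -> pd.DataFrame:
    """Local insulation minima with strength above threshold, by position."""
    out = track.minima[track.minima["strength"] > min_strength]
    return out.sort_values(["chrom", "bin"], ignore_index=True)


def merge_boundaries(boundary_lists: list[pd.DataFrame],
                     radius: int = 3) -> pd.DataFrame:
    """Greedy non-redundant boundary set across samples.

    All boundaries are pooled and sorted by strength descending (ties by
    chromosome then leftmost position, for determinism).  The strongest is
    accepted and every remaining boundary within ``radius`` bins of it on
    the same chromosome is discarded; repeat until the pool is exhausted.
    """
    pool = pd.concat(boundary_lists, ignore_index=True)
    pool = pool.sort_values(["strength", "chrom", "bin"],
                            ascending=[False, True, True],
                            kind="stable", ignore_index=True)
    accepted: list[tuple[str, int, float]] = []
    alive = np.ones(len(pool), dtype=bool)
    chroms = pool["chrom"].to_numpy()
    bins = pool["bin"].to_numpy()
    strengths = pool["strength"].to_numpy()
    for k in range(len(pool)):
        if not alive[k]:
            continue
        accepted.append((chroms[k], int(bins[k]), float(strengths[k])))
        near = (chroms == chroms[k]) & (np.abs(bins - bins[k]) <= radius)
        alive &= ~near
    out = pd.DataFrame(accepted, columns=["chrom", "bin", "strength"])
    return out.sort_values(["chrom", "bin"], ignore_index=True)


def reference_tads_standin(track: InsulationTrack,
                           min_strength: float = 0.1,
                           min_len: int = 6) -> pd.DataFrame:
    """Domains between successive called boundaries (insulation-only caller).

    A stand-in reference TAD set built from the insulation track itself:
    intervals between adjacent boundaries (and chromosome ends), at least
    ``min_len`` bins long.  With zero boundaries the whole chromosome is
    one domain.  Deterministic given the track.
    """
    bounds = call_boundaries(track, min_strength)
    rows = []
    for chrom, score in track.scores.items():
        n = len(score)
        bpos = bounds.loc[bounds["chrom"] == chrom, "bin"].tolist()
        edges = [0] + bpos + [n]
        for a, b in zip(edges[:-1], edges[1:]):
            if b - a >= min_len:
                rows.append((chrom, int(a), int(b)))
    return pd.DataFrame(rows, columns=["chrom", "start_bin", "end_bin"])


def consensus_tads(boundaries: pd.DataFrame, reference_tads: pd.DataFrame,
                   min_overlap: float = 0.5, min_len: int = 6,
                   pc1: dict[str, np.ndarray] | None = None) -> pd.DataFrame:
    """Filter adjacent-boundary intervals against a reference TAD set.

    Every pair of adjacent non-redundant boundaries forms a potential TAD;
    it is kept iff its best fractional overlap with any reference TAD
    (overlap length / potential-TAD length) exceeds ``min_overlap`` and its
    length is at least ``min_len`` bins.  If ``pc1`` is given each kept TAD
    is labelled A when the mean PC1 of its bins is positive, else B.
    """
    if reference_tads is None or len(reference_tads) == 0:
        raise ValueError("supply a non-empty reference TAD set "
                         "(external BED or reference_tads_standin)")
    rows = []
    for chrom in boundaries["chrom"].unique():
        bpos = boundaries.loc[boundaries["chrom"] == chrom, "bin"] \
            .sort_values().tolist()
        refs = reference_tads[reference_tads["chrom"] == chrom]
        r_start = refs["start_bin"].to_numpy()
        r_end = refs["end_bin"].to_numpy()
        for a, b in zip(bpos[:-1], bpos[1:]):
            length = b - a
            if length < min_len:
                continue
            if len(r_start):
                ov = (np.minimum(b, r_end) - np.maximum(a, r_start)).clip(min=0)
                best = ov.max() / length
            else:
                best = 0.0
            if best > min_overlap:
                label = ""
                if pc1 is not None and chrom in pc1:
                    m = np.nanmean(pc1[chrom][a:b])
                    label = "A" if m > 0 else "B"
                rows.append((chrom, int(a), int(b), label))
    return pd.DataFrame(rows, columns=["chrom", "start_bin", "end_bin",
                                       "compartment"])


def intra_tad_frequency(obsexp: dict[str, np.ndarray],
                        tads: pd.DataFrame) -> np.ndarray:
    """Mean obs/exp over intra-domain bin pairs, excluding the diagonal."""
    out = np.full(len(tads), np.nan)
    for idx, (_, tad) in enumerate(tads.iterrows()):
        mat = obsexp[tad["chrom"]]
        a, b = int(tad["start_bin"]), int(tad["end_bin"])
        block = mat[a:b, a:b]
        iu = np.triu_indices(b - a, k=1)
        vals = block[iu]
        vals = vals[np.isfinite(vals)]
        if len(vals):
            out[idx] = vals.mean()
    return out


def differential_tads(cond1: np.ndarray, cond2: np.ndarray,
                      p_gate: float = 0.05, fc_gate: float = 0.15
                      ) -> pd.DataFrame:
    """Paired t-test of per-TAD intra-domain contact between conditions.

    ``cond1``/``cond2`` are (n_tads x n_replicates) arrays of per-replicate
    intra-TAD means, paired by replicate index.  Returns per-TAD log2 fold
    change (cond2 over cond1), two-sided p, Cohen's d on the paired
    differences, and the significance flag p <= p_gate and |log2FC| >
    fc_gate.  No multiple-testing correction is applied to the per-TAD
    p-values.
    """
    cond1 = np.atleast_2d(np.asarray(cond1, dtype=float))
    cond2 = np.atleast_2d(np.asarray(cond2, dtype=float))
    if cond1.shape != cond2.shape or cond1.shape[1] < 2:
        raise ValueError("need matching arrays with >=2 paired replicates")
    diffs = cond2 - cond1
    mean_d = diffs.mean(axis=1)
    sd_d = diffs.std(axis=1, ddof=1)
    n = diffs.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean_d / (sd_d / np.sqrt(n))
        p = 2 * stats.t.sf(np.abs(t), df=n - 1)
        log2fc = np.log2(cond2.mean(axis=1) / cond1.mean(axis=1))
        cohens_d = mean_d / sd_d
    zero_var = sd_d == 0
    p[zero_var] = np.nan
    flag = np.isfinite(p) & (p <= p_gate) & (np.abs(log2fc) > fc_gate)
    direction = np.where(flag, np.where(log2fc > 0, "up", "down"), "")
    return pd.DataFrame({
        "log2fc": log2fc, "t": t, "p": p, "cohens_d": cohens_d,
        "significant": flag, "direction": direction,
    })


def tad_overlap_hypergeom(set_a: set, set_b: set, universe: set
                          ) -> tuple[int, float, float]:
    """One-sided hypergeometric overlap test of two flagged TAD sets.

    Returns (observed overlap, expected overlap |A||B|/|U|, upper-tail p of
    P(X >= observed)).
    """
    if not universe:
        raise ValueError("empty universe")
    if not (set_a <= universe and set_b <= universe):
        raise ValueError("sets must be subsets of the universe")
    n_u, n_a, n_b = len(universe), len(set_a), len(set_b)
    k = len(set_a & set_b)
    expected = n_a * n_b / n_u
    p = float(stats.hypergeom.sf(k - 1, n_u, n_a, n_b))
    return k, expected, p


def boundary_pileup(obsexp_by_cond: dict[str, dict[str, np.ndarray]],
                    boundaries: pd.DataFrame, bin_size: int,
                    flank: int = 250_000,
                    insulation_by_cond: dict[str, InsulationTrack] | None = None
                    ) -> dict:
    """Aggregate obs/exp windows centred on boundaries, per condition.

    Returns per-condition mean (2w+1)x(2w+1) maps, the element-wise
    log2(cond2/cond1) difference map (for exactly two conditions), and —
    when insulation tracks are supplied — the 1-D mean insulation profile
    over the same flank.
    """
    w = flank // bin_size
    conds = list(obsexp_by_cond)
    maps = {}
    used = 0
    for cond in conds:
        stack_sum = np.zeros((2 * w + 1, 2 * w + 1))
        stack_n = np.zeros_like(stack_sum)
        for _, row in boundaries.iterrows():
            chrom, b = row["chrom"], int(row["bin"])
            mat = obsexp_by_cond[cond].get(chrom)
            if mat is None:
                continue
            n = mat.shape[0]
            if b - w < 0 or b + w + 1 > n:
                continue
            win = mat[b - w:b + w + 1, b - w:b + w + 1]
            good = np.isfinite(win)
            stack_sum[good] += win[good]
            stack_n += good
            used += 1
        with np.errstate(invalid="ignore"):
            maps[cond] = stack_sum / stack_n
    if used == 0:
        raise ValueError("no usable boundary (all within a flank of an edge)")
    result: dict = {"maps": maps}
    if len(conds) == 2:
        with np.errstate(invalid="ignore", divide="ignore"):
            diff = np.log2(maps[conds[1]] / maps[conds[0]])
        diff[~np.isfinite(diff)] = np.nan
        result["log2_ratio"] = diff
    if insulation_by_cond is not None:
        profiles = {}
        for cond, track in insulation_by_cond.items():
            acc = np.zeros(2 * w + 1)
            cnt = np.zeros(2 * w + 1)
            for _, row in boundaries.iterrows():
                sc = track.scores.get(row["chrom"])
                if sc is None:
                    continue
                b = int(row["bin"])
                if b - w < 0 or b + w + 1 > len(sc):
                    continue
                seg = sc[b - w:b + w + 1]
                good = np.isfinite(seg)
                acc[good] += seg[good]
                cnt += good
            with np.errstate(invalid="ignore"):
                profiles[cond] = acc / cnt
        result["insulation_profiles"] = profiles
    return result
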
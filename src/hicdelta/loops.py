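"""Focal chromatin-loop calling and differential loop analysis.

Raw cis contact counts are first normalized to a distance-normalized
interaction frequency:

    IFnorm(i, j) = IF(i, j) / mean{ IF(a, b) : same 10-kb distance class }

where the distance class of a pair is floor(genomic separation / 10,000 bp).
Candidate loop pixels are scored with the donut filter:

    score(i, j) = P(i, j) / maxFlank(i, j)

with P the mean IFnorm over the peak square of half-width p and maxFlank
the maximum of the donut-annulus, vertical-strip and horizontal-strip
means (defaults p = 50 kb, w = 100 kb).  Significance comes from a
distance-controlled permutation null (IFnorm values shuffled within
distance classes); differential loops between two samples are flagged by a
z-score on diff(score) = score_s1 - score_s2, with 1.0 substituted where a
pixel is not a loop in a sample, at the threshold |z| > 1.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "NormalizedMatrix", "ifnorm", "donut_kernels", "donut_score",
    "call_loops", "differential_loops", "overlap_percentage",
    "loop_overlap_permutation",
]


@dataclass
class NormalizedMatrix:
    """Distance-normalized interaction frequencies per chromosome."""

    values: dict[str, np.ndarray]
    bin_size: int
    distance_class: int

    def class_of_offset(self, d_bins: int) -> int:
        return (d_bins * self.bin_size) // self.distance_class


def ifnorm(counts: dict[str, np.ndarray], bin_size: int,
           distance_class: int = 10_000) -> NormalizedMatrix:
    """Divide each pair by the mean count of its genomic-distance class.

    The class mean is taken over all pairs of the same chromosome whose
    separation falls in the same ``distance_class``-bp window (zeros
    included).  Pairs in an empty (all-zero) class get NaN.
    """
    out = {}
    for chrom, mat in counts.items():
        n = mat.shape[0]
        classes = np.array([(d * bin_size) // distance_class
                            for d in range(n)])
        n_classes = classes.max() + 1
        sums = np.zeros(n_classes)
        cnts = np.zeros(n_classes)
        for d in range(n):
            diag = np.diagonal(mat, offset=d)
            sums[classes[d]] += diag.sum()
            cnts[classes[d]] += len(diag)
        with np.errstate(invalid="ignore", divide="ignore"):
            means = sums / cnts
        norm = np.full((n, n), np.nan)
        for d in range(n):
            m = means[classes[d]]
            if np.isfinite(m) and m > 0:
                idx = np.arange(n - d)
                norm[idx, idx + d] = mat[idx, idx + d] / m
                norm[idx + d, idx] = norm[idx, idx + d]
        out[chrom] = norm
    return NormalizedMatrix(values=out, bin_size=bin_size,
                            distance_class=distance_class)


def donut_kernels(p_bins: int, w_bins: int) -> dict[str, np.ndarray]:
    """Boolean masks (frozen geometry) for the donut-filter regions.

    On the (2w+1)x(2w+1) offset grid centred on the pixel:

    * ``peak``       |di| <= p and |dj| <= p
    * ``donut``      p < max(|di|, |dj|) <= w, excluding the width-1 cross
                     arms di == 0 and dj == 0
    * ``vertical``   |dj| <= p and p < |di| <= w   (top/bottom flanks)
    * ``horizontal`` |di| <= p and p < |dj| <= w   (left/right flanks)
    """
    if w_bins <= p_bins:
        raise ValueError("window w must exceed peak size p")
    off = np.arange(-w_bins, w_bins + 1)
    di = off[:, None]
    dj = off[None, :]
    cheb = np.maximum(np.abs(di), np.abs(dj))
    peak = (np.abs(di) <= p_bins) & (np.abs(dj) <= p_bins)
    donut = (cheb > p_bins) & (cheb <= w_bins) & (di != 0) & (dj != 0)
    vert = (np.abs(dj) <= p_bins) & (np.abs(di) > p_bins)
    horiz = (np.abs(di) <= p_bins) & (np.abs(dj) > p_bins)
    return {"peak": peak, "donut": donut, "vertical": vert,
            "horizontal": horiz}


def _region_boxes(p: int, w: int) -> dict[str, list[tuple[int, int, int, int]]]:
    """Each donut-filter region as signed unions of offset rectangles.

    A rectangle (a1, a2, b1, b2) covers offsets di in [a1, a2], dj in
    [b1, b2].  The donut is assembled as window - peak - arms; the
    decomposition matches :func:`donut_kernels` exactly (verified in the
    test suite against direct convolution).
    """
    arms = [(0, 0, -w, -p - 1), (0, 0, p + 1, w),
            (-w, -p - 1, 0, 0), (p + 1, w, 0, 0)]
    return {
        "peak": [(-p, p, -p, p)],
        "window": [(-w, w, -w, w)],
        "arms": arms,
        "horizontal": [(-p, p, -w, -p - 1), (-p, p, p + 1, w)],
        "vertical": [(-w, -p - 1, -p, p), (p + 1, w, -p, p)],
    }


def _sat(mat: np.ndarray, w: int) -> np.ndarray:
    """Zero-padded summed-area table (out-of-matrix offsets contribute 0)."""
    n = mat.shape[0]
    pad = np.zeros((n + 2 * w + 1, n + 2 * w + 1))
    pad[w + 1:w + 1 + n, w + 1:w + 1 + n] = mat
    return pad.cumsum(axis=0).cumsum(axis=1)


def _box_sums(sat: np.ndarray, n: int, w: int,
              boxes: list[tuple[int, int, int, int]]) -> np.ndarray:
    """Sum over the given offset rectangles for every pixel (slice views)."""
    out = np.zeros((n, n))
    for a1, a2, b1, b2 in boxes:
        rl, rh = w + a1, w + a2 + 1          # row slice starts in sat
        cl, ch = w + b1, w + b2 + 1
        out += (sat[rh:rh + n, ch:ch + n] - sat[rl:rl + n, ch:ch + n]
                - sat[rh:rh + n, cl:cl + n] + sat[rl:rl + n, cl:cl + n])
    return out


def _region_means(mat: np.ndarray, p_bins: int, w_bins: int
                  ) -> dict[str, np.ndarray]:
    valid = np.isfinite(mat).astype(float)
    filled = np.where(np.isfinite(mat), mat, 0.0)
    n = mat.shape[0]
    boxes = _region_boxes(p_bins, w_bins)
    sat_f = _sat(filled, w_bins)
    sat_v = _sat(valid, w_bins)
    sums = {k: _box_sums(sat_f, n, w_bins, v) for k, v in boxes.items()}
    cnts = {k: _box_sums(sat_v, n, w_bins, v) for k, v in boxes.items()}
    means = {}
    for name in ("peak", "horizontal", "vertical"):
        c = cnts[name]
        with np.errstate(invalid="ignore", divide="ignore"):
            means[name] = np.where(c > 0.5, sums[name] / np.maximum(c, 1e-12),
                                   np.nan)
    dsum = sums["window"] - sums["peak"] - sums["arms"]
    dcnt = cnts["window"] - cnts["peak"] - cnts["arms"]
    with np.errstate(invalid="ignore", divide="ignore"):
        means["donut"] = np.where(dcnt > 0.5, dsum / np.maximum(dcnt, 1e-12),
                                  np.nan)
    return means


def donut_score(norm: NormalizedMatrix, p: int = 50_000, w: int = 100_000,
                max_dist: int | None = None) -> dict[str, np.ndarray]:
    """Donut-filter score map per chromosome.

    Scores are defined only for upper-triangle pixels whose full window
    geometry fits (at least w bins from every matrix edge and j - i >
    2w + 1 bins, so the window never touches the diagonal).  ``max_dist``
    optionally limits the anchor separation in bins.
    """
    if w <= p:
        raise ValueError("window w must exceed peak size p")
    bs = norm.bin_size
    p_bins = max(p // bs, 1)
    w_bins = max(w // bs, p_bins + 1)
    out = {}
    for chrom, mat in norm.values.items():
        n = mat.shape[0]
        means = _region_means(mat, p_bins, w_bins)
        flanks = np.fmax(np.fmax(means["donut"], means["vertical"]),
                         means["horizontal"])
        with np.errstate(invalid="ignore", divide="ignore"):
            score = means["peak"] / flanks
        ii, jj = np.indices((n, n))
        defined = (jj - ii > 2 * w_bins + 1) & (ii >= w_bins) \
            & (jj < n - w_bins)
        if max_dist is not None:
            defined &= (jj - ii) <= max_dist
        score[~defined] = np.nan
        score[~np.isfinite(score)] = np.nan
        out[chrom] = score
    return out


def _shuffle_within_classes(mat: np.ndarray, norm: NormalizedMatrix,
                            rng: np.random.Generator,
                            max_offset: int | None = None) -> np.ndarray:
    """Permute upper-triangle values within genomic-distance classes.

    ``max_offset`` limits the shuffle to diagonals that can influence the
    scored band (a pure efficiency device; classes are never mixed)."""
    n = mat.shape[0]
    perm = np.array(mat)
    lim = n if max_offset is None else min(n, max_offset + 1)
    classes = np.array([norm.class_of_offset(d) for d in range(lim)])
    for cls in np.unique(classes):
        ds = np.nonzero(classes == cls)[0]
        vals = np.concatenate([np.diagonal(mat, offset=d) for d in ds])
        shuffled = rng.permutation(vals)
        pos = 0
        for d in ds:
            ln = n - d
            idx = np.arange(ln)
            perm[idx, idx + d] = shuffled[pos:pos + ln]
            perm[idx + d, idx] = perm[idx, idx + d]
            pos += ln
    return perm


def call_loops(norm: NormalizedMatrix, p: int = 50_000, w: int = 100_000,
               n_perm: int = 200, alpha: float = 0.01,
               max_dist: int | None = None, seed: int = 0) -> pd.DataFrame:
    """Permutation-calibrated loop calls.

    The observed donut-score map is compared, per distance class, with the
    pooled score distribution of ``n_perm`` distance-controlled shuffles of
    the IFnorm matrix.  A pixel is called when its score exceeds the
    (1 - alpha) null quantile of its class; adjacent called pixels
    (8-connectivity) are merged into one loop at the maximal-score pixel.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    scores = donut_score(norm, p=p, w=w, max_dist=max_dist)
    rows = []
    for chrom, obs in scores.items():
        n = obs.shape[0]
        ii, jj = np.indices((n, n))
        offsets = jj - ii
        pixel_class = np.array([norm.class_of_offset(d) if d >= 0 else -1
                                for d in range(n)])
        defined = np.isfinite(obs)
        if not defined.any():
            continue
        bs = norm.bin_size
        w_bins = max(w // bs, max(p // bs, 1) + 1)
        shuffle_lim = None if max_dist is None else max_dist + 2 * w_bins + 2
        null_by_class: dict[int, list[np.ndarray]] = {}
        for _ in range(n_perm):
            shuf = _shuffle_within_classes(norm.values[chrom], norm, rng,
                                           max_offset=shuffle_lim)
            nm = NormalizedMatrix({chrom: shuf}, norm.bin_size,
                                  norm.distance_class)
            smap = donut_score(nm, p=p, w=w, max_dist=max_dist)[chrom]
            ok = np.isfinite(smap)
            cls_map = pixel_class[offsets[ok]]
            vals = smap[ok]
            for cls in np.unique(cls_map):
                null_by_class.setdefault(cls, []).append(vals[cls_map == cls])
        thresholds = {cls: np.quantile(np.concatenate(chunks), 1 - alpha)
                      for cls, chunks in null_by_class.items()}
        null_pool = np.concatenate([np.concatenate(c)
                                    for c in null_by_class.values()])
        if np.ptp(null_pool) == 0:
            warnings.warn(f"{chrom}: degenerate permutation null; no calls")
            continue
        called = np.zeros_like(obs, dtype=bool)
        ok = defined.copy()
        for cls, thr in thresholds.items():
            sel = ok & (pixel_class[np.clip(offsets, 0, n - 1)] == cls) \
                & (offsets > 0)
            called |= sel & (obs > thr)
        labels, n_comp = ndimage.label(called,
                                       structure=np.ones((3, 3), dtype=int))
        for comp in range(1, n_comp + 1):
            mask = labels == comp
            flat = np.argmax(np.where(mask, obs, -np.inf))
            bi, bj = np.unravel_index(flat, obs.shape)
            rows.append((chrom, int(bi), int(bj), float(obs[bi, bj]),
                         int(mask.sum())))
    return pd.DataFrame(rows, columns=["chrom", "bin1", "bin2", "score",
                                       "n_pixels"])


def differential_loops(loops1: pd.DataFrame, scores1: dict[str, np.ndarray],
                       loops2: pd.DataFrame, scores2: dict[str, np.ndarray],
                       z_threshold: float = 1.5, match_tol: int = 2
                       ) -> pd.DataFrame:
    """Z-score the per-region score difference between two samples.

    Common regions are the union of the two call sets, with calls whose
    anchors agree within ``match_tol`` bins treated as shared.  Per region,
    diff = score_s1 - score_s2 where a sample's score defaults to 1.0 at
    regions that are not loops in that sample.  z = (diff - mean) / sd
    (sample sd, n-1); a region is flagged when |z| > z_threshold, direction
    "lost" (weaker in s2) for positive diff, "gained" for negative.
    """
    regions = []  # (chrom, i, j, score1 or None, score2 or None)
    used2 = np.zeros(len(loops2), dtype=bool)
    l2_by_chrom = {c: sub for c, sub in loops2.groupby("chrom")}
    for _, r1 in loops1.iterrows():
        s2_val = None
        sub = l2_by_chrom.get(r1["chrom"])
        if sub is not None:
            near = (np.abs(sub["bin1"] - r1["bin1"]) <= match_tol) \
                & (np.abs(sub["bin2"] - r1["bin2"]) <= match_tol)
            if near.any():
                k = sub.index[near][0]
                s2_val = float(loops2.loc[k, "score"])
                used2[loops2.index.get_loc(k)] = True
        regions.append((r1["chrom"], int(r1["bin1"]), int(r1["bin2"]),
                        float(r1["score"]), s2_val))
    for pos, (_, r2) in enumerate(loops2.iterrows()):
        if not used2[pos]:
            regions.append((r2["chrom"], int(r2["bin1"]), int(r2["bin2"]),
                            None, float(r2["score"])))
    if len(regions) < 3:
        raise ValueError("fewer than 3 common regions; z-score undefined")
    diff = np.array([
        (s1 if s1 is not None else 1.0) - (s2 if s2 is not None else 1.0)
        for _, _, _, s1, s2 in regions])
    sd = diff.std(ddof=1)
    z = (diff - diff.mean()) / sd if sd > 0 else np.zeros_like(diff)
    flag = np.abs(z) > z_threshold
    direction = np.where(flag, np.where(diff > 0, "lost", "gained"), "")
    return pd.DataFrame({
        "chrom": [r[0] for r in regions],
        "bin1": [r[1] for r in regions],
        "bin2": [r[2] for r in regions],
        "in_s1": [r[3] is not None for r in regions],
        "in_s2": [r[4] is not None for r in regions],
        "diff": diff, "z": z, "differential": flag, "direction": direction,
    })


def overlap_percentage(overlap: int, total: int) -> int:
    """Overlap count as a percentage of the set size, nearest integer."""
    if total <= 0:
        raise ValueError("total must be positive")
    return int(round(100 * overlap / total))


def _count_matches(a: pd.DataFrame, b: pd.DataFrame, match_tol: int) -> int:
    count = 0
    b_by_chrom = {c: (sub["bin1"].to_numpy(), sub["bin2"].to_numpy())
                  for c, sub in b.groupby("chrom")}
    for _, r in a.iterrows():
        entry = b_by_chrom.get(r["chrom"])
        if entry is None:
            continue
        b1, b2 = entry
        if ((np.abs(b1 - r["bin1"]) <= match_tol)
                & (np.abs(b2 - r["bin2"]) <= match_tol)).any():
            count += 1
    return count


def loop_overlap_permutation(set_a: pd.DataFrame, set_b: pd.DataFrame,
                             universe: pd.DataFrame, n_perm: int = 1000,
                             match_tol: int = 0, seed: int = 0) -> dict:
    """Permutation test for the overlap of two loop sets.

    Observed overlap counts members of A whose anchors both match a member
    of B within ``match_tol`` bins.  The null redraws |A| loops from the
    universe uniformly without replacement ``n_perm`` times; the p-value
    uses the add-one correction (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    if len(set_a) > len(universe):
        raise ValueError("|A| exceeds the universe size")
    rng = np.random.default_rng(seed)
    observed = _count_matches(set_a, set_b, match_tol)
    null_counts = np.empty(n_perm, dtype=int)
    uni = universe.reset_index(drop=True)
    for k in range(n_perm):
        draw = uni.iloc[rng.choice(len(uni), size=len(set_a), replace=False)]
        null_counts[k] = _count_matches(draw, set_b, match_tol)
    p = (1 + int((null_counts >= observed).sum())) / (n_perm + 1)
    random_overlap = float(null_counts.mean())
    return {
        "overlap": observed,
        "overlap_pct": overlap_percentage(observed, len(set_a)),
        "random_overlap": random_overlap,
        "random_pct": overlap_percentage(int(round(random_overlap)),
                                         len(set_a)),
        "p": p,
    }
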
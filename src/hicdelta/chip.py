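"""ChIP-seq background normalization and peak-to-expression association.

Normalization follows the flank-background recipe: the union U of all
samples' peaks defines 10-kb flank regions U_f (peak-overlapping bases
removed), whose per-sample read counts feed a median-of-ratios size-factor
estimator; samples are then binomially downsampled so all share the
smallest background level.

Association with differential expression scores each gene as

    s_g = sum over peaks c mapping to g of f_c / n_c

with f_c = -log10 of the peak's differential-binding p-value and n_c the
number of genes the peak maps to (TSS within +/- 25 kb).  Genes ranked by
s_g are cut into ventiles; a left-skewed overlap of DE genes with the top
ventiles is quantified by the minimum-hypergeometric statistic and its
exact p-value.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import mhg_statistic, mhg_pvalue

__all__ = [
    "union_peaks", "flank_regions", "size_factors", "downsample",
    "differential_peaks", "gene_scores", "ventile_association",
    "region_expression_fisher",
]


def _merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping or adjacent half-open intervals per chromosome."""
    rows = []
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values(["start", "end"])
        cur_s, cur_e = None, None
        for s, e in zip(sub["start"], sub["end"]):
            if s >= e:
                raise ValueError("malformed interval (start >= end)")
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _subtract_intervals(df: pd.DataFrame, remove: pd.DataFrame
                        ) -> pd.DataFrame:
    """Remove all bases of ``remove`` from the intervals of ``df``."""
    remove = _merge_intervals(remove)
    rows = []
    for chrom, sub in df.groupby("chrom", sort=True):
        cuts = remove[remove["chrom"] == chrom]
        for s, e in zip(sub["start"], sub["end"]):
            pieces = [(s, e)]
            for rs, re_ in zip(cuts["start"], cuts["end"]):
                nxt = []
                for a, b in pieces:
                    if re_ <= a or rs >= b:
                        nxt.append((a, b))
                    else:
                        if a < rs:
                            nxt.append((a, rs))
                        if re_ < b:
                            nxt.append((re_, b))
                pieces = nxt
            rows.extend((chrom, a, b) for a, b in pieces if b > a)
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def union_peaks(peak_lists: list[pd.DataFrame]) -> pd.DataFrame:
    """Union of all samples' peaks (overlapping/adjacent intervals merged)."""
    pooled = pd.concat(peak_lists, ignore_index=True)[["chrom", "start", "end"]]
    if (pooled["start"] < 0).any():
        raise ValueError("malformed interval (negative start)")
    return _merge_intervals(pooled)


def flank_regions(union: pd.DataFrame, chromsizes: dict[str, int],
                  flank: int = 10_000) -> pd.DataFrame:
    """Background flanks of the peak union.

    For each union peak, the (-flank, 0) upstream and (0, +flank)
    downstream windows, clipped at chromosome ends, with every base that
    overlaps any union peak removed; the result is itself merged, so
    shared flank bases are counted once.
    """
    rows = []
    for _, pk in union.iterrows():
        clen = chromsizes[pk["chrom"]]
        for a, b in ((pk["start"] - flank, pk["start"]),
                     (pk["end"], pk["end"] + flank)):
            a, b = max(a, 0), min(b, clen)
            if b > a:
                rows.append((pk["chrom"], a, b))
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    cand = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return _merge_intervals(_subtract_intervals(cand, union))


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors from background-region counts.

    The reference per region is the geometric mean across samples; each
    sample's factor is the median over regions of its count over the
    reference.  Regions containing any zero are excluded (the estimator's
    standard default).
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    mat = counts.to_numpy(dtype=float)
    usable = (mat > 0).all(axis=1)
    if not usable.any():
        raise ValueError("no region with all-positive counts")
    sub = mat[usable]
    log_ref = np.log(sub).mean(axis=1)
    ratios = np.exp(np.log(sub) - log_ref[:, None])
    return pd.Series(np.median(ratios, axis=0), index=counts.columns)


def downsample(counts: pd.DataFrame, factors: pd.Series,
               seed: int = 0) -> pd.DataFrame:
    """Binomial thinning so all samples match the smallest background.

    Sample x is retained at fraction min(q)/q_x, so the smallest-background
    sample is kept whole and subsampling only removes reads.
    """
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    rng = np.random.default_rng(seed)
    qmin = factors.min()
    out = {}
    for col in counts.columns:
        retain = qmin / factors[col]
        out[col] = rng.binomial(counts[col].to_numpy(dtype=np.int64), retain)
    return pd.DataFrame(out, index=counts.index)


def differential_peaks(counts: pd.DataFrame, conditions: dict[str, str]
                       ) -> pd.DataFrame:
    """Per-peak two-sided differential-binding test on pooled counts.

    A conditional binomial (Poisson exact) test of the condition-2 total
    against the condition-1 total per peak — a stand-in for any upstream
    differential-binding caller; its per-peak p-values are what the
    association stage consumes.
    """
    groups = pd.Series(conditions)
    cond_names = sorted(groups.unique())
    if len(cond_names) != 2:
        raise ValueError("need exactly two conditions")
    c1 = counts[groups[groups == cond_names[0]].index].sum(axis=1)
    c2 = counts[groups[groups == cond_names[1]].index].sum(axis=1)
    n1 = len(groups[groups == cond_names[0]])
    n2 = len(groups[groups == cond_names[1]])
    expect = n2 / (n1 + n2)
    total = (c1 + c2).to_numpy(dtype=np.int64)
    k2 = c2.to_numpy(dtype=np.int64)
    p = np.ones(len(total))
    nz = total > 0
    p[nz] = [stats.binomtest(int(k), int(t), expect).pvalue
             for k, t in zip(k2[nz], total[nz])]
    with np.errstate(divide="ignore"):
        log2fc = np.log2((k2 / max(n2, 1) + 0.5) / (c1.to_numpy() / max(n1, 1) + 0.5))
    return pd.DataFrame({"pvalue": p, "log2fc": log2fc}, index=counts.index)


def gene_scores(diff_peaks: pd.DataFrame, tss: pd.DataFrame,
                window: int = 25_000) -> pd.DataFrame:
    """Aggregate peak-change evidence into per-gene scores s_g.

    ``diff_peaks`` needs columns chrom, start, end, pvalue (in (0, 1]).
    A peak maps to every gene whose TSS lies within ``window`` bp of the
    peak interval; each peak contributes -log10(p) split evenly over the
    n_c genes it maps to.  Genes are ranked by s_g descending (ties broken
    by gene id) and assigned ventiles 1-20.
    """
    if ((diff_peaks["pvalue"] <= 0) | (diff_peaks["pvalue"] > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    scores = {g: 0.0 for g in tss["gene_id"]}
    n_unmapped = 0
    for chrom, sub in diff_peaks.groupby("chrom"):
        gsub = tss[tss["chrom"] == chrom]
        pos = gsub["pos"].to_numpy()
        ids = gsub["gene_id"].to_numpy()
        for _, pk in sub.iterrows():
            hit = (pos >= pk["start"] - window) & (pos < pk["end"] + window)
            n_c = int(hit.sum())
            if n_c == 0:
                n_unmapped += 1
                continue
            f_c = -np.log10(pk["pvalue"])
            for g in ids[hit]:
                scores[g] += f_c / n_c
    if n_unmapped:
        warnings.warn(f"{n_unmapped} peaks mapped to no gene and were dropped")
    out = pd.DataFrame({"gene": list(scores), "s_g": list(scores.values())})
    out = out.sort_values(["s_g", "gene"], ascending=[False, True],
                          kind="stable", ignore_index=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out["ventile"] = 1 + (20 * (out["rank"] - 1) // len(out)).astype(int)
    return out


def ventile_association(table: pd.DataFrame, de_genes: set) -> dict:
    """Overlap of DE genes with gene-score ventiles, plus mHG significance.

    Returns per-ventile DE counts (index 1-20), the mHG statistic over rank
    prefixes, and its exact p-value.  DE genes outside the scored universe
    are dropped with a warning.
    """
    universe = set(table["gene"])
    de = set(de_genes) & universe
    dropped = len(set(de_genes)) - len(de)
    if dropped:
        warnings.warn(f"{dropped} DE genes outside the scored universe dropped")
    membership = table["gene"].isin(de).to_numpy(dtype=int)
    counts = (table.assign(de=membership).groupby("ventile")["de"].sum()
              .reindex(range(1, 21), fill_value=0))
    if len(de) == 0:
        return {"ventile_counts": counts, "mhg_statistic": 1.0,
                "mhg_cutoff": 0, "p": 1.0}
    stat, cutoff = mhg_statistic(membership)
    p = mhg_pvalue(len(membership), int(membership.sum()), stat)
    return {"ventile_counts": counts, "mhg_statistic": stat,
            "mhg_cutoff": cutoff, "p": p}


def region_expression_fisher(table: np.ndarray) -> dict:
    """One-sided Fisher's exact test on a 2x2 contingency table.

    Returns the conditional odds ratio, the one-sided (greater) p, and the
    Woolf logit 95% CI of the sample odds ratio.  A zero margin makes the
    odds ratio undefined and p = 1.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("need a 2x2 table of non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return {"odds_ratio": np.nan, "p": 1.0, "ci95": (np.nan, np.nan)}
    res = stats.fisher_exact(t, alternative="greater")
    a, b, c, d = t.ravel().astype(float)
    if min(a, b, c, d) == 0:
        ci = (np.nan, np.nan)
    else:
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        log_or = np.log(a * d / (b * c))
        ci = (float(np.exp(log_or - 1.96 * se)),
              float(np.exp(log_or + 1.96 * se)))
    return {"odds_ratio": float(res.statistic), "p": float(res.pvalue),
            "ci95": ci}
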
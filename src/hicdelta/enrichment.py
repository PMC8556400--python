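"""Hypergeometric set enrichment and the minimum-hypergeometric (mHG)
statistic for ranked lists.

``hypergeom_tail`` is the exact upper tail P(X >= k) of the hypergeometric
distribution, evaluated in log space.  ``enrich`` applies it to gene-set
lists with a minimum term size and Benjamini-Hochberg correction.  The mHG
statistic of a ranked binary list is the minimum, over all rank prefixes,
of the hypergeometric enrichment tail of the prefix; its exact p-value is
computed by dynamic programming over the (rank, successes) path lattice,
which accounts for the minimization over prefixes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = ["hypergeom_tail", "enrich", "mhg_statistic", "mhg_pvalue"]


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact P(X >= k) drawing n from N with K marked, in log space.

    Parameters follow the gene-set convention: N genes total, K in the
    term, n in the query list, k in the overlap.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("require 0 <= K, n <= N")
    if k < 0 or k > min(K, n):
        if k <= 0:
            return 1.0
        if k > min(K, n):
            raise ValueError("k cannot exceed min(K, n)")
    if k <= 0:
        return 1.0
    i = np.arange(k, min(K, n) + 1)
    logp = stats.hypergeom.logpmf(i, N, K, n)
    return float(min(1.0, np.exp(logsumexp(logp))))


def enrich(de_genes: set, terms: dict[str, set], universe: set,
           min_term: int = 10) -> pd.DataFrame:
    """Hypergeometric enrichment of each term in a ranked-free gene list.

    Terms with fewer than ``min_term`` members inside the universe are
    skipped.  q-values are Benjamini-Hochberg across the tested terms.
    """
    if not universe:
        raise ValueError("empty universe")
    de = set(de_genes) & universe
    rows = []
    for term_id, members in terms.items():
        mem = set(members) & universe
        if len(mem) < min_term:
            continue
        k = len(mem & de)
        p = hypergeom_tail(k, len(mem), len(de), len(universe))
        rows.append((term_id, len(mem), k, p))
    out = pd.DataFrame(rows, columns=["term", "K", "k", "p"])
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["q"] = []
    return out


def _prefix_tails(membership: np.ndarray) -> np.ndarray:
    """HGT(b_n; n) for every prefix length n = 1..N of a ranked 0/1 list."""
    v = np.asarray(membership, dtype=int)
    N = len(v)
    B = int(v.sum())
    n = np.arange(1, N + 1)
    b = np.cumsum(v)
    return stats.hypergeom.sf(b - 1, N, B, n)


def mhg_statistic(membership: np.ndarray) -> tuple[float, int]:
    """Minimum hypergeometric tail over rank prefixes.

    ``membership`` is the ranked 0/1 indicator of query-set membership
    (rank 1 first).  Returns (statistic, prefix length achieving it).
    """
    tails = _prefix_tails(membership)
    if len(tails) == 0:
        return 1.0, 0
    idx = int(np.argmin(tails))
    return float(tails[idx]), idx + 1


def mhg_pvalue(N: int, B: int, stat: float) -> float:
    """Exact p-value of an observed mHG statistic.

    Probability, over uniformly random arrangements of B successes among N
    ranks, that some prefix attains a hypergeometric tail <= ``stat``.
    Computed by the O(N*B) lattice dynamic programme: walk the ranked list,
    track the probability of each (prefix length, successes-so-far) state,
    and absorb the mass of states whose tail already beats the statistic.
    """
    if B == 0 or N == 0:
        return 1.0
    if stat >= 1.0:
        return 1.0
    B = min(B, N)
    # significance region: HGT(b; n) <= stat
    surv = np.zeros(B + 1)
    surv[0] = 1.0
    absorbed = 0.0
    for n in range(1, N + 1):
        nxt = np.zeros(B + 1)
        bmax = min(n - 1, B)
        b = np.arange(0, bmax + 1)
        p_one = (B - b) / (N - (n - 1))
        nxt[b] += surv[b] * (1 - p_one)
        up = b[b < B]
        nxt[up + 1] += surv[up] * p_one[b < B]
        # absorb newly significant states at prefix length n
        bs = np.arange(0, min(n, B) + 1)
        tails = stats.hypergeom.sf(bs - 1, N, B, n)
        hit = tails <= stat * (1 + 1e-12)
        if hit.any():
            absorbed += nxt[bs[hit]].sum()
            nxt[bs[hit]] = 0.0
        surv = nxt
    return float(min(1.0, absorbed))
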
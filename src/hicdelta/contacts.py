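"""Contact-matrix container, balancing, expected-by-distance and P(s) curves.

The :class:`ContactMatrix` stores one dense symmetric cis matrix per
chromosome (trans contacts are out of scope for every analysis in this
package).  Balancing is iterative correction (ICE): multiplicative per-bin
weights are fitted so that every unmasked row of the weighted matrix sums to
one.  A per-chromosome low-coverage mask (bottom 1% of bins by marginal
count, plus empty bins) is applied once and shared by all downstream stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeModel

__all__ = [
    "ContactMatrix", "ExpectedProfile", "ContactProbabilityCurve",
    "balance_dense",
]


@dataclass
class ExpectedProfile:
    """Mean balanced interaction per bin separation (cis).

    ``values[d]`` is the mean over all unmasked pairs at separation ``d``
    bins, averaged across chromosomes weighted by the number of contributing
    pairs; ``n_pairs[d]`` is that number.  Separations with no valid pair
    have ``values`` = NaN.
    """

    values: np.ndarray
    n_pairs: np.ndarray


@dataclass
class ContactProbabilityCurve:
    """P(s) curve: contact frequency vs genomic separation, log-binned."""

    s: np.ndarray            # geometric centre of each distance bin, bp
    p: np.ndarray            # normalized contact frequency, sums to 1
    derivative: np.ndarray   # d log P / d log s (NaN at undefined points)


def balance_dense(mat: np.ndarray, mask: np.ndarray,
                  tol: float = 1e-5, max_iter: int = 200) -> np.ndarray:
    """ICE-balance one dense symmetric matrix.

    Returns per-bin weights w such that ``w[i]*w[j]*mat[i,j]`` has unit row
    sums over unmasked bins; masked bins get NaN weights.  Warns if the
    relative row-sum spread has not reached ``tol`` within ``max_iter``.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    n = mat.shape[0]
    if mat.shape != (n, n):
        raise ValueError("matrix must be square")
    if not np.allclose(mat, mat.T):
        raise ValueError("matrix must be symmetric")
    valid = ~mask
    w = np.ones(n)
    sub = mat[np.ix_(valid, valid)].astype(float)
    wv = np.ones(valid.sum())
    achieved = np.inf
    for _ in range(max_iter):
        s = (sub * wv).sum(axis=1) * wv
        m = s[s > 0].mean() if (s > 0).any() else 0.0
        if m == 0:
            break
        rel = s / m
        achieved = np.abs(rel - 1).max()
        if achieved < tol:
            break
        rel[rel == 0] = 1.0
        wv /= np.sqrt(rel)
    else:
        warnings.warn(
            f"balancing did not converge within {max_iter} iterations "
            f"(max relative row-sum deviation {achieved:.2e})")
    # rescale so unmasked row sums equal exactly 1 on average
    s = (sub * wv).sum(axis=1) * wv
    m = s[s > 0].mean() if (s > 0).any() else 1.0
    if m > 0:
        wv /= np.sqrt(m)
    w = np.full(n, np.nan)
    w[valid] = wv
    return w


class ContactMatrix:
    """Symmetric binned cis contact matrices with weights and validity mask."""

    def __init__(self, genome: GenomeModel, counts: dict[str, np.ndarray]):
        self.genome = genome
        self.counts: dict[str, np.ndarray] = {}
        for chrom in genome.chroms:
            c = np.asarray(counts[chrom], dtype=float)
            n = genome.n_bins(chrom)
            if c.shape != (n, n):
                raise ValueError(f"count matrix for {chrom} has wrong shape")
            if not np.allclose(c, c.T):
                raise ValueError(f"count matrix for {chrom} is not symmetric")
            if (c < 0).any():
                raise ValueError("negative counts")
            self.counts[chrom] = c
        self.weights: dict[str, np.ndarray] = {}
        self.mask: dict[str, np.ndarray] = {
            chrom: np.zeros(genome.n_bins(chrom), dtype=bool)
            for chrom in genome.chroms
        }

    # ------------------------------------------------------------------ IO
    @classmethod
    def from_triples(cls, genome: GenomeModel,
                     triples: pd.DataFrame | str) -> "ContactMatrix":
        """Build from sparse upper-triangle triples.

        ``triples`` is a DataFrame or TSV path with columns
        ``chrom, bin1, bin2, count`` (0-based chromosome-local bin indices).
        Pairs given as (j, i) are folded onto (i, j); the matrix is
        symmetrized.
        """
        if isinstance(triples, str):
            triples = pd.read_csv(triples, sep="\t")
        counts = {}
        for chrom in genome.chroms:
            n = genome.n_bins(chrom)
            mat = np.zeros((n, n))
            sub = triples[triples["chrom"] == chrom]
            i = sub["bin1"].to_numpy(dtype=np.int64)
            j = sub["bin2"].to_numpy(dtype=np.int64)
            v = sub["count"].to_numpy(dtype=float)
            lo, hi = np.minimum(i, j), np.maximum(i, j)
            np.add.at(mat, (lo, hi), v)
            mat = mat + np.triu(mat, 1).T
            counts[chrom] = mat
        return cls(genome, counts)

    def to_triples(self, path: str | None = None) -> pd.DataFrame:
        """Upper-triangle sparse triples (chrom, bin1, bin2, count)."""
        rows = []
        for chrom, mat in self.counts.items():
            i, j = np.nonzero(np.triu(mat))
            rows.append(pd.DataFrame({
                "chrom": chrom, "bin1": i, "bin2": j, "count": mat[i, j],
            }))
        out = pd.concat(rows, ignore_index=True)
        if path is not None:
            out.to_csv(path, sep="\t", index=False)
        return out

    # ------------------------------------------------------------ balancing
    def balance(self, tolerance: float = 1e-5, max_iter: int = 200,
                mask_low_coverage: float = 0.01) -> None:
        """Fit ICE weights per chromosome.

        Bins with zero marginal count, plus the ``mask_low_coverage``
        fraction with the lowest marginals on each chromosome, are masked
        and excluded from every downstream analysis.
        """
        for chrom, mat in self.counts.items():
            marg = mat.sum(axis=1)
            mask = marg == 0
            nonzero = marg[~mask]
            if mask_low_coverage > 0 and len(nonzero):
                cutoff = np.quantile(nonzero, mask_low_coverage)
                mask |= marg <= cutoff
            self.mask[chrom] = mask
            self.weights[chrom] = balance_dense(
                mat, mask, tol=tolerance, max_iter=max_iter)

    def balanced(self, chrom: str) -> np.ndarray:
        """Dense weighted matrix; masked rows/cols are NaN."""
        if chrom not in self.weights:
            raise RuntimeError("call balance() first")
        w = self.weights[chrom]
        return self.counts[chrom] * np.outer(w, w)

    def masked_counts(self, chrom: str) -> np.ndarray:
        """Raw counts with masked rows/cols as NaN (no weights applied).

        For data whose bins are uniformly visible (e.g. the synthetic
        generator), raw-count obs/exp preserves per-class contact-level
        changes that iterative correction would absorb into its weights.
        """
        mat = self.counts[chrom].astype(float).copy()
        mask = self.mask[chrom]
        mat[mask, :] = np.nan
        mat[:, mask] = np.nan
        return mat

    # ------------------------------------------------- expected and obs/exp
    def expected_by_distance(self, balanced: bool = True) -> ExpectedProfile:
        """Per-separation mean interaction over unmasked pairs."""
        max_n = max(self.genome.n_bins(c) for c in self.genome.chroms)
        sums = np.zeros(max_n)
        npairs = np.zeros(max_n)
        for chrom in self.genome.chroms:
            mask = self.mask[chrom]
            if mask.all():
                warnings.warn(f"chromosome {chrom} fully masked; skipped")
                continue
            bal = self.balanced(chrom) if balanced \
                else self.masked_counts(chrom)
            n = bal.shape[0]
            for d in range(n):
                diag = np.diagonal(bal, offset=d)
                ok = ~np.isnan(diag)
                sums[d] += diag[ok].sum()
                npairs[d] += ok.sum()
        values = np.full(max_n, np.nan)
        nz = npairs > 0
        values[nz] = sums[nz] / npairs[nz]
        return ExpectedProfile(values=values, n_pairs=npairs.astype(np.int64))

    def obs_over_exp(self, expected: ExpectedProfile | None = None,
                     balanced: bool = True) -> dict[str, np.ndarray]:
        """Observed/expected maps; masked or undefined entries are NaN."""
        if expected is None:
            expected = self.expected_by_distance(balanced=balanced)
        out = {}
        for chrom in self.genome.chroms:
            bal = self.balanced(chrom) if balanced \
                else self.masked_counts(chrom)
            n = bal.shape[0]
            d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
            exp = expected.values[d]
            with np.errstate(invalid="ignore", divide="ignore"):
                oe = bal / exp
            oe[~np.isfinite(oe)] = np.nan
            out[chrom] = oe
        return out

    # ----------------------------------------------------------------- P(s)
    def contact_probability(self, log_bin_factor: float = 1.3,
                            smooth_window: int = 3) -> ContactProbabilityCurve:
        """P(s) over log-spaced distance bins, plus its log-log derivative.

        P is the mean raw contact count per pair in each distance bin,
        normalized so the curve sums to one (depth-invariant).  The
        derivative is taken by central differences on a rolling-mean
        smoothed log P vs log s.
        """
        if log_bin_factor <= 1:
            raise ValueError("log_bin_factor must exceed 1")
        bs = self.genome.bin_size
        max_sep = max(self.genome.n_bins(c) for c in self.genome.chroms) - 1
        edges = [1]
        while edges[-1] < max_sep:
            nxt = max(edges[-1] + 1, int(round(edges[-1] * log_bin_factor)))
            edges.append(nxt)
        edges = np.array(edges)
        nb = len(edges) - 1
        sums = np.zeros(nb)
        npairs = np.zeros(nb)
        for chrom in self.genome.chroms:
            mat = self.counts[chrom]
            n = mat.shape[0]
            for k in range(nb):
                for d in range(edges[k], min(edges[k + 1], n)):
                    diag = np.diagonal(mat, offset=d)
                    sums[k] += diag.sum()
                    npairs[k] += len(diag)
        keep = npairs > 0
        s = np.sqrt(edges[:-1] * edges[1:])[keep] * bs
        p = sums[keep] / npairs[keep]
        if p.sum() > 0:
            p = p / p.sum()
        if len(s) < 3:
            warnings.warn("fewer than 3 distance bins; derivative undefined")
            deriv = np.full(len(s), np.nan)
            return ContactProbabilityCurve(s=s, p=p, derivative=deriv)
        with np.errstate(divide="ignore"):
            logp = np.log(p)
            logs = np.log(s)
        # rolling mean over smooth_window log-bins before differencing
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        logp_s = np.convolve(np.pad(logp, pad, mode="edge"), kernel, "valid")
        deriv = np.full(len(s), np.nan)
        deriv[1:-1] = (logp_s[2:] - logp_s[:-2]) / (logs[2:] - logs[:-2])
        return ContactProbabilityCurve(s=s, p=p, derivative=deriv)
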
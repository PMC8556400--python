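"""Synthetic Hi-C / ChIP-seq / expression data with planted ground truth.

The contact-matrix generator uses a multiplicatively factorized expectation

    E[count(i, j)] = scale * |i - j|^(-alpha) * comp(i, j) * tad(i, j) * loop(i, j)

where ``comp`` multiplies homotypic (A-A or B-B) bin pairs by their
compartment multiplier and heterotypic pairs by the A-B multiplier, ``tad``
attenuates each pair by (1 - d_ins) per planted boundary it crosses, and
``loop`` multiplies planted anchor pixels by k_loop (with a 1-bin halo at
half effect, so donut scores are robust to off-by-one anchor binning).
Counts are Poisson draws around the expectation, symmetrized; ``scale`` is
set so the expected total count equals the requested sequencing depth.

A "KO-like" perturbation weakens A-A contacts, strengthens B-B contacts,
shallows boundary insulation, drops a subset of loops, and (on the ChIP
side) preferentially silences weakly bound peaks — emulating the loss of a
nuclear-matrix scaffold protein.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import GenomeModel
from .contacts import ContactMatrix

__all__ = [
    "PlantedTruth", "default_truth", "simulate_hic", "perturb_truth",
    "ChipSim", "simulate_chip", "simulate_expression",
]


@dataclass
class PlantedTruth:
    """Ground truth for one synthetic condition.

    ``labels[chrom]`` holds +1 (A) / -1 (B) per bin; ``boundaries[chrom]``
    is a sorted list of (bin index, insulation depth d_ins in [0, 1]);
    ``loops[chrom]`` is a list of (i, j, k_loop) with i < j and k_loop > 1.
    ``comp_aa``/``comp_bb``/``comp_ab`` are the homotypic/heterotypic
    contact multipliers; ``alpha`` the distance-decay exponent; ``depth``
    the expected total read count.  ``perturbation`` records what a KO-like
    perturbation changed (empty for a baseline truth).
    """

    labels: dict[str, np.ndarray]
    boundaries: dict[str, list[tuple[int, float]]]
    loops: dict[str, list[tuple[int, int, float]]]
    comp_aa: float
    comp_bb: float
    comp_ab: float
    alpha: float
    depth: float
    perturbation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, blist in self.boundaries.items():
            pos = [b for b, _ in blist]
            if pos != sorted(set(pos)):
                raise ValueError("boundaries must be sorted and unique")
            if any(not (0 <= d <= 1) for _, d in blist):
                raise ValueError("insulation depth must lie in [0, 1]")
        for chrom, llist in self.loops.items():
            for i, j, k in llist:
                if j <= i:
                    raise ValueError("loop anchors must be off-diagonal (i < j)")
                if k <= 1:
                    raise ValueError("loop enrichment k_loop must exceed 1")
        if min(self.comp_aa, self.comp_bb, self.comp_ab) < 0:
            raise ValueError("compartment multipliers must be non-negative")

    # ------------------------------------------------------------- JSON IO
    def to_json(self, path: str | None = None) -> str:
        obj = {
            "labels": {c: v.tolist() for c, v in self.labels.items()},
            "boundaries": {c: [[int(b), float(d)] for b, d in v]
                           for c, v in self.boundaries.items()},
            "loops": {c: [[int(i), int(j), float(k)] for i, j, k in v]
                      for c, v in self.loops.items()},
            "comp_aa": self.comp_aa, "comp_bb": self.comp_bb,
            "comp_ab": self.comp_ab, "alpha": self.alpha,
            "depth": self.depth, "perturbation": self.perturbation,
        }
        text = json.dumps(obj, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: str) -> "PlantedTruth":
        if source.lstrip().startswith("{"):
            obj = json.loads(source)
        else:
            with open(source) as fh:
                obj = json.load(fh)
        return cls(
            labels={c: np.asarray(v, dtype=np.int8)
                    for c, v in obj["labels"].items()},
            boundaries={c: [(int(b), float(d)) for b, d in v]
                        for c, v in obj["boundaries"].items()},
            loops={c: [(int(i), int(j), float(k)) for i, j, k in v]
                   for c, v in obj["loops"].items()},
            comp_aa=obj["comp_aa"], comp_bb=obj["comp_bb"],
            comp_ab=obj["comp_ab"], alpha=obj["alpha"],
            depth=obj["depth"], perturbation=obj.get("perturbation", {}),
        )


def default_truth(genome: GenomeModel, c_comp: float = 0.5,
                  block_bins: int = 20, tad_bins: int = 16,
                  d_ins: float = 0.6, n_loops: int = 30,
                  k_loop: float = 4.0, alpha: float = 1.0,
                  depth: float = 5_000_000, seed: int = 0) -> PlantedTruth:
    """Construct a baseline planted truth.

    Compartments alternate in blocks of ``block_bins`` (checkerboard); TAD
    boundaries are placed every ``tad_bins`` bins with +/-25% jitter; loops
    are placed at random anchor pairs 12-60 bins apart, kept pairwise
    separated (Chebyshev distance > 8 bins) and away from matrix edges.
    """
    if c_comp < 0 or c_comp >= 1:
        raise ValueError("c_comp must lie in [0, 1)")
    if alpha <= 0:
        raise ValueError("decay exponent alpha must be positive")
    rng = np.random.default_rng(seed)
    labels, boundaries, loops = {}, {}, {}
    for chrom in genome.chroms:
        n = genome.n_bins(chrom)
        lab = np.where((np.arange(n) // block_bins) % 2 == 0, 1, -1)
        labels[chrom] = lab.astype(np.int8)
        bpos = []
        pos = tad_bins
        while pos < n - 3:
            jitter = int(rng.integers(-tad_bins // 4, tad_bins // 4 + 1))
            p = min(max(pos + jitter, 3), n - 4)
            if not bpos or p - bpos[-1] >= 4:
                bpos.append(p)
            pos += tad_bins
        boundaries[chrom] = [(p, d_ins) for p in sorted(set(bpos))]
        # anchors need locally homogeneous context (no boundary or
        # compartment edge within `clear` bins) so the planted enrichment
        # factor is identifiable by a local background filter
        clear = 4
        bset = np.array(sorted({p for p, _ in boundaries[chrom]}))

        def _homogeneous(a: int) -> bool:
            lo, hi = a - clear, a + clear + 1
            if lo < 0 or hi > n:
                return False
            if len(bset) and np.any((bset > lo) & (bset < hi)):
                return False
            return bool((lab[lo:hi] == lab[a]).all())

        llist: list[tuple[int, int, float]] = []
        margin = 12
        attempts = 0
        while len(llist) < n_loops and attempts < n_loops * 500:
            attempts += 1
            i = int(rng.integers(margin, n - margin - 12))
            off = int(rng.integers(12, 61))
            j = i + off
            if j >= n - margin:
                continue
            if not (_homogeneous(i) and _homogeneous(j)):
                continue
            if any(max(abs(i - a), abs(j - b)) <= 8 for a, b, _ in llist):
                continue
            llist.append((i, j, float(k_loop)))
        loops[chrom] = sorted(llist)
    return PlantedTruth(
        labels=labels, boundaries=boundaries, loops=loops,
        comp_aa=1 + c_comp, comp_bb=1 + c_comp, comp_ab=max(1 - c_comp, 0.0),
        alpha=alpha, depth=depth)


def bias_tss_to_a(genome: GenomeModel, truth: PlantedTruth,
                  a_fraction: float = 0.75, seed: int = 0) -> GenomeModel:
    """Re-place TSS so ``a_fraction`` of genes fall in A-labelled bins.

    Emulates the gene-richness of the active compartment, which is what
    makes the TSS-density sign rule for PC1 orientation meaningful.  Gene
    ids and counts are preserved; only positions move.
    """
    if not 0 <= a_fraction <= 1:
        raise ValueError("a_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    tss = genome.tss.copy()
    bs = genome.bin_size
    for chrom in genome.chroms:
        lab = truth.labels[chrom]
        a_bins = np.nonzero(lab > 0)[0]
        b_bins = np.nonzero(lab < 0)[0]
        sel = (tss["chrom"] == chrom).to_numpy()
        n_g = sel.sum()
        if n_g == 0 or len(a_bins) == 0 or len(b_bins) == 0:
            continue
        in_a = rng.random(n_g) < a_fraction
        bins = np.where(in_a, rng.choice(a_bins, size=n_g),
                        rng.choice(b_bins, size=n_g))
        pos = bins * bs + rng.integers(0, bs, size=n_g)
        tss.loc[sel, "pos"] = pos
    return GenomeModel(chromsizes=genome.chromsizes, bin_size=bs, tss=tss)


def expected_matrix(genome: GenomeModel, truth: PlantedTruth,
                    chrom: str) -> np.ndarray:
    """Noise-free expectation (before depth scaling to counts)."""
    n = genome.n_bins(chrom)
    idx = np.arange(n)
    d = np.abs(np.subtract.outer(idx, idx))
    base = np.maximum(d, 1).astype(float) ** (-truth.alpha)

    lab = truth.labels[chrom].astype(float)
    same = np.equal.outer(lab, lab)
    a_pair = np.logical_and.outer(lab > 0, lab > 0)
    comp = np.where(a_pair, truth.comp_aa,
                    np.where(same, truth.comp_bb, truth.comp_ab))

    # cross-boundary attenuation applied once, at the deepest crossed boundary
    dmax = np.zeros((n, n))
    for b, dins in truth.boundaries[chrom]:
        crosses = np.not_equal.outer(idx < b, idx < b)
        np.maximum(dmax, np.where(crosses, dins, 0.0), out=dmax)
    tad = 1 - dmax

    loop = np.ones((n, n))
    for i, j, k in truth.loops[chrom]:
        halo = 1 + (k - 1) / 2
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                ii, jj = i + di, j + dj
                if 0 <= ii < n and 0 <= jj < n:
                    f = k if (di == 0 and dj == 0) else halo
                    loop[ii, jj] = max(loop[ii, jj], f)
                    loop[jj, ii] = loop[ii, jj]
    return base * comp * tad * loop


def simulate_hic(genome: GenomeModel, truth: PlantedTruth,
                 seed: int = 0) -> ContactMatrix:
    """Poisson-sample a contact matrix around the planted expectation."""
    if truth.alpha <= 0:
        raise ValueError("decay exponent alpha must be positive")
    for chrom in genome.chroms:
        if len(truth.labels[chrom]) != genome.n_bins(chrom):
            raise ValueError("truth labels inconsistent with genome binning")
    rng = np.random.default_rng(seed)
    counts = {}
    depth_per_chrom = truth.depth / len(genome.chroms)
    for chrom in genome.chroms:
        e = expected_matrix(genome, truth, chrom)
        total = np.triu(e).sum()
        scale = depth_per_chrom / total if total > 0 else 0.0
        lam = np.triu(e * scale)
        draw = rng.poisson(lam)
        mat = draw + np.triu(draw, 1).T
        counts[chrom] = mat.astype(float)
    return ContactMatrix(genome, counts)


def perturb_truth(truth: PlantedTruth, delta_aa: float = -0.2,
                  delta_bb: float = 0.2, delta_ins: float = 0.4,
                  loop_drop: float = 0.3, seed: int = 0) -> PlantedTruth:
    """KO-like perturbation of a planted truth.

    A-A multipliers are scaled by (1 + delta_aa), B-B by (1 + delta_bb);
    every insulation depth is scaled by (1 - delta_ins); a uniformly chosen
    ``loop_drop`` fraction of loops is removed.  The dropped loop set is
    recorded in ``perturbation``.
    """
    if not 0 <= delta_ins <= 1:
        raise ValueError("delta_ins must lie in [0, 1]")
    if not 0 <= loop_drop <= 1:
        raise ValueError("loop_drop must lie in [0, 1]")
    new_aa = truth.comp_aa * (1 + delta_aa)
    new_bb = truth.comp_bb * (1 + delta_bb)
    if new_aa <= 0 or new_bb <= 0:
        raise ValueError("perturbed compartment multipliers must stay positive")
    rng = np.random.default_rng(seed)
    new_bounds = {c: [(b, d * (1 - delta_ins)) for b, d in v]
                  for c, v in truth.boundaries.items()}
    new_loops, dropped = {}, {}
    for chrom, llist in truth.loops.items():
        n_drop = int(round(loop_drop * len(llist)))
        drop_idx = set(rng.choice(len(llist), size=n_drop, replace=False)
                       ) if n_drop else set()
        new_loops[chrom] = [l for k, l in enumerate(llist) if k not in drop_idx]
        dropped[chrom] = [list(llist[k]) for k in sorted(drop_idx)]
    record = {
        "delta_aa": delta_aa, "delta_bb": delta_bb, "delta_ins": delta_ins,
        "loop_drop": loop_drop, "dropped_loops": dropped,
    }
    return replace(truth, comp_aa=new_aa, comp_bb=new_bb,
                   boundaries=new_bounds, loops=new_loops,
                   perturbation=record)


# ---------------------------------------------------------------- ChIP-seq

@dataclass
class ChipSim:
    """Synthetic ChIP-seq experiment over two conditions.

    ``peaks``: one row per peak (chrom, start, end, strength, weak, lost).
    ``counts``: peak x sample read counts.  ``flank_counts``: background
    (flank-region) x sample read counts used for size-factor estimation.
    Samples are named ``<condition>_rep<i>``; condition 2 carries the
    peak-loss perturbation.
    """

    peaks: pd.DataFrame
    counts: pd.DataFrame
    flank_regions: pd.DataFrame
    flank_counts: pd.DataFrame
    library_sizes: dict[str, float]
    conditions: dict[str, str]


def simulate_chip(genome: GenomeModel, n_peaks: int = 600,
                  strength_mean: float = 60.0, strength_sigma: float = 0.8,
                  weak_quantile: float = 0.3, weak_loss_prob: float = 0.8,
                  strong_loss_prob: float = 0.02, background: float = 2.0,
                  library_sizes: dict[str, float] | None = None,
                  peak_width: int = 1000, n_reps: int = 2,
                  seed: int = 0) -> ChipSim:
    """Simulate binding peaks whose weak members are lost in condition 2.

    Peak strengths are log-normal; a peak is "weak" if its strength falls in
    the lowest ``weak_quantile`` of the distribution.  In condition 2 a weak
    peak collapses to flank background with probability ``weak_loss_prob``
    (strong peaks with the much smaller ``strong_loss_prob``).  Per-sample
    expected counts are strength x library scale; counts are Poisson.
    """
    if genome.n_bins() == 0:
        raise ValueError("empty genome")
    if not 0 <= weak_loss_prob <= 1:
        raise ValueError("weak_loss_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    samples = ([f"cond1_rep{i + 1}" for i in range(n_reps)]
               + [f"cond2_rep{i + 1}" for i in range(n_reps)])
    if library_sizes is None:
        library_sizes = {s: 1.0 for s in samples}
    conditions = {s: ("cond1" if s.startswith("cond1") else "cond2")
                  for s in samples}

    # non-overlapping peak placement
    rows = []
    for chrom, clen in genome.chromsizes.items():
        n_c = max(1, int(round(n_peaks * clen
                               / sum(genome.chromsizes.values()))))
        starts = np.sort(rng.integers(0, clen - peak_width, size=n_c))
        keep = np.concatenate([[True], np.diff(starts) >= peak_width])
        for s in starts[keep]:
            rows.append((chrom, int(s), int(s) + peak_width))
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    m = len(peaks)
    strength = background + strength_mean * rng.lognormal(
        0.0, strength_sigma, size=m)
    weak_cut = np.quantile(strength, weak_quantile)
    weak = strength <= weak_cut
    loss_p = np.where(weak, weak_loss_prob, strong_loss_prob)
    lost = rng.random(m) < loss_p
    peaks["strength"] = strength
    peaks["weak"] = weak
    peaks["lost"] = lost

    counts = {}
    for s in samples:
        scale = library_sizes[s]
        mean = strength.copy()
        if conditions[s] == "cond2":
            mean = np.where(lost, background, strength)
        counts[s] = rng.poisson(mean * scale)
    counts = pd.DataFrame(counts)

    # flank background regions (one synthetic 10 kb window per peak side)
    frows, fcounts = [], {s: [] for s in samples}
    for chrom, clen in genome.chromsizes.items():
        sub = peaks[peaks["chrom"] == chrom]
        for _, pk in sub.iterrows():
            for a, b in ((pk["start"] - 10_000, pk["start"]),
                         (pk["end"], pk["end"] + 10_000)):
                a, b = max(a, 0), min(b, clen)
                if b > a:
                    frows.append((chrom, a, b))
    flank_regions = pd.DataFrame(frows, columns=["chrom", "start", "end"])
    span = (flank_regions["end"] - flank_regions["start"]).to_numpy()
    for s in samples:
        scale = library_sizes[s]
        fcounts[s] = rng.poisson(background * scale * span / 10_000 * 10)
    flank_counts = pd.DataFrame(fcounts)
    return ChipSim(peaks=peaks, counts=counts, flank_regions=flank_regions,
                   flank_counts=flank_counts, library_sizes=library_sizes,
                   conditions=conditions)


# -------------------------------------------------------------- expression

def simulate_expression(genome: GenomeModel, lost_peaks: pd.DataFrame,
                        effect: float = 1.5, frac_linked: float = 0.8,
                        background_rate: float = 0.05, window: int = 25_000,
                        seed: int = 0) -> pd.DataFrame:
    """Per-gene differential-expression table linked to lost peaks.

    A gene whose TSS lies within ``window`` bp of a lost peak is flagged DE
    with probability ``frac_linked``; any other gene at ``background_rate``.
    Adjusted p-values are drawn below 0.05 for DE genes and above for the
    rest, so flags and p-values are consistent by construction.
    """
    if not 0 <= frac_linked <= 1:
        raise ValueError("frac_linked must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    tss = genome.tss
    near = np.zeros(len(tss), dtype=bool)
    for chrom in genome.chroms:
        gsel = (tss["chrom"] == chrom).to_numpy()
        if not gsel.any():
            continue
        pos = tss.loc[gsel, "pos"].to_numpy()
        sub = lost_peaks[lost_peaks["chrom"] == chrom]
        hit = np.zeros(gsel.sum(), dtype=bool)
        for _, pk in sub.iterrows():
            hit |= (pos >= pk["start"] - window) & (pos < pk["end"] + window)
        near[gsel] = hit
    de_prob = np.where(near, frac_linked, background_rate)
    de = rng.random(len(tss)) < de_prob
    n = len(tss)
    sign = rng.choice([-1.0, 1.0], size=n)
    log2fc = np.where(de, sign * (effect + rng.normal(0, 0.3, n)),
                      rng.normal(0, 0.2, n))
    padj = np.where(de, 10 ** rng.uniform(-8, np.log10(0.05), n),
                    rng.uniform(0.051, 1.0, n))
    return pd.DataFrame({
        "gene": tss["gene_id"].to_numpy(),
        "log2FC": log2fc,
        "pvalue": padj / 2,
        "padj": padj,
        "de": de,
        "near_lost_peak": near,
    })
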
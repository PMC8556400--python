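"""Configuration-driven two-condition comparison pipeline.

``run_pipeline`` sequences the full analysis on a synthetic two-condition
dataset with planted ground truth: simulate -> balance/obs-exp ->
compartments (PC1, saddle, strengths, difference) -> domains (insulation,
non-redundant boundaries, consensus TADs, paired differential test) ->
loops (IFnorm, donut calling, differential z-scores) -> ChIP association
(size factors, downsampling, gene scores, ventile/mHG) -> enrichment.
Every stage writes its artifacts under one run directory and the report
collects the headline numbers.  A single seed is fanned out to named
per-stage sub-seeds so each stage is individually reproducible.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chip, compartments, domains, loops, synthetic
from .contacts import ContactMatrix
from .genome import make_genome

__all__ = ["RunConfig", "run_pipeline", "simulate_command"]


@dataclass
class RunConfig:
    """All knobs of the two-condition comparison (defaults = demo scale)."""

    seed: int = 0
    outdir: str = "hicdelta_run"
    cond1: str = "parental"
    cond2: str = "ko"
    # genome / synthetic truth
    chrom_len: int = 15_000_000
    bin_size: int = 25_000
    n_genes: int = 300
    c_comp: float = 0.5
    block_bins: int = 20
    tad_bins: int = 16
    d_ins: float = 0.6
    n_loops: int = 30
    k_loop: float = 4.0
    alpha_decay: float = 1.0
    depth: float = 5_000_000
    n_reps: int = 2
    # KO-like perturbation
    delta_aa: float = -0.2
    delta_bb: float = 0.2
    delta_ins: float = 0.4
    loop_drop: float = 0.3
    # analysis thresholds
    n_quantiles: int = 50
    insulation_window: int = 250_000
    boundary_strength: float = 0.1
    merge_radius: int = 3
    tad_min_len: int = 6
    tad_p_gate: float = 0.05
    tad_fc_gate: float = 0.15
    loop_p: int = 25_000   # resolution-matched: one bin at the default grid
    loop_w: int = 75_000
    loop_alpha: float = 0.01
    loop_n_perm: int = 200
    loop_max_dist: int = 70
    z_threshold: float = 1.5
    tss_window: int = 25_000
    # ChIP / expression
    n_peaks: int = 600
    weak_loss_prob: float = 0.8
    frac_linked: float = 0.8

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _sub_seed(seed: int, name: str) -> int:
    """Stable named sub-seed below 2^31."""
    h = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def simulate_command(config: RunConfig) -> dict:
    """Generate the synthetic dataset on disk; returns in-memory handles."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    genome = make_genome(1, config.chrom_len, config.bin_size,
                         config.n_genes, seed=_sub_seed(config.seed, "genome"))
    truth1 = synthetic.default_truth(
        genome, c_comp=config.c_comp, block_bins=config.block_bins,
        tad_bins=config.tad_bins, d_ins=config.d_ins,
        n_loops=config.n_loops, k_loop=config.k_loop,
        alpha=config.alpha_decay, depth=config.depth,
        seed=_sub_seed(config.seed, "truth"))
    truth2 = synthetic.perturb_truth(
        truth1, delta_aa=config.delta_aa, delta_bb=config.delta_bb,
        delta_ins=config.delta_ins, loop_drop=config.loop_drop,
        seed=_sub_seed(config.seed, "perturb"))
    # gene-rich A compartment, so PC1 sign orientation is identifiable
    genome = synthetic.bias_tss_to_a(genome, truth1,
                                     seed=_sub_seed(config.seed, "tss"))
    matrices = {}
    for cond, truth in ((config.cond1, truth1), (config.cond2, truth2)):
        for rep in range(1, config.n_reps + 1):
            cm = synthetic.simulate_hic(
                genome, truth, seed=_sub_seed(config.seed, f"hic:{cond}:{rep}"))
            matrices[(cond, rep)] = cm
            cm.to_triples(str(out / f"contacts_{cond}_rep{rep}.tsv"))
    genome.bins().to_csv(out / "bins.tsv", sep="\t", index=False)
    truth1.to_json(str(out / f"truth_{config.cond1}.json"))
    truth2.to_json(str(out / f"truth_{config.cond2}.json"))
    chip_sim = synthetic.simulate_chip(
        genome, n_peaks=config.n_peaks, weak_loss_prob=config.weak_loss_prob,
        seed=_sub_seed(config.seed, "chip"))
    chip_sim.peaks.to_csv(out / "chip_peaks.tsv", sep="\t", index=False)
    chip_sim.counts.to_csv(out / "chip_counts.tsv", sep="\t", index=False)
    lost = chip_sim.peaks[chip_sim.peaks["lost"]]
    expr = synthetic.simulate_expression(
        genome, lost, frac_linked=config.frac_linked,
        window=config.tss_window, seed=_sub_seed(config.seed, "expr"))
    expr.to_csv(out / "expression.tsv", sep="\t", index=False)
    return {"genome": genome, "truth1": truth1, "truth2": truth2,
            "matrices": matrices, "chip": chip_sim, "expression": expr}


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the machine-readable report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(str(out / "config.yaml"))
    data = simulate_command(config)
    genome = data["genome"]
    conds = [config.cond1, config.cond2]
    report: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "conditions": conds,
    }

    # ---------------------------------------------------------- contacts
    pooled = {}
    oe_rep = {}
    for cond in conds:
        mats = [data["matrices"][(cond, r)] for r in range(1, config.n_reps + 1)]
        agg = ContactMatrix(genome, {
            c: sum(m.counts[c] for m in mats) for c in genome.chroms})
        agg.balance()
        pooled[cond] = agg
        # raw-count obs/exp: the generator has uniform bin visibility and
        # the KO contrast changes per-class contact totals, which ICE
        # weights would absorb (see methods note); balance() still
        # supplies the low-coverage mask
        for r, m in enumerate(mats, start=1):
            m.balance()
            oe_rep[(cond, r)] = m.obs_over_exp(balanced=False)
    oe = {cond: pooled[cond].obs_over_exp(balanced=False) for cond in conds}

    # ------------------------------------------------------ compartments
    tracks = {cond: compartments.compute_pc1(oe[cond], genome)
              for cond in conds}
    saddles = {cond: compartments.saddle(oe[cond], tracks[cond],
                                         n_quantiles=config.n_quantiles,
                                         exclude=("chrY", "chrM"))
               for cond in conds}
    strengths = {cond: compartments.compartment_strength(saddles[cond])
                 for cond in conds}
    sdiff = compartments.saddle_difference(saddles[config.cond1],
                                           saddles[config.cond2])
    np.savetxt(out / "saddle_difference.tsv", sdiff, delimiter="\t")
    for cond in conds:
        _write_bedgraph(out / f"pc1_{cond}.bedgraph", genome,
                        tracks[cond].pc1)
        np.savetxt(out / f"saddle_{cond}.tsv", saddles[cond].matrix,
                   delimiter="\t")
    report["compartments"] = {
        cond: {"a_strength": strengths[cond][0],
               "b_strength": strengths[cond][1]} for cond in conds}

    # ----------------------------------------------------------- domains
    ins = {cond: domains.insulation(
        {c: pooled[cond].balanced(c) for c in genome.chroms},
        config.bin_size, window=config.insulation_window) for cond in conds}
    bounds = {cond: domains.call_boundaries(ins[cond],
                                            config.boundary_strength)
              for cond in conds}
    merged = domains.merge_boundaries(list(bounds.values()),
                                      radius=config.merge_radius)
    reference = domains.reference_tads_standin(
        ins[config.cond1], config.boundary_strength, config.tad_min_len)
    tads = domains.consensus_tads(merged, reference,
                                  min_len=config.tad_min_len,
                                  pc1=tracks[config.cond1].pc1)
    rep_means = {
        cond: np.column_stack([
            domains.intra_tad_frequency(oe_rep[(cond, r)], tads)
            for r in range(1, config.n_reps + 1)])
        for cond in conds}
    diff_tads = domains.differential_tads(
        rep_means[config.cond1], rep_means[config.cond2],
        p_gate=config.tad_p_gate, fc_gate=config.tad_fc_gate)
    diff_tads = pd.concat([tads.reset_index(drop=True), diff_tads], axis=1)
    diff_tads.to_csv(out / "differential_tads.tsv", sep="\t", index=False)
    merged.to_csv(out / "boundaries.tsv", sep="\t", index=False)
    pileup = domains.boundary_pileup(
        oe, merged, config.bin_size, flank=config.insulation_window,
        insulation_by_cond=ins)
    np.savetxt(out / "boundary_pileup_log2.tsv", pileup["log2_ratio"],
               delimiter="\t")
    sig = diff_tads[diff_tads["significant"]]
    report["domains"] = {
        "n_boundaries": int(len(merged)),
        "n_consensus_tads": int(len(tads)),
        "n_significant_tads": int(len(sig)),
        "significant_by_compartment": {
            lab: int((sig["compartment"] == lab).sum()) for lab in ("A", "B")},
        "boundary_insulation_change": float(
            pileup["insulation_profiles"][config.cond2][
                config.insulation_window // config.bin_size]
            - pileup["insulation_profiles"][config.cond1][
                config.insulation_window // config.bin_size]),
    }

    # ------------------------------------------------------------- loops
    norms = {cond: loops.ifnorm(pooled[cond].counts, config.bin_size)
             for cond in conds}
    calls = {}
    smaps = {}
    for cond in conds:
        smaps[cond] = loops.donut_score(norms[cond], p=config.loop_p,
                                        w=config.loop_w,
                                        max_dist=config.loop_max_dist)
        calls[cond] = loops.call_loops(
            norms[cond], p=config.loop_p, w=config.loop_w,
            n_perm=config.loop_n_perm, alpha=config.loop_alpha,
            max_dist=config.loop_max_dist,
            seed=_sub_seed(config.seed, f"loops:{cond}"))
        _write_bedpe(out / f"loops_{cond}.bedpe", genome, calls[cond])
    dloops = loops.differential_loops(
        calls[config.cond1], smaps[config.cond1],
        calls[config.cond2], smaps[config.cond2],
        z_threshold=config.z_threshold)
    dloops.to_csv(out / "differential_loops.tsv", sep="\t", index=False)
    report["loops"] = {
        cond: {"n_loops": int(len(calls[cond]))} for cond in conds}
    report["loops"]["differential"] = {
        "n_lost": int((dloops["direction"] == "lost").sum()),
        "n_gained": int((dloops["direction"] == "gained").sum()),
    }

    # --------------------------------------------------- ChIP association
    chip_sim = data["chip"]
    per_sample_peaks = [chip_sim.peaks[["chrom", "start", "end"]]
                        for _ in chip_sim.counts.columns]
    union = chip.union_peaks(per_sample_peaks)
    flanks = chip.flank_regions(union, genome.chromsizes)
    q = chip.size_factors(chip_sim.flank_counts)
    down = chip.downsample(chip_sim.counts, q,
                           seed=_sub_seed(config.seed, "downsample"))
    diff_pk = chip.differential_peaks(down, chip_sim.conditions)
    diff_pk = pd.concat([chip_sim.peaks[["chrom", "start", "end"]],
                         diff_pk], axis=1)
    table = chip.gene_scores(diff_pk, genome.tss, window=config.tss_window)
    de_genes = set(data["expression"].loc[data["expression"]["de"], "gene"])
    assoc = chip.ventile_association(table, de_genes)
    table.to_csv(out / "gene_scores.tsv", sep="\t", index=False)
    # 2x2: near-lost-peak membership vs DE membership
    expr = data["expression"]
    a = int((expr["near_lost_peak"] & expr["de"]).sum())
    b = int((expr["near_lost_peak"] & ~expr["de"]).sum())
    c = int((~expr["near_lost_peak"] & expr["de"]).sum())
    d = int((~expr["near_lost_peak"] & ~expr["de"]).sum())
    fisher = chip.region_expression_fisher(np.array([[a, b], [c, d]]))
    report["chip_assoc"] = {
        "size_factors": {k: float(v) for k, v in q.items()},
        "n_union_peaks": int(len(union)),
        "n_flank_regions": int(len(flanks)),
        "ventile_counts": [int(v) for v in assoc["ventile_counts"]],
        "mhg_statistic": float(assoc["mhg_statistic"]),
        "mhg_p": float(assoc["p"]),
        "fisher_odds_ratio": fisher["odds_ratio"],
        "fisher_p": fisher["p"],
    }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    return report


def _write_bedgraph(path: Path, genome, values: dict[str, np.ndarray]) -> None:
    rows = []
    for chrom, vals in values.items():
        bs = genome.bin_size
        for i, v in enumerate(vals):
            if np.isfinite(v):
                rows.append((chrom, i * bs, (i + 1) * bs, v))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def _write_bedpe(path: Path, genome, loop_df: pd.DataFrame) -> None:
    bs = genome.bin_size
    rows = [(r["chrom"], r["bin1"] * bs, (r["bin1"] + 1) * bs,
             r["chrom"], r["bin2"] * bs, (r["bin2"] + 1) * bs, r["score"])
            for _, r in loop_df.iterrows()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)
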
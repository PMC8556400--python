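import numpy as np
import pandas as pd
import pytest

from hicdelta import domains, synthetic
from hicdelta.domains import (InsulationTrack, boundary_pileup,
                              call_boundaries, consensus_tads,
                              differential_tads, insulation,
                              intra_tad_frequency, merge_boundaries,
                              reference_tads_standin, tad_overlap_hypergeom)


# --------------------------------------------------------------- oracles

def greedy_merge_oracle(pool: pd.DataFrame, radius: int) -> list[tuple]:
    """Independent brute-force greedy: re-sort pool each round, accept the
    strongest remaining, delete everything within radius on its chromosome."""
    remaining = [tuple(r) for r in
                 pool[["chrom", "bin", "strength"]].itertuples(index=False)]
    accepted = []
    while remaining:
        best = max(remaining, key=lambda r: (r[2], -ord(r[0][-1]), -r[1]))
        accepted.append(best)
        remaining = [r for r in remaining
                     if not (r[0] == best[0] and abs(r[1] - best[1]) <= radius)]
    return sorted(accepted)


def interval_overlap_oracle(a, b, starts, ends):
    """Best fractional overlap of [a, b) with reference intervals, per base."""
    length = b - a
    best = 0.0
    for s, e in zip(starts, ends):
        ov = len(set(range(a, b)) & set(range(s, e)))
        best = max(best, ov / length)
    return best


# ------------------------------------------------------------ insulation

class TestInsulation:
    def test_uniform_matrix_constant_score_no_boundaries(self):
        mat = np.full((60, 60), 3.0)
        track = insulation({"chr1": mat}, 25_000)
        sc = track.scores["chr1"]
        assert np.allclose(sc[np.isfinite(sc)], 0.0, atol=1e-12)
        assert len(call_boundaries(track)) == 0

    def test_window_must_divide(self):
        with pytest.raises(ValueError):
            insulation({"chr1": np.ones((40, 40))}, 25_000, window=260_000)

    def test_edge_bins_have_no_score(self):
        mat = np.full((60, 60), 3.0)
        track = insulation({"chr1": mat}, 25_000)
        w = track.window_bins
        assert np.isnan(track.scores["chr1"][:w]).all()
        assert np.isnan(track.scores["chr1"][-w:]).all()

    def test_planted_boundary_detected_within_one_bin(self, genome400):
        hits = 0
        for seed in range(5):
            truth = synthetic.default_truth(genome400, d_ins=0.6, seed=seed)
            cm = synthetic.simulate_hic(genome400, truth, seed=100 + seed)
            cm.balance()
            track = insulation({"chr1": cm.balanced("chr1")}, 25_000)
            called = call_boundaries(track, 0.1)["bin"].to_numpy()
            planted = np.array([p for p, _ in truth.boundaries["chr1"]])
            inner = planted[(planted > 12) & (planted < 388)]
            rec = np.mean([np.min(np.abs(called - p)) <= 1 for p in inner])
            hits += rec >= 0.9
        assert hits >= 4

    def test_strength_monotone_in_planted_depth(self, genome400):
        means = []
        for d_ins in (0.3, 0.5, 0.7):
            truth = synthetic.default_truth(genome400, d_ins=d_ins, seed=4)
            cm = synthetic.simulate_hic(genome400, truth, seed=44)
            cm.balance()
            track = insulation({"chr1": cm.balanced("chr1")}, 25_000)
            planted = {p for p, _ in truth.boundaries["chr1"]}
            near = track.minima[
                track.minima["bin"].apply(
                    lambda b: min(abs(b - p) for p in planted) <= 1)]
            means.append(near["strength"].mean())
        assert means[0] < means[1] < means[2]


class TestCallAndMergeBoundaries:
    def _track(self, minima_rows):
        minima = pd.DataFrame(minima_rows,
                              columns=["chrom", "bin", "score", "strength"])
        return InsulationTrack(scores={}, minima=minima, window_bins=10,
                               bin_size=25_000)

    def test_threshold_limits(self):
        track = self._track([("chr1", 5, -1.0, 0.5), ("chr1", 9, -0.5, 0.05)])
        assert len(call_boundaries(track, np.inf)) == 0
        assert len(call_boundaries(track, 0.0)) == 2
        assert call_boundaries(track, 0.1)["bin"].tolist() == [5]

    def test_two_close_boundaries_stronger_survives(self):
        lists = [pd.DataFrame({"chrom": ["chr1"], "bin": [10],
                               "strength": [0.5]}),
                 pd.DataFrame({"chrom": ["chr1"], "bin": [12],
                               "strength": [0.9]})]
        out = merge_boundaries(lists, radius=3)
        assert out["bin"].tolist() == [12]

    def test_distant_boundaries_all_kept(self):
        lists = [pd.DataFrame({"chrom": "chr1", "bin": [0, 10, 20],
                               "strength": [0.2, 0.9, 0.4]})]
        out = merge_boundaries(lists, radius=3)
        assert out["bin"].tolist() == [0, 10, 20]

    def test_matches_independent_greedy_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            pool = pd.DataFrame({
                "chrom": rng.choice(["chr1", "chr2"], size=200),
                "bin": rng.integers(0, 300, size=200),
                "strength": np.round(rng.random(200), 6),
            })
            got = merge_boundaries([pool], radius=3)
            want = greedy_merge_oracle(pool, 3)
            got_set = sorted(tuple(r) for r in
                             got[["chrom", "bin", "strength"]]
                             .itertuples(index=False))
            assert got_set == want
            # pairwise separation > radius
            for chrom, sub in got.groupby("chrom"):
                assert (np.diff(sub["bin"]) > 3).all()


class TestConsensusTads:
    def test_exact_reference_match_kept(self):
        bounds = pd.DataFrame({"chrom": "chr1", "bin": [10, 20],
                               "strength": [1, 1]})
        refs = pd.DataFrame({"chrom": ["chr1"], "start_bin": [10],
                             "end_bin": [20]})
        out = consensus_tads(bounds, refs)
        assert out[["start_bin", "end_bin"]].values.tolist() == [[10, 20]]

    def test_short_potential_tad_removed(self):
        bounds = pd.DataFrame({"chrom": "chr1", "bin": [10, 15],
                               "strength": [1, 1]})
        refs = pd.DataFrame({"chrom": ["chr1"], "start_bin": [10],
                             "end_bin": [15]})
        assert len(consensus_tads(bounds, refs, min_len=6)) == 0

    def test_empty_reference_rejected(self):
        bounds = pd.DataFrame({"chrom": "chr1", "bin": [10, 20],
                               "strength": [1, 1]})
        with pytest.raises(ValueError):
            consensus_tads(bounds, pd.DataFrame(
                columns=["chrom", "start_bin", "end_bin"]))

    def test_overlap_decisions_match_interval_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            bpos = np.sort(rng.choice(100, size=6, replace=False))
            bounds = pd.DataFrame({"chrom": "chr1", "bin": bpos,
                                   "strength": 1.0})
            s = np.sort(rng.choice(100, size=3, replace=False))
            refs = pd.DataFrame({"chrom": "chr1", "start_bin": s,
                                 "end_bin": s + rng.integers(4, 30, size=3)})
            out = consensus_tads(bounds, refs, min_overlap=0.5, min_len=6)
            kept = {(r.start_bin, r.end_bin)
                    for r in out.itertuples(index=False)}
            for a, b in zip(bpos[:-1], bpos[1:]):
                expect = (b - a >= 6) and interval_overlap_oracle(
                    a, b, refs["start_bin"], refs["end_bin"]) > 0.5
                assert ((a, b) in kept) == expect

    def test_compartment_label_from_pc1_sign(self):
        bounds = pd.DataFrame({"chrom": "chr1", "bin": [0, 10, 20],
                               "strength": 1.0})
        refs = pd.DataFrame({"chrom": ["chr1", "chr1"],
                             "start_bin": [0, 10], "end_bin": [10, 20]})
        pc1 = {"chr1": np.concatenate([np.ones(10), -np.ones(10)])}
        out = consensus_tads(bounds, refs, pc1=pc1)
        assert out["compartment"].tolist() == ["A", "B"]


class TestReferenceStandin:
    def test_no_boundaries_whole_chromosome(self):
        mat = np.full((60, 60), 2.0)
        track = insulation({"chr1": mat}, 25_000)
        tads = reference_tads_standin(track)
        assert tads.values.tolist() == [["chr1", 0, 60]]

    def test_planted_domains_recovered(self, genome400, truth400, hic400):
        track = insulation({"chr1": hic400.balanced("chr1")}, 25_000)
        tads = reference_tads_standin(track)
        planted = [p for p, _ in truth400.boundaries["chr1"]]
        edges = np.unique(np.concatenate([tads["start_bin"],
                                          tads["end_bin"]]))
        hit = np.mean([np.min(np.abs(edges - p)) <= 1 for p in planted
                       if 12 < p < 388])
        assert hit >= 0.85

    def test_size_times_count_conserves_coverage(self, hic400):
        track = insulation({"chr1": hic400.balanced("chr1")}, 25_000)
        tads = reference_tads_standin(track, min_len=1)
        covered = (tads["end_bin"] - tads["start_bin"]).sum()
        assert covered == 400


class TestIntraTadFrequency:
    def test_unit_obsexp_gives_unit_means(self):
        tads = pd.DataFrame({"chrom": ["chr1"], "start_bin": [5],
                             "end_bin": [15]})
        oe = {"chr1": np.ones((30, 30))}
        assert intra_tad_frequency(oe, tads)[0] == pytest.approx(1.0)

    def test_constructed_domain_mean(self):
        oe = {"chr1": np.ones((30, 30))}
        oe["chr1"][5:15, 5:15] = 2.0
        tads = pd.DataFrame({"chrom": ["chr1"], "start_bin": [5],
                             "end_bin": [15]})
        assert intra_tad_frequency(oe, tads)[0] == pytest.approx(2.0)

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        mat = rng.random((50, 50))
        mat = (mat + mat.T) / 2
        tads = pd.DataFrame({"chrom": "chr1", "start_bin": [3, 20],
                             "end_bin": [14, 47]})
        got = intra_tad_frequency({"chr1": mat}, tads)
        for k, (a, b) in enumerate([(3, 14), (20, 47)]):
            vals = [mat[i, j] for i in range(a, b) for j in range(a, b)
                    if i < j]
            assert got[k] == pytest.approx(np.mean(vals))


class TestDifferentialTads:
    def test_identical_conditions_no_flags(self):
        x = np.tile([[1.0, 1.1]], (10, 1))
        out = differential_tads(x, x)
        assert not out["significant"].any()
        assert np.allclose(out["log2fc"], 0.0)

    def test_two_replicate_closed_form(self):
        """Paired t with n=2: t = mean(d) / (sd(d)/sqrt(2)), df = 1."""
        c1 = np.array([[1.0, 1.2]])
        c2 = np.array([[1.5, 1.5]])
        out = differential_tads(c1, c2)
        d = np.array([0.5, 0.3])
        t_expect = d.mean() / (d.std(ddof=1) / np.sqrt(2))
        p_expect = 2 * (0.5 - np.arctan(t_expect) / np.pi)  # t-cdf, df=1
        assert out["t"][0] == pytest.approx(t_expect)
        assert out["p"][0] == pytest.approx(p_expect, rel=1e-9)

    def test_zero_variance_reported_absent(self):
        out = differential_tads(np.array([[1.0, 1.0]]),
                                np.array([[2.0, 2.0]]))
        assert np.isnan(out["p"][0])
        assert not out["significant"][0]

    def test_double_gate_definition(self):
        out = differential_tads(np.array([[1.0, 1.001]]),
                                np.array([[1.0008, 1.0009]]))
        # tiny fold change: even if p small, |log2FC| <= 0.15 blocks the flag
        assert not out["significant"][0]

    def test_planted_direction_by_compartment(self, genome400, truth400,
                                              ko_pair):
        t2, cm1, cm2 = ko_pair
        oe1 = cm1.obs_over_exp(balanced=False)
        oe2 = cm2.obs_over_exp(balanced=False)
        lab = truth400.labels["chr1"]
        tads = []
        for (a, da), (b, _) in zip(truth400.boundaries["chr1"][:-1],
                                   truth400.boundaries["chr1"][1:]):
            if b - a >= 6:
                tads.append(("chr1", a, b, "A" if lab[a:b].mean() > 0 else "B"))
        tads = pd.DataFrame(tads, columns=["chrom", "start_bin", "end_bin",
                                           "compartment"])
        # single matrices per condition; emulate 2 replicates by splitting
        rng = np.random.default_rng(0)
        m1 = intra_tad_frequency(oe1, tads)
        m2 = intra_tad_frequency(oe2, tads)
        fc = np.log2(m2 / m1)
        a_fc = fc[tads["compartment"] == "A"]
        b_fc = fc[tads["compartment"] == "B"]
        assert np.nanmean(a_fc) < 0 < np.nanmean(b_fc)


class TestTadOverlapHypergeom:
    def test_full_overlap_boundary_case(self):
        u = set(range(10))
        k, expected, p = tad_overlap_hypergeom(u, u, u)
        assert k == 10
        assert expected == pytest.approx(10.0)
        assert p == pytest.approx(1.0)

    def test_disjoint_sets_no_enrichment(self):
        u = set(range(100))
        k, expected, p = tad_overlap_hypergeom(set(range(5)),
                                               set(range(50, 55)), u)
        assert k == 0
        assert p == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n_u = int(rng.integers(8, 13))
            universe = set(range(n_u))
            a = set(rng.choice(n_u, size=rng.integers(1, n_u),
                               replace=False).tolist())
            b = set(rng.choice(n_u, size=rng.integers(1, n_u),
                               replace=False).tolist())
            k, _, p = tad_overlap_hypergeom(a, b, universe)
            # enumerate all placements of |b| among n_u
            from itertools import combinations
            tail = sum(1 for comb in combinations(range(n_u), len(b))
                       if len(a & set(comb)) >= k)
            from math import comb as ncr
            assert p == pytest.approx(tail / ncr(n_u, len(b)), rel=1e-9)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            tad_overlap_hypergeom(set(), set(), set())


class TestBoundaryPileup:
    def test_identical_conditions_zero_difference(self):
        rng = np.random.default_rng(2)
        mat = rng.random((80, 80))
        mat = (mat + mat.T) / 2
        bounds = pd.DataFrame({"chrom": "chr1", "bin": [30, 50],
                               "strength": 1.0})
        out = boundary_pileup({"a": {"chr1": mat}, "b": {"chr1": mat}},
                              bounds, 25_000)
        assert np.allclose(out["log2_ratio"], 0.0)

    def test_aggregate_equals_stacked_window_mean(self):
        rng = np.random.default_rng(4)
        mat = rng.random((120, 120))
        mat = (mat + mat.T) / 2
        bins = [20, 40, 60, 80, 100, 25, 45, 65, 85, 105]
        bounds = pd.DataFrame({"chrom": "chr1", "bin": bins, "strength": 1.0})
        out = boundary_pileup({"a": {"chr1": mat}}, bounds, 25_000)
        w = 10
        stack = np.mean([mat[b - w:b + w + 1, b - w:b + w + 1]
                         for b in bins], axis=0)
        assert np.allclose(out["maps"]["a"], stack)

    def test_weakened_insulation_raises_cross_boundary_quadrants(
            self, genome400, truth400, ko_pair):
        t2, cm1, cm2 = ko_pair
        oe = {"wt": cm1.obs_over_exp(balanced=False),
              "ko": cm2.obs_over_exp(balanced=False)}
        planted = [p for p, _ in truth400.boundaries["chr1"] if 12 < p < 388]
        bounds = pd.DataFrame({"chrom": "chr1", "bin": planted,
                               "strength": 1.0})
        out = boundary_pileup(oe, bounds, 25_000)
        diff = out["log2_ratio"]
        w = 10
        off_diag = diff[:w - 2, w + 3:]  # cross-boundary quadrant
        assert np.nanmean(off_diag) > 0

    def test_unusable_boundaries_rejected(self):
        mat = np.ones((30, 30))
        bounds = pd.DataFrame({"chrom": "chr1", "bin": [2], "strength": 1.0})
        with pytest.raises(ValueError):
            boundary_pileup({"a": {"chr1": mat}}, bounds, 25_000)
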
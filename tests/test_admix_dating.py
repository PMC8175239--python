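"""Admixture dating: top-k segment lengths and ancestry-covariance decay."""

import numpy as np
import pandas as pd
import pytest

from archseg.admix_dating import (DecayCurve, date_from_top_segments, fit_decay,
                                  genetic_lengths, state_decay_curve)
from archseg.io_formats import GeneticMap
from archseg.segment_hmm import AncestrySegment
from archseg.synthetic_data import simulate_admixed_diploid, simulate_calls, simulate_map

from conftest import uniform_map


def segs_from_lengths(lengths_cM, spacing_bp=10_000_000):
    """Segments with the given genetic lengths on a uniform 1 cM/Mb map."""
    segs = []
    for i, length in enumerate(lengths_cM):
        start = 1 + i * spacing_bp
        segs.append(AncestrySegment("1", start, start + int(length * 1e4 * 100),
                                    n_sites=10, n_archaic=5, mean_posterior=0.95,
                                    length_cM=float(length)))
    return segs


class TestGeneticLengths:
    def test_span_between_anchors(self):
        gmap = GeneticMap({"1": (np.array([100, 200]), np.array([1.0, 2.5]))})
        seg = AncestrySegment("1", 100, 200, 5, 3, 0.9)
        genetic_lengths([seg], gmap)
        assert seg.length_cM == pytest.approx(1.5)

    def test_zero_width(self):
        gmap = uniform_map()
        seg = AncestrySegment("1", 500, 500, 1, 1, 0.9)
        genetic_lengths([seg], gmap)
        assert seg.length_cM == 0.0

    def test_linear_in_map(self):
        bp = np.array([1, 10_000_000])
        g1 = GeneticMap({"1": (bp, np.array([0.0, 10.0]))})
        g2 = GeneticMap({"1": (bp, np.array([0.0, 20.0]))})
        seg = AncestrySegment("1", 1_000_000, 4_000_000, 5, 3, 0.9)
        l1 = genetic_lengths([seg], g1)[0].length_cM
        l2 = genetic_lengths([seg], g2)[0].length_cM
        assert l2 == pytest.approx(2 * l1)

    def test_unknown_chromosome(self):
        with pytest.raises(KeyError):
            genetic_lengths([AncestrySegment("9", 1, 2, 1, 0, 0.5)], uniform_map())


class TestTopSegmentsDating:
    def test_closed_form(self):
        # 99 excesses averaging exactly 1/74 Morgan above the 100th longest
        k = 100
        base = 0.5                             # cM threshold (k-th longest)
        excess_cM = np.full(k - 1, 100.0 / 74)  # each excess = 1/74 Morgan
        lengths = np.concatenate([base + excess_cM, [base], np.full(50, 0.1)])
        date = date_from_top_segments(segs_from_lengths(lengths), k=k, n_boot=10)
        # g_hat = (k-1)/sum(E) = 99 / (99/74) = 74 exactly
        assert date.generations == pytest.approx(74.0)
        assert date.interval[0] < 74.0 < date.interval[1]

    def test_all_equal_lengths_degenerate(self):
        with pytest.raises(ValueError, match="no excess"):
            date_from_top_segments(segs_from_lengths(np.full(120, 1.0)),
                                   k=100, n_boot=0)

    def test_too_few_segments(self):
        with pytest.raises(ValueError, match="k=100"):
            date_from_top_segments(segs_from_lengths([1.0, 2.0]), k=100)

    def test_scale_consistency_cM_vs_morgan(self):
        rng = np.random.default_rng(7)
        lengths = rng.exponential(1 / 74, 300) * 100  # cM
        segs = segs_from_lengths(lengths)
        d_m = date_from_top_segments(segs, k=100, n_boot=0, unit="M")
        d_cm = date_from_top_segments(segs, k=100, n_boot=0, unit="cM")
        assert d_m.generations == pytest.approx(d_cm.generations)

    def test_exponential_limit_consistency(self):
        # i.i.d. exponential(g) lengths: estimator converges to g at large k
        rng = np.random.default_rng(11)
        g = 80.0
        lengths = rng.exponential(1 / g, 20_000) * 100
        date = date_from_top_segments(segs_from_lengths(lengths), k=10_000, n_boot=0)
        assert date.generations == pytest.approx(g, rel=0.02)

    def test_ci_covers_truth_on_simulated_tracts(self):
        # date the true heterozygous tracts directly (no HMM): exact-gamma CI
        # should cover the simulated truth in nearly all replicates
        g = 94.0
        hits = 0
        for seed in range(10):
            gmap = simulate_map(n_chrom=30, chrom_cM=115, n_anchors=3, seed=seed)
            truth = simulate_admixed_diploid(gmap, g, 0.032, seed=100 + seed)
            lengths = [e - s for chrom in truth.tracts
                       for hap in truth.tracts[chrom] for s, e, *_ in hap]
            date = date_from_top_segments(segs_from_lengths(lengths),
                                          k=100, n_boot=0)
            hits += date.interval[0] <= g <= date.interval[1]
        assert hits >= 9

    def test_bootstrap_interval_reported(self):
        rng = np.random.default_rng(3)
        lengths = rng.exponential(1 / 60, 200) * 100
        date = date_from_top_segments(segs_from_lengths(lengths), k=100,
                                      n_boot=200, rng_seed=1)
        lo, hi = date.bootstrap_interval
        assert lo < date.generations < hi


class TestDecayCurve:
    def test_iid_calls_have_no_decay_signal(self):
        gmap = uniform_map(length_cM=200)
        rng = np.random.default_rng(0)
        n = 5000
        pos = np.sort(rng.choice(np.arange(1, int(2e8)), n, replace=False))
        sites = pd.DataFrame({"chrom": "1", "pos": pos})
        calls = (rng.random(n) < 0.1).astype(np.int8)
        curve = state_decay_curve(sites, calls, gmap)
        mc_se = np.sqrt(0.1 * 0.9 * 0.1 * 0.9 / curve.pair_counts)
        assert np.all(np.abs(curve.covariance) < 3.5 * mc_se)

    def test_constant_calls_center_to_zero(self):
        gmap = uniform_map()
        pos = (np.arange(2000) + 1) * 10_000
        sites = pd.DataFrame({"chrom": "1", "pos": pos})
        curve = state_decay_curve(sites, np.ones(2000, dtype=np.int8), gmap)
        np.testing.assert_allclose(curve.covariance, 0.0, atol=1e-15)

    def test_no_pairs_in_range_errors(self):
        gmap = uniform_map()
        sites = pd.DataFrame({"chrom": "1", "pos": [1, 50_000_000]})
        with pytest.raises(ValueError, match="pairs"):
            state_decay_curve(sites, np.array([1, 0], dtype=np.int8), gmap)

    def test_decay_rate_visible_in_binned_covariance(self):
        # tracts simulated at g=63: covariance halves roughly every ln2/63 Morgans
        gmap = simulate_map(n_chrom=20, chrom_cM=115, seed=51)
        truth = simulate_admixed_diploid(gmap, 63.0, 0.032, seed=52)
        sites, calls = simulate_calls(truth, seed=53)
        curve = state_decay_curve(sites, calls, gmap)
        d = curve.bin_centers_cM / 100
        near = curve.covariance[d < 0.005].mean()
        far = curve.covariance[(d > 0.015) & (d < 0.02)].mean()
        implied_g = np.log(near / far) / (0.0175 - 0.0025)
        assert implied_g == pytest.approx(63.0, rel=0.35)


class TestFitDecay:
    def noiseless_curve(self, a=0.05, g=63.0, c=0.001):
        centers = np.arange(0.075, 2.0, 0.05)
        cov = a * np.exp(-g * centers / 100) + c
        pairs = np.full(len(centers), 10_000, dtype=np.int64)
        return DecayCurve(centers, cov, pairs)

    def test_noiseless_recovery(self):
        date = fit_decay(self.noiseless_curve())
        assert date.generations == pytest.approx(63.0, rel=1e-3)

    def test_flat_curve_rejected(self):
        curve = self.noiseless_curve(a=0.0)
        with pytest.raises(ValueError, match="no detectable decay|converge"):
            fit_decay(curve)

    def test_weight_scale_invariance(self):
        c1 = self.noiseless_curve()
        c2 = self.noiseless_curve()
        c2.pair_counts = c2.pair_counts * 2
        assert fit_decay(c1).generations == pytest.approx(fit_decay(c2).generations)

    def test_too_few_bins(self):
        curve = DecayCurve(np.array([0.1, 0.2, 0.3]), np.ones(3), np.ones(3, int))
        with pytest.raises(ValueError, match="5 bins"):
            fit_decay(curve)

    def test_jackknife_se_from_chromosome_partials(self):
        gmap = simulate_map(n_chrom=12, chrom_cM=115, seed=61)
        truth = simulate_admixed_diploid(gmap, 63.0, 0.032, seed=62)
        sites, calls = simulate_calls(truth, seed=63)
        date = fit_decay(state_decay_curve(sites, calls, gmap))
        assert date.se is not None and date.se > 0
        assert date.interval[0] < date.generations < date.interval[1]
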
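"""Two-state ancestry HMM: exact small-chain behaviour and segment calling."""

import itertools

import numpy as np
import pandas as pd
import pytest

from archseg.io_formats import Region
from archseg.segment_hmm import (AncestrySegment, HmmParams, decode_segments,
                                 estimate_background_rate, fit_params_baumwelch,
                                 forward_backward, intersect_with_regions,
                                 viterbi)
from archseg.synthetic_data import (simulate_admixed_diploid, simulate_calls,
                                    simulate_map)

from conftest import uniform_map


def enumerate_posteriors(obs, gaps, params):
    """Exhaustive-path oracle: posterior P(N) per site by summing all 2^T paths."""
    T = len(obs)
    piN = params.prior_N
    q = params.total_intensity
    pe = {0: params.p_archaic_given_H, 1: params.p_archaic_given_N}
    marg = np.zeros((T, 2))
    total = 0.0
    for path in itertools.product((0, 1), repeat=T):
        prob = piN if path[0] == 1 else 1 - piN
        prob *= pe[path[0]] if obs[0] == 1 else 1 - pe[path[0]]
        for t in range(1, T):
            s = 1 - np.exp(-q * gaps[t - 1])
            trans = {(0, 0): 1 - piN * s, (0, 1): piN * s,
                     (1, 0): (1 - piN) * s, (1, 1): 1 - (1 - piN) * s}
            prob *= trans[(path[t - 1], path[t])]
            prob *= pe[path[t]] if obs[t] == 1 else 1 - pe[path[t]]
        total += prob
        for t in range(T):
            marg[t, path[t]] += prob
    return marg[:, 1] / total, np.log(total)


def sites_frame(positions_bp, chrom="1"):
    return pd.DataFrame({"chrom": chrom, "pos": positions_bp,
                         "archaic_allele": "A", "other_allele": "G"})


class TestForwardBackward:
    @pytest.mark.parametrize("seed,T", [(0, 5), (1, 8), (2, 12)])
    def test_matches_exhaustive_enumeration(self, seed, T):
        rng = np.random.default_rng(seed)
        obs = rng.integers(0, 2, T).astype(np.uint8)
        gaps = rng.uniform(1e-4, 0.05, T - 1)
        params = HmmParams(0.5, 0.02, rate_in=2.0, rate_out=70.0)
        post, ll = forward_backward(obs, gaps, params)
        oracle_post, oracle_ll = enumerate_posteriors(obs, gaps, params)
        np.testing.assert_allclose(post, oracle_post, atol=1e-10)
        assert ll == pytest.approx(oracle_ll, abs=1e-10)

    def test_posteriors_normalized_on_long_chain(self):
        rng = np.random.default_rng(3)
        T = 200_000  # scaled arithmetic must survive very long chains
        obs = (rng.random(T) < 0.02).astype(np.uint8)
        gaps = np.full(T - 1, 1e-4)
        params = HmmParams()
        post, ll = forward_backward(obs, gaps, params)
        assert np.isfinite(ll)
        assert np.all((post >= 0) & (post <= 1))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            HmmParams(p_archaic_given_N=0.01, p_archaic_given_H=0.5).validate()
        with pytest.raises(ValueError, match="positive"):
            HmmParams(rate_in=-1.0).validate()


class TestDecodeSegments:
    def setup_method(self):
        self.gmap = uniform_map()
        self.params = HmmParams(0.5, 0.01, rate_in=2.4, rate_out=72.0)

    def test_background_only_calls_nothing(self):
        pos = (np.arange(500) + 1) * 10_000  # 0.01 cM spacing
        calls = np.zeros(500, dtype=np.int8)
        segs = decode_segments(sites_frame(pos), calls, self.gmap, self.params)
        assert segs == []

    def test_dense_archaic_run_called_once(self):
        pos = (np.arange(220) + 1) * 10_000
        calls = np.zeros(220, dtype=np.int8)
        calls[100:120] = 1
        segs = decode_segments(sites_frame(pos), calls, self.gmap, self.params)
        assert len(segs) == 1
        seg = segs[0]
        assert seg.start == pos[100] and seg.end == pos[119]
        assert seg.n_sites == 20 and seg.n_archaic == 20
        assert seg.mean_posterior >= 0.8
        # viterbi decoder agrees on this clean instance
        vsegs = decode_segments(sites_frame(pos), calls, self.gmap, self.params,
                                decoder="viterbi")
        assert len(vsegs) == 1 and vsegs[0].start == seg.start

    def test_uncovered_sites_skipped(self):
        pos = (np.arange(220) + 1) * 10_000
        calls = np.zeros(220, dtype=np.int8)
        calls[100:120] = 1
        calls[::7] = np.where(calls[::7] == 0, -1, calls[::7])
        segs = decode_segments(sites_frame(pos), calls, self.gmap, self.params)
        assert len(segs) == 1

    def test_min_posterior_monotone_in_called_length(self):
        gmap = simulate_map(n_chrom=2, chrom_cM=100, seed=11)
        truth = simulate_admixed_diploid(gmap, 74, 0.05, seed=12)
        sites, calls = simulate_calls(truth, seed=13)
        lengths = []
        for mp in (0.5, 0.7, 0.9, 0.99):
            segs = decode_segments(sites, calls, gmap, self.params, min_posterior=mp)
            lengths.append(sum(s.end - s.start + 1 for s in segs))
        assert lengths == sorted(lengths, reverse=True)

    def test_unsorted_sites_rejected(self):
        sites = sites_frame([2000, 1000])
        with pytest.raises(ValueError, match="unsorted"):
            decode_segments(sites, np.array([0, 0]), self.gmap, self.params)

    def test_recall_precision_on_long_tracts(self):
        # tracts >= 0.5 cM at 100 sites/cM should be recovered almost perfectly
        gmap = simulate_map(n_chrom=6, chrom_cM=115, seed=21)
        truth = simulate_admixed_diploid(gmap, 74, 0.032, seed=22)
        sites, calls = simulate_calls(truth, seed=23)
        segs = decode_segments(sites, calls, gmap, self.params)
        called = {}
        for s in segs:
            start_cm = float(gmap.interpolate(s.chrom, s.start))
            end_cm = float(gmap.interpolate(s.chrom, s.end))
            called.setdefault(s.chrom, []).append((start_cm, end_cm))

        def overlap(iv, ivs):
            return sum(max(0.0, min(iv[1], e) - max(iv[0], s)) for s, e in ivs)

        true_tracts = {}
        for chrom, haps in truth.tracts.items():
            for hap in haps:
                for s_cm, e_cm, *_ in hap:
                    true_tracts.setdefault(chrom, []).append((s_cm, e_cm))
        long_true = [(c, iv) for c, ivs in true_tracts.items()
                     for iv in ivs if iv[1] - iv[0] >= 0.5]
        recalled = sum(overlap(iv, called.get(c, [])) > 0.5 * (iv[1] - iv[0])
                       for c, iv in long_true)
        long_called = [(c, iv) for c, ivs in called.items()
                       for iv in ivs if iv[1] - iv[0] >= 0.5]
        precise = sum(overlap(iv, true_tracts.get(c, [])) > 0.5 * (iv[1] - iv[0])
                      for c, iv in long_called)
        assert recalled / max(len(long_true), 1) >= 0.9
        assert precise / max(len(long_called), 1) >= 0.9


class TestBackgroundRate:
    def test_no_archaic_is_floored(self):
        assert estimate_background_rate(np.zeros(5000, dtype=np.int8)) == 1e-4

    def test_uniform_rate_recovered(self):
        rng = np.random.default_rng(0)
        calls = (rng.random(50_000) < 0.10).astype(np.int8)
        assert estimate_background_rate(calls) == pytest.approx(0.10, abs=0.01)

    def test_tract_mixture_decomposed(self):
        # carriage ~2.7% from ~3% archaic at 50% emission over a ~1.2% background:
        # masking dense windows should recover the background, not the mixture
        gmap = simulate_map(n_chrom=10, chrom_cM=115, seed=31)
        truth = simulate_admixed_diploid(gmap, 74, 0.015, seed=32)
        _, calls = simulate_calls(truth, p_archaic_given_H=0.0124, seed=33)
        est = estimate_background_rate(calls)
        assert est == pytest.approx(0.0124, rel=0.25)
        assert est < calls[calls >= 0].mean()  # below the raw mixture rate

    def test_too_few_sites(self):
        with pytest.raises(ValueError, match="100"):
            estimate_background_rate(np.zeros(50, dtype=np.int8))


class TestBaumWelch:
    def test_zero_iterations_returns_init(self):
        gmap = uniform_map()
        pos = (np.arange(200) + 1) * 10_000
        calls = np.zeros(200, dtype=np.int8)
        init = HmmParams(0.5, 0.01, 2.0, 70.0)
        out = fit_params_baumwelch(sites_frame(pos), calls, gmap, init, max_iter=0)
        assert out == init

    @staticmethod
    def sample_from_chain(params, n_chrom=10, sites_per_chrom=10_000,
                          gap_morgan=1e-4, seed=0):
        """Draw observations from the HMM's own generative model."""
        rng = np.random.default_rng(seed)
        pos_parts, call_parts, chrom_parts = [], [], []
        s = 1 - np.exp(-params.total_intensity * gap_morgan)
        for c in range(1, n_chrom + 1):
            states = np.empty(sites_per_chrom, dtype=np.int8)
            states[0] = rng.random() < params.prior_N
            flips_to_n = rng.random(sites_per_chrom) < params.prior_N * s
            flips_to_h = rng.random(sites_per_chrom) < (1 - params.prior_N) * s
            for t in range(1, sites_per_chrom):
                states[t] = (flips_to_n[t] if states[t - 1] == 0
                             else not flips_to_h[t])
            p_emit = np.where(states == 1, params.p_archaic_given_N,
                              params.p_archaic_given_H)
            call_parts.append((rng.random(sites_per_chrom) < p_emit).astype(np.int8))
            pos_parts.append((np.arange(sites_per_chrom) + 1)
                             * int(gap_morgan * 1e8))  # 1 cM/Mb uniform map
            chrom_parts.extend([str(c)] * sites_per_chrom)
        sites = pd.DataFrame({"chrom": chrom_parts,
                              "pos": np.concatenate(pos_parts)})
        return sites, np.concatenate(call_parts)

    def test_loglik_monotone_and_params_recovered(self):
        # pi = 0.15 gives a few hundred tracts in 1e5 sites, enough for the
        # switch intensity to be identifiable to the asserted precision
        truth = HmmParams(0.5, 0.01, rate_in=74 * 0.15, rate_out=74 * 0.85)
        sites, calls = self.sample_from_chain(truth, seed=41)  # 1e5 sites
        gmap = uniform_map(chroms=[str(c) for c in range(1, 11)])
        fitted, hist = fit_params_baumwelch(sites, calls, gmap, truth,
                                            max_iter=15, tol=1e-8,
                                            return_history=True)
        assert np.all(np.diff(hist) >= -1e-6 * np.abs(hist[:-1]))
        assert fitted.p_archaic_given_N == pytest.approx(0.5, rel=0.2)
        assert fitted.p_archaic_given_H == pytest.approx(0.01, rel=0.2)
        assert fitted.total_intensity == pytest.approx(74.0, rel=0.2)
        assert fitted.prior_N == pytest.approx(0.15, rel=0.2)


class TestIntersect:
    def seg(self, chrom, start, end):
        return AncestrySegment(chrom, start, end, 10, 5, 0.9)

    def test_overlap_arithmetic(self):
        segments = [self.seg("1", 101, 200), self.seg("1", 151, 250),
                    self.seg("2", 1, 100)]
        regions = [Region("1", 0, 1000), Region("1", 200, 300), Region("3", 0, 10)]
        report = intersect_with_regions(segments, regions)
        assert list(report["n_segments"]) == [2, 1, 0]
        # seg2 half-open [150, 250) vs [200, 300) -> 50 bp
        assert list(report["overlap_bp"]) == [100 + 100, 50, 0]

    def test_nested_segment(self):
        report = intersect_with_regions([self.seg("1", 101, 200)],
                                        [Region("1", 0, 1000)])
        assert report.iloc[0]["overlap_bp"] == 100
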
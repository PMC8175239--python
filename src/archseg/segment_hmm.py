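"""Two-state HMM labelling segments of Neanderthal ancestry.

Hidden states: H (no archaic tract) and N (heterozygous archaic tract).
Observations are binary archaic-allele indicators at covered
Neanderthal-informative sites; inside a heterozygous tract the archaic
allele is drawn at roughly 50% frequency, outside at a small background
rate, and it is this contrast in spatial clustering that the chain
decodes.  Transitions follow a continuous-time two-state Markov chain
along the genetic coordinate: over an inter-site gap of d Morgans,

    P(H -> N) = pi_N * (1 - exp(-q d))
    P(N -> H) = (1 - pi_N) * (1 - exp(-q d))

with pi_N the stationary archaic prior and q the total switch
intensity per Morgan.  Forward-backward runs with per-site scaled
normalization, so chains of millions of sites cannot underflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .io_formats import GeneticMap

_EPS = 1e-12


@dataclass
class HmmParams:
    """Emission and switching parameters of the ancestry chain.

    ``rate_in`` / ``rate_out`` are the H->N and N->H switch intensities
    per Morgan; the stationary prior and total intensity are derived.
    Defaults follow :meth:`from_admixture`: an admixture proportion p
    and age g generations give rate_in = g*p, rate_out = g*(1-p), i.e.
    expected heterozygous-tract length 1/(g*(1-p)) Morgans.
    """

    p_archaic_given_N: float = 0.5
    p_archaic_given_H: float = 0.01
    rate_in: float = 75 * 0.03
    rate_out: float = 75 * 0.97

    @property
    def prior_N(self) -> float:
        return self.rate_in / (self.rate_in + self.rate_out)

    @property
    def total_intensity(self) -> float:
        return self.rate_in + self.rate_out

    @classmethod
    def from_admixture(cls, generations: float = 75.0, proportion: float = 0.03,
                       p_archaic_given_N: float = 0.5,
                       p_archaic_given_H: float = 0.01) -> "HmmParams":
        return cls(p_archaic_given_N, p_archaic_given_H,
                   generations * proportion, generations * (1.0 - proportion))

    def validate(self) -> None:
        for name in ("p_archaic_given_N", "p_archaic_given_H"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.p_archaic_given_N <= self.p_archaic_given_H:
            raise ValueError("p_archaic_given_N must exceed p_archaic_given_H")
        if self.rate_in <= 0 or self.rate_out <= 0:
            raise ValueError("switch intensities must be positive")


@dataclass
class AncestrySegment:
    """A called run of Neanderthal ancestry.

    Physical bounds are the first and last supporting site positions
    (1-based inclusive); genetic length is filled by the dating stage.
    """

    chrom: str
    start: int
    end: int
    n_sites: int
    n_archaic: int
    mean_posterior: float
    length_cM: float | None = None

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("segment start > end")
        if not 0 <= self.n_archaic <= self.n_sites:
            raise ValueError("n_archaic must lie in [0, n_sites]")
        if not 0.0 <= self.mean_posterior <= 1.0 + 1e-9:
            raise ValueError("mean posterior outside [0, 1]")


# ---------------------------------------------------------------------------
# chain preparation
# ---------------------------------------------------------------------------


def _chains(sites: pd.DataFrame, calls: np.ndarray, gmap: GeneticMap):
    """Split covered sites into per-chromosome chains.

    Yields (chrom, site_row_indices, obs uint8, gaps_morgan) with
    gaps_morgan of length len(obs)-1.  Raises on unsorted input.
    """
    calls = np.asarray(calls)
    if len(calls) != len(sites):
        raise ValueError("calls not aligned to sites")
    pos_all = sites["pos"].to_numpy()
    chrom_all = sites["chrom"].to_numpy()
    for chrom in pd.unique(chrom_all):
        m = chrom_all == chrom
        pos = pos_all[m]
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"sites unsorted on chromosome {chrom}")
        idx = np.flatnonzero(m)
        covered = calls[idx] >= 0
        idx = idx[covered]
        if idx.size == 0:
            continue
        cm = np.asarray(gmap.interpolate(str(chrom), pos_all[idx]), dtype=float)
        gaps = np.maximum(np.diff(cm) / 100.0, 1e-9)  # Morgans; zero gaps nudged
        yield str(chrom), idx, (calls[idx] == 1).astype(np.uint8), gaps


# ---------------------------------------------------------------------------
# forward-backward / Viterbi
# ---------------------------------------------------------------------------


def forward_backward(obs: np.ndarray, gaps_morgan: np.ndarray, params: HmmParams,
                     want_xi: bool = False):
    """Scaled forward-backward on one chain.

    Returns (posterior_N array, loglik) or, with ``want_xi``,
    (posterior_N, loglik, gamma (T,2), xi (T-1,2,2)) where state order
    is (H, N).  Posteriors at every site sum to one by construction.
    """
    params.validate()
    T = len(obs)
    pN, pH = params.p_archaic_given_N, params.p_archaic_given_H
    piN = params.prior_N
    piH = 1.0 - piN
    q = params.total_intensity

    eH = np.where(obs == 1, pH, 1.0 - pH)
    eN = np.where(obs == 1, pN, 1.0 - pN)
    s = -np.expm1(-q * np.asarray(gaps_morgan, dtype=float))  # 1 - exp(-qd)
    a_hn = piN * s          # P(H->N) per interval
    a_nh = piH * s          # P(N->H)

    alpha = np.empty((T, 2))
    c = np.empty(T)
    aH, aN = piH * eH[0], piN * eN[0]
    c0 = aH + aN
    alpha[0, 0], alpha[0, 1] = aH / c0, aN / c0
    c[0] = c0
    for t in range(1, T):
        hn, nh = a_hn[t - 1], a_nh[t - 1]
        prevH, prevN = alpha[t - 1, 0], alpha[t - 1, 1]
        aH = (prevH * (1.0 - hn) + prevN * nh) * eH[t]
        aN = (prevH * hn + prevN * (1.0 - nh)) * eN[t]
        ct = aH + aN
        alpha[t, 0], alpha[t, 1] = aH / ct, aN / ct
        c[t] = ct
    loglik = float(np.sum(np.log(c)))

    beta = np.empty((T, 2))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        hn, nh = a_hn[t], a_nh[t]
        bH = beta[t + 1, 0] * eH[t + 1]
        bN = beta[t + 1, 1] * eN[t + 1]
        beta[t, 0] = ((1.0 - hn) * bH + hn * bN) / c[t + 1]
        beta[t, 1] = (nh * bH + (1.0 - nh) * bN) / c[t + 1]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    post_N = gamma[:, 1]
    if not want_xi:
        return post_N, loglik

    xi = np.empty((T - 1, 2, 2))
    for t in range(T - 1):
        hn, nh = a_hn[t], a_nh[t]
        bH = beta[t + 1, 0] * eH[t + 1] / c[t + 1]
        bN = beta[t + 1, 1] * eN[t + 1] / c[t + 1]
        aHt, aNt = alpha[t, 0], alpha[t, 1]
        xi[t, 0, 0] = aHt * (1.0 - hn) * bH
        xi[t, 0, 1] = aHt * hn * bN
        xi[t, 1, 0] = aNt * nh * bH
        xi[t, 1, 1] = aNt * (1.0 - nh) * bN
        xi[t] /= xi[t].sum()
    return post_N, loglik, gamma, xi


def viterbi(obs: np.ndarray, gaps_morgan: np.ndarray, params: HmmParams) -> np.ndarray:
    """Most probable state path (0=H, 1=N), log-space."""
    params.validate()
    T = len(obs)
    pN, pH, piN = params.p_archaic_given_N, params.p_archaic_given_H, params.prior_N
    q = params.total_intensity
    le = np.stack([np.where(obs == 1, math.log(pH), math.log1p(-pH)),
                   np.where(obs == 1, math.log(pN), math.log1p(-pN))], axis=1)
    s = -np.expm1(-q * np.asarray(gaps_morgan, dtype=float))
    ptr = np.zeros((T, 2), dtype=np.int8)
    v = np.array([math.log(1 - piN), math.log(piN)]) + le[0]
    for t in range(1, T):
        hn = max(piN * s[t - 1], _EPS)
        nh = max((1 - piN) * s[t - 1], _EPS)
        lt = np.log(np.array([[1 - hn, hn], [nh, 1 - nh]]))
        scores = v[:, None] + lt
        ptr[t] = scores.argmax(axis=0)
        v = scores.max(axis=0) + le[t]
    path = np.empty(T, dtype=np.int8)
    path[-1] = v.argmax()
    for t in range(T - 1, 0, -1):
        path[t - 1] = ptr[t, path[t]]
    return path


# ---------------------------------------------------------------------------
# segment calling
# ---------------------------------------------------------------------------


def decode_segments(sites: pd.DataFrame, calls: np.ndarray, gmap: GeneticMap,
                    params: HmmParams, min_posterior: float = 0.8,
                    min_sites: int = 3, decoder: str = "posterior"
                    ) -> list[AncestrySegment]:
    """Call ancestry segments from pseudohaploid calls at informative sites.

    Maximal runs of covered sites with posterior(N) >= ``min_posterior``
    (or Viterbi state N, with ``decoder='viterbi'``) containing at least
    ``min_sites`` sites become segments; bounds are the first/last
    supporting site positions.
    """
    if not 0.0 < min_posterior <= 1.0:
        raise ValueError("min_posterior must lie in (0, 1]")
    if decoder not in ("posterior", "viterbi"):
        raise ValueError(f"unknown decoder {decoder!r}")
    calls = np.asarray(calls)
    pos_all = sites["pos"].to_numpy()
    segments: list[AncestrySegment] = []
    for chrom, idx, obs, gaps in _chains(sites, calls, gmap):
        if decoder == "posterior":
            post, _ = forward_backward(obs, gaps, params)
            in_state = post >= min_posterior
        else:
            path = viterbi(obs, gaps, params)
            in_state = path == 1
            post, _ = forward_backward(obs, gaps, params)
        boundaries = np.flatnonzero(np.diff(in_state.astype(np.int8)))
        starts = np.r_[0, boundaries + 1]
        ends = np.r_[boundaries, len(in_state) - 1]
        for s0, e0 in zip(starts, ends):
            if not in_state[s0] or e0 - s0 + 1 < min_sites:
                continue
            run = idx[s0:e0 + 1]
            segments.append(AncestrySegment(
                chrom=chrom,
                start=int(pos_all[run[0]]),
                end=int(pos_all[run[-1]]),
                n_sites=int(len(run)),
                n_archaic=int((calls[run] == 1).sum()),
                mean_posterior=float(post[s0:e0 + 1].mean()),
            ))
    segments.sort(key=lambda s: (s.chrom, s.start))
    return segments


def estimate_background_rate(calls: np.ndarray, window: int = 50,
                             dense_fraction: float = 0.25,
                             floor: float = 1e-4) -> float:
    """Moment estimate of the background archaic-call probability.

    The genome-wide archaic fraction is contaminated by true tracts, so
    covered calls are scanned in non-overlapping windows of ``window``
    sites and windows with archaic fraction >= ``dense_fraction``
    (provisional tract territory) are masked before averaging.  Floored
    at ``floor`` for numerical safety.
    """
    calls = np.asarray(calls)
    covered = calls[calls >= 0]
    if covered.size < 100:
        raise ValueError(f"need >= 100 covered sites, got {covered.size}")
    n_win = covered.size // window
    trimmed = covered[:n_win * window].reshape(n_win, window)
    frac = trimmed.mean(axis=1)
    keep = frac < dense_fraction
    if not keep.any():
        return float(max(covered.mean(), floor))
    return float(max(trimmed[keep].mean(), floor))


# ---------------------------------------------------------------------------
# Baum-Welch
# ---------------------------------------------------------------------------


def fit_params_baumwelch(sites: pd.DataFrame, calls: np.ndarray, gmap: GeneticMap,
                         init: HmmParams, max_iter: int = 100, tol: float = 1e-6,
                         return_history: bool = False):
    """Fit emissions and switch intensities by expectation-maximization.

    Emissions update in closed form from state posteriors; the
    stationary prior and total intensity maximize the expected
    complete-data transition log-likelihood numerically (a generalized
    M-step), so the observed-data log-likelihood is non-decreasing.
    A decrease beyond ``tol`` raises, as an implementation-bug guard.
    """
    init.validate()
    params = init
    chains = list(_chains(sites, calls, gmap))
    if not chains:
        raise ValueError("no covered sites to fit on")
    history: list[float] = []
    prev_ll = -np.inf
    for _ in range(max_iter):
        gam_arch = np.zeros(2)   # sum over sites of gamma weighted by obs==1
        gam_tot = np.zeros(2)
        first_gamma = np.zeros(2)
        xi_list, gap_list = [], []
        ll = 0.0
        for _, _, obs, gaps in chains:
            _, chain_ll, gamma, xi = forward_backward(obs, gaps, params, want_xi=True)
            ll += chain_ll
            w = (obs == 1).astype(float)
            gam_arch += gamma.T @ w
            gam_tot += gamma.sum(axis=0)
            first_gamma += gamma[0]
            xi_list.append(xi)
            gap_list.append(np.asarray(gaps, dtype=float))
        history.append(ll)
        if ll < prev_ll - tol * max(1.0, abs(prev_ll)):
            raise RuntimeError(f"EM log-likelihood decreased: {prev_ll} -> {ll}")
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * max(1.0, abs(prev_ll)):
            break
        prev_ll = ll

        p_H = float(np.clip(gam_arch[0] / max(gam_tot[0], _EPS), 1e-6, 1 - 1e-6))
        p_N = float(np.clip(gam_arch[1] / max(gam_tot[1], _EPS), 1e-6, 1 - 1e-6))
        if p_N <= p_H:  # keep the state identity fixed: N is the archaic-rich state
            p_N = min(p_H + 1e-6, 1 - 1e-6)

        xi_all = np.concatenate(xi_list, axis=0)
        gaps_all = np.concatenate(gap_list)

        def neg_q(theta):
            pi = 1.0 / (1.0 + np.exp(-theta[0]))
            q = np.exp(theta[1])
            s = np.clip(-np.expm1(-q * gaps_all), _EPS, 1 - _EPS)
            pi = np.clip(pi, _EPS, 1 - _EPS)
            la = np.stack([
                np.log1p(-pi * s), np.log(pi * s),
                np.log((1 - pi) * s), np.log1p(-(1 - pi) * s)], axis=1)
            trans = float(np.sum(xi_all.reshape(-1, 4) * la))
            init_term = float(first_gamma[0] * np.log1p(-pi) + first_gamma[1] * np.log(pi))
            return -(trans + init_term)

        theta0 = np.array([np.log(params.prior_N / (1 - params.prior_N)),
                           np.log(params.total_intensity)])
        res = minimize(neg_q, theta0, method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 400})
        theta = res.x if res.fun <= neg_q(theta0) else theta0
        pi_new = 1.0 / (1.0 + np.exp(-theta[0]))
        q_new = float(np.exp(theta[1]))
        params = HmmParams(p_N, p_H, rate_in=pi_new * q_new,
                           rate_out=(1 - pi_new) * q_new)
    if return_history:
        return params, np.array(history)
    return params


# ---------------------------------------------------------------------------
# interval intersection
# ---------------------------------------------------------------------------


def intersect_with_regions(segments: list[AncestrySegment], regions) -> pd.DataFrame:
    """Overlap report of called segments against annotated BED regions.

    ``regions`` are 0-based half-open (as read by
    :func:`archseg.io_formats.read_regions_bed`); segments' 1-based
    inclusive spans are converted before the half-open intersection
    arithmetic.  Returns one row per region with the overlapping
    segment count and total overlap in bp.
    """
    rows = []
    for region in regions:
        n_overlap = 0
        bp = 0
        for seg in segments:
            if seg.chrom != region.chrom:
                continue
            s0, e0 = seg.start - 1, seg.end  # to half-open
            ov = min(e0, region.end) - max(s0, region.start)
            if ov > 0:
                n_overlap += 1
                bp += ov
        rows.append((region.chrom, region.start, region.end, n_overlap, bp))
    return pd.DataFrame(rows, columns=["chrom", "start", "end",
                                       "n_segments", "overlap_bp"])
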
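"""Allele-sharing statistics (f3, f4, D), the f4-ratio ancestry estimator,
and weighted block-jackknife standard errors.

All statistics run on alternate-allele frequencies; a pseudohaploid
individual contributes frequencies in {0, 1}.  Sites missing in any
population required by a statistic are dropped for that statistic only.
Uncertainty comes from a weighted delete-one-block jackknife over
contiguous genomic blocks (default 5 Mb), the standard guard against
linkage along the chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import SitePanel, is_transition


@dataclass
class FStatResult:
    kind: str                     # f3 | f4 | D | f4ratio
    estimate: float
    se: float
    z: float
    n_sites: int
    n_blocks: int
    pseudohaploid_target: bool = False   # f3 only: no het correction applied

    def __post_init__(self):
        if self.kind == "D" and not -1.0000001 <= self.estimate <= 1.0000001:
            raise ValueError(f"D outside [-1, 1]: {self.estimate}")


def make_blocks(panel: SitePanel, block_mb: float = 5.0) -> np.ndarray:
    """Assign each panel site to a contiguous physical block.

    Blocks are ``block_mb`` megabases wide within each chromosome;
    returns an integer block id per site (ids are globally unique).
    """
    chroms = panel.sites["chrom"].to_numpy()
    pos = panel.sites["pos"].to_numpy()
    width = int(block_mb * 1e6)
    ids = np.empty(len(pos), dtype=np.int64)
    next_id = 0
    for chrom in pd_unique(chroms):
        m = chroms == chrom
        local = pos[m] // width
        _, inv = np.unique(local, return_inverse=True)
        ids[m] = inv + next_id
        next_id = ids[m].max() + 1 if m.any() else next_id
    return ids


def pd_unique(values: np.ndarray) -> np.ndarray:
    """Unique values in order of first appearance."""
    _, idx = np.unique(values, return_index=True)
    return values[np.sort(idx)]


def block_jackknife(block_estimates, block_weights, full_estimate: float | None = None
                    ) -> tuple[float, float]:
    """Weighted delete-one-block jackknife.

    ``block_estimates`` are leave-one-block-out estimates, ``block_weights``
    the deleted blocks' site counts.  With equal weights the standard
    error reduces to the classic delete-one formula
    sqrt((G-1)/G * sum((theta_bar - theta_i)^2)).
    """
    theta = np.asarray(block_estimates, dtype=float)
    w = np.asarray(block_weights, dtype=float)
    if theta.ndim != 1 or theta.shape != w.shape:
        raise ValueError("block estimates and weights must be 1-d and congruent")
    if len(theta) < 2:
        raise ValueError("need at least 2 blocks for a jackknife")
    if np.any(w <= 0):
        raise ValueError("block weights must be positive")
    n = w.sum()
    g = len(theta)
    if full_estimate is None:
        full_estimate = float(np.average(theta, weights=w))
    h = n / w
    # Busing-style weighted jackknife pseudovalues
    tau = h * full_estimate - (h - 1.0) * theta
    theta_j = float(g * full_estimate - np.sum((1.0 - w / n) * theta))
    var = float(np.sum((tau - theta_j) ** 2 / (h - 1.0)) / g)
    return full_estimate, float(np.sqrt(max(var, 0.0)))


def _gather(panel: SitePanel, pops, blocks, transversions_only: bool):
    freqs = []
    for p in pops:
        if p not in panel.freqs:
            raise ValueError(f"population {p!r} not in panel")
        freqs.append(np.asarray(panel.freqs[p], dtype=float))
    mask = np.ones(panel.n_sites, dtype=bool)
    for f in freqs:
        mask &= np.isfinite(f)
    if transversions_only:
        tv = np.array([not is_transition(r, a)
                       for r, a in zip(panel.sites["ref"], panel.sites["alt"])])
        mask &= tv
    if blocks is None:
        blocks = make_blocks(panel)
    blocks = np.asarray(blocks)
    if not mask.any():
        raise ValueError("no overlapping non-missing sites for the requested populations")
    return [f[mask] for f in freqs], blocks[mask]


def _block_sums(values: np.ndarray, blocks: np.ndarray):
    ids, inv = np.unique(blocks, return_inverse=True)
    sums = np.bincount(inv, weights=values)
    counts = np.bincount(inv)
    return sums, counts


def _linear_stat(terms: np.ndarray, blocks: np.ndarray, kind: str,
                 pseudohaploid_target: bool = False) -> FStatResult:
    sums, counts = _block_sums(terms, blocks)
    total, n = sums.sum(), counts.sum()
    full = total / n
    if len(sums) < 2:
        loo = np.array([full, full])
        est, se = full, 0.0
        n_blocks = 1
    else:
        loo = (total - sums) / (n - counts)
        est, se = block_jackknife(loo, counts, full_estimate=full)
        n_blocks = len(sums)
    z = est / se if se > 0 else np.inf * np.sign(est) if est else 0.0
    return FStatResult(kind, float(est), float(se), float(z), int(n),
                       n_blocks, pseudohaploid_target)


def compute_f4(panel: SitePanel, a: str, b: str, c: str, d: str,
               blocks=None, transversions_only: bool = False) -> FStatResult:
    """f4(A, B; C, D) = mean over sites of (a-b)(c-d) on alt frequencies."""
    (fa, fb, fc, fd), blk = _gather(panel, (a, b, c, d), blocks, transversions_only)
    return _linear_stat((fa - fb) * (fc - fd), blk, "f4")


def compute_f3(panel: SitePanel, x: str, a: str, b: str,
               blocks=None, transversions_only: bool = False,
               pseudohaploid_target: bool = False) -> FStatResult:
    """f3(X; A, B) = mean of (x-a)(x-b).

    No small-sample heterozygosity correction is applied; with a
    pseudohaploid target that omission is flagged in the result.
    """
    (fx, fa, fb), blk = _gather(panel, (x, a, b), blocks, transversions_only)
    return _linear_stat((fx - fa) * (fx - fb), blk, "f3",
                        pseudohaploid_target=pseudohaploid_target)


def _ratio_stat(num: np.ndarray, den: np.ndarray, blocks: np.ndarray,
                kind: str, den_tol: float = 1e-12) -> FStatResult:
    num_sums, counts = _block_sums(num, blocks)
    den_sums, _ = _block_sums(den, blocks)
    tot_num, tot_den, n = num_sums.sum(), den_sums.sum(), counts.sum()
    if abs(tot_den) < den_tol:
        raise ValueError("no informative sites (denominator ~ 0)")
    full = tot_num / tot_den
    if len(num_sums) < 2:
        return FStatResult(kind, float(full), 0.0, np.inf if full else 0.0, int(n), 1)
    loo = (tot_num - num_sums) / (tot_den - den_sums)
    est, se = block_jackknife(loo, counts, full_estimate=full)
    z = est / se if se > 0 else np.inf * np.sign(est) if est else 0.0
    return FStatResult(kind, float(est), float(se), float(z), int(n), len(num_sums))


def compute_d(panel: SitePanel, w: str, x: str, y: str, z: str,
              blocks=None, transversions_only: bool = False) -> FStatResult:
    """D(W, X; Y, Z) = sum (w-x)(y-z) / sum (w+x-2wx)(y+z-2yz).

    For haploid 0/1 frequencies this is the ABBA-BABA count statistic
    (nBABA - nABBA)/(nBABA + nABBA); the jackknife acts on the ratio.
    """
    (fw, fx, fy, fz), blk = _gather(panel, (w, x, y, z), blocks, transversions_only)
    num = (fw - fx) * (fy - fz)
    den = (fw + fx - 2 * fw * fx) * (fy + fz - 2 * fy * fz)
    return _ratio_stat(num, den, blk, "D")


def f4_ratio_ancestry(panel: SitePanel, outgroup: str, archaic_num: str,
                      test: str, african: str, archaic_denom: str,
                      blocks=None, transversions_only: bool = False) -> FStatResult:
    """Admixture proportion alpha by f4 ratio.

    alpha = f4(Outgroup, ArchaicNum; Test, African)
          / f4(Outgroup, ArchaicNum; ArchaicDenom, African),
    the excess allele sharing of the test genome with an archaic,
    normalized by the expected sharing between two archaics.  The
    jackknife deletes each block from numerator and denominator jointly.
    """
    (fo, fn, ft, fa, fd), blk = _gather(
        panel, (outgroup, archaic_num, test, african, archaic_denom),
        blocks, transversions_only)
    num = (fo - fn) * (ft - fa)
    den = (fo - fn) * (fd - fa)
    if abs(den.sum()) < 1e-12:
        raise ValueError("f4-ratio denominator below tolerance")
    return _ratio_stat(num, den, blk, "f4ratio")
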
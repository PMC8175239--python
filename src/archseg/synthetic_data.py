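"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here: a recombination
map, a diploid genome that is a recombination-driven mosaic of archaic
tracts, pseudohaploid observations at informative sites, and
allele-frequency panels for populations related by a tree with an
admixture edge.  All generators are deterministic per seed.

The tract model is a stationary two-state Markov mosaic along the
genetic coordinate (not a coalescent): g generations after an admixture
pulse contributing proportion p, each haplotype switches
archaic -> non-archaic at rate g*(1-p) per Morgan and back at rate g*p,
which makes heterozygous tract lengths exponential — exactly the
assumption the two dating methods rest on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GeneticMap


@dataclass
class SimTruth:
    """Ground truth of one simulated diploid genome.

    ``tracts[chrom][hap]`` is a list of (start_cM, end_cM, start_bp,
    end_bp) archaic tracts, non-overlapping within a haplotype.
    """

    generations: float
    proportion: float
    gmap: GeneticMap
    tracts: dict[str, tuple[list, list]]
    seed: int
    emission_rates: dict = field(default_factory=dict)

    def archaic_fraction(self) -> float:
        """Realized archaic fraction of genetic length, averaged over haplotypes."""
        total = 2.0 * self.gmap.total_cM()
        arch = sum(e - s for chrom in self.tracts
                   for hap in self.tracts[chrom]
                   for s, e, *_ in hap)
        return arch / total

    def n_tracts(self) -> int:
        return sum(len(hap) for chrom in self.tracts for hap in self.tracts[chrom])


def simulate_map(n_chrom: int = 30, chrom_cM: float = 115.0, n_anchors: int = 200,
                 rate_variability: float = 0.3, seed: int = 0) -> GeneticMap:
    """Simulate a recombination map with log-normal local rate variation.

    Each chromosome gets ``n_anchors`` anchors spanning exactly
    ``chrom_cM``; between anchors the local rate is log-normal with
    unit mean around 1 cM/Mb and sigma ``rate_variability`` (0 gives a
    uniform 1 cM/Mb map).
    """
    if n_chrom <= 0 or chrom_cM <= 0 or n_anchors < 2:
        raise ValueError("map dimensions must be positive (>= 2 anchors)")
    rng = np.random.default_rng(seed)
    anchors = {}
    d_cm = chrom_cM / (n_anchors - 1)
    for i in range(1, n_chrom + 1):
        if rate_variability > 0:
            rates = rng.lognormal(-rate_variability**2 / 2, rate_variability,
                                  n_anchors - 1)
        else:
            rates = np.ones(n_anchors - 1)
        bp_spans = np.maximum((d_cm / rates * 1e6).astype(np.int64), 1)
        bp = np.concatenate([[1], 1 + np.cumsum(bp_spans)])
        cm = np.linspace(0.0, chrom_cM, n_anchors)
        anchors[str(i)] = (bp, cm)
    gmap = GeneticMap(anchors=anchors, name=f"simulated(seed={seed})")
    gmap.validate()
    return gmap


def _mosaic_tracts(length_cM: float, g: float, p: float, rng: np.random.Generator
                   ) -> list[tuple[float, float]]:
    """Archaic tracts (start_cM, end_cM) of one haplotype mosaic."""
    if p <= 0:
        return []
    if p >= 1:
        return [(0.0, length_cM)]
    scale_arch = 100.0 / (g * (1.0 - p))    # mean archaic sojourn, cM
    scale_non = 100.0 / (g * p)
    tracts = []
    pos = 0.0
    archaic = rng.random() < p
    while pos < length_cM:
        sojourn = rng.exponential(scale_arch if archaic else scale_non)
        end = min(pos + sojourn, length_cM)
        if archaic and end > pos:
            tracts.append((pos, end))
        pos = end
        archaic = not archaic
    return tracts


def simulate_admixed_diploid(gmap: GeneticMap, g: float, p: float,
                             seed: int = 0) -> SimTruth:
    """Simulate both haplotypes of an admixed diploid as Markov mosaics.

    The initial state is archaic with probability p (stationarity), so
    the expected archaic fraction is exactly p and the expected
    heterozygous-tract length is 1/(g*(1-p)) Morgans.
    """
    if g <= 0:
        raise ValueError("generations must be positive")
    if not 0.0 <= p <= 1.0:
        raise ValueError("admixture proportion must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    tracts: dict[str, tuple[list, list]] = {}
    for chrom in gmap.chroms:
        length = gmap.length_cM(chrom)
        haps = []
        for _ in range(2):
            cm_tracts = _mosaic_tracts(length, g, p, rng)
            full = [(s, e,
                     int(gmap.physical(chrom, s)),
                     int(gmap.physical(chrom, e)))
                    for s, e in cm_tracts]
            haps.append(full)
        tracts[chrom] = (haps[0], haps[1])
    return SimTruth(generations=g, proportion=p, gmap=gmap, tracts=tracts, seed=seed)


def _tract_membership(cm_positions: np.ndarray, tracts: list) -> np.ndarray:
    """Boolean in-tract indicator for sorted tract list (genetic coords)."""
    if not tracts:
        return np.zeros(len(cm_positions), dtype=bool)
    edges = np.array([[s, e] for s, e, *_ in tracts]).ravel()
    return np.searchsorted(edges, cm_positions, side="right") % 2 == 1


def simulate_calls(truth: SimTruth, site_density_per_cM: float = 100.0,
                   p_archaic_given_N: float = 0.5,
                   p_archaic_given_H: float = 0.01,
                   missing_rate: float = 0.0, seed: int = 0
                   ) -> tuple[pd.DataFrame, np.ndarray]:
    """Place informative sites and draw pseudohaploid observations.

    Sites are uniform on the genetic coordinate (density per cM).  A
    site inside a heterozygous tract (exactly one haplotype archaic)
    shows the archaic allele with probability ``p_archaic_given_N``
    (~0.5 for an error-free single-read draw from a het); inside a
    homozygous tract with min(1, 2*p_archaic_given_N); outside tracts
    with the background rate.  ``missing_rate`` thins coverage.

    Returns a site table in :data:`archseg.ascertainment.SITE_COLUMNS`
    layout (plus a truth column ``n_archaic_haplotypes``) and the
    aligned call indicator array {1 archaic, 0 other, -1 missing}.
    """
    for name, v in (("p_archaic_given_N", p_archaic_given_N),
                    ("p_archaic_given_H", p_archaic_given_H),
                    ("missing_rate", missing_rate)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    gmap = truth.gmap
    p_hom = min(1.0, 2.0 * p_archaic_given_N)
    frames = []
    calls_parts = []
    for chrom in gmap.chroms:
        length = gmap.length_cM(chrom)
        n_sites = int(round(site_density_per_cM * length))
        if n_sites == 0:
            continue
        cm = np.sort(rng.uniform(0.0, length, n_sites))
        bp = np.asarray(gmap.physical(chrom, cm)).astype(np.int64)
        if n_sites > 1:  # break physical-position ties left by rounding
            bp += np.concatenate([[0], np.cumsum(np.diff(bp) == 0)])
        hap0, hap1 = truth.tracts[chrom]
        n_arch_hap = (_tract_membership(cm, hap0).astype(np.int8)
                      + _tract_membership(cm, hap1).astype(np.int8))
        p_emit = np.select([n_arch_hap == 0, n_arch_hap == 1],
                           [p_archaic_given_H, p_archaic_given_N], p_hom)
        calls = (rng.random(n_sites) < p_emit).astype(np.int8)
        if missing_rate > 0:
            calls[rng.random(n_sites) < missing_rate] = -1
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": bp, "archaic_allele": "A",
            "other_allele": "G", "archaic_is_alt": True,
            "african_freq": 0.0, "n_archaic_haplotypes": n_arch_hap,
        }))
        calls_parts.append(calls)
    sites = pd.concat(frames, ignore_index=True)
    truth.emission_rates = {"p_archaic_given_N": p_archaic_given_N,
                            "p_archaic_given_H": p_archaic_given_H,
                            "missing_rate": missing_rate,
                            "site_density_per_cM": site_density_per_cM}
    return sites, np.concatenate(calls_parts)


# ---------------------------------------------------------------------------
# frequency panels
# ---------------------------------------------------------------------------

#: default per-branch drift (Balding-Nichols c); larger = more drift
DEFAULT_DRIFT = {
    "outgroup": 0.3,        # root -> Outgroup
    "archaic_split": 0.2,   # root -> archaic ancestor
    "archaic_num": 0.05,    # archaic ancestor -> ArchaicNum
    "archaic_denom": 0.05,  # archaic ancestor -> admixture source
    "african": 0.05,        # root -> African ancestor
    "terminal": 0.02,       # each terminal branch below the admixture
}


def _drift(freq: np.ndarray, c: float, rng: np.random.Generator) -> np.ndarray:
    """One branch of Balding-Nichols drift: child ~ Beta with mean freq."""
    if c <= 0:
        return freq.copy()
    a = freq * (1.0 - c) / c
    b = (1.0 - freq) * (1.0 - c) / c
    return rng.beta(np.maximum(a, 1e-8), np.maximum(b, 1e-8))


def simulate_frequency_panels(n_sites: int = 200_000, alpha: float = 0.032,
                              drift_scales: dict | None = None, seed: int = 0,
                              n_chrom: int = 22, spacing_bp: int = 1000):
    """Allele-frequency panels on a tree with one admixture edge.

    Populations Outgroup, ArchaicNum, ArchaicDenom, African and Test
    descend from uniform ancestral frequencies; each branch applies
    Balding-Nichols drift (mean-preserving Beta around the parent
    frequency).  Test is built as alpha * archaic-source lineage +
    (1-alpha) * African lineage before its own terminal drift, so the
    f4-ratio estimand equals alpha exactly.

    Sites are laid out on ``n_chrom`` pseudo-chromosomes at
    ``spacing_bp`` so physical jackknife blocks behave normally.
    Returns a :class:`archseg.io_formats.SitePanel`.
    """
    from .io_formats import SitePanel

    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    c = dict(DEFAULT_DRIFT)
    if drift_scales:
        c.update(drift_scales)
    rng = np.random.default_rng(seed)

    anc = rng.uniform(0.05, 0.95, n_sites)
    outgroup = _drift(anc, c["outgroup"], rng)
    archaic_anc = _drift(anc, c["archaic_split"], rng)
    archaic_num = _drift(archaic_anc, c["archaic_num"], rng)
    source = _drift(archaic_anc, c["archaic_denom"], rng)   # admixture source lineage
    african_anc = _drift(anc, c["african"], rng)
    mixture = alpha * source + (1.0 - alpha) * african_anc
    term = c["terminal"]
    freqs = {
        "Outgroup": outgroup,
        "ArchaicNum": archaic_num,
        "ArchaicDenom": _drift(source, term, rng),
        "African": _drift(african_anc, term, rng),
        "Test": _drift(mixture, term, rng),
    }

    per_chrom = n_sites // n_chrom + 1
    chroms = np.array([str(i // per_chrom + 1) for i in range(n_sites)])
    pos = (np.arange(n_sites) % per_chrom + 1) * spacing_bp
    sites = pd.DataFrame({"chrom": chroms, "pos": pos, "ref": "A", "alt": "G"})
    counts = {p: np.full(n_sites, 100, dtype=int) for p in freqs}
    panel = SitePanel(sites=sites, freqs=freqs, counts=counts)
    panel.validate()
    return panel
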
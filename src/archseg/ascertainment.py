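"""Ascertainment of Neanderthal-informative sites and carriage summaries.

A site is informative when an archaic individual is homozygous for an
allele that is essentially absent (frequency <= ``max_minor_freq``)
among African alleles and absent from great-ape outgroups: observing
that allele in a test genome then points to introgression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .io_formats import SitePanel

logger = logging.getLogger(__name__)

_NON_AUTOSOMES = {"X", "Y", "MT", "M", "XY"}

#: column order of the ascertained-site table
SITE_COLUMNS = ["chrom", "pos", "archaic_allele", "other_allele",
                "archaic_is_alt", "african_freq"]


def _is_autosome(chrom: str) -> bool:
    name = str(chrom)
    if name.lower().startswith("chr"):
        name = name[3:]
    return name.upper() not in _NON_AUTOSOMES


def ascertain_informative_sites(panel: SitePanel, archaic: str, african: str,
                                outgroups: list[str] | tuple[str, ...] = (),
                                max_minor_freq: float = 0.001,
                                autosomes_only: bool = True) -> pd.DataFrame:
    """Return the table of Neanderthal-informative sites.

    A site qualifies iff the archaic population is homozygous (every
    sample, both chromosomes) for one allele, that allele's frequency
    among African alleles is <= ``max_minor_freq``, and the allele is
    absent from every outgroup population.  The rule is
    allele-symmetric: an archaic homozygous-reference site with Africans
    near-fixed for the alternate also qualifies.

    Returns a DataFrame with columns :data:`SITE_COLUMNS`, sorted by
    (chrom, pos).  Sites with a missing archaic genotype or missing
    African/outgroup frequency are skipped, not errors.
    """
    for pop in (archaic, african, *outgroups):
        if pop not in panel.freqs and pop not in panel.genotypes:
            raise ValueError(f"population {pop!r} not in panel")
    if archaic not in panel.genotypes or panel.genotypes[archaic].size == 0:
        raise ValueError(f"archaic population {archaic!r} has no diploid genotypes")

    g = panel.genotypes[archaic]           # (n_sites, n_samples)
    called = g >= 0
    all_called = called.all(axis=1)
    hom_alt = all_called & (g == 2).all(axis=1)
    hom_ref = all_called & (g == 0).all(axis=1)

    f_afr = panel.freqs[african]
    out_freqs = [panel.freqs[o] for o in outgroups]

    rows = []
    sites = panel.sites
    chroms = sites["chrom"].to_numpy()
    poss = sites["pos"].to_numpy()
    refs = sites["ref"].to_numpy()
    alts = sites["alt"].to_numpy()
    for i in range(panel.n_sites):
        if autosomes_only and not _is_autosome(chroms[i]):
            continue
        if hom_alt[i]:
            arch_is_alt = True
        elif hom_ref[i]:
            arch_is_alt = False
        else:
            continue
        fa = f_afr[i]
        if not np.isfinite(fa):
            continue
        arch_freq_afr = fa if arch_is_alt else 1.0 - fa
        if arch_freq_afr > max_minor_freq:
            continue
        absent_in_outgroups = True
        for fo in out_freqs:
            fi = fo[i]
            if not np.isfinite(fi):
                absent_in_outgroups = False
                break
            arch_freq_out = fi if arch_is_alt else 1.0 - fi
            if arch_freq_out > 0:
                absent_in_outgroups = False
                break
        if not absent_in_outgroups:
            continue
        archaic_allele = alts[i] if arch_is_alt else refs[i]
        other_allele = refs[i] if arch_is_alt else alts[i]
        rows.append((chroms[i], poss[i], archaic_allele, other_allele,
                     arch_is_alt, arch_freq_afr))
    out = pd.DataFrame(rows, columns=SITE_COLUMNS)
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


@dataclass
class CarriageSummary:
    """Archaic-allele carriage of the test individual at informative sites."""

    n_ascertained: int
    n_covered: int
    n_archaic_allele: int
    percent_archaic: float

    def __post_init__(self):
        if not 0 <= self.n_archaic_allele <= self.n_covered <= self.n_ascertained:
            raise ValueError("carriage counts violate 0 <= archaic <= covered <= ascertained")


def percent_one_decimal(numerator: int, denominator: int) -> float:
    """100*numerator/denominator rounded half-up to one decimal place."""
    if denominator == 0:
        return 0.0
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_carriage(sites: pd.DataFrame, calls: np.ndarray) -> CarriageSummary:
    """Count covered sites and archaic-allele carriage.

    ``calls`` is an int array aligned to ``sites`` rows with values
    1 (archaic allele drawn), 0 (other allele), -1 (missing/uncovered).
    """
    calls = np.asarray(calls)
    if len(calls) != len(sites):
        raise ValueError(f"{len(calls)} calls for {len(sites)} sites")
    covered = calls >= 0
    n_cov = int(covered.sum())
    n_arch = int((calls == 1).sum())
    return CarriageSummary(
        n_ascertained=len(sites),
        n_covered=n_cov,
        n_archaic_allele=n_arch,
        percent_archaic=percent_one_decimal(n_arch, n_cov),
    )


def calls_to_indicator(sites: pd.DataFrame, calls) -> np.ndarray:
    """Convert PseudohaploidCall records to the {1, 0, -1} indicator array."""
    arch = sites["archaic_allele"].to_numpy()
    out = np.full(len(sites), -1, dtype=np.int8)
    for i, call in enumerate(calls):
        if call.allele is None:
            continue
        out[i] = 1 if call.allele == arch[i] else 0
    return out
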
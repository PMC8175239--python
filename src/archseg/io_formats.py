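"""Readers, writers and the small data containers the pipeline moves around.

Formats covered: VCF site panels (via cyvcf2), recombination maps in the
HapMap/Oxford four-column dialect or PLINK ``.map`` dialect, and BED for
called ancestry segments.  Coordinate conventions: VCF and everything
in-memory are 1-based; BED on disk is 0-based half-open.  Genetic
positions are cumulative centimorgans; rates in map files are ignored
for interpolation (the cM column is authoritative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: transition SNP pairs (purine<->purine, pyrimidine<->pyrimidine)
TRANSITION_PAIRS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

#: number of bases at each read terminus masked for transition calls,
#: guarding against cytosine-deamination damage in ancient DNA
TERMINAL_TRIM_BP = 2


def is_transition(ref: str, alt: str) -> bool:
    return (ref.upper(), alt.upper()) in TRANSITION_PAIRS


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class SitePanel:
    """Per-site allele states for named populations.

    Attributes
    ----------
    sites : pandas.DataFrame
        Columns ``chrom, pos, ref, alt``; strictly sorted by
        (chrom, pos), one row per biallelic SNP.
    freqs : dict of str -> ndarray
        Alternate-allele frequency per population, NaN where every
        sample is missing.
    counts : dict of str -> ndarray
        Number of non-missing alleles behind each frequency.
    genotypes : dict of str -> ndarray
        Optional per-sample diploid dosage matrices (n_sites, n_samples),
        values in {0, 1, 2, -1=missing}.  Present for populations read
        from VCF; frequency-only panels leave this empty.
    samples : dict of str -> list of str
        Sample names per population, parallel to genotype columns.
    """

    sites: pd.DataFrame
    freqs: dict[str, np.ndarray] = field(default_factory=dict)
    counts: dict[str, np.ndarray] = field(default_factory=dict)
    genotypes: dict[str, np.ndarray] = field(default_factory=dict)
    samples: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def populations(self) -> list[str]:
        return list(self.freqs)

    def validate(self) -> None:
        """Raise ValueError on any violated container invariant."""
        chrom = self.sites["chrom"].to_numpy()
        pos = self.sites["pos"].to_numpy()
        if len(chrom) > 1:
            new_chrom = chrom[1:] != chrom[:-1]
            if not np.all((pos[1:] > pos[:-1]) | new_chrom):
                raise ValueError("positions must be strictly increasing within chromosomes")
            n_runs = 1 + int(new_chrom.sum())
            if n_runs != len(set(chrom)):
                raise ValueError("each chromosome's sites must form one contiguous run")
        for pop, f in self.freqs.items():
            if len(f) != self.n_sites:
                raise ValueError(f"frequency vector for {pop!r} has wrong length")
            finite = f[np.isfinite(f)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError(f"frequencies for {pop!r} outside [0, 1]")
        for pop, c in self.counts.items():
            if np.any(np.asarray(c) < 0):
                raise ValueError(f"negative allele count for {pop!r}")


@dataclass
class GeneticMap:
    """Piecewise-linear physical -> genetic coordinate transform.

    ``anchors`` maps chromosome name to a pair of parallel arrays
    (physical positions bp, cumulative cM), both strictly increasing
    in position and non-decreasing in cM.
    """

    anchors: dict[str, tuple[np.ndarray, np.ndarray]]
    dialect: str = "hapmap"
    name: str = "map"

    @property
    def chroms(self) -> list[str]:
        return list(self.anchors)

    def _require(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        try:
            return self.anchors[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in genetic map") from None

    def interpolate(self, chrom: str, pos) -> np.ndarray | float:
        """Genetic position (cM) at physical position(s); clamped outside anchors."""
        bp, cm = self._require(chrom)
        return np.interp(pos, bp, cm)

    def physical(self, chrom: str, cm_pos) -> np.ndarray | float:
        """Inverse transform, genetic (cM) -> physical (bp); clamped."""
        bp, cm = self._require(chrom)
        return np.interp(cm_pos, cm, bp)

    def length_cM(self, chrom: str) -> float:
        bp, cm = self._require(chrom)
        return float(cm[-1] - cm[0])

    def total_cM(self) -> float:
        return sum(self.length_cM(c) for c in self.chroms)

    def validate(self) -> None:
        for chrom, (bp, cm) in self.anchors.items():
            if len(bp) < 2:
                raise ValueError(f"chromosome {chrom!r}: need at least 2 anchors")
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"chromosome {chrom!r}: physical positions not strictly increasing")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"chromosome {chrom!r}: cM not non-decreasing")


def interpolate_cM(gmap: GeneticMap, chrom: str, pos) -> np.ndarray | float:
    """Functional alias for :meth:`GeneticMap.interpolate`."""
    return gmap.interpolate(chrom, pos)


@dataclass
class PseudohaploidCall:
    """A single randomly drawn read allele at one site."""

    site_index: int
    allele: str | None          # None == missing
    is_transition: bool = False
    n_reads: int = 0            # usable reads the draw was made from

    @property
    def missing(self) -> bool:
        return self.allele is None


@dataclass
class AlleleCounts:
    """Read support at a site, split by terminal-overlap status.

    ``*_terminal`` counts reads whose supporting base lies within
    :data:`TERMINAL_TRIM_BP` of either read terminus; those reads are
    discarded before drawing at transition sites.
    """

    ref_interior: int = 0
    ref_terminal: int = 0
    alt_interior: int = 0
    alt_terminal: int = 0

    def __post_init__(self):
        if min(self.ref_interior, self.ref_terminal, self.alt_interior, self.alt_terminal) < 0:
            raise ValueError("read counts must be nonnegative")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_site_panel(path: str, population_map: dict[str, list[str]]) -> SitePanel:
    """Read a VCF into a :class:`SitePanel` of per-population frequencies.

    Only biallelic SNP records are used; multiallelic and indel records
    are skipped (a count is logged).  Frequencies are computed from
    non-missing genotypes; a population with no called genotype at a
    site gets NaN there.

    Parameters
    ----------
    path : str
        VCF (plain or bgzipped).
    population_map : dict
        Population name -> list of sample names, all of which must be
        present in the VCF header.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)  # gt_types: 0/1/2 = alt dosage, 3 = missing
    header_samples = list(vcf.samples)
    sample_idx: dict[str, list[int]] = {}
    for pop, names in population_map.items():
        idx = []
        for name in names:
            if name not in header_samples:
                raise ValueError(f"sample {name!r} (population {pop!r}) not present in {path}")
            idx.append(header_samples.index(name))
        sample_idx[pop] = idx

    rows = []
    geno_rows: dict[str, list[list[int]]] = {pop: [] for pop in population_map}
    n_skipped = 0
    last_key: tuple[str, int] | None = None
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        key = (var.CHROM, var.POS)
        if last_key is not None and key <= last_key and key[0] == last_key[0]:
            raise ValueError(f"VCF not sorted at {var.CHROM}:{var.POS}")
        last_key = key
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        gt = var.gt_types
        dosage = {0: 0, 1: 1, 2: 2, 3: -1}
        for pop, idx in sample_idx.items():
            geno_rows[pop].append([dosage[int(gt[i])] for i in idx])
    if n_skipped:
        logger.info("skipped %d non-biallelic-SNP records in %s", n_skipped, path)

    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    freqs, counts, genos = {}, {}, {}
    for pop in population_map:
        g = np.asarray(geno_rows[pop], dtype=np.int8).reshape(len(sites), -1)
        genos[pop] = g
        called = g >= 0
        n_alleles = 2 * called.sum(axis=1)
        alt_alleles = np.where(called, g, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(n_alleles > 0, alt_alleles / np.maximum(n_alleles, 1), np.nan)
        freqs[pop] = f.astype(float)
        counts[pop] = n_alleles.astype(int)
    panel = SitePanel(sites=sites, freqs=freqs, counts=counts,
                      genotypes=genos, samples={p: list(s) for p, s in population_map.items()})
    panel.validate()
    return panel


# ---------------------------------------------------------------------------
# recombination maps
# ---------------------------------------------------------------------------


def read_genetic_map(path: str, dialect: str = "hapmap") -> GeneticMap:
    """Read a recombination map.

    dialect ``hapmap``: whitespace-separated ``chrom pos rate(cM/Mb) cM``
    with one header line allowed; dialect ``plink``: ``chrom id cM pos``.
    The cumulative-cM column is used directly; the rate column of the
    hapmap dialect is ignored.
    """
    if dialect not in ("hapmap", "plink"):
        raise ValueError(f"unknown map dialect {dialect!r}")
    per_chrom: dict[str, list[tuple[int, float]]] = {}
    last_cm: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if lineno == 1 and dialect == "hapmap":
                try:
                    float(parts[1])
                except ValueError:
                    continue  # header line
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            if dialect == "hapmap":
                chrom, pos, cm = parts[0], int(parts[1]), float(parts[3])
            else:
                chrom, pos, cm = parts[0], int(parts[3]), float(parts[2])
            if chrom in last_cm and cm < last_cm[chrom]:
                raise ValueError(f"{path}:{lineno}: cM decreases on chromosome {chrom}")
            last_cm[chrom] = cm
            per_chrom.setdefault(chrom, []).append((pos, cm))
    anchors = {}
    for chrom, pairs in per_chrom.items():
        pairs.sort()
        bp = np.array([p for p, _ in pairs], dtype=np.int64)
        cm = np.array([c for _, c in pairs], dtype=float)
        anchors[chrom] = (bp, cm)
    gmap = GeneticMap(anchors=anchors, dialect=dialect)
    gmap.validate()
    return gmap


def write_genetic_map(gmap: GeneticMap, path: str) -> None:
    """Write in the hapmap dialect (rate column recomputed from anchors)."""
    with open(path, "w") as fh:
        fh.write("chrom\tposition\trate_cM_Mb\tcM\n")
        for chrom, (bp, cm) in gmap.anchors.items():
            rates = np.append(np.diff(cm) / np.maximum(np.diff(bp), 1) * 1e6, 0.0)
            for p, r, c in zip(bp, rates, cm):
                fh.write(f"{chrom}\t{int(p)}\t{r:.6f}\t{c:.6f}\n")


# ---------------------------------------------------------------------------
# pseudohaploid calling
# ---------------------------------------------------------------------------


def pseudohaploid_call(counts: AlleleCounts, ref: str, alt: str,
                       site_index: int = 0, rng=None) -> PseudohaploidCall:
    """Draw one read allele uniformly at random (pseudohaploid genotype).

    At transition sites, reads whose supporting base sits within
    :data:`TERMINAL_TRIM_BP` of a read terminus are removed first — the
    usual guard against deamination damage.  With no usable read the
    call is missing.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    trans = is_transition(ref, alt)
    n_ref = counts.ref_interior + (0 if trans else counts.ref_terminal)
    n_alt = counts.alt_interior + (0 if trans else counts.alt_terminal)
    total = n_ref + n_alt
    if total == 0:
        return PseudohaploidCall(site_index, None, trans, 0)
    allele = alt if rng.integers(total) < n_alt else ref
    return PseudohaploidCall(site_index, allele, trans, total)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


@dataclass
class Region:
    """0-based half-open genomic interval with optional extra columns."""

    chrom: str
    start: int
    end: int
    extra: tuple = ()

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(f"region end < start: {self}")


def write_segments_bed(segments, path: str) -> None:
    """Write ancestry segments as BED (1-based inclusive spans -> 0-based half-open).

    Columns 5+ carry mean posterior, genetic length (cM), n_sites and
    n_archaic so that a round trip preserves the call's evidence.
    """
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tmean_posterior\tcM\tn_sites\tn_archaic\n")
        for i, seg in enumerate(segments):
            cm = "" if seg.length_cM is None else f"{seg.length_cM:.6f}"
            fh.write(f"{seg.chrom}\t{seg.start - 1}\t{seg.end}\tseg{i}\t"
                     f"{seg.mean_posterior:.6f}\t{cm}\t{seg.n_sites}\t{seg.n_archaic}\n")


def read_regions_bed(path: str) -> list[Region]:
    """Read a BED file into 0-based half-open :class:`Region` records."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from None
            regions.append(Region(parts[0], start, end, tuple(parts[3:])))
    return regions
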
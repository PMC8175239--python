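import numpy as np
import pandas as pd
import pytest

from archseg.io_formats import GeneticMap, SitePanel


def panel_from_freqs(freqs: dict, pos=None, chrom="1", ref="A", alt="G") -> SitePanel:
    """Build a frequency-only SitePanel from parallel per-population arrays."""
    n = len(next(iter(freqs.values())))
    if pos is None:
        pos = (np.arange(n) + 1) * 1000
    sites = pd.DataFrame({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt})
    f = {p: np.asarray(v, dtype=float) for p, v in freqs.items()}
    counts = {p: np.full(n, 100) for p in freqs}
    panel = SitePanel(sites=sites, freqs=f, counts=counts)
    panel.validate()
    return panel


def uniform_map(chroms=("1",), length_cM=100.0, cm_per_mb=1.0) -> GeneticMap:
    """Uniform-rate map: length_cM over length_cM/cm_per_mb Mb per chromosome."""
    anchors = {}
    for c in chroms:
        span_bp = int(length_cM / cm_per_mb * 1e6)
        anchors[str(c)] = (np.array([1, span_bp]), np.array([0.0, length_cM]))
    return GeneticMap(anchors=anchors, name="uniform")


@pytest.fixture
def toy_map():
    return uniform_map()


@pytest.fixture
def vcf_writer(tmp_path):
    """Write a small VCF from (chrom, pos, ref, alt, genotypes-per-sample) rows."""

    def write(records, samples, name="panel.vcf"):
        path = tmp_path / name
        lines = [
            "##fileformat=VCFv4.2",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        ]
        chroms = {r[0] for r in records}
        for c in sorted(chroms):
            lines.append(f"##contig=<ID={c}>")
        lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(samples))
        for chrom, pos, ref, alt, gts in records:
            lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                         + "\t".join(gts))
        path.write_text("\n".join(lines) + "\n")
        return str(path)

    return write
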
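"""Ascertain Neanderthal-informative sites from a VCF panel.

Writes a tiny VCF of one archaic genome, two Africans and a chimpanzee,
then keeps the sites where the archaic is homozygous for an allele
absent from the Africans (frequency <= 0.1%) and from the outgroup.
"""

import tempfile
from pathlib import Path

import archseg as A

VCF = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tnea\tmb1\tmb2\tchimp
1\t1000\t.\tA\tG\t.\tPASS\t.\tGT\t1/1\t0/0\t0/0\t0/0
1\t2000\t.\tC\tT\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\t0/0
1\t3000\t.\tA\tG\t.\tPASS\t.\tGT\t1/1\t0/1\t0/0\t0/0
1\t4000\t.\tC\tT\t.\tPASS\t.\tGT\t1/1\t0/0\t0/0\t1/1
1\t5000\t.\tA\tC\t.\tPASS\t.\tGT\t1/1\t0/0\t0/0\t0/0
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "panel.vcf"
    path.write_text(VCF)
    panel = A.read_site_panel(str(path), {"Nea": ["nea"],
                                          "Mbuti": ["mb1", "mb2"],
                                          "Chimp": ["chimp"]})
sites = A.ascertain_informative_sites(panel, "Nea", "Mbuti", ["Chimp"])
print(sites.to_string(index=False))
print(f"\n{len(sites)} of {panel.n_sites} sites are Neanderthal-informative")
# Rejected: pos 2000 (archaic heterozygous), pos 3000 (allele common in
# Africans), pos 4000 (allele shared with the chimpanzee outgroup).
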
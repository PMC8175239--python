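"""Simulate an admixed diploid genome and call its archaic segments.

Builds a 10-chromosome genome whose haplotypes are Markov mosaics of
Neanderthal tracts (3.2% ancestry, admixture 74 generations back),
draws pseudohaploid observations at 100 informative sites per cM, and
decodes segments with the two-state ancestry HMM.
"""

import archseg as A

gmap = A.simulate_map(n_chrom=10, chrom_cM=115, seed=1)
truth = A.simulate_admixed_diploid(gmap, g=74, p=0.032, seed=2)
sites, calls = A.simulate_calls(truth, seed=3)

summary = A.summarize_carriage(sites, calls)
print(f"simulated {summary.n_ascertained} informative sites; "
      f"{summary.percent_archaic}% carry the archaic allele")

background = A.estimate_background_rate(calls)
init = A.HmmParams.from_admixture(proportion=0.032, p_archaic_given_H=background)
params = A.fit_params_baumwelch(sites, calls, gmap, init, max_iter=8, tol=1e-4)
segments = A.decode_segments(sites, calls, gmap, params)
A.genetic_lengths(segments, gmap)

inside = sum(s.n_archaic for s in segments) / sum(s.n_sites for s in segments)
print(f"true heterozygous tracts: {truth.n_tracts()}; called segments: {len(segments)}")
print(f"archaic-allele frequency inside segments: {inside:.2f} "
      "(~0.5 expected for heterozygous tracts)")
print(f"longest segment: {max(s.length_cM for s in segments):.2f} cM")
# The ~50% within-segment frequency is the fingerprint of heterozygous
# Neanderthal ancestry: one chromosome archaic, one not.
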
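# Methods

This note documents the models behind `archseg`, the parameters that
matter, what the synthetic-data generator does and does not emulate,
and the numerical and design choices made where the design was open.

## Site ascertainment

A site is Neanderthal-informative when the archaic population is
homozygous (every sample, both chromosomes) for an allele whose
frequency among African alleles is ≤ `max_minor_freq` (default 0.001,
i.e. "not observed in more than 99.9% of Africans") and which is absent
from every great-ape outgroup. Three interpretation choices are made
explicit and exposed as parameters:

* the threshold is inclusive (frequency exactly 0.001 qualifies);
* outgroups act as hard filters (the allele must be absent), because
  ape panels are typically single genomes where a frequency threshold
  is meaningless; sites with a missing outgroup frequency are skipped
  conservatively;
* the rule is allele-symmetric: an archaic homozygous-reference site
  with Africans near-fixed for the alternate allele also qualifies.

Carriage percentages are rounded half-up to one decimal, matching how
such summaries are conventionally printed.

## Pseudohaploid calling

A genotype is a single read allele drawn uniformly at random. At
transition SNPs (A/G, C/T), reads whose supporting base lies within
2 bp of either read terminus are removed before the draw — the
standard guard against cytosine-deamination damage in ancient DNA.
The trim operates on per-read terminal-overlap counts supplied by the
caller rather than on alignments; the package consumes allele counts,
not BAMs. Whether a per-read or per-site masking rule better matches
existing callers at mixed sites is ambiguous; per-read is used here.

## f-statistics

All statistics run on alternate-allele frequencies; a pseudohaploid
individual contributes frequencies in {0, 1}. Per-site terms:
f4 = (a−b)(c−d); f3 = (x−a)(x−b) with no small-sample heterozygosity
correction (flagged in the result when the target is pseudohaploid);
D = Σ(w−x)(y−z) / Σ(w+x−2wx)(y+z−2yz). The f4-ratio ancestry estimator
divides block sums jointly, so each jackknife replicate deletes the
block from numerator and denominator together.

Uncertainty uses a weighted delete-one-block jackknife (Busing-style
pseudovalues) over contiguous physical blocks, default 5 Mb — the
field-standard scale at which linkage is broken. With equal weights it
reduces to the classic delete-one formula. Sites missing in any
population required by a statistic are dropped for that statistic only.
A transversions-only mode (damage guard) is available, default off.

## The ancestry HMM

Two hidden states: background (H) and heterozygous Neanderthal tract
(N). Homozygous tracts are not modelled separately: at ~3% ancestry
they arise with probability ~p² and are negligible; the simulator still
produces them and the decoder treats them as N. Observations are
binary archaic-allele indicators at covered informative sites.

Transitions follow a continuous-time two-state chain along the genetic
coordinate: over a gap of d Morgans, P(H→N) = π_N(1−e^(−qd)) and
P(N→H) = (1−π_N)(1−e^(−qd)), with stationary prior π_N and total
switch intensity q per Morgan. Defaults tie the chain to the admixture
model: π_N = p (0.03) and q = g with g = 75, i.e. expected tract length
1/(g(1−p)) Morgans; these are initialization only and Baum–Welch
refines them. Default emissions: 0.5 inside tracts (heterozygous
sampling), background fitted from the data by masking provisional
high-density windows (50-site windows with ≥ 25% archaic calls) and
flooring at 1e-4.

Numerics: forward–backward uses per-site scaled normalization, which is
algebraically equivalent to log-space arithmetic and cannot underflow
on chains of millions of sites (posterior normalization is tested at
2×10⁵ sites); zero genetic gaps are nudged to 1e-9 Morgans to keep the
transition matrix non-singular; Viterbi (available behind a flag) runs
in log space. Baum–Welch updates emissions in closed form and
maximizes the expected transition log-likelihood over (π_N, q)
numerically (Nelder–Mead on logit/log scales) — a generalized M-step
that keeps the observed-data log-likelihood non-decreasing; a decrease
beyond tolerance raises, as an implementation-bug guard. When the
emission labels threaten to swap, the archaic-rich state is pinned as N.

Segments are maximal runs of covered sites with posterior(N) ≥ 0.8 and
≥ 3 sites (posterior-run calling is more robust to isolated background
hits than raw Viterbi). Segment bounds are the first/last supporting
site positions — conservative, and the convention under which genetic
lengths are computed. The constant end-truncation this induces largely
cancels in the top-k dating, which uses only length differences.

## Dating

**Top-k segments.** Rank segments by genetic length (ranking by
physical length before scaling is the documented alternative), keep the
k = 100 longest, set the threshold t to the k-th longest. Under
per-generation exponential breakage the excesses over t of the other
k−1 lengths are exponential with rate g per Morgan (memorylessness), so
ĝ = (k−1)/ΣE. This threshold-excess form is preferred over fitting the
full length distribution because the short-length tail is shaped by the
min-sites/min-posterior calling thresholds, while excesses over the
100-th longest are not. The 95% interval is exact-gamma
(2gΣE ~ χ² with 2(k−1) df); a nonparametric bootstrap over segments is
reported alongside as a cross-check. Generations are per-Morgan rates;
no conversion to calendar years is provided.

**State decay.** For all within-chromosome pairs of covered sites with
genetic separation in [0.05, 2.0] cM, the products of globally
mean-centered archaic-state indicators are accumulated into 0.05-cM
bins; cov(d) = A·e^(−gd) + c is fitted by least squares weighted by
pair counts. The affine constant c absorbs long-range background
covariance (e.g. chromosome-scale fluctuations in realized tract
density); the lower bound of the fit range avoids zero-distance
artifacts. The fit initializes c from the curve tail, A from the first
bin and g from a log-linear regression, then refines with
`scipy.optimize.curve_fit`. A non-positive fitted amplitude or rate is
reported as "no detectable decay". The standard error is a
leave-one-chromosome-out jackknife of the whole curve-plus-fit, using
per-chromosome partial sums retained by the curve builder.

Under the simulator's emission model the call covariance is exactly
proportional to e^(−gd): the archaic-call probability is linear in the
number of archaic haplotypes (0.01, 0.5, 1.0), and each haplotype's
indicator is a two-state Markov chain with total intensity
g·p + g·(1−p) = g.

## The synthetic-data generator

The generator emulates the study conditions, not sequence data:

* **Maps** — 30 chromosomes × 115 cM (34.5 Morgans, roughly an
  autosomal genome), 200 anchors each, log-normal local rate variation
  (σ = 0.3) around 1 cM/Mb.
* **Genomes** — each haplotype is a stationary two-state Markov mosaic
  along the genetic coordinate: archaic→non at g(1−p), non→archaic at
  g·p per Morgan, initial state archaic with probability p. This
  matches the exponential-tract assumption the dating methods rest on;
  it is not a coalescent and carries no drift, no tract-length
  correlations and no background LD.
* **Calls** — sites uniform on the genetic coordinate at 100/cM
  (~345,000 sites per genome, similar in order to a genome-wide
  informative-site panel); archaic-allele probability 0.5 in
  heterozygous tracts, min(1, 2×0.5) in homozygous tracts, background
  0.01 outside; optional missingness thins coverage (default 0.0: the
  site table already represents covered sites, and partial coverage is
  an opt-in emulation).
* **Frequency panels** — five populations (Outgroup, two archaics,
  African, Test) on a fixed tree; each branch applies Balding–Nichols
  Beta drift (mean-preserving around the parent frequency), chosen over
  truncated-Gaussian perturbations because truncation at [0, 1] is not
  mean-preserving and would bias the f4-ratio away from the programmed
  α. Test = α·(archaic source) + (1−α)·(African lineage) before its
  terminal drift, so the f4-ratio estimand equals α exactly. Ancestral
  frequencies are uniform on [0.05, 0.95]; default drift scales
  (outgroup 0.3, archaic split 0.2, archaic terminals 0.05, African
  0.05, post-admixture terminals 0.02) give f4 signal-to-noise broadly
  comparable to hominin panels.

Because the generator implements the same breakage model the estimators
assume, passing recovery tests demonstrates correctness of the
inference machinery, not robustness to real-data violations (gene
conversion, tract clustering, reference bias, contamination, map
error). Map misspecification can be probed by decoding under a
different simulated map than the truth used to generate tracts.

## Problem sizes and determinism

Every generator is deterministic per seed (numpy Generator); the
pipeline forks one global seed per stage via `SeedSequence`, and
identical config yields byte-identical outputs. The bundled validation
runs use 20 replicates × 200,000 sites for the f4-ratio, and 10
replicates × 34.5-Morgan genomes (345,000 sites) for each dating
scenario — sizes at which the Monte-Carlo error of the replicate means
is a few percent, adequate for the recovery checks they support. The
HMM fit uses 8 EM iterations at tolerance 1e-4, which is past the point
where the segment calls stop changing materially.

## Known limitations

* Two states only: homozygous archaic tracts are folded into N rather
  than modelled; at ancestry proportions well above ~10% a three-state
  diploid model would be preferable.
* The background-rate moment estimator assumes tracts occupy a minority
  of windows; at very high ancestry it converges to the mixture rate.
* The decay fit's exponential-plus-constant family can trade amplitude
  against the constant when the fit range is short relative to 1/g;
  the default 0.05–2.0 cM range is adequate for g in the tens to low
  hundreds.
* Ascertainment requires diploid archaic genotypes; frequency-only
  archaic panels are rejected rather than guessed at.
* No contamination, damage or alignment modelling anywhere: inputs are
  assumed to be clean allele counts or genotypes.
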
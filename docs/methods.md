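# Methods

This note documents the models and procedures venomkit implements, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical conventions fixed where published variants
of the methods differ.

## NG86 Ka/Ks estimation

For a frame-aligned pair of coding sequences, each codon contributes
fractional synonymous sites s = (number of synonymous single-nucleotide
neighbors)/3 and nonsynonymous sites n = 3 − s, under the standard genetic
code (translation table 1, fixed). Changes that would create a stop codon
count as nonsynonymous, which keeps s + n = 3 exactly. S and N for the pair
are the means of the two sequences' per-sequence totals. Differences between
codons are classified directly when one position differs; with two or three
differences the synonymous/nonsynonymous step counts are averaged with equal
weight over the 2 or 6 mutational pathways, excluding pathways that pass
through a stop codon (if every pathway does, all are used and a warning is
logged; this affects a handful of the 61×61 sense-codon pairs). The
proportions pS = Sd/S and pN = Nd/N are corrected with Jukes–Cantor,
d = −(3/4)·ln(1 − 4p/3).

Conventions fixed here because published NG86 implementations differ:

* **Masking.** Any codon column containing a gap, an ambiguous base, or an
  in-frame stop in either sequence is dropped pairwise — a deterministic
  replacement for manual alignment curation. A pair with no surviving column
  is rejected.
* **Jukes–Cantor domain.** p ≥ 3/4 leaves the distance undefined (NaN,
  flagged `correction_undefined_s`/`_n`), never clamped.
* **Undefined ratios.** Ks = 0 with Ka > 0 yields an infinite-ratio
  sentinel; Ks = 0 with Ka = 0 (identical sequences) yields NaN with an
  `identical` flag. Sentinel ratios are excluded from group means and
  counted. `classify_selection` maps any non-finite ratio, and exactly 1,
  to `undefined`.
* **Precision.** No internal rounding; report formatting is 3 decimals.

The estimator is validated two ways: exhaustive pathway enumeration (an
independent implementation translating each step with Biopython) over all
61×61 sense-codon pairs, and parameter recovery on simulated pairs (below).

## Group statistics and the acceleration rule

Within one family and one label (SV or NV), all unordered pairs are
estimated; retained (finite) ratios give the group mean and the standard
error using the n−1 sample standard deviation over √n. Groups with fewer
than two usable genes or fewer than two retained ratios are undefined.

A family is flagged *accelerated* when a one-sided two-sample location test
(SV > NV) on the retained ratios rejects at α = 0.05 — Welch's t when both
groups hold at least five ratios, otherwise a permutation test on the mean
difference (9,999 resamples, internally seeded so results are
deterministic). Whether the SV mean exceeds 1 is reported as a separate
field: an SV group can evolve significantly faster than its NV paralogs
while its mean ratio stays below 1, so the two readings must not be
conflated. Families with a single SV copy have no SV pairs and their
acceleration flag is undefined (reported as not flagged).

Duplication categories are a pure function of the SV copy number: 1 → I,
2–4 → II, ≥5 → III. Observed highly expanded families have 9–11 SV copies;
the ≥5 boundary makes the map total over the unobserved 5–8 range. Ks strata
use half-open bins [0, 0.2), [0.2, 0.5), [0.5, ∞) by default — Ks is
roughly clock-like, so the strata order duplication events in time.

## Microchromosome enrichment

Scaffolds are anchored through synteny markers: every gene on a scaffold
carrying at least one marker inherits the marker's chromosome; scaffolds
whose markers disagree are left unanchored (conservative; no majority vote).
The focal-vs-other MIC/MAC table is tested with a two-sided Fisher exact
test under the probability-mass convention — the sum of hypergeometric
probabilities of all tables with the observed margins whose probability does
not exceed the observed table's (relative slack 1e-12 on the comparison) —
computed from log-factorials. This is the convention of standard exact-test
implementations; the test suite verifies agreement with an independent PMF
enumeration for every margin configuration with N ≤ 60 and with
scipy.stats.fisher_exact on spot tables. Fractions are reported as
round-half-up integer percentages to match printed-table formatting. GC
content over scaffold sets is the length-weighted pooled fraction, not the
mean of per-scaffold fractions.

## Genome size

The k-mer estimator discards histogram entries below the error cutoff
(default depth 10, covering the error/heterozygosity shoulder), takes the
modal depth of the remainder as peak coverage (ties resolve to the lowest
depth, logged), and divides the retained k-mer instances by the peak. The
estimate is invariant to any amount of sub-cutoff error mass and scales
linearly with counts. One caveat the tests document: at an *integer*
Poisson mean λ the pmf ties exactly at λ−1 and λ, so the empirical mode of
a simulated histogram can land one below the nominal depth, bounding
recovery error by ~1/λ rather than pure sampling noise.

Flow-cytometry size is ordinary least squares of reference genome size on
fluorescence, evaluated at the sample's fluorescence; with two references
this is exact linear interpolation.

## Tree scenarios

Monophyly of the SV tip set on an unrooted tree is defined as the existence
of an edge whose bipartition induces exactly that set — no rooting choice is
involved. Branch lengths and support values are ignored; the scenario
classification is a pure topology test. ≥2 SV tips forming one clade →
single co-option of one post-2R-WGD ohnolog; SV tips split across two or
more maximal clades separated by NV tips → independent diversification; a
single SV tip is trivially monophyletic and therefore uninformative →
undetermined.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of their config (same seed →
byte-identical output), with a single RNG stream per config consumed in a
documented order: ancestor first, then lineages in declaration order.

**Codon pairs.** A uniform stop-free ancestor of n codons evolves into two
independent descendants along t/2 each, under a continuous-time process
where a single-nucleotide change has rate κ^[transition] × (ω if
nonsynonymous else 1) and rate 0 into stop codons. Branch lengths are in
expected substitutions per codon, normalized against the ancestor's realized
exit rates, since divergence units are otherwise conventional. Defaults:
n = 500 codons, t = 0.2 (low divergence, where multiple-hit collapse is
small and the counting estimator is near-unbiased), κ = 1. The κ = 1
default is deliberate: NG86 assumes no transition/transversion bias, so the
estimator-validation conditions use the model it is unbiased under; κ is a
free parameter for studying that bias.

**Families.** One ancestor per family → four ohnolog lineages (branch 0.15
substitutions/codon each), one co-opted lineage expanded to n_sv SV copies
at ω_sv and the other three carrying n_nv NV copies round-robin at ω_nv,
each copy on a terminal branch of 0.1. Copy numbers and ω contrasts follow
the catalog's structure (highly expanded families: ~10 SV / ~40 NV copies,
SV ω ≈ 1.5 vs NV ω ≈ 0.4; single-copy families: ω ≈ 0.5 on both sides).
Genes are laid on scaffolds in blocks of three, producing tandem-cluster
structure.

**Anchoring.** Genes land on MIC with a baseline probability (default 0.33,
the observed background MIC fraction) and focal genes with odds multiplied
by the configured odds ratio; scaffolds (default one gene each) carry a
marker with the configured density. Default margins mirror the real study
(47 focal / 2,602 other). The type-I calibration runs instead use 300
focal / 3,000 other genes at MIC fraction 0.4: the exact test is
conservative at small focal counts (analytic size 0.041 at the study's own
margins versus 0.048 at the calibration margins), and a calibration check
should be performed where discreteness is negligible.

**k-mer histograms.** Poisson(mean depth) over genome-size distinct k-mers
plus error k-mers uniform on depths 1–3 at the configured fraction of the
genome size. Real error spectra are heavy-tailed rather than capped at 3,
and real genomes add heterozygosity and repeat peaks; none of that is
modeled, so passing tests show correct peak-finding and shoulder exclusion,
not robustness to repeat structure.

**What passing tests do not show.** The simulators omit indels (all
alignments are gap-free), rate heterogeneity across sites, codon-usage bias
(uniform ancestors), gene conversion between paralogs, and alignment error.
Results on real venom-gene alignments depend on upstream alignment quality
in ways these tests cannot probe.

## Problem sizes

The validation suite uses 200 pairs × 500 codons per ω for parameter
recovery; 50 replicate family sets (10 SV / 40 NV genes, 300 codons) for
end-to-end acceleration detection and 50 single-SV null families; 1,000
replicates for exact-test calibration; and a 1-Mb genome for k-mer recovery
— sizes chosen so each check has clear statistical resolution (e.g. SE of a
5% rejection rate over 1,000 replicates is ~0.7%) while the whole suite
runs in a few minutes.

## Known limitations

* NG86 is a counting estimator: no maximum-likelihood codon model, no
  transition/transversion or codon-frequency correction; estimates at κ far
  from 1 are biased (downward for Ka/Ks at κ > 1), which is a property of
  the method, not a defect of the implementation.
* The acceleration flag compares pairwise ratio distributions, whose pairs
  share genes and are therefore not independent; the location test treats
  them as exchangeable units, which is anticonservative for very small
  groups. The permutation fallback mitigates the small-n normality issue,
  not the dependence.
* The exact-test p-value uses the probability-mass two-sided convention;
  other conventions (doubling the one-sided p, Blaker) give different values
  on asymmetric margins.
* Scenario classification trusts tip labels and topology; it does not model
  incomplete lineage sorting, gene conversion, or tree-inference error.
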
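# Methods

## The statistic

Each microsatellite marker yields a multiset of normalized tract-length
deltas Δ (observed tract length minus reference tract length, in bp),
one per spanning read. Instability is scored with Pearson's second
skewness coefficient, PSC = 3·(mean − median)/sd. In a microsatellite-
stable locus, reads concentrate at Δ = 0 with symmetric polymerase
stutter, so mean ≈ median and PSC ≈ 0. An unstable locus mixes
reference-length reads with a shifted (usually contracted) tumor allele:
the mean moves toward the shifted mode while the median stays on the
majority mode, so |PSC| grows. Because |mean − median| ≤ sd for any
distribution, |PSC| ≤ 3 always; using the sample (n−1) standard
deviation only enlarges the denominator, so the bound is preserved.

Numerical conventions, chosen where the procedure itself leaves them
open and applied consistently:

* sd uses the n−1 denominator (the default in standard statistical
  environments).
* sd = 0 (all reads the same length) defines PSC = 0 rather than NaN: a
  zero-variance distribution is the most stable observation possible.
  A corollary worth knowing: a *homozygous* shifted allele at 100%
  tumor fraction also has sd = 0 and is invisible to any skewness
  statistic — the method detects allele mixtures, not pure shifts.
* Median for even n is the midpoint of the two central order statistics.
* PSC is computed on deltas; by location invariance this is identical to
  computing it on raw tract lengths.
* Thresholds are strict: a marker is unstable iff PSC > 1 or PSC < −1;
  a marker is valid iff coverage > 20 (a marker with exactly 20 reads is
  filtered). PSC exactly 1 in magnitude is stable.

## Tract-length extraction

A read contributes to a marker only if its aligned reference span covers
the marker ± `flank` (default 5 bp) anchor bases with aligned or deleted
bases; soft/hard clips or reference skips inside that window disqualify
it, since an indel at the tract edge is only measurable against anchored
flanking alignment. The tract length is ref_length + inserted − deleted,
accumulated in one CIGAR walk:

* deletions count by closed-open overlap with [start, end);
* insertions count only when strictly interior to (start, end) — an
  insertion at either tract boundary is attributed to the flank. The
  ambiguity is unavoidable; the convention is fixed one way and the
  emitter and tests exercise both sides of it.

Reads flagged duplicate, secondary, supplementary or QC-fail, and reads
below MAPQ 20, are excluded. The CIGAR is trusted as produced by the
aligner; there is no realignment or stutter-aware regenotyping. A
pre-extracted length table (TSV) is accepted everywhere a BAM is, so the
statistical core runs without alignment data.

## Classification

The unstable fraction uses *valid* markers as denominator; low-coverage
markers are excluded entirely and can never dilute the fraction. The
cutoff comparison is inclusive (fraction ≥ cutoff ⇒ MSI-H). Defaults:
0.4 for fresh tissue and cell lines, 0.25 for FFPE. Both are exposed as
parameters because they were determined empirically on modest cohorts
and should be re-tuned for new panels or chemistries. A sample with zero
valid markers is reported `indeterminate`, and `n_valid` is always
surfaced so users can impose their own floor.

## The simulator

The generator emulates the study conditions the caller targets:

| parameter | default | meaning |
|---|---|---|
| `unstable_marker_rate` | 0.6 | fraction of panel markers made unstable per MSI-H sample |
| `stutter_rate` | 0.05 | per-read probability of a ±1-repeat-unit slip |
| `shift_units` | 3 | tumor-allele contraction, in repeat units (negative ⇒ insertion mode) |
| `tumor_fraction` | 0.5 | per-read probability of drawing from the shifted allele |
| `coverage_mean` | 100 | negative-binomial coverage mean |
| `coverage_dispersion` | 50 fresh/cell line, 5 FFPE | NB shape; smaller ⇒ wider spread |
| `dropout_rate` | 0.15 (FFPE only) | probability a marker's coverage is resampled uniformly on [0, 25], straddling the 20× filter |
| `ffpe_noise_rate` | 0.05 (FFPE only) | extra per-read ±1 bp artifact probability |

Coverage is negative binomial with the given mean and shape. A stable
marker draws Δ = 0 except for symmetric stutter; an unstable marker is a
Bernoulli(tumor_fraction) per-read mixture of the stable law and a
shifted allele at −shift_units·unit_length with its own stutter. The
FFPE regime adds the dropout and artifact-noise channels, reproducing
the qualitative FFPE behaviour the caller must tolerate: wider
across-marker coverage dispersion, markers falling under the coverage
filter, and a depressed, more variable unstable fraction (hence the
lower 0.25 cutoff). All randomness flows through one seeded
`numpy.random.Generator`; identical parameters and seed give
bit-identical cohorts and SAM output.

A property of the default mixture worth documenting: with
`tumor_fraction = 0.5` the binomial allele split lands near 50/50 in a
few percent of markers, where the median falls between (or on the
stutter edge of) the two modes and |PSC| drops just below 1. Under
defaults about 84% of simulated unstable mononucleotide markers exceed
the threshold individually; sample-level calls remain robust because the
unstable fraction (~0.5 of the panel) sits far above both cutoffs. Any
tumor fraction away from 0.5 detects more reliably.

The SAM emitter turns every simulated delta into one 150 bp read with a
40 bp left anchor whose CIGAR encodes the indel inside the tract
(deletions centered, insertions at the strict-interior midpoint), over a
random toy reference with the repeat tracts embedded and tract-edge
bases forced off-motif. Extraction from emitted SAM reproduces every
delta multiset exactly; this round trip is the extraction module's
central oracle.

What the simulator does **not** model: base-call errors and quality
variation, paired-end structure, length-dependent stutter, multi-allele
subclonality, G-C bias, alignment ambiguity in long homopolymers.
Passing simulation twins therefore demonstrates the statistical pipeline
end to end — not performance on real FFPE libraries, where aligner
behaviour in repeats is an additional error source.

## Fixture panels

The three panel sizes used in evaluation (23 / 230 / 3,154 markers)
mirror the published design. The marker lists are not redistributable,
so the 23-marker panel is a packaged synthetic fixture of
Bethesda-style mononucleotide loci on a toy genome, the 3,154-marker
candidate set is generated deterministically (seed 3154) on toy
chromosomes, and the 230-marker panel is a uniform random subset of it
(seed 230). The random subsets are reproducible within this package but
cannot correspond to the original unpublished draw.

## Evaluation

MSI-H is the positive class. Sensitivity, specificity and accuracy come
from the confusion matrix with indeterminate calls excluded and counted
separately; zero-denominator metrics are NA, never 0. McNemar's test on
paired classifier correctness uses the exact two-sided binomial test on
the discordant counts when b + c < 25, and the continuity-corrected
chi-square (|b − c| − 1)²/(b + c) on 1 df otherwise.

## Problem sizes and runtime

The acceptance experiments simulate fresh cohorts of 16 MSI-H + 68 MSS
samples on each panel and FFPE cohorts of 40 MSI-H + 77 MSS on the
23-marker panel, five replicate cohorts each (a single small cohort is a
noticeably noisier estimate of the same quantities); the full script
runs in a few minutes on one CPU, dominated by the 3,154-marker panel.

## Known limitations

* The coverage filter and PSC thresholds assume ~100× panels; shallow
  data pushes markers under the filter rather than degrading gracefully.
* A pure homozygous shift (no reference-length reads left) has PSC 0;
  in practice stroma and stutter keep mixtures mixed, but very high
  purity plus loss of heterozygosity is a blind spot of the statistic.
* Cutoffs are empirical; the FFPE cutoff in particular trades
  sensitivity against specificity in an overlapping-fraction regime.
* MSI-low is not modeled; the classifier is binary MSI-H vs MSS.
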
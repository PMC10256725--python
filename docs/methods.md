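# Methods

This note records the model behind `serptools`, the defaults and why they
were chosen, the numerical conventions, and what the synthetic-data tests do
and do not demonstrate about real data.

## From count tracks to enrichment profiles

The input is a per-nucleotide normalized footprint count track per replicate
of each condition (bait IP, bait total, no-bait IP, no-bait total). Tracks
are strandless; strand is applied when a gene profile is extracted, so that
index 1 of every profile is the first ORF nucleotide in mRNA orientation.
Intron positions stay in the profile vector (flagged in an exon mask) — they
carry whatever counts the track holds, and smoothing runs across them.

Each replicate profile is smoothed with a moving average over a 100 nt
window before anything else. The window is *centered* by default, with
truncation to available positions at the profile ends (a constant profile is
preserved exactly). A trailing alignment is available
(`smoothing.alignment`), matching the convention of common rolling-window
tooling; centered is the default because it does not shift threshold
crossings systematically by half a window. On a noiseless step of amplitude
A, the centered-smoothed profile crosses a threshold t where
`(A-1)·k ≥ (t-1)·w` post-step positions have entered the window, i.e.
`w·(t-1)/(A-1) − w/2` nucleotides *before* the true step — 25 nt (~8 codons)
early for A = 5, t = 2, w = 100, and never more than w/2. A regression test
pins this value.

Replicates are smoothed individually, averaged position-wise, and the
enrichment profile is the ratio of the averaged smoothed IP to the averaged
smoothed total. Wherever the smoothed total is zero the ratio is recorded as
undefined (NaN) — no pseudocount is introduced; the coverage filter bounds
how much of a profile can be undefined. Undefined positions are excluded
from area calculations exactly as introns are, and they break runs during
onset detection (binding must be observed, not interpolated).

Mean replicate correlation is the average pairwise Pearson r across the
smoothed IP replicate profiles — the IP is where the selective signal lives,
so that is where replicate agreement is demanded. Pairs in which either
vector has zero variance are undefined; a gene whose every pair is undefined
fails the correlation filter. Note that shared deterministic structure —
most prominently the near-zero intron dip present in every replicate —
inflates this correlation for intron-bearing genes regardless of signal;
the correlation filter is therefore a quality gate, not a specificity gate,
and specificity comes from the scaled-AUC threshold.

## Per-gene scoring and the filter cascade

The area under each profile is computed by the trapezoidal rule over the
exonic, defined positions concatenated in ORF order with unit spacing
(a constant profile c over L usable positions has AUC `c·(L−1)`). A gene's
decision record carries the IP and total AUCs, the fold-change AUCs of the
bait and no-bait enrichment profiles, IP and total coverage (percent of
positions with smoothed signal > 0, introns included, consistent with
smoothing across them), and the mean replicate correlation.

Filters, in order:

1. coverage ≥ 80% in *both* IP and total (the conservative reading of a
   per-gene coverage requirement);
2. pulldown AUC strictly > 5 (removes the low-signal quantile);
3. bait fold-change AUC ≥ no-bait fold-change AUC (the first point where
   the no-bait control enters);
4. after threshold calibration, at hit-calling time: mean replicate
   correlation ≥ 0.6 (undefined fails).

Transposon-flagged genes are excluded before scoring. Genes are flagged from
a GTF attribute (`transposon "true"`) or a configurable gene-ID regex; no
naming convention is assumed by default. A `pending/accepted/rejected`
inspection field records the manual-inspection step of the workflow; an
override file can reject called hits, but no inspection logic is automated.

## Scaled AUC and FDR calibration

The statistic thresholded for hit calling is the no-bait-scaled AUC,

    S = 100 · AUC_fc,bait / (AUC_fc,bait + AUC_fc,no-bait)   [percent],

which is 50 for a gene indistinguishable from the control and approaches 100
for strong, specific enrichment. Candidate cut-offs are the distinct
observed values of S among prefiltered genes; for each threshold T the scan
counts TP (curated positives ≥ T) and FP, estimates FDR = FP/(TP+FP), and
returns the *smallest* T with estimated FDR at or below the target (1% by
default) — maximizing sensitivity subject to the constraint. The cut-off is
data-derived on every run; a fixed percentage can be supplied instead
(`threshold.fixed_percent`) to reproduce a previously published choice.

**Who counts as a false positive is the load-bearing choice.** By default
every non-curated gene above T is an FP. That estimate is honest only when
the curated positive list is near-complete: genuine targets missing from the
list are booked as false discoveries, and since an FDR of 1% with a few
dozen positives forces FP = 0, a single high-scoring uncurated target pushes
the cut-off to the top of the score range and collapses sensitivity. This is
not a small-sample artifact but an identifiability limit: an uncurated true
target and a false positive are indistinguishable to the scan. `serptools`
therefore also accepts a curated *negative* list (genes known not to be
targets); when provided, only curated negatives count as FP and unlabeled
genes stay out of the calibration, the way literature-documented
non-cargoes would be used. With an incomplete positive list this is the
configuration that recovers planted targets in simulation (sensitivity 1.0
at empirical FDR < 0.5% under the default study conditions), and it is the
default in the synthetic experiments, whose generator emits both lists.

If no threshold meets the FDR target, calling anything would break the
guarantee; the scan falls back to the top of the score range (so at most the
top-scoring genes are called) and warns with the best achievable estimate.
This keeps the null case — positives and negatives identically
distributed — at a near-zero hit rate.

A calibration bait (the one with the curated truth list) fixes the cut-off
for all baits analyzed in a run.

## Onset and release detection

Enrichment values at exonic positions, in ORF coordinates, are scanned for
the first run of at least `min_run` = 30 consecutive defined positions at or
above the onset threshold (default 2.0; per-gene overrides, e.g. 1.5 for
weakly enriched genes, are read from a TSV). The onset nucleotide is the
first position of that run; codon c covers nucleotides 3c−2..3c, so
`onset_codon = ceil(onset_nt / 3)`. The 30 nt persistence requirement is
this implementation's guard against single-point noise — threshold crossing
alone carries no persistence rule — and is exposed in configuration.

Release: the first post-onset run of ≥ `min_run` defined values *below* the
threshold whose run ends before the final `tail_exclusion` = 90 nt of the
ORF marks a release (mode *transient*, release codon at the run start);
otherwise binding is *enduring*. The tail exclusion (~30 codons, roughly the
ribosome exit tunnel) prevents run-off decay at the stop codon from being
classified as release.

## Metagene and onset-aligned occupancy

For metagene profiles each gene vector is mean-normalized (`v · L / Σv`, so
its mean is exactly 1) and scaled to a common 0–100% axis: position i of a
length-L profile falls in bin `floor(100·(i−1)/L) + 1`; a gene contributes
its per-bin mean, bins are averaged across genes, and the band is the
normal-approximation 95% interval (mean ± 1.96·SEM). Genes shorter than the
bin count simply leave some bins empty. The normal band was chosen over a
bootstrap because it is deterministic and matches the familiar
figure-style ribbon; a seeded bootstrap could be added behind the same
interface.

Onset-aligned occupancy uses *raw* (unsmoothed), replicate-averaged,
mean-normalized total-translatome profiles over ORF coordinates — raw
because a 60 nt pause bump would be smeared over ±50 nt by the standard
smoothing, and total because the question is ribosome occupancy, not
capture. Windows of ±90 nt around each onset are stacked (clipped per-offset
at ORF bounds), and per-gene mean occupancy before (offsets < 0) versus
at-and-after (≥ 0) the onset is compared by a two-sided t-test — paired by
default, since pairing removes between-gene level differences; an unpaired
variant is one flag away.

## Sequence and set statistics

*Fisher's exact test* uses the probability-mass two-sided definition: the
p-value sums hypergeometric probabilities (margins fixed) of all tables no
more probable than the observed one. For tables with total ≤ 1000 the sum is
evaluated in exact integer arithmetic (`math.comb`), which makes
probability ties exact rather than float-fuzzy; larger tables delegate to
scipy. The reported odds ratio is the sample version ad/bc (+inf with a
flag when bc = 0 and ad > 0). Any zero margin gives p = 1 by convention.

*Amino-acid enrichment at onsets* pools residues over all onset-window
peptides (default window −50..−30 codons relative to the onset, the stretch
synthesized just before engagement once the exit tunnel is accounted for;
a −50..−40 preset is also provided) against pooled full-length proteins:
one 2×2 Fisher test per standard residue, BH-adjusted across the 20 tests.
Non-standard residues are dropped from counts and totals with a warning.

*Isoelectric point* solves `Q(pH) = 0` by bisection on [0, 14], with
Henderson–Hasselbalch charges for K, R, H, the N-terminus (positive) and
D, E, C, Y, the C-terminus (negative), using the EMBOSS pKa set by default;
the table is a configurable value object because published calculators
differ in their pKa choices, so tests assert self-consistency (|Q(pI)| <
1e−4, agreement with a dense grid scan, composition-only dependence) rather
than agreement with any external service. The bisection converges the
bracket to 1e−9 pH units: stopping on |Q| alone can sit millipH-units from
the root where the titration curve is flat.

*GO enrichment* tests each term annotating strictly more than 100 background
genes (2×2 of hit × term membership over the quantified background, Fisher
two-sided), reports terms with unadjusted p ≤ 0.1 — mirroring a
screening-style convention — and emits a BH column alongside for reference.

*Mann–Whitney U* uses midrank ties, exact enumeration for combined n ≤ 12
without ties and the tie- and continuity-corrected normal approximation
otherwise; the *two-sample KS test* uses the asymptotic Kolmogorov
distribution. *BH adjustment* is the standard step-up with monotonicity
enforcement, capped at 1, order preserved. (Step-up adjusted values are not
a fixed point of re-adjustment; no idempotence is claimed.)

*NLS fragment tiling* cuts a protein into 100-residue fragments starting
every 50 residues from the N-terminus up to residue 550, keeping the final
short fragment — the scheme used to build pairwise structure-prediction
input lists. Every residue up to the last fragment end is covered at least
once and at most twice.

## The synthetic-data generator

The generator emulates the *structure* of a SeRP experiment, not its
sequencing physics. One synthetic chromosome carries non-overlapping genes
(≥ 150 nt gaps, random strand); ~10% of genes get a single intron so the
intron-exclusion paths are exercised, and transposon-flagged decoys exercise
their removal. Footprint density is ORF-restricted: expected counts are flat
at a per-gene expression level (lognormal across genes, σ = 0.5, mean
`depth_mean`) and counts are drawn negative-binomial with overdispersion
α = 0.3 (variance μ + αμ²; α → 0 recovers Poisson). The count-noise family
of real SeRP libraries is not identified by this package — negative binomial
is the standard overdispersed choice for sequencing counts, recorded here as
a modeling decision.

Enrichment is planted on the *expectation*, never on realized counts: for a
target gene the IP expectation is `capture · total_expectation(i) · e(i)`
with `e(i)` a step — 1 before the onset codon, the planted amplitude from
onset to stop (enduring) or to a planted release codon (transient, then back
to 1). Background genes, and every gene of the no-bait control, get a
constant per-gene × replicate lognormal factor centered on 1 (σ = 0.1).
An optional pre-onset pause multiplies the expectation of *both* IP and
total over the 60 nt before the onset — it models a ribosome-occupancy
effect, so it cancels in the enrichment ratio and is detectable in totals,
which is exactly how the onset-aligned analysis looks for it.

Default study conditions (one decision, not a dial): 50 targets among 300
genes, genes 300–600 codons, 4 replicates, depth 20 counts/nt, amplitudes
4–10, onsets at 10–50% of the ORF (the N-terminal-leaning regime in which
enrichment is detectable over a usable stretch of the ORF), 10% transient
with rectangles of 150–250 codons (the scale of a documented mid-ORF release
event), pause factor 2 over 60 nt, K/R frequencies tripled in the −50..−30
window of target proteins. The curated positive list covers 50% of planted
targets — deliberately incomplete, emulating a literature-derived list — and
a curated negative list covers 50% of background genes. Reproducibility:
every track draws from a generator seeded by (seed, bait, condition,
replicate), so single files regenerate independently of order and identical
configs give byte-identical datasets.

What passing parameter-recovery tests shows: the pipeline's estimators
recover what the generator planted, at realistic depth and noise, including
calibration behavior under an incomplete truth list. What it does not show:
robustness to alignment artifacts, nucleotide-level biases (the generator is
flat within genes), 3-nt periodicity (absent by design; crosslinking blurs
it in the real assay), UTR signal, library-size mismatches beyond a scalar,
or biological co-regulation between genes.

## Problem sizes in the test suite

The suite runs the full study conditions where the claim depends on them
(target recovery, seeds 1–10; null calibration, seeds 1–20) and smaller
designs where per-gene behavior is what matters (onset recovery: 25 targets
× 20 seeds; pause: 100 genes × 10 seeds; composition: 50 proteins × 10
seeds). The oracle sweep for Fisher's test enumerates all ~164,000 tables
with margins ≤ 30 against an exact integer oracle. The whole suite completes
in a few minutes on one CPU; `scripts/acceptance.py` re-measures the
headline quantities in about a minute.

## Known limitations

* The calibration's default FP counting is only meaningful with a
  near-complete positive list; see the discussion above. The curated-negative
  mode shifts the burden to the quality of the negative list.
* Replicate correlation is inflated by shared deterministic structure
  (introns, coverage gaps); it must not be read as evidence of signal.
* Onset estimates inherit a systematic early bias of up to half the
  smoothing window on steep enrichment steps; downstream window analyses
  (e.g. −50..−30 composition) tolerate this by construction, but
  codon-accurate claims should use the bias bound, not the point estimate.
* Coverage is computed on smoothed profiles, so isolated zero stretches
  shorter than the window are invisible to the coverage filter.
* The GO module tests marginal 2×2 enrichment only; no term hierarchy,
  conditional testing, or annotation propagation.
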
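# Methods

This note documents the models and procedures implemented in `cnatrack`,
the assumptions behind them, the defaults that matter, and what the
synthetic cohorts do and do not establish about real data.

## Input model

The analysis consumes the *outputs* of allele-specific copy-number
callers, not raw array or sequencing data. A sample is a segmented
genome with, per segment: probe count, average total and minor-allele
copy number, and (when the subclonality fit succeeded) an integer
copy-number state pair with a mixing fraction. Sample metadata carries
ploidy, the aberrant cell fraction (ACF; the fraction of tumor cells in
the bulk, a.k.a. purity), and a profile-quality flag:

- `good` — purity/subclonality fit succeeded; the segment table stores
  tumor-adjusted copy numbers and the metadata ACF is trusted.
- `poor` — the fit failed; the table stores raw bulk values and the ACF
  must be re-estimated downstream.
- `non_aberrant` — too few aberrations for the caller to lock onto; the
  tumor cell fraction is resolved manually (see below).

Coordinates are 1-based inclusive; the gene annotation is BED-like on
disk and converted on read. The on-disk segment schema stores only the
second state of a subclonal mixture; the first state is recovered from
the identity `total = f1*s1 + (1-f1)*s2` and rounded. With the default
observation noise this rounding is essentially error-free for clonal
segments; for subclonal segments at small mixing fractions an occasional
state misassignment can occur, which mirrors the behavior of real
subclonality fits at low cellularity.

## Aberration scoring and genomic instability

A segment of total copy number *n* in a sample of ploidy *ψ* is a gain
when *n > ψ + m* and a deletion when *n < ψ − m*, strictly, with margin
*m = 0.6*; gains and amplifications are one event. The genomic
instability index is the probe-weighted fraction of the genome on
aberrant segments. The margin is reused as the GII's deviation
tolerance: it is the only aberration threshold the scoring system
defines, and probes are the natural weighting unit. GII is invariant
under splitting a segment into pieces with the same copy number.

Because per-patient breakpoints differ, cross-sample quantities
(frequency profiles, the selection scan) live on a fixed bin grid
(default 1 Mb); a bin takes the value of the segment covering its
midpoint. The midpoint rule is deterministic for straddling segments and
genes; maximal-overlap assignment would differ only for features
spanning a breakpoint.

## Adjusted logR and the expression filter

Gene-level dosage is expressed as `gamma * log2(n / psi)` with
γ = 0.55, an array-noise attenuation factor that compresses log ratios
the way hybridization intensities do. Zero copies are floored at 0.05
before the log (the value stays finite; a warning flags the event).
Genes are assigned the segment covering their midpoint.

The expression filter keeps genes whose adjusted logR correlates with
their mRNA expression at Pearson r ≥ 0.5 (pairwise-complete; genes with
fewer than 3 complete pairs or zero variance are dropped as undefined).
Beyond selecting dosage-responsive genes this acts as a germline-CNV
screen, since copy-number polymorphisms with little expression effect
fail it; no separate CNV blacklist is applied. The filter and the
differential test use diagnosis (week 0) samples with good profiles:
bulk values of unadjustable profiles would mix purity into the dosage
signal. Both choices are configurable.

## Differential testing and group comparisons

The per-gene test between good responders (GR) and non-responders (NR)
is the classic pooled-variance two-sample t-test (a Welch switch
exists), with Benjamini–Hochberg correction across tested genes and
significance at q < 0.05. Significant genes are merged into unique
genomic regions when their midpoints fall in the same or adjacent bins.
GII group comparisons use the pooled t-test (two groups, e.g. pCR vs
non-pCR) or one-way ANOVA (three response groups); GII–proliferation
association uses Pearson correlation. BH, t, F and Pearson are delegated
to statsmodels/scipy and verified in the test suite against independent
hand computations.

## Clinical derivations

Response ratio RR = size at surgery / size at diagnosis; RR < 0.10 is
good response (> 90% shrinkage), RR > 0.90 no response, the rest
intermediate. Values exactly on a cut are intermediate: the extreme
groups are phrased as strict shrinkage bounds, and observed group ranges
leave a gap between them. pCR is read from the clinical table, never
inferred from imaging sizes (good responders can miss pCR on node
status). The proliferation score is the mean normalized expression of
the 11 PAM50 proliferation genes; the historical listing "NUF" is
interpreted as NUF2 (the NDC80-complex partner), and the list is
configurable so either symbol can be supplied.

For non-aberrant profiles, the tumor cell fraction is set to zero when
the profile is flat and the pathologist saw 0% tumor cells; when the
non-aberrant profile is at week 0 or 12 while other time points are
aberrant, it is unknown (a real tumor was present but invisible to the
caller); otherwise unknown.

## Clonal dynamics

Per patient, the reference sample is week 0 if its profile is good, else
week 12, else the patient is excluded (reason-coded in the manifest).
Patients whose reference ploidy is ≥ 3 are excluded from this module
only: on non-diploid backgrounds a single "aberrant state" is not well
defined against a normal-cell mixture. On the diploid reference, every
segment with exactly one aberrant state — clonal aberrant, or a
subclonal mixture of one aberrant and one normal state — becomes a
tracked CNA (gain / loss / copy-neutral LOH; clonal or subclonal; the
reference carrier fraction is 1 or the mixture fraction).

Assuming the per-cell aberrant state is constant over time, the bulk
signal at a tracked segment is

    bulk_total = 2(1 − ρ) + ρ(2 + f(n − 2))        (gain/loss)
    bulk_minor = 1(1 − ρ) + ρ(1 − f)               (LOH)

solved for the carrier fraction f at each time point and clamped to
[0, 1]. Good profiles store adjusted values; these are converted back to
bulk with the known ACF first. ACFs below `min_acf` (0.01) make the
division ill-posed ("tumor absent") and yield missing fractions.

ACF of a follow-up sample: the caller's estimate when the profile is
good; otherwise each segment that was a clonal gain/loss in the
reference implies ρ = (bulk − 2)/(n − 2), and the sample ACF is the main
peak of a Gaussian KDE (Silverman bandwidth) of these implied values on
a fixed grid 0.01–1.00. The reported value is the median of the implied
values within a ±0.02 window of the grid peak: segments still clonal in
the sample pile up exactly at ρ, so this refinement returns the peak at
full precision rather than grid resolution (and degenerates gracefully:
identical implied values are returned directly). At least 3 informative
segments are required, else the sample is dropped from tracking.

### Selection scan

Changes in carrier fraction are called separately for each follow-up
sample relative to the reference: increase if f_t − f_ref > δ, decrease
if f_ref − f_t > δ, with dead zone δ = 0.05; smaller moves and missing
fractions are "unchanged" and excluded. The dead zone is a tie rule —
without it, observation noise generates symmetric spurious counts that
dilute power; calibration tests verify it introduces no bias. Each
patient contributes at most two counts per bin (week-12 and week-25
comparisons).

Counts are summed across patients per bin and per aberration class, and
each informative bin (I + D ≥ 1) is tested with the one-degree
goodness-of-fit statistic (I − D)²/(I + D) against the upper tail of
χ²₁ — the canonical test of "as many increases as decreases on average"
— without continuity correction (the null is symmetric; calibration is
verified by simulation). BH correction runs within each class (gains,
losses, LOH as separate families, matching how per-class genome scans
are reported); a bin is under positive selection when I > D and
q < 0.05, negative when D > I and q < 0.05. Counts are pooled across
treatment arms by default (a per-arm run is a filter away): the pooled
test is the one that reaches significance when the same shift appears in
both arms.

## Synthetic cohorts

The generator emulates the study design the analysis assumes: biopsies
at weeks 0/12/25; a GR/IR/NR mix matching a 33/68/22 split with response
ratios drawn inside each group's range (0–0.0976, 0.106–0.83,
0.903–2.35); tumor sizes back-computed from the drawn ratio on a
lognormal baseline (only the ratio matters downstream); ACF
trajectories whose means depend on the response group (good responders
collapse to ~0 by surgery, non-responders stay near 0.6); a miniature
genome (22 chromosomes × 10 Mb, 1 Mb bins, 100 probes per bin) so full
runs finish in seconds, with real-genome coordinates accepted via
config.

CNAs are placed as non-overlapping bin runs (Poisson count, default 10
per genome; geometric lengths up to 5 bins; gain/loss/LOH at
0.45/0.45/0.10; 60% clonal; 15% of patients tetraploid, exercising the
ploidy exclusion). Subclonal carrier fractions start uniform on
(0.2, 0.8) and evolve by bounded additive Gaussian steps (s.d. 0.15)
clamped to [0, 1] — the simplest mechanism consistent with rising and
falling subclone abundances. Planted selection loci instead move by a
fixed ±0.3 per interval in a configurable fraction of patients.
Observed segment copy numbers get Gaussian noise (s.d. 0.05 total,
0.025 minor), the scale of segment-mean noise on dense arrays.

The *null* generator draws each follow-up sample's deviation
independently and symmetrically around the reference fraction. This is
deliberate: the scan's chi-squared statistic models the counted signs as
independent fair coin flips, and the per-sample comparison design
("each 12- or 25-week sample relative to diagnosis") matches that. A
random-walk null instead correlates the week-12 and week-25 signs
(the week-25 change contains the week-12 step), overdispersing
(I − D)²/(I + D); this is a known limitation of the pooled statistic on
strongly autocorrelated dynamics and is why calibration is stated, and
tested, under the independent-deviation null.

Expression: 30% of genes are linearly coupled to their true tumor-dosage
logR with slope 2.0 and noise s.d. 0.2 — chosen so a typical coupled
gene has population r ≈ 0.7, comfortably above the 0.5 filter threshold,
per the design requirement that coupled genes exceed the threshold in
expectation. The 11 proliferation-panel genes track the sample's true
genomic instability (slope 3 on GII) instead, giving the GII–
proliferation association the analysis looks for. Ground-truth tables
record per-sample ACFs, per-CNA carrier fractions at every time point,
and each gene's coupling slope and realized population r.

What the synthetic cohorts do *not* emulate: raw probe intensities and
BAF tracks, segmentation error (breakpoints are exact), caller bias in
purity/ploidy estimates (good-profile values are truth), expression-array
probe effects, and realistic CNA size/state distributions (defaults are
chosen for testability). Passing tests therefore establish the internal
consistency and statistical behavior of the analysis chain given
caller-style inputs, not robustness to upstream caller error.

## Numerical choices and problem sizes

- Strict inequalities at the ±0.6 margin and the 0.10/0.90 response cuts
  (boundary values are neutral/intermediate).
- Zero copy number floored at 0.05 before logs; carrier fractions and
  implied ACFs clamped to [0, 1].
- KDE: Gaussian kernel, Silverman bandwidth, grid 0.01–1.00 step 0.01,
  peak refined by the windowed median described above.
- The chi-squared p-value is the analytic upper tail; BH is the
  step-up procedure capped at 1, computed per family over informative
  bins only.
- Test problem sizes: parameter recovery on 20-patient noise-free
  cohorts; calibration on 200 null replicates of 40 patients × 100 bins
  (one subclonal gain per bin per patient, good profiles throughout, so
  the counting + testing chain is what is calibrated); power on 50
  replicates of the default 40-patient mixed-quality cohort with planted
  ±0.3 loci (the full chain, density ACF estimation included); filter
  fidelity on 60 patients × ~200 genes. These sizes keep the whole suite
  in a few minutes on one CPU while leaving Monte-Carlo intervals tight
  enough for the stated bounds.

## Known limitations

- The tracked-state assumption (same aberrant state per cell at all time
  points) confounds a rising carrier fraction with the acquisition of
  further gains on the same locus; the scan detects the net dosage
  shift either way but cannot distinguish the mechanisms.
- Bulk mixtures at very low ACF amplify observation noise by 1/ρ in the
  recovered fractions; the `min_acf` cutoff bounds but does not remove
  this.
- The pooled chi-squared treats all counted comparisons as independent;
  within-patient correlation between the two follow-up comparisons
  (e.g. under smooth monotone dynamics) makes it anticonservative, as
  discussed above.
- Reference selection trusts the caller's quality flag; a "good" but
  biased reference propagates into every carrier fraction of that
  patient.
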
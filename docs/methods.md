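# Methods

This note documents the models, conventions and design choices behind
`megfeedback`, in the order the pipeline runs them.

## Synthetic study generator

The generator produces every input the analysis needs, with planted ground
truth, so that calibration and recovery can be measured rather than assumed.

**Mesh.** A synthetic cortical surface stands in for a template brain:
points sampled uniformly on the unit sphere, connected by symmetrised
6-nearest-neighbour edges (residual components stitched through their
closest vertex pairs), which reproduces the local adjacency of a
triangulated surface without anatomical files.  Parcels are Voronoi cells of
random seed vertices — contiguous, atlas-like labels.  Each vertex carries
0.1527 cm² of area, so a 15-vertex patch covers ≈ 2.29 cm², making the
conventional small-cluster exclusion rule self-consistent at fixture scale.
A contiguous polar cap (default 10% of vertices) is flagged as medial wall.

**Task.** Three blocks of 160 trials (480 total); four stimuli in balanced
shuffled order; per card-type pair one stimulus is sun-dominant and one
rain-dominant (randomised per session); outcomes are independent draws at
90/10 contingency.  Feedback follows the task's asymmetric table: positive
cards reward optimal answers and are silent otherwise; negative cards punish
non-optimal answers and are silent otherwise.  Response agents answer
optimally with a configurable per-card-type probability; reaction times are
lognormal (median 600 ms, σ = 0.35), the standard positive-skew RT shape —
the task itself prescribes no RT distribution.

**Source epochs.** Per subject and event type, an epochs × vertices × time
array spanning −250 to 600 ms around feedback onset (default 200 Hz in unit
tests; the pipeline default is 100 Hz).  Baseline activity is white Gaussian
noise in arbitrary units scaled by the baseline SD — downstream z-scoring
makes the absolute scale irrelevant, which is also why no inverse-solution
units are modelled.  An optional AR(1) coefficient adds temporal
autocorrelation (marginal variance renormalised) to stress-test cluster
inference under correlated noise.  Effects are planted as a constant
amplitude shift (in baseline-SD units) over named parcels within a time
window, optionally plus a Hann-windowed sinusoid for narrow-band power
effects.  The default study configuration mirrors the target design: 20
control vs 55 trauma subjects, heterogeneous trial counts (each subject's
epoch count follows their simulated feedback counts), a 1.5-SD positive-
feedback effect with a 6 Hz component and a 1.5-SD negative-feedback effect
carried by the trauma group, and a 0.75-SD extra amplitude for non-learners.

What the generator does *not* emulate: realistic head geometry or forward
models, spatially correlated sensor noise projected through an inverse
operator (source-level noise here is spatially white), 1/f background
spectra, or evoked components in the null condition.  Passing tests
therefore demonstrate the statistics' calibration and sensitivity under
known ground truth, not performance on any particular recording system.

## Behavioral statistics

Accuracy is the fraction of optimal responses, computed separately for
positive- and negative-feedback cards; RT is aggregated per card type (mean
by default, median by flag).  The first-block sensitivity re-run slices the
session *prefix*, never a sample.  A card type with zero trials yields a
missing cell, and subjects with missing cells are dropped listwise from the
MANOVA (which requires complete vectors).

The group comparison is a one-way MANOVA (statsmodels) on the four dependent
variables, reported as Wilks' Λ with its exact-F conversion — df (4, N−5),
i.e. (4, 71) for 76 subjects.  Two degenerate inputs are handled explicitly
rather than inherited from the backend: exactly-equal group means return
Λ = 1, F = 0, p = 1 (the no-effect limit), and rank-deficient within-group
covariance raises an error instead of being silently rank-reduced.

Learners are subjects with accuracy *strictly above* 0.65 ("more than 65%"
is a strict inequality).  Learner proportions are compared with a 2×2
chi-square without Yates correction (flag available).  When a feedback type
has fewer than 2 non-learners overall — the near-ceiling case that occurs by
design for negative-feedback cards — the pipeline excludes that feedback
type from the chi-square and records why; the threshold of 2 is a
configurable generalisation of that ceiling rule.

## Epoch preparation

**Baseline z-scoring.**  The baseline interval is the closed interval
[−250, 0] ms (endpoint conventions follow MNE).  By default the per-vertex
mean and sample SD (ddof = 1) are pooled across the baseline samples of all
of a subject's epochs — this stabilises the SD estimate; a per-epoch mode
exists behind a flag.  A vertex with (near-)zero baseline SD raises a
`DegenerateBaselineError` naming the vertex.  The transform is exactly
affine-invariant: z(a·x + b) = z(x) for a > 0.

**Amplitude rejection.** Epochs whose peak |amplitude| exceeds a threshold
are dropped (threshold in the data's own units; the 5 pT convention is
sensor-level, so at source level it is a free parameter, default 6 noise-SD
units in the pipeline).  A subject losing all epochs is an error, mirroring
subject exclusion.

**Trial-density matching.** Per event type, both groups are sorted by trial
count; the larger group is partitioned into n_bins contiguous rank blocks of
2–3 subjects (n_bins = size of the smaller group, default 20), each paired
with the rank-matched member of the smaller group.  Every bin member is
truncated to the bin minimum by uniform seeded subsampling without
replacement — random selection avoids the temporal bias of truncation.
Rank pairing makes the two groups' count distributions match bin by bin; a
random-assignment mode exists for comparison.

## Cluster permutation engine

One engine serves three lattices: space×time (mesh edges at equal time,
self-adjacency across neighbouring samples, no diagonal edges — built as a
Kronecker sum of the mesh adjacency and the time chain), the time chain, and
the 4-connected time×frequency grid.

The element-wise statistic is the pooled-variance two-sample t (paired t
available for genuinely paired designs; group contrasts between independent
unequal-sized groups always use the two-sample form).  Zero-variance
elements get t = 0 with a warning, so degenerate elements can never join a
cluster or produce infinite masses.  Clusters are connected components of
the positive and negative excursion sets separately — opposite signs never
merge — scored by mass (sum of t); both signs are compared against the
permutation distribution of the maximum *absolute* cluster mass, the
standard two-sided max-statistic scheme.

Permutations relabel whole subjects (or flip within-pair signs).  When the
number of distinct relabelings does not exceed the permutation budget the
engine enumerates all of them — the test is then exact, p = #{null ≥
observed}/n_total with the identity labeling included, and agrees with
brute-force enumeration to machine precision (verified in the tests).
Otherwise it samples uniformly and uses the standard Monte-Carlo estimator
p = (1 + k)/(1 + N), which is strictly positive and valid.  Mass
comparisons use a 10⁻¹² tie tolerance so that the identity permutation's tie
with the observed mass is always counted.  The null-distribution loop is
optionally numba-accelerated (a fused t/flood-fill kernel over the CSR
adjacency); the numpy/scipy fallback computes identical values.

Cluster-forming thresholds: derived from the cluster α and the design df
(α = 0.05 → t = 1.99 at df = 73; α = 0.001 → t = 3.43 at df = 72, echoed
rounded to two decimals), or set explicitly — the spectro-temporal test uses
an explicit threshold of 2.0, which does not correspond to a derivable df
and is therefore configured, not computed.  The positive-feedback SCPT
defaults to cluster α = 0.05 and the negative-feedback SCPT to 0.001: with
far fewer negative-feedback trials, significant clusters are expected to be
briefer, and a stricter forming threshold preserves sensitivity to them.
Cluster significance is always judged at 0.05.  The choice of forming
threshold affects sensitivity, not the false-alarm rate — the calibration
experiment below verifies this empirically.

## ROI analysis

Surviving clusters must span at least 16 distinct vertices (i.e. clusters of
15 or fewer are excluded), cover ≥ 2.29 cm² (both rules enforced; they
coincide only on the template-scale mesh), and last ≥ 20 ms, with duration
measured as elapsed time between the cluster's first and last sample.
Medial-wall vertices are removed *before* any counting.  Filtering is
idempotent and order-independent.

A surviving cluster is projected onto the parcellation: each touched parcel
yields one ROI whose members are the cluster's vertices inside it
(fragments below the vertex/area minima are dropped); coverage is the
percentage of the parcel's non-medial vertices inside the cluster.

The representative source time course (rSTC) averages over epochs first,
then over the ROI's member vertices — the cluster's significant vertices,
not the whole parcel — then baseline z-scores; the order does not change the
linear mean but fixes which baseline SD normalises the trace, so it is
pinned and tested.  Temporal clusters are reported as onset–offset in ms
with their midpoint (onset+offset)/2 as an across-cluster descriptor.  TOI
summaries are means over the half-open interval [onset, offset) — half-open
makes sample accounting unambiguous.  Learner contrasts use the pooled
(Student) two-sample t with df = n − 2 (55 subjects split 36/19 → df = 53);
Welch's correction is deliberately not applied, to keep the df convention.

## Time-frequency analysis

Complex Morlet wavelets, 4–45 Hz at 1 Hz resolution, n_cycles = f/3 —
implemented literally although this yields only 1.33 cycles at 4 Hz (the
package warns below 2 cycles): temporal resolution is bought at the price of
a constant ≈ 3 Hz spectral bandwidth.  Wavelets are unit-L2-norm,
Gaussian-windowed over ±5 σ_t.  The epoch is reflect-padded by half the
widest wavelet's support and cropped after convolution, because the 850 ms
epoch is shorter than the 4 Hz wavelet support (an unpadded mode exists).
Power — the squared coefficient magnitude, not amplitude or dB — is z-scored
per frequency row against the baseline (a global mode exists behind a flag;
per-frequency is the standard choice since raw power spans orders of
magnitude across rows).  TFRs are computed on per-subject ROI time courses,
not per vertex, since the spectro-temporal test operates on previously
identified ROIs.  The implementation is cross-checked in the test suite
against an independent reference implementation (MNE-Python's Morlet TFR)
for frequency localisation and per-row agreement.

## Pipeline and reproducibility

All randomness flows from one root seed through named CRC32-derived
substreams per stage, so re-running one stage never perturbs another and
identical configs produce byte-identical JSON reports (tested).  Stage
outputs are written as they complete; a failure raises an error naming the
stage and keeps partial outputs.  The orchestration is importable
(`simulate_study`, `run_pipeline`) with a thin click CLI over it (exit codes:
2 config error, 3 stage failure).

## Validation experiments and problem sizes

`megfeedback.validation` measures, at sizes chosen to keep a full run on one
CPU in the minutes range while preserving the study's group structure:

- **Task contingency** — 100,000 outcome draws for one sun-dominant
  stimulus; the empirical percentage sits within binomial error of 90%.
- **Family-wise error calibration** — 500 null studies of 20 vs 55 subjects
  on a 200-vertex mesh × 40 samples, 500 permutations each, threshold 1.99:
  the fraction of studies with any cluster p ≤ 0.05 stays within two
  binomial standard errors of 0.05.
- **Amplitude recovery** — 50 studies of 15 vs 15 subjects, 30 epochs each,
  with a 1.5-SD effect in one parcel (200–400 ms): detection and
  planted-parcel identification rates are ≥ 90%.
- **Oscillation recovery** — 50 studies with a planted 6 Hz power effect:
  the significant time-frequency cluster covers 6 Hz in ≥ 90% of runs.
- **Learner-contrast power** — 200 draws of a 1.5-SD gap at n = 36/19:
  p < 0.05 in ≥ 90% of runs with df = 53.

## Known limitations

- Source-level noise is spatially white; real source estimates have strong
  spatial correlation from the inverse operator, which inflates cluster
  sizes under the null.  The max-statistic scheme remains calibrated (it is
  distribution-free over exchangeable subjects), but empirical cluster-size
  intuitions from the synthetic data do not transfer.
- Sensor-level preprocessing (bad channels, reference noise, ICA) and
  inverse modelling are out of scope; the entry point is source-space
  epochs.
- The amplitude-rejection threshold at source level is a free parameter;
  only its sensor-level counterpart has a physical unit.
- No TFCE or cluster-size statistics; only two-sided mass-based tests.
- Learner status interacts with matched trial counts through the baseline
  SD of averaged traces, so planted learner gaps in *amplitude* are
  attenuated or amplified by per-subject epoch counts; the learner-contrast
  validation therefore plants the gap directly on the TOI summaries.
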
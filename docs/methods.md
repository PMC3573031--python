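# Methods

`p300apt` replicates, on synthetic data, the offline analysis chain of a
P300 brain-computer-interface (BCI) aptitude study: a short auditory
oddball screening measurement, a visual and an auditory P300 speller
session per participant, SWLDA classification, a repetitions-to-criterion
performance metric, and rank correlations between oddball ERP components
and speller performance.  This note documents the models, the parameters
that matter, and the choices made where the design was open.

## The simulated study

Each synthetic participant carries a latent **aptitude** `a ∈ [0, 1]`, the
quantity the analysis tries to predict.  Three sessions are generated per
participant:

* **Auditory oddball** — 3 runs x 20 sequences of five 160 ms tones (four
  standards, one deviant at a uniformly random position within each
  sequence), 800 ms inter-stimulus interval (960 ms onset asynchrony), i.e.
  96 s of stimulation per run, 60 deviants and 240 standards per session.
* **Visual speller** — 6 runs x 5 letters (BRAIN and POWER alternating),
  15 sequences of 10 row/column flashes per letter (80 ms flash + 160 ms
  inter-flash interval = 240 ms SOA), 2.4 s classification pause after each
  letter: 38.4 s per letter selection.  Row/column order is randomly
  permuted within each sequence.
* **Auditory speller** — same letter schedule with spoken-number stimuli
  (450 ms stimulus + 550 ms ISI = 1 s SOA; rows 0-4 then columns 0-4
  sequentially): 150 s of stimulation per letter.

### Planted ERP components

Responses are sums of Gaussian bumps in time (sigma = "width") times fixed
spatial maps (Gaussian in a 2-D azimuthal projection of the standard 10-05
electrode positions, unit maximum weight).  Non-targets carry only the
exogenous N1-P2 complex; targets add N2, P3 and a late slow wave.

| component | amplitude (µV)             | latency (ms)        | width | map center |
|-----------|----------------------------|---------------------|-------|------------|
| N1        | −(2.0 ± 0.5)               | 105 ± 8             | 14    | Fz         |
| P2        | +(2.5 ± 0.7)               | 185 ± 10            | 18    | FCz        |
| N2        | linked, mean −3.25, SD 2.25| 229 ± 43 [150,320]  | 22    | Cz         |
| P3        | +(4.99 ± 2.66), independent| 378 ± 89 [≥N2+60]   | 45    | Cz         |
| late      | linked, mean 3.61, SD 2.10 | 549 ± 100 [≥P3+70]  | 65    | POz − Fz   |

Amplitude links: `|N2| = base + gain·a + ε` with the gain chosen so the
population mean/SD match the values above and the planted Pearson/Spearman
link between |N2| and aptitude is ≈ 0.47 (late component: ≈ 0.46).  The P3
amplitude is drawn independently of aptitude — the planted null the
prediction analysis must preserve.  The latency SD of the late component is
drawn with SD 100 ms (not the cohort SD of ~169 ms) because latencies are
truncated to stay inside the 0–800 ms epoch and after the P3 peak; an
untruncated draw at the full SD would pile up on the boundaries.

Two deliberate geometry choices keep the *measured* components separable
under the analysis pipeline:

* The exogenous N1 is kept smaller at Cz than the planted N2 range and
  centered slightly frontally, so the sequential peak detector's
  "minimum before the P300" finds the N2 (as in the grand averages the
  analysis is modelled on) rather than the N1.
* The late slow wave is anterior-negative/posterior-positive with its sign
  flip at the vertex: its **common-average-referenced projection at Cz is
  exactly zero** by construction (the frontal-lobe gain is solved per
  montage).  This is why the late component is measured at POz while the
  P300 is measured at Cz; without it, the aptitude-linked late amplitude
  would leak into the Cz-based P3 measurement and corrupt the planted P3
  null.

### Speller signal and modality differences

In speller sessions the endogenous target response uses the *population
mean* amplitudes scaled by `0.45 + 1.30·a` — aptitude drives speller
signal-to-noise directly, so classification performance covaries with the
same latent that the oddball N2 and late components index, but not with
the oddball P3 amplitude.  Modality adjustments: visual latencies shifted
−69 ms (P3 near 309 ms) at scale 0.95; auditory +130 ms (P3 near 508 ms) at
scale 0.67 with the exogenous complex attenuated to 0.25 (no clear N1-P2 in
the auditory speller).  These gains were calibrated once so that a default
cohort lands in the regime the study reports (visual accuracy near ceiling,
auditory intermediate with a broad spread).

### Noise model

Per channel: 1/f-power Gaussian background (85% channel-specific, 53%
shared across channels; RMS = `noise_sigma`, default 9 µV drawn per
participant with SD 1), an amplitude-modulated 10 Hz alpha oscillation with
an occipital topography (1–3 µV), blink transients (Poisson, 4–15/min,
60–140 µV, 200–400 ms, frontal topography) and signed saccade transients,
both mirrored into the four EOG channels with realistic polarity
(above-eye positive, below-eye inverted; left/right canthus opposed).
The generator does not model habituation, fatigue, drifting electrode
impedances, line noise, or non-stationary alpha reactivity — passing tests
therefore show that the *analysis chain* behaves correctly under its
assumptions, not that it is robust to every property of real EEG.

## Preprocessing

Band-pass: least-squares FIR, high-pass 0.5 Hz then low-pass 20 Hz, each
applied forward and backward (zero phase; the effective response is the
squared single-pass response).  Filter orders follow the classic heuristic
of 3·fs/cutoff taps, forced odd; the high-pass taps are shifted to an exact
DC null.  Edges are padded by odd reflection of one filter length.

AMUSE: whiten via the eigendecomposition of the zero-lag covariance
(regularized with a warning if rank-deficient), then eigendecompose the
symmetrized lag-1 covariance of the whitened data; components are ordered
by descending eigenvalue.  Components whose absolute correlation with
either bipolar EOG derivation (vertical: above − below the eye;
horizontal: left − right canthus) exceeds 0.7 are zeroed and the EEG is
rebuilt from the rest.  AMUSE runs once per session (per recording passed
to the pipeline), not per run.

Re-referencing: common average over the EEG channels (EOG untouched).
Epochs: half-open [0, 800) ms windows (400 samples at 500 Hz), baseline
subtraction of the per-channel mean over [−100, 0) ms; events too close to
a recording edge are dropped and counted.

## Classification and performance

Features: per channel, a trailing 25-sample moving average decimated by 25
(with width = decimation this is exactly the block mean over
`[b·25, (b+1)·25)`), giving 63 x 16 = 1008 features for 400-sample epochs.
When the pipeline runs at 250 Hz (scaled-down studies), the analysis keeps
the ~50 ms bin width by using width = decimation = 12.

SWLDA: forward inclusion of the candidate with the smallest partial-F
p-value (threshold 0.10), backward removal of included features above 0.15,
at most 60 iterations, ordinary-least-squares weights on ±1 labels, no
bias term (the row/column decision is an arg-max of summed scores, which is
invariant to a shared offset; ties break toward the lower index).  The
inclusion/removal thresholds are the published P300-speller SWLDA
convention and are configurable.  If no feature passes on the first step,
model generation fails; the cross-validation loop records all-zero scores
for such a fold.

Performance: leave-one-run-out cross-validation over the 6 runs; letter
accuracy as a function of the number of repetitions k = 1..15 (scores are
summed over the first k sequences before the arg-max); repetitions to 70%
accuracy by linear interpolation between adjacent curve points, anchored at
(0, 0) when the first repetition already meets the criterion, and the
sentinel value 16 (one beyond the maximum) when it is never met — the
sentinel preserves rank order without discarding participants.  Selection
time = reps x 10 x SOA + 2.4 s.  Two information-transfer rates: Pierce's
symmetric-channel formula, and the mutual information of the empirical
(selection − target) offset distribution, with targets uniform over the
5 x 5 matrix and per-target re-normalization of the offsets clipped to the
reachable cells (the offset histogram aggregates over targets, so border
cells need this correction).  The study-level MI rate pools the offset
distribution over the whole cohort; the per-participant MI column uses each
participant's own (sparse) offset matrix and is NaN when that matrix leaves
some target with no reachable probability mass.

## ERP features and prediction

Sequential peak detection on the deviant-average waveform: P300 = Cz
maximum in [250, 700] ms, then N200 = Cz minimum before the P300 latency
(search floor 0 ms, configurable), then late = POz maximum after it.
Latencies are reported on the sample grid (2 ms at 500 Hz).  Degenerate
cases (flat signal, P300 at the window edge) are flagged rather than
silently reported.

Aptitude prediction: median split at or below the median = high aptitude
(fewer repetitions = better); channel x time Spearman maps (mid-rank ties,
t-approximation p-values) reported as signed r² = sign(ρ)·ρ²; component
amplitude/latency vs performance rank correlations per modality.  Sign
convention: the performance metric counts repetitions, so *positive*
correlations mean worse performance with larger amplitude.  Not-reached
participants enter at their sentinel rank.  Raw p-values are reported over
the grid; a Benjamini-Hochberg layer can be added by the caller but is not
applied by default.

## Problem sizes

The default configuration is the full study protocol (63 EEG + 4 EOG
channels, 500 Hz, 40 participants).  The test-suite and the acceptance
script use scaled-down problem sizes chosen once: sparse montages
(16 or 8 EEG channels that retain Cz/POz and lateral coverage), 250 Hz
sampling, fewer letters/sequences per run, with the oddball kept at (or
near) its full 60-deviant schedule because the component measurement is
the quantity under study.  The end-to-end recovery cohort and the
acceptance script's study run the full 63-channel montage at 250 Hz (the
oddball component measurement needs the spatial coverage; sparse montages
lose roughly half of every focal topography to the common average
reference); the 100-replicate null-retention check runs the 8-channel
montage.  Scaling down lowers the signal-to-noise of every
derived quantity, so recovered correlations are attenuated relative to the
planted links; the tests therefore check recovered values against sampling
intervals obtained by re-simulating the generator, and signs/nulls rather
than exact magnitudes where attenuation applies.

## Numerical notes

* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical seeds give bit-identical sessions
  and byte-identical study outputs.
* Session seeds are derived from the participant seed by fixed offsets
  (oddball +10007, visual +20011, auditory +30011, modulo 2³¹−1).
* EDF export quantizes to 16 bits over a per-channel symmetric physical
  range (rounded to 4 significant digits); the reader trims the zero-padded
  final record using the sample count stored in the JSON sidecar.
* Stepwise regression uses incremental modified Gram-Schmidt
  residualization; candidates whose residual norm falls below 1e-10 of
  their original norm are treated as collinear and skipped.
* A zero-variance paired t-test (identical vectors) is reported as
  t = 0, p = 1 rather than NaN.

## Known limitations

* The generator's aptitude → speller-SNR link is linear and monotone; it
  cannot produce participants whose oddball response and speller
  performance dissociate (reported in real cohorts).
* Peak amplitudes measured after the common average reference are
  attenuated relative to the planted values (the reference removes the
  spatial mean of each topography); population amplitude calibration holds
  at the profile level, not after the pipeline.
* The auditory speller's longer latencies push the late component's tail
  against the 800 ms epoch edge; its measured latency saturates for
  late-latency participants.
* EDF export requires an integer sampling rate.
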
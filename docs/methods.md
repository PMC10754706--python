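# Methods

This package re-implements, against synthetic data, a dyadic (mother-infant)
EEG frequency-tagging analysis: time-resolved SSVEP signal-to-noise
statistics within each brain, and amplitude-envelope correlation (AEC)
between the two brains, with the statistical machinery (paired tests, mixed
models, cluster-based and max-t permutation tests, FDR) that such analyses
use.  No human data are involved; a generative model of the experiment
stands in for the recordings, which makes every estimator testable against
known ground truth.

## Paradigm model

A session presents 15 natural images, each shown twice per block in four
blocks that alternate between two conditions — joint attention with
communicative cues (JA) and joint watching (JW) — for 120 image events, 60
per condition.  Every image is shown for 2 s flickering at f0 = 4 Hz,
preceded by a 1-s attention-getter and a 0.5-0.8 s blank baseline gap;
every third image is preceded by a 3-s pre-phase.  Image order within a
block is drawn by rejection sampling (up to 1000 tries) so no image repeats
back-to-back; the starting condition is a counterbalancing parameter.
Gaze coding marks an image attended when on-screen gaze starts within a
500 ms grace window (30 frames at 60 fps) of image onset and lasts
continuously to image offset.

## Synthetic dyad generator

Each channel of each member carries

    x(t) = sum_images gate(t) * w(ch) * A(role, cond) * (1 + m e(t)) * sin(2 pi f0 (t - onset))
           + pink_noise(alpha, RMS)

- `gate`: cosine-ramped 2-s window (ramp 100 ms).
- `w(ch)`: role topography.  Infants project mainly to
  central-occipital-parietal channels (CPz, Cz, O1, O2, POz, P3, P4, P7,
  P8, Pz; weight 1.0), mothers to central channels (C3, C4, CPz, Cz);
  remaining scalp channels get 0.3 and the mastoids 0.1.
- `A(role, cond)`: evoked amplitude in microvolt.  Defaults: infant 6 (JA)
  / 5 (JW), mother 4.8 / 4 — a 20 % boost in the JA direction, the size of
  effect the analysis should detect at cohort scale.
- `e(t)`: slow envelope, restarted at each image onset: low-pass (1 Hz,
  4th-order Butterworth, zero-phase) Gaussian noise, standardized, and
  mixed as `sqrt(rho) shared + sqrt(1-rho) own` so the infant and mother
  envelopes of one epoch have population correlation rho.  rho is
  condition-dependent; the default is 0 in both conditions (the null
  synchrony scenario).  Modulation depth m defaults to 0.3.
- `pink_noise`: 1/f^alpha Gaussian noise sampled in the spectral domain
  (alpha = 1, RMS 20 uV over the band), per channel, spatially independent.
- Attendance and artifact occurrence are Bernoulli per image with
  per-role/condition rates taken from the study being emulated
  (attendance: infant .65/.54, mother .78/.79 for JA/JW; artifact rates
  chosen so attended-and-clean epoch counts match the reported ~33/27 %
  for infants and ~47/64 % for mothers).  Artifact-flagged epochs also
  receive a 600 uV slow transient so the peak-to-peak rejection stage
  detects exactly the epochs the generator marked.

What the generator does *not* emulate: volume conduction / spatially
correlated noise (available behind a mixing matrix but off by default),
ocular or muscle artifact waveforms, non-stationary noise levels, phase
drift of the SSVEP (stimulus-locked phase by default; a jitter parameter
exists), and monitor-level stimulus physics (the flicker frequency is a
direct parameter).  Tests passing on these data therefore validate the
estimators and their calibration, not robustness to every real-world
artifact.

Two simulation paths produce identical statistics: a continuous recording
(24 channels at 500 Hz, used by the end-to-end acceptance run and fixture
files) and a direct per-epoch path that can materialize only the epochs
surviving the attendance/artifact flags.  The shortcut is
distribution-preserving because epochs are independent in the generative
model and discarded epochs never enter any statistic; it is what makes
replicate studies (hundreds of cohorts) affordable.

## Preprocessing

Band-pass 1-48 Hz (zero-phase forward-backward Butterworth; order 8 so the
stopband residual at 60 Hz stays below 5 % — a 4th-order band-pass leaves
~14 %), epochs from -1000 to +3000 ms around image onset (half-open window,
exactly 2000 samples at 500 Hz), baseline subtraction of the -500..0 ms
mean, peak-to-peak rejection at 250 uV (stand-in for visual artifact
screening; ICA is out of scope since the synthetic data carry no ocular
components), gaze-based attendance flags (epochs are flagged, not dropped,
so the intra- and inter-brain paths can use different subsets), and
re-referencing to the channel average.  The original reference (FCz) is not
a data channel; if an explicit FCz channel is present in external data it
joins the average and is dropped.  Mastoids are included in the reference
average by default (flag available) and always excluded from SNR/AEC
channel averages.  Participants need >= 5 attended-and-clean epochs per
condition; dyads need >= 5 *mutual* epochs (attended and clean for both
members) per condition.

## Spectral analysis and SNR

Complex Morlet wavelets, 7 cycles, on the 1-15 Hz grid in 0.5 Hz steps (29
bands), over -1000..2500 ms.  Wavelets are amplitude-normalized: a unit
stationary sinusoid at a grid frequency yields envelope 1 (power 1), which
makes analytic checks exact; the SNR is a power ratio, so any global
normalization cancels.  Evoked mode averages epochs before transforming;
per-epoch mode transforms single epochs (used for AEC envelopes).

The time-resolved SNR at band f is

    SNR(ch, t) = P(ch, f, t) / N(ch, f) - 1

with the noise proxy N = the average over the four neighbor bands (f-2,
f-1, f+1, f+2 Hz) of their time-averaged power over the full wavelet
window.  Two numerical properties of this statistic matter and are
documented here because they shape the calibration checks:

- **Edge correction.**  Near the epoch boundaries the wavelet hangs off the
  data, deflating the measured power of the low bands across much of the
  -1000..2500 ms noise window.  Each neighbor band's power is therefore
  divided by its deterministic edge-energy gain (the fraction of wavelet
  energy falling inside the epoch) before time-averaging; this is exact
  for stationary noise.  Without the correction the zero-signal SNR sits
  around +0.24 instead of 0.
- **Spectrum curvature.**  For 1/f background noise the neighbor average
  exceeds the center-band power (convexity), so the statistic's own
  expectation at 4 Hz is about -0.17 even with a perfect noise estimate.
  Zero-signal calibration checks therefore use white noise, where the
  proxy is unbiased; on pink noise the offset is a property of the
  statistic, common to both conditions, and cancels in every condition
  contrast.

Aggregation is the flat mean over a channel set and the 0-2000 ms image
window; the grand mean averages subjects elementwise.  Condition-level
grand means are tested against the noise level 0 with one-sample t tests.

## Inter-brain synchrony (AEC)

For each mutual epoch: per-epoch wavelet amplitude at 4 Hz per channel,
baseline-corrected by the -500..-200 ms pre-stimulus mean, averaged across
scalp channels (mastoids excluded), and the two members' envelopes Pearson-
correlated over the 0-2000 ms image window (the full-epoch window is a
parameter; outside the image the envelope is baseline noise).  Per-epoch r
values are Fisher z-transformed (r clipped at 1 - 1e-7 so z stays finite),
averaged within condition per dyad, and reported as r = tanh(mean z) —
averaging always happens in z space.  Zero-variance envelopes drop the
epoch with a logged count.  The channel-pair variant computes the same
quantity per (infant channel, mother channel) pair without channel
averaging; the 22 x 22 matrix is not symmetric because the roles differ.

Known limitation: both members' envelopes contain the wavelet-smoothed
onset/offset transient of the evoked response.  At strong modulation depth
and low noise this shared deterministic component biases single-condition
AEC levels upward; it is identical across conditions and cancels in the
JA-JW contrast, which is the quantity under test.  The unbiasedness of the
correlation/aggregation chain itself is checked at the envelope level.

## Statistics

- Paired condition tests are classical dependent t tests (df = n-1);
  zero-variance differences are flagged degenerate instead of dividing by
  zero.
- The mixed model (window-averaged SNR per channel ~ condition x region,
  random intercept per individual; epoch-level AEC z ~ condition, random
  intercept per dyad) is fitted by REML via statsmodels.  Fixed-term F
  tests use sum-to-zero coding (type-III) with denominator df
  n_obs - n_groups - rank + 1, which equals the Satterthwaite value for
  these balanced designs (it reduces to the paired-t df in the two-
  condition case) and was verified against lmerTest/emmeans output.
  Pairwise JA-JW contrasts per region are adjusted by the multivariate-t
  max-|t| method (Monte-Carlo on the estimated contrast correlation,
  20 000 seeded draws).
- Cluster-based permutation: per-unit paired t maps, two-sided threshold
  at p < .05, connected components under the supplied adjacency (electrode
  neighbor graph; temporal contiguity; their graph product for
  channel-time, where diagonal neighbors are not adjacent), cluster mass =
  sum of member t values, minimum cluster size one unit.  The null is the
  per-permutation maximum |mass| over both signs under within-subject sign
  flips; p values use the add-one convention and are never exactly 0.  The
  observed t map is computed through the same vectorized arithmetic as the
  permuted maps so that permutations reproducing the identity tie the
  observed statistic exactly.  Critical alphas default to the source
  analysis's printed values — 0.25 for the channel dimension and 0.025 for
  the time dimension.  The 0.25 value is unusually liberal (possibly a
  typo for 0.025 in the source); both are plain configuration values and
  no silent correction is applied.
- Channel-pair testing uses the max-|t| permutation null over all 484
  pairs followed by Benjamini-Hochberg FDR (statsmodels).
- Electrode adjacency: Euclidean threshold 0.8 on unit-sphere template
  positions (10-20 montage), giving a median degree of 4-6 over the 22
  scalp electrodes; the threshold is exposed in configuration.

## Problem sizes and seeds

Every stochastic component draws from a child of one master seed
(`numpy` SeedSequence), so runs are bit-reproducible.  Replicate studies
use: cluster type-I, 100 null cohorts of 37 subjects x 22 channels with
1000 permutations each; mixed-model type-I, 200 null tables of
37 x 22 x 2; FDR null, 500 draws of 1000 uniform p values; detection power,
15 cohorts of 37 infants (amplitude boost) and 15 cohorts of 31 dyads
(envelope coupling, rho .8 vs 0 at modulation depth 0.9 and noise RMS
5 uV), plus 10 equal-coupling cohorts for the null pattern.  The
analysis drivers under `analysis/` run smaller versions of the same
studies; the test suite owns the full-size ones.

## Numerical choices and degenerate inputs

Half-open windows everywhere (`[t0, t1)`) so sample counts are exact and
an epoch's onset sample belongs to it.  r = +-1 is clipped before atanh at
1 - 1e-7.  Permutation ties are counted with >= (conservative).  A zero
noise floor, an empty channel set, an empty mutual-epoch set, fewer than
two subjects/dyads, and double re-referencing raise typed errors rather
than returning NaN.  Mixed-model fits with one grouping level or a zero
random-effect variance are reported with a singular-fit diagnostic, never
silently.
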
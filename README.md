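# dyadssvep

Analysis pipeline for dyadic (mother-infant) EEG frequency tagging:
within-brain steady-state visual evoked potential (SSVEP) signal-to-noise
statistics and between-brain amplitude-envelope correlation (AEC), driven
by a synthetic two-person EEG generator so every estimator can be validated
against known ground truth.

**Who it is for.**  Researchers analysing rhythmic-visual-stimulation
hyperscanning experiments — two people watching 4 Hz-flickering images in
alternating joint-attention (JA) and joint-watching (JW) blocks — who need
the full chain from raw continuous EEG to calibrated statistics, plus a
generative model for power analysis and method validation.

## The statistics at the core

For each participant, evoked activity is decomposed with 7-cycle complex
Morlet wavelets on a 1–15 Hz grid (0.5 Hz steps, 29 bands).  The
time-resolved SNR at band *f* is

    SNR(ch, t) = P(ch, f, t) / N(ch, f) − 1

where the noise proxy *N* averages the power of the four neighbouring
bands (f ± 1, f ± 2 Hz) over the −1000..2500 ms wavelet window
(edge-corrected; see `docs/methods.md`).  SNR = 0 marks the noise floor.
Condition contrasts use dependent *t* tests, a condition × region mixed
model with a random intercept per individual (Satterthwaite-equivalent
denominator df, multivariate-*t*-adjusted contrasts), and cluster-based
permutation tests in the channel, time and channel-time dimensions
(cluster mass = Σt, within-subject sign-flip null).

For each dyad, mutual epochs (attended and artifact-free for both members)
yield per-epoch 4 Hz amplitude envelopes, baseline-corrected and averaged
over scalp channels; the two members' envelopes are Pearson-correlated per
epoch, Fisher *z*-transformed, averaged within condition, and reported as
r = tanh(z̄).  Channel-pair AEC matrices (22 × 22) are compared between
conditions with a max-|t| permutation test and Benjamini–Hochberg FDR.

The synthetic generator writes, per channel,

    x(t) = Σ_images gate(t) · w(ch) · A(role, cond) · (1 + m·e(t)) · sin(2π·4·(t − onset)) + 1/f noise

with condition-dependent evoked amplitudes, role topographies, coupled
slow envelopes (coupling coefficient ρ per condition), Bernoulli gaze
attendance and artifact attrition matching the emulated study's rates.

## Worked example

```python
from dyadssvep.pipeline import RunConfig, run_intra, run_inter

report = run_intra(RunConfig(seed=11, n_dyads=12, n_perm=500, time_decim=20))
print(report.peak_frequency_hz)
print(report.paired.query("role == 'infant'").head(2).round(3))
```

prints (numbers from this exact configuration):

```
4.0
     role channel_set  mean_JA  mean_JW      t  df      p
0  infant         all    2.425    1.688  4.110  11  0.002
1  infant         cop    3.394    2.423  4.070  11  0.002
```

The grand-mean SNR spectrum of the simulated cohort peaks at the 4 Hz
stimulation frequency; infants' SNR averaged over all scalp channels (and
over the central-occipital-parietal set, `cop`) is higher during JA than
JW, reflecting the 20 % JA amplitude boost the generator injects.  Grand
means are far above the noise floor (e.g. infant JA mean SNR 2.57,
t(11) = 19.1 against 0).  The companion inter-brain run with the default
generator (envelope coupling 0 in both conditions) shows the null pattern:
region AECs near zero — all-channel JA mean 0.055 vs JW −0.025,
t(9) = 1.28, p = .23 — and 0 of 484 channel pairs significant after FDR.

The same flow, with commentary and on-disk tables under `results/`, lives
in the numbered drivers:

```
python analysis/01_simulate_fixtures.py   # synthetic datasets (scratch/)
python analysis/02_intra_ssvep.py         # within-subject SSVEP analysis
python analysis/03_inter_aec.py           # inter-brain AEC analysis
python analysis/04_calibration_power.py   # type-I error and power rates
```

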
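# Methods

This note documents the models, parameter choices and numerical conventions
behind the package, and what the synthetic validation study does and does not
demonstrate.

## The analysis pipeline

The package analyzes two-task (easy/hard) choice-reaction cohorts with
epoched EEG. The chain is:

1. **Behavioral scoring.** Per subject and task, accuracy (percent; misses
   counted as errors) and hit RT (mean RT of correct responses, ms) give the
   performance ratio `Acc/RT` (%/ms). The adaptability score is
   `(Acc/RT)_easy − (Acc/RT)_hard`; a cohort median split assigns "low"/"high"
   adaptability groups. Tie rule: scores strictly above the median go to
   "high"; the median subject (and exact ties) go to "low", so an odd cohort
   puts the extra subject in the low group. This rule is deterministic, which
   the decoder's labels require.
2. **ERP pipeline.** Band-pass 0.5–20 Hz at 48 dB/oct (8th-order Butterworth
   high- and low-pass cascade, applied forward-backward, hence zero-phase —
   a documented choice; the phase behavior of vendor filters is typically
   unspecified), polyphase resampling to 256 Hz, average reference,
   sliding-window artifact rejection (reject if any channel has a >200 µV
   range within any 200 ms window, or a <0.5 µV range within any 100 ms
   window; step one sample), spherical-spline surface Laplacian (CSD;
   spline stiffness m=4, Legendre series truncated at degree 10,
   regularization λ=1e-5, unit head radius — output rescales as 1/r²),
   baseline correction (−300..0 ms stimulus-locked; +300..+400 ms
   response-locked), and per subject × task averaging of correct trials.
   Component amplitudes are window means averaged over fixed electrode sets
   (P1 95–105 ms at P7/P8; N1 170–180 ms at P7/P8/P9/P10; N2 230–250 ms and
   fronto-central P3 500–700 ms at Cz; N450 at Cz with task-specific windows
   380–400 / 395–415 ms; stimulus parietal P3 305–325 ms at PO1/PO2;
   response-locked parietal P3 −35..−25 ms at Pz). Electrode choices can be
   validated data-driven: each electrode's window mean is compared against
   the mean of the other 59 with paired t-tests, Bonferroni-corrected for 60
   comparisons.
3. **Statistics.** Per component, a 2×2 mixed ANOVA (within: task; between:
   group) with partial η²; Bonferroni-corrected post hoc paired/independent
   t-tests plus Mann–Whitney U for the between-group contrasts; OLS
   regressions of the adaptability score on amplitude; and the BIC
   approximation to the posterior probability of the alternative,
   `p_BIC(H1|D) = 1/(1+exp(ΔBIC/2))` with
   `ΔBIC = n·ln(SSE1/SSE0) + k·ln(n)`. Greenhouse–Geisser correction is
   moot for two-level factors (ε = 1) and therefore omitted.
4. **Decoding.** Features are all CSD samples of all 60 channels of the
   response-locked easy-task subject-average ERPs in −300..+1000 ms at
   256 Hz (60 × 333 = 19,980 columns). Columns are z-scored (sample sd),
   filtered by two-sample t-test at p < 0.01, ordered by SFFS under a
   stratified 10-fold CV criterion with an RBF-SVM (C=1, gamma='scale' — the
   common toolbox defaults), and the retained feature count follows the 99%
   confidence-bound non-overlap rule. Significance comes from a
   1000-label-permutation test.

## Window and tie conventions

Analysis windows are half-open `[start, end)` on sample periods: the first
sample is the one at or immediately before `start`, the end is exclusive, so
a window of W ms always covers `ceil(W·fs/1000)` samples regardless of grid
phase (a 1300 ms window at 256 Hz has 333 samples). SFFS ties break toward
the lowest column index; CV fold assignment is drawn once per run and reused
across all SFFS evaluations, making the criterion a deterministic function
of the feature subset. Confidence bounds are not clipped for the overlap
rule (clipping to [0,1] is reporting-only).

## Leakage

The default decoding protocol z-scores and filters on the full sample before
cross-validation — the classical procedure, which is optimistically biased
on null data (the bias is measured in the test suite). A `nested` mode moves
z-scoring and filtering inside each training fold; on null data it stays at
chance. The default permutation test keeps the selected features fixed;
`reselect` mode re-runs filter+SFFS per permutation and additionally accounts
for selection bias, at ~selection-cost × n_perm.

## The synthetic cohort generator

The generator emulates the study conditions so every stage can be tested
against planted ground truth without any recorded data.

**Behavior.** RTs are log-normal (shape σ=0.25) around subject-specific
means; draws beyond the 2000 ms response deadline become misses (no RT,
coded incorrect). Correctness is Bernoulli per trial. Between-subject traits
— a log-normal RT multiplier (sd 0.065) shared across tasks and logit-scale
accuracy jitter (sd 0.3), both truncated at ±2.33 sd so cohort extremes stay
bounded — are calibrated so that a 227-subject cohort's
per-task performance-ratio ranges fall inside the reference ranges (easy
0.14–0.28, hard 0.08–0.20) with grand means near 0.212 (easy, acc 0.98 /
460 ms) and 0.14 (hard, acc 0.92 / 660 ms). The high-adaptability group's
advantage is confined to the easy task and expressed in ratio units
(default 0.03 %/ms), implemented by scaling the easy-task RT mean down
(high) / up (low) symmetrically.

**EEG.** Each correct trial's signal is a sum of component templates:
Hanning bumps in time (smooth, compactly supported, analytic integrals for
tests) with spatial-Gaussian topographies (σ=0.45 rad geodesic fall-off from
the peak electrodes) on a 60-channel equidistant unit-sphere montage.
Template amplitudes are specified on the CSD scale (µV/m²): because the
generator emits potentials that the pipeline later pushes through the CSD
transform, each topography is pre-compensated through the default CSD
operator so that the planted amplitude is what the standard quantification
recovers at the peak electrodes. Per-trial signals are synthesized on a
−2000..+4000 ms stimulus-clock buffer; the stimulus-locked segment and the
response-locked segment (re-cut at the grid-rounded RT) therefore share
signal and noise, preserving locking semantics without simulating continuous
recordings. Noise is white Gaussian (default sd 10 µV), spectrally shaped to
1/f above 1 Hz with total variance preserved, and spatially mixed by an
exponential-decay covariance (length 0.6 rad). Optional artifacts (spikes,
flat channels, drifts) exist to exercise the rejector and are off by
default. Default amplitudes follow the reference grand means: task effects
on all components (e.g. response P3 easy 21.04 / hard 14.66 µV/m²), and a
group × task interaction planted *only* on the response-locked parietal P3
(high−low difference of task differences 3.69 µV/m²).

**What the generator does not model.** No between-subject variability of ERP
amplitudes (subject-level amplitude variance comes from trial noise only),
no ocular/ECG artifacts realistic enough to need ICA, no biophysical forward
model, no trial-to-trial latency jitter, and the group effect on EEG is
categorical (via the latent group), so score–amplitude regressions can pick
up the planted interaction even where the reference analysis found none.
Passing the planted-truth tests shows the pipeline recovers what was planted
under these idealized conditions; it does not certify performance on real
recordings.

## The reduced validation study

Tests and the acceptance script run a reduced study: 60 subjects, 100
trials/task, full 60-channel montage — about 8 minutes of compute instead of
hours. Sizing the planted interaction for that design is a power question:
with the realistic noise defaults, the per-subject sd of the quantified
response-P3 task difference is ≈10 µV/m², so the full-size interaction of
3.69 µV/m² yields an expected interaction t ≈ 2.5 only at n = 227 — at
n = 60 it is undetectable by design. The reduced study therefore plants a
12 µV/m² interaction (expected t ≈ 4.8 at n = 60), preserving the detection
margin of the full-size design; everything else keeps the cohort defaults.
Its recovery criteria: ≥80% median-split agreement with the latent groups,
interaction detected (p < 0.01) only on the response-locked parietal P3 with
`p_BIC` favoring the null on all stimulus-locked components, and the
top-ranked decoding feature within 0.5 rad of the planted electrodes and
±50 ms of the planted peak.

## Numerical notes

- The CSD operator is a dense 60×60 matrix applied per sample; constants map
  to zero to ~1e-11 and the operator agrees with an independent
  implementation (mne's spherical-spline CSD, identical m/degree/λ) to
  machine precision. Degree-n Legendre topographies reproduce the
  eigenvalue n(n+1) of the sphere Laplacian to a few percent — the residual
  reflects 60-electrode sampling, not the estimator.
- The 0.5 Hz high-pass settles over seconds; epochs are reflect-padded up to
  3/low_hz seconds before filtfilt. Filter roll-off should be measured on
  long signals (the tests use 30 s tones).
- Mann–Whitney U uses exact enumeration for tie-free samples of ≤10 per
  group, otherwise the tie-corrected normal approximation.
- `mixed_anova_2x2` delegates the sums-of-squares computation to pingouin;
  its F statistics are checked in the tests against the algebraic squared-t
  identities of the 2×2 design.
- All randomness flows through named integer seeds
  (simulation / folds / permutation derived from one master seed);
  identical configs reproduce byte-identical CSV/JSON artifacts.
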
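# metacontrol

Analysis pipeline for studying *metacontrol* — how well individuals adapt
the amount of cognitive control they exert to the demands of the task —
from behavior and EEG in two-task (easy/hard) choice-reaction cohorts.

It is aimed at cognitive-neurophysiology groups who want the complete chain
as tested, reusable code: behavioral adaptability scoring and group
formation, ERP preprocessing and component quantification on
current-source-density (CSD) data, the within–between statistics battery,
and data-driven group decoding — plus a synthetic cohort generator so the
entire chain is validated end to end against planted ground truth.

## The model in brief

**Adaptability score.** With `Acc` the accuracy in percent (misses counted
as errors) and `RT` the mean reaction time of correct responses in ms,

    score = Acc_easy / RT_easy − Acc_hard / RT_hard        [%/ms]

Each task's term is the *performance ratio* (larger = faster and/or more
accurate); the difference captures how much a subject benefits from the low
control demand of the easy task while controlling speed–accuracy tradeoffs.
A cohort median split forms "low"/"high" adaptability groups.

**ERP pipeline.** 0.5–20 Hz band-pass (48 dB/oct, zero-phase), 256 Hz,
average reference, sliding-window artifact rejection (>200 µV range in
200 ms, <0.5 µV range in 100 ms), spherical-spline surface Laplacian
(Perrin-type CSD, m = 4, Legendre degree 10), baseline correction, and
per-condition averaging. Components quantified as window means over fixed
electrode sets (P1, N1, N2, N450 with task-specific windows, fronto-central
P3, stimulus- and response-locked parietal P3), with an optional
Bonferroni-corrected electrode-validation procedure.

**Statistics.** Mixed 2×2 ANOVAs (task × group) with partial η², Bonferroni
post hocs, Mann–Whitney U tests, per-component regressions of the score on
amplitude, and the BIC posterior probability of the alternative,
`p_BIC(H1|D) = 1/(1+exp(ΔBIC/2))`.

**Decoding.** Every CSD sample of every channel of the response-locked
subject-average ERPs (−300..+1000 ms, 60 × 333 = 19,980 features) is
z-scored, filtered by a two-sample t-test (p < 0.01), ordered by sequential
floating forward selection (SFFS) under a stratified 10-fold CV RBF-SVM
criterion, cut by the 99% confidence-bound non-overlap rule, and tested with
1000 label permutations.

See `docs/methods.md` for conventions, parameter rationale and limitations.

## Worked example

Run the reduced synthetic validation study (60 subjects, 100 trials/task,
60 channels; the generator plants a group × task interaction only on the
response-locked parietal P3):

```bash
metacontrol run-full --reduced --seed 1 --out-dir out/
```

This prints the built-in recovery checks; with seed 1 it ends with:

```
"split_recovers_groups":     {"agreement": 0.8667, "threshold": 0.8, "passed": true}
"interaction_only_on_response_p3":
    "detected": ["P3_parietal_resp"]          (p = 3.1e-07, alpha 0.01)
    "p_bic_h1": {"P3_parietal_resp": 0.99999, all others < 0.29}
"top_feature_on_planted_component":
    {"electrode": "Pz", "time_ms": -7.8, "distance_rad": 0.0, "dt_ms": 22.2}
all recovery checks passed: True
```

Reading the numbers: 87% of subjects land in their true (latent) generator
group after the behavioral median split; among the seven quantified
components only the response-locked parietal P3 shows a group × task
interaction (its Bayesian posterior favors H1 while every stimulus-locked
component favors the null); and the decoder's first-ranked feature sits at
Pz, 22 ms from the planted peak — the decoder finds the planted effect
without being told where it is. `out/` also holds `behavior.csv`
(per-subject ratios ≈ 0.213 easy / 0.140 hard, scores, groups),
`amplitudes.csv` (response P3 ≈ 20.5 µV/m² easy vs 15.0 hard), `stats.json`,
`selection.csv` (the ranked feature table: first feature Pz @ −7.8 ms,
83.3% mean predictability, filter p = 9.3e-07, 100% of permutations beaten)
and `report.json` with stage provenance and artifact checksums.

The same stages are available as library functions
(`metacontrol.behavior.score_cohort`, `metacontrol.erp_pipeline.preprocess`,
`metacontrol.stats.mixed_anova_2x2`, `metacontrol.ml_classify.run_decoding`,
…) and as individual CLI subcommands
(`simulate`, `behavior`, `stats`, `classify`).

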
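# copreact

Analysis of **reactive postural control** from force-plate recordings:
perturbation-aligned center-of-pressure (COP) epoching, reactive-balance
feature extraction, and split-plot factorial statistics — with a
ground-truth synthetic generator so the whole chain is testable without
access to raw laboratory data.

## Who this is for

Balance and motor-control researchers who deliver unexpected mechanical
perturbations (e.g. pneumatic actuators at the pelvis) to standing
participants and record the COP trajectory on a force plate, then ask
whether an intervention changed the compensatory response between a
pre-test and a post-test across two groups.

## What it computes

**Signal chain.** COP channels (mediolateral ML, anteroposterior AP, mm,
100 Hz) are smoothed with a zero-phase low-pass Butterworth filter
(10 Hz cutoff, 4th order per pass, applied forward–backward). Perturbation
onsets (t = 0 at actuator contact) are located from rising edges of the
synchronization trigger plus the rig's mechanical delay. Around each onset
an epoch from −0.4 to 2.0 s is cut, the ML axis is signed so the
perturbation-force direction is positive (AP: anterior positive), and the
mean over the baseline window −0.35 to −0.2 s is subtracted per axis.

**Features** (per axis, over the compensatory window 0–0.4 s):

| symbol | meaning | units |
|---|---|---|
| D-COP | peak displacement in the positive direction | mm |
| T-COP | time of that peak | s |
| V-COP | peak velocity in the positive direction | mm/s |
| RMS | root mean square of the corrected signal | mm |

Several perturbations per test are averaged into one value per
participant and session; recordings failing QC (missing samples, wrong
event count, truncated epochs) are excluded, never imputed.

**Statistics.** For each feature, a balanced split-plot ANOVA — group
(between-subject: WBED / Sham) × time (within-subject: pre / post) — with

- F(group) = MS_group / MS_subjects(group); F(time), F(group×time)
  against the within-subject residual;
- partial eta-squared η²ₚ = SS_effect / (SS_effect + SS_error-term),
  classified small / moderate / large at 0.01 / 0.06 / 0.14;
- four simple-effect t contrasts (time within each group, group at each
  time) corrected with **Shaffer's sequentially rejective Bonferroni
  procedure**: the step-i divisor is the largest number of nulls that can
  simultaneously be true after i−1 rejections, which the logic of the four
  cell-mean equalities caps at (4, 2, 2, 1);
- noncentral-F power utilities (a-priori sample size, post-hoc achieved
  power from observed η²ₚ).

## Worked example

Simulate a full 18-participant study (9 per group, three lateral
perturbations per 60-s tandem-stance trial) in which the device group's
peak ML displacement drops by 3 mm at post-test, then run the pipeline:

```bash
copreact simulate study --out demo --seed 7 --n-per-group 9 --wbed-post-delta -3
copreact extract --manifest demo/truth.json --out demo/features.csv
copreact analyze demo/features.csv --out demo/results.json
copreact report demo/results.json
```

which prints, for the peak ML displacement:

```
== d_ml ==
  group       F(1,16) = 4.442, p = 0.0512   eta_p^2 = 0.217 (large)
  time        F(1,16) = 15.085, p = 0.0013*  eta_p^2 = 0.485 (large)
  group:time  F(1,16) = 9.768, p = 0.0065*  eta_p^2 = 0.379 (large)
    post vs pre within WBED      p = 0.0003 (adj 0.0014) rejected
    Sham vs WBED at post         p = 0.0177 (adj 0.0353) rejected
    Sham vs WBED at pre          p = 0.1715 (adj 0.3431) retained
    post vs pre within Sham      p = 0.6515 (adj 0.6515) retained
```

Read: the injected post-only decrease in the device group shows up as a
significant time main effect and group×time interaction, and the
Shaffer-corrected contrasts localize it — the pre-to-post change is
significant within the device group but not within sham, while the groups
did not differ at baseline. The same objects are available as a library
(`copreact.run_extract`, `copreact.run_analyze`, `copreact.splitplot_anova`,
`copreact.shaffer_adjust`, ...).

## Layout

- `src/copreact/io.py` — recording/feature I/O, COP from force/moment channels
- `src/copreact/preprocess.py` — zero-phase Butterworth filtering
- `src/copreact/epochs.py` — onset detection, epoching, baseline correction
- `src/copreact/features.py` — D-COP / T-COP / V-COP / RMS, trial aggregation
- `src/copreact/stats.py` — split-plot ANOVA, Shaffer, power
- `src/copreact/synthetic.py` — ground-truth generators (recording / table / study)
- `src/copreact/pipeline.py`, `cli.py`, `config.py` — orchestration

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.
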
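# hiftload

Internal training-load quantification and psychometric evaluation for
high-intensity functional training (HIFT) session logs.

HIFT programmes (CrossFit-style, constantly varied, multi-modal) make
external-load quantification impractical, so practitioners monitor
*internal* load instead. The cheapest internal measure is the session-RPE
load — but is a participant's perception a valid and reliable stand-in for
what their cardiovascular system actually did? `hiftload` implements the
three session-level load metrics and the statistical machinery to answer
that question on any per-session log of duration, heart rate and Borg RPE,
plus a synthetic cohort generator so the whole pipeline is testable without
wearable data.

## The metrics

For one session of duration *D* minutes:

- **sRPE** = *D* × RPE, with RPE on the original Borg 6–20 scale;
- **Edwards' TL** = Σ₅ (minutes in %HRmax zone *z*) × factor *z*, with
  zones 50–60, 60–70, 70–80, 80–90, 90–100 %HRmax weighted 1…5 (time below
  50 % counts 0);
- **Banister TRIMP** = *D* × HRr × 0.64·e^(1.92·HRr), where
  HRr = (HR<sub>session</sub> − HR<sub>rest</sub>) / (HR<sub>max</sub> − HR<sub>rest</sub>)
  is the fractional heart-rate reserve.

## The evaluation

- **Criterion validity**: Pearson *r* between sRPE and each HR-based
  criterion at the individual, pooled-group and per-sex level (pairwise
  deletion per criterion), plus per-training-block OLS of the criterion on
  sRPE with a bootstrap 95 % CI for *R*², a Durbin–Watson check (1.5–2.5
  window) and a Breusch–Pagan homoscedasticity screen.
- **Intra-rater reliability**: each participant's RPE values and mean
  session HRs are split into *within-subject* quartiles (their own
  empirical 25/50/75 percentiles); agreement between the two quartile
  labels per session is summarised by the coefficient of agreement (CoA,
  the raw proportion of matches) and an intraclass correlation
  (ICC(A,1), absolute agreement, single measurement) with a 95 % CI —
  overall and per 3-week training block.

## Worked example

Quantify one 60-minute session (RPE 15, mean HR 150 bpm, resting 60,
maximum 190, zone minutes 5/10/15/15/10/5 from below-50 % up to 90–100 %):

```python
import hiftload as hl

srpe = hl.compute_srpe(60.0, 15)
hrr = hl.compute_hrr(150.0, 60.0, 190.0)
trimp = hl.compute_trimp(60.0, hrr)
edw = hl.compute_edwards((5, 10, 15, 15, 10, 5))
print(f"sRPE       = {srpe:.1f}")
print(f"HRr        = {hrr:.4f}")
print(f"TRIMP      = {trimp:.2f}")
print(f"Edwards TL = {edw:.1f}")
```

```
sRPE       = 900.0
HRr        = 0.6923
TRIMP      = 100.44
Edwards TL = 150.0
```

sRPE says this hour "cost" 900 arbitrary units (60 min at "hard"); the
session used 69 % of the heart-rate reserve on average, worth about 100
Banister units once the exponential intensity weighting is applied; and the
zone-weighted Edwards load is 150 (an all-out hour in the top zone would
score 300).

Or run the whole pipeline from the shell on a simulated cohort:

```bash
hiftload simulate --seed 1 --out-dir cohort/
hiftload run --participants cohort/participants.csv \
             --sessions cohort/sessions.csv --seed 1 --out-dir results/
```

`results/` then contains per-session loads (`loads.csv`), the quartile
agreement report (`reliability.json`), the Table-style correlation sheet
(`validity_correlations.csv`, one row per participant plus Overall / Males
/ Females), the block regressions (`validity_regression.json`), and a
`manifest.json` recording the config hash, seed and output checksums —
re-running with the same seed reproduces every byte.

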
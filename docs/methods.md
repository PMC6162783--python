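# Methods

## Load metrics

Each completed session is reduced to three internal-load numbers.

**sRPE.** Duration (min) × Borg 6–20 RPE. RPE outside 6–20 is rejected; an
absent RPE gives an absent load, never zero. Range for a session of
duration *D* is therefore [6·*D*, 20·*D*].

**Edwards' TL.** Minutes in the five %HRmax zones (50–60 … 90–100) weighted
1…5 and summed. Zone bands are half-open [lower, upper) with the top band
closed at 100 %, which avoids double counting at shared boundaries; time
below 50 % HRmax carries factor 0, consistent with the method's intent that
easy time contributes nothing. Bound: 0 ≤ TL ≤ 5·*D*.

**Banister TRIMP.** *D* × HRr × b·e^(k·HRr) with
HRr = (HR_session − HR_rest)/(HR_max − HR_rest). The default coefficient
pair (b, k) = (0.64, 1.92) is applied to all participants; the classic
sex-specific pairs (male 0.64/1.92, female 0.86/1.67) are available behind
`weighting="sex_specific"` because the original method differs by sex.
TRIMP is strictly increasing in both *D* and HRr and is zero iff HRr = 0.

**HRr clamping.** When a session's mean HR falls outside
[HR_rest, HR_max] — plausible whenever HR_max is age-predicted — HRr is
clamped to [0, 1] with a warning rather than the session being dropped:
dropping would silently change the analysable n.

## Within-subject quartile agreement

Reliability asks whether a participant's *perceived* effort ranking of
their own sessions matches their *physiological* ranking. For each
participant, RPE values and mean session HRs are independently mapped to
quartiles 1–4 using that participant's own empirical 25/50/75 percentiles
(linear interpolation). A value exactly at a cutpoint goes to the lower
quartile, so tied values always share a quartile and the assignment is
deterministic. Participants contributing fewer than 4 complete sessions are
excluded with a warning; an all-constant vector is assigned quartile 1
throughout, with a warning.

Two indices summarise agreement over the pooled session pairs:

- **CoA**: the exact proportion of sessions with matching quartiles. Chance
  level for independent uniform quartiles is 1/4; no chance correction is
  applied (kappa is deliberately out of scope).
- **ICC**: computed by pingouin on the paired quartile indices treated as
  two ratings (perception, physiology) of each session. The default variant
  is ICC(A,1) — two-way, absolute agreement, single measurement — because
  absolute agreement matches the "correct matching" framing; the variant
  string is recorded in every result. Identical vectors with spread give
  ICC exactly 1 (degenerate CI [1, 1]); zero variance in both vectors makes
  the ICC undefined and it is reported absent; with fewer than 10 pairs the
  CI is suppressed. pingouin reports the CI bounds to two decimals.

**Blocks.** The study calendar is split into two 3-week training blocks
(default weeks 2–4 and 6–8; fully configurable, and the definition must
partition the observed weeks). Per-block quartiles are recomputed from the
block's own sessions by default (`block-local`), reading the question as
"reliability within the period analysed"; `study-wide` mode (full-study
quartiles, then split) is also available because the choice materially
affects results and neither reading is canonical.

## Validity analysis

Pearson *r* between sRPE and each criterion at individual, group and sex
scope, two-sided p-values, significance at α = 0.05. Sessions are selected
by pairwise deletion per criterion, so Edwards and TRIMP generally have
different n. Participants with fewer than 3 complete pairs get an entry
with r absent plus a warning, and count as non-significant in the
fraction-significant summary.

Per-block validity uses OLS of the criterion on sRPE. For a simple
regression R² equals the squared Pearson r to machine precision, and the
suite asserts this identity at 1e-12. The 95 % CI for R² is a seeded
percentile bootstrap over sessions (2000 resamples by default) — a
deliberately assumption-light default; an analytic alternative
(`ci_method="fisher"`) squares the Fisher-z interval for r, flooring the
lower bound at 0 when the r interval straddles zero. Both are labeled in
output. Diagnostics: Durbin–Watson with a pass flag for the conventional
1.5–2.5 window, and a Breusch–Pagan screen whose flag (p ≥ 0.05 ⇒
homoscedastic) is advisory only; a perfect fit has no residual spread to
screen and reports the flag as absent.

## Synthetic cohort generator

The generator emulates the monitoring structure of a six-week HIFT cohort
study; its defaults are the study conditions, fixed once:

| parameter | default | why |
|---|---|---|
| n_participants | 25 (13 M / 12 F) | cohort size and sex ratio of the emulated study |
| sessions_per_participant | 30 over 6 weeks | 5 sessions/week schedule |
| week_labels | (2,3,4,6,7,8) | study calendar; makes the default block split (2–4 vs 6–8) a partition |
| adherence_rate | 0.879 | observed adherence 87.9 % |
| duration | N(60, 10) min, floor 20 | ~1 h sessions |
| intensity_mean | 0.67 | block-mean RPE ≈ 15 ⇒ perceived fraction ≈ 0.67 |
| intensity_sd | 0.25 | RPE SD ≈ 3.3–3.7 ⇒ 14·σ ≈ 3.5 |
| perceptual_noise_sd | 0.15 | implied perception–physiology r ≈ 0.86, matching observed group validity |
| block_drift | −0.25 | second block perceptually less noisy (learning curve) |
| missing_hr_rate, missing_rpe_rate | 0.05 each | a few percent device/reporting dropout |
| zone_concentration | 12 | zone occupancy tight around the session mean %HRmax |
| hr_max_formula | 220 − age | standard convention; 208 − 0.7·age available |

Per session: true relative intensity I ~ truncated normal on (0.05, 0.99);
mean HR = rest + I·(max − rest); zone minutes are a Dirichlet draw whose
concentration weights follow a Gaussian kernel (bandwidth 0.08) around the
session's mean %HRmax, scaled to the duration (so they sum to it exactly);
perceived intensity P = clip(I + ε, 0, 1) with
ε ~ N(0, noise_sd·(1 + drift·sign)), sign −1/+1 for first/second half of
the weeks; RPE = round-half-up(6 + 14·P) clipped to 6–20. Attendance is
Bernoulli per scheduled session; HR mean, zone minutes and RPE are blanked
by independent draws, which is what produces slightly different analysable
n for the two criteria. One seeded NumPy generator drives everything, so a
config is bit-reproducible.

**What the generator does not emulate.** No autocorrelation across sessions
(fatigue, periodisation), no participant-level heterogeneity in mean
intensity or perceptual bias, no workout-type structure, and RPE depends on
heart-rate reserve only — no duration or modality effect on perception.
Passing tests therefore show the *pipeline* behaves correctly under a
plausible data-generating process, not that real HIFT data would yield
these effect sizes.

**A structural ceiling on noise-free agreement.** Even with zero perceptual
noise, pooled CoA does not approach 1: RPE is an integer on a 15-point
scale, so ~30 sessions per participant force tied RPE values (2–3 sessions
per value). Whenever an empirical quartile cutpoint falls inside a tie
group, the whole RPE group takes the lower quartile while the continuous
HR values split across the boundary. Under the defaults this caps
noise-free CoA near 0.83 (≈ 0.87 even with near-uniform RPE spread); the
group-level Pearson validity in the same limit exceeds 0.9 on every seed.
This is a property of discretised ratings plus within-subject quartile
binning, worth remembering when interpreting CoA on real data too.

## Numerical and design choices

- Percentile convention: NumPy's default linear interpolation; documented
  boundary rule "at the cutpoint ⇒ lower quartile"; no random
  tie-breaking anywhere.
- CSV dialect: comma, UTF-8, header mandatory, '.' decimal; absent values
  are empty cells, never 0; floats written with shortest round-trip repr
  and read back with pandas' round-trip parser so write∘read is the
  identity.
- All stochastic steps (generator, bootstrap) take explicit seeds; the
  pipeline manifest records the config hash, seed and per-file SHA-256, and
  contains no timestamps, so re-runs are byte-identical.
- Pipeline problem size: the default cohort (25 × 30 sessions) runs the
  full quantify → reliability → validity chain, bootstrap included, in a
  few seconds on one CPU.

## Limitations

- The ICC is applied to ordinal quartile indices 1–4, as the agreement
  procedure prescribes; treating ordinal labels as interval-scaled is part
  of the method being implemented, not a recommendation.
- The bootstrap CI for R² is percentile-based and can be optimistic for
  very small blocks; below 10 pairs it is suppressed rather than reported.
- Wearable binary formats (FIT/TCX) are out of scope; the CSV schema is
  documented for adapter authors.
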
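# Methods

## Data model and validity gating

The raw unit of data is a 60-second epoch carrying one of six classifier
labels (walking, standing, sitting, lying, running, cycling). Analysis uses
only the first four: cycling is remapped to walking (in this population,
cycling calls arise from walker-assisted walking, whose low stepping frequency
and forward lean mimic cycling's accelerometer signature) and running — which
does not occur in faithful data — is remapped to walking too, so the remap is
total and deterministic. The remap table is configurable; every applied remap
is counted in the provenance log.

A participant enters analysis only with at least 24 consecutive hours of
labelled epochs; a contiguous 24-h span necessarily covers both day-time and
night-time clock hours. Missing epochs are kept explicit as gap markers and
are never imputed or bridged: any gap terminates a run, and a participant
without a long-enough run is excluded (logged), never patched.

A "day" is a rolling 1440-epoch window anchored at the first epoch of the
longest valid run, not a calendar day: it maximises usable data and makes the
24-hour perspective literal. The trailing remainder shorter than one day is
excluded from daily means. Bouts are detected on the whole contiguous
segment, so a bout running across the final day boundary keeps its full
duration and is attributed to the window in which it starts; bouts starting
inside the remainder are not counted. Transitions are counted over adjacent
epoch pairs whose first epoch lies within the full-day span.

## Pattern metrics

* **Time use**: per-activity epoch counts × epoch minutes, averaged over full
  day windows. On fully labelled days the four activities sum to exactly
  1440 min — an invariant the tests assert on every generated participant.
* **Bouts**: maximal same-label runs (run-length encoding). Durations are
  binned half-open `[lo, hi)` at 1–2, 2–3, 3–10, 10–30, >30 min for walking
  and standing and 1–5, 5–10, 10–30, 30–60, >60 min for sitting and lying, so
  a 2.0-min walking bout is "2–3 min" and a 60.0-min sitting bout is
  ">60 min". The published bin labels share endpoints and do not disambiguate
  this; half-open intervals are chosen because at 60-s epochs all durations
  are whole minutes and the bins then partition them uniquely. With 60-s
  epochs no bout can be shorter than 1 min; if sub-minute epochs are
  configured, sub-minute bouts are excluded from histograms and logged.
* **Transitions**: adjacent-epoch pairs matching exactly lying→standing,
  lying→walking, sitting→standing or sitting→walking. Indirect paths
  (lying→sitting→standing) count once, at the sedentary→active step, and
  within-class changes (lying→sitting, standing→walking) never count.

## Clinical scoring

NPI-NH items (each frequency × severity, 0–12) cluster into agitation
(agitation/aggression + disinhibition + irritability, 0–36), psychosis
(delusions + hallucinations, 0–24), affective (depression + anxiety, 0–24)
and apathy (0–12); four items (euphoria, aberrant motor, night-time
behaviour, appetite/eating) remain unclustered and enter only the 0–144
total. Items may be supplied as products or as separate frequency (0–4) and
severity (0–3) ratings multiplied on ingest.

SPPB sub-tests (balance, 4-m gait, chair stand; each 0–4) sum to 0–12; a
sub-test attempted but not completed scores 0, which keeps non-ambulant
residents in the analysis.

Severity staging is DSM-5-diagnosis-first: residents without dementia (with
or without MCI) form one combined group; dementia cases are banded on CDR
sum-of-boxes (4.5–9.0 mild, 9.5–15.5 moderate, 16.0–18.0 severe). A dementia
diagnosis with CDR-SOB ≤ 4.0 falls outside the named bands; the default
stages it as mild dementia (the clinical diagnosis dominates the staging)
with a warning, and a policy switch assigns it to the combined group instead.

## Group comparison

Tie-corrected Kruskal–Wallis (`H` divided by `1 − Σ(t³−t)/(N³−N)`; all-tied
input returns the degenerate `H = 0, p = 1`) followed by Dunn's pairwise
z tests on the pooled mid-ranks with the tie-adjusted variance
`N(N+1)/12 − Σ(t³−t)/(12(N−1))`. All tests are two-sided. Multiplicity
adjustment of Dunn's p-values is **off by default** — no particular
correction is imposed silently — with Holm and Bonferroni selectable; the
choice is recorded in the output. The Kruskal–Wallis implementation is
cross-checked against an independent library implementation in the tests.

## Association models

For each of the five activity metrics as outcome, a gamma GLM with log link
on the six clinical predictors plus intercept, fitted by IRLS (relative
tolerance 1e-8, up to 100 iterations) with dispersion estimated by Pearson
chi-square / (n − p) and Wald SEs, p-values and 95% CIs. Severity enters as a
single ordinal 1–4 covariate (one coefficient, not three dummy contrasts).
Coefficients are also reported as percent changes `100·(exp(β)−1)`.

Zero outcomes (e.g. a resident who never walked) are incompatible with the
gamma likelihood; the default policy adds half the metric's resolution
(0.5 min, or 0.5 transitions) to the zero values only and reports how many
were shifted; `zero_policy="drop"` removes them instead. Robust or clustered
standard errors are deliberately not used. The model direction is activity ~
clinical; the results object states explicitly that the reverse reading is
the same cross-sectional association and makes no causal claim.

## Synthetic cohort generator

Each participant's behaviour is a semi-Markov process: an embedded Markov
chain over the four states (defaults have no self-transitions, so chain
steps and bouts coincide) with log-normal dwell times in minutes, rounded to
whole epochs with a 1-epoch floor. All state-to-state moves are allowed —
lying→sitting is realistic and common — while only the four listed pairs
feed the transition metric.

**Defaults are solved, not tuned.** For a group with daily time-use targets
`T_s` (minutes) and counted-transition target `tr`, the stationary
distribution `π` of the embedded chain gives the expected time fraction
`π_s E[d_s] / Σ π_k E[d_k]` and the counted-transition rate
`(1440/Σ π_k E[d_k]) · Σ_pairs π_i P_ij`. Inverting these yields the mean
dwells `m_s = T_s·C/π_s` with `C = Σ_pairs π_i P_ij / tr`, and the
log-normal location for each state is then solved numerically so the
*discretised* dwell mean (whole-epoch rounding, 1-min floor) equals `m_s`.
Group targets use published group-level values where available (standing in
mild and severe dementia; lying in the no-impairment/MCI, mild and severe
groups; transition means in all four groups) and are otherwise back-solved so
the size-weighted (25/73/47/18) cohort means equal the published overall
means — 17.6 min walking, 66 min standing, 594 min sitting, 762 min lying,
22 transitions/day — with sitting taken as the 1440-minute remainder. The
analytic time-fraction and transition-rate identities are the generator's
correctness oracles and are verified by long-run simulation in the tests.

Dwell spreads (log-SD 0.55 / 0.80 / 1.10 / 1.00 for walking / standing /
sitting / lying) give short, narrow upright bouts and long-tailed sedentary
bouts. Between-participant heterogeneity has two parts: a common tempo
multiplier on all dwells (log-normal, log-SD 0.45, centred so the expected
transition *rate* is unchanged), which spreads daily transition counts
without moving time-use fractions, and independent per-state multipliers
(log-SD 0.20) that spread time use. Near the 1-epoch floor the dwell
discretisation responds asymmetrically to these multipliers, which biases
mean walking time upward by roughly 5–10% relative to the analytic target —
well inside the generator's Monte-Carlo acceptance bands, and documented
rather than corrected to keep the parameterisation transparent. The severe
group's back-solved walking dwell falls below the smallest discretisable
mean, so it clamps at the floor (that group's walking minutes run slightly
above target; the cohort effect is < 0.2 min).

Clinical scores are generated after the activity sequences. NPI items are
Poisson draws around per-item means derived from the published group
subsyndrome means (clipped at 12); SPPB is a latent group baseline plus
configured "truth" loadings on the participant's standardised activity
metrics plus Gaussian noise, rounded and clipped to 0–12 and split into
sub-scores. The default truth encodes the reported association pattern —
physical function loads positively on walking, standing and transitions and
negatively on lying, with no NPI loadings. With all loadings zero the
clinical table is exactly independent of activity; `null_config()`
additionally gives every group the identical overall activity process so all
six model predictors (severity included) are genuinely null — the
configuration used for the type-I-error calibration check. The truth ledger
written beside each cohort records the per-group analytic expectations and
the generative loadings, and notes that the loadings are generative, not
reverse-regression coefficients: the fitted activity~clinical magnitudes are
not expected to equal them, but signs and independence are, and both are
verified in the tests.

Default cohorts use two 24-h wear days per participant; simulation studies in
the test suite use one day and the summary-level fast path (metric-identical
to expanding epochs and running the pipeline — asserted exactly in a test) to
keep many-replicate runs cheap. The type-I calibration uses 200 replicate
cohorts of n = 163; the sign-recovery check uses 25 replicates at n = 500.

## What the synthetic data do and do not show

The generator reproduces group-level time-use, bout-scale and transition
structure and a known clinical dependence, so passing tests demonstrate the
pipeline's correctness, calibration of the nominal test level under the null,
and recoverability of encoded associations. It does not emulate circadian
structure (no day/night dwell modulation), classifier error processes,
within-epoch mixed behaviour, medication or ward effects, or the full
between-resident dispersion of the real cohort (published group SDs are only
partly available); conclusions about real nursing-home data rest on the
method, not on these simulations.

## Numerical choices

* Bout bins half-open `[lo, hi)`; ties impossible at 60-s resolution.
* Longest-run selection on ties: earliest run wins (deterministic).
* Kruskal–Wallis guards tiny negative round-off in `H` at 0; the all-tied
  tie-correction ≤ 0 short-circuits to `H = 0, p = 1`.
* GLM rank deficiency is detected before fitting and reported with the
  collinear column names; non-convergence raises rather than returning a
  partial fit. CIs use the exact normal 0.975 quantile, so "CI excludes 0"
  and "p < 0.05" agree.
* All simulation randomness flows through one `numpy` Generator seeded from
  the cohort config; identical configs produce byte-identical output files.
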
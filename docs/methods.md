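# Methods

This note documents the analysis model, the parameter choices, the
synthetic-data generator, and the numerical decisions behind `cprqual`.

## Data model

The unit of analysis is one resuscitation attempt: an ordered stream of
compression events, each a `(time, peak depth)` pair with time in seconds
from scenario start (t = 0 when the patient is found) and depth in mm.
This event-level abstraction deliberately discards the displacement
waveform: per-compression peak depth and timing are sufficient for every
quantity computed here, and they are what compression-sensing manikins and
feedback pucks log. Ventilation events may appear in input files but are
ignored; leaning/incomplete release and hand position are not modelled.

The analysis span is the first 12 minutes (720 s). Longer attempts are
truncated; shorter ones are an error by default, or analysed over their
complete minutes only when explicitly allowed (`allow_short`), since a
partial final minute would bias its mean.

## Per-minute metrics

Minute *m* (1-based) is the half-open window `[60(m−1), 60m)` s, so a
boundary event belongs to exactly one minute. Mean depth is the arithmetic
mean over compressions in the window; a compression-free minute has
undefined depth.

Rate is the *active* compression rate: `60 / mean(Δt)` over
inter-compression intervals with `Δt ≤ pause_threshold` (1.5 s), each
interval attributed to the minute containing its midpoint. The midpoint
rule is a deterministic, unbiased tie-break for intervals spanning a minute
boundary. The active-rate definition (rather than compressions per elapsed
minute) is the internally consistent choice: it lets rates of 100–120/min
coexist with a no-flow ratio near 20%, which elapsed-time rates cannot.

## Quality classification

Each attempt is labelled twice, independently, against 2005-guideline
criteria — depth `≥ 40 mm`, rate inside `[100, 120]/min`:

* **good** — every analysed minute satisfies the criterion;
* **bad** — minute 1 fails it. "Initial" means minute 1's average, the
  finest granularity the per-minute reduction offers. The label is frozen
  at minute 1: an attempt that starts inadequate and later comes into
  range stays *bad* (its problem is initial technique, not fatigue);
* **decay** — a compliant minute 1 with some later failing minute; the
  onset is the first failing minute.

Comparisons are inclusive at the printed boundaries (exactly 40 mm, or
exactly 100 or 120/min, is compliant) and made on exact stored values with
no pre-rounding. An undefined minute metric fails its criterion — a minute
without compressions cannot satisfy "for every minute". The three labels
partition any cohort; raising `depth_min` can only move a label along
good → decay → bad. `depth_min` is configurable (e.g. 50 mm for the 2010
guidelines), but no separate 50 mm analysis is built in.

## No-flow ratio

A pause is any maximal compression-free interval longer than
`pause_threshold` = 1.5 s — roughly three missed compressions at guideline
rate, the convention in CPR-quality work; the threshold is exposed as a
knob because recording devices differ. When a gap exceeds the threshold
the *entire* gap counts as hands-off, which keeps hands-off time monotone
in gap length. The leading interval from t = 0 to the first compression
counts (initial patient assessment is genuine no-flow), as does the
trailing interval after the last compression.

NFR is hands-off time divided by span, reported overall (720 s) and in
four 180 s windows with boundaries at 0/180/360/540/720 s, matching the
three-minute rhythm-check cycle of Norwegian ALS guidelines; pauses are
clipped at window boundaries, so window hands-off seconds sum exactly to
the overall total and the overall NFR equals the mean of the four window
ratios. NFR depends only on event timing, never on depth.

## Trend statistics

The NFR trend over the four periods is tested with a one-way
repeated-measures ANOVA computed from the textbook within-subject
decomposition (implemented directly so it can be verified against a
brute-force oracle; distribution functions come from scipy):

    SS_total = Σᵢⱼ (xᵢⱼ − x̄)²        SS_subj = k·Σᵢ (x̄ᵢ. − x̄)²
    SS_cond  = n·Σⱼ (x̄.ⱼ − x̄)²       SS_err  = SS_total − SS_subj − SS_cond
    F = (SS_cond/(k−1)) / (SS_err/((k−1)(n−1)))

No sphericity correction is applied by default (the plain test is the
reference analysis); a Greenhouse–Geisser option is available, leaving F
unchanged and computing the p-value from epsilon-scaled degrees of
freedom. With k = 2 the F statistic equals the
squared paired-t statistic exactly. Degenerate inputs: an all-identical
matrix raises a zero-variance error; pure subject shifts (no condition
effect at all) return F = 0, p = 1; zero error variance with a nonzero
condition effect raises, since F is unbounded.

Pairwise follow-ups are two-sided paired t-tests (sidedness is the
conservative default) of period 1 against periods 2, 3 and 4, flagged at
the Bonferroni level `0.05/3 ≈ 0.0167` (reported rounded as 0.017).
Identical paired vectors return t = 0, p = 1; a constant nonzero
difference has no sampling variance and raises.

## Synthetic-data generator

The generator emulates the scenario the analysis targets: a 12-minute ALS
attempt on a recording manikin, found in ventricular fibrillation,
converting to pulseless electrical activity (PEA) after the first shock
(so no later shocks), intubated around five minutes (after which
compressions continue through ventilations and hands-off time shrinks),
with a single provider delivering all compressions.

Per attempt, compressions are laid down sequentially: the next compression
falls `60 / rate(t)` after the previous one and jumps to the end of any
scheduled pause it lands in. The rate model is
`rate(t) = baseline + drift·t/60 + N(0, σ_rate)` per compression; the
depth model is `depth(t) = baseline + slope·max(0, t/60 − (onset−1)) +
N(0, σ_depth)`, truncated at 0 — linear fatigue decay beginning at the
start of the 1-based onset minute. Per-compression Gaussian noise is the
simplest model consistent with the within-provider spread seen in such
recordings; no claim of biomechanical realism is made. Piecewise
per-minute mean profiles (`depth_minute_means` / `rate_minute_means`) can
override the parametric mean where a trajectory is not baseline-plus-line
(e.g. an attempt adequate only in its middle minutes). Everything is
deterministic given the config seed; cohort sub-seeds derive independently
from a master seed, so regenerating one attempt never perturbs another.

### Reference cohort

`reference_cohort()` (master seed 4040, an arbitrary documented constant)
builds a 19-attempt cohort whose *group structure* mirrors what a
prolonged-ALS manikin study typically finds, and which the test suite and
acceptance script verify end to end:

* depth: 5 good / 9 bad / 5 decay, decay onsets at minutes 2, 4, 8, 11
  and 12; one bad attempt reaches ≥ 40 mm during minutes 3–8 only (and
  stays *bad* — the label freezes at minute 1);
* rate: 6 good / 6 bad / 7 decay with a single onset within the first five
  minutes; five attempts start above 120/min; two bad attempts are in band
  from minute 2 on;
* NFR: cohort window means 22%, 22%, 14%, 10% (integer-rounded), overall
  mean 17%, per-attempt overall range 10–32%; the trend ANOVA is
  significant at p < 0.001, with period 1 vs 2 non-significant and 1 vs
  3/4 significant at the 0.017 level.

Mechanically, each attempt's hands-off budget is a scale factor `s_i`
(mean exactly 1.0 over the cohort, extremes 0.59 and 1.88) times per-window
targets (39.6, 39.6, 25.2, 18.0) s, split across a fixed narrative
schedule: initial assessment from t = 0, defibrillation near 60 s, rhythm
checks at 180/360/540 s, intubation near 300 s, with post-intubation gaps
smaller. Because compressions resume exactly at a pause's end, each
scheduled non-leading pause is measured with an overshoot of less than one
inter-compression interval (~0.27 s on average), a bias small against the
±0.5-point integer-rounding slack of every cohort-level target. Depth
noise is 1.5 mm and rate noise 3/min per compression, with every profile
placed ≥ 2 mm or ≥ 3/min clear of its threshold, so minute means sit many
standard errors from the decision boundaries and the classifications are
stable. The per-attempt trajectories and pause durations are invented
tuning constants — plausible synthetic stand-ins, not measurements from
any study.

### What passing on synthetic data does and does not show

The generator produces exactly the structure the analyzer assumes:
piecewise/linear minute-mean trajectories, i.i.d. Gaussian per-compression
noise, cleanly separated pauses, no drift within a minute, no missing or
spurious events. Passing tests therefore demonstrate that the pipeline's
arithmetic, window logic, classification and statistics are correct — not
that real recordings satisfy these assumptions. Real data add sensor
noise and dropouts, non-monotone timestamps, provider switches,
incomplete release, and chest-stiffness variation, none of which are
emulated; the analyzer is insensitive to pause *causes* by design, so the
generator's cause tags are never consumed downstream.

## Numerical choices

* Parameter recovery (simulation, 200 seeds per setting): the classifier
  recovers a configured depth-decay onset exactly in ≥ 95% of runs at
  slope −2 mm/min with 0.5 mm noise, and within ±1 minute at slopes ≥ 1
  mm/min with noise ≤ 1 mm. A slope of −1 mm/min is systematically caught
  one minute late from a 40.8 mm baseline — the onset minute's mean
  (baseline − 0.5 mm) is still above 40 mm — which is a property of
  minute-resolution thresholding, not an estimator bug.
* Oracle agreements (brute-force window means, gap scans, sums of
  squares) are asserted to 1e-9; generator/analyzer noise-free
  consistency likewise, as both sides evaluate the same depth function at
  the same event times.
* Attempt CSVs use shortest round-trip float formatting, so
  write → read is exact and rewriting is byte-identical; report CSVs use
  fixed 6-decimal formatting for stable diffs. Human-readable summaries
  round percentages to integers; machine outputs keep full precision.
* Problem sizes in the test suite (19×4 matrices, 100–200 replicates,
  ≤ 150-event random streams) keep the whole suite around ten seconds
  while leaving every statistical check far from its decision threshold.

## Known limitations

* Minute-resolution classification cannot see sub-minute decay; an onset
  is never earlier than minute 2 by construction.
* The bad label is frozen at minute 1; transient initial failures (e.g. a
  slow first minute from a delayed start) are not distinguished from
  persistent ones, though the classification table retains the full
  per-minute record for inspection.
* The pause threshold and the leading-interval convention are device
  conventions, not physiology; both are configurable and cohort NFR values
  shift with them.
* The pipeline offers no non-parametric fallback for the trend analysis;
  with n = 19 and k = 4 the paired t follow-ups carry the inferential
  weight, and sphericity violations are addressed only by the optional
  Greenhouse–Geisser correction.
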
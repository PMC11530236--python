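# Methods

This note records the models, conventions and calibration choices behind
`ratpheno`, in the order data flows through the pipeline.

## Study tables and imputation

The study is three tidy CSV tables (rats, sessions, irritability) validated
against explicit invariants: phase-specific session durations (2 h ShA, 6 h
LgA, 1 h pre-shock/shock), day indices within phase ranges (ShA 1–10, LgA
1–14, PR 1–3), count ordering (`hour1_infusions ≤ infusions ≤
active_presses` under FR1), naive animals carrying no self-administration
sessions, and irritability totals equal to aggressive + defensive. Day
indices count sessions (5 sessions/week), not calendar days. Excluded
animals (catheter-patency failures) are dropped before any group statistic
is computed, so they never contribute to the normalising μ/σ.

A session lost to equipment failure is imputed as the mean of the adjacent
days' values. That rule only defines isolated interior gaps; runs of two or
more missing days and missing first/last days are left unresolved, flagged,
and excluded from any summary that needs them (a warning is emitted). In
practice such failures affect well under 2% of sessions, so nothing more
elaborate is warranted.

## Behavioral metrics

* **Escalation** — mean of LgA days 12–14 after imputation; undefined if any
  of those three days is unresolved.
* **Progressive ratio** — the requirement for reward *j* is the printed
  schedule for j ≤ 18 and `round(5·e^(0.2 j)) − 5` (half away from zero)
  beyond it; the module verifies at import that the closed form regenerates
  the printed 18 terms. The breakpoint scan treats the gap from session
  start to the first completion, and from the last completion to session
  end, as eligible 60-min lapses; this start-edge convention is not forced
  by the stated rule and is isolated in one predicate. A session with no
  completion has breakpoint 0. The motivation metric is the infusion count
  of the first post-LgA PR test (the one preceding the shock session);
  a switch selects the post-shock test instead, since the protocol runs PR
  twice after LgA and the choice is not fully determined.
* **Compulsivity** — infusions in the 1-h shock session; the pre-shock 1-h
  session provides the paired baseline, and suppression is reported both as
  a difference and a ratio (undefined at zero pre-shock responding).
* **Irritability** — per-assay scores are observer means of summed
  aggressive and defensive responses; the index metric is the withdrawal −
  baseline difference of the total.

## Indices and classification

Z-scores use the sample SD (n−1), matching the default of the common
statistical environments, and are computed per (cohort, sex) group; groups
with fewer than two values or zero SD are rejected rather than silently
propagated. The Addiction Index is the unweighted mean of the escalation,
motivation and compulsivity z-scores, complete cases only — a rat missing
any one of the three has no AI and is left out of severity grouping
(missing irritability does not affect the AI).

The resilient/vulnerable boundary is 50 mean infusions per LgA session,
with 50 itself classified vulnerable (resilience is the strict inequality).
Severity quartiles rank the AI ascending, break ties by stable input order,
and cut at cumulative counts `round_half_up(N·k/4)`, k = 1..3. This
convention is anchored by the divisible case (equal quarters) and by the
N = 511 case, where it yields 128/128/127/128 — the third (Moderate) group
is the short one; conventions that shortchange a different quartile are
thereby excluded. Because indices are standardized per sex, quartile
membership is approximately sex-balanced by construction.

## Statistical battery

Cohen's d uses the pooled SD and, by default, the asymptotic-variance
interval d ± 1.96·√((n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂−2))) — deterministic and
transparent; a noncentral-t inversion is available behind a flag and agrees
to first order. Pearson r carries a Fisher-z interval and the usual
t-transform p-value. PCA centers and scales each column to unit sample SD
and eigendecomposes the correlation matrix; loading signs are fixed so each
component's largest-magnitude loading is positive, making output
reproducible across linear-algebra backends. Power/sample-size uses the
exact noncentral-t power of the two-sided pooled t-test and increments n
from 2, so the returned n is minimal by construction (cross-checked in the
tests against an independent solver: d = 1.0 → 17, 0.67 → 36, 0.2 → 394
per group).

## Synthetic cohort: what it emulates

The generator's defaults are the study conditions: 567 cocaine rats plus
49 naive, 12 balanced cohorts, 50% female, 80% vulnerable.

A single-factor latent model drives the addiction behaviors: per rat a
severity factor a ~ N(0,1), behavior latents b_k = λ·a + √(1−λ²)·ε_k for
k ∈ {escalation, motivation, compulsivity}, and an independent irritability
latent. Equal loadings with λ = 0.678 (λ² ≈ 0.46) are the simplest
structure consistent with three indices sharing one dominant component: the
leading eigenvalue of the implied 4×4 correlation matrix is (1+2λ²)/4 ≈
48% of variance. Sex effects are additive on the standardized latent scale,
±d/2, at d = 0.41 (escalation), 0.32 (motivation), 0.67 (compulsivity),
0 (irritability).

Observable channels:

* ShA intake N(16, 4) rounded to counts, females ramping +0–4 infusions
  across days 1–10 (faster female acquisition).
* LgA intake: resilient rats flat N(35, 6); vulnerable rats ramp linearly
  from 55 to 95 by day 14, the ramp scaled by (1 + 0.3·b_esc), plus N(0, 8)
  noise. Class is Bernoulli(0.80), independent of the latents.
* PR rewards: round(12 + 6·b_mot + 5·[after LgA]), floored at 0.
* Pre-shock 1-h infusions: round(10 + 3·a), floored at 0. Shock infusions:
  round(pre·s + N(0, 2.7²)) with suppression s = logistic(0.8·b′ − 0.4),
  where b′ is the compulsivity latent with its sex shift amplified by 2.25.
* Irritability: baseline N(15, 4); withdrawal = baseline + 0.89·4·[cocaine]
  + 4·b_irr, split 60/40 into aggressive/defensive. Writing the withdrawal
  noise as 4·b_irr ties the irritability index to the rat's latent so
  recovery tests can target it; distributionally it is N(0, 4) noise.

**Calibration.** The shock channel is nonlinear (a logistic multiplying a
count), which attenuates both the latent sex shift and tempers the
pre/shock correlation in ways no closed form captures, so two constants
were solved jointly on a single 2×10⁶-rat calibration run and frozen as
defaults: the count-noise SD 2.7 sets corr(preshock, shock) ≈ 0.58, and the
sex-shift gain 2.25 makes the realized count-scale female−male effect size
equal the configured compulsivity d (≈ 0.66 at the population level).
Without them the raw model yields corr ≈ 0.83 and d ≈ 0.41 — inconsistent
with the statistical structure the generator exists to emulate. No other
channel is recalibrated: in particular the escalation channel's
resilient/vulnerable mixture dominates its count-scale variance, so the
realized count-scale sex d there (~0.14) is much smaller than the latent
d = 0.41; the configured values are statements about the standardized
latent scale except where noted.

**What the generator does not emulate.** Within-session event timing (FR1
lever pressing, cue lights, timeouts, shock delivery) — sessions are
summarized at the counts level, with evenly spaced PR event logs available
only as breakpoint fixtures. Real cohort batch effects, attrition,
catheter-patency exclusions and session failures are absent by default
(the exclusion and missing flags exist in the schema and are exercised by
hand-built fixtures in the tests). Real behavioral distributions are
heavier-tailed and the true index correlations arise from biology, not a
literal one-factor Gaussian; passing recovery tests therefore shows the
pipeline's arithmetic and classification rules are correct under the
assumed structure, not that the structure is true of rats.

A consequence worth noting: the full behavioral pipeline's nonlinearities
(rounding, the intake mixture, logistic suppression) attenuate the
index-battery correlations, so PCA of indices computed end-to-end from
simulated sessions yields PC1 ≈ 39% rather than the latent model's 48%,
while preserving the qualitative structure (three same-sign addiction
loadings, irritability orthogonal). Checks of the 48% figure therefore
draw the battery from the latent model itself, where the closed-form
eigenvalue is the oracle.

## Problem sizes and determinism

All stochastic checks run at desk scale: cohorts of 567 (20 seeds for the
vulnerable-fraction and PC1 recoveries), 50 replicates at n = 275/292 for
the sex-effect recovery, 4,000-rat cohorts where a tight sex-balance bound
needs small binomial noise, and 2×10⁵-row draws for closed-form PCA
limits. Every simulation seeds `numpy.random.default_rng` explicitly;
identical (config, seed) reproduce byte-identical tables, and the pipeline
manifest deliberately omits wall-clock time and output paths so that
re-runs of the same configuration are byte-identical bundles.

## Known limitations

* The Cohen's d interval is asymptotic; at very small n it can differ from
  noncentral-t-based intervals in the second decimal.
* The breakpoint start-edge convention (a rat earning its first reward at
  minute ≥ 60 scores 0) is one of two defensible readings of the lapse
  rule; it is documented above and trivially changed in one predicate.
* Quartile labels depend on the stated rounding convention at non-divisible
  N; alternative conventions shift one animal between adjacent groups.
* The generator's naive animals receive irritability assays only, so
  cocaine-vs-naive contrasts on self-administration measures are undefined
  by design.
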
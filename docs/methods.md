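# Methods

## The problem and the model

When a bystander watches one person divide a sum of money with another,
their emotional reaction and their willingness to punish the divider are
assumed to be driven by two social values: *selfishness aversion* (a
negative weight on the share the allocator keeps for themselves) and
*inequality aversion* (a negative weight on how unequal the final split
is, regardless of which direction the inequality runs). The package
models a participant's standardized response on each observed trial as a
linear function of trial features:

```
response = β0 + β1·selfishness + β2·inequality
         + β3·selfishness×endowment + β4·inequality×endowment
         + β5·even_split + ε,      ε ~ N(0, σ²)
```

where *selfishness* is the fraction of the endowment the allocator ends
up with, *inequality* = |2·selfishness − 1| is the absolute difference
between the two players' final shares, *endowment* is the standardized
stake size, and *even_split* is an indicator that fires only at the
exact 50/50 split — a "stick" capturing the discontinuous premium
observers place on perfect equality. The same functional form serves as
a *feeling function* (response = affect rating) and a *punishment
function* (response = punishment choice).

## Task designs

Two designs are generated, 4 blocks × 60 trials each, endowments £1–£15
each appearing 4 times per block:

- **Experiment 1 (taking).** The allocator takes 10–100% of the other
  player's endowment in 10% steps; selfish takes are over-represented
  (60–100% appear 9 times per block, 10–50% three times) so the observed
  behaviour looks realistic. Feelings are rated on blocks 2 and 4;
  punishment is available on all four blocks.
- **Experiment 2 (giving).** The allocator gives 0–90% of their own
  endowment away, uniformly (6 trials per level per block). Feelings are
  rated on blocks 1 and 3; punishment on blocks 2 and 4.

Endowment and allocation sequences are independent uniform permutations
of their fixed multisets: the stated counts are the whole constraint,
and no run-length or balancing restriction is imposed beyond them.
Per-(participant, block) sub-seeds are derived from the master seed via
`SeedSequence([seed, experiment, participant, block])`, so any single
block is reproducible in isolation.

## Regressor scaling

Printed descriptions of the regressors use a 0–100 percent scale and
leave the endowment units open. The package fixes one internal scaling
and uses it identically for generation and fitting, which makes every
recovery result invariant to the choice:

| regressor      | scale                                   | default range |
|----------------|-----------------------------------------|---------------|
| selfishness    | fraction of endowment kept              | 0.1 … 1.0     |
| inequality     | \|2·selfishness − 1\|                   | 0 … 1         |
| endowment      | (e − 8)/σ_grid, σ_grid = sd of 1..15 ≈ 4.3205 | −1.62 … 1.62 |
| even_split     | indicator                               | {0, 1}        |
| interactions   | products of the scaled terms            | —             |

The even-split comparison is exact floating-point equality, which is
safe because allocations live on a 10%-step integer grid until feature
construction.

## Model space and selection

The model space is every non-empty subset of the five regressors, each
with a constant — 31 models, enumerated by subset size and then
lexicographically in the canonical order (selfishness, inequality,
selfishness×endowment, even_split, inequality×endowment). Under this
numbering the selfishness-only model is model 1 and the four-regressor
model {selfishness, inequality, selfishness×endowment, even_split} —
the winning model in both experiments and for both response types — is
model 26.

Each model is fitted to each participant separately by OLS on their
z-scored responses (z-scoring uses the n−1 spread). Models are scored
with the concentrated-Gaussian BIC, `n·ln(RSS/n) + k·ln(n)`, with `k`
counting the constant plus regressors only; the noise variance term
would add an equal offset to every model and cannot change the ranking.
Group-level selection sums BIC across participants; ties break to the
lowest model id. A perfect fit (RSS = 0) has no finite BIC and is
reported as −∞, which only arises on noiseless synthetic data.
Group-level inference on the winning model's coefficients uses
one-sample two-sided t-tests against zero with t-based 95% CIs.

## Synthetic participants

The generator produces responses from any member of the model space:
linear prediction on the trial features plus additive Gaussian noise on
the standardized response scale, emitted only on trials where the design
collects that response. The published group-level winning-model
equations for both experiments and both responses ship as constants, so
cohorts with the published structure are one call away. Defaults:

- **Noise spread 0.5** on the standardized scale, which puts
  single-participant r² in the ballpark of the published fits (≈0.7).
- **Heterogeneity** (optional): per-participant coefficients drawn
  Normal(group mean, SEM·√n) using the published standard errors
  (n = 32 and 35 for the two source cohorts). No SEM is published for
  the constant, so it stays homogeneous by default.
- **Ratings stay continuous** — the −3..+3 slider is not re-imposed,
  because all fitting operates on z-scored continuous responses.
- **Punishment clipping off.** Punishment is generated on the same
  standardized linear scale the models are fitted on. A `clip` option
  truncates it to the feasible [0, 1] fraction range, but truncation
  biases OLS recovery, so it is off by default and in every recovery
  procedure.

What the generator deliberately does *not* emulate: slider motor noise,
response discretization, order and carry-over effects, post-punishment
affect, and any dependence of responses on previous trials. Passing
recovery tests therefore show that the estimation machinery is correct
under the model's own assumptions, not that the model is true of human
observers.

## Recovery diagnostics

**Parameter recovery** takes each participant's fitted coefficients and
residual spread, simulates a fresh data set from them (own coefficients,
own noise), refits, and reports the Pearson correlation between true and
recovered coefficients across participants, per regressor. A cohort with
no between-participant spread makes the correlation undefined; this is
flagged as degenerate rather than raised. Refitting skips
re-standardization so coefficients are recovered on the generative
scale.

**Model recovery** simulates a cohort from each generator model the same
way, fits every candidate model, and selects by summed BIC. The winner
is recorded only when it beats the runner-up by more than a ΔBIC
decision threshold (default 30); otherwise the row is undecided. The
empirical winner's margin is reported against a stricter threshold of
50. One simulated replicate per generator is the headline setting; a
weakly-identified generator (an extra coefficient small relative to the
noise and the BIC penalty) is correctly absorbed by its nested
neighbour, which is a property of BIC, not a defect of the procedure.

## Out-of-sample prediction

One experiment's *group-averaged* winning-model coefficients are applied
to the other experiment's trials (the regressor scales are shared across
designs), and each participant's observed standardized responses are
regressed on the predictions. Calibration is summarized by group
one-sample t-tests of the slopes against 1 and the intercepts against 0,
plus mean r².

## Behavioral descriptives

Trials partition by allocator type: selfish (keeps > half), equal
(exactly half), generous (keeps < half). Punishment is a fraction of the
punishable amount; deductions under 1% count as non-punishment (an
allowance for slider motor error; the 1% boundary itself counts as
punishment). Frequency is the proportion of punished trials and amount
is the mean fraction over all trials in a category. Allocator-type
effects use one-way repeated-measures ANOVAs (uncorrected degrees of
freedom, partial η² = SS_effect/(SS_effect + SS_error); the matrix with
identical condition means returns F = 0 by definition), with paired
t-tests and Cohen's d for follow-ups. The feelings–punishment coupling
is the per-participant Pearson correlation between standardized
feelings and punishment on trials carrying both (experiment 1's blocks
2 and 4 layout), aggregated by raw averaging of r with a group t-test
against zero; if every participant has the identical r the t statistic
degenerates to its sign.

## Problem sizes and numerical choices

The recovery runs that reproduce the published coefficient scale use
200 homogeneous simulated participants per condition (noise sd 0.5),
giving Monte-Carlo standard errors of roughly 0.01–0.02 per group-mean
coefficient — comfortably inside the ±0.1 acceptance band the runs are
judged against. Model-recovery checks run at the source cohort size
(32 participants) against the full 31-model space. OLS is solved by
`numpy.linalg.lstsq` after an explicit rank check; noiseless round
trips reproduce generating coefficients to better than 1e-8, and the
fitter agrees with the closed-form normal-equations solution to 1e-10.
All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; derived sub-seeds stay below 2³¹.

## Known limitations

- Punishment is modeled on an unbounded linear scale; the bounded
  fraction scale is only reached through the optional clip, whose
  truncation bias is acknowledged rather than corrected.
- The empirical coefficients were estimated on human data; with
  synthetic cohorts the package reproduces the *recoverability* of the
  published equations, not the human estimates themselves.
- No hierarchical or mixed-effects estimation: participants are fitted
  independently and aggregated by summary statistics, mirroring the
  two-stage procedure the package implements.
- Sphericity corrections are not applied in the repeated-measures
  ANOVA (uncorrected df are reported by design).
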
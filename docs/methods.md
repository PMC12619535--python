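# Methods

This note documents the statistical model, the numerical choices, and the
design decisions behind `mcidnorm`, in the order the pipeline applies them.

## MCID-unit normalization

Let an instrument have minimal clinically important difference `M` (scale
points).  A reported mean `x` becomes `x / M` MCID units; a reported SD
`s` becomes `s / M`.  Level normalization is orientation-agnostic (dividing
by a positive constant preserves order); orientation matters only for
*change* scores, where improvement on a higher-is-worse instrument (WOMAC)
is a score decrease, so the pre-minus-post difference is sign-flipped before
dividing so that positive always means improvement.

Change scores are paired data.  Their SD is

    SD_delta = sqrt(SD_pre^2 + SD_post^2 - 2 r SD_pre SD_post),

with `r` the pre/post correlation.  Primary studies almost never report `r`;
the default is `r = 0.5`, the conventional conservative midpoint, and any
change-score synthesis should be repeated over the sensitivity sweep
{0.2, 0.5, 0.8} (`SENSITIVITY_CORRELATIONS`).

**SD resolution order** for each record: (1) reported SD; (2) quarter-range
estimate `SD = (range_max - range_min)/4` when only a range is given;
(3) imputation borrowing the *largest* SD among donors sharing the
instrument and timepoint.  The maximum-donor rule is deliberately
conservative — an imputed SD can only shrink the study's weight, never
inflate it — and deterministic; a mean-of-donors variant is available.  A
record with no reported SD, no range and no donor is excluded with an
audited warning rather than aborting the batch.  Means outside the
instrument's scale bounds are kept but audited (source-table typos are
common; silent passage and hard failure are both worse than a logged flag).

**Rounding.** Published summary tables round ties away from zero
(half-up); Python's built-in banker's rounding differs at exactly .x5.
Reported one-decimal values therefore go through `round_half_up`; internal
computation always stays at full precision.

## Instrument registry

The packaged registry carries ten hip instruments.  Six have published
MCIDs — mHHS 9.5, iHOT-12 13.0, HOS-SSS 12.1, NAHS 8.5, HOS-ADL 9.8,
iHOT-33 10.7 points — sourced from hip-arthroscopy validation studies
(Nwachukwu 2018; Martin 2019; Bloom 2022; see the `mcid_source` column).
HOOS, WOMAC, HAGOS and HHS appear *without* MCIDs: they can be counted and
ranked, but normalizing them raises a `NonNormalizableError` (the pipeline
variant drops the record with an audited exclusion).  An instrument without
a divisor must be a visible decision, never a silent skip.

All shipped instruments are higher-is-better except WOMAC
(higher-is-worse).  Name lookup canonicalizes case, Unicode dash variants
and whitespace, and applies a synonym map carried in the registry *file*
(e.g. "HOS-Sport" → "HOS-SSS"), because reporting in the literature is
inconsistent and the synonym list is data, not code.

## Frequency ranking and prioritization

The ranking counts distinct (study, instrument) mentions in a long-format
incidence matrix; the packaged matrix covers 100 recent hip-arthroscopy
studies (218 mentions).  Mentions that cannot be resolved against the
registry — e.g. a bare "iHOT" with no version — are excluded from counts
(audited), while the study itself stays in the matrix.  Percentages use the
matrix's own total, never a hard-coded denominator.

NAHS and HOS-ADL tie at 27 mentions.  `rank_proms` breaks ties
lexicographically by default and records the rule; an explicit tie order
can override it.  The packaged default ranking file places NAHS ahead of
HOS-ADL, the order the worked demonstration tables use; prioritization
takes its governing ranking as an explicit input (file or packaged default)
rather than recomputing it implicitly, so the ranking that governed
selection is always a reproducible artifact.

Prioritization retains, per study, the highest-ranked instrument reported
by *every* arm — an instrument present in only one arm cannot produce an
effect size, so retention is decided on the intersection of the arms'
instrument sets (partially-reported instruments are audited).  Arms with
disjoint sets are an error, not a guess.  Running prioritization twice is
idempotent; discarded instruments are listed on each unified outcome and in
the audit log.

## Random-effects pooling

Per study, the mean difference in MCID units is `y = mean_1 - mean_2` with
the independent two-arm variance `v = sd_1^2/n_1 + sd_2^2/n_2`.  The arm
order is explicit: callers name the reference (subtrahend) arm; the
direction of "favors" is never inferred.

The random-effects model is `y_i ~ N(mu, v_i + tau^2)`.  `tau^2` is
estimated by REML, maximizing

    l(tau^2) = -1/2 [ sum_i log(v_i + tau^2) + log sum_i 1/(v_i + tau^2)
                      + sum_i (y_i - mu_hat)^2 / (v_i + tau^2) ],

with `mu_hat` the weighted mean at the current `tau^2`.  The maximizer is
found by Fisher scoring started at the DerSimonian–Laird moment estimate,
clamped to `tau^2 >= 0` after every step, converged when successive
iterates differ by < 1e-10, capped at 100 iterations.  Undamped Fisher
steps can oscillate around flat optima, so the iteration maintains a
score-sign bracket and falls back to bisecting it whenever a step
oscillates or leaves the bracket; boundary solutions at 0 are returned as
exactly 0.  Non-convergence raises an error carrying the last iterate.

Pooling uses inverse-variance weights `w_i = 1/(v_i + tau^2)`;
`se(mu) = (sum w_i)^{-1/2}`; the default 95% CI is Wald,
`mu ± 1.959964 se`.  An optional Knapp–Hartung interval
(`ci_method="knapp-hartung"`, CLI flag `--knapp-hartung`) rescales the
pooled-mean variance by the weighted residual mean square and uses a
`t(k-1)` quantile; it is not the default because the plain normal interval
is the baseline CI definition here.  Heterogeneity
is summarized by Cochran's `Q = sum (1/v_i)(y_i - mu_FE)^2` with
fixed-effect weights, `I^2 = max(0, (Q - df)/Q) * 100`, banded low
(< 25%), moderate (25–75%, boundaries inclusive), high (> 75%).  With
`tau^2 = 0` the random-effects pool reduces exactly to the fixed-effect
pool.

Forest-plot rows carry per-study Wald CIs and normalized weight
percentages; the rendered figure marks the null line, draws a diamond for
the pooled estimate, and annotates `tau^2`, `I^2` and `Q`.

## Synthetic data

Two generators, two purposes.

`simulate_dataset` emulates the data the pipeline ingests: `k` two-arm
studies, true per-study effects `theta_i = delta + tau z_i`, one to three
instruments per study drawn with literature-frequency probabilities, and
raw-scale arm summaries.  Arm means receive sampling noise `sd^2/n`;
observed SDs are drawn from the chi sampling law of a normal-sample SD.
Summaries are generated analytically — no patient-level scores — because
the pipeline consumes summaries only.  Defaults mirror the demonstration
dataset: k = 7, per-arm n in 20–180, raw SDs 9–19 points, delta = 0.4 and
tau = 0.2 MCID units (the effect scale the demonstration tables imply).
A `missing_sd_prob` knob replaces the SD with a mean ± 2 SD range to
exercise the quarter-range rule.  True means are placed so both arms fit
the instrument scale; observed means that still fall outside are truncated
to the bounds and audited, and a run truncating > 1% of arm summaries fails
fast, since silent truncation would bias recovery studies.  Randomness
derives one named stream per study from the global seed, so study `i`'s
data is unchanged when `k` grows.  The ground-truth record carries
`theta_i`, the design parameters and the expected retained instrument per
study, letting tests verify selection correctness exactly.

`simulate_effects` works at the effect level for estimator calibration:
`y_i ~ N(theta_i, v_i)` with `v_i` known — the random-effects model's own
data-generating process, the standard design for checking an estimator
against its model.  SD-estimation noise is deliberately *absent* here and
present in `simulate_dataset`; the test suite uses each accordingly.

**What passing synthetic tests shows — and does not.** The generators
produce normal summaries, truthful SDs, shared instrument sets across arms
and no publication bias, selective reporting, skew, ceiling effects or
construct differences between instruments.  Calibration results (bias
< 0.02, CI coverage 92–93% at k = 15 over 500 replicates) certify the
arithmetic and the estimator under the stated model, not performance on
real literatures.

## Problem sizes used by the test suite

The shipped checks run the grid-oracle REML comparison on 100 random
instances with k ≤ 10 (coarse 1e-3 grid on [0, 10] refined at 1e-6 around
the winner), the calibration study at 500 replicates of k = 15, and the
end-to-end recovery study at 200 replicates of k = 15 through the full
normalize → prioritize → pool pipeline; these sizes give Monte-Carlo
standard errors comfortably below the tolerances being asserted.

## Known limitations

* Published MCIDs vary by population, indication and derivation method
  (anchor-, distribution-, ROC-based); a single registry value per
  instrument ignores that spread.  The registry's `mcid_source` column at
  least keeps the provenance visible.
* MCID normalization aligns scales, not constructs; pooled MCID units still
  mix instruments measuring somewhat different things.
* The default `r = 0.5` for change scores is an assumption, not an
  estimate; conclusions sensitive to `r` should report the sweep.
* Wald CIs with REML `tau^2` are known to undercover slightly at small k
  (the calibration study observes ~93% for nominal 95% at k = 15); the
  Knapp–Hartung option tightens this at the cost of wider intervals.
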
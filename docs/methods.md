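# Methods

This note documents the models, estimators and design choices behind
`gnao1kit`, and what the synthetic-data experiments do and do not
demonstrate about real measurements.

## Kinetic model of the BODIPY assays

A Gαo variant mixed with a fluorescent nucleotide analog is modelled as a
two-step irreversible sequential (first-order) scheme,

    free nucleotide  --k_bind-->  Gαo·GTP* (fluorescent)  --k_hydr-->  dark product,

where `k_bind` (s⁻¹) is the lumped pseudo-first-order uptake constant
(nucleotide is in large excess, so its concentration is absorbed into the
constant) and `k_hydr` (s⁻¹) the first-order hydrolysis constant.  For the
non-hydrolysable GTPγS analog the second step is absent and the
fluorescence follows

    F(t) = F0 + A · (1 − exp(−k_bind · t)),

while for GTP the bound, fluorescent intermediate follows the Bateman
solution

    F(t) = F0 + A · k_bind/(k_hydr − k_bind) · (exp(−k_bind t) − exp(−k_hydr t)),

with the limit `F0 + A·k_bind·t·exp(−k_bind t)` at equal rates.  This is
the minimal model containing exactly the two constants of interest; it
assumes hydrolysed product contributes no fluorescence above baseline.  An
optional residual plateau (bound BODIPY-GDP remaining above `F0`) is *not*
modelled: curves are assumed to decay to baseline.  Numerically the
Bateman shape is evaluated with a series expansion when
`|k_bind − k_hydr|·t < 1e−5` (cancellation) and with the plain
two-exponential difference otherwise (which cannot overflow, since both
exponentials are ≤ 1).

## Fitting

All fits are bounded nonlinear least squares (`scipy.optimize.least_squares`,
trust-region reflective, tolerances 1e−12, rates bounded below at 0).
Starting values are derivative-free: `k_bind` from the time to half-maximal
rise, `k_hydr` from the log-slope of the last 20% of the trace, and the
amplitude scaled so the model peak matches the observed peak.
Non-convergence is reported in the result, never masked.

Two baseline conventions apply to GTP traces, switched automatically:

* **direct** — the terminal value has decayed to within 10% (configurable)
  of the peak excursion above the initial value, i.e. hydrolysis completed
  within the window.  The baseline is a free parameter initialised at the
  end point.  (Fixing it exactly at the last sample would bias noiseless
  round-trips by the ~1% residual excursion left at five hydrolysis
  half-lives, so the end point is used as an anchor, not a constraint.)
* **extrapolated** — hydrolysis too slow to complete; the baseline is
  projected from the initial fluorescence value and held fixed while
  `(k_bind, k_hydr, A)` are fitted.

A monotone GTP trace yields `k_hydr` at its lower bound of zero with a
`k_hydr_uncertain` flag rather than an exception — this is the expected
behaviour of GTPase-dead variants.

**Activity classification.**  A variant is "inactive" (no measurable
nucleotide binding) when the empirical amplitude `max(F) − F(t0)` is below
`k·σ` of the read noise, default `k = 3`; σ is estimated from first
differences of the earliest samples when not supplied.  A trace exactly at
threshold counts as active — the conservative direction, attempting a fit
rather than discarding data.  Fold-changes are ratios of fitted constants
(mean-constant ratios, not per-replicate ratio means), reported magnitude-
≥-1 with a direction flag.

## GDP/GTP cycling model

Between assays the nucleotide state of Gαo follows the linear two-state
exchange

    d[Gαo·GDP]/dt = k_hydr[Gαo·GTP] − k_bind[Gαo·GDP]
    d[Gαo·GTP]/dt = k_bind[Gαo·GDP] − k_hydr[Gαo·GTP]

in the absence of GEFs, GAPs and GDIs.  The assumed cellular context
(10 μM total Gαo, ~100-fold nucleotide excess over G protein, ~10-fold
free GTP over GDP) justifies the lumped pseudo-first-order constants and is
stored with results for provenance; it does not enter the dynamics.
Integration is fixed-step classical RK4 with `dt` auto-shrunk so
`(k_bind + k_hydr)·dt ≤ 0.01` — the system is linear and non-stiff, and a
fixed-step scheme is bit-reproducible across runs.  Default horizon is
`30/(k_bind + k_hydr)` (slowest mode decayed to ~1e−13), with early stop
when the per-step change falls below 1e−12 of the pool.  Mass conservation
holds to rounding (≤ 1e−9 relative) because the two derivatives cancel
exactly at every RK4 stage.  The analytic equilibrium ratio
`[GTP-bound]/[GDP-bound] = k_bind/k_hydr` is exposed separately and the two
routes are asserted to agree within 1e−6 in the test suite.  `k_hydr = 0`
is the absorbing all-GTP limit: the converged state is snapped to exactly
all-GTP and the ratio reported as a `+inf` sentinel (with a warning), never
as an overflow.  Trajectories start fully GDP-loaded by default, matching
how the recombinant protein is prepared; the equilibrium is independent of
that choice.

## Clinical score

Disease onset in postnatal days is the clinical score.  Onset classes are
half-open bins `[0,10) / [10,90) / [90,730) / [730,∞)` — "3 months" and
"2 years" are converted at 90 and 730 days; both boundaries are
configurable because the day equivalents are conventions.  Group medians
are taken over patients (not over per-mutation medians) with the usual
mean-of-central-pair rule for even counts.  The packaged dictionary
(`data/mutations.csv`) carries 18 mutations: the 17 systematically
characterised ones plus Q52P, which is included for the activity grouping
(it is biochemically inactive) even though it was not part of the kinetic
panel.

## Statistics

Sample sizes here are tiny, so exact small-sample behaviour is the point:

* **Spearman** — `r_s` is the Pearson correlation of average ranks.  The
  two-tailed p is `P(|r*| ≥ |r_s|)` under random pairing: full enumeration
  of the `n!` pairings for `n ≤ 8`; seeded Monte-Carlo permutation
  (100,000 draws, +1-corrected so `p > 0`) for `9 ≤ n ≤ 12`; the
  t-approximation `t = r_s√((n−2)/(1−r_s²))` beyond.  Comparisons against
  the observed value use a 1e−12 tolerance so ties in the permutation
  distribution are counted, not lost to rounding.
* **Mann–Whitney** — U of the first sample from average ranks; for
  `n1+n2 ≤ 12`, enumeration of all `C(n1+n2, n1)` assignments of the
  observed pooled values (ties included), with
  `p = P(|U* − n1n2/2| ≥ |U − n1n2/2|)`; otherwise the normal
  approximation with tie-corrected variance and 0.5 continuity correction.
* **Biomarker ranking** — every numeric metric is Spearman-correlated with
  per-variant median onset and sorted by descending `|r_s|`; nothing is
  filtered by significance, constant metrics are kept but flagged.  No
  multiplicity correction by default (per-metric results are reported
  as-is); a Holm adjustment is available behind a flag.  Onset enters on
  the day scale — a log display axis would not change ranks.

ΔBRET is the mean BRET ratio over a post-injection window minus the mean
over a pre-injection window (defaults ~30 s before, ~50 s after), and
localization is quantified as region-mean over total-cell-mean
fluorescence.  Wild-type normalization divides each phenotype column by
the reference row, making the operation idempotent.

## Synthetic data

* **Traces** — closed-form curves plus iid Gaussian noise with s.d.
  `sigma_rel × amplitude` (a single SNR knob approximating plate-reader
  read noise).  Default acquisition grid: 0–3,600 s at 5 s cadence;
  fluorescence units are arbitrary RFU.  The pipeline's demo configuration
  samples at 1 s because its fastest variant rises with a ~6 s time
  constant.
* **Cohorts** — onsets per mutation are log-normal (onset spans days to
  years, so a log-scale dispersion is the natural spread model), rounded
  to whole days, floored at 0.  The default spec mirrors the study's
  structure: 29 DEE17 patients (13 of them carrying inactive mutations)
  and 31 NEDIM patients across 18 mutations.  Per-mutation medians were
  calibrated once, by root-finding on the log-normal mixture CDF, so that
  at the default dispersion of 0.25 the *group mixture medians* equal 43
  (DEE17), 569 (NEDIM) and 31 days (inactive); each calibrated median also
  stays inside its mutation's onset class.  A `n_scale` factor grows every
  per-mutation count proportionally for Monte-Carlo use.
* **Phenotype tables** — per-variant metric means follow a monotone
  (linear-in-onset-rank) map of per-mutation median onset with a
  configurable sign and span, plus Gaussian noise clipped at zero.  The
  rank-based construction makes the noiseless Spearman correlation exactly
  ±1 — the simplest generator whose association sign is controllable.  In
  the default spec Ric8B co-IP carries the strongest negative association
  (the candidate severity biomarker), expression/PM localization/Gβγ
  binding rise with onset, and RGS19, Ric8A and ΔBRET are unassociated.

**What the synthetic path does not show.**  The generators emulate curve
shapes and association structure, not instrument physics: no drift,
photobleaching, injection artefacts, heteroscedastic or correlated noise,
no inter-batch variability, and the phenotype generator imposes the very
monotonicity the correlation machinery then measures.  Passing tests
demonstrate that the estimators recover known ground truth under the
stated noise model — they are statements about the software, not new
evidence about the biology.

## Problem sizes and tolerances used in the test suite

Noiseless round-trips are checked to 1e−6 (binding) and 1e−4 (joint GTP)
relative; estimator bias for `k_bind` at 2% noise is bounded at 2% over
200 replicates; truncated-window (one hydrolysis time constant)
extrapolated fits recover `k_hydr` within 10%.  The ODE/closed-form
equilibrium agreement is checked on a 100-point random log-uniform rate
grid at 1e−6 with mass conservation at 1e−9.  The exact statistics are
validated against brute-force enumeration on 1,000 random small inputs,
the exact Mann–Whitney type-I error is bounded at the nominal 5% over
10,000 null simulations, and biomarker-ranking recovery is required in
≥95% of 500 replicates at SNR 5 (s.d. of the per-variant means over the
noise s.d.).  Group-median reproduction uses the default cohort scaled
200-fold (12,000 patients) so sampling noise in the medians is negligible.

## Known limitations

* The two-step model ignores any post-hydrolysis fluorescence plateau; if
  real curves plateau above baseline, `k_hydr` will be biased until such a
  plateau term is added.
* The extrapolated branch assumes the initial fluorescence equals the true
  baseline — correct when mixing starts the reaction at the first read,
  optimistic if binding begins before acquisition.
* The cycling model deliberately omits GEF/GAP/GDI regulation; its ratios
  characterise intrinsic variant biochemistry, not cellular signalling
  flux.
* Exact-method thresholds (`n ≤ 8` Spearman, `n1+n2 ≤ 12` Mann–Whitney)
  are feasibility choices; beyond them, approximation error is the usual
  large-sample kind and is cross-checked against scipy in the tests.
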
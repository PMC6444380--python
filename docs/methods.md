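# Methods

## Model and procedure

The unit of analysis is a *stratum*: all study-level measurement groups that
share a phenotype, a strain (or parent strain group), a sex group, an age
bin, and — when configured — a measurement method and experimental
condition. Each record contributes a study mean `y_i`, a sample size `n_i`
and a dispersion. All pooling weights use the **variance of the study
mean**: `s_i^2 = SD^2 / n_i` for SD records and `SEM^2` for SEM records.
(The dispersion kind is a required input column: study-level sources are
inconsistent about SD vs SEM and guessing silently corrupts weights.)

Pooling follows the standard two-level model `y_i = theta_i + e_i`,
`var(e_i) = s_i^2`, with `theta_i ~ N(mu, tau^2)` under the random-effect
model. The fixed-effect estimate uses inverse-variance weights
`w_i = 1/s_i^2`; heterogeneity is quantified by Cochran's
`Q = sum w_i (y_i - m_w)^2` on `k - 1` df and
`I^2 = max(0, (Q - df)/Q)`; the between-study variance is the non-iterative
DerSimonian-Laird moment estimator; the random-effect pool re-weights by
`1/(tau2_hat + s_i^2)`. Note the pooled *variance* is `1/sum(w)` and the
standard error `1/sqrt(sum(w))` — some presentations of this workflow print
`var(m_w) = 1/sqrt(sum w)`, conflating the two; we use the standard
inverse-variance result throughout and label the quantity `se`.

The per-stratum decision tree:

1. Egger regression of `y_i/s_i` on `1/s_i` (needs `k >= 3`); asymmetry
   score `Asy = intercept / mean(y_i)` with the unweighted mean.
   `|Asy| > 1.5` sets a *bias-suspect* flag — never an automatic exclusion,
   because the Egger test's false-positive rate is high.
2. `k < 4` labels the stratum `low_confidence`: in funnel diagnostics the
   asymmetry score only settles from about four experiments upward, and
   the max-min study range of small strata is often falsely small.
3. `I^2 > 0.85` selects the random-effect model, otherwise fixed.
   The boundary value routes to *fixed* (the threshold is read as the
   highest still-fixed-eligible band). The (|Asy|, I^2) plane is reported
   as quadrants Q1-Q4; Q3 -> fixed advice, Q4 -> random advice, Q1/Q2 call
   for closer inspection before trusting the pool.
4. Leave-one-out sensitivity: omitting study *i*, the influence is
   `|mean_without_i - mean_all| / se_all`; a study is flagged when this
   exceeds 1.0 or when its omission moves `I^2` across the model threshold.
   Flags are advisory; explicit include/exclude lists are the override.

**Expected range** = pooled mean ± 1 SD with
`SD = sqrt(tau2_hat + pooled animal-level variance)` (inverse-variance-
weighted mean of the per-study animal-level variances; `tau2_hat = 0` under
the fixed model). This choice makes ranges widen under real between-study
heterogeneity and collapse to the familiar animal-level SD for homogeneous
strata. The alternative — the SE of the pooled mean — is available via
`RangeConfig(sd_source="pooled_se")` and flagged in the output, but it
describes the uncertainty of the mean, not the spread of typical values,
and is usually far too narrow to serve as a reference interval.

**Control range construction**: founder control strains (for blood
pressure, BN and WKY) define the initial interval from their range
extremes; every other non-vetoed strain whose expected range intersects the
current interval is admitted and the interval updated to the min/max over
admitted strains. Default is a single pass over candidates in sorted-symbol
order (matching the enumerated four-step procedure); a fixed-point mode
iterates to closure, whose result is provably order-independent (the update
is a monotone closure) and verified so by permutation tests. Touching
endpoints count as intersection; `min_overlap_frac` can require a minimum
overlap fraction of the candidate's range to guard against hairline
contacts. A veto list exists because the original procedure kept a domain
expert in the loop; automation must remain overridable.

Strains classify against the control range as `within` (contained),
`outside` (disjoint) or `overlapping`; for expert comparison, within and
overlapping both map to "normal".

## Stratification choices

- Age is carried as a `[low, high]` day interval and binned by integer
  midpoint. Default bins: age1 < 70, age2 70-99, age3 100+ days (the
  young/adult/old split used for cardiovascular phenotypes); schemes are
  per-run config because the right split is phenotype-dependent (body
  weight prefers 20-79 / 80-99). Records whose interval straddles a bin
  edge can optionally be dropped (`drop_cross_bin`) — a 65-day animal is
  not always a homogeneous member of a "young" group.
- Sex `both` is its own group, never merged into male or female.
- Units are compared after trimming and case-folding only; mixed units in a
  stratum is a hard error (no unit conversion — out of scope).
- No automatic age-bin optimization: bins are config, and the per-stratum
  I^2 report is the diagnostic an expert would use to revise them.

## Numerical choices and degenerate inputs

- CI multiplier 1.96 (normal); no small-k t correction. Consequence: at
  small k the random-effect CI *undercovers* (at k = 8 the true coverage of
  the nominal 95% interval is about 91%, essentially `P(|t_7| <= 1.96)`),
  because the interval ignores the sampling error of `tau2_hat`. This is a
  documented property of the plain DerSimonian-Laird interval, visible
  directly in `scripts/acceptance.py` (`re_ci_coverage_percent`).
- Zero within-study variances are floored at (smallest positive variance in
  the stratum) × 1e-3 and flagged, so curated zero-SD records do not
  produce infinite weights; a stratum that is all-zero-variance is a hard
  degenerate-input error.
- `k = 1` strata are pooled trivially and flagged `het-undefined` rather
  than dropped: suppressing them would hide data gaps the reports exist to
  reveal.
- Egger with all precisions equal is undefined (collinear design); called
  directly it raises, inside the workflow it degrades to
  "Asy not evaluable" so equal-precision strata still pool.
- `Asy` with `mean(y) = 0` is reported as undefined. Note that Asy is not
  unit-invariant: rescaling `y -> c*y` leaves the Egger intercept unchanged
  but scales Asy by `1/c`; the 1.5 threshold is therefore calibrated for
  measurements whose values are O(1) or larger in their natural units.
- The leave-one-out influence threshold (1.0 pooled-SE shift) is a
  pragmatic default, not an estimate of anything: under pure within-study
  noise at k = 6 it false-flags some study in roughly 15-20% of panels
  (each study's null exceedance is ~2.5%). Flags are accordingly advisory.

## Synthetic data: what it does and does not emulate

`simulate_stratum` draws `theta_i ~ N(mu, tau^2)` and
`y_i ~ N(theta_i, sigma^2/n_i)` with `n_i` uniform on a configurable range
(default 5-30 animals, spanning the small groups typical of published rat
studies). Reported SDs default to the exact `sigma` so within-study
variances are exact and estimator checks are sharp; `sampled_sd=True` draws
the SD from its chi-square sampling distribution instead. Censoring
emulates publication bias as one-sided suppression of small studies
(side/threshold-or-quantile/max-n rule); outlier injection shifts chosen
study means by a multiple of sigma. The built-in panel spreads 14
normal-like strains over 112-130 mmHg (tau = 4, sigma = 9, k = 6 studies
per strain) and places 5 shifted strains at least 4 total SDs above the
highest normal mean, mirroring a normotensive-vs-hypertensive split with
BN and WKY as founders.

What passing tests on this generator do **not** show about real curated
data: real records have non-normal and skewed errors, correlated studies
(same lab, shared protocols), dispersions of unlabelled kind, unit
heterogeneity, and confounding between strain and method/age — none of
which the generator produces. The generator validates the statistical
machinery, not the curation assumptions.

## Problem sizes

Simulation-based checks use 1000 random strata for oracle agreement, 500
seeded funnels (k = 20) for Egger calibration, 2000 strata (k = 8) for
coverage/recovery, 200 panels (k = 6) for sensitivity rates and 40
multi-strain panels for end-to-end classification — sizes at which the
Monte-Carlo error of each reported rate is well under the margins being
checked, while a full run stays in the seconds range.

## Known limitations

- No REML or Paule-Mandel tau^2, no Knapp-Hartung adjustment, no
  meta-regression; the DL + normal-CI combination is the deliberate,
  documented baseline.
- No unit conversion and no ontology traversal: strain grouping is a flat
  substrain -> parent table.
- Trim-and-fill, Begg's test and any automatic outlier deletion are
  intentionally absent; bias handling stops at flags plus explicit
  exclusion lists.
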
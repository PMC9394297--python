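# Methods

## Data model

A study is two tidy CSV tables. The timecourse table holds one row per
(subject, observation time): `subject,arm,time_min,count`, counts being
flinches per 5-min bin on the grid 5, 10, …, 60 min. Times follow the
bin-*end* convention (the count recorded "every 5 min" is attributed to
the end of its interval); nothing downstream depends on this choice
except the labels of the phase windows. The arms table keys each
treatment arm by label with a role (`vehicle_control`, `monotherapy`,
`combination`, `combination_with_antagonist`), up to four drug slots
(drug, dose, unit, route), and the planned group size. Validation is
strict: exactly one vehicle-control arm, integer non-negative counts,
strictly increasing times, no duplicate (subject, time) rows, no unknown
arm references — missing bins are an error, never imputed, because a
silently short grid would bias every AUC.

## Phase windows and the effect statistic

Defaults are phase 1 = [0, 10] min and phase 2 = [15, 60] min, the
conventional formalin-test windows; both are configurable. Only phase 2
is analysed: treatments of this class show no early-phase effect, and
the generator likewise leaves early bins untouched. AUC is the
trapezoidal rule over observations inside the closed window; window
endpoints must lie on the observation grid (with the default grid the
phase-1 window starting at t = 0 has no left-edge observation, so
per-subject phase-1 rows are simply omitted from the metrics table).

Percent antinociception for a subject is computed against the
*control-group mean* AUC, then averaged within the arm to give
mean ± SEM. This per-subject reading is what makes a group SEM
well-defined; it also makes the control arm's own mean effect exactly
zero, a useful internal check. The statistic is invariant under a common
rescaling of all counts and strictly decreasing in the subject's AUC.

## Dose–response and EDx

DRCs are straight lines in (log10 dose, % effect), fit by OLS to group
mean effects — one point per dose, matching how such studies construct
their curves. (Log dose is the default; a linear-dose scale is
available, and per-subject fitting is possible by passing subject-level
effects, but neither is the default.) ED30 is used as the effect level
because the local partial agonist tops out near 50%, making ED50
extrapolative. EDx inverts the line, `dose = 10^((x − b0)/b1)`, with

```
Var(g) = (Var(b0) + g² Var(b1) + 2 g Cov(b0,b1)) / b1²,   g = (x − b0)/b1
se(dose) = ln(10) · dose · se(g)
```

by the delta method; the tests verify this against a 10,000-draw
parametric bootstrap from the coefficient covariance (agreement within
10%). Requesting an x outside the observed effect range warns
(`ExtrapolationWarning`) rather than failing — with a shallow-topped
curve this is a situation the analyst should see, not be blocked by.
Two-point fits are exact and get zero residual variance and covariance.
A slope numerically at zero (|b1| < 1e-12) cannot be inverted and
raises.

## Fixed-ratio design and the fused dose axis

Combination arms keep the two components at the constant ratio of their
ED30s, serially diluted by factors (1, 4, 16, 32). Because one component
is systemic (mg/kg) and one local (µg/paw), combination totals are
expressed on a fused scalar axis, `z = mg/kg + µg/1000`. This convention
is applied consistently to the combination DRC, the additive point, and
the interaction index; it is the only scaling under which published
combination totals of this design reconstruct exactly from their
components (39.54 + 2.74 → 39.54274). Component doses are rounded
half-up to two decimals *before* fusing — the order matters:
39.54/32 = 1.2356 → 1.24 and 2.74/32 = 0.0856 → 0.09 fuse to 1.24009,
which no round-after-fusing scheme reproduces. One published rendering
of the 1/16 row (2.48, 0.18) is inconsistent with its own arithmetic
(39.54/16 = 2.47125, 2.74/16 = 0.17125 under any standard rounding);
the implementation reproduces the computed 2.47/0.17 and this note
documents the discrepancy rather than matching it silently.

## Additivity testing

The theoretical additive ED30 **T** is the midpoint of the isobologram's
additive line — half of each component ED30 on the fused axis — with
variance `(se_A² + (se_B/1000)²)/4` and df the sum of the component
regression dfs. The experimental point **E** is the ED30 of the
combination DRC. The interaction index γ = E/T is reported both raw and
truncated toward zero at two decimals (0.1396 → 0.13; truncation is the
conservative convention for supra-additive indices). T vs E is a
two-sample Student t,

```
t = (z_T − z_E) / sqrt(se_T² + se_E²)
```

with df defaulting to (n_A_points − 2) + (n_comb_points − 2) from the two
regressions that dominate the variance (drug B's contribution is
suppressed by the 1/1000 fusion scale); the df is configurable since the
method's literature does not fix it. Classification: not significant →
additive; otherwise γ < 1 supra-additive, γ > 1 infra-additive, with
γ = 1 additive regardless.

Note one internal inconsistency of the reference analysis this package
re-implements: its text states the 30% combination effect at "2.75 mg/kg
+ 0.01 µg", which matches neither its combination ED30 (2.76 fused) nor
the fixed ratio (≈0.19 µg of drug B at that total). The package flags
such arithmetic in this note and computes from the tabulated values.

## Antagonist participation and group comparisons

Percent reversal of an antagonist pre-treatment is
`(E_comb − E_antag)/E_comb × 100` against the combination arm sharing
its drug doses; residuals below zero (hyperalgesia beyond full reversal)
are reported as-is and flagged, not clipped. The reading of "reversal"
here is *fraction of the combination effect abolished*; the alternative
"fell to x%" reading is not adopted because it cannot accommodate the
negative residual observed when both receptors are blocked.

Group comparisons use one-way ANOVA (with the degenerate all-equal case
returning F = 0, p = 1, and zero within-group variance with distinct
means raising an error — this arises only on noise-free synthetic data)
followed by Tukey's HSD via the studentized range distribution; the
tests check the two-group case against the q = √2·|t| identity and a
three-group case against a 10,000-permutation max-q reference. Group
sizes follow the resource equation: ANOVA error df K(n − 1) kept within
[10, 20], i.e. n between ceil(10/K) + 1 and ceil(20/K) + 1. (The widely
reproduced "(10/K) + 1" formula is implemented in its df-bound reading,
which is the only reading consistent with n = 6 at K ≥ 2.)

## The synthetic generator

Because raw per-animal time courses for such experiments are not
published, the generator produces studies whose ground truth is known in
closed form:

* **Baseline curve** (counts/bin at 5…60 min): (30, 12, 4, 8, 14, 18,
  20, 19, 16, 12, 8, 5) — an invented biphasic shape with an early peak,
  a 10–15 min trough, and a broad late hump. It is config, not ground
  truth, and is unconstrained by any published data.
* **Subject frailty**: lognormal(0, σ = 0.08) multiplying all of a
  subject's bin means — between-animal variability.
* **Treatment**: scales only late-phase bins (t ≥ 15) by (1 − E/100).
  Monotherapy E follows (b0, b1) in log10 dose; combinations follow a
  line in log10 fused dose whose ED30 equals `gamma_true ×` the additive
  midpoint of the model-implied single-drug ED30s — so additivity or
  synergy is built in exactly, and the analysis model is correctly
  specified (recovery failures indict the code, not model mismatch).
  Antagonist arms lose a blockade fraction of the combination's
  drug-B-attributable share, minus a hyperalgesia offset. Expected
  effects are clipped to [−50, 100] %.
* **Counts**: negative binomial with size k = 10 around each bin mean
  (real flinch counts are overdispersed between animals);
  `dispersion = inf` with `frailty_sd = 0` is the deterministic
  noise-off mode in which counts are the rounded means.

`default_paper_config()` calibrates the models so the closed-form
expected effects reproduce the reference study's reported group means
exactly: the systemic drug's line passes through ED30 = 39.54 mg/kg and
56.6% at 160 mg/kg; the local drug's line through 31.15% at 3 µg and
46.15% at 10 µg (which lands its ED30 at 2.737 ≈ the reported 2.74 —
evidently how that value arose); the combination slope puts 63.56% at
the undiluted fixed-ratio total with γ = 0.14; blockade parameters give
45% and 76% reversal and a −21% residual with both antagonists. With
the default baseline the attainable group SEMs at n = 6 are ≈3–6
percentage points, somewhat above the 1.7–3.1 reported — the published
precision would require higher or less dispersed counts than the
documented baseline produces; this gap is a known limitation and is why
recovery targets are framed on medians and calibrated error rates.

What passing tests show — and don't: the simulation shares the
analysis's functional form, so recovery tests validate the estimation
chain, not the biological realism of straight-line log-dose responses,
nor pharmacokinetics, receptor occupancy, or phase-1 analgesia, none of
which are modelled.

## Numerical and design choices

* Rounding in the design table is decimal half-up (9.885 → 9.89), via
  the `decimal` module, not float banker's rounding.
* The trapezoid includes both closed window endpoints; windows must hit
  grid points exactly (no interpolation), keeping every reported number
  bit-reproducible.
* OLS is delegated to statsmodels; ANOVA/Tukey to scipy
  (`f_oneway`, `tukey_hsd`); the q statistic is computed from MSW
  directly alongside scipy's p values.
* `AnalysisConfig.group_comparisons=False` skips the ANOVA/Tukey section;
  the studentized-range CDF dominates pipeline runtime (~2.6 s for 105
  pairs at 15 arms) and replicate calibration loops do not need it.
* Reports are plain dicts of floats; re-running the same study and
  config yields byte-identical JSON.

## Validation problem sizes

The oracle-equivalence check runs the noise-off generator with the
baseline amplitude ×100: at the documented count scale, integer
quantization alone perturbs recovered ED30s by up to ≈5% (worst for the
µg-scale drug), which would measure count resolution rather than code
correctness; at ×100 the pipeline inverts the generator to ≈0.01% and is
held to 0.5% on every ED30 and 0.02 absolute on γ. Statistical
calibration uses the default conditions unchanged: 200 replicates of the
full 16-arm design at n = 6 for γ recovery (median within 20% of 0.14),
and 500 replicates at γ_true = 1 for the additive-null type-I error
(within 3 Monte-Carlo SEs of α = 0.05). The full suite runs in well
under a minute on one CPU.

## Known limitations

* Two drugs only; fixed-ratio designs only (no response-surface models
  such as Bliss or ZIP).
* Straight-line DRCs; no 4PL/Emax fitting.
* The fused-axis convention hard-codes the mg/kg + µg/1000 pairing of a
  systemic and an intraplantar component.
* The t-test df for T vs E is a convention, not derived; it is exposed
  in config.
* Phase-1 analgesia is neither simulated nor scored.
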
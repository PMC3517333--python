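# Methods

This note documents the models implemented in `paee`, the defaults and the
reasoning behind them, what the simulator does and does not emulate, and the
numerical choices that matter.

## Instruments and scoring

The diary instrument records one behavior per 15-minute slot (96 slots,
local midnight to midnight, 0-based half-open slots). A day with missing or
unresolvable slots is non-compliant and is reported as such, never silently
scored. Days that are not exactly 96 slots long (e.g. daylight-saving
transitions) are rejected as malformed. The 24-h average MET value is the
unweighted mean over slots (slots are equal length, so this is the
time-weighted mean), and

TEE [MJ/d] = BMR [kcal/d] · avgMET · (sitting factor / DIT factor) · 4.184·10⁻³,

with sitting factor 1.1 and diet-induced-thermogenesis (DIT) factor 0.9 by
default. Both factors are configuration values: the MET scale is anchored at
sitting rest rather than supine fasting BMR (hence ×1.1), and DIT is taken
as ~10 % of total expenditure (hence ÷0.9). BMR enters in kcal/day — that is
what makes the printed 4.184·10⁻³ kcal→MJ factor dimensionally coherent —
and the file readers accept MJ/day with an explicit column name, converting
at the boundary. AEE = DIT factor · TEE − BMR and PAL = TEE/BMR. Rounding
(MJ to 2 decimals, percentages to 1, r to 3) happens only in report writers.

The recall instrument's scoring uses the fixed class METs (sleep 0.9, light
2.2, moderate 3.5, moderate-to-high 4.5, high 7.0, very high 10.0); the
residual of the 24-hour budget after sleep and reported entries is scored as
very-light time at 1.3 METs, and a day whose reported time exceeds 24 h is
an error, never clipped. Scoring is deliberately period-agnostic: only
class-hour totals matter, the morning/afternoon/evening split is metadata.
**Design choice:** the recall instrument reuses the diary's TEE conversion
(including the 1.1 sitting factor). A single documented conversion keeps the
two instruments comparable in joint analyses; if the original deployment
used a different constant for recall scoring, the `constants` block can
express that.

Descriptive class ranges (light 1.5–2.9, moderate 3.0–3.9, moderate-to-high
4.0–5.9, high 6.0–7.9, very high ≥ 8.0) are extended to half-open bins
[low, next-low) so classification is total over positive METs; values inside
the printed 2.9–3.0 gap therefore fall to the lower class. Below 1.5 METs
the screen offers no class; the mapping returns sleep or very-light
according to a caller-supplied context flag.

The shipped activity catalog (70 behaviors over the four diary categories)
uses standard compendium-of-physical-activities MET values for behaviors
common to adult time-use surveys. The original instrument's per-activity
list is not published; the catalog is a documented stand-in, and any CSV
with columns `code,label,category,mets` can replace it.

## BMR from gas exchange

Energy expenditure uses the abbreviated protein-free Weir form,
EE [kcal] = 3.941 VO₂ + 1.106 VCO₂ (litres). A basal collection is accepted
when the VO₂ range (max − min) inside the averaging window is below
25 mL/min. The original averaging duration is not documented, so the window
is a parameter: when given, the *last* qualifying contiguous window of that
length is used (late in a rest period is where steady state lives); when
absent, the whole series is the window. An unaccepted collection still
returns its value, flagged — censoring is the analyst's decision.

## DLW chain

Enrichments arrive as δ‰ vs VSMOW and are converted to atom fractions with
the VSMOW absolute ratios (²H/¹H = 155.76 ppm, ¹⁸O/¹⁶O = 2005.20 ppm);
excess is formed by subtraction in atom-fraction space (subtraction in δ
space is only approximate). The single pre-dose sample defines the baseline
per isotope.

Tracer mass balance: moles of excess labeled water = dose mass / molar mass
of the labeled water × (dose atom fraction − natural atom fraction), with
molar masses built from isotopic atomic masses. Because dose water and body
water both carry two hydrogens per molecule, the per-molecule site count
cancels, and dividing by the per-site time-zero excess yields mol of body
water for both isotopes.

Elimination rates and time-zero intercepts come from OLS of ln(excess) on
time (the intercept method); duplicates enter the regression as separate
observations. Dilution spaces use the intercept fit over *all* post-dose
samples; each observation week's elimination rates are two-point log slopes
between that week's endpoint days (1→8 or 8→15) with same-morning duplicates
averaged first. TBW = mean(N_d/1.041, N_O/1.007), rCO₂ = 0.4554 · TBW ·
(1.007 k_O − 1.041 k_D) — the constants embody the standard breath-water
fractionation assumptions with the revised dilution-space proportion — and
TEE follows from rCO₂ via the molar volume (ideal-gas 22.414 L/mol by
default; the real-gas 22.26 is selectable, a ~0.7 % sensitivity) at an
assumed RQ of 0.85 through the Weir equation. The N_d/N_O ratio is checked
against a plausibility band (default 1.000–1.070); violations warn and flag
but never suppress the result.

A consequence of the single-exponential intercept fit: when the two weeks
have genuinely different turnover (different TEE), the full-period fit is
mildly mis-specified and the back-extrapolated intercepts absorb a small
bias. The exact zero-noise round-trip (< 0.1 % recovery, in practice machine
precision) therefore holds for mono-exponential kinetics; with weekly TEE
differences of a few percent the induced error stays well under 1 % and is
visible in the noiseless end-to-end run as a sub-0.05 MJ Bland–Altman SD.

## Statistics

Pearson r carries a two-sided p from t = r√(df/(1−r²)) with df = n−2;
partial correlation is the correlation of OLS residuals on the covariates
with df reduced by the covariate count (cross-checked against an
independent implementation in the tests). Bland–Altman uses differences
a−b against pair means, sample SD (ddof 1), limits of agreement ±1.96 SD,
and reports the difference-on-mean OLS trend (slope, intercept, r, p — the
slope's t-test p and the correlation p coincide). The outlier rule is
one-sided: values more than k·SD (default 3) *above* the mean, matching the
gross-overestimation failure mode it exists to catch; the sensitivity pass
recomputes correlations on the retained set. Group means are compared with a
paired t-test (the comparison is within-participant); the significance
threshold (default .01) is reported, never used to censor output. Which
covariates to adjust for is analysis-specific; the pipeline adjusts for age
when ages are available, and the operation itself accepts any numeric
covariate matrix.

## Simulator

The simulator is truth-first: instrument reports and isotope series are both
derived from a generated ground truth, so parameter recovery is well
defined. Per participant it draws, from sex-stratified truncated normals
matching the reference cohort (20 adults, 10 men/10 women, ages 25–61; male
BMR ~N(6.50, 0.89) MJ/d on 4.77–8.00; PAL ~N(1.90, 0.12) and N(1.76, 0.22)
by sex): age, weight, height, BMR, true PAL, a body-water fraction (0.60
male / 0.50 female, SD 0.02), a dilution-space ratio ~N(1.027, 0.007)
truncated to 1.011–1.043, a water-turnover rate k_D ~N(0.10, 0.012)/day,
and an occupation (fulltime/parttime/self-employed/homemaker at
50/10/20/20 %). The crossover assignment is balanced: half the cohort uses
the diary in week 1 and the recall in week 2, half the reverse.

Truth schedules place a 7.5–8.5 h sleep block, a few occupation-typed
behaviors, and a calibrated count of the occupation's main activity so each
day's implied PAL equals the participant's true PAL within 1 % (a final
single-slot substitution from the catalog trims the residual to ~0.1 %);
waking slots are shuffled. Reporting channels: diary slots flip to a random
other behavior with probability 0.05/slot; recall entries are the truth
aggregated to period × class (sub-light truth time is left unreported,
becoming the very-light fill), perturbed multiplicatively at CV 0.15; with
probability 0.05 a participant reports all waking time as moderate activity
(the constant-class gross-overestimation error); an optional female positive
bias exists and is off by default. These magnitudes are free parameters —
deliberately not tuned to reproduce any published correlation, which would
be circular. Isotope series invert the DLW chain exactly (per-week k_O from
weekly truth TEE, piecewise-exponential enrichment, protocol doses of 0.12
and 2.5 g per kg predicted TBW) and add Gaussian analytic noise of 0.7‰
(²H) and 0.05‰ (¹⁸O) to the δ values; sampling is one baseline plus
duplicates on days 1, 8 and 15. Gas series fluctuate around the VO₂ implied
by true BMR at RQ 0.85, clipped to ±10 mL/min so collections always pass
the steadiness rule.

What the simulator does not emulate: behavioral realism beyond
occupation-typed schedules (no weekday/weekend structure, no learning
effects), correlated reporting error across days, recall-period boundary
ambiguity, isotope exchange or dose-spillage artifacts, and unsteady basal
collections. Passing recovery tests therefore demonstrates correctness of
the computational chain under the stated error model, not field validity of
the instruments.

## Problem sizes and determinism

All stochastic tests run with fixed seeds (hypothesis suites are
derandomized). The unbiasedness check uses 200 simulated participants; the
limits-of-agreement coverage check uses 10,000 Gaussian pairs; the
simulator-calibration check uses a 2000-person cohort, where the mean
dilution-space ratio estimates the configured 1.027 with a standard error
of ~0.00016. End-to-end runs in the tests use 6–20 participants over the
full 14-day crossover. Reports are written with sorted keys and rounded
presentation values, so identical configurations produce byte-identical
JSON.

## Known limitations

- The per-activity MET table is a stand-in (the original list is
  unpublished); analyses sensitive to individual MET assignments should
  supply their own catalog CSV.
- The recall conversion constant (sitting factor 1.1) is an assumption
  carried over from the diary conversion, as discussed above.
- Weekly elimination rates use two-point slopes; with only two usable days
  per week there is no within-week redundancy, so single-sample analytic
  error propagates directly into weekly TEE (~1–2 % at the default noise).
- The intercept method assumes mono-exponential decay over the full 14 days;
  see the bias discussion in the DLW section.
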
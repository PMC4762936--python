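# Methods

This note documents the statistical procedures implemented in `vsalert`,
the assumptions behind them, the synthetic-data model used to exercise
them, and the numerical choices made where conventions differ.

## Cohort model and eligibility

A cohort is a set of patient records, each carrying an ordered series of
timed vital-sign observations (pulse in BPM, systolic/diastolic pressure
in mmHg, nominally on a 15-minute grid), estimated blood loss (EBL, mL)
at study entry, a hemorrhage-etiology diagnosis, and raw outcome fields.
Study eligibility follows the enrollment rule of the underlying trial
populations: EBL above a context threshold (strictly > 750 mL at
tertiary facilities, > 500 mL at primary health clinics) together with
entry SBP ≤ 100 mmHg and/or entry pulse ≥ 100 BPM. "Entry" vitals are
the first observation (minute 0); the data do not distinguish an
enrollment measurement from the first grid interval, so the
first-observation convention is fixed here and documented. A missing EBL
makes eligibility indeterminate (`None`) rather than raising.

Exclusions remove records with no death-outcome data and records with no
usable vital-sign observation in the first hour — including patients
whose only readings were recorded as non-palpable (the CSV token `NP`,
parsed to missing with a flag). Exclusion is idempotent and logged per
patient with a reason code.

## Derived indices and the worst point

At a single observation: SI = pulse/SBP; MAP = (2·DBP + SBP)/3;
pulse pressure = SBP − DBP; severe shock ⇔ MAP < 60 mmHg (strict).
All arithmetic is unrounded; presentation rounding (half-up, one
decimal) happens only in reporting helpers.

The analysis point per patient is the observation with the highest SI in
the closed window [0, 60] minutes. The window endpoint is included
because the 15-minute grid makes 60′ a natural reading. SI is computed
per observation *before* maximization — the worst point is one interval,
not a max-pulse/min-SBP composite across intervals. Ties break toward
the earliest time (earlier detection is the clinical framing). Three
alternative rules (highest pulse, lowest SBP, lowest MAP) feed a
sensitivity report of AUCs across rules, flagging cells whose spread
exceeds 0.05. Observations missing a field a rule needs are skipped;
a patient with no scoreable observation drops out of analyses for that
rule only.

## Outcomes

Death, SMO (death or severe end-organ failure) and SMO-CI (SMO or ICU
admission or transfusion ≥ 5 units — inclusive — or emergency
hysterectomy restricted to uterine-atony diagnoses) are nested by
construction. Missing component fields are treated as false with a
logged warning rather than dropping the record: every patient with a
known death status contributes to every composite, which mirrors
analyses that use all individuals with data for each comparison rather
than complete cases. A missing death status is a contract violation at
this stage (such records are removed by exclusion).

## ROC and DeLong machinery

AUC is the Mann–Whitney U-statistic with midrank tie handling; it equals
the trapezoidal area under the empirical ROC curve, whose tied-score
plateaus appear as diagonal segments. Predictors are oriented before
ranking: SBP, DBP and MAP are negated (lower is worse); SI and pulse are
used as-is. Pulse pressure is deliberately *not* re-oriented, so a
weakly protective pulse pressure yields AUC below 0.5 — reproducing how
such predictors are conventionally reported.

Variances and covariances of correlated AUCs use the DeLong structural
components: V10 (per positive, mean placement against all negatives with
midranks) and V01 (per negative), with
Cov = S10/n_pos + S01/n_neg from the sample covariance matrices of the
components. The paired equality test is
χ² = (A₁ − A₂)²/(v₁ + v₂ − 2c) on 1 df, computed on the complete-pairs
subset (both predictors non-missing). If the variance of the difference
collapses to zero, the test degenerates explicitly: p = 1 for identical
AUCs, p = 0 otherwise. Bonferroni adjustment multiplies by the number of
comparisons per outcome against the reference predictor (5 for the full
six-predictor set); multiplicity is counted per outcome, not across
outcomes, because significance markers are reported per outcome column.

AUC confidence intervals are Wald on the AUC scale, truncated to [0, 1];
a logit-scale variant is available via `auc_ci(..., scale="logit")` for
boundary-near AUCs. Exact reproduction of any published CI is not
claimed, since the CI transform used by legacy software is rarely
stated.

## Threshold metrics

Test-positive means score ≥ threshold (inclusive, matching "SI ≥ 0.9"
phrasing). Sensitivity, specificity, PPV, NPV and prevalence are
reported as percentages with exact Clopper–Pearson intervals on their
own denominators — PPV/NPV intervals are plain exact binomial on the
test-positive/test-negative counts, not prevalence-adjusted. The exact
method is identifiable from published all-success bounds: the lower
bound for x = n is (α/2)^(1/n), e.g. 0.9075 for n = 38. A metric with an
empty denominator is reported as undefined, never as zero. Missing
predictor values are dropped per analysis with the count logged.

## Specificity centiles

The specificity-p threshold is the empirical p-quantile (linear
interpolation between order statistics, NumPy default / R type 7) of the
predictor among outcome-negative patients. Under ≥-positivity the
realised specificity is the fraction of negatives strictly below the
threshold; when a tied block would drag it more than one order statistic
below target, the value steps to the midpoint between the tied block and
the next distinct value, resolving ties toward higher specificity. The
CI comes from binomial order-statistic bounds
(ranks `Binom(n, p).ppf(α/2)` and `.ppf(1−α/2)+1`), distribution-free
and slightly conservative; it is not attempted below 20 negatives, where
both bounding ranks would sit at the sample edge.

## Synthetic cohort generator

The generator is the package's test bed; its defaults are the study
conditions the pipeline is meant to face.

**Latent structure.** Each patient has severity z ~ N(0,1). Worst-point
vitals load on z with a shared signal fraction a: pulse = 117 + a·9·z +
√(1−a²)·9·ε, SBP = 90 − a·14.8·z + √(1−a²)·14.8·ε′ (SDs chosen to match
the target IQRs: pulse 110–122, SBP 80–100). Pulse pressure is drawn
nearly independently of z (median 31, SD 6, loading −1.5 mmHg per
severity SD), and DBP = SBP − PP, clamped so 5 ≤ PP ≤ SBP − 20. Vitals
are rounded to integers, which creates realistic ties. Earlier intervals
derive from the worst point by non-negative offsets (half-normal,
SD 6 BPM / 8 mmHg), with the worst point at one random interval of the
grid (default 4 intervals over 0–45′), so worst-point selection is
non-trivial. Eligibility and plausibility are enforced by resampling
rejected draws; EBL is lognormal (median 1000 mL, log-SD 0.35)
truncated above the context threshold.

**Outcomes.** A liability L = z + w/b with shared w ~ N(0,1) and slope
b = 3 is thresholded at the (1 − π) quantiles of its distribution for
π = 0.041 (death), 0.066 (SMO), 0.157 (SMO-CI). One shared w and ordered
thresholds give exact nesting and exact expected prevalences. Raw fields
(end-organ failure, ICU, transfusion units, hysterectomy) are then drawn
consistently with the latent flags, so `build_outcomes` reproduces them
exactly; non-SMO-CI patients never receive a qualifying intervention.
DBP is set missing completely at random for 10% of patients (plus tiny
pulse/SBP missingness, 0.2%/0.4%), reproducing per-predictor n patterns.

**Calibration.** `calibrate_to_targets` chooses a so the expected
SI-vs-death AUC hits its target (default 0.87): it first inverts the
liability-model AUC — computed by deterministic Gauss–Legendre
quadrature over the truncated liability distributions of the two classes
— for the required score–liability correlation, converts that to a via a
delta-method linearization of the SI ratio, then refines by Brent root
finding against a large fixed-seed draw of the generator itself
(120k–400k patients), which absorbs the nonlinearity of the ratio,
integer rounding and eligibility truncation. The shipped default
a = 0.5828 comes from a 400k-draw calibration; over 100 seeds at n = 958
the empirical AUC has mean 0.870 and SD ≈ 0.027 — the irreducible
Monte-Carlo noise of an AUC estimated from ~39 events, consistent with a
CI half-width of ±0.07 at this scale. Calibration therefore controls the
*expectation*, not single-cohort realisations.

**What the generator does not emulate.** Real cohorts have outcome
heterogeneity beyond one severity factor, so the generated SMO and
SMO-CI discrimination runs somewhat higher than observed in real data
with the same death-AUC; the worst point dominates all rules at one
interval for pulse and SBP, so the selection rules disagree only through
pulse-pressure noise (MAP) and analysis-subset differences — their
spread is a few hundredths of AUC, smaller than on real data; vital
correlations within patients are induced solely by z; treatment effects,
referral delays and informative missingness are not modelled. Passing tests on synthetic cohorts therefore demonstrate
the estimators and plumbing, not clinical performance.

## Problem sizes in the test suite

Property tests use sizes chosen to make their Monte-Carlo bands sharp at
desk scale: 1,000 random instances (n ≤ 30) for estimator-equivalence,
2,000 replicates at n = 200 for the paired test's type-I error, 1,000
replicates for CI coverage (AUC at n = 200; quantile at 900 negatives),
60–100 seeds at n = 958 for generator recovery. The deterministic
quadratures use 64 Gauss–Legendre nodes, giving ~1e-9 accuracy for the
liability AUC.

## Known limitations

* Wald AUC intervals can undercover for AUC near 1 with few events; the
  logit option mitigates but is not the default.
* The centile CI is conservative with heavy ties (attainable specificity
  jumps in blocks).
* The generator's eligibility resampling slightly truncates the severity
  distribution, so realised prevalences sit a few tenths of a percent
  above targets; the effect is well inside the binomial test bands.
* `read_cohort` loads the whole table into memory; cohorts here are
  thousands of rows, so no streaming path is provided.
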
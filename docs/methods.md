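# Methods

`sepseval` evaluates a streaming sepsis risk score — a 0–100 prediction
emitted every 15 minutes for every adult hospital encounter — against three
electronically computable sepsis definitions, the way a health system would
during a *silent deployment* (scores stored but hidden from clinicians).
Because real silent-deployment data are protected health information, the
package ships a synthetic event-stream generator whose planted structure
makes every downstream stage exactly testable.

## Outcome phenotypes and time zero

Each definition is computed from the raw event stream with criterion-level
provenance; **time zero** is the earliest timestamp at which the
definition's qualifying criteria are met.

**Sepsis-3.** Suspected infection is a blood-culture order and an IV
antibiotic administration paired within standard windows (antibiotic ≤ 72 h
after culture, or culture ≤ 24 h after antibiotic); the suspicion time is
the earlier member. The encounter is a case when the SOFA score rises by
≥ 2 points inside (suspicion − 48 h, suspicion + 24 h], measured against a
baseline equal to the minimum SOFA at event times in the 48 h before
suspicion (0 if unmeasured). SOFA subscores use the worst value in a 24 h
component lookback; missing components score 0, vasopressor use scores the
cardiovascular component at 3 (dose information is not modeled), and the
severe respiratory bands require ventilatory support. Time zero is the
suspicion time of the earliest qualifying pair.

**SEP-1 (severe-sepsis logic).** Two or more SIRS criteria (temperature
> 38.3 °C or < 36.0 °C; heart rate > 90; respiratory rate > 20; WBC > 12 or
< 4 ×10³/µL or bands > 10 %) concurrent with at least one organ-dysfunction
criterion (SBP < 90, MAP < 65, SBP drop > 40 mmHg from the running maximum,
lactate > 2.0, creatinine > 2.0, bilirubin > 2.0, platelets < 100,
INR > 1.5) inside a rolling 6 h window. All SEP-1 thresholds are strict
inequalities. Time zero is the earliest event time at which the conjunction
completes. The 6 h concurrency window is an operational choice — quality
abstraction manuals do not fix one — and is configurable.

**ASE (CDC Adult Sepsis Event).** A blood culture, a qualifying
antibiotic-day (QAD) run — a *new* IV antibiotic (none in the prior 2
calendar days) starting within ± 2 calendar days of the culture and
continuing ≥ 4 consecutive calendar days with single-day gaps bridged, or
until in-hospital death — and at least one organ-dysfunction criterion
(vasopressor initiation, mechanical ventilation, lactate ≥ 2.0, creatinine
≥ 2× baseline, bilirubin ≥ 2.0 and ≥ 2× baseline, platelets < 100 with a
baseline ≥ 100 and ≥ 50 % decline) within ± 2 calendar days of the culture.
Baselines are the best pre-window values in the encounter. The ASE lactate
threshold is inclusive (≥), following the surveillance wording, where SEP-1
uses a strict inequality; both conventions are per-criterion configurable.
Time zero defaults to the minimum over culture, QAD start and first organ
dysfunction of the earliest qualifying episode; a culture-anchored mode is
available because the surveillance wording admits either reading.
Discharge-to-hospice is not modeled; the death exception covers in-hospital
death only.

Calendar-day semantics (midnight boundaries) govern QAD counting, since ASE
counts antibiotic *days*, not 24-hour blocks. Timestamps everywhere are
timezone-naive at minute resolution — lead times are reported in hours, so
finer precision carries no information. Events up to a configurable
lookback before arrival are accepted on ingest but excluded from criteria
by default.

## Evaluation design

* **Encounter level** — one instance per included encounter, scored by the
  maximum prediction strictly before min(time zero, discharge). "Strictly
  before" is applied at every boundary (time zero, discharge, treatment
  action): a score produced at the moment of recognition is not advance
  warning.
* **Prediction level** — every 15-minute score becomes an instance; for a
  horizon H (8 h and 24 h by default) the label is positive iff time zero
  falls within H after the prediction. Case predictions at/after time zero
  are excluded by default (labeling them positive is available by option).
  The unit (ED/ward/ICU) at each prediction is resolved by half-open
  [start, end) containment on the encounter's unit timeline.
* **Pre-treatment censoring** — a sensitivity analysis keeps only
  predictions strictly before the encounter's first sepsis-related action
  (lactate order, blood-culture order, IV antibiotic), quantifying how much
  of the apparent performance rides on recognizing treatment already under
  way.
* **Lead time** — for a score threshold t, the gap between the first
  prediction ≥ t and time zero; cases first crossing at/after time zero are
  tallied separately as late detections.

Metrics: AUROC in Mann–Whitney form (ties ½, verified against exhaustive
pairwise concordance); AUPRC as average precision (step integral, no linear
interpolation, so cross-checks against standard implementations agree
exactly); ECE over **equal-count** deciles of the normalized score
(score/100) — the 0–100 score is explicitly not a probability, and the
calibration report is the diagnostic of exactly that mismatch; decision
curves as net benefit NB(pt) = TPR·π − FPR·(1−π)·pt/(1−pt) with the
standardized form sNB = NB/π; and a full integer-threshold sweep 0–100 with
precision, recall, FPR, flagged fraction and the number needed to evaluate
(NNE = 1/precision, reported to one decimal, half-up, as are all reported
percentages). Operating points follow three predefined policies: highest
threshold with recall ≥ 0.8; maximum recall subject to precision ≥ 0.15;
and the "Youden top-left" point. The top-left point minimizes
√(FPR² + (1−TPR)²); because the phrase is sometimes used for the Youden J
maximizer, both are implemented, with top-left the default and ties broken
toward the higher threshold.

Confidence intervals are percentile bootstrap over **patient-level**
cluster resamples: patients are drawn with replacement and each draw keeps
all of the patient's encounters, respecting within-patient correlation.
Percentile intervals were chosen over BCa as reproducible and
assumption-light; the method field exists for extension. Replicates on
which a statistic is undefined (single-class resamples) are dropped, and
the estimate is flagged when more than 20 % fail. Default 1000 replicates;
the seed is mandatory for any published report. Weekly drift recomputes
AUROC/AUPRC per ISO week of arrival, with single-class weeks reported as
undefined.

## The synthetic cohort

The generator's defaults are the study conditions: a 24-week enrollment
window; encounter mix 68.1 % ED-only, 21.8 % ED-to-admission, 4.5 % direct
admission, 4.9 % post-operative, 0.7 % obstetric; incidences 2.9 %
(Sepsis-3), 1.2 % (SEP-1), 2.0 % (ASE); a planted short-stay fraction
(8995/207489) removed by the ≥ 1 h inclusion filter; and per-definition
arrival-to-time-zero lognormals parameterized to the reported medians and
IQRs (medians 4.1 h / 5.8 h / 1.7 h; σ from the IQR ratio,
σ = ln(q3/q1)/(2·0.6745)). Ten percent of patients contribute 2–3
encounters to exercise the clustered bootstrap.

**Constructive case planting.** Case status per definition comes from a
Gaussian copula (correlation 0.6 by default) over the three indicators; the
joint overlap is a free parameter because no joint distribution is
published. Criterion events are *inserted*, not rejection-sampled, so the
truth table is an exact phenotyping oracle. The construction keeps
definitions orthogonal: the Sepsis-3 SOFA rise uses two one-point
subscores (creatinine 1.5, platelets 118) that sit below every SEP-1 and
ASE organ-dysfunction threshold; ASE organ dysfunction uses lactate, which
is outside SOFA; a shared infection episode serves Sepsis-3 and ASE (their
time zeros coincide for overlapping cases, which is also the clinical
reality of a single septic episode); antibiotics run five calendar days for
ASE cases but only two otherwise, and non-ASE deaths are pushed two days
past the last antibiotic so the ASE death exception cannot fire. SEP-1
blocks are shifted 7 h away from any lactate event that could complete the
conjunction early. Background vitals and labs are clipped strictly inside
every criterion threshold (heart rate < 90, SBP in 100–140 so no drop can
exceed 40 mmHg, creatinine 0.7–1.0, platelets 160–320), so non-case
encounters cannot fire any definition. Planted-truth recovery is therefore
an exact equality test, and a phenotype regression shows up as a hard
failure, not a statistical drift.

**Score law.** A latent discrimination variable follows the equal-variance
binormal model, z ~ N(δ, 1) for primary-definition cases and N(0, 1)
otherwise, with δ = √2·Φ⁻¹(AUROC*) so the implied AUROC is exactly the
target. The emitted peak score is 100 × the exact Bayes posterior
P(case | z) — a strictly monotone transform, so the AUROC is unchanged
while the score becomes perfectly calibrated by construction; planted
miscalibration is a logit-scale slope/intercept on that risk. The stream
ramps linearly from below 0.2×peak to exactly the peak at the last cadence
tick strictly before the earliest planted time zero (ramp onset a
lognormal lead, mean 4 h), so the encounter-level maximum equals the latent
peak *exactly* and discrimination/calibration recovery tests are limited
only by sampling noise, not stream mechanics. For thresholds inside the
ramp's dynamic range (between 0.2 and 0.5 of the peak) the first crossing
is the onset tick itself, giving exact per-case lead recovery; thresholds
above half the peak cross mid-ramp, which shortens the recovered median by
about 0.25 h at the default shape — the lead-recovery test asserts exact
equality on the guaranteed band and a ±0.5 h band on the median, derived
from repeated generator runs.

**What the generator does not emulate.** Scores are informative for the
*primary* definition only; the other definitions inherit discrimination
solely through case overlap, so per-definition AUROC differences are
qualitative, not calibrated to any published spread. Physiology is
piecewise-constant plants over sub-threshold background, with no disease
trajectories, comorbidity structure, missingness patterns, or
unit-dependent case mix; in the generated data the first sepsis-related
action coincides with the culture at time zero, so pre-treatment censoring
is a near no-op by construction (on real data it is not). Passing recovery
tests therefore demonstrates correctness of the evaluation machinery under
known truth — not clinical performance of any model on real patients.

## Problem sizes and numerical choices

Recovery tests run at the sizes where their tolerances were derived:
discrimination/calibration at n = 20 000 encounters (|AUROC − target|
< 0.02, ECE < 0.02), phenotype recovery at n = 5 000, lead recovery at
~5 000 cases, bootstrap coverage at 100 repetitions of n = 2 000 with 1000
replicates (≥ 90/100 nominal-95 % coverage; percentile intervals at ~60
positives per repetition sit close to that bound, which is expected
behavior, not slack). The acceptance script reruns the full pipeline at
n = 20 000. Equal-count ECE bins use a stable argsort split, so tied scores
may straddle bins; sweeps use integer thresholds 0–100 to match the printed
score scale. Reported percentages and NNE round half-up to one decimal.
Degenerate inputs (single-class samples, empty positive class, fewer
instances than bins, zero-precision thresholds) raise a typed
`UndefinedMetricError` rather than returning silent NaNs; stratified and
weekly tables are the exception, reporting NaN to mirror "NA" cells in
subgroup tables.

## Known limitations

The exact thresholds of site-operational implementations differ (the
computable SEP-1 here is not the CMS abstraction; urine output and
GCS-based criteria participate only when measured, and urine output is
omitted from SEP-1 organ dysfunction by default); `CriteriaConfig` exposes
every number so a site can override them. ASE's pending revision is not
implemented. Encounter type is taken as ground truth (no transfer
reconciliation). The bootstrap treats encounters of a patient as the only
dependence structure; temporal dependence within an encounter's prediction
stream is handled by instance construction, not resampling.
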
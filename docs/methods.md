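# Methods

## Sigma metrics

Per control level, `sigma = (TEa − |bias|) / CV`, all terms in percent.
Where the quality requirement is stated as an absolute concentration
(calcium ±0.25 mmol/L, potassium ±0.5 mmol/L, sodium ±4 mmol/L in the CLIA
specifications used by the bundled panel), it is converted to percent of the
control level's target before use.  Bias enters as magnitude: external-QA
biases are averaged per level (arithmetic mean of the three matched EQA
samples) and folded to absolute value before subtraction; the bundled panel
prints only positive biases, consistent with this convention.  Patient-risk
sigma caps the calculated value at 6 — beyond six sigma the normal-tail
defect rate (≈ 2·10⁻⁹) is planning-irrelevant.  A bias exceeding TEa gives a
negative sigma; it is reported with an `unacceptable` flag rather than
clamped, since "method needs improvement" is different information from
"sigma zero".

All arithmetic is done at full precision; the 2-decimal half-up rounding of
reports is applied only at the formatting boundary.  The bundled panel's
published per-level sigmas, capped values and both averages reproduce under
this convention exactly (full-precision average, then rounding).

## Control rules and power

A QC event holds N ∈ {1, 3, 6} control measurements, one per level,
expressed as z-scores.  Within an event the z-scores are modelled as
independent standard normals shifted by a common systematic error `se` (in
analytical-SD units).  Counted rules use the same-side multirule
convention — 2of3:2s and 3:1s fire only when the counted exceedances fall on
one side of target; this convention reproduces the published false-rejection
probability 0.02 of the `1:3s/2of3:2s/3:1s` N3 multirule, while either-side
conventions do not.  For N=6 the 3-measurement counted rules are evaluated
over every window of three consecutive measurements; 6:X requires all six on
one side of the mean.  No across-event memory is modelled (bracketed,
per-event evaluation).

`Pfr`/`Ped` are estimated by Monte Carlo (default 2·10⁵ events, explicit
seed, standard error ≤ ~0.0011) with a closed form available for N=1
single-limit rules, `Φ(−k−se) + Φ(−k+se)`.  Power curves share one base
normal draw across the error grid (common random numbers), so estimated
curves are smooth in `se`.

Known discrepancy: the candidate registry carries nominal planning Pfr
values of 0.03 (1:2.5s N3) and 0.06 (1:2.5s N6) as published for this
candidate set, while the independence model gives 0.037 and 0.072 (rounding
to 0.04 and 0.07).  The origin of the published figures is unknown; the
registry keeps them as nominal metadata (used only for procedure selection,
where the ordering is unaffected) and the golden Pfr tests cover only the
unambiguous rows.

## Bracketed run size

In bracketed mode a run's results are released only after its closing QC
event is accepted, so unreliable *final* results accrue only across runs
whose QC missed the error.  With per-event detection probability `Ped(se)`,
the number of accepted runs before detection is geometric, giving

    E(Nuf)(n, se) = n · ΔPE(se) · (1 − Ped(se)) / Ped(se),

with `ΔPE(se) = p_u(se) − p_u(0)` and `p_u(se) = Φ(se − s) + Φ(−se − s)`
the probability that a patient result's total error exceeds TEa at quality
sigma `s`.  The planned run size is the largest `n` ≤ 1000 (the reporting
cap mirrors the evident ceiling of published run-size tables) with
`max_se E(Nuf)(n, se)` ≤ patient risk factor (default 1).  Since E(Nuf) is
linear in `n`, the search is an integer bisection against the worst-case
per-result rate; the error grid defaults to 0…2·s in 0.05-SD steps and the
reported `binding_se` is the grid argmax.

**Level aggregation.**  The assay's quality across its measuring range is
summarized by the *average patient-risk sigma* (per-level cap at 6, then
mean over the three levels) — the same scalar the sigma-strategy
categorization uses, and the quantity run-size nomograms are keyed on.  This
is a deliberate design choice: aggregating instead by the single worst level
mis-ranks analytes whose weakest level is unrepresentative of the range (a
chloride-like profile with one weak and one very strong level would rank
below a uniformly mediocre calcium-like profile, inverting the ordering that
published run-size tables show).  A `worst_level` policy remains available;
`binding_level` always reports the weakest level as the concentration region
of concern.  Because the exact formulation and aggregation of the online
run-size calculator used in practice are unpublished, individual cells of
the published matrix are *not* reproduction targets; the model is held to
the cap, the cross-analyte ordering, and agreement with a discrete-event
simulation of the bracketed process itself.

## Moving-average procedures

Simple block MA is the sliding mean of the last `block_size` *included*
results; EWMA is `v ← λx + (1−λ)v`, initialized by the first included
result.  Truncation limits exclude a result from the statistic but still
consume it from the stream (an excluded result still delays detection).
Alarms are raised when a defined MA value leaves the control limits.

Control limits default to the *extrema policy*: the (min, max) MA values
observed on an unbiased calibration baseline, with optional widening margin;
replaying the calibration stream then alarms zero times, the strictest
policy consistent with routine use (a percentile policy is available).  The
false-alarm behaviour on new data depends on the calibration length relative
to the MA's correlation length: with a block-10 MA calibrated on 20 days of
50 results/day, an independent equal-length stream stays at or below one
alarm per daily volume in ≥ 90% of seeds; short calibration baselines or
large blocks produce materially tighter limits and more false alarms.

Bias-injection simulation: per iteration a fresh unbiased baseline (2
warm-up days) brings the MA to steady state; the onset position is uniform
over the second half of the last warm-up day; from onset every raw result is
multiplied by `1 + bias/100` *before* truncation screening (a proportional
instrument shift moves results across the inclusion bounds); results are
counted from the onset (inclusive) to the first alarm, with a horizon of
10× the daily volume.  Min/median/max are summarized over detected
iterations only, with the censored fraction reported separately; summaries
are withheld when fewer than half the iterations detect.  The optimization
criterion is the published one: median detection of a ±TEa bias within one
day's volume (with the worst direction deciding ties), subject to a
false-alarm constraint on an independent baseline.

The synthetic patient streams are lognormal by default (clinical analytes
are right-skewed); the bundled per-analyte population medians and spreads
are realistic adult-population values chosen for simulation, **not**
measured data from any laboratory.  Consequently the bias-detection numbers
computed here characterize the simulation machinery, not any real LIS
population: real streams carry time-of-day structure, demographic mixtures
and preanalytical artifacts that the generator deliberately omits, so
passing tests demonstrate correctness of the engine, not transferability of
specific detection counts.  The published detection summaries bundled in
`datasets` are used as fixture inputs to the plan builder for exactly this
reason.

## Plan assembly

Categories by average patient-risk sigma: high ≥ 5.0, moderate 4.5–5.0, low
3.5–4.5; below 3.5 the analyte is flagged unacceptable ("maximum QC +
method improvement required") — the published strategy bands stop at 3.5,
so the flag is this package's extension.  Start-up selection: among
candidates with N = 3 (one measurement per level, covering the measuring
range) whose run size covers every analyte's daily volume, lowest nominal
Pfr wins, ties to fewer sub-rules.  Monitor selection: among N = 1
candidates with Pfr ≤ 0.05 whose run size reaches at least 90% of every
analyte's reporting interval (the 10% tolerance encodes acceptance of a
borderline analyte; configurable), the largest admissible Pfr wins as the
power proxy.

The MA integration rule codifies the published qualitative reasoning as the
unique simple rule consistent with all ten published decisions: MA replaces
the monitor iff (high sigma AND both directions' *median* TEa-detection ≤
daily volume) OR (moderate sigma AND both directions' *maximum* ≤ daily
volume); low/unacceptable analytes always keep the SQC monitor with MA as a
supplement.  Both bias directions are required.  One known source
inconsistency: the narrative text of the study this panel derives from
counts five MA replacements in one passage while its summary table and
abstract give six (chloride is the difference); the table/abstract count is
followed here.

## Problem sizes and numerical choices

Monte-Carlo defaults: 2·10⁵ events for probabilities (tests use 4·10⁴–2·10⁵
as precision demands), 100 iterations per bias point for MA simulation,
3000–4000 replicates for the discrete-event bracketed oracle with agreement
asserted within 4 standard errors, 5% relative, floored at 0.01 expected
results where events are too rare for a meaningful standard error.  All
stochastic APIs take explicit seeds; identical seeds give bitwise-identical
results.  Degenerate inputs are defined: zero power → infinite E(Nuf)
sentinel; no feasible run size → 0 with an `insufficient` flag; constant
calibration baseline → collapsed limits widened by machine epsilon.

## Limitations

- Run-size cells are model outputs, not reproductions of the unpublished
  calculator; only ordering-level agreement is claimed.
- Random (imprecision) error conditions, across-run rules with memory
  (4:1s, R:4s), report-as-you-go (non-bracketed) release and time-based QC
  frequency are out of scope.
- MA statistics beyond simple block mean and EWMA (moving median, moving
  SD, average-of-normals) are not implemented.
- Synthetic streams are i.i.d. within and across days; no within-day drift
  or patient-mix structure.
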
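# labqcplan

Risk-based statistical quality control (SQC) planning for clinical
laboratories with a small daily testing volume, combining three strands of
laboratory QC practice in one tested pipeline:

1. **Sigma metrics** — for each analyte and control level,
   `sigma = (TEa − |Bias|) / CV` (all in %), with TEa the total allowable
   error, bias from external quality assessment and CV from internal QC.
   For risk calculations the per-level sigma is capped at 6 (*patient-risk
   sigma*) and the three levels are averaged.
2. **Bracketed run sizes** — how many patient samples may be released
   between two QC events so that, if a systematic error arises, the expected
   number of unreliable final results stays at or below a patient risk
   factor (default 1).  The model is the bracketed MaxE(Nuf) formulation
   `E(Nuf)(n, SE) = n · ΔPE(SE) · (1 − Ped(SE)) / Ped(SE)`, maximized over
   the error magnitude SE, where `Ped` is the power function of the Westgard
   control rule in use and `ΔPE` is the excess probability that a patient
   result exceeds TEa.
3. **Moving-average patient-based QC (PBRTQC)** — simple block MA and EWMA
   procedures on the patient-result stream, with truncation and control
   limits, evaluated by bias-injection simulation: how many patient results
   does a bias of a given size (notably ±TEa) need before the MA alarms?

A plan builder assembles the pieces into a multistage plan: one panel-wide
**start-up** multirule run each morning, and per analyte either a cheap
single-measurement **monitor** rule or — when the analyte's sigma category
and its MA procedure's detection speed allow — MA surveillance alone.

The package ships a complete worked example (`labqcplan.datasets`): a
10-analyte clinical chemistry panel (30–150 tests/analyte/day) with CLIA
TEa, EQA bias and IQC CV inputs, the run-size matrix of its candidate
procedures, and the bias-detection summaries of its optimized MA
procedures.  `labqcplan.synthetic_data` generates patient streams, IQC
series and EQA triplets with known ground truth so every stage is testable
without real laboratory data.

## Worked example

The numbered drivers under `analysis/` run the whole pipeline on the bundled
panel and write tables to `results/`:

```sh
python analysis/02_sigma_metrics.py
```

```
analyte            avg sigma  avg risk  category
Albumin                 7.38      5.51  high
AST                    12.86      6.00  high
Calcium                 4.09      4.09  low
Chloride                5.54      4.75  moderate
...
Sodium                  3.89      3.89  low
```

Average *risk* sigma (capped per level at 6) is the planning quantity: ≥ 5.0
is a high-sigma strategy, 4.5–5.0 moderate, 3.5–4.5 low.  Sodium, at 3.89,
is the weakest assay on the panel and drives every panel-wide choice.

```sh
python analysis/06_build_plan.py
```

```
        analyte category              startup        monitor
        Albumin     high 1:3s/2of3:2s/3:1s N3             MA
        Calcium      low 1:3s/2of3:2s/3:1s N3 1:2s N1 and MA
     Creatinine moderate 1:3s/2of3:2s/3:1s N3 1:2s N1 and MA
...
6 of 10 analytes monitored by MA alone;
4 keep the SQC monitor with MA as supplement.
```

The start-up procedure is the N3 multirule (false rejection 0.02) — the
cheapest 3-measurement design whose run size covers every analyte's daily
volume.  The monitor is 1:2s with one measurement (Pfr 0.05), feasible for
the whole panel within a 10% tolerance that admits sodium's borderline run
size.  For six analytes the MA procedure detects a TEa-sized bias fast
enough to replace the monitor rule outright; creatinine stays on the SQC
monitor because its EWMA needs up to 360 results to catch a positive
TEa-bias against a daily volume of 120.

The other drivers: `01` generates the synthetic LIS/IQC/EQA data, `03`
estimates false-rejection probabilities and power curves for the candidate
rules, `04` computes the model's run-size matrix, `05` runs bias-detection
simulations for representative MA designs.

## Layout

- `src/labqcplan/` — library: `synthetic_data`, `sigma_metrics`,
  `sqc_rules`, `run_size`, `ma_pbrtqc`, `plan_builder`, `datasets`
- `analysis/` — numbered narrative drivers writing to `results/`
- `tests/` — pytest suite with brute-force and event-level simulation
  oracles
- `docs/methods.md` — model assumptions, parameter choices and limitations
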
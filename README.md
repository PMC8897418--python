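# hisims — automated morphology matching for His bundle pacing

During His bundle pacing (HBP) implantation, the operator paces within the
His-cloud region and decides, beat by beat, whether the stimulus produced
**selective His capture (S-HBP)** — a paced QRS essentially identical to the
patient's intrinsic QRS — **nonselective His capture (NS-HBP)** — fusion
with local septal myocardium, widened by a pseudodelta wave — or plain
**right-ventricular myocardial pacing (RVP)**. Conventionally this is a
visual comparison of all 12 surface-ECG leads against the intrinsic
morphology. `hisims` implements the automated alternative: an **intrinsic
morphology match score (IMS)** computed for every beat, plus the statistics
needed to validate it and to derive classification cutoffs.

For a beat *x* and a frozen intrinsic template *y*, the score inside the
operator-set independent scoring interval (ISI) is

```
IMS = round( 100 · (1/12) · Σ_k ρ_k ),    ρ_k = Pearson corr(x_k, y_k)
```

with the beat aligned to the reference by its detected QRS onset, negative
values kept for statistics but displayed as 0, and beats whose local
activation time (LAT) is positive — non-captured or atrial-capture beats —
excluded before any analysis. On top of the score the package provides:

* a **beta-distribution accuracy/precision summary** of the intrinsic
  reference (accuracy = mode of the ML-fitted Beta(α, β); precision = its
  2.25th–97.5th percentile interval; 95% CIs by parametric bootstrap),
* a **generalized-Youden multi-class threshold search** returning the
  cutoff pair (c_low, c_high) that best separates RVP / NS-HBP / S-HBP,
* per-class **sensitivity/specificity/PPV/NPV** with exact Clopper–Pearson
  CIs, and Mann–Whitney group comparisons,
* a calibrated **synthetic 12-lead beat generator** (sum-of-Gaussian QRS
  wavelets, two source morphologies, convex fusion mixing with a
  pseudodelta ramp) whose cohorts stand in for the non-deposited patient
  recordings.

## Worked example

```python
from hisims import RunConfig, run_reproduction

bundle = run_reproduction(RunConfig(out_dir="results/full_run",
                                    preset="his_lead", seed=42,
                                    write_beats_csv=False))
print(bundle.table2)
```

prints the per-class score summary of a simulated His-lead cohort at the
published class counts:

```
true_class   n  ims_median  ims_q1  ims_q3  ims_min  ims_max
 INTRINSIC 354        99.0    99.0   100.0     87.0    100.0
     S_HBP 478        95.0    93.0    96.0     89.0     99.0
    NS_HBP 268        84.0    82.0    86.0     75.0     91.0
       RVP 125        50.0    43.0    58.0     19.0     79.0
```

Read: 354 intrinsic beats match their own template at a median IMS of 99%
(the reference passes the acceptance rule — at least 75% of intrinsic beats
at IMS ≥ 97%); selective capture sits near 95%, fusion beats near 84%, and
pure RV capture near 50%, so the three responses separate cleanly on the
score. The bundle also carries the diagnostic metrics at the cutoffs
(78.4, 88.9) — S-HBP sensitivity 1.00, NS-HBP specificity 1.00 on this run
— and the beta accuracy summary of the reference (accuracy 99.4%,
precision 96.2–99.9%).

The numbered drivers under `analysis/` run the same steps as a narrative
sequence (simulate/score → reference accuracy → threshold search →
diagnostic metrics → full reproduction) and write their tables under
`results/`. The `hisims` console script exposes each stage
(`simulate`, `score`, `classify`, `optimize-thresholds`, `metrics`,
`reproduce`) for shell use; stages are re-runnable from the intermediate
CSVs.

## Layout

```
src/hisims/        library: synthetic_ecg, morphology, classification,
                   stats, io, pipeline, presets, cli
analysis/          numbered narrative drivers (01…05)
scripts/           acceptance.py
tests/             pytest suite
docs/methods.md    model, calibration and design notes
```
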
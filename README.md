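# actiphase

Actigraphy-based classification of acute bipolar illness phase.

Wrist actigraphy gives an objective, minute-by-minute record of motor
activity, and the *pattern* of that activity — its variability,
regularity, complexity and spectral balance, not just its mean level —
differs between mania, bipolar depression and mixed states.
`actiphase` implements the full analysis chain for inpatient recordings
sampled at 1-min epochs:

1. **Day windows** — restrict each ~22-h recording to 06:00–24:00 and
   split it into a morning [06:00, 15:00) and an evening
   [15:00, 24:00) window.
2. **Active periods** — find one 64-min segment of sustained activity
   per window by tolerance escalation: the first (morning) or latest
   (evening) 64-min stretch with no run of more than k consecutive
   zero-count minutes, k = 2, 3, … .
3. **Six activity parameters** per segment: mean counts/min, SD%,
   RMSSD%, lag-1 autocorrelation, sample entropy (m = 2, r = 0.2), and
   the high/low-frequency spectral variance ratio (2–8 min vs 8–64 min
   periods).
4. **Canonical discriminant-function analysis** on the 12 standardized
   residual scores (age/gender-adjusted): eigenvalues λᵢ of W⁻¹B,
   canonical correlations √(λᵢ/(1+λᵢ)), Wilks' Λ with Bartlett χ², the
   structure matrix of pooled within-group loadings (|r| ≥ .3 reported),
   Fisher classification functions, confusion tables with Pearson χ²,
   leave-one-out cross-validation and a stratified 1000-replicate case
   bootstrap.

Because raw recordings for this population are not publicly deposited,
the package includes a first-class **synthetic cohort generator** whose
extracted features are calibrated to the published phase-specific group
means (all 36 phase × period × feature means fall inside the published
95% CIs; this is a standing test). It is intended for methodologists
and clinical researchers who want to reuse, stress-test or extend the
analysis on their own actigraphy data or on simulated cohorts.

## Worked example

Run the whole pipeline on a synthetic 34-subject cohort (12 bipolar
depression / 16 mania / 6 mixed, the study split):

```python
from actiphase.pipeline import RunConfig, run_pipeline

manifest = run_pipeline(RunConfig(output_dir="run", seed=17))
print(manifest["apparent_accuracy_pct"], manifest["loocv_accuracy_pct"])
```

```
76.47058823529412 44.11764705882353
```

The run directory then contains the cohort CSVs, the extracted
segments, the 34 × 12 feature table, `model.json` and the
classification tables. For seed 17 the fitted model is:

```
eigenvalues            [1.42, 0.37]
canonical correlations [0.77, 0.52]
Wilks' lambda          [0.30, 0.73]
group centroids        BDep (1.54, -0.02)  mania (-0.82, 0.45)  mixed (-0.90, -1.17)

apparent classification (rows = true phase):
                    bipolar_depression  mania  mixed
bipolar_depression                   9      2      1
mania                                0     14      2
mixed                                0      3      3
```

Reading this: the first discriminant function separates bipolar
depression from the other phases (centroid 1.54 vs −0.82/−0.90) and
loads on morning SD% and morning sample entropy in the filtered
structure matrix; the second function separates mixed states and loads
on evening measures. 26/34 (76.5%) of cases are classified correctly
in-sample; accuracy drops to 44% under leave-one-out, the expected
optimism gap at n = 34 with 12 predictors. Exact numbers vary with the
seed — the cohort is simulated.

The same stages are scriptable from a shell:

```bash
actiphase simulate --n-subjects 34 --seed 17
actiphase extract  --input cohort_counts.csv --out segments.csv
actiphase features --segments segments.csv --subjects subjects.csv --out features.csv
actiphase dfa      --features features.csv --boot 1000 --seed 17 --out report/
actiphase run      --config run.yaml       # or everything at once
```

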
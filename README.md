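# dosestab

Stability analysis of dosiomic texture features under random
interfractional setup error.

Radiotherapy delivers a planned 3D dose distribution over n treatment
fractions. Each fraction's patient setup carries a random isocenter error,
so the dose actually accumulated is a blurred version of the plan. Texture
("dosiomic") features extracted from the planned dose are increasingly used
in outcome models — but a feature is only useful if it survives this
blurring. `dosestab` answers, feature by feature: *how much does each of 93
dosiomic features change under realistic setup error, and how does that
depend on the number of fractions and the region of interest?*

The package provides:

- a **synthetic patient generator** (ellipsoidal target, penumbra + dose
  bath, heart and lung regions) so the whole study runs without clinical
  data — real dose grids can be supplied as NRRD/NIfTI volumes or DICOM
  RTDOSE instead;
- an **error simulator**: truncated-Gaussian per-fraction shifts (SD 1.2 mm
  per axis, capped at ±3 mm), trilinear rigid translation, accumulation over
  fraction counts 2/10/20/30 with 20 replicates each (81 dose volumes per
  patient);
- a from-scratch **93-feature dosiomic extractor** (first order, GLCM,
  GLRLM, GLSZM, NGTDM, GLDM), validated against an independent brute-force
  oracle to 1e-9;
- **stability statistics**: coefficient of variation with the four-way
  category scheme, absolute-agreement intraclass correlation ICC(A,1) with
  F-test p-values, signed percent difference vs. the error-free plan, and a
  fraction-consistency ICC;
- a **pipeline + CLI** that runs the full study reproducibly and resumably.

See [docs/methods.md](docs/methods.md) for the model, conventions and
limitations.

## Worked example

```python
import numpy as np
from dosestab import (ErrorModel, PhantomSettings, ProtocolSpec,
                      extract_features, generate_patient, run_error_protocol,
                      sample_shift_schedule)

grid, masks = generate_patient(PhantomSettings(seed=42))
print("dose shape:", grid.values.shape, " spacing:", grid.spacing)
print("GTV mean dose: %.2f Gy" % grid.values[masks["GTV"].values].mean())

sched = sample_shift_schedule(30, ErrorModel(), seed=0)
print("first shift (mm):", np.round(sched.shifts[0], 3))

doses = run_error_protocol(
    grid, ProtocolSpec(fraction_groups=(2, 30), replicates=3, base_seed=0)
)
print("volumes:", len(doses))

fv_ori = extract_features(doses["original"], masks["GTV"])
fv_err = extract_features(doses[(2, 0)], masks["GTV"])
for key in [("firstorder", "Mean"), ("glcm", "Contrast"),
            ("glszm", "ZoneEntropy")]:
    print(f"{key[0]}.{key[1]}: original {fv_ori[key]:.4f}  "
          f"2-fraction replicate {fv_err[key]:.4f}")
```

Output:

```
dose shape: (64, 64, 64)  spacing: (2.5, 2.5, 2.5)
GTV mean dose: 58.46 Gy
first shift (mm): [ 0.151 -0.159  0.769]
volumes: 7
firstorder.Mean: original 58.4603  2-fraction replicate 58.2106
glcm.Contrast: original 1.2454  2-fraction replicate 1.4471
glszm.ZoneEntropy: original 3.7004  2-fraction replicate 4.0875
```

Already with 2 fractions the error blurs texture visibly (Contrast and
ZoneEntropy move) while the mean dose barely changes — the cohort study
quantifies exactly this, per feature.

## Running the full study

The model/results split follows the statsmodels pattern: build a
`StabilityStudy` from a tidy feature table, `fit()` it, inspect the
`StabilityResults`.

```python
from dosestab import RunConfig, run_study

results = run_study(RunConfig(output_dir="study_out"))  # 15 patients, seed 1
print(results.summary())
unstable = results.unstable_features(threshold=0.9)
```

or from the shell:

```bash
dosestab run-all --out study_out                # full default study
dosestab make-phantom --patients 15 --out cohort/
dosestab extract --out study_out --patients 4 --fractions 2 10 --replicates 5
dosestab analyze --out study_out
```

Outputs under `study_out/`: per-patient feature CSVs (`features/`, reused on
re-run so an interrupted study resumes), `cv_table.csv`, `icc_table.csv`,
`pd_table.csv`, `cv_category_counts.csv`, `fraction_consistency_icc.csv`,
`cv_categories.png`, `summary.txt` and a `manifest.json` recording the
configuration and seed.

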
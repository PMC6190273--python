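# avfppg

Bilateral-photoplethysmography analysis for grading arteriovenous
fistula (AVF) stenosis.

Hemodialysis patients depend on a surgically created arteriovenous
fistula for vascular access, and progressive stenosis is the main reason
these accesses fail.  When the fistula arm narrows, the pulse arriving at
that hand is delayed and damped, so photoplethysmography (PPG) recorded
simultaneously at both thumbs becomes asynchronous.  `avfppg` turns that
asynchrony into a severity grade: it filters and segments two-channel
1 kHz PPG, extracts four bilateral asymmetry features, and classifies the
degree of stenosis (DOS) into three clinical classes with an
error-correcting output-coding one-vs-rest kernel SVM (a
Levenberg–Marquardt-trained MLP baseline is included).  Because no public
bilateral-PPG stenosis corpus exists, the package ships a synthetic
cohort generator whose inter-arm asymmetry grows monotonically with DOS.

It is aimed at biomedical-signal-processing researchers who want a
reproducible, fully inspectable reference pipeline for bilateral pulse
asynchrony analysis.

## The model in brief

- **Grading.**  DOS = 1 − (d/D)², with lesion diameter `d` and normal
  vessel diameter `D`; class 1 for DOS ≤ 30 %, class 2 for
  30 % < DOS ≤ 50 %, class 3 for DOS > 50 %.
- **Features.**  Per matched heartbeat, the absolute left/right
  differences of pulse-foot time (d1), systolic-peak time (d2, the
  transit-time asymmetry), rise time (d3) and normalized pulse amplitude
  (d4), median-aggregated per subject and min-max normalized across the
  training cohort.
- **Classifier.**  Three soft-margin kernel SVMs (default quadratic
  kernel `(x·z + γ)²`, trained by a built-in SMO solver) combined through
  the code matrix class 1 → (1,1,1), class 2 → (0,1,0), class 3 → (0,0,1)
  with nearest-codeword Hamming decoding, margin-weighted tie-breaks.

See `docs/methods.md` for the full account, defaults and limitations.

## Worked example

```python
from avfppg.synth import generate_cohort
from avfppg.features import cohort_feature_table
from avfppg.evaluate import cross_validate, noise_robustness, ClassifierSpec
from avfppg.ecoc_svm import KernelSpec

cohort = generate_cohort(n_per_class=22, seed=1)   # 66 synthetic subjects
table = cohort_feature_table(cohort)               # subject_id, d1..d4, class
print(table.head(3).round(4).to_string(index=False))

rep = cross_validate(table, ClassifierSpec(kernel=KernelSpec("quadratic", 1.0)))
print(f"LOSO accuracy {rep.accuracy:.2f}%  precision {rep.precision:.2f}%")

df = noise_robustness(cohort, n_seeds=10, seed=0)  # SNR 40/30/20 dB protocol
print(df[["snr_db", "accuracy"]].round(2).to_string(index=False))
```

prints

```
subject_id     d1     d2     d3     d4    dos  class
    C1S000 0.0170 0.0220 0.0050 0.0894 0.1780      1
    C1S001 0.0085 0.0085 0.0020 0.0303 0.0860      1
    C1S002 0.0290 0.0360 0.0075 0.1154 0.2872      1
LOSO accuracy 89.39%  precision 90.84%
 snr_db  accuracy
   40.0    100.00
   30.0     99.17
   20.0     81.00
```

The feature columns are in seconds (d1–d3) and dimensionless (d4) and
grow with the subject's DOS.  Leave-one-subject-out accuracy of the
quadratic-kernel ensemble on the 66-subject cohort is ~89 %, and the
noise protocol — signal-band noise injected into the raw recordings of
correctly classified subjects, re-processed and re-classified with the
fixed clean-trained model — degrades gracefully from SNR 40 dB down to
20 dB.

The same workflow is available from the shell:

```sh
avfppg synth --n-per-class 22 --seed 1 --out data/
avfppg features --data data/ --out features.csv
avfppg train --features features.csv --kernel quadratic --out model.json
avfppg evaluate --features features.csv --scheme loso
avfppg noise-test --n-per-class 22 --seed 1
```

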
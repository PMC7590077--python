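# nirscreen

Multistage chemometric screening of powder samples for cocaine from
**740–1070 nm handheld NIR spectra**.

Field screening of drug-suspected powders is usually done with colorimetric
tests (Scott/Ruybal), which react falsely to common cutting agents such as
levamisole and lidocaine and require handling the material. Low-cost handheld
NIR spectrometers scan through a glass vial in seconds, but their narrow
740–1070 nm window carries only weak overtone features, so raw spectra are
nearly uninformative. `nirscreen` implements the machine-learning pipeline that
turns such spectra into a presumptive positive/negative cocaine call, a
concentration estimate, and a sample-identity suggestion — for forensic
chemists and chemometricians who want a tested, reusable implementation of
this screening strategy.

## The model

Each scan `x ∈ ℝ³³¹` (reflectance on the 1 nm grid) is preprocessed with
**SNV** followed by a **Savitzky–Golay derivative**:

* SNV: `x ↦ (x − x̄) / s_x` — removes additive baseline offsets and
  multiplicative scatter exactly (`SNV(a·x + b) = SNV(x)`, a > 0);
* Savitzky–Golay: a cubic is least-squares fitted in a sliding 19-point
  window and its 1st (or 2nd) derivative evaluated at the centre; 9 edge
  points per side are dropped (331 → 313 points). Optionally the spectrum is
  cropped to the cocaine-selective ROI (839–939 nm for d1, 839–914 nm for d2).

The decision then runs through two stages:

1. **Abstaining dual kNN (submodel A).** The query is ranked against every
   library scan by Euclidean distance and by Pearson correlation. Up to 9
   neighbours per metric are accepted, but only within hard thresholds
   (d ≤ 0.1, r ≥ 0.98). Accepted neighbours (≤ 18, duplicates count twice)
   majority-vote the identity, and the predicted concentration is the mean of
   their known wt%. **No accepted neighbour → the model abstains** instead of
   guessing — the defence against novel compounds. Library scans whose mean
   PC-score distance to their sample's other replicates exceeds the sample's
   99 % quantile are flagged as outliers and excluded beforehand.
2. **ANN gate + bagged trees (submodel B).** PCA compresses the spectra to
   the fewest components holding 99 % of variance; a committee of small
   feed-forward networks scores P(base). Only near-certain scores assign a
   salt form (p ≤ 0.05 → HCl, p ≥ 0.95 → base; otherwise *unassigned*), then
   a per-form bagged regression-tree ensemble predicts the concentration.

**Decision rule (per scan):** if the kNN stage answered, positive ⇔ its
concentration > 20 wt% (submodel B is ignored); if it abstained, positive ⇔ a
form was assigned *and* the treebag concentration > 20 wt%; everything else is
negative. **Per sample:** majority vote over the replicate scans, ties →
negative (false positives are the costliest error of a presumptive test).
The 20 wt% threshold is adjustable; sweeping it traces the FP/TP trade-off
curve for tuning to a specific forensic setting.

Because the original 10,000-scan casework library cannot be redistributed,
the package ships a seeded **synthetic-spectrum simulator**
(`nirscreen.synthetic_data`): Gaussian-band component signatures, linear
mixing by mass fraction, per-scan multiplicative scatter, per-scanner and
per-scan additive offsets, i.i.d. noise, and optional spike corruption, plus
a frozen 61-sample benchmark design (cocaine HCl/base dilution ladders in
common cutting agents — including the 42/34/30/25/20/19/10/5/0 wt% caffeine
reference series — pure negatives and binary negative mixtures, 5 scanners ×
5 replicates).

## Worked example

```python
from nirscreen import benchmark_design, generate_library
from nirscreen.decision_eval import (concentration_fit_metrics,
                                     confusion_report, loso_cross_validate)

gen = generate_library(benchmark_design())          # frozen 61-sample benchmark
library = gen.to_library()                          # 1525 scans, 740-1070 nm
cv = loso_cross_validate(library, seed=1)           # SNV + 1st derivative, 20 wt% rule

scan = confusion_report(cv.spectrum_verdicts, library.sample_meta, level="scan")
sample = confusion_report(cv.sample_verdicts, library.sample_meta, level="sample")
answered = [p for p in cv.scan_predictions if p.knn_status == "ok"]
r2, rmse = concentration_fit_metrics(
    [p.knn_conc for p in answered],
    [library.sample_meta[p.sample_id].cocaine_wt_pct for p in answered],
)
print(f"scan level:   TP {scan.tp_rate:.1f}%  TN {scan.tn_rate:.1f}%  "
      f"(FN {scan.fn}, FP {scan.fp} of {scan.tp+scan.fn+scan.tn+scan.fp} scans)")
print(f"sample level: TP {sample.tp_rate:.1f}%  TN {sample.tn_rate:.1f}%  FP count {sample.fp}")
print(f"kNN concentration: R^2 {r2:.3f}, RMSE {rmse:.2f} wt% over {len(answered)} scans")
```

prints

```
scan level:   TP 95.4%  TN 100.0%  (FN 28, FP 0 of 1301 scans)
sample level: TP 96.0%  TN 100.0%  FP count 0
kNN concentration: R^2 0.953, RMSE 7.01 wt% over 1497 scans
```

Scans are evaluated leave-one-sample-out (all replicates of the queried
sample are excluded from its library), so these are held-out rates. The 28
false-negative scans all come from samples at 21–25 wt%, just above the
threshold — the expected failure band of a neighbour-averaged concentration
near a hard cutoff. Sub-threshold cocaine samples (≤ 20 wt%) are deliberate
negatives of the screening rule and are excluded from the tally (1301 of
1497 scans scored).

The same workflow is available from the shell:

```bash
nirscreen simulate --out-scans scans.csv --out-meta meta.csv
nirscreen cv --scans scans.csv --meta meta.csv --threshold 20 --seed 1 --out-dir results/
nirscreen curve --scans scans.csv --meta meta.csv --grid 0:100:1 --out curve.csv
```

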
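# actidx

Actigraphy feature extraction and diagnostic classification for memory-
clinic populations.

Week-long recordings from body-worn accelerometer systems are commonly
exported as 5-second epochs, each labeled with an activity category
(sitting, walking, lying rest, ...) and a unitless intensity count.
`actidx` turns such exports into per-subject circadian and activity
features and asks how well they separate dementia etiologies —
Alzheimer's disease (AD), dementia with Lewy bodies (DLB), vascular
cognitive dysfunction (merged with mixed-pathology AD into a CVD class)
— from each other and from healthy controls (HC).

The pipeline:

1. **Ingest** — epoch CSVs are validated and aggregated into
   clock-aligned 15-minute windows (per-category time fractions, summed
   counts, wear fraction, sit-to-stand and step events), then sliced
   into three periods: the full 24 h anchored at 22:00, night
   (00:00–06:00) and day (09:00–21:00).
2. **Features** — per day, period and category: mean fraction,
   percentage of windows above 5/10/25% time in category, and the
   intra-daily variability

       IV = n Σᵢ(xᵢ−xᵢ₋₁)² / ((n−1) Σᵢ(xᵢ−x̄)²),

   plus, for the intensity counts, the mean, the mean during
   sitting-modal windows, M10 and L5 (mean count over the most active
   10 h / least active 5 h with onset times) and the relative amplitude
   RA = (M10−L5)/(M10+L5). Per-day vectors are summarized per subject by
   across-day average and variance (322 features by default).
3. **Classifier** — unregularized logistic regression with per-fold
   mRMR filtering (mutual-information difference, 3-bin discretization,
   k = 30) and sequential forward selection scored by inner
   leave-one-out accuracy, all inside nested leave-one-out
   cross-validation; thresholds at 0.5 and at the ROC point closest to
   (0,1); sensitivity/specificity/accuracy/precision with exact 95%
   Clopper–Pearson intervals, F1, a single-feature (mean 24-h count)
   comparator and coefficient-based feature importance.
4. **Group statistics** — Kruskal–Wallis feature tables, smoothed
   group-average 24-h intensity curves, actograms, and an OLS probe of
   whether output probabilities are confounded by age, sex or
   medication.
5. **Synthetic cohorts** — because no real recordings ship with the
   package, a generator produces epoch-level cohorts with configurable
   circadian structure (cosinor + behavioral-state gating,
   fragmentation, nighttime wakes, category mixes, between-subject
   heterogeneity). The bundled preset encodes the direction and coarse
   magnitude of published group contrasts (HC most active, elevated
   nighttime activity and fragmentation in DLB/CVD, an afternoon
   activity peak only in HC) at the study-scale group sizes
   (70/29/8/15/48). See `docs/methods.md` for the model and its limits.

## Worked example

```python
import numpy as np
from actidx import (paper_like_cohort, generate_cohort,
                    aggregate_to_windows, extract_features,
                    nested_loocv_predict, optimal_threshold,
                    performance_metrics, feature_importance)
from actidx.diagnostic_ml import TASKS, prepare_matrix

cfg = paper_like_cohort(days=7, seed=1, sizes={"AD": 50, "DLB": 50})
series, manifest = generate_cohort(cfg)
table = extract_features([aggregate_to_windows(s) for s in series],
                         manifest)

X, y, names, sids = prepare_matrix(table, TASKS["AD_vs_DLB"])
result = nested_loocv_predict(X, y, names, sids)
thr = optimal_threshold(result.probabilities, result.y)
rep = performance_metrics(result.probabilities, result.y, thr)
print(f"accuracy {rep.accuracy:.1f}%  "
      f"sensitivity {rep.sensitivity:.1f}%  F1 {rep.f1:.1f}%")
print(feature_importance(result).head(3))
```

prints

```
accuracy 99.0%  sensitivity 100.0%  F1 99.0%
                feature  importance  n_folds_selected
0  avg__full__count__ra        15.0               100
```

The nested classifier separates the two synthetic groups at 99%
accuracy at the optimized threshold, and the single feature it selects
in every fold is the across-day average relative amplitude — exactly the
circadian-robustness contrast the preset plants between the AD and DLB
profiles (DLB subjects have fragmented rhythms and elevated nighttime
activity, which compresses RA). The importance of 15.0 is the
coefficient cap: a feature this strong separates the training folds
completely.

The same flow is available from the shell:

```bash
actidx simulate --preset paper_like --days 7 --seed 1 --out-dir sim/
actidx ingest  --epochs sim/ --window-min 15 --out windows.csv
actidx extract --windows windows.csv --manifest sim/manifest.csv --out features.csv
actidx classify --features features.csv --task AD_vs_DLB --out result.json
actidx run --config pipeline.yaml        # all stages from one YAML
```

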
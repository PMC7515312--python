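# pulsescale

Multi-scale heart-beat entropy analysis for mental-workload research.

Heart rate variability (HRV) — the beat-to-beat fluctuation of RR
intervals — reflects autonomic regulation, and its *complexity at
multiple time scales* separates mental states better than classical
time/frequency HRV statistics, especially when the wearer is moving.
`pulsescale` is a toolkit for researchers working with ECG or RR data
from wearables. It provides:

* an ECG→RR chain: 4–40 Hz zero-phase band-pass, energy-based
  (Pan–Tompkins-style) QRS detection, three-stage RR artifact
  rejection, 5-min/4-min-overlap windowing;
* five series scalings — coarse graining `cg`, moving average `mavg`,
  composite coarse graining `comp_cg`, and their second-moment
  ("volatility") counterparts `mom` and `mavg_mom`;
* three entropy estimators — sample entropy, modified permutation
  entropy (mPE, with tie symbols), and variance-weighted mPE — applied
  at scales s = 1..10 to both the RR and |ΔRR| series (24 features per
  estimator/scaling pair);
* inter-scale ordinal distances: D = (m!/(m!−1)) Σ_π (p_x(π) − p_y(π))²
  between motif distributions of moving-average-scaled series,
  anchors s = 1..3 against s = 1..10 (66 features);
* the 15 benchmark HRV features (time domain + Lomb–Scargle band
  powers);
* a synthetic RR/ECG generator with workload-like class structure, so
  every stage is testable without access to private physiological
  recordings;
* an evaluation harness: stratified 5-fold CV × 50 repeats, recursive
  feature elimination (extra-trees) to 20 features, RBF-SVM scoring,
  and selection-frequency feature ranking.

Feature extraction is exposed as sklearn-style transformers
(`BenchmarkFeatures`, `IsodFeatures`, `EntropyFeatures`) plus a
`WorkloadClassifier` estimator, so everything composes with sklearn
pipelines and model selection.

## Worked example

```python
import numpy as np
import pulsescale as ps

# a 10-min synthetic recording with LF/HF modulation and pink noise
rr = ps.gen_rr(ps.SyntheticConfig(), duration=610, seed=7)
clean = ps.filter_rr_outliers(rr)
windows = ps.window_rr(clean)
print(f"{len(clean)} beats -> {len(windows)} five-minute windows")

w = windows[0]
bench = ps.time_domain_features(w)
print(f"mean RR {bench['mean_rr']:.1f} ms, SDNN {bench['sdnn']:.1f} ms, "
      f"RMSSD {bench['rmssd']:.1f} ms")
print(f"LF/HF {ps.frequency_domain_features(w)['lf_hf']:.2f}")

profile = ps.multiscale_profile(w.intervals, scaling="comp_cg", entropy="mpe")
print("mPE/comp_cg profile:", np.round(profile, 3))
print(f"isod s1-s4 (RR): {ps.isod_features(w)['isod_rr_s1_s4']:.4f}")

# small labeled dataset and the CV harness
X, y = ps.gen_labeled_dataset(10, seed=5)          # 20 windows, 129 features
plan = ps.make_splits(y, folds=5, repeats=4, base_seed=5)
res = ps.run_experiment(X, y, plan, base_seed=5)
print(f"accuracy {res.mean_accuracy:.3f} +/- {res.std_accuracy:.3f} "
      f"over {len(res.accuracies)} splits")
```

Output:

```
683 beats -> 6 five-minute windows
mean RR 893.8 ms, SDNN 30.0 ms, RMSSD 27.9 ms
LF/HF 1.03
mPE/comp_cg profile: [1.683 1.785 1.758 1.771 1.661 1.669 1.739 1.71  1.646 1.686]
isod s1-s4 (RR): 0.0564
accuracy 1.000 +/- 0.000 over 20 splits
```

The six windows come from starts 0..5 min of the 10-min recording.
The mPE profile stays near log 6 ≈ 1.79 at low scales (rich ordinal
structure) and is computed by averaging member entropies for the
composite scaling. The default low/high-workload generator configs
differ in mean RR, LF/HF ratio and spectral slope, so the toy
classification is easy — accuracy 1.0 — while identical configs
stay at chance.

A `pulsescale` CLI wraps the same functions: `preprocess`,
`benchmark`, `entropy`, `isod`, `simulate`, `evaluate`,
`rank-features`; see `pulsescale --help`.

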
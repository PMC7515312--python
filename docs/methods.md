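# Methods

`pulsescale` quantifies heart-rate-variability (HRV) complexity at
multiple time scales and evaluates how well the resulting features
separate two mental-workload states. This note records the models,
parameter choices and numerical conventions the package commits to,
and what its synthetic-data tests do and do not establish.

## From ECG to RR intervals

The analysis object is the RR series: the times between successive R
peaks of the ECG, in milliseconds, each interval timestamped by the
beat that ends it. The preprocessing chain is:

1. **Band-pass 4–40 Hz.** A 4th-order Butterworth filter applied
   forward–backward (`sosfiltfilt`), so the response is zero-phase and
   R-peak timing is not shifted. The band keeps QRS energy while
   rejecting baseline wander, T-wave energy and 50/60 Hz interference.
2. **Energy-based QRS detection.** Differentiate, square, integrate
   over a 150 ms moving window, pick envelope peaks at least 200 ms
   apart (the physiological refractory period), accept them against an
   adaptive signal/noise threshold (running signal level SPK, noise
   level NPK, threshold NPK + 0.25·(SPK − NPK), exponential updates
   with weight 0.125), and refine each acceptance to the local maximum
   of the absolute band-passed signal within ±100 ms. A flat signal
   returns an empty peak train with a warning rather than an error.
3. **Artifact rejection**, three cascaded rules applied in order:
   range (intervals outside [280, 1500] ms are removed), moving
   average (beats deviating more than 20% from the centred 5-beat mean
   of their surviving neighbours, the beat itself excluded), and
   percent change (beats differing more than 20% from the previous
   *kept* beat, so one rejection cannot cascade). The moving-average
   parameters (window 5, threshold 20%) are this package's choice,
   aligned with the percent-change threshold; published pipelines vary
   here and no single convention is canonical.
4. **Windowing.** Clean series are cut into 5-min windows advanced by
   1 min (4-min overlap), the standard short-term HRV frame; a 10-min
   recording yields 6 windows. Windows are half-open `[start,
   start+300)` over beat timestamps; windows with fewer than 60 beats
   are dropped, since entropy estimates on shorter series are
   unreliable.

The dRR series |RR(i+1) − RR(i)| is carried alongside RR everywhere;
its long-range structure is known to carry complementary information.

## Scaling algorithms

Five ways to produce a scale-s series from x(1..N):

| method     | definition                          | length    |
|------------|-------------------------------------|-----------|
| `cg`       | non-overlapping block mean          | ⌊N/s⌋     |
| `mavg`     | sliding-window mean                 | N − s + 1 |
| `comp_cg`  | the s offset coarse grainings       | s members |
| `mom`      | non-overlapping block std           | ⌊N/s⌋     |
| `mavg_mom` | sliding-window std                  | N − s + 1 |

Standard deviations use the population convention (divide by s); the
sample convention would scale every volatility value by √(s/(s−1))
without changing any ordinal structure. Trailing partial blocks are
discarded. `mom` and `mavg_mom` at s = 1 are the all-zero series (the
std of a single point); the scale is kept in feature blocks so every
block has a fixed width, and the entropy of the degenerate series is a
well-defined 0 for the permutation estimators.

## Entropy estimators

**Sample entropy.** SampEn = −log(N_{m+1}/N_m) with template length
m = 2, Chebyshev distance, strict `< r` matching, self-matches
excluded, pairs counted once (i < j), both counts over the N − m
templates that admit an extension. The tolerance is r = 0.2 × the
population std of the *unscaled* window, resolved once per window and
held fixed across scales — the original multi-scale convention;
recomputing r per scale would measure a different quantity. When
either count is zero the value is undefined and reported as NaN, never
silently zero.

**Modified permutation entropy (mPE).** Each embedded triplet
(x(i), x(i+λ), x(i+2λ)), λ = 1, maps to one of the six strict ordinal
motifs or to one of four tie symbols (a=b<c, a=b>c, a>b=c, a<b=c);
mPE is the Shannon entropy (nats, unnormalized) of the symbol
frequencies. The ten published rules do not cover two configurations;
the package closes them with a fixed convention: an all-equal triplet
gets its own symbol 11, and an outer tie (a = c, b distinct) is broken
as a < c before lookup. Both have measure zero on continuous data but
occur in integer-quantized RR series; a declared total map keeps the
estimator deterministic. The upper bound is therefore log 11 in
principle, log 6 in practice on continuous data.

**Weighted mPE.** Motif occurrences are weighted by the population
variance of their embedded vector before normalizing, folding
amplitude information into the ordinal distribution. A constant series
has all-zero weights; the estimator falls back to unweighted
frequencies with a warning (the value is 0 either way here, but the
fallback keeps the function total).

**Multi-scale profiles.** Entropy at scales 1..10. For `comp_cg` the
per-scale value is the mean of the member entropies (composite
multi-scale entropy), which reduces estimator variance at high scales;
member 1 is the plain coarse graining, so the s = 1 composite value
equals the plain entropy. Unreachable scales are NaN sentinels,
excluded from cross-scale statistics, never imputed. One entropy block
= 10 scales × {RR, dRR} + cross-scale mean and std per source = 24
named features.

## Inter-scale ordinal distance (isod)

Scaled versions of the same series are compared through their ordinal
distributions over the six *strict* motifs only (ties broken toward
"<"), with the squared-difference distance
D = (m!/(m!−1)) Σ (p_x − p_y)², bounded by 2.4. Scaling is
moving-average, which keeps series long at every scale. The block
takes anchors sx ∈ {1,2,3} against sy ∈ 1..10: the literal "sx ≠ sy"
enumeration would double-count the three anchor–anchor pairs (72
entries); deduplicating unordered pairs gives 9 + 8 + 7 = 24 distances
per source, which is the count consistent with the 66-feature total,
so that is what the package implements. Per-anchor statistics (mean,
std, and the mean of first differences of the distance profile over
ascending sy — one number per anchor) add 9 per source:
(24 + 9) × 2 sources = 66 features. D is not a metric; no triangle
inequality is claimed or tested.

## Benchmark HRV features

Nine time-domain statistics — mean RR, SDNN, CV = SDNN/mean, RMSSD,
pNN50 (strictly > 50 ms), mean signed first difference, std and mean
of |first difference|, and the latter normalized by mean RR — plus six
spectral features. Published benchmark tables in this line of work
list 14 names yet count 15 and later rank a "mean absolute first
difference"; the package includes mean |diff| explicitly as the 15th
feature, which reconciles the count with the ranked name. The spectrum
of the unevenly sampled (beat time, RR) pairs is estimated by
Lomb–Scargle — avoiding the low-pass bias of interpolating onto a
uniform grid — integrated over the standard bands VLF 0.0033–0.04,
LF 0.04–0.15, HF 0.15–0.4 Hz, with nLF = LF/(LF+HF), nHF symmetric,
and the LF/HF ratio. A constant window has zero band powers and NaN
normalized features (degenerate, flagged).

## Synthetic data

The generator emulates what the pipeline assumes of real data, not ECG
physiology:

* RR(t) = mean_rr + lf_amp·sin(2π·0.1·t) + hf_amp·sin(2π·0.25·t) +
  1/f^β noise, accumulated so beat times sample the modulation
  unevenly exactly as real HRV does. Defaults: mean_rr 900 ms, lf_amp
  = hf_amp = 25 ms, noise_sd 20 ms, β = 1 (pink) — a resting adult
  with balanced sympathovagal modulation.
* The high-workload class shifts mean RR by −8%, LF/HF power by ×1.5
  (LF amplitude × √1.5) and β by −0.3 — the direction real workload
  moves these quantities; the magnitudes are tooling constants chosen
  to make separability testable at 50 windows per class, not
  physiological claims.
* ECG rendering places a 10 ms-σ Gaussian R wave at every beat time
  (0.5 s edge padding) with optional white noise; P/T waves and
  morphology variation are deliberately absent.
* Artifact injection corrupts beats at a configured rate with
  out-of-range values (1600–2400 or 150–270 ms) or ×1.35 jumps,
  recording the ground-truth mask.
* Colored noise is synthesized by spectral shaping (amplitude ∝
  f^(−β/2)) of white Gaussian noise, rescaled to the target sd.

Passing tests on this generator show the pipeline recovers *planted*
structure of the assumed form; they cannot show robustness to
morphology-dependent QRS errors, ectopy, respiration–heart-rate
coupling or nonstationarity, none of which the generator produces.

## Evaluation harness

Stratified 5-fold CV repeated 50 times (250 splits), per split:
z-score with training-fold statistics, recursive feature elimination
under a 100-tree extremely-randomized-trees importance estimator down
to 20 features, RBF-SVM (C = 1, gamma = 'scale', both sklearn
defaults; no search), accuracy and F1 with high workload positive. RFE
removes 10% of the remaining features per iteration: selection is
nearly identical to one-at-a-time elimination on these table sizes at
about a tenth of the cost, and the step is exposed as a parameter for
anyone wanting the slower schedule. Feature importance is the
percentage of splits selecting a feature, ranked and filtered at
strictly > 70%.

Two significance helpers: a paired two-sided Wilcoxon signed-rank test
between two runs on the same split plan, and a one-sample test against
chance 0.5 — both with the documented caveat that repeated-CV splits
are not independent, so these p-values are heuristic. Stratification
(the paper-level design says only "five-fold") and the fold scheme are
package choices; subject-grouped splitting is out of scope because the
synthetic windows are independent by construction.

## Problem sizes and numerics

Default test and acceptance problem sizes: 5-min windows of ~330
beats; 50 windows per class for classification (the scale at which the
class shifts above are calibrated); 250 CV splits; SampEn oracle
checks at N ≤ 500; asymptotic motif checks at N = 5000; white-noise
profile checks at N = 3000 over 20 seeds (majority vote, since single
draws can be non-monotone at adjacent scales). All randomness flows
from explicit integer seeds through `numpy` Generators; identical
seeds give bit-identical outputs. NaN is the universal
missing/undefined sentinel. Known limitations: single-lead ECG only,
no streaming, motif degree fixed at 3, scales fixed at 1..10 in the
feature blocks (configurable but untested beyond 10).
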
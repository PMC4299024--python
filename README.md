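# actiseg

Long-term activity segmentation from a single wrist-worn triaxial
accelerometer.  `actiseg` is aimed at digital-health and wearable-sensing
researchers who want to turn a multi-day 20 Hz acceleration stream plus a
handful of user-provided interval labels ("working 9:10–11:40", "commuting
17:05–17:40") into a per-window segmentation of the whole recording into
long-term activities — including the large untagged remainder, which is
treated as an ordinary class.

## Method

The pipeline has four stages:

1. **Featurization.** Each axis is smoothed with a causal average filter
   `v_s(t) = (1/n) Σ_{i=t-n}^{t-1} v(i)` (n = 10 samples), cut into windows
   of l = 60 samples (≈3 s) with 33% overlap, and reduced to 12 features:
   per-axis mean and variance, the three pairwise axis correlations, and
   mean, variance and mean absolute first difference of the magnitude.

2. **Vector quantization.** A codebook of M centroids is learned with
   k-means on training windows only; every window is replaced by the ID of
   its nearest centroid.  A day becomes a string of discrete *primitives*
   `O = o_1 … o_T` over an alphabet of size M.

3. **Sequence modeling and decoding.** From the labeled training strings
   the package estimates the transition matrix `A = {a_ij}`, the emission
   matrix `B = {b_j(k)}`, a uniform initial distribution π, per-state k-mer
   conditional frequencies `P(o_t … o_{t+k-1} | q_t)` (counted with
   overlaps, additively smoothed), and a duration array
   `κ(i) = max(1, ⌊min-run(i)/2⌋)`.  Decoding maximizes either the HMM
   joint `log π(q_1) + Σ log b(o_t|q_t) + Σ log a(q_{t-1} q_t)` or the
   linear-chain CRF score `Σ_t Σ_i ω_i f_i(q_{t-1}, q_t, O, t)` with
   feature functions f1 = log P(o_t|q_t), f2 = transition/initial
   log-probability and f3 = k-mer log-frequency (the normalizer Z is not
   needed for the argmax).  The duration-constrained Viterbi variant
   (`hmm_c`, and always for `crf`) only considers paths whose every maximal
   run of state i spans at least κ(i) positions.

4. **Subclassing.** A single label often covers kinematically distinct
   behaviours (commuting by vehicle vs. on foot).  Each labeled episode is
   summarised as an M-bin primitive histogram; per class, k-means splits are
   scored with a cluster validity index (Silhouette, PBM, or generalized
   Dunn GDI33) and a split is kept only if it strictly improves
   leave-one-instance-out naive-Bayes accuracy.  Predicted subclasses are
   mapped back to the original label before scoring.

Everything is exposed both as scikit-learn-style estimators
(`PrimitiveQuantizer`, `ActivitySegmenter`) and as a CLI
(`actiseg simulate | featurize | train | segment | evaluate`).
A seeded synthetic-data generator (`actiseg.synthgen`) emulates multi-day
recordings — regime-based activities, a planted fragmented commute class,
short gesture bursts, and ~45% untagged time — so the whole pipeline is
testable without any recorded dataset.

## Worked example

```python
import dataclasses
from actiseg import default_scenario, leave_one_day_out, synthetic_pipeline_config

days = default_scenario(10, seed=1)          # ten 1-hour synthetic days
cfg = synthetic_pipeline_config(seed=1)      # M=24 primitives, k=2, alpha=1
for method in ("hmm", "hmm_c", "crf"):
    res = leave_one_day_out(days, dataclasses.replace(cfg, method=method))
    print(f"{method:6s} accuracy {res.accuracy:.4f}")
```

prints

```
hmm    accuracy 0.8961
hmm_c  accuracy 0.9036
crf    accuracy 0.9205
```

i.e. on data whose activities have minimum lifespans, adding the duration
constraint improves window-level accuracy over plain Viterbi decoding, and
adding the k-mer sequence-pattern feature improves it again — the same
monotone pattern the method is designed to produce.  The remaining errors
are dominated by untagged episodes whose motion genuinely is some activity
the user just did not label.

The same experiment from the shell:

```sh
actiseg simulate --days 10 --seed 1 --out data/
actiseg evaluate --data data/ --method hmm_c --out results/
```

which writes per-day accuracies, the pooled confusion matrix and per-class
sensitivities as CSV.

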
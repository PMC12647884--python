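# lawtime

Adaptive law-based transformation (ALT) for time-series classification:
a lightweight, transparent feature representation for uni- and
multivariate labeled series (physiological, motion, spectroscopy and
industrial sensor signals), aimed at practitioners who want noise-robust
fixed-length features that work with any standard classifier.

## The method

A labeled training series is scanned by a schedule `R = {(r, l, k)}` of
windows: length `r`, embedding dimension `l`, stride `k`, with the
structural constraint

```
r = s (2l - 2) + 1,   s a positive integer,
```

so each window contributes `2l - 1` evenly spaced samples with spacing
`s`. Every window is arranged into a symmetric Hankel-type delay
embedding `S[p, q] = x[t + (p + q - 2) s]` (`l x l`), and its **shapelet
law** is extracted: the unit eigenvector `v` belonging to the eigenvalue
of minimal magnitude, i.e. the direction minimising `||S v||`. If the
window locally obeys a linear recurrence of order `< l` (a sinusoid, a
trend, an AR motif), its law annihilates every other window of the same
signal — laws are locally stable, class-typical patterns.

Laws from all law-training windows are collected into per-channel,
per-triplet **class-labeled dictionaries** `P` (`l x N`, each column
tagged with the class of its source instance). Only a fraction `rho`
(the LT ratio) of the training instances feeds the dictionaries; the
rest train the downstream classifier on transformed features.

A new series `z` of length `H` is unrolled into
`o = floor((H - (l-1)s - 1)/k) + 1` strided rows `A` (`o x l`) and
projected, `M = A P`. Squared responses (energy) are pooled in two
stages per class: a mean or q-quantile **across laws** within each
window row, then a population moment (mean, variance, 3rd/4th central
moment, excess kurtosis) **across windows**. The result is a feature
vector of fixed length `|R| * m * c * n` (schedule size x channels x
classes x pooling pairs) — small responses against a class dictionary
mean "this series conforms to that class's local laws".

The package also ships the single-scale baseline (LLT, the exact
one-triplet special case), a raw-sample baseline, a deterministic
built-in KNN, noise-sweep and repeated-benchmark protocols with paired
Wilcoxon signed-rank + Holm–Bonferroni significance testing, an exact
counting cost model, synthetic recurrence-structured data generators,
and UCR `.ts` / long-CSV I/O.

## Worked example

Two synthetic classes of sinusoids (angular frequency 0.3 vs 0.9,
amplitude 10, random phase, 20 instances each, length 100) with Gaussian
noise of standard deviation 2 added to every sample:

```python
import numpy as np
from lawtime import (ALTModel, LTSplitConfig, PoolingSpec, Schedule,
                     add_noise, generate_recurrence_dataset, knn_fit_predict,
                     evaluate_accuracy, resample_split, two_class_sinusoid_spec)

ds = generate_recurrence_dataset(two_class_sinusoid_spec(seed=0))
noisy = add_noise(ds, 2, seed=1)
train, test = resample_split(noisy, 0.5, seed=42)

model = ALTModel.fit(train, Schedule([(5, 3, 1)]), [PoolingSpec()],
                     LTSplitConfig(rho=0.25, seed=0))
feats_train = model.transform(train.subset(model.clf_ids))
feats_test = model.transform(test)
pred = knn_fit_predict(feats_train.values, feats_train.labels,
                       feats_test.values, k=1)
print(feats_test.names)
print(np.round(feats_test.values[0], 3), np.round(feats_test.values[-1], 3))
print(evaluate_accuracy(pred, feats_test.labels))
```

prints

```
['t0_r5_l3_k1|ch0|class1|mean-mean', 't0_r5_l3_k1|ch0|class2|mean-mean']
[13.859 12.279] [29.975  5.968]
1.0
```

Each instance is reduced to two features: its mean squared response
energy against the class-1 law dictionary and against the class-2
dictionary (schedule `(5, 3, 1)`, mean–mean pooling, 384 stored laws).
The last test instance belongs to class 2: its energy against its own
class's laws (5.97) is far below its energy against class-1 laws
(29.98), because class-2 laws annihilate class-2 structure. 1-NN on
these two coordinates classifies the noisy test split perfectly (1.0).

The same pipeline is available from the shell:

```sh
lawtime synth --seed 0 --out data.ts
lawtime split data.ts --fraction 0.5 --seed 42 --train-out tr.ts --test-out te.ts
lawtime fit tr.ts --schedule "(5,3,1)" --specs mean-mean --lt-ratio 0.25 --model-out model.npz
lawtime transform te.ts --model model.npz --out fte.csv
lawtime noise-sweep --multipliers 0:8 --repetitions 10 --seed 0 --out sweep.csv
```

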
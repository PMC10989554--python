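# cvpfi — cross-validated permutation feature importance

Model-agnostic feature importance for regression and classification models
built on small tabular datasets, such as QSPR/QSAR models mapping molecular
descriptors to physical properties. It addresses two well-known failure
modes of conventional permutation feature importance (PFI):

* **instability at small n** — PFI needs a train/validation split, and a
  validation set of a handful of rows makes the importance estimate noisy;
* **under- and mis-crediting of correlated features** — permuting one
  feature while its strongly correlated partners stay intact lets the
  partners stand in for it.

## The method

Conventional PFI for feature *i* with *J* shuffling repetitions is

```
PFI_i = rs − (1/J) Σ_j s_{i,j}
```

where `rs` is the model's validation score (r² for regression, accuracy for
classification) and `s_{i,j}` the score after randomly shuffling validation
column *i*.

The cross-validated variant (CVPFI) replaces the single split with N-fold
cross-validation (leave-one-out below 30 samples, 10-fold below 100, 5-fold
otherwise). Out-of-fold predictions are pooled into one full-length vector
and scored once, giving the reference score `rs_cv`. Because a leave-one-out
validation block has a single row and cannot be shuffled, corruption is done
by *resampling*: validation column *i* is replaced by values drawn without
replacement from the full original column. In addition, every companion
feature *q* is replaced the same way with probability `r_{i,q}`, the absolute
Pearson correlation between features *i* and *q* — so features that move
together in the data are corrupted together.

To stop chance correlations at small n from triggering co-corruption, each
pairwise correlation is *gated*: with the Fisher transform
`z = ½ ln((1+r)/(1−r))`, whose sampling distribution is approximately
Normal(z, 1/(m−3)), the central interval with coverage α (default 0.999) is
mapped back to the correlation scale, and `r_{i,q}` is set to exactly 0
whenever the interval straddles zero. The importance is then

```
CVPFI_i = rs_cv − (1/J) Σ_j scv_{i,j}
```

with `scv_{i,j}` the pooled score after corrupting feature *i* (and,
probabilistically, its gated companions) in every validation block.

## Worked example

A 20-sample dataset with 15 uniform features, of which the first 10 carry
unit weights to the response and the last 5 none:

```python
from cvpfi import CVPFI, build_estimator
from cvpfi.datasets import generate_case1

X, y, roles = generate_case1(seed=0)
model = CVPFI(X, y, build_estimator("pls"))
result = model.fit(J=5, seed=0)
print(result.summary())
```

```
CVPFI results (pls)
  reference score:  0.8531   J=5  seed=0  alpha=0.999
  feature               importance   sd over J
  x1                        0.0382      0.0361
  x2                        0.1462      0.0334
  x3                        0.0340      0.0260
  x4                        0.3860      0.1458
  x5                        0.2108      0.0761
  x6                        0.1516      0.0539
  x7                        0.0101      0.0215
  x8                       -0.0007      0.0152
  x9                        0.0988      0.0216
  x10                       0.1226      0.0510
  x11                       0.0143      0.0121
  x12                      -0.0188      0.0041
  x13                       0.0037      0.0130
  x14                      -0.0062      0.0098
  x15                      -0.0012      0.0014
```

The reference score 0.8531 is the pooled leave-one-out r² of the PLS model.
Each importance is the drop in that r² when the feature (and any gated
companions) is resampled; the irrelevant features x11–x15 sit near zero
(slightly negative values are normal sampling noise — corruption can
accidentally help). `result.rank()` sorts features by importance,
`result.to_csv(...)` / `result.to_json(...)` serialise the table and the
full per-repetition audit trail, and `result.gated_correlations` holds the
co-sampling probability matrix.

The same run from the shell:

```
cvpfi --case 1 --estimator pls --method both --seed 0 --output-dir run1
```

writes importance tables for CVPFI and PFI, the gated correlation matrix,
pooled predictions and a manifest that reproduces the run exactly. User
data goes through `--input data.csv --response <column>`.

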
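# dpcsig

A tested pipeline for finding and validating a **spatio-temporal neural
signature of imagined social support** in trial-structured fMRI parcel time
series — and for linking its expression to emotion-regulation outcomes.

The scientific setting: participants in a scanner recall negative
autobiographical memories and, on each 20 s trial, either imagine a
supportive conversation with a peer (*imagined support*) or dwell on their own
feelings (*self-feel*).  `dpcsig` asks whether a stable whole-brain pattern
separates these two modes, whether it decodes condition in held-out
participants, which parcels carry it, and whether trials (and people) that
express it more strongly feel less negative afterwards.

## What it computes

Given per-trial parcel x time matrices (214 parcels x 20 TRs by default),
the pipeline:

1. **demixed PCA** — splits the trial-averaged tensor into a
   condition-independent time course and a condition-dependent part, then fits
   a rank-1 decoder/encoder pair `(d, f)` by regularized reduced-rank
   regression: `min ‖X_cond − f dᵀ X‖²_F + ridge(λ)`.  A trial's *dPC
   expression* is `z(t) = dᵀ(x(:,t) − x̄)`, one value per TR.
2. **decoding** — bootstrap out-of-sample classification of imagined support
   vs. self-feel from the 20-point `z` time course (or a 214-parcel
   mean-activity baseline), refitting the dPCA inside every train split,
   with a balanced (uniform-prior) logistic model and a label-permutation
   null for significance.
3. **parcel reliability** — participant-level bootstrap of the decoder
   loadings with Student-t parametric-bootstrap p-values and
   Benjamini–Hochberg FDR across parcels.
4. **behavioral linking** — *dPC similarity* (the Pearson correlation of a
   trial's `z` with the mean imagined-support `z`) related to trial outcomes
   via a random-intercept mixed model, to traits (loneliness, life
   satisfaction, support nominations) via OLS controlling wave and age, and
   the condition contrast on negativity ratings via Welch's t.

A synthetic-data module generates the whole study design with known planted
structure (spatial pattern, temporal profile, rating and trait couplings), at
both parcel and voxel/NIfTI level, so every stage is testable without any
download.  See `docs/methods.md` for the model, defaults, and numerical
choices.

## Worked example

```python
import numpy as np
from dpcsig import (SimConfig, generate_dataset, fit_signature,
                    bootstrap_decode, parcel_inference, similarity_table,
                    trial_level_test, condition_contrast)

trials, traits, truth = generate_dataset(SimConfig(seed=1))

model = fit_signature(trials)
print(f"decoder vs planted axis: {abs(model.decoder @ truth.spatial_pattern):.3f}")
print(f"condition variance fraction: {model.variance_explained['condition']:.3f}")

res = bootstrap_decode(trials, B=200, seed=1)
print(f"out-of-sample accuracy: {res.mean_accuracy:.3f}")

stats = parcel_inference(trials, B=200, seed=1)
print(f"parcels at BH q<0.05: {(stats.p_adj < 0.05).sum()}")

table = similarity_table(trials, model)
link = trial_level_test(table, scope="all")
beh = condition_contrast(trials)
print(f"similarity, less- vs more-negative trials: t = {link.t:.2f}")
print(f"behavioral contrast (support - self): t = {beh.t:.2f}")
```

Output:

```
decoder vs planted axis: 0.997
condition variance fraction: 0.805
out-of-sample accuracy: 0.998
parcels at BH q<0.05: 21
similarity, less- vs more-negative trials: t = 15.91
behavioral contrast (support - self): t = -12.38
```

The decoder recovers the planted 20-parcel pattern almost exactly, decoding
is at ceiling at the default planted signal-to-noise ratio, parcel inference
finds essentially the planted support set, and both behavioral couplings come
out with the planted signs (support trials rated less negative; trials with
higher signature similarity followed by better outcomes).

## Command line

Each stage is also a deterministic CLI step (same seed ⇒ byte-identical
outputs):

```bash
dpcsig simulate --config cfg.yaml --out ds/ --seed 1 --voxel-session
dpcsig extract  --img ds/func.nii --atlas ds/atlas.nii \
                --confounds ds/confounds.tsv --events ds/events.tsv --out ext/
dpcsig fit-dpca --trials ds/ --out model/
dpcsig decode   --trials ds/ --B 1000 --seed 1 --out decode.json
dpcsig parcels  --trials ds/ --B 1000 --seed 1 --out parcels.tsv
dpcsig link     --trials ds/ --model model/ --out link/
```

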
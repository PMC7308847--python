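# rankflat

Retrospective flat-field shading correction for brightfield whole-slide
imaging (WSI), using per-pixel rank statistics instead of smoothness
priors — so it corrects fixed-pattern sensor noise along with the
illumination vignette.

## The problem

A whole-slide scanner acquires hundreds of tiles at different stage
positions and stitches them into one image. Each tile is distorted by the
same spatially varying gain — uneven Köhler illumination plus static
per-pixel sensor-gain nonuniformity ("fixed-pattern noise") — which
produces dark plaid seams in the stitched result. Under the standard
linear image-formation model,

```
Y_i(k) = X_i(k) · F(k) + D(k),        D(k) ≈ 0
```

where `Y_i` is tile *i*, `X_i` its true content, `F` the flat field and
`D` the dark field, correction is the division `X̂_i(k) = Y_i(k) / F̂(k)`.
The whole task is estimating `F̂` from the tiles themselves, with no
reference images of an empty slide.

## The method

Brightfield background pixels (no cell blocking the light) are brighter
than object pixels, so at each pixel the upper order statistics of the
stack sample `F` directly:

1. **Candidates.** For every pixel and channel independently, sort the
   `n` intensities in descending order. The rank-`r` *candidate image*
   holds the r-th largest value at each pixel; rank 1 is the per-pixel
   maximum.
2. **Selection.** Rank 1 would be ideal, but bright artifacts (dust,
   bubbles) in a few tiles contaminate the top ranks. For each candidate
   compute the smoothness

   `S_r = Σ_k σ_r(k) / μ_r(k)`

   the image-wide sum of the local coefficient of variation (LCoV) over a
   5×5 sliding window. Per channel, select the rank `r*` minimizing
   `S_r`; ties break toward the brighter rank.

No smoothing is ever applied to the winner: the per-pixel gain pattern
survives in `F̂` and is removed by the division — the property that
distinguishes this estimator from smoothness-regularized methods.

Evaluation follows the correction score

`Γ = Σ_i |X̂_i − X_i^true| / Σ_i |Y_i − X_i^true|`

(0 = perfect, 1 = no better than uncorrected) and PSNR, with ground truth
from the *empty-zero* reference (per-pixel average of empty-slide tiles).
A synthetic generator (`rankflat.synth`) produces collections with known
`F` — vignette × per-pixel gain, cell-like objects, dust/bubble
artifacts, acquisition noise — so everything is testable end to end.

## Worked example

```python
import numpy as np
import rankflat as rf

cfg = rf.SynthConfig(height=64, width=64, n_tiles=30, seed=1)
observed, content, truth = rf.make_collection(cfg)

result = rf.RankedFlatField(observed, window=5).fit()
print(result.summary())

corrected = result.correct(observed)
gt = rf.intensity_ground_truth(content, truth)
print(f"gamma = {rf.correction_score(corrected, observed, gt):.3f}")
print(f"psnr  = {rf.psnr(corrected, gt):.2f} dB")
```

prints

```
Rank-statistics flat-field model
========================================
field shape:      64 x 64 x 3
field mean:       166.498, 165.426, 165.923
field min/max:    132.977 / 208.381
selected rank:    9, 15, 12
LCoV window:      5 x 5
epsilon:          0.000255
min smoothness S: 97.7917, 98.4211, 100.3536
gamma = 0.092
psnr  = 44.34 dB
```

The selected ranks sit well below the contaminated brightest candidates;
Γ = 0.092 means the corrected tiles carry ~9% of the uncorrected error,
and the estimated field correlates with the true vignette-times-gain
field at Pearson r = 0.9993.

## Command line

```
rankflat simulate --output sim/ --n-tiles 100 --size 256 --seed 17
rankflat estimate --input sim/tiles --output flatfield.tif --window 5 --profile-csv profile.csv
rankflat correct  --input sim/tiles --output corrected/ --flatfield flatfield.tif
rankflat evaluate --input sim/tiles --corrected corrected/ --empty sim/empty \
                  --report report.json --convergence 5,10,20,30,50,100 --repeats 5 --seed 17
```

Exit codes: 0 success, 1 named data error (dimension, insufficient-stack,
degenerate-field, undefined-score), 2 usage error. YAML config files
(`--config`) supply defaults that explicit flags override.

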
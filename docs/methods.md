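# Methods

## Model and assumptions

The package corrects multiplicative shading in brightfield WSI tile
stacks under the linear image-formation model `Y_i = X_i · F + D` with
the dark field `D` assumed zero (it is nearly uniform and only a few
intensity counts on typical cameras; an optional user-supplied dark frame
can still be subtracted, clamped at zero, before estimation). The flat
field `F` bundles everything multiplicative and static: the smooth
illumination vignette *and* the per-pixel sensor-gain pattern
(fixed-pattern noise).

Two assumptions make the rank estimator work:

1. **Background brightness.** Background pixels transmit the full
   illumination; object (cell) pixels attenuate it. Hence at any pixel,
   tiles in which that pixel is background contribute the largest
   intensities, and those intensities equal `F(k)` up to acquisition
   noise.
2. **Background majority.** Each pixel is background in enough tiles
   that some upper order statistic is artifact- and object-free. With
   typical tissue coverage (< 50% per pixel across the stack) this holds
   with large margin for `n = 100` tiles.

The estimator deliberately applies **no smoothing** to the selected
field. A smoothness prior would regress the per-pixel gain toward its
neighbourhood mean and the gain pattern would then survive in the
corrected tiles. The acceptance suite demonstrates the cost directly: a
5×5 mean-filtered copy of the estimate always agrees less well with the
true field than the raw estimate.

## Algorithm

1. `build_candidates`: per pixel and channel, sort the `n` stack values
   descending (`numpy` sort along the tile axis). Rank 1 = per-pixel
   maximum. Channels are sorted independently; a candidate need not
   coincide with any single tile.
2. `select_flat_field`: for each channel and each searched rank, compute
   `S_r = Σ_k σ_r(k)/(μ_r(k)+ε)` with window statistics from
   `scipy.ndimage.uniform_filter`; select `argmin_r S_r` per channel,
   first minimum (smaller, brighter rank) on ties; assemble the selected
   channels into one RGB field.
3. `apply_correction`: `X̂_i = (Y_i − D)/F̂`, optionally rescaled per
   channel by `mean(F̂)`.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `window` | 5 | LCoV sliding-window side (pixels, odd). 5×5 is small enough to respond to single-pixel artifacts and large enough for a stable σ/μ. |
| `epsilon` | `1e-6 · bit_depth_max` | added to μ in the LCoV denominator. Candidate pixels can be exactly 0 in pathological stacks; the guard keeps the score finite while being ~5 orders below any real background level. Set `epsilon=0` to obtain exact scale invariance of `S`. |
| `search_ranks` | all `n` | optional restriction of the ranks scored (e.g. the top third) for speed on very large stacks; selection within the restricted set is unchanged. |
| `scale_mode` | `preserve_mean` | literal division (`raw`) lives on a transmittance scale near 1; `preserve_mean` multiplies back by the spatial mean of `F̂` per channel so corrected tiles stay in the input intensity range. |

## Numerical choices

- **Window statistics** use the population standard deviation (divide by
  the window area) and edge-duplicating reflect padding
  (`a b c → a | a b c | c`), so `S` sums over all `H×W` pixels including
  borders. Variance is computed on a globally centred image
  (`E[(x−x̄)²] − (E[x−x̄])²`) to avoid catastrophic cancellation for
  bright, low-contrast candidates; the batched implementation agrees with
  a per-pixel double-loop oracle to ~1e-15 relative.
- **Tie-breaking**: equal `S` selects the smaller rank (brighter
  candidate, closer to the background-maximum ideal). A stack of
  identical tiles therefore selects rank 1 and returns the tile itself.
- **Global minimum** of `S` over the searched ranks is selected, not the
  first local minimum: the selection criterion is "fewest artifacts",
  and on all collections we generate the profile is unimodal, making the
  two rules coincide.
- **Degenerate inputs**: a selected field with any nonpositive pixel
  raises a degenerate-field error (division undefined); a stack with
  fewer than two tiles raises insufficient-stack; Γ with a zero
  denominator (input already equals truth) raises undefined-score.
- **Scale alignment for Γ/PSNR**: corrected stacks are compared in
  `preserve_mean` scale, and the ground-truth stack is defined the same
  way (tile divided by the reference field, rescaled by that field's
  mean), so both operands share one convention. Γ is the single global
  ratio of summed absolute errors, not a per-tile average; per-tile
  ratios are exposed only as a diagnostic. PSNR uses `bit_depth_max` as
  the peak, not the observed maximum, and reports `inf` at zero MSE.
- **Reproducibility**: the convergence experiment derives the subset for
  size `m`, repeat `r` from `SeedSequence(seed, spawn_key=(m, r))`, so
  tables are bit-identical across runs and machines.

## Synthetic generator

`make_collection` realizes the forward model `Y_i = X_i · F · (1+η_i)`:

- `F` = `background_level` (200 of 255) × radial cosine-squared vignette
  (corner/centre ratio exactly `1 − vignette_strength`, default 0.3) ×
  i.i.d. per-pixel Gamma gain with mean 1 and sd `fixed_pattern_sd`
  (default 0.02; Gamma keeps the gain strictly positive). Gain is drawn
  once per field — static across tiles — while `η_i` (relative sd
  `photon_noise_sd`, default 0.01) is drawn per tile; that separation is
  precisely what makes fixed-pattern noise recoverable by rank statistics
  and temporal noise not.
- `X_i` = unit background with a Poisson number (mean `object_density`,
  default 20) of randomly oriented ellipses (semi-axes 3–8% of the image
  side) multiplied by `object_attenuation` (0.55), giving ≈20% object
  coverage per tile.
- Exactly `⌈artifact_rate · n⌉` tiles (default rate 0.1) carry one
  artifact — a bright bubble ring (×1.3) or a dark dust speck (×0.3),
  equiprobable — stamped into the content *before* multiplication by `F`,
  so bright artifacts surface in the high-rank candidates as they do in
  real acquisitions.
- `make_empty_collection` produces empty-slide tiles (`X = 1`) for the
  empty-zero reference.

What the generator does **not** emulate: realistic histology texture,
tile-overlap geometry, chromatic aberration, defocus variation, Poisson
(signal-dependent) shot noise, or saturation. Passing tests therefore
demonstrate correctness of the algorithmic pipeline under the model's own
assumptions, not performance on any particular scanner's data.

## Problem sizes

The default study condition is 100 tiles of 256×256 RGB. The convergence
experiment (subset sizes 5–100, five repeats each) completes in about a
minute on one CPU; unit and property tests use 16–64 pixel tiles, where
the brute-force oracles remain exact and fast. The empty-zero
Monte-Carlo check bounds the mean relative error of a 50-tile average by
`noise_sd/√50` and the maximum by five such standard errors — a bound at
matched confidence for the few thousand pixels tested (a 3σ max bound
would be exceeded with near certainty at that pixel count).

## Known limitations

- Pixels that are never background in any tile (dense tissue everywhere)
  make every candidate an object sample there; the method then
  underestimates `F` locally. The background-majority test documents the
  regime in which this cannot happen.
- Darkfield and fluorescence imaging invert the background-brightest
  assumption; the estimator does not apply.
- The selected field inherits one acquisition's noise realization at
  each pixel (no averaging), bounding field accuracy at roughly the
  per-acquisition noise level — the price of preserving fixed-pattern
  detail.
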
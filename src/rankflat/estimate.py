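"""Flat-field estimation from a tile stack by per-pixel rank statistics.

The method exploits a property of brightfield acquisition: background
pixels, where no cell blocks the illumination, are brighter than object
pixels, so at every pixel the upper order statistics of the stack sample
the flat field itself (illumination shading times per-pixel sensor gain).

Step 1 builds *candidates*: for each pixel and channel independently, the
intensities across the stack are sorted in descending order; rank ``r``
collects the r-th largest value at every pixel.  Rank 1 — the per-pixel
maximum — would be the ideal flat field, except that bright artifacts
(dust, bubbles) present in a few tiles contaminate the top ranks.

Step 2 selects, per channel, the candidate whose image-wide sum of the
local coefficient of variation (LCoV, sigma/mu over a sliding window) is
smallest.  Artifacts raise the LCoV sum; the smoothest candidate is the
brightest one free of them.  No smoothing is applied to the winner, so the
static per-pixel gain pattern (fixed-pattern noise) survives in the
estimate and is removed by the subsequent division.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
from scipy.ndimage import uniform_filter

from .core import (
    FlatFieldCandidates,
    FlatFieldModel,
    ParameterError,
    SmoothnessProfile,
    TileStack,
)

__all__ = [
    "build_candidates",
    "local_coefficient_of_variation",
    "smoothness_score",
    "select_flat_field",
    "estimate_flat_field",
    "default_epsilon",
    "RankedFlatField",
]

#: relative guard added to the LCoV denominator, in units of bit_depth_max
EPSILON_REL = 1e-6


def default_epsilon(bit_depth_max: float) -> float:
    """Denominator guard for the LCoV: 1e-6 of the representable maximum."""
    return EPSILON_REL * float(bit_depth_max)


def _check_window(window: int) -> int:
    window = int(window)
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"window must be a positive odd integer, got {window}")
    return window


def build_candidates(stack: TileStack) -> FlatFieldCandidates:
    """Sort the stack per pixel and channel into descending rank images.

    Channels are sorted independently, so a given rank image need not
    correspond to any single input tile.
    """
    stack.require_pairable()
    ranks = np.sort(stack.data, axis=0)[::-1].copy()
    return FlatFieldCandidates(ranks, bit_depth_max=stack.bit_depth_max)


def local_coefficient_of_variation(
    image: np.ndarray, window: int = 5, epsilon: float = 0.0
) -> np.ndarray:
    """Per-pixel sigma/(mu + epsilon) over a window x window neighbourhood.

    Statistics use the population standard deviation and edge-duplicating
    reflect padding at the borders (``a b c -> a | a b c | c``), so every
    pixel of the input gets a value.  Pixels whose
    window is identically zero (mu = sigma = 0) map to 0 when epsilon = 0.
    """
    window = _check_window(window)
    if epsilon < 0:
        raise ParameterError(f"epsilon must be >= 0, got {epsilon}")
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ParameterError(f"expected a single-channel H×W image, got {image.shape}")
    # centring before the moment filters avoids catastrophic cancellation in
    # E[x^2] - E[x]^2 for bright, low-contrast candidates
    shift = image.mean()
    centred = image - shift
    mu_c = uniform_filter(centred, size=window, mode="reflect")
    var = uniform_filter(centred * centred, size=window, mode="reflect") - mu_c**2
    sigma = np.sqrt(np.clip(var, 0.0, None))
    denom = mu_c + shift + epsilon
    out = np.zeros_like(image)
    np.divide(sigma, denom, out=out, where=denom != 0)
    return out


def _smoothness_batch(images: np.ndarray, window: int, epsilon: float) -> np.ndarray:
    """S for a batch of single-channel images (R, H, W) in one filter pass.

    Equivalent to mapping :func:`smoothness_score` over the batch; the
    window never mixes batch members (filter size 1 along the batch axis).
    """
    shift = images.mean()
    centred = images - shift
    size = (1, window, window)
    mu_c = uniform_filter(centred, size=size, mode="reflect")
    var = uniform_filter(centred * centred, size=size, mode="reflect") - mu_c**2
    sigma = np.sqrt(np.clip(var, 0.0, None))
    denom = mu_c + shift + epsilon
    out = np.zeros_like(images)
    np.divide(sigma, denom, out=out, where=denom != 0)
    return out.sum(axis=(1, 2))


def smoothness_score(
    candidate_channel: np.ndarray, window: int = 5, epsilon: float = 0.0
) -> float:
    """Image-wide smoothness S: the sum of the LCoV over all pixels.

    S = 0 for a constant image and, at epsilon = 0, is invariant to scaling
    the image by any positive factor.  Rough candidates (artifact edges,
    object remnants) score higher.
    """
    return float(
        local_coefficient_of_variation(candidate_channel, window, epsilon).sum()
    )


def select_flat_field(
    candidates: FlatFieldCandidates,
    window: int = 5,
    epsilon: Optional[float] = None,
    search_ranks: Optional[Iterable[int]] = None,
) -> FlatFieldModel:
    """Pick, per channel, the candidate rank with minimum smoothness S.

    Ties break toward the smaller rank (the brighter candidate, closer to
    the background-maximum ideal).  ``search_ranks`` restricts the ranks
    examined; unsearched ranks appear as NaN in the stored profile.
    """
    window = _check_window(window)
    if epsilon is None:
        epsilon = default_epsilon(candidates.bit_depth_max)
    n, _, _, n_ch = candidates.ranks.shape
    if search_ranks is None:
        searched = list(range(1, n + 1))
    else:
        searched = sorted(set(int(r) for r in search_ranks))
        if not searched:
            raise ParameterError("search_ranks must be nonempty")
        if searched[0] < 1 or searched[-1] > n:
            raise ParameterError(f"search_ranks must lie in [1, {n}], got {searched}")

    scores = np.full((n_ch, n), np.nan)
    idx = np.array(searched) - 1
    for c in range(n_ch):
        scores[c, idx] = _smoothness_batch(
            candidates.ranks[idx, :, :, c], window, epsilon
        )

    selected = []
    field = np.empty(candidates.ranks.shape[1:], dtype=np.float64)
    for c in range(n_ch):
        vals = [scores[c, r - 1] for r in searched]
        r_star = searched[int(np.argmin(vals))]  # argmin is first min: smaller rank
        selected.append(r_star)
        field[:, :, c] = candidates.ranks[r_star - 1, :, :, c]

    profile = SmoothnessProfile(scores, window=window, epsilon=float(epsilon))
    return FlatFieldModel(
        field,
        selected_rank=tuple(selected),
        smoothness=profile,
        bit_depth_max=candidates.bit_depth_max,
    )


def estimate_flat_field(
    stack: TileStack,
    window: int = 5,
    epsilon: Optional[float] = None,
    search_ranks: Optional[Iterable[int]] = None,
    dark_frame: Optional[np.ndarray] = None,
) -> FlatFieldModel:
    """One-call entry point: build candidates, then select the smoothest.

    Parameters
    ----------
    stack
        The input tiles (>= 2, same shape).
    window
        Side of the square LCoV sliding window; odd, default 5.
    epsilon
        LCoV denominator guard; default ``1e-6 * bit_depth_max``.
    search_ranks
        Optional subset of ranks to examine (1-based; 1 = brightest).
    dark_frame
        Optional dark-field image subtracted from every tile (clamped at
        zero) before estimation.  The method itself assumes a zero dark
        field.
    """
    if dark_frame is not None:
        dark = np.asarray(dark_frame, dtype=np.float64)
        if dark.ndim == 2:
            dark = dark[:, :, None]
        if dark.shape != stack.tile_shape:
            raise ParameterError(
                f"dark frame shape {dark.shape} differs from tile shape "
                f"{stack.tile_shape}"
            )
        stack = stack.copy_with(np.clip(stack.data - dark, 0.0, None))
    candidates = build_candidates(stack)
    return select_flat_field(
        candidates, window=window, epsilon=epsilon, search_ranks=search_ranks
    )


class RankedFlatField:
    """Model-style front end: a flat-field estimator bound to one stack.

    Mirrors the fit/results idiom of statistical modelling packages::

        model = RankedFlatField(stack, window=5)
        result = model.fit()          # a FlatFieldModel
        print(result.summary())
        corrected = result.correct(stack)

    Parameters
    ----------
    stack : TileStack
        Tiles to estimate from.
    window : int
        LCoV window side (odd), default 5.
    epsilon : float, optional
        LCoV denominator guard; default ``1e-6 * bit_depth_max``.
    dark_frame : ndarray, optional
        Dark field subtracted (clamped at 0) before estimation.
    """

    def __init__(
        self,
        stack: TileStack,
        window: int = 5,
        epsilon: Optional[float] = None,
        dark_frame: Optional[np.ndarray] = None,
    ):
        stack.require_pairable()
        self.stack = stack
        self.window = _check_window(window)
        self.epsilon = (
            default_epsilon(stack.bit_depth_max) if epsilon is None else float(epsilon)
        )
        self.dark_frame = dark_frame

    def fit(self, search_ranks: Optional[Iterable[int]] = None) -> FlatFieldModel:
        """Estimate the flat field; returns the results object."""
        return estimate_flat_field(
            self.stack,
            window=self.window,
            epsilon=self.epsilon,
            search_ranks=search_ranks,
            dark_frame=self.dark_frame,
        )
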
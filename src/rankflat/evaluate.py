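"""Quantitative evaluation: correction score, PSNR, empty-zero reference.

The correction score Γ compares a corrected stack with an uncorrected one,
both against ground truth, as a single ratio of summed absolute errors:

    Γ = Σ_i |X̂_i − X_i^true| / Σ_i |Y_i − X_i^true|

summed over all pixels, channels and tiles.  Γ = 0 means perfect
correction, Γ = 1 the same error as doing nothing, Γ > 1 a degradation.

Ground truth is built prospectively by the empty-zero method: the flat
field of an empty slide imaged at several stage positions is its per-pixel
average, and the true content of a tile is the tile divided by that field
(rescaled to the intensity range by the field's mean so that operands of Γ
and PSNR share one scale).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    DegenerateFieldError,
    DimensionError,
    EvaluationReport,
    FlatFieldModel,
    InsufficientStackError,
    ParameterError,
    TileStack,
    UndefinedScoreError,
)
from .correct import apply_correction
from .estimate import estimate_flat_field

__all__ = [
    "empty_zero_reference",
    "ground_truth_stack",
    "correction_score",
    "psnr",
    "evaluate_correction",
    "score_convergence",
]


def empty_zero_reference(empty_stack: TileStack) -> FlatFieldModel:
    """Flat field as the per-pixel average of empty-slide tiles.

    This is the prospective reference estimator used to construct ground
    truth; it needs images of an *empty* slide, which the retrospective
    method deliberately avoids.
    """
    if empty_stack.n < 1:
        raise InsufficientStackError("empty-slide stack holds no tiles")
    field = empty_stack.data.mean(axis=0)
    if not np.all(field > 0):
        raise DegenerateFieldError("empty-slide average contains nonpositive pixels")
    return FlatFieldModel(
        field, selected_rank=None, smoothness=None,
        bit_depth_max=empty_stack.bit_depth_max,
    )


def ground_truth_stack(stack: TileStack, reference: FlatFieldModel) -> TileStack:
    """Ground-truth content of ``stack`` under a reference flat field.

    Divides every tile by the reference field and rescales per channel by
    the field's spatial mean, matching the ``preserve_mean`` convention of
    the correction step so Γ and PSNR compare commensurate intensities.
    """
    return apply_correction(stack, reference, scale_mode="preserve_mean")


def _check_same_shape(*stacks: TileStack) -> None:
    shapes = {s.data.shape for s in stacks}
    if len(shapes) != 1:
        raise DimensionError(f"stacks have differing shapes: {sorted(shapes)}")


def correction_score(
    corrected: TileStack,
    uncorrected: TileStack,
    ground_truth: TileStack,
    per_tile: bool = False,
):
    """Correction score Γ of a corrected stack (lower is better).

    All three stacks must share shape and tile count and be expressed on a
    common intensity scale.  With ``per_tile=True`` also returns the vector
    of per-tile ratios (a diagnostic; Γ itself is the single global ratio).
    """
    _check_same_shape(corrected, uncorrected, ground_truth)
    err_corr = np.abs(corrected.data - ground_truth.data)
    err_raw = np.abs(uncorrected.data - ground_truth.data)
    denom = err_raw.sum()
    if denom == 0:
        raise UndefinedScoreError(
            "uncorrected stack equals ground truth; score undefined"
        )
    gamma = float(err_corr.sum() / denom)
    if not per_tile:
        return gamma
    tile_denom = err_raw.sum(axis=(1, 2, 3))
    with np.errstate(divide="ignore", invalid="ignore"):
        per = err_corr.sum(axis=(1, 2, 3)) / tile_denom
    return gamma, per


def psnr(
    corrected: TileStack, ground_truth: TileStack, max_value: Optional[float] = None
) -> float:
    """Peak signal-to-noise ratio in dB over the whole stack.

    ``max_value`` defaults to the stack's ``bit_depth_max`` (the standard
    convention for 8-bit imagery), not the observed maximum.  Identical
    stacks return ``inf``.
    """
    _check_same_shape(corrected, ground_truth)
    if max_value is None:
        max_value = ground_truth.bit_depth_max
    if max_value <= 0:
        raise ParameterError(f"max_value must be > 0, got {max_value}")
    mse = float(np.mean((corrected.data - ground_truth.data) ** 2))
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(max_value**2 / mse))


def evaluate_correction(
    corrected: TileStack,
    uncorrected: TileStack,
    ground_truth: TileStack,
    max_value: Optional[float] = None,
) -> EvaluationReport:
    """Bundle Γ (with per-tile diagnostics) and PSNR into one report."""
    gamma, per = correction_score(corrected, uncorrected, ground_truth, per_tile=True)
    return EvaluationReport(
        gamma=gamma,
        psnr_db=psnr(corrected, ground_truth, max_value=max_value),
        per_tile_gamma=per,
    )


def score_convergence(
    stack: TileStack,
    ground_truth: TileStack,
    subset_sizes: Sequence[int],
    repeats: int = 5,
    seed: int = 0,
    window: int = 5,
    epsilon: Optional[float] = None,
) -> pd.DataFrame:
    """Correction score versus the number of tiles used for estimation.

    For each subset size ``m``, draws ``repeats`` random m-subsets of the
    stack (without replacement), estimates the flat field on each subset,
    corrects the *full* stack in ``preserve_mean`` mode and computes Γ
    against ``ground_truth``.  Returns a table with columns
    ``m, gamma_mean, gamma_sd`` (population sd across repeats).

    Randomness is reproducible: the subset for size ``m``, repeat ``r``
    comes from ``numpy.random.SeedSequence(seed, spawn_key=(m, r))``.
    """
    _check_same_shape(stack, ground_truth)
    if repeats < 1:
        raise ParameterError(f"repeats must be >= 1, got {repeats}")
    n = stack.n
    rows = []
    for m in subset_sizes:
        m = int(m)
        if m < 2:
            raise InsufficientStackError(f"subset size {m} < 2")
        if m > n:
            raise ParameterError(f"subset size {m} exceeds stack size {n}")
        gammas = []
        for r in range(repeats):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=int(seed), spawn_key=(m, r))
            )
            idx = rng.choice(n, size=m, replace=False)
            sub = stack.copy_with(stack.data[np.sort(idx)])
            model = estimate_flat_field(sub, window=window, epsilon=epsilon)
            corrected = apply_correction(stack, model, scale_mode="preserve_mean")
            gammas.append(correction_score(corrected, stack, ground_truth))
        gammas = np.asarray(gammas)
        rows.append(
            {"m": m, "gamma_mean": gammas.mean(), "gamma_sd": gammas.std(ddof=0)}
        )
    return pd.DataFrame(rows)
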
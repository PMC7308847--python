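"""Shading correction: divide each tile by the estimated flat field.

Under the linear image-formation model Y_i(k) = X_i(k) * F(k) + D(k) with
D = 0, the corrected tile is X̂_i(k) = Y_i(k) / F̂(k).  Taken literally the
quotient lives on a transmittance-like scale near 1 (F̂ is in intensity
units), so the default ``preserve_mean`` mode rescales each channel by the
spatial mean of F̂, restoring the original intensity range.  Values are
never clipped in memory; clipping to the integer range happens only when
tiles are written.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .core import (
    DegenerateFieldError,
    DimensionError,
    FlatFieldModel,
    ParameterError,
    TileStack,
    load_stack,
    save_flat_field,
    write_stack,
)
from .estimate import estimate_flat_field

__all__ = ["apply_correction", "correct_collection"]

log = logging.getLogger(__name__)

_SCALE_MODES = ("raw", "preserve_mean")


def apply_correction(
    stack: TileStack, model: FlatFieldModel, scale_mode: str = "preserve_mean"
) -> TileStack:
    """Correct every tile of ``stack`` with ``model``'s flat field.

    ``raw`` mode returns (Y - D) / F̂ exactly; ``preserve_mean`` multiplies
    the quotient per channel by mean(F̂), keeping the original intensity
    scale.  Dark-field subtraction is clamped at zero before division.
    """
    if scale_mode not in _SCALE_MODES:
        raise ParameterError(f"scale_mode must be one of {_SCALE_MODES}")
    if model.field.shape != stack.tile_shape:
        raise DimensionError(
            f"field shape {model.field.shape} differs from tile shape "
            f"{stack.tile_shape}"
        )
    if not np.all(model.field > 0):
        raise DegenerateFieldError("field contains nonpositive pixels")
    numer = stack.data
    if np.any(model.dark_field != 0):
        numer = np.clip(numer - model.dark_field, 0.0, None)
    corrected = numer / model.field
    if scale_mode == "preserve_mean":
        corrected = corrected * model.field.mean(axis=(0, 1))
    return stack.copy_with(corrected)


def correct_collection(
    input_paths: Union[str, Path, Sequence[Union[str, Path]]],
    output_dir: Union[str, Path],
    model: Optional[FlatFieldModel] = None,
    window: int = 5,
    epsilon: Optional[float] = None,
    scale_mode: str = "preserve_mean",
    suffix: str = "_corrected",
    float_output: bool = False,
):
    """Load a collection, correct it, and write one file per input tile.

    When no model is given the flat field is first estimated from the very
    stack being corrected (the retrospective usage).  The model used is
    persisted as ``model/flatfield.tif`` (with a JSON sidecar) under the
    output directory, kept out of the corrected-tile listing.  Returns
    ``(corrected_stack, model, written_paths)``.
    """
    stack = load_stack(input_paths)
    if model is None:
        log.info("no flat-field model given; estimating from the input stack")
        model = estimate_flat_field(stack, window=window, epsilon=epsilon)
    corrected = apply_correction(stack, model, scale_mode=scale_mode)
    out_dir = Path(output_dir)
    dtype = np.float32 if float_output else None
    paths = write_stack(corrected, out_dir, suffix=suffix, dtype=dtype)
    save_flat_field(model, out_dir / "model" / "flatfield.tif")
    return corrected, model, paths
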
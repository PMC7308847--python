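"""Synthetic brightfield tile collections with known ground truth.

The generator realises the image-formation model forward: a true flat
field F (smooth radial vignette times a static per-pixel gain) multiplies
a content image X_i of unit background carrying darker cell-like ellipses,
with optional per-acquisition multiplicative noise:

    Y_i = X_i * F * (1 + noise_i),   D = 0.

A minority of tiles additionally carry an artifact — a bright ring
(bubble) or a dark speck (dust) — stamped into the content before
multiplication by F, so artifacts contaminate the high-rank candidates
exactly as they do in real acquisitions.  The static gain is drawn once
per field while the noise is drawn per tile: that separation is what makes
fixed-pattern noise recoverable by rank statistics and temporal noise not.

Every random draw is governed by ``SynthConfig.seed`` through independent
substreams, so collections are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from skimage.draw import disk, ellipse

from .core import FlatFieldModel, ParameterError, TileStack

__all__ = [
    "SynthConfig",
    "make_flat_field",
    "make_collection",
    "make_empty_collection",
    "intensity_ground_truth",
]

#: multiplicative factor of the bright bubble ring
BUBBLE_GAIN = 1.3
#: multiplicative factor of the dark dust speck
DUST_GAIN = 0.3


@dataclass
class SynthConfig:
    """Parameters of a synthetic tile collection.

    Defaults describe a typical brightfield acquisition: bright background
    (200 of 255), 30% corner vignetting, 2% static per-pixel gain spread,
    about 20% of each tile covered by cells that transmit 55% of the
    light, one tile in ten carrying a dust/bubble artifact, and 1%
    per-acquisition noise.
    """

    height: int = 256
    width: int = 256
    n_tiles: int = 100
    channels: int = 3
    background_level: float = 200.0
    vignette_strength: float = 0.3
    fixed_pattern_sd: float = 0.02
    object_density: float = 20.0
    object_attenuation: float = 0.55
    artifact_rate: float = 0.1
    photon_noise_sd: float = 0.01
    bit_depth_max: float = 255.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.channels not in (1, 3):
            raise ParameterError(f"channels must be 1 or 3, got {self.channels}")
        if self.n_tiles < 1 or self.height < 1 or self.width < 1:
            raise ParameterError("height, width and n_tiles must be positive")
        if not 0.0 <= self.vignette_strength < 1.0:
            raise ParameterError("vignette_strength must lie in [0, 1)")
        if not 0.0 < self.object_attenuation <= 1.0:
            raise ParameterError("object_attenuation must lie in (0, 1]")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ParameterError("artifact_rate must lie in [0, 1]")
        for name in ("fixed_pattern_sd", "photon_noise_sd", "object_density"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.background_level * (1.0 - self.vignette_strength) <= 0:
            raise ParameterError("background must stay positive under the vignette")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one named substream of the seed."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=int(self.seed), spawn_key=(stream,))
        )


_FIELD_STREAM, _CONTENT_STREAM, _NOISE_STREAM, _EMPTY_STREAM = 0, 1, 2, 3


def _vignette(config: SynthConfig) -> np.ndarray:
    """Radial cosine-squared falloff: 1 at centre, 1 - strength at corners."""
    h, w, s = config.height, config.width, config.vignette_strength
    y = np.arange(h)[:, None] - (h - 1) / 2.0
    x = np.arange(w)[None, :] - (w - 1) / 2.0
    r = np.hypot(y, x)
    r_max = np.hypot((h - 1) / 2.0, (w - 1) / 2.0)
    if r_max == 0:
        return np.ones((h, w))
    return (1.0 - s) + s * np.cos(0.5 * np.pi * r / r_max) ** 2


def make_flat_field(config: SynthConfig) -> FlatFieldModel:
    """Ground-truth flat field: background x vignette x per-pixel gain.

    The gain is i.i.d. per pixel and channel from a Gamma distribution
    with mean 1 and sd ``fixed_pattern_sd`` (positive by construction),
    frozen by the config seed; it models static sensor-gain nonuniformity.
    """
    rng = config.rng(_FIELD_STREAM)
    vignette = _vignette(config)[:, :, None]
    shape = (config.height, config.width, config.channels)
    if config.fixed_pattern_sd > 0:
        k = 1.0 / config.fixed_pattern_sd**2
        gain = rng.gamma(shape=k, scale=1.0 / k, size=shape)
    else:
        gain = np.ones(shape)
    field = config.background_level * vignette * gain
    return FlatFieldModel(field, bit_depth_max=config.bit_depth_max)


def _stamp_objects(content: np.ndarray, config: SynthConfig, rng) -> None:
    """Multiply random ellipses (cells) into one tile's content, in place."""
    h, w = config.height, config.width
    scale = min(h, w)
    n_obj = rng.poisson(config.object_density)
    for _ in range(n_obj):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        ry, rx = rng.uniform(0.03, 0.08, size=2) * scale
        theta = rng.uniform(0, np.pi)
        rr, cc = ellipse(cy, cx, max(ry, 1.0), max(rx, 1.0),
                         shape=(h, w), rotation=theta)
        content[rr, cc, :] *= config.object_attenuation


def _stamp_artifact(content: np.ndarray, config: SynthConfig, rng) -> None:
    """Stamp one bubble ring (bright) or dust speck (dark) into a tile."""
    h, w = config.height, config.width
    scale = min(h, w)
    cy, cx = rng.uniform(0, h), rng.uniform(0, w)
    if rng.random() < 0.5:  # bubble: bright ring
        r_out = rng.uniform(0.10, 0.25) * scale
        r_in = max(r_out - max(0.02 * scale, 1.0), 0.0)
        rr_o, cc_o = disk((cy, cx), max(r_out, 1.0), shape=(h, w))
        mask = np.zeros((h, w), dtype=bool)
        mask[rr_o, cc_o] = True
        if r_in > 0:
            rr_i, cc_i = disk((cy, cx), r_in, shape=(h, w))
            mask[rr_i, cc_i] = False
        content[mask, :] *= BUBBLE_GAIN
    else:  # dust: dark speck
        r = max(rng.uniform(0.01, 0.03) * scale, 1.0)
        rr, cc = disk((cy, cx), r, shape=(h, w))
        content[rr, cc, :] *= DUST_GAIN


def make_collection(
    config: SynthConfig,
) -> Tuple[TileStack, TileStack, FlatFieldModel]:
    """Generate ``(observed, content, truth_field)`` for one collection.

    ``observed`` holds Y_i = X_i * F * (1 + noise); ``content`` holds the
    unit-background X_i; ``truth_field`` holds F.  Exactly
    ``ceil(artifact_rate * n_tiles)`` tiles carry an artifact.
    """
    truth = make_flat_field(config)
    rng = config.rng(_CONTENT_STREAM)
    n, h, w, c = config.n_tiles, config.height, config.width, config.channels
    content = np.ones((n, h, w, c), dtype=np.float64)
    for i in range(n):
        _stamp_objects(content[i], config, rng)
    n_art = int(np.ceil(config.artifact_rate * n)) if config.artifact_rate > 0 else 0
    if n_art > 0:
        for i in rng.choice(n, size=n_art, replace=False):
            _stamp_artifact(content[i], config, rng)
    observed = content * truth.field[None]
    if config.photon_noise_sd > 0:
        noise_rng = config.rng(_NOISE_STREAM)
        observed = observed * (
            1.0 + noise_rng.normal(0.0, config.photon_noise_sd, size=observed.shape)
        )
        observed = np.clip(observed, 0.0, None)
    kwargs = dict(bit_depth_max=config.bit_depth_max, source_dtype=np.dtype("uint8"))
    return (
        TileStack(observed, **kwargs),
        TileStack(content, **kwargs),
        truth,
    )


def make_empty_collection(config: SynthConfig, n_tiles: int = 20) -> TileStack:
    """Empty-slide tiles: pure flat field plus per-acquisition noise.

    These emulate the reference images the prospective empty-zero method
    acquires; averaging them recovers F as their count grows.
    """
    truth = make_flat_field(config)
    rng = config.rng(_EMPTY_STREAM)
    shape = (int(n_tiles), config.height, config.width, config.channels)
    tiles = np.broadcast_to(truth.field[None], shape).copy()
    if config.photon_noise_sd > 0:
        tiles = tiles * (1.0 + rng.normal(0.0, config.photon_noise_sd, size=shape))
        tiles = np.clip(tiles, 0.0, None)
    return TileStack(
        tiles, bit_depth_max=config.bit_depth_max, source_dtype=np.dtype("uint8")
    )


def intensity_ground_truth(content: TileStack, truth: FlatFieldModel) -> TileStack:
    """Ground-truth stack on the intensity scale of ``preserve_mean`` output.

    Multiplies the unit-scale content X_i per channel by the spatial mean
    of the true field, making it directly comparable with corrected tiles.
    """
    return content.copy_with(content.data * truth.field.mean(axis=(0, 1)))
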
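"""Domain types, validation and tile I/O shared by all stages.

The central container is :class:`TileStack`, an ordered stack of same-sized
brightfield tiles acquired at different stage positions of one slide.  All
intensities are held as nonnegative ``float64`` so that the division in the
shading-correction step is exact; the native integer dtype is retained as
metadata and re-applied (with clipping) only when tiles are written back to
disk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "RankflatError",
    "DimensionError",
    "InsufficientStackError",
    "DegenerateFieldError",
    "UndefinedScoreError",
    "ParameterError",
    "TileStack",
    "FlatFieldCandidates",
    "SmoothnessProfile",
    "FlatFieldModel",
    "EvaluationReport",
    "load_stack",
    "write_stack",
    "save_flat_field",
    "load_flat_field",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class RankflatError(Exception):
    """Base class for all domain errors raised by this package."""

    #: short machine-readable name used by the CLI
    name = "error"


class DimensionError(RankflatError):
    """Images in a stack (or a stack and a field) do not share one shape."""

    name = "dimension"


class InsufficientStackError(RankflatError):
    """Fewer tiles than the operation requires (estimation needs >= 2)."""

    name = "insufficient-stack"


class DegenerateFieldError(RankflatError):
    """A flat-field estimate contains nonpositive pixels; division undefined."""

    name = "degenerate-field"


class UndefinedScoreError(RankflatError):
    """Correction-score denominator is zero (input already equals truth)."""

    name = "undefined-score"


class ParameterError(RankflatError):
    """An algorithm parameter is out of its admissible range."""

    name = "parameter"


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

_INT_MAXVALS = {
    np.dtype("uint8"): 255.0,
    np.dtype("uint16"): 65535.0,
    np.dtype("int16"): 32767.0,
    np.dtype("uint32"): 4294967295.0,
}


def _infer_bit_depth_max(dtype: np.dtype, data: np.ndarray) -> float:
    dtype = np.dtype(dtype)
    if dtype in _INT_MAXVALS:
        return _INT_MAXVALS[dtype]
    if np.issubdtype(dtype, np.floating):
        # Float sources carry no bit depth; assume unit range unless the
        # values clearly live on an 8-bit-like scale.
        return 1.0 if float(np.max(data, initial=0.0)) <= 1.0 else 255.0
    raise ParameterError(f"unsupported image dtype {dtype!r}")


def _as_hwc(arr: np.ndarray) -> np.ndarray:
    """Coerce one image to (H, W, C) with C in {1, 3} (alpha dropped)."""
    if arr.ndim == 2:
        return arr[:, :, None]
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        if arr.shape[2] in (1, 3):
            return arr
    raise DimensionError(f"cannot interpret image of shape {arr.shape} as H×W or H×W×3")


# ---------------------------------------------------------------------------
# TileStack
# ---------------------------------------------------------------------------

@dataclass
class TileStack:
    """Ordered stack of ``n`` same-shaped tiles, held as (n, H, W, C) floats.

    Parameters
    ----------
    data
        Array of shape ``(n, H, W, C)`` with ``C`` in ``{1, 3}``; converted
        to ``float64`` on construction.
    bit_depth_max
        Maximum representable intensity of the source (255 for 8-bit).
    source_dtype
        Native dtype of the source images, used when writing output.
    """

    data: np.ndarray
    bit_depth_max: float = 255.0
    source_dtype: np.dtype = dc_field(default_factory=lambda: np.dtype("uint8"))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim == 3:  # (n, H, W) grayscale convenience
            self.data = self.data[..., None]
        if self.data.ndim != 4 or self.data.shape[3] not in (1, 3):
            raise DimensionError(
                f"tile stack must have shape (n, H, W, C) with C in {{1,3}}, "
                f"got {self.data.shape}"
            )
        self.source_dtype = np.dtype(self.source_dtype)
        self.bit_depth_max = float(self.bit_depth_max)

    # -- basic geometry ----------------------------------------------------
    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def tile_shape(self) -> tuple:
        return self.data.shape[1:]

    @property
    def channels(self) -> int:
        return self.data.shape[3]

    def __len__(self) -> int:
        return self.n

    def __iter__(self):
        return iter(self.data)

    # -- construction ------------------------------------------------------
    @classmethod
    def from_tiles(
        cls,
        tiles: Sequence[np.ndarray],
        bit_depth_max: Optional[float] = None,
        source_dtype: Optional[np.dtype] = None,
        names: Optional[Sequence[str]] = None,
    ) -> "TileStack":
        """Build a stack from individual images, checking shape agreement."""
        if len(tiles) == 0:
            raise InsufficientStackError("no tiles given")
        imgs = [_as_hwc(np.asarray(t)) for t in tiles]
        ref = imgs[0].shape
        for i, im in enumerate(imgs):
            if im.shape != ref:
                label = names[i] if names is not None else f"tile #{i}"
                raise DimensionError(
                    f"{label} has shape {im.shape[:2]}, expected {ref[:2]}"
                )
        dtype = source_dtype if source_dtype is not None else np.asarray(tiles[0]).dtype
        stacked = np.stack(imgs).astype(np.float64)
        if bit_depth_max is None:
            bit_depth_max = _infer_bit_depth_max(dtype, stacked)
        return cls(stacked, bit_depth_max=bit_depth_max, source_dtype=dtype)

    # -- validation --------------------------------------------------------
    def validate_intensities(self) -> None:
        """Check the loaded-data invariant 0 <= I <= bit_depth_max.

        Only freshly loaded stacks must satisfy this; corrected stacks may
        legitimately exceed ``bit_depth_max`` (they are clipped at write
        time, not in memory).
        """
        lo = float(self.data.min(initial=0.0))
        hi = float(self.data.max(initial=0.0))
        if lo < 0:
            raise DimensionError(f"negative intensity {lo} in stack")
        if hi > self.bit_depth_max:
            raise DimensionError(
                f"intensity {hi} exceeds bit_depth_max={self.bit_depth_max}"
            )

    def require_pairable(self) -> None:
        if self.n < 2:
            raise InsufficientStackError(
                f"flat-field estimation needs >= 2 tiles, got {self.n}"
            )

    # -- convenience -------------------------------------------------------
    def copy_with(self, data: np.ndarray) -> "TileStack":
        return TileStack(
            np.asarray(data, dtype=np.float64),
            bit_depth_max=self.bit_depth_max,
            source_dtype=self.source_dtype,
        )


# ---------------------------------------------------------------------------
# Candidates / smoothness / model / report
# ---------------------------------------------------------------------------

@dataclass
class FlatFieldCandidates:
    """Per-pixel rank-sorted stack: ``ranks[r-1]`` holds, at each pixel and
    channel, the r-th largest intensity across the tile stack (rank 1 is the
    brightest)."""

    ranks: np.ndarray  # (n, H, W, C), descending along axis 0
    bit_depth_max: float = 255.0

    @property
    def n(self) -> int:
        return self.ranks.shape[0]

    @property
    def channels(self) -> int:
        return self.ranks.shape[3]

    def rank(self, r: int) -> np.ndarray:
        """Return the rank-``r`` candidate image (1-based, 1 = brightest)."""
        if not 1 <= r <= self.n:
            raise ParameterError(f"rank {r} outside [1, {self.n}]")
        return self.ranks[r - 1]


@dataclass
class SmoothnessProfile:
    """LCoV smoothness S_r per candidate rank and channel.

    ``scores[c, r-1]`` is the image-wide sum of the local coefficient of
    variation of channel ``c`` of the rank-``r`` candidate.  Ranks excluded
    from a restricted search are stored as NaN.
    """

    scores: np.ndarray  # (C, n)
    window: int = 5
    epsilon: float = 0.0

    @property
    def n(self) -> int:
        return self.scores.shape[1]

    def to_dataframe(self):
        import pandas as pd

        cols = ["S_red", "S_green", "S_blue"][: self.scores.shape[0]]
        if self.scores.shape[0] == 1:
            cols = ["S"]
        df = pd.DataFrame(self.scores.T, columns=cols)
        df.insert(0, "rank", np.arange(1, self.n + 1))
        return df


@dataclass
class FlatFieldModel:
    """A selected flat-field estimate F̂ with its provenance.

    This is the results object of the estimator: it carries the per-pixel
    field, the rank selected per channel, the full smoothness profile, and a
    (by assumption all-zero) dark field.  ``field`` must be strictly
    positive everywhere — division by it is the correction step.
    """

    field: np.ndarray  # (H, W, C) > 0
    selected_rank: Optional[tuple] = None  # per-channel 1-based rank
    smoothness: Optional[SmoothnessProfile] = None
    dark_field: Optional[np.ndarray] = None
    bit_depth_max: float = 255.0

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=np.float64)
        if self.field.ndim == 2:
            self.field = self.field[:, :, None]
        if self.field.ndim != 3 or self.field.shape[2] not in (1, 3):
            raise DimensionError(f"field must be H×W×C, got {self.field.shape}")
        if not np.all(self.field > 0):
            raise DegenerateFieldError(
                "flat-field estimate contains nonpositive pixels; "
                "correction by division is undefined"
            )
        if self.dark_field is None:
            self.dark_field = np.zeros_like(self.field)
        else:
            self.dark_field = np.asarray(self.dark_field, dtype=np.float64)
            if self.dark_field.shape != self.field.shape:
                raise DimensionError("dark_field shape differs from field shape")

    @property
    def channels(self) -> int:
        return self.field.shape[2]

    # -- results-object conveniences ----------------------------------------
    def correct(self, stack: TileStack, scale_mode: str = "preserve_mean") -> TileStack:
        """Shading-correct a stack with this field (see :mod:`rankflat.correct`)."""
        from .correct import apply_correction

        return apply_correction(stack, self, scale_mode=scale_mode)

    def summary(self) -> str:
        """Plain-text summary in the spirit of statistical results objects."""
        h, w, c = self.field.shape
        lines = [
            "Rank-statistics flat-field model",
            "=" * 40,
            f"field shape:      {h} x {w} x {c}",
            f"field mean:       "
            + ", ".join(f"{m:.3f}" for m in self.field.mean(axis=(0, 1))),
            f"field min/max:    {self.field.min():.3f} / {self.field.max():.3f}",
        ]
        if self.selected_rank is not None:
            lines.append(
                "selected rank:    "
                + ", ".join(str(r) for r in self.selected_rank)
            )
        if self.smoothness is not None:
            s = self.smoothness
            lines.append(f"LCoV window:      {s.window} x {s.window}")
            lines.append(f"epsilon:          {s.epsilon:g}")
            with np.errstate(invalid="ignore"):
                smin = np.nanmin(s.scores, axis=1)
            lines.append(
                "min smoothness S: " + ", ".join(f"{v:.4f}" for v in smin)
            )
        return "\n".join(lines)

    def plot_smoothness(self, ax=None):
        """Plot S_r against candidate rank per channel (the selection curve)."""
        if self.smoothness is None:
            raise ParameterError("model carries no smoothness profile")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        names = ["red", "green", "blue"] if self.channels == 3 else ["gray"]
        colors = ["tab:red", "tab:green", "tab:blue"][: self.channels]
        ranks = np.arange(1, self.smoothness.n + 1)
        for c in range(self.channels):
            ax.plot(ranks, self.smoothness.scores[c], color=colors[c], label=names[c])
            if self.selected_rank is not None:
                r = self.selected_rank[c]
                ax.axvline(r, color=colors[c], ls=":", lw=0.8)
        ax.set_xlabel("candidate rank (1 = brightest)")
        ax.set_ylabel("smoothness S (sum of LCoV)")
        ax.legend()
        return ax


@dataclass
class EvaluationReport:
    """Quantitative evaluation of a corrected stack against ground truth."""

    gamma: float
    psnr_db: float
    per_tile_gamma: Optional[np.ndarray] = None

    def to_dict(self) -> dict:
        d = {"gamma": float(self.gamma), "psnr_db": float(self.psnr_db)}
        if self.per_tile_gamma is not None:
            d["per_tile_gamma"] = [float(g) for g in self.per_tile_gamma]
        return d


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_IMAGE_EXTS = {".tif", ".tiff", ".png", ".jpg", ".jpeg"}


def _read_image(path: Path) -> np.ndarray:
    import tifffile
    import imageio.v3 as iio

    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            return tifffile.imread(path)
        return iio.imread(path)
    except RankflatError:
        raise
    except Exception as exc:  # pragma: no cover - backend specific
        raise IOError(f"cannot read image file {path}: {exc}") from exc


def _apply_channel_mode(img: np.ndarray, channel_mode: str, maxval: float) -> np.ndarray:
    img = _as_hwc(img)
    if channel_mode == "auto":
        return img
    if channel_mode == "gray":
        if img.shape[2] == 1:
            return img
        from skimage.color import rgb2gray

        return (rgb2gray(img / maxval) * maxval)[:, :, None]
    if channel_mode == "rgb":
        if img.shape[2] == 3:
            return img
        return np.repeat(img, 3, axis=2)
    raise ParameterError(f"unknown channel_mode {channel_mode!r}")


def load_stack(
    paths_or_multipage: Union[str, Path, Sequence[Union[str, Path]]],
    channel_mode: str = "auto",
) -> TileStack:
    """Load a tile stack from a directory, a file list, or a multi-page TIFF.

    A directory is read in lexicographic file order; a single TIFF file is
    interpreted page-by-page.  All tiles must share one shape; intensities
    are converted to ``float64`` and ``bit_depth_max`` is inferred from the
    source dtype (255 for ``uint8``, 65535 for ``uint16``).
    """
    if isinstance(paths_or_multipage, (str, Path)):
        p = Path(paths_or_multipage)
        if p.is_dir():
            files = sorted(
                f for f in p.iterdir() if f.suffix.lower() in _IMAGE_EXTS
            )
            if len(files) < 2:
                raise InsufficientStackError(
                    f"directory {p} holds {len(files)} image files; need >= 2"
                )
            return load_stack(files, channel_mode=channel_mode)
        # single file: must be a multi-page TIFF
        if p.suffix.lower() in (".tif", ".tiff"):
            import tifffile

            with tifffile.TiffFile(p) as tif:
                n_pages = len(tif.pages)
                arr = tif.asarray()
        else:
            arr = _read_image(p)
            n_pages = arr.shape[0] if arr.ndim == 4 else 1
        dtype = arr.dtype
        if n_pages < 2:
            raise InsufficientStackError(
                f"{p} holds a single image; a stack needs >= 2 tiles"
            )
        pages = [arr[i] for i in range(n_pages)]
        maxval = _infer_bit_depth_max(dtype, arr)
        pages = [_apply_channel_mode(pg, channel_mode, maxval) for pg in pages]
        stack = TileStack.from_tiles(
            pages, bit_depth_max=maxval, source_dtype=dtype,
            names=[f"{p}[page {i}]" for i in range(len(pages))],
        )
        stack.validate_intensities()
        return stack

    files = [Path(f) for f in paths_or_multipage]
    if len(files) < 2:
        raise InsufficientStackError(f"got {len(files)} files; need >= 2")
    imgs = [_read_image(f) for f in files]
    dtype = imgs[0].dtype
    maxval = max(_infer_bit_depth_max(im.dtype, im) for im in imgs)
    imgs = [_apply_channel_mode(im, channel_mode, maxval) for im in imgs]
    stack = TileStack.from_tiles(
        imgs, bit_depth_max=maxval, source_dtype=dtype, names=[str(f) for f in files]
    )
    stack.validate_intensities()
    return stack


def write_stack(
    stack: TileStack,
    out_dir: Union[str, Path],
    prefix: str = "tile",
    suffix: str = "",
    dtype: Optional[np.dtype] = None,
    clip: bool = True,
) -> list:
    """Write each tile as a TIFF, by default in the stack's source dtype.

    Integer outputs are clipped to ``[0, bit_depth_max]`` and rounded; pass
    ``dtype=np.float32`` for a lossless float output.  Returns the written
    paths.
    """
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dtype = np.dtype(dtype) if dtype is not None else stack.source_dtype
    width = max(3, len(str(stack.n - 1)))
    paths = []
    for i, tile in enumerate(stack.data):
        img = tile[:, :, 0] if tile.shape[2] == 1 else tile
        if np.issubdtype(dtype, np.integer):
            if clip:
                img = np.clip(img, 0.0, stack.bit_depth_max)
            img = np.rint(img).astype(dtype)
        else:
            img = img.astype(dtype)
        path = out_dir / f"{prefix}_{i:0{width}d}{suffix}.tif"
        photometric = "rgb" if img.ndim == 3 else "minisblack"
        tifffile.imwrite(path, img, photometric=photometric)
        paths.append(path)
    return paths


def save_flat_field(model: FlatFieldModel, path: Union[str, Path]) -> Path:
    """Persist a flat-field model: 32-bit float TIFF plus a JSON sidecar."""
    import tifffile

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = model.field[:, :, 0] if model.channels == 1 else model.field
    photometric = "rgb" if img.ndim == 3 else "minisblack"
    tifffile.imwrite(path, img.astype(np.float32), photometric=photometric)
    sidecar = {
        "selected_rank": list(model.selected_rank) if model.selected_rank else None,
        "bit_depth_max": model.bit_depth_max,
    }
    if model.smoothness is not None:
        sidecar["window"] = int(model.smoothness.window)
        sidecar["epsilon"] = float(model.smoothness.epsilon)
        sidecar["smoothness"] = [
            [None if np.isnan(v) else float(v) for v in row]
            for row in model.smoothness.scores
        ]
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_flat_field(path: Union[str, Path]) -> FlatFieldModel:
    """Load a flat-field model saved by :func:`save_flat_field`."""
    import tifffile

    path = Path(path)
    field = np.asarray(tifffile.imread(path), dtype=np.float64)
    sidecar_path = path.with_suffix(".json")
    selected, smooth, maxval = None, None, 255.0
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        if meta.get("selected_rank"):
            selected = tuple(int(r) for r in meta["selected_rank"])
        maxval = float(meta.get("bit_depth_max", 255.0))
        if "smoothness" in meta:
            scores = np.array(
                [[np.nan if v is None else v for v in row] for row in meta["smoothness"]],
                dtype=np.float64,
            )
            smooth = SmoothnessProfile(
                scores, window=int(meta["window"]), epsilon=float(meta["epsilon"])
            )
    return FlatFieldModel(
        field, selected_rank=selected, smoothness=smooth, bit_depth_max=maxval
    )
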
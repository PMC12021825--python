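"""Reading, writing and tiling of semantic label images.

The pipeline consumes 2D single-channel label images in which each pixel
carries one of three class codes:

====  ==================
code  meaning
====  ==================
0     background
1     axon lumen (axoplasm cross-section)
2     myelin sheath
====  ==================

Physical scale is carried as a pixel pitch in nanometres; all derived
lengths are reported in micrometres and areas in square micrometres.
Coordinates are (row, col), 0-based, and patch tilings are half-open:
patch (i, j) covers rows [i*patch_px, (i+1)*patch_px) and likewise for
columns, so every pixel belongs to exactly one patch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "SemanticMask",
    "PatchGrid",
    "VALID_CLASS_CODES",
    "read_label_image",
    "write_label_image",
    "build_pyramid",
    "make_patch_grid",
    "write_metric_table",
    "read_metric_table",
]

#: legal codes of a semantic mask
VALID_CLASS_CODES = (0, 1, 2)

CLASS_BACKGROUND = 0
CLASS_AXON = 1
CLASS_MYELIN = 2


@dataclass
class SemanticMask:
    """Per-pixel class map of one EM section (or tile).

    Parameters
    ----------
    classes
        2D integer array with codes 0 (background), 1 (axon lumen),
        2 (myelin).
    pixel_size
        Pixel pitch in nanometres (> 0).
    exclusion
        Optional boolean array of the same shape; ``True`` marks pixels
        outside the region of interest (e.g. tissue adjacent to the
        corpus callosum) that must not contribute to analysis.
    """

    classes: np.ndarray
    pixel_size: float
    exclusion: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes)
        if self.classes.ndim != 2:
            raise ValueError(f"classes must be 2D, got shape {self.classes.shape}")
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        bad = np.setdiff1d(np.unique(self.classes), VALID_CLASS_CODES)
        if bad.size:
            raise ValueError(
                f"semantic mask contains invalid class codes {bad.tolist()}; "
                f"expected a subset of {list(VALID_CLASS_CODES)}"
            )
        if self.exclusion is not None:
            self.exclusion = np.asarray(self.exclusion, dtype=bool)
            if self.exclusion.shape != self.classes.shape:
                raise ValueError(
                    "exclusion mask shape "
                    f"{self.exclusion.shape} != classes shape {self.classes.shape}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.classes.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class PatchGrid:
    """Half-open square tiling of an image.

    The last row/column of patches may be partial when the image side is
    not a multiple of ``patch_px``; such boundary patches are flagged by
    :meth:`is_full` and excluded from per-area densities by default
    (counts at unequal patch area are not comparable).
    """

    patch_px: int
    image_shape: tuple[int, int]
    pixel_size: float
    origin: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.patch_px < 1:
            raise ValueError("patch_px must be >= 1")

    @property
    def n_rows(self) -> int:
        return -(-(self.image_shape[0] - self.origin[0]) // self.patch_px)

    @property
    def n_cols(self) -> int:
        return -(-(self.image_shape[1] - self.origin[1]) // self.patch_px)

    @property
    def patch_area_um2(self) -> float:
        """Physical area of one *full* patch in μm²."""
        side_um = self.patch_px * self.pixel_size / 1000.0
        return side_um * side_um

    def patch_of(self, row: float, col: float) -> tuple[int, int]:
        """Patch index (i, j) containing a (possibly fractional) pixel position."""
        i = int((row - self.origin[0]) // self.patch_px)
        j = int((col - self.origin[1]) // self.patch_px)
        return i, j

    def is_full(self, i: int, j: int) -> bool:
        """Whether patch (i, j) lies entirely inside the image."""
        r1 = self.origin[0] + (i + 1) * self.patch_px
        c1 = self.origin[1] + (j + 1) * self.patch_px
        return r1 <= self.image_shape[0] and c1 <= self.image_shape[1]

    def full_mask(self) -> np.ndarray:
        """Boolean (n_rows, n_cols) grid, True for full patches."""
        out = np.zeros((self.n_rows, self.n_cols), dtype=bool)
        for i in range(self.n_rows):
            for j in range(self.n_cols):
                out[i, j] = self.is_full(i, j)
        return out


def read_label_image(path: str | Path, pixel_size: float) -> SemanticMask:
    """Read a single-channel TIFF/PNG label image into a :class:`SemanticMask`.

    Codes outside {0, 1, 2} raise a ``ValueError`` naming the offending
    codes rather than being silently remapped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(
            f"{path.name}: expected a single-channel label image, got shape {arr.shape}"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"{path.name}: expected integer codes, got dtype {arr.dtype}")
    return SemanticMask(classes=arr, pixel_size=pixel_size)


def write_label_image(mask: SemanticMask, path: str | Path,
                      sidecar: bool = True) -> Path:
    """Write a semantic mask as uint8 TIFF or PNG.

    When ``sidecar`` is set, a ``<path>.json`` file records the pixel
    pitch and the class-code legend so the image remains interpretable
    on its own.
    """
    path = Path(path)
    arr = mask.classes.astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)
    if sidecar:
        meta = {
            "pixel_size_nm": mask.pixel_size,
            "class_codes": {"0": "background", "1": "axon", "2": "myelin"},
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))
    return path


def _block_reduce_mean(arr: np.ndarray) -> np.ndarray:
    """2x2 block mean; odd trailing row/col replicated before reduction."""
    arr = _pad_to_even(arr)
    h, w = arr.shape
    return arr.reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))


def _block_reduce_majority(arr: np.ndarray) -> np.ndarray:
    """2x2 majority vote on label codes; ties resolved to the lowest code."""
    arr = _pad_to_even(arr)
    h, w = arr.shape
    blocks = arr.reshape(h // 2, 2, w // 2, 2)
    codes = np.unique(arr)
    counts = np.stack([(blocks == c).sum(axis=(1, 3)) for c in codes])
    # argmax over ascending code order -> lowest code wins ties
    return codes[np.argmax(counts, axis=0)]


def _pad_to_even(arr: np.ndarray) -> np.ndarray:
    pr = arr.shape[0] % 2
    pc = arr.shape[1] % 2
    if pr or pc:
        arr = np.pad(arr, ((0, pr), (0, pc)), mode="edge")
    return arr


def build_pyramid(grid: np.ndarray, pixel_size: float,
                  levels: list[float], kind: str = "label") -> dict[float, np.ndarray]:
    """Build a multiresolution pyramid by repeated 2x2 reduction.

    Whole sections are processed at a working pitch (8 nm in the
    reference setup) but examined at coarser scales as well; levels are
    requested as physical resolutions and must be ``pixel_size * 2**k``.

    Parameters
    ----------
    grid
        2D array, either a label image (``kind="label"``, reduced by
        majority vote with ties going to the lowest code) or a grayscale
        image (``kind="intensity"``, reduced by block averaging).
    pixel_size
        Pitch of ``grid`` in nm.
    levels
        Target resolutions in nm, each an exact power-of-two multiple of
        ``pixel_size``. ``pixel_size`` itself may be included.

    Returns
    -------
    dict mapping requested resolution -> downsampled array.
    """
    if kind not in ("label", "intensity"):
        raise ValueError(f"kind must be 'label' or 'intensity', got {kind!r}")
    steps = {}
    for lv in levels:
        ratio = lv / pixel_size
        k = int(round(np.log2(ratio))) if ratio > 0 else -1
        if k < 0 or not np.isclose(ratio, 2 ** k):
            raise ValueError(
                f"level {lv} nm is not a power-of-two multiple of the base "
                f"pitch {pixel_size} nm"
            )
        steps[lv] = k
    reduce = _block_reduce_majority if kind == "label" else _block_reduce_mean
    out: dict[float, np.ndarray] = {}
    cache = {0: np.asarray(grid)}
    for lv, k in sorted(steps.items(), key=lambda kv: kv[1]):
        top = max(c for c in cache if c <= k)
        arr = cache[top]
        for step in range(top, k):
            arr = reduce(arr)
            cache[step + 1] = arr
        out[lv] = cache[k]
    return out


def make_patch_grid(mask: SemanticMask | np.ndarray, patch_px: int,
                    pixel_size: float | None = None) -> PatchGrid:
    """Tile a mask into square patches of ``patch_px`` pixels.

    The reference analysis tiles sections into 2,048-px patches at 8 nm,
    i.e. 268.4 μm² per full patch.
    """
    if isinstance(mask, SemanticMask):
        shape = mask.shape
        px = mask.pixel_size
    else:
        shape = np.asarray(mask).shape
        if pixel_size is None:
            raise ValueError("pixel_size required when tiling a bare array")
        px = pixel_size
    return PatchGrid(patch_px=patch_px, image_shape=tuple(shape), pixel_size=px)


def write_metric_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a per-instance (or per-patch) metric table as CSV.

    Floats are written at 6 significant digits; ids and labels survive a
    round-trip verbatim.
    """
    path = Path(path)
    table.to_csv(path, index=False, float_format="%.6g")
    return path


def read_metric_table(path: str | Path) -> pd.DataFrame:
    """Read a metric table written by :func:`write_metric_table`."""
    return pd.read_csv(path)
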
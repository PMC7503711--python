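"""Micrograph and instance-mask containers and file I/O.

Conventions used throughout the package:

* images are 2-D grayscale arrays indexed ``(row, col)``, 0-based;
* windows are half-open rectangles ``[x0, x1) x [y0, y1)`` in
  ``(col, row)`` pixel coordinates;
* instance masks are boolean arrays congruent in shape with their parent
  micrograph; the canonical on-disk format is a multi-page TIFF (one page
  per instance, so overlapping instances can be represented), with flat
  integer label images accepted as a convenience.

Calibration (nm per pixel) is always supplied explicitly; it is never
inferred from file metadata.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import imageio.v3 as iio
import tifffile

__all__ = [
    "Micrograph",
    "InstanceSet",
    "Window",
    "read_micrograph",
    "write_micrograph",
    "read_label_image",
    "write_label_image",
    "central_window",
]


@dataclass
class Micrograph:
    """A calibrated 2-D grayscale image.

    Parameters
    ----------
    image
        2-D intensity array (any integer or float dtype).
    nm_per_pixel
        Positive pixel calibration in nanometres per pixel.
    id
        Free-form identifier (defaults to empty string).
    """

    image: np.ndarray
    nm_per_pixel: float
    id: str = ""

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 2:
            raise ValueError(
                f"micrograph image must be 2-D grayscale, got shape {self.image.shape}"
            )
        if self.image.shape[0] < 2 or self.image.shape[1] < 2:
            raise ValueError("micrograph must have at least 2 rows and 2 columns")
        if not (float(self.nm_per_pixel) > 0):
            raise ValueError("nm_per_pixel must be positive")
        self.nm_per_pixel = float(self.nm_per_pixel)

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape


@dataclass(frozen=True)
class Window:
    """Half-open rectangular window [x0, x1) x [y0, y1); x = column, y = row."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError("window must satisfy x1 > x0 and y1 > y0")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height

    def check_within(self, shape: tuple[int, int]) -> None:
        h, w = shape
        if self.x0 < 0 or self.y0 < 0 or self.x1 > w or self.y1 > h:
            raise ValueError(f"window {self} exceeds image bounds {shape}")


def _bbox_of(mask: np.ndarray) -> tuple[int, int, int, int]:
    """(rmin, cmin, rmax, cmax), inclusive, of a non-empty boolean mask."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return int(rows[0]), int(cols[0]), int(rows[-1]), int(cols[-1])


class InstanceSet:
    """An ordered collection of instance masks over one image.

    Masks are stored internally as bounding-box crops to keep memory
    proportional to particle area rather than image area; :meth:`full_mask`
    materialises the congruent full-frame boolean mask for any instance.

    Parameters
    ----------
    masks
        Iterable of full-frame boolean masks (all congruent, all non-empty).
    shape
        Image shape; required when ``masks`` is empty.
    scores
        Optional per-mask confidence values in [0, 1], aligned 1:1 with masks.
    source
        One of ``{"annotation", "prediction", "simulation"}``.
    """

    SOURCES = ("annotation", "prediction", "simulation")

    def __init__(
        self,
        masks: Sequence[np.ndarray] | None = None,
        *,
        shape: tuple[int, int] | None = None,
        scores: Sequence[float] | None = None,
        source: str = "annotation",
    ) -> None:
        if source not in self.SOURCES:
            raise ValueError(f"source must be one of {self.SOURCES}, got {source!r}")
        self.source = source
        self._bboxes: list[tuple[int, int, int, int]] = []
        self._crops: list[np.ndarray] = []
        masks = list(masks) if masks is not None else []
        if shape is None:
            if not masks:
                raise ValueError("shape is required for an empty InstanceSet")
            shape = tuple(np.asarray(masks[0]).shape)  # type: ignore[assignment]
        self.shape: tuple[int, int] = (int(shape[0]), int(shape[1]))
        for m in masks:
            self.append(m)
        if scores is not None:
            scores = list(float(s) for s in scores)
            if len(scores) != len(self._crops):
                raise ValueError("scores must align 1:1 with masks")
            if any(s < 0 or s > 1 for s in scores):
                raise ValueError("scores must lie in [0, 1]")
        self.scores: list[float] | None = scores

    # -- construction -------------------------------------------------

    def append(self, mask: np.ndarray) -> None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.shape:
            raise ValueError(
                f"mask shape {mask.shape} not congruent with image shape {self.shape}"
            )
        if not mask.any():
            raise ValueError("instance masks must be non-empty")
        bb = _bbox_of(mask)
        self._bboxes.append(bb)
        self._crops.append(mask[bb[0] : bb[2] + 1, bb[1] : bb[3] + 1].copy())

    def append_crop(
        self, crop: np.ndarray, bbox: tuple[int, int, int, int]
    ) -> None:
        """Append an instance given its tight crop and inclusive bbox."""
        crop = np.asarray(crop, dtype=bool)
        if not crop.any():
            raise ValueError("instance masks must be non-empty")
        r0, c0, r1, c1 = bbox
        if crop.shape != (r1 - r0 + 1, c1 - c0 + 1):
            raise ValueError("crop shape does not match bbox")
        if r0 < 0 or c0 < 0 or r1 >= self.shape[0] or c1 >= self.shape[1]:
            raise ValueError("bbox exceeds image bounds")
        self._bboxes.append((int(r0), int(c0), int(r1), int(c1)))
        self._crops.append(crop)

    @classmethod
    def empty(cls, shape: tuple[int, int], source: str = "annotation") -> "InstanceSet":
        return cls([], shape=shape, source=source)

    # -- access -------------------------------------------------------

    def __len__(self) -> int:
        return len(self._crops)

    def bbox(self, i: int) -> tuple[int, int, int, int]:
        """Inclusive (rmin, cmin, rmax, cmax) bounding box of instance i."""
        return self._bboxes[i]

    def crop(self, i: int) -> np.ndarray:
        """Tight boolean crop of instance i (view of internal storage)."""
        return self._crops[i]

    def full_mask(self, i: int) -> np.ndarray:
        """Full-frame boolean mask for instance i."""
        out = np.zeros(self.shape, dtype=bool)
        r0, c0, r1, c1 = self._bboxes[i]
        out[r0 : r1 + 1, c0 : c1 + 1] = self._crops[i]
        return out

    def __getitem__(self, i: int) -> np.ndarray:
        return self.full_mask(i)

    def iter_masks(self) -> Iterator[np.ndarray]:
        for i in range(len(self)):
            yield self.full_mask(i)

    @property
    def masks(self) -> list[np.ndarray]:
        return list(self.iter_masks())

    def area(self, i: int) -> int:
        return int(self._crops[i].sum())

    def areas(self) -> np.ndarray:
        return np.array([int(c.sum()) for c in self._crops], dtype=np.int64)

    def subset(self, indices: Sequence[int]) -> "InstanceSet":
        out = InstanceSet.empty(self.shape, source=self.source)
        for i in indices:
            out._bboxes.append(self._bboxes[i])
            out._crops.append(self._crops[i])
        if self.scores is not None:
            out.scores = [self.scores[i] for i in indices]
        return out

    def to_label_image(self) -> np.ndarray:
        """Flat label image (later instances overwrite earlier on overlap)."""
        lab = np.zeros(self.shape, dtype=np.int32)
        for i in range(len(self)):
            r0, c0, r1, c1 = self._bboxes[i]
            view = lab[r0 : r1 + 1, c0 : c1 + 1]
            view[self._crops[i]] = i + 1
        return lab


# -- file operations --------------------------------------------------


def read_micrograph(path: str | os.PathLike, nm_per_pixel: float, id: str | None = None) -> Micrograph:
    """Read a grayscale TIFF/PNG micrograph and attach a calibration.

    Intensities are preserved exactly (no rescaling). RGB or stacked
    images are rejected.
    """
    path = os.fspath(path)
    if path.lower().endswith((".tif", ".tiff")):
        image = tifffile.imread(path)
    else:
        image = iio.imread(path)
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D grayscale image, got shape {image.shape}")
    return Micrograph(image=image, nm_per_pixel=nm_per_pixel, id=id if id is not None else os.path.basename(path))


def write_micrograph(micrograph: Micrograph, path: str | os.PathLike) -> None:
    """Write a micrograph to TIFF or PNG without intensity rescaling."""
    path = os.fspath(path)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, micrograph.image)
    else:
        iio.imwrite(path, micrograph.image)


def read_label_image(path: str | os.PathLike, source: str = "annotation") -> InstanceSet:
    """Read instance masks from a TIFF/PNG.

    A multi-page TIFF is read as one binary mask per page (the canonical
    format, which can represent overlapping instances). A single 2-D
    integer label image yields one mask per distinct positive label, in
    increasing label order; 0 is background. An image with no positive
    labels yields an empty InstanceSet.
    """
    path = os.fspath(path)
    if path.lower().endswith((".tif", ".tiff")):
        pages = tifffile.imread(path)
    else:
        pages = iio.imread(path)
    pages = np.asarray(pages)
    if pages.ndim == 3:  # one page per instance
        masks = [np.asarray(p) != 0 for p in pages]
        masks = [m for m in masks if m.any()]
        return InstanceSet(masks, shape=pages.shape[1:], source=source)
    if pages.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D label image or page stack")
    if np.issubdtype(pages.dtype, np.signedinteger) and (pages < 0).any():
        raise ValueError(f"{path}: label image contains negative labels")
    labels = np.unique(pages)
    labels = labels[labels > 0]
    return InstanceSet(
        [pages == lab for lab in labels], shape=pages.shape, source=source
    )


def write_label_image(instances: InstanceSet, path: str | os.PathLike, *, flat: bool = False) -> None:
    """Write masks as a multi-page TIFF (default) or a flat label image."""
    path = os.fspath(path)
    if flat:
        tifffile.imwrite(path, instances.to_label_image())
        return
    if len(instances) == 0:
        tifffile.imwrite(path, np.zeros((1,) + instances.shape, dtype=np.uint8))
        return
    stack = np.zeros((len(instances),) + instances.shape, dtype=np.uint8)
    for i in range(len(instances)):
        r0, c0, r1, c1 = instances.bbox(i)
        stack[i, r0 : r1 + 1, c0 : c1 + 1] = instances.crop(i)
    tifffile.imwrite(path, stack)


def central_window(micrograph: Micrograph | tuple[int, int], side_px: int) -> Window:
    """Centered square window of side ``side_px`` (floor division for odd remainders)."""
    shape = micrograph.shape if isinstance(micrograph, Micrograph) else tuple(micrograph)
    h, w = int(shape[0]), int(shape[1])
    side_px = int(side_px)
    if side_px <= 0:
        raise ValueError("side_px must be positive")
    if side_px > min(h, w):
        raise ValueError(f"side_px {side_px} exceeds image dimensions {(h, w)}")
    y0 = (h - side_px) // 2
    x0 = (w - side_px) // 2
    return Window(x0=x0, y0=y0, x1=x0 + side_px, y1=y0 + side_px)
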
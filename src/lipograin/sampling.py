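"""Unbiased particle-selection rules.

Two stereological selection devices are implemented:

* a central evaluation window with a minimum-area-fraction rule (an
  instance is kept when at least half of its area falls inside the
  window), and
* a horizontal scanning band bounded by a *forbidden* line and an
  *acceptance* line: events wholly inside the band are kept, events
  touching the acceptance line are kept, events touching the forbidden
  line are excluded (the forbidden line wins when both are touched).
  For uniformly placed convex particles this counts exactly those whose
  topmost/bottommost edge lies within the band, so counts per band area
  estimate number density without edge bias.

Fields of view are chosen by systematic uniform random sampling: a
regular grid of non-overlapping fields with a single random phase, from
which every k-th field is taken starting at a random index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging_io import InstanceSet, Window

__all__ = ["Band", "window_filter", "band_select", "sur_sample_positions"]


@dataclass(frozen=True)
class Band:
    """Horizontal scanning band delimited by an acceptance and a forbidden row."""

    acceptance_y: int
    forbidden_y: int

    def __post_init__(self) -> None:
        if self.acceptance_y == self.forbidden_y:
            raise ValueError("acceptance and forbidden lines must differ")


def window_filter(
    instances: InstanceSet, window: Window, min_area_frac: float = 0.5
) -> InstanceSet:
    """Keep instances with (area inside window)/(total area) >= min_area_frac."""
    window.check_within(instances.shape)
    keep = []
    for i in range(len(instances)):
        r0, c0, r1, c1 = instances.bbox(i)
        crop = instances.crop(i)
        # overlap of the (inclusive) bbox with the half-open window
        rr0, rr1 = max(r0, window.y0), min(r1, window.y1 - 1)
        cc0, cc1 = max(c0, window.x0), min(c1, window.x1 - 1)
        if rr0 > rr1 or cc0 > cc1:
            inside = 0
        else:
            inside = int(
                crop[rr0 - r0 : rr1 - r0 + 1, cc0 - c0 : cc1 - c0 + 1].sum()
            )
        if inside / crop.sum() >= min_area_frac:
            keep.append(i)
    return instances.subset(keep)


def band_select(instances: InstanceSet, band: Band) -> InstanceSet:
    """Apply the forbidden/acceptance-line counting rule.

    An instance "touches" a line when its mask intersects that 1-px row.
    Kept: instances strictly between the two lines, or touching the
    acceptance line; touching the forbidden line always excludes.
    """
    lo, hi = sorted((band.acceptance_y, band.forbidden_y))
    keep = []
    for i in range(len(instances)):
        r0, _, r1, _ = instances.bbox(i)
        touches_acc = r0 <= band.acceptance_y <= r1
        touches_forb = r0 <= band.forbidden_y <= r1
        inside = lo < r0 and r1 < hi
        if touches_forb:
            continue
        if inside or touches_acc:
            keep.append(i)
    return instances.subset(keep)


def sur_sample_positions(
    image_shape: tuple[int, int],
    field_shape: tuple[int, int],
    fraction: float,
    seed: int,
) -> list[Window]:
    """Systematic uniform random sample of non-overlapping fields.

    The full grid of ``(field_h, field_w)`` tiles is positioned with a
    single random offset inside the slack the image leaves, then every
    k-th tile (k = round(1/fraction)) is taken in raster order starting
    from a random index in [0, k).  ``fraction = 1`` returns the full
    tiling.  Deterministic for a fixed seed.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    h, w = image_shape
    fh, fw = field_shape
    if fh > h or fw > w:
        raise ValueError("field larger than image")
    rng = np.random.default_rng(seed)
    ny, nx = h // fh, w // fw
    oy = int(rng.integers(0, h - ny * fh + 1))
    ox = int(rng.integers(0, w - nx * fw + 1))
    k = max(1, int(round(1.0 / fraction)))
    start = int(rng.integers(0, k))
    fields = []
    for idx in range(start, ny * nx, k):
        iy, ix = divmod(idx, nx)
        x0 = ox + ix * fw
        y0 = oy + iy * fh
        fields.append(Window(x0=x0, y0=y0, x1=x0 + fw, y1=y0 + fh))
    return fields
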
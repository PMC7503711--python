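"""Particle measurement: callipers, moment ellipses, the spheroid
orientation correction, size summaries and edge-contrast profiles.

The measurement convention follows routine practice for positively
rim-contrasted EM preparations: a particle's size is the horizontal
calliper across its profile (a random direction relative to the
particle), masks delimit the inner edge of the stain rim, and summaries
are reported as mean, sample SD (n-1 denominator), CV% and a 2-nm-bin
relative-frequency histogram labelled by bin lower limits.

Flattened spheroidal particles adsorbed to thin films lie en face, so
calliper measurements report the particle's maximal (equatorial)
diameter.  To compare with methods sensitive to orientation-averaged
size, the *spheroid-equivalent diameter* maps a measured en-face
diameter D onto the mean of the three axes of the corresponding oblate
spheroid (D, D, r*D), i.e. D * (2 + r) / 3, with aspect ratio
r = minor/major taken from reference LDL cryo-EM axes 21.4 x 12.1 nm
by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage import measure as skmeasure

from .imaging_io import InstanceSet, Micrograph

__all__ = [
    "ParticleRecord",
    "SpheroidModel",
    "SizeSummary",
    "horizontal_calliper",
    "fit_axes",
    "spheroid_equivalent_diameter",
    "summarize_sizes",
    "linear_size_from_area",
    "edge_profile",
    "contrast_range",
    "sec_trend_fit",
    "measure_instances",
]


@dataclass(frozen=True)
class SpheroidModel:
    """Oblate-spheroid shape prior: reference major/minor axes in nm."""

    ref_major: float = 21.4
    ref_minor: float = 12.1

    def __post_init__(self) -> None:
        if not (0 < self.ref_minor <= self.ref_major):
            raise ValueError("need 0 < ref_minor <= ref_major")

    @property
    def aspect(self) -> float:
        """r = minor/major, in (0, 1]."""
        return self.ref_minor / self.ref_major

    @property
    def correction_factor(self) -> float:
        """(2 + r) / 3: mean of the three spheroid axes per unit major axis."""
        return (2.0 + self.aspect) / 3.0


@dataclass
class ParticleRecord:
    """Per-particle measurements (sizes in nm, areas in px^2)."""

    instance: int
    calliper_h: float
    major: float
    minor: float
    ratio: float
    area_px2: int
    linear_size_px: float
    centroid: tuple[float, float]


@dataclass
class SizeSummary:
    """Summary of a size sample: mean/SD/CV and a binned histogram.

    ``histogram`` maps each occupied bin's lower limit (nm) to its
    relative frequency in percent; frequencies sum to 100.
    """

    n: int
    mean: float
    sd: float
    cv_percent: float
    bin_width: float
    histogram: dict[float, float]


def horizontal_calliper(mask: np.ndarray, nm_per_pixel: float) -> float:
    """Horizontal extent of a mask: (max col - min col + 1) * nm/px."""
    mask = np.asarray(mask, dtype=bool)
    cols = np.flatnonzero(mask.any(axis=0))
    if cols.size == 0:
        raise ValueError("empty mask has no calliper")
    return float((cols[-1] - cols[0] + 1) * nm_per_pixel)


def fit_axes(mask: np.ndarray, nm_per_pixel: float) -> tuple[float, float, float]:
    """Axes of the second-moment-equivalent ellipse, in nm.

    Returns (major, minor, ratio = major/minor).  Requires >= 5 pixels;
    degenerate (collinear) masks are rejected.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 5:
        raise ValueError("fit_axes requires a mask with at least 5 pixels")
    props = skmeasure.regionprops(mask.astype(np.uint8))[0]
    major = props.axis_major_length * nm_per_pixel
    minor = props.axis_minor_length * nm_per_pixel
    if minor <= 0:
        raise ValueError("degenerate (collinear) mask: minor axis is zero")
    return float(major), float(minor), float(major / minor)


def spheroid_equivalent_diameter(
    measured_major: float, model: SpheroidModel = SpheroidModel()
) -> float:
    """Mean-of-axes diameter of the oblate spheroid with the measured major axis.

    ``measured_major * (2 + r) / 3`` with r = ref_minor/ref_major; linear in
    its input, and the identity when r = 1 (a sphere).
    """
    if not measured_major > 0:
        raise ValueError("measured_major must be positive")
    return float(measured_major * model.correction_factor)


def summarize_sizes(values: Sequence[float], bin_width: float = 2.0) -> SizeSummary:
    """Mean, sample SD, CV% and 2-nm-bin relative-frequency histogram.

    Bins are half-open [lower, lower + bin_width) and labelled by their
    lower limit; a single observation yields SD = CV = 0.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("summarize_sizes requires at least one value")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    cv = 100.0 * sd / mean if mean != 0 else float("nan")
    lowers = np.floor(x / bin_width) * bin_width
    hist: dict[float, float] = {}
    for lo in np.unique(lowers):
        hist[float(lo)] = 100.0 * float(np.sum(lowers == lo)) / x.size
    return SizeSummary(
        n=int(x.size), mean=mean, sd=sd, cv_percent=float(cv),
        bin_width=float(bin_width), histogram=hist,
    )


def linear_size_from_area(area_px2: float) -> float:
    """sqrt(area): the square root of the area as a linear measure of size."""
    if area_px2 < 0:
        raise ValueError("area must be nonnegative")
    return float(np.sqrt(area_px2))


def edge_profile(
    micrograph: Micrograph,
    p0: tuple[float, float],
    p1: tuple[float, float],
) -> list[tuple[float, float]]:
    """Intensity profile along a segment, sampled at 1-px steps.

    ``p0``/``p1`` are (row, col) endpoints inside the image; samples use
    nearest-pixel lookup and positions are reported in nm from ``p0``.
    """
    img = micrograph.image
    h, w = img.shape
    for p in (p0, p1):
        if not (0 <= p[0] <= h - 1 and 0 <= p[1] <= w - 1):
            raise ValueError(f"profile endpoint {p} outside image of shape {img.shape}")
    length = float(np.hypot(p1[0] - p0[0], p1[1] - p0[1]))
    n_steps = int(np.floor(length)) + 1
    ts = np.linspace(0.0, 1.0, n_steps) if n_steps > 1 else np.array([0.0])
    out = []
    for t in ts:
        r = int(round(p0[0] + t * (p1[0] - p0[0])))
        c = int(round(p0[1] + t * (p1[1] - p0[1])))
        out.append((float(t * length * micrograph.nm_per_pixel), float(img[r, c])))
    return out


def contrast_range(profile: Sequence[tuple[float, float]] | Sequence[float]) -> float:
    """Range (max - min) of grey values along a profile."""
    vals = [p[1] if isinstance(p, (tuple, list)) else float(p) for p in profile]
    if len(vals) == 0:
        raise ValueError("empty profile")
    return float(max(vals) - min(vals))


def sec_trend_fit(
    points: Sequence[tuple[float, float]],
) -> tuple[float, float, float]:
    """OLS line through (fraction index, mean size) points.

    Returns (slope, intercept, R^2); R^2 is NaN when y is constant.
    Used for the across-fraction size trend of size-exclusion
    chromatography eluates.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two points")
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size < 2:
        raise ValueError("need at least two distinct x values")
    res = stats.linregress(x, y)
    if np.allclose(y, y[0]):
        return float(res.slope), float(res.intercept), float("nan")
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def measure_instances(
    instances: InstanceSet, nm_per_pixel: float
) -> pd.DataFrame:
    """One ParticleRecord row per instance.

    Columns: instance, calliper_h_nm, major_nm, minor_nm, ratio,
    area_px2, linear_size_px, centroid_row, centroid_col.  Instances too
    small for a moment-ellipse fit (< 5 px) get NaN axes.
    """
    rows = []
    for i in range(len(instances)):
        crop = instances.crop(i)
        r0, c0, r1, c1 = instances.bbox(i)
        calliper = (c1 - c0 + 1) * nm_per_pixel
        area = int(crop.sum())
        try:
            major, minor, ratio = fit_axes(crop, nm_per_pixel)
        except ValueError:
            major = minor = ratio = float("nan")
        rr, cc = np.nonzero(crop)
        rows.append(
            {
                "instance": i,
                "calliper_h_nm": float(calliper),
                "major_nm": major,
                "minor_nm": minor,
                "ratio": ratio,
                "area_px2": area,
                "linear_size_px": linear_size_from_area(area),
                "centroid_row": float(rr.mean() + r0),
                "centroid_col": float(cc.mean() + c0),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "instance", "calliper_h_nm", "major_nm", "minor_nm", "ratio",
            "area_px2", "linear_size_px", "centroid_row", "centroid_col",
        ],
    )
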
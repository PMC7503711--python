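"""Antibody-labelling and aggregation statistics.

Covers the quantities used to characterise immunolabelled lipoprotein
preparations: per-particle antibody-blob counts and the percent of
labelled particles, saturation of labelling with antibody concentration,
label positivity per size bin, an aggregate census over events
(singles and aggregates of 2, 3 or >= 4 touching particles), chi-square
comparison of censuses, the particle-weighted redistribution between
aggregate categories, and nonparametric comparisons of size
distributions (tie-corrected Kruskal-Wallis, pairwise two-sample
Kolmogorov-Smirnov).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .imaging_io import InstanceSet

__all__ = [
    "LabelCount",
    "AggregateCensus",
    "attach_densities",
    "labelling_fraction",
    "saturation_curve",
    "positive_fraction_by_bin",
    "aggregate_census",
    "chi_square_census",
    "redistribution_percent",
    "compare_size_distributions",
]

CATEGORIES = (1, 2, 3, "4+")


@dataclass(frozen=True)
class LabelCount:
    """Antibody-blob count for one particle."""

    particle: int
    n_densities: int

    @property
    def positive(self) -> bool:
        return self.n_densities >= 1


@dataclass
class AggregateCensus:
    """Counts of events by number of component particles {1, 2, 3, >= 4}.

    ``component_sizes`` optionally records the exact size of every event,
    which the particle-weighted redistribution statistic uses for the
    open-ended >= 4 category.
    """

    counts: dict
    component_sizes: Optional[list[int]] = None

    def __post_init__(self) -> None:
        self.counts = {c: int(self.counts.get(c, 0)) for c in CATEGORIES}
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("census counts must be nonnegative")

    @classmethod
    def from_sizes(cls, sizes: Sequence[int]) -> "AggregateCensus":
        sizes = [int(s) for s in sizes]
        counts = {1: 0, 2: 0, 3: 0, "4+": 0}
        for s in sizes:
            counts[s if s in (1, 2, 3) else "4+"] += 1
        return cls(counts=counts, component_sizes=sizes)

    @property
    def n_events(self) -> int:
        return sum(self.counts.values())

    def as_array(self) -> np.ndarray:
        return np.array([self.counts[c] for c in CATEGORIES], dtype=float)


# ---------------------------------------------------------------------
# blob attachment


def _chebyshev_gap(
    set_a: InstanceSet, i: int, set_b: InstanceSet, j: int
) -> float:
    """Minimum Chebyshev distance between pixels of two instances.

    0 means the masks share a pixel; 8-adjacent pixels are at distance 1.
    """
    ar0, ac0, ar1, ac1 = set_a.bbox(i)
    br0, bc0, br1, bc1 = set_b.bbox(j)
    # quick lower bound from bboxes
    dr = max(br0 - ar1, ar0 - br1, 0)
    dc = max(bc0 - ac1, ac0 - bc1, 0)
    lower = max(dr, dc)
    ay, ax = np.nonzero(set_a.crop(i))
    by, bx = np.nonzero(set_b.crop(j))
    ay = ay + ar0
    ax = ax + ac0
    by = by + br0
    bx = bx + bc0
    # exact min over pixel pairs, chunked to bound memory
    best = np.inf
    for s in range(0, ay.size, 2048):
        dy = np.abs(ay[s : s + 2048, None] - by[None, :])
        dx = np.abs(ax[s : s + 2048, None] - bx[None, :])
        d = np.maximum(dy, dx).min()
        if d < best:
            best = float(d)
        if best == lower:
            break
    return best


def attach_densities(
    particles: InstanceSet, blobs: InstanceSet, max_gap_px: int = 2
) -> tuple[list[LabelCount], list[int]]:
    """Assign each blob to its nearest particle within ``max_gap_px``.

    A blob is attached when its mask overlaps or lies within
    ``max_gap_px`` (Chebyshev) of a particle mask; each blob goes to the
    nearest qualifying particle.  Returns per-particle label counts and
    the indices of unbound blobs.
    """
    if particles.shape != blobs.shape:
        raise ValueError("particle and blob masks must be congruent")
    counts = np.zeros(len(particles), dtype=int)
    unbound: list[int] = []
    for j in range(len(blobs)):
        br0, bc0, br1, bc1 = blobs.bbox(j)
        best_d, best_i = np.inf, -1
        for i in range(len(particles)):
            pr0, pc0, pr1, pc1 = particles.bbox(i)
            dr = max(pr0 - br1, br0 - pr1, 0)
            dc = max(pc0 - bc1, bc0 - pc1, 0)
            if max(dr, dc) > max_gap_px:
                continue
            d = _chebyshev_gap(blobs, j, particles, i)
            if d < best_d:
                best_d, best_i = d, i
        if best_i >= 0 and best_d <= max_gap_px:
            counts[best_i] += 1
        else:
            unbound.append(j)
    label_counts = [LabelCount(particle=i, n_densities=int(c)) for i, c in enumerate(counts)]
    return label_counts, unbound


def labelling_fraction(counts: Sequence[LabelCount]) -> float:
    """Percent of particles with at least one attached density."""
    counts = list(counts)
    if not counts:
        raise ValueError("labelling_fraction requires at least one particle")
    return 100.0 * sum(c.positive for c in counts) / len(counts)


def saturation_curve(
    concentrations: Sequence[float],
    fractions: Sequence[float],
    tol: float = 2.0,
) -> dict:
    """Detect a labelling plateau across increasing antibody concentration.

    The plateau is the mean labelled fraction over the longest top-end
    run (>= 2 concentrations) whose values span no more than ``tol``
    percentage points; with no such run the curve has not stabilised and
    ``plateau`` is None.  Returns a dict with the sorted table, Spearman
    trend, the plateau estimate and the concentrations it covers.
    """
    conc = np.asarray(list(concentrations), dtype=float)
    frac = np.asarray(list(fractions), dtype=float)
    if conc.size != frac.size:
        raise ValueError("concentrations and fractions must align")
    if conc.size < 3:
        raise ValueError("need at least 3 concentrations")
    order = np.argsort(conc)
    conc, frac = conc[order], frac[order]
    if np.allclose(frac, frac[0]):
        rho = 0.0
    else:
        rho = float(stats.spearmanr(conc, frac).statistic)
    # grow the candidate plateau down from the top concentration
    k = 1
    while k < conc.size:
        window = frac[-(k + 1):]
        if window.max() - window.min() <= tol:
            k += 1
        else:
            break
    if k >= 2:
        plateau = float(frac[-k:].mean())
        plateau_conc = conc[-k:].tolist()
    else:
        plateau, plateau_conc = None, []
    return {
        "table": pd.DataFrame({"concentration": conc, "fraction_percent": frac}),
        "spearman_rho": rho,
        "plateau_percent": plateau,
        "plateau_concentrations": plateau_conc,
    }


def positive_fraction_by_bin(
    sizes: Sequence[float],
    positives: Sequence[bool],
    bin_width: float = 2.0,
) -> pd.DataFrame:
    """Percent of positive particles per size bin (bins labelled by lower limit)."""
    sizes = np.asarray(list(sizes), dtype=float)
    positives = np.asarray(list(positives), dtype=bool)
    if sizes.size != positives.size:
        raise ValueError("sizes and positives must align")
    lowers = np.floor(sizes / bin_width) * bin_width
    rows = []
    for lo in np.unique(lowers):
        in_bin = lowers == lo
        n = int(in_bin.sum())
        rows.append(
            {
                "bin_lower_nm": float(lo),
                "n": n,
                "percent_positive": 100.0 * float(positives[in_bin].sum()) / n,
            }
        )
    return pd.DataFrame(rows, columns=["bin_lower_nm", "n", "percent_positive"])


# ---------------------------------------------------------------------
# aggregation


class _DSU:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _touching(instances: InstanceSet, i: int, j: int, gap: int) -> bool:
    r0, c0, r1, c1 = instances.bbox(i)
    s0, d0, s1, d1 = instances.bbox(j)
    dr = max(s0 - r1, r0 - s1, 0)
    dc = max(d0 - c1, c0 - d1, 0)
    if max(dr, dc) > gap:
        return False
    return _chebyshev_gap(instances, i, instances, j) <= gap


def aggregate_census(
    instances: InstanceSet, touch_gap_px: int = 1
) -> AggregateCensus:
    """Census of events formed by the transitive closure of "touching".

    Two particles touch when their masks lie within ``touch_gap_px``
    (Chebyshev distance; 1 px closes an 8-connected gap).  Connected
    components of the touch relation are events, categorised by their
    number of component particles collapsed to {1, 2, 3, >= 4}.
    """
    n = len(instances)
    dsu = _DSU(n)
    for i in range(n):
        for j in range(i + 1, n):
            if _touching(instances, i, j, touch_gap_px):
                dsu.union(i, j)
    sizes: dict[int, int] = {}
    for i in range(n):
        r = dsu.find(i)
        sizes[r] = sizes.get(r, 0) + 1
    return AggregateCensus.from_sizes(list(sizes.values()))


def chi_square_census(
    a: AggregateCensus, b: AggregateCensus
) -> tuple[float, int, float]:
    """Two-sample chi-square on the 2 x 4 census contingency table.

    Expected counts come from the marginals; categories whose expected
    count is zero are pooled before testing (>= 4 merges into 3 first,
    then 3 into 2), reducing the degrees of freedom accordingly.
    """
    if a.n_events < 1 or b.n_events < 1:
        raise ValueError("both censuses must contain at least one event")
    table = np.vstack([a.as_array(), b.as_array()])
    # A column's expected counts are zero iff its column total is zero.
    # Pool right-to-left ("4+" into 3, then 3 into 2) until none remain.
    while table.shape[1] > 1 and (table.sum(axis=0) == 0).any():
        zero_cols = np.flatnonzero(table.sum(axis=0) == 0)
        col = int(zero_cols[-1])
        tgt = col - 1 if col > 0 else col + 1
        table[:, tgt] += table[:, col]
        table = np.delete(table, col, axis=1)
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def _particle_weighted_small_share(census: AggregateCensus) -> float:
    """Share of particles held in events of 1-3 particles."""
    small = sum(k * census.counts[k] for k in (1, 2, 3))
    if census.component_sizes is not None:
        big = sum(s for s in census.component_sizes if s >= 4)
    else:
        big = 4 * census.counts["4+"]
    total = small + big
    if total == 0:
        raise ValueError("census holds no particles")
    return small / total


def redistribution_percent(
    before: AggregateCensus, after: AggregateCensus
) -> float:
    """Percentage points of particles moving out of categories {1, 2, 3}.

    Shares are particle-weighted: a category-k event contributes k
    particles, and >= 4 events contribute their recorded component sizes
    (or 4 when unrecorded).
    """
    return 100.0 * (
        _particle_weighted_small_share(before) - _particle_weighted_small_share(after)
    )


# ---------------------------------------------------------------------
# distribution comparisons


def compare_size_distributions(groups: Sequence[Sequence[float]]) -> dict:
    """Kruskal-Wallis H (tie-corrected) plus pairwise two-sample KS tests."""
    groups = [np.asarray(list(g), dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups, each with n >= 2")
    try:
        H, p = stats.kruskal(*groups)
    except ValueError:  # all observations identical
        H, p = 0.0, 1.0
    pairwise = {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            ks = stats.ks_2samp(groups[i], groups[j], method="asymp")
            pairwise[(i, j)] = (float(ks.statistic), float(ks.pvalue))
    return {
        "kruskal_H": float(H),
        "kruskal_df": len(groups) - 1,
        "kruskal_p": float(p),
        "pairwise_ks": pairwise,
    }
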
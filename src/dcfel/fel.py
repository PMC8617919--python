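"""Stitched free-energy landscape assembly and landscape measurements.

Each retained sample from region i enters a 2-D histogram with weight
e^{W_i} / M(v), where W_i is the region's stitched log-weight and M(v) the
multiplicity — the number of sampling regions covering the sample's CV
point — which prevents double counting inside overlaps.  The free energy is
the Boltzmann inversion of the weighted density,

    F(v1, v2) = -k_B T ln rho_w(v1, v2),

shifted so the lowest populated bin sits at zero.  Empty bins are masked.

One-dimensional profiles are rectangle averages of the 2-D landscape, and
basin-to-saddle barriers are measured with a minimax path search over
4-connected bins.
"""

from __future__ import annotations

import dataclasses
import heapq

import numpy as np

from dcfel.constants import thermal_energy
from dcfel.regions import Rect, RegionGrid, RegionSamples, WeightTable


class NoPathError(ValueError):
    """Raised when no unmasked bin path connects two landscape regions."""


@dataclasses.dataclass
class FELGrid:
    """Binned free-energy surface F(v1, v2).

    ``F`` has shape (n_v1_bins, n_v2_bins) in kcal/mol with NaN on masked
    (unpopulated) bins; ``mask`` is True where no samples landed.  ``counts``
    records the raw (unweighted) per-bin sample counts for effective-sample
    diagnostics, and ``total_weighted_count`` the normalization of the
    weighted histogram.
    """

    v1_edges: np.ndarray
    v2_edges: np.ndarray
    F: np.ndarray
    mask: np.ndarray
    kT: float
    total_weighted_count: float = float("nan")
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.v1_edges = np.asarray(self.v1_edges, dtype=float)
        self.v2_edges = np.asarray(self.v2_edges, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.kT <= 0:
            raise ValueError("kT must be positive")
        if self.F.shape != (len(self.v1_edges) - 1, len(self.v2_edges) - 1):
            raise ValueError("F shape inconsistent with bin edges")

    @property
    def v1_centers(self) -> np.ndarray:
        return 0.5 * (self.v1_edges[:-1] + self.v1_edges[1:])

    @property
    def v2_centers(self) -> np.ndarray:
        return 0.5 * (self.v2_edges[:-1] + self.v2_edges[1:])

    def min_shift(self) -> None:
        """Shift F so the minimum unmasked bin is exactly zero."""
        if np.all(self.mask):
            return
        self.F = self.F - np.nanmin(self.F[~self.mask])


def fel_from_weighted_counts(
    weighted: np.ndarray,
    v1_edges: np.ndarray,
    v2_edges: np.ndarray,
    kT: float,
    counts: np.ndarray | None = None,
) -> FELGrid:
    """Boltzmann-invert a weighted histogram into a min-shifted FELGrid."""
    weighted = np.asarray(weighted, dtype=float)
    mask = weighted <= 0
    total = float(weighted.sum())
    F = np.full_like(weighted, np.nan)
    with np.errstate(divide="ignore"):
        F[~mask] = -kT * np.log(weighted[~mask] / total)
    grid = FELGrid(
        v1_edges=v1_edges,
        v2_edges=v2_edges,
        F=F,
        mask=mask,
        kT=kT,
        total_weighted_count=total,
        counts=counts,
    )
    grid.min_shift()
    return grid


def assemble_fel(
    region_samples: list[RegionSamples],
    weights: WeightTable,
    grid: RegionGrid,
    bins: tuple[np.ndarray, np.ndarray],
    temperature_K: float,
) -> FELGrid:
    """Stitch per-region CV samples into one free-energy landscape.

    Samples must already satisfy the exclusion rule (clipped to their
    sampling rectangle).  Each sample contributes e^{W_i} / M to its bin;
    bins that receive no samples are masked and the result is shifted so the
    lowest populated bin is zero.
    """
    v1_edges, v2_edges = (np.asarray(b, dtype=float) for b in bins)
    if not region_samples or all(s.L == 0 for s in region_samples):
        raise ValueError("no samples to assemble")
    kT = thermal_energy(temperature_K)
    shape = (len(v1_edges) - 1, len(v2_edges) - 1)
    weighted = np.zeros(shape)
    counts = np.zeros(shape)
    for samples in region_samples:
        if samples.L == 0:
            continue
        w_i = weights.W[samples.region_id]
        if not np.isfinite(w_i):
            raise ValueError(
                f"region {samples.region_id} has samples but no stitched weight"
            )
        pts = samples.cv_table
        m = grid.multiplicity_many(pts)
        if np.any(m == 0):
            raise ValueError(
                f"region {samples.region_id} has samples outside every "
                "sampling region; clip samples first"
            )
        w = np.exp(w_i) / m
        h, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=(v1_edges, v2_edges), weights=w)
        weighted += h
        c, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=(v1_edges, v2_edges))
        counts += c
    return fel_from_weighted_counts(weighted, v1_edges, v2_edges, kT, counts=counts)


def _bins_in_rect(fel: FELGrid, rect: Rect) -> tuple[np.ndarray, np.ndarray]:
    in1 = (fel.v1_centers >= rect[0]) & (fel.v1_centers <= rect[1])
    in2 = (fel.v2_centers >= rect[2]) & (fel.v2_centers <= rect[3])
    return in1, in2


def marginal_fel(fel: FELGrid, rectangle: Rect, axis: int | str = 0):
    """Rectangle-averaged one-dimensional free-energy profile.

    For each bin along the kept axis (0 or "v1" keeps v1), the profile is
    the arithmetic mean of unmasked F values across the rectangle's extent
    along the other axis.  Returns (bin_centers, profile, profile_mask);
    all-masked columns are masked (NaN).
    """
    axis = {"v1": 0, "v2": 1, 0: 0, 1: 1}[axis]
    in1, in2 = _bins_in_rect(fel, rectangle)
    if not in1.any() or not in2.any():
        raise ValueError(f"rectangle {rectangle} does not intersect the grid")
    sub_f = fel.F[np.ix_(in1, in2)]
    sub_mask = fel.mask[np.ix_(in1, in2)]
    transverse = 1 - axis
    with np.errstate(invalid="ignore"):
        valid = (~sub_mask).sum(axis=transverse)
        total = np.where(sub_mask, 0.0, sub_f).sum(axis=transverse)
    profile = np.full(valid.shape, np.nan)
    nonempty = valid > 0
    profile[nonempty] = total[nonempty] / valid[nonempty]
    centers = (fel.v1_centers[in1], fel.v2_centers[in2])[axis]
    return centers, profile, ~nonempty


def barrier_delta_delta_f(
    fel: FELGrid, region_a: Rect, region_b: Rect
) -> tuple[float, float]:
    """Barrier heights (F_saddle - F_a, F_saddle - F_b) between two basins.

    F_a and F_b are the minimum free energies inside each rectangle; the
    saddle is the minimax over 4-connected paths of unmasked bins from the
    minimum bin of one rectangle to the minimum bin of the other (masked
    bins are impassable).
    """
    starts = []
    for rect in (region_a, region_b):
        in1, in2 = _bins_in_rect(fel, rect)
        sub = np.where(fel.mask, np.nan, fel.F)[np.ix_(in1, in2)]
        if np.all(np.isnan(sub)):
            raise ValueError(f"rectangle {rect} contains no unmasked bins")
        flat = np.nanargmin(sub)
        i_local, j_local = np.unravel_index(flat, sub.shape)
        i = np.flatnonzero(in1)[i_local]
        j = np.flatnonzero(in2)[j_local]
        starts.append(((int(i), int(j)), float(sub[i_local, j_local])))
    (a_bin, f_a), (b_bin, f_b) = starts

    # minimax (widest-path) Dijkstra from a_bin to b_bin
    n1, n2 = fel.F.shape
    best = np.full((n1, n2), np.inf)
    best[a_bin] = f_a
    heap = [(f_a, a_bin)]
    while heap:
        d, (i, j) = heapq.heappop(heap)
        if (i, j) == b_bin:
            f_saddle = d
            break
        if d > best[i, j]:
            continue
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ni, nj = i + di, j + dj
            if not (0 <= ni < n1 and 0 <= nj < n2) or fel.mask[ni, nj]:
                continue
            nd = max(d, fel.F[ni, nj])
            if nd < best[ni, nj]:
                best[ni, nj] = nd
                heapq.heappush(heap, (nd, (ni, nj)))
    else:
        raise NoPathError(
            f"no unmasked 4-connected path between bins {a_bin} and {b_bin}"
        )
    return (f_saddle - f_a, f_saddle - f_b)


def export_fel_csv(fel: FELGrid, path) -> None:
    """Write the landscape as CSV rows (v1_center, v2_center, F, masked)."""
    import pandas as pd

    v1c, v2c = np.meshgrid(fel.v1_centers, fel.v2_centers, indexing="ij")
    pd.DataFrame(
        {
            "v1_center": v1c.ravel(),
            "v2_center": v2c.ravel(),
            "F": fel.F.ravel(),
            "masked": fel.mask.ravel().astype(int),
        }
    ).to_csv(path, index=False)
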
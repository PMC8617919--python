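"""Division of the CV plane into overlapping sampling regions and the
overlap-count weight stitching.

The (v1, v2) plane is tiled by disjoint axis-aligned "small areas"; each is
enlarged by a fixed margin on every edge interior to the domain to form its
"sampling region", so neighboring regions overlap by twice the margin along
the shared axis.  After per-region restrained sampling, the number of samples
each region places inside a shared overlap strip fixes the relative
log-weight of the pair, and a breadth-first propagation from a seed region
assigns every region an absolute log-weight W_i.

Sign convention: matching the weighted sample densities inside a strip,
e^{W_i} N_i = e^{W_j} N_j, requires W_j - W_i = ln(N_i / N_j).  This
density-matching convention is the default; the alternative sign
(ln N_j - ln N_i, ``convention="inverted"``) is kept as a documented option
but fails the analytic landscape-recovery property.
"""

from __future__ import annotations

import dataclasses
import math
from collections import deque
from typing import Iterable, Mapping, Sequence

import numpy as np

Rect = tuple[float, float, float, float]  # (v1_min, v1_max, v2_min, v2_max)


class UnusableEdgeError(ValueError):
    """Raised when a pairwise weight is requested with a zero overlap count."""


class DisconnectedRegionsError(ValueError):
    """Raised when weight propagation cannot link all populated regions."""

    def __init__(self, components: list[set[int]]):
        self.components = components
        super().__init__(
            "region graph is disconnected; components: "
            + ", ".join(sorted(str(sorted(c)) for c in components))
        )


def _rect_intersection(a: Rect, b: Rect) -> Rect | None:
    lo1, hi1 = max(a[0], b[0]), min(a[1], b[1])
    lo2, hi2 = max(a[2], b[2]), min(a[3], b[3])
    if lo1 > hi1 or lo2 > hi2:
        return None
    return (lo1, hi1, lo2, hi2)


def _in_rect(points: np.ndarray, rect: Rect) -> np.ndarray:
    p = np.atleast_2d(np.asarray(points, dtype=float))
    return (
        (p[:, 0] >= rect[0])
        & (p[:, 0] <= rect[1])
        & (p[:, 1] >= rect[2])
        & (p[:, 1] <= rect[3])
    )


@dataclasses.dataclass
class RegionGrid:
    """Small areas, their enlarged sampling regions, and adjacency."""

    small_areas: np.ndarray
    sampling_regions: np.ndarray
    margin: float
    domain: Rect
    adjacency: frozenset[tuple[int, int]]

    @property
    def n_regions(self) -> int:
        return len(self.small_areas)

    def are_adjacent(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in self.adjacency

    def overlap_rect(self, i: int, j: int) -> Rect | None:
        return _rect_intersection(
            tuple(self.sampling_regions[i]), tuple(self.sampling_regions[j])
        )

    def multiplicity_many(self, points: np.ndarray) -> np.ndarray:
        """Number of sampling regions covering each point."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        m = np.zeros(len(p), dtype=int)
        for rect in self.sampling_regions:
            m += _in_rect(p, tuple(rect)).astype(int)
        return m

    @classmethod
    def from_rectangles(
        cls,
        small_areas: Sequence[Rect],
        margin: float,
        domain: Rect | None = None,
    ) -> "RegionGrid":
        """Build a grid from an explicit small-area list (irregular layouts).

        Each sampling region is its small area extended by ``margin`` on
        every edge that does not lie on the domain hull.
        """
        areas = np.asarray(small_areas, dtype=float)
        if domain is None:
            domain = (
                float(areas[:, 0].min()),
                float(areas[:, 1].max()),
                float(areas[:, 2].min()),
                float(areas[:, 3].max()),
            )
        if margin < 0:
            raise ValueError("margin must be >= 0")
        eps = 1e-9
        regions = areas.copy()
        for r in regions:
            if r[0] > domain[0] + eps:
                r[0] -= margin
            if r[1] < domain[1] - eps:
                r[1] += margin
            if r[2] > domain[2] + eps:
                r[2] -= margin
            if r[3] < domain[3] - eps:
                r[3] += margin
        pairs = set()
        for i in range(len(regions)):
            for j in range(i + 1, len(regions)):
                if _rect_intersection(tuple(regions[i]), tuple(regions[j])) is not None:
                    pairs.add((i, j))
        return cls(
            small_areas=areas,
            sampling_regions=regions,
            margin=float(margin),
            domain=tuple(float(x) for x in domain),
            adjacency=frozenset(pairs),
        )


def partition_plane(
    domain: Rect, n_rows: int, n_cols: int, margin: float
) -> RegionGrid:
    """Tile a rectangular CV domain into an n_rows x n_cols grid of small
    areas (columns along v1, rows along v2, row-major region ids) with
    overlapping sampling regions.

    Adjacent sampling regions overlap by ``2 * margin`` along the shared
    axis; a margin of at least half a small-area width would swallow the
    neighbor and is rejected.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("need at least one row and one column")
    v1_lo, v1_hi, v2_lo, v2_hi = domain
    if not (v1_hi > v1_lo and v2_hi > v2_lo):
        raise ValueError(f"degenerate domain {domain}")
    w1 = (v1_hi - v1_lo) / n_cols
    w2 = (v2_hi - v2_lo) / n_rows
    if n_cols > 1 and margin >= w1 / 2:
        raise ValueError(f"margin {margin} >= half the small-area v1 width {w1 / 2}")
    if n_rows > 1 and margin >= w2 / 2:
        raise ValueError(f"margin {margin} >= half the small-area v2 width {w2 / 2}")
    areas = []
    for row in range(n_rows):
        for col in range(n_cols):
            areas.append(
                (
                    v1_lo + col * w1,
                    v1_lo + (col + 1) * w1,
                    v2_lo + row * w2,
                    v2_lo + (row + 1) * w2,
                )
            )
    return RegionGrid.from_rectangles(areas, margin, domain=domain)


@dataclasses.dataclass
class RegionSamples:
    """CV samples retained for one region after the exclusion rule."""

    region_id: int
    cv_table: np.ndarray  # (L, 2)

    def __post_init__(self) -> None:
        self.cv_table = np.asarray(self.cv_table, dtype=float).reshape(-1, 2)

    @property
    def L(self) -> int:
        return len(self.cv_table)


def clip_to_region(raw_cv_rows: np.ndarray, region_rect: Rect, region_id: int = 0) -> RegionSamples:
    """Apply the exclusion rule: drop samples outside the sampling rectangle.

    Samples with v_m < v_m^min or v_m > v_m^max in either CV dimension are
    excluded; boundary values are kept (the flat branch of the restraint
    includes equality).
    """
    rows = np.asarray(raw_cv_rows, dtype=float).reshape(-1, 2)
    if len(rows) == 0:
        return RegionSamples(region_id=region_id, cv_table=rows)
    keep = _in_rect(rows, region_rect)
    return RegionSamples(region_id=region_id, cv_table=rows[keep])


def count_overlap(
    samples_i: RegionSamples, samples_j: RegionSamples, grid: RegionGrid
) -> tuple[int, int]:
    """Counts (N_i, N_j) of each region's samples in the pair's overlap strip."""
    i, j = samples_i.region_id, samples_j.region_id
    if not grid.are_adjacent(i, j):
        raise ValueError(f"regions {i} and {j} are not adjacent")
    strip = grid.overlap_rect(i, j)
    if strip is None:
        return (0, 0)
    n_i = int(_in_rect(samples_i.cv_table, strip).sum()) if samples_i.L else 0
    n_j = int(_in_rect(samples_j.cv_table, strip).sum()) if samples_j.L else 0
    return (n_i, n_j)


def relative_weight(n_i: int, n_j: int, convention: str = "density") -> float:
    """Pairwise log-weight increment omega_ij such that W_j = W_i + omega_ij.

    With the default density-matching convention omega_ij = ln(N_i / N_j), so
    that e^{W_i} N_i = e^{W_j} N_j inside the strip.  ``convention="inverted"``
    flips the sign (ln N_j - ln N_i).
    """
    if n_i <= 0 or n_j <= 0:
        raise UnusableEdgeError(
            f"overlap counts must both be positive, got ({n_i}, {n_j})"
        )
    w = math.log(n_i) - math.log(n_j)
    if convention == "density":
        return w
    if convention == "inverted":
        return -w
    raise ValueError(f"unknown convention {convention!r}")


@dataclasses.dataclass
class WeightTable:
    """Per-region log-weights W_i with the seed fixed at W = 0."""

    W: np.ndarray
    linked: np.ndarray
    seed_region: int


def _usable_edges(
    overlap_counts: Mapping[tuple[int, int], tuple[int, int]]
) -> dict[tuple[int, int], tuple[int, int]]:
    return {
        (min(i, j), max(i, j)): (n_i, n_j) if i < j else (n_j, n_i)
        for (i, j), (n_i, n_j) in overlap_counts.items()
        if n_i > 0 and n_j > 0
    }


def choose_seed_region(
    grid: RegionGrid,
    overlap_counts: Mapping[tuple[int, int], tuple[int, int]],
    populated: Iterable[int] | None = None,
) -> int:
    """Region with the most usable overlap edges (ties: lowest index)."""
    if populated is None:
        populated = {r for pair in overlap_counts for r in pair}
    populated = set(populated)
    if not populated:
        raise ValueError("no populated regions")
    degree = {r: 0 for r in populated}
    for (i, j) in _usable_edges(overlap_counts):
        degree[i] += 1
        degree[j] += 1
    best = max(sorted(degree), key=lambda r: degree[r])
    return best


def propagate_weights(
    grid: RegionGrid,
    overlap_counts: Mapping[tuple[int, int], tuple[int, int]],
    seed_region: int | None = None,
    populated: Iterable[int] | None = None,
    convention: str = "density",
    method: str = "bfs",
) -> WeightTable:
    """Assign absolute log-weights W_i to all populated regions.

    ``method="bfs"`` (default) propagates W_j = W_i + omega_ij over a
    breadth-first spanning tree of usable edges starting from the seed, so
    each region is assigned exactly once.  ``method="lstsq"`` instead solves
    all usable edges simultaneously in least squares, which averages away
    cycle inconsistencies of noisy counts; both give identical results on
    cycle-consistent inputs.

    Regions never sampled are left at NaN and excluded from the connectivity
    requirement.  If the usable-edge graph does not connect all populated
    regions, :class:`DisconnectedRegionsError` lists the components.
    """
    if populated is None:
        populated = {r for pair in overlap_counts for r in pair}
    populated = set(populated)
    if seed_region is None:
        seed_region = choose_seed_region(grid, overlap_counts, populated)
    if seed_region not in populated:
        raise ValueError(f"seed region {seed_region} is not populated")
    edges = _usable_edges(overlap_counts)
    neighbors: dict[int, list[int]] = {r: [] for r in populated}
    for (i, j) in edges:
        neighbors[i].append(j)
        neighbors[j].append(i)

    # connectivity check over usable edges
    components: list[set[int]] = []
    seen: set[int] = set()
    for start in sorted(populated):
        if start in seen:
            continue
        comp = {start}
        queue = deque([start])
        while queue:
            u = queue.popleft()
            for w in neighbors[u]:
                if w not in comp:
                    comp.add(w)
                    queue.append(w)
        seen |= comp
        components.append(comp)
    if len(components) > 1:
        raise DisconnectedRegionsError(components)

    W = np.full(grid.n_regions, np.nan)
    linked = np.zeros(grid.n_regions, dtype=bool)

    if method == "bfs":
        W[seed_region] = 0.0
        linked[seed_region] = True
        queue = deque([seed_region])
        while queue:
            i = queue.popleft()
            for j in sorted(neighbors[i]):
                if linked[j]:
                    continue
                key = (min(i, j), max(i, j))
                n_a, n_b = edges[key]
                omega = relative_weight(n_a, n_b, convention)  # W_b - W_a
                W[j] = W[i] + (omega if i < j else -omega)
                linked[j] = True
                queue.append(j)
    elif method == "lstsq":
        order = sorted(populated)
        pos = {r: k for k, r in enumerate(order)}
        rows = []
        rhs = []
        for (i, j), (n_a, n_b) in edges.items():
            row = np.zeros(len(order))
            row[pos[j]] = 1.0
            row[pos[i]] = -1.0
            rows.append(row)
            rhs.append(relative_weight(n_a, n_b, convention))
        anchor = np.zeros(len(order))
        anchor[pos[seed_region]] = 1.0
        rows.append(anchor)
        rhs.append(0.0)
        sol, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
        sol = sol - sol[pos[seed_region]]
        for r, k in pos.items():
            W[r] = sol[k]
            linked[r] = True
    else:
        raise ValueError(f"unknown method {method!r}")

    return WeightTable(W=W, linked=linked, seed_region=seed_region)


def multiplicity(v, grid: RegionGrid) -> int:
    """Number of sampling regions whose rectangle contains the CV point v.

    Returns 0 (with no error) for a point outside every region; such points
    are excluded upstream by the clipping rule.
    """
    return int(grid.multiplicity_many(np.asarray(v, dtype=float).reshape(1, 2))[0])
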
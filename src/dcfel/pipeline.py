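"""End-to-end divide-and-conquer landscape pipeline on the toy model.

The demo reproduces the full workflow at desk scale:

1. a short unbiased run of the bead chain provides a structure ensemble;
2. fitted PCA of that ensemble defines the collective variables (v1, v2);
3. the thermally accessible CV domain is tiled into overlapping sampling
   regions;
4. each region that contains at least one presampled structure gets its own
   restrained Langevin run (regions with no starting structure are skipped);
5. retained samples are clipped to their region, overlap counts fix the
   relative weights, and the stitched landscape is assembled with the
   multiplicity correction;
6. optionally, an independent long unbiased run supplies the reference
   landscape for validation.

All stochastic stages draw their seeds from one root seed, so a run is fully
reproducible.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from dcfel.bias import FlatBottomRestraint
from dcfel.fel import FELGrid, assemble_fel
from dcfel.fitting import FitReference, PCABasis, build_pca_basis, make_fit_reference, project_many
from dcfel.regions import (
    RegionGrid,
    RegionSamples,
    WeightTable,
    clip_to_region,
    count_overlap,
    propagate_weights,
)
from dcfel.structure_io import AtomRecord, ConformationEnsemble
from dcfel.toy import ToyBeadModel, Trajectory, build_toy_model, langevin_run, reference_fel_oracle

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class DemoConfig:
    """Tunable knobs of the toy demonstration pipeline.

    The defaults are sized so the full pipeline (including the reference
    run) completes in a few minutes on one CPU while leaving every stage
    statistically meaningful: ~10^4 presample frames for the PCA basis,
    ~3x10^4 retained samples per region, and ~4x10^5 reference samples.
    """

    temperature_K: float = 300.0
    model_params: dict | None = None
    dt: float = 0.01
    friction: float = 1.0
    # presampling / PCA basis
    presample_steps: int = 300_000
    presample_save_every: int = 30
    presample_equil: int = 10_000
    domain_percentile: float = 0.5  # clip this much off each CV tail
    # region layout
    n_rows: int = 2
    n_cols: int = 3
    margin_frac: float = 0.25  # margin as a fraction of the smaller cell width
    # per-region sampling
    restraint_k: float = 2.0  # kcal/mol/A^2
    region_steps: int = 120_000
    region_save_every: int = 4
    region_equil: int = 4_000
    # landscape binning and reference
    bins_per_cell: int = 6
    reference_steps: int = 2_000_000
    reference_save_every: int = 5
    min_count_compare: int = 100

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")


@dataclasses.dataclass
class PipelineResult:
    model: ToyBeadModel
    basis: PCABasis
    ref: FitReference
    grid: RegionGrid
    region_samples: list[RegionSamples]
    skipped_regions: list[int]
    weights: WeightTable
    fel: FELGrid
    reference_fel: FELGrid | None
    mean_abs_df: float | None
    n_compared_bins: int
    trajectories: dict[int, Trajectory]


def _chain_ensemble(frames: np.ndarray, n_beads: int, label: str) -> ConformationEnsemble:
    atoms = [AtomRecord(i + 1, "GLY", "CA", "C", "A") for i in range(n_beads)]
    return ConformationEnsemble(models=frames, atoms=atoms, label=label)


def presample_basis(
    model: ToyBeadModel,
    start_coords: np.ndarray,
    config: DemoConfig,
    seed: int,
) -> tuple[PCABasis, FitReference, np.ndarray, np.ndarray]:
    """Unbiased presample and the PCA basis built from it.

    Returns (basis, fit reference, presample frames, presample CVs).  The fit
    reference is the first presampled frame with all beads as fit atoms.
    """
    traj = langevin_run(
        model,
        start_coords,
        restraint=None,
        n_steps=config.presample_steps,
        dt=config.dt,
        friction=config.friction,
        seed=seed,
        save_every=config.presample_save_every,
        n_equil=config.presample_equil,
    )
    ens = _chain_ensemble(traj.frames, model.n_beads, "presample")
    ref = make_fit_reference(ens, np.arange(model.n_beads))
    basis = build_pca_basis(ens, ref)
    cvs = project_many(traj.frames, basis, ref)
    return basis, ref, traj.frames, cvs


def domain_from_samples(cvs: np.ndarray, percentile: float) -> tuple[float, float, float, float]:
    """Axis-aligned CV domain covering the central mass of the presample."""
    lo1, hi1 = np.percentile(cvs[:, 0], [percentile, 100 - percentile])
    lo2, hi2 = np.percentile(cvs[:, 1], [percentile, 100 - percentile])
    return (float(lo1), float(hi1), float(lo2), float(hi2))


def sample_regions(
    model: ToyBeadModel,
    grid: RegionGrid,
    presample_frames: np.ndarray,
    presample_cvs: np.ndarray,
    basis: PCABasis,
    ref: FitReference,
    config: DemoConfig,
    seed: int,
) -> tuple[list[RegionSamples], list[int], dict[int, Trajectory]]:
    """Restrained Langevin run per populated region.

    A region's run starts from a presampled structure whose CV lies inside
    its sampling rectangle; regions with no such structure are skipped (the
    analogue of small areas holding no experimental model).  Samples are
    clipped to the sampling rectangle (the exclusion rule).
    """
    rng = np.random.default_rng(seed)
    region_samples: list[RegionSamples] = []
    skipped: list[int] = []
    trajectories: dict[int, Trajectory] = {}
    for i in range(grid.n_regions):
        rect = tuple(grid.sampling_regions[i])
        inside = np.flatnonzero(
            (presample_cvs[:, 0] >= rect[0])
            & (presample_cvs[:, 0] <= rect[1])
            & (presample_cvs[:, 1] >= rect[2])
            & (presample_cvs[:, 1] <= rect[3])
        )
        if len(inside) == 0:
            logger.info("region %d: no starting structure, skipped", i)
            skipped.append(i)
            continue
        start = presample_frames[rng.choice(inside)]
        restraint = FlatBottomRestraint(
            k=config.restraint_k,
            v_min=[rect[0], rect[2]],
            v_max=[rect[1], rect[3]],
        )
        traj = langevin_run(
            model,
            start,
            restraint=restraint,
            n_steps=config.region_steps,
            dt=config.dt,
            friction=config.friction,
            seed=int(rng.integers(2**31 - 1)),
            save_every=config.region_save_every,
            n_equil=config.region_equil,
            basis=basis,
            ref=ref,
        )
        trajectories[i] = traj
        samples = clip_to_region(traj.cv_series, rect, region_id=i)
        logger.info(
            "region %d: %d samples retained of %d", i, samples.L, len(traj.cv_series)
        )
        region_samples.append(samples)
    return region_samples, skipped, trajectories


def stitch(
    region_samples: list[RegionSamples],
    grid: RegionGrid,
    bins: tuple[np.ndarray, np.ndarray],
    temperature_K: float,
    convention: str = "density",
    method: str = "bfs",
) -> tuple[FELGrid, WeightTable]:
    """Overlap counts, weight propagation and landscape assembly."""
    by_id = {s.region_id: s for s in region_samples}
    counts = {}
    for (i, j) in sorted(grid.adjacency):
        if i in by_id and j in by_id:
            counts[(i, j)] = count_overlap(by_id[i], by_id[j], grid)
    weights = propagate_weights(
        grid, counts, populated=set(by_id), convention=convention, method=method
    )
    fel = assemble_fel(region_samples, weights, grid, bins, temperature_K)
    return fel, weights


def compare_fels(
    fel_a: FELGrid, fel_b: FELGrid, min_count: int = 100
) -> tuple[float, int]:
    """Mean |F_a - F_b| over mutually well-sampled bins.

    Bins enter the comparison when both landscapes are unmasked and both raw
    per-bin counts reach ``min_count``.  Free energies are defined up to a
    constant, so the mean offset over the compared bins is removed first.
    """
    if fel_a.F.shape != fel_b.F.shape:
        raise ValueError("landscapes must share the same binning")
    ok = ~fel_a.mask & ~fel_b.mask
    if fel_a.counts is not None:
        ok &= fel_a.counts >= min_count
    if fel_b.counts is not None:
        ok &= fel_b.counts >= min_count
    n = int(ok.sum())
    if n == 0:
        return float("nan"), 0
    diff = fel_a.F[ok] - fel_b.F[ok]
    diff = diff - diff.mean()
    return float(np.mean(np.abs(diff))), n


def run_demo(
    seed: int,
    config: DemoConfig | None = None,
    compute_reference: bool = True,
) -> PipelineResult:
    """Run the full divide-and-conquer pipeline on the toy model."""
    config = config or DemoConfig()
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(4)]

    params = dict(config.model_params or {})
    params.setdefault("temperature", config.temperature_K)
    model, start = build_toy_model(params, seed=seeds[0])

    basis, ref, frames, cvs = presample_basis(model, start, config, seeds[1])
    domain = domain_from_samples(cvs, config.domain_percentile)
    cell_w = min(
        (domain[1] - domain[0]) / config.n_cols,
        (domain[3] - domain[2]) / config.n_rows,
    )
    grid = partition = partition_from_config(domain, config, cell_w)
    region_samples, skipped, trajectories = sample_regions(
        model, grid, frames, cvs, basis, ref, config, seeds[2]
    )

    v1_edges = np.linspace(domain[0], domain[1], config.n_cols * config.bins_per_cell + 1)
    v2_edges = np.linspace(domain[2], domain[3], config.n_rows * config.bins_per_cell + 1)
    fel, weights = stitch(
        region_samples, grid, (v1_edges, v2_edges), config.temperature_K
    )

    reference = None
    mean_abs_df = None
    n_bins = 0
    if compute_reference:
        reference = reference_fel_oracle(
            model,
            (v1_edges, v2_edges),
            basis,
            ref,
            start_coords=start,
            n_steps=config.reference_steps,
            dt=config.dt,
            friction=config.friction,
            seed=seeds[3],
            save_every=config.reference_save_every,
        )
        mean_abs_df, n_bins = compare_fels(fel, reference, config.min_count_compare)

    return PipelineResult(
        model=model,
        basis=basis,
        ref=ref,
        grid=grid,
        region_samples=region_samples,
        skipped_regions=skipped,
        weights=weights,
        fel=fel,
        reference_fel=reference,
        mean_abs_df=mean_abs_df,
        n_compared_bins=n_bins,
        trajectories=trajectories,
    )


def partition_from_config(domain, config: DemoConfig, cell_w: float) -> RegionGrid:
    from dcfel.regions import partition_plane

    margin = config.margin_frac * cell_w
    return partition_plane(domain, config.n_rows, config.n_cols, margin)
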
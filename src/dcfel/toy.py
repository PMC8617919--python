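"""Synthetic bead-chain sampler standing in for per-region MD runs.

The model is a chain of beads with harmonic bonds plus a quartic double-well
"mode potential" acting on the end-to-end distance d = |r_last - r_first|:

    W(d) = h * ((d - d_c)^2 - delta^2)^2 / delta^4 + tilt * (d - d_c)

with minima near d_c +/- delta and a barrier of height ~h between them (an
optional linear tilt makes the wells inequivalent by a known energy gap).
The two metastable states — compact and extended chain — separate along the
first principal component of a pre-sampled ensemble, so the model exercises
the whole landscape pipeline: fitted-PCA collective variables, flat-bottom
region restraints, overlap-weight stitching.

Sampling uses overdamped Langevin (Euler-Maruyama) dynamics,

    x <- x + (dt / gamma) F(x) + sqrt(2 kT dt / gamma) xi,

whose stationary distribution is the Boltzmann distribution of the model
potential (up to O(dt) discretization bias).  Time is in reduced units; only
the ratio dt/gamma matters for the sampled distribution.

Two independent ground-truth routes are provided: a long unbiased run
histogrammed on the CV grid (:func:`reference_fel_oracle`) and direct
Boltzmann quadrature of one-dimensional potentials
(:func:`boltzmann_profile_1d`).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from dcfel.bias import FlatBottomRestraint, flat_bottom_force
from dcfel.constants import thermal_energy
from dcfel.fel import FELGrid, fel_from_weighted_counts
from dcfel.fitting import FitReference, PCABasis, project_many


class IntegrationError(RuntimeError):
    """Raised when a trajectory blows up numerically."""


@dataclasses.dataclass(frozen=True)
class DoubleWell:
    """Quartic double well on an internal coordinate, plus optional tilt."""

    center: float = 8.0
    half_separation: float = 3.0
    barrier_height: float = 1.8  # kcal/mol, ~3 kT at 300 K
    tilt: float = 0.0  # kcal/mol/A

    def __post_init__(self) -> None:
        if self.barrier_height < 0:
            raise ValueError(
                "barrier_height must be >= 0 (negative values make the "
                "potential unbounded below)"
            )
        if self.half_separation <= 0:
            raise ValueError("half_separation must be positive")

    def energy(self, d: np.ndarray | float):
        x = np.asarray(d, dtype=float) - self.center
        quartic = self.barrier_height * (x**2 - self.half_separation**2) ** 2
        return quartic / self.half_separation**4 + self.tilt * x

    def derivative(self, d: np.ndarray | float):
        x = np.asarray(d, dtype=float) - self.center
        return (
            4.0
            * self.barrier_height
            * (x**2 - self.half_separation**2)
            * x
            / self.half_separation**4
            + self.tilt
        )

    @property
    def minima(self) -> tuple[float, float]:
        """Well positions of the untilted quartic."""
        return (
            self.center - self.half_separation,
            self.center + self.half_separation,
        )


@dataclasses.dataclass(frozen=True)
class ToyBeadModel:
    """Harmonic bead chain with a double-well end-to-end mode potential.

    ``stiff_k``/``stiff_length`` add harmonic springs between second
    neighbors, giving the chain bending stiffness so that the extension mode
    dominates the shape covariance instead of drowning among floppy
    transverse modes.
    """

    n_beads: int = 10
    bond_k: float = 5.0  # kcal/mol/A^2
    bond_length: float = 2.0  # A
    mode_potential: DoubleWell = dataclasses.field(default_factory=DoubleWell)
    temperature: float = 300.0  # K
    stiff_k: float = 1.5  # kcal/mol/A^2, second-neighbor springs
    stiff_length: float = 3.0  # A

    def __post_init__(self) -> None:
        if self.n_beads < 4:
            raise ValueError(f"need at least 4 beads, got {self.n_beads}")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.bond_k <= 0:
            raise ValueError("bond_k must be positive")
        if self.stiff_k < 0:
            raise ValueError("stiff_k must be >= 0")

    @property
    def kT(self) -> float:
        return thermal_energy(self.temperature)

    def end_to_end(self, coords: np.ndarray) -> float:
        return float(np.linalg.norm(coords[-1] - coords[0]))

    @staticmethod
    def _spring_pair(coords, sep, k, length, f=None):
        """Energy (and accumulated force) of harmonic springs between beads
        ``sep`` apart."""
        vec = coords[sep:] - coords[:-sep]
        dist = np.linalg.norm(vec, axis=1)
        if f is not None:
            pulls = (k * (dist - length) / dist)[:, None] * vec
            f[:-sep] += pulls
            f[sep:] -= pulls
        return 0.5 * k * np.sum((dist - length) ** 2)

    def energy(self, coords: np.ndarray) -> float:
        e = self._spring_pair(coords, 1, self.bond_k, self.bond_length)
        if self.stiff_k > 0:
            e += self._spring_pair(coords, 2, self.stiff_k, self.stiff_length)
        return float(e + self.mode_potential.energy(self.end_to_end(coords)))

    def force(self, coords: np.ndarray) -> np.ndarray:
        f = np.zeros_like(coords)
        self._spring_pair(coords, 1, self.bond_k, self.bond_length, f)
        if self.stiff_k > 0:
            self._spring_pair(coords, 2, self.stiff_k, self.stiff_length, f)
        dvec = coords[-1] - coords[0]
        d = np.linalg.norm(dvec)
        dw = self.mode_potential.derivative(d)
        u = dvec / d
        f[0] += dw * u
        f[-1] -= dw * u
        return f


def build_toy_model(
    params: dict | None = None, seed: int = 0
) -> tuple[ToyBeadModel, np.ndarray]:
    """Construct the default toy model and a starting structure near the
    compact (inner) well.

    The chain is laid out as a zig-zag whose opening angle places the
    end-to-end distance near the inner minimum, plus a small seeded jitter
    that breaks planarity.  Construction is deterministic given the seed.
    """
    model = ToyBeadModel(**(params or {}))
    n = model.n_beads
    b0 = model.bond_length
    target = model.mode_potential.minima[0]
    span = (n - 1) * b0
    cos_theta = min(0.95, max(0.05, target / span))
    sin_theta = float(np.sqrt(1.0 - cos_theta**2))
    coords = np.zeros((n, 3))
    for i in range(1, n):
        step = np.array([cos_theta, sin_theta if i % 2 else -sin_theta, 0.0]) * b0
        coords[i] = coords[i - 1] + step
    rng = np.random.default_rng(seed)
    coords += rng.normal(scale=0.05, size=coords.shape)
    return model, coords


@dataclasses.dataclass
class Trajectory:
    """Saved frames and CV values of one Langevin run."""

    frames: np.ndarray
    cv_series: np.ndarray
    step_indices: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.cv_series):
            raise ValueError("frames and cv_series must be the same length")


_BLOWUP_LIMIT = 1.0e4  # A


def langevin_run(
    model,
    start_coords: np.ndarray,
    restraint: FlatBottomRestraint | None,
    n_steps: int,
    dt: float = 0.01,
    friction: float = 1.0,
    seed: int = 0,
    save_every: int = 10,
    n_equil: int = 0,
    basis: PCABasis | None = None,
    ref: FitReference | None = None,
) -> Trajectory:
    """Overdamped Langevin sampling of ``model`` (duck-typed: needs
    ``force(coords)`` and ``kT``), optionally under a flat-bottom CV
    restraint.

    CV values are recorded every ``save_every`` steps after ``n_equil``
    equilibration steps (a restraint requires ``basis``; otherwise CVs are
    recorded only when a basis is supplied).  The default dt = 0.01 with
    friction = 1 keeps dt * k_max / gamma ~ 0.1 for the default model
    stiffness.  Identical inputs and seed give identical trajectories.
    """
    coords = np.array(start_coords, dtype=float)
    if restraint is not None and basis is None:
        raise ValueError("a restraint requires a PCA basis for the CVs")
    rng = np.random.default_rng(seed)
    kT = model.kT
    noise_scale = np.sqrt(2.0 * kT * dt / friction)
    mobility = dt / friction

    frames = []
    cvs = []
    step_idx = []
    chunk = 512
    total = n_equil + n_steps
    for chunk_start in range(0, total, chunk):
        n_chunk = min(chunk, total - chunk_start)
        noise = rng.normal(size=(n_chunk, *coords.shape))
        for s in range(n_chunk):
            step = chunk_start + s
            force = model.force(coords)
            v = None
            if restraint is not None:
                bias, v = flat_bottom_force(
                    coords, basis, ref, restraint, return_cv=True
                )
                force = force + bias
            coords = coords + mobility * force + noise_scale * noise[s]
            if step >= n_equil and (step - n_equil) % save_every == 0:
                frames.append(coords.copy())
                if basis is not None:
                    if v is None:
                        v = project_many(coords[None], basis, ref)[0]
                    cvs.append(np.asarray(v, dtype=float))
                else:
                    cvs.append(np.full(2, np.nan))
                step_idx.append(step)
        if not np.all(np.isfinite(coords)) or np.max(np.abs(coords)) > _BLOWUP_LIMIT:
            raise IntegrationError(
                f"coordinate exceeded {_BLOWUP_LIMIT} A by step "
                f"{chunk_start + n_chunk}; reduce dt"
            )
    return Trajectory(
        frames=np.array(frames),
        cv_series=np.array(cvs),
        step_indices=np.array(step_idx, dtype=int),
        seed=seed,
    )


def reference_fel_oracle(
    model,
    bins: tuple[np.ndarray, np.ndarray],
    basis: PCABasis,
    ref: FitReference | None = None,
    start_coords: np.ndarray | None = None,
    n_steps: int = 2_000_000,
    dt: float = 0.01,
    friction: float = 1.0,
    seed: int = 12345,
    save_every: int = 5,
    n_equil: int = 20_000,
    min_count: int = 1,
) -> FELGrid:
    """Ground-truth FEL from one long *unbiased* run on the same CV grid.

    F_ref = -kT ln rho(v1, v2), min-shifted to zero.  Bins receiving fewer
    than ``min_count`` samples are masked (a warning is issued if that masks
    bins inside the requested grid that received any samples at all).
    """
    if start_coords is None:
        _, start_coords = build_toy_model(
            {"n_beads": model.n_beads} if hasattr(model, "n_beads") else None, seed=seed
        )
    traj = langevin_run(
        model,
        start_coords,
        restraint=None,
        n_steps=n_steps,
        dt=dt,
        friction=friction,
        seed=seed,
        save_every=save_every,
        n_equil=n_equil,
        basis=basis,
        ref=ref,
    )
    v1_edges, v2_edges = (np.asarray(b, dtype=float) for b in bins)
    h, _, _ = np.histogram2d(
        traj.cv_series[:, 0], traj.cv_series[:, 1], bins=(v1_edges, v2_edges)
    )
    thin = (h > 0) & (h < min_count)
    if thin.any():
        warnings.warn(
            f"{int(thin.sum())} bins had fewer than {min_count} samples and "
            "were masked",
            stacklevel=2,
        )
    counts = h.copy()
    h = np.where(h >= min_count, h, 0.0)
    return fel_from_weighted_counts(h, v1_edges, v2_edges, model.kT, counts=counts)


def boltzmann_profile_1d(
    potential, grid: np.ndarray, kT: float, n_sub: int = 32
) -> np.ndarray:
    """Free-energy profile from direct quadrature of a 1-D potential.

    For bin edges ``grid``, integrates exp(-U/kT) over each bin (composite
    midpoint rule with ``n_sub`` subdivisions) and returns
    F = -kT ln(integral), min-shifted to zero.  This is the closed-form
    oracle for potentials defined directly on the binned coordinate.
    """
    grid = np.asarray(grid, dtype=float)
    F = np.empty(len(grid) - 1)
    for b in range(len(grid) - 1):
        xs = np.linspace(grid[b], grid[b + 1], n_sub, endpoint=False)
        xs = xs + 0.5 * (grid[b + 1] - grid[b]) / n_sub
        F[b] = -kT * np.log(np.mean(np.exp(-np.asarray(potential(xs)) / kT)))
    return F - F.min()


def export_cv_tables(trajectories: dict[int, Trajectory], path) -> None:
    """Write per-region CV samples as CSV (region_id, step, v1, v2).

    This is the exchange format the stitching stage consumes, so tables from
    a real MD engine can be substituted for the toy sampler's output.
    """
    import pandas as pd

    rows = []
    for region_id, traj in trajectories.items():
        frame = pd.DataFrame(
            {
                "region_id": region_id,
                "step": traj.step_indices,
                "v1": traj.cv_series[:, 0],
                "v2": traj.cv_series[:, 1],
            }
        )
        rows.append(frame)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def export_trajectory_pdb(traj: Trajectory, path, label: str = "toy-trajectory"):
    """Write saved frames as a multi-model PDB of dummy CA beads.

    Lets standard structure viewers and the package's own ensemble analyses
    consume toy trajectories.
    """
    from dcfel.structure_io import AtomRecord, ConformationEnsemble, write_pdb_models

    n_beads = traj.frames.shape[1]
    atoms = [AtomRecord(i + 1, "GLY", "CA", "C", "A") for i in range(n_beads)]
    ens = ConformationEnsemble(models=traj.frames, atoms=atoms, label=label)
    return write_pdb_models(ens, path, remarks=[f"seed {traj.seed}"])


def load_cv_tables(path) -> dict[int, np.ndarray]:
    """Read a (region_id, step, v1, v2) CSV back into per-region CV arrays."""
    import pandas as pd

    table = pd.read_csv(path)
    return {
        int(region_id): group[["v1", "v2"]].to_numpy()
        for region_id, group in table.groupby("region_id")
    }
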
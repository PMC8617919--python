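"""Bead-chain sampler: determinism, thermodynamic sanity, oracles."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from dcfel.bias import FlatBottomRestraint, flat_bottom_energy
from dcfel.constants import thermal_energy
from dcfel.fitting import project_many
from dcfel.toy import (
    DoubleWell,
    IntegrationError,
    ToyBeadModel,
    boltzmann_profile_1d,
    build_toy_model,
    langevin_run,
    reference_fel_oracle,
)


@dataclasses.dataclass
class HarmonicTethers:
    """Independent isotropic tethers: U = k/2 sum_i |r_i|^2 (test system)."""

    k: float
    kT: float

    def force(self, coords):
        return -self.k * coords


class TestBuildToyModel:
    def test_deterministic_given_seed(self):
        m1, c1 = build_toy_model(seed=5)
        m2, c2 = build_toy_model(seed=5)
        assert m1 == m2
        np.testing.assert_array_equal(c1, c2)
        _, c3 = build_toy_model(seed=6)
        assert not np.array_equal(c1, c3)

    def test_too_few_beads_rejected(self):
        with pytest.raises(ValueError):
            build_toy_model({"n_beads": 2})

    def test_unbounded_potential_rejected(self):
        with pytest.raises(ValueError):
            DoubleWell(barrier_height=-1.0)

    def test_start_near_inner_well(self):
        model, coords = build_toy_model(seed=0)
        d = model.end_to_end(coords)
        inner = model.mode_potential.minima[0]
        assert abs(d - inner) < 1.5

    def test_wells_separate_along_first_mode(self, toy_setup):
        """The two metastable states project far apart on v1 and barely on
        v2 (the first PCA mode is the extension mode)."""
        model, start, basis, ref, traj = toy_setup
        d = np.linalg.norm(traj.frames[:, -1] - traj.frames[:, 0], axis=1)
        cv = project_many(traj.frames, basis, ref)
        compact = cv[d < model.mode_potential.center]
        extended = cv[d > model.mode_potential.center]
        assert len(compact) > 50 and len(extended) > 50
        sep = np.abs(compact.mean(axis=0) - extended.mean(axis=0))
        assert sep[0] > 3.0  # wells far apart on v1 (angstroms)
        assert sep[0] > 2.0 * sep[1]  # and mostly along v1

    def test_force_is_minus_energy_gradient(self):
        model, coords = build_toy_model(seed=2)
        f = model.force(coords)
        h = 1e-6
        rng = np.random.default_rng(0)
        for _ in range(10):
            i, a = rng.integers(model.n_beads), rng.integers(3)
            cp = coords.copy()
            cp[i, a] += h
            cm = coords.copy()
            cm[i, a] -= h
            fd = (model.energy(cp) - model.energy(cm)) / (2 * h)
            assert f[i, a] == pytest.approx(-fd, abs=1e-5)


class TestLangevinRun:
    def test_deterministic_given_seed(self):
        model, coords = build_toy_model(seed=1)
        t1 = langevin_run(model, coords, None, n_steps=2000, seed=9, save_every=100)
        t2 = langevin_run(model, coords, None, n_steps=2000, seed=9, save_every=100)
        np.testing.assert_array_equal(t1.frames, t2.frames)

    def test_equipartition_in_harmonic_well(self):
        """Stationary coordinate variance in an isotropic harmonic well is
        kT/k (closed-form equipartition)."""
        k, kT = 2.0, thermal_energy(300.0)
        system = HarmonicTethers(k=k, kT=kT)
        start = np.zeros((4, 3))
        traj = langevin_run(system, start, None, n_steps=300_000, dt=0.01,
                            seed=17, save_every=10, n_equil=5_000)
        var = traj.frames.reshape(-1, 12).var(axis=0).mean()
        assert var == pytest.approx(kT / k, rel=0.05)

    def test_low_temperature_descends_to_local_minimum(self):
        model, coords = build_toy_model({"temperature": 0.05}, seed=3)
        traj = langevin_run(model, coords, None, n_steps=20_000, seed=4,
                            save_every=20_000 // 2)
        final = traj.frames[-1]
        # near-zero force and end-to-end distance at the nearest well
        assert np.abs(model.force(final)).max() < 0.2
        d = model.end_to_end(final)
        assert d == pytest.approx(model.mode_potential.minima[0], abs=0.3)

    def test_restraint_confines_samples(self, toy_setup):
        """Wall penetration beyond 3 sqrt(kT/k) is rare (< 1%)."""
        model, start, basis, ref, traj = toy_setup
        v0 = project_many(start[None], basis, ref)[0]
        k = 2.0
        restraint = FlatBottomRestraint(k=k, v_min=v0 - 1.0, v_max=v0 + 1.0)
        run = langevin_run(model, start, restraint, n_steps=40_000, seed=19,
                           save_every=4, n_equil=2_000, basis=basis, ref=ref)
        delta = 3.0 * np.sqrt(model.kT / k)
        inside = np.all(
            (run.cv_series >= restraint.v_min - delta)
            & (run.cv_series <= restraint.v_max + delta),
            axis=1,
        )
        assert inside.mean() >= 0.99

    def test_blowup_raises_integration_error(self):
        model, coords = build_toy_model(seed=1)
        with pytest.raises(IntegrationError, match="step"):
            langevin_run(model, coords, None, n_steps=5_000, dt=5.0, seed=2)

    def test_bond_length_distribution_matches_boltzmann(self):
        """Detailed balance: with the mode potential switched off, each bond
        vector is independent with density ~ b^2 exp(-k(b-b0)^2 / 2kT);
        a chi-square test against quadrature must not reject at 1%.

        A small time step keeps the Euler-Maruyama discretization bias well
        below the test's statistical resolution."""
        well = DoubleWell(barrier_height=0.0, tilt=0.0)
        model = ToyBeadModel(mode_potential=well, stiff_k=0.0)
        _, coords = build_toy_model(seed=0)
        traj = langevin_run(model, coords, None, n_steps=400_000, dt=0.002,
                            seed=23, save_every=400, n_equil=20_000)
        bonds = np.linalg.norm(np.diff(traj.frames, axis=1), axis=2).ravel()
        kT = model.kT
        # bin edges wide enough to cover essentially all mass
        edges = np.linspace(0.6, 3.4, 11)
        inside = (bonds >= edges[0]) & (bonds <= edges[-1])
        assert inside.mean() > 0.995
        obs, _ = np.histogram(bonds[inside], bins=edges)

        def density(b):
            return b**2 * np.exp(-0.5 * model.bond_k * (b - model.bond_length) ** 2 / kT)

        probs = np.empty(len(edges) - 1)
        for i in range(len(edges) - 1):
            xs = np.linspace(edges[i], edges[i + 1], 200)
            probs[i] = np.trapezoid(density(xs), xs)
        probs /= probs.sum()
        chi2, p = stats.chisquare(obs, probs * obs.sum())
        assert p > 0.01

    def test_restrained_run_reweights_to_unbiased_density(self, toy_setup):
        """Multiplying restrained-run histogram weights by exp(+phi/kT)
        recovers the unbiased CV density inside well-sampled bins."""
        model, start, basis, ref, traj = toy_setup
        cv = project_many(traj.frames, basis, ref)
        vc = np.median(cv, axis=0)  # a well-populated CV location
        start_frame = traj.frames[np.argmin(np.abs(cv[:, 0] - vc[0]))]
        restraint = FlatBottomRestraint(
            k=2.0, v_min=vc + np.array([-1.5, -30.0]), v_max=vc + np.array([1.5, 30.0])
        )
        run = langevin_run(model, start_frame, restraint, n_steps=80_000, seed=29,
                           save_every=4, n_equil=4_000, basis=basis, ref=ref)
        phi = np.array([flat_bottom_energy(v, restraint) for v in run.cv_series])
        w = np.exp(phi / model.kT)
        edges = np.linspace(vc[0] - 1.2, vc[0] + 1.2, 7)
        h_biased, _ = np.histogram(run.cv_series[:, 0], bins=edges, weights=w)
        unbiased = langevin_run(model, start_frame, None, n_steps=160_000, seed=31,
                                save_every=4, n_equil=4_000, basis=basis, ref=ref)
        h_ref, _ = np.histogram(unbiased.cv_series[:, 0], bins=edges)
        ok = (h_biased > 200) & (h_ref > 200)
        assert ok.sum() >= 4
        f_b = -model.kT * np.log(h_biased[ok] / h_biased[ok].sum())
        f_r = -model.kT * np.log(h_ref[ok] / h_ref[ok].sum())
        diff = f_b - f_r
        diff -= diff.mean()
        assert np.abs(diff).max() < 0.15


def test_trajectory_pdb_round_trip(tmp_path, toy_setup):
    from dcfel.structure_io import read_pdb_ensemble
    from dcfel.toy import Trajectory, export_trajectory_pdb

    model, start, basis, ref, traj = toy_setup
    small = Trajectory(
        frames=traj.frames[:4].round(3), cv_series=traj.cv_series[:4],
        step_indices=traj.step_indices[:4], seed=traj.seed)
    path = export_trajectory_pdb(small, tmp_path / "traj.pdb")
    back = read_pdb_ensemble(path)
    assert back.n_models == 4
    np.testing.assert_allclose(back.models, small.frames, atol=1e-3)


class TestQuadratureOracles:
    def test_symmetric_double_well_equal_minima(self):
        well = DoubleWell(center=0.0, half_separation=2.0, barrier_height=2.0)
        kT = thermal_energy(300.0)
        edges = np.linspace(-4.0, 4.0, 81)
        F = boltzmann_profile_1d(well.energy, edges, kT)
        centers = 0.5 * (edges[:-1] + edges[1:])
        f_left = F[centers < 0].min()
        f_right = F[centers > 0].min()
        assert f_left == pytest.approx(f_right, abs=1e-10)

    def test_equal_width_wells_recover_energy_gap(self):
        """Two harmonic wells of equal curvature separated by a known energy
        gap dU give basin dF = dU from quadrature."""
        kT = thermal_energy(300.0)
        dU = 0.8
        k_well = 8.0

        def potential(x):
            x = np.asarray(x)
            left = 0.5 * k_well * (x + 2.0) ** 2
            right = 0.5 * k_well * (x - 2.0) ** 2 + dU
            return np.minimum(left, right)

        edges = np.linspace(-4.0, 4.0, 161)
        F = boltzmann_profile_1d(potential, edges, kT)
        centers = 0.5 * (edges[:-1] + edges[1:])
        d_basin = F[centers > 0].min() - F[centers < 0].min()
        assert d_basin == pytest.approx(dU, abs=0.02)

    def test_gaussian_well_gives_quadratic_profile(self):
        kT = thermal_energy(300.0)
        k_well = 3.0
        edges = np.linspace(-1.5, 1.5, 61)

        def potential(x):
            return 0.5 * k_well * np.asarray(x) ** 2

        F = boltzmann_profile_1d(potential, edges, kT)
        centers = 0.5 * (edges[:-1] + edges[1:])
        expected = 0.5 * k_well * centers**2
        expected -= expected.min()
        np.testing.assert_allclose(F, expected, atol=0.02)


class TestReferenceFelOracle:
    def test_two_wells_and_masked_thin_bins(self, toy_setup):
        model, start, basis, ref, traj = toy_setup
        cv = project_many(traj.frames, basis, ref)
        v1_edges = np.linspace(np.percentile(cv[:, 0], 1), np.percentile(cv[:, 0], 99), 13)
        v2_edges = np.linspace(np.percentile(cv[:, 1], 1), np.percentile(cv[:, 1], 99), 7)
        fel = reference_fel_oracle(
            model, (v1_edges, v2_edges), basis, ref, start_coords=start,
            n_steps=150_000, seed=37, save_every=10, n_equil=5_000, min_count=5)
        assert np.nanmin(fel.F[~fel.mask]) == 0.0
        # landscape is bimodal along v1: two separated populated minima
        profile = np.nanmin(np.where(fel.mask, np.nan, fel.F), axis=1)
        finite = np.isfinite(profile)
        assert finite.sum() >= 8
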
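"""Shared fixtures: synthetic ensembles and a presampled toy-model basis."""

import numpy as np
import pytest

from dcfel.structure_io import AtomRecord, ConformationEnsemble
from dcfel.fitting import build_pca_basis, make_fit_reference
from dcfel.toy import build_toy_model, langevin_run


def chain_atoms(n, atom_name="CA", res_name="GLY"):
    return [AtomRecord(i + 1, res_name, atom_name, "C", "A") for i in range(n)]


@pytest.fixture(scope="session")
def random_ensemble():
    """12 random 8-atom conformers with a 5-atom fit selection."""
    rng = np.random.default_rng(42)
    n_atoms = 8
    models = rng.normal(scale=2.0, size=(12, n_atoms, 3))
    models += np.arange(n_atoms)[None, :, None] * 2.0
    ens = ConformationEnsemble(models=models, atoms=chain_atoms(n_atoms))
    fit_idx = np.arange(5)
    ref = make_fit_reference(ens, fit_idx)
    basis = build_pca_basis(ens, ref)
    return ens, ref, basis


@pytest.fixture(scope="session")
def toy_setup():
    """Toy bead model plus a PCA basis from a short unbiased presample."""
    model, start = build_toy_model(seed=3)
    traj = langevin_run(
        model, start, restraint=None, n_steps=160_000, seed=11,
        save_every=20, n_equil=4_000,
    )
    ens = ConformationEnsemble(models=traj.frames, atoms=chain_atoms(model.n_beads))
    ref = make_fit_reference(ens, np.arange(model.n_beads))
    basis = build_pca_basis(ens, ref)
    return model, start, basis, ref, traj
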
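"""Rigid-body superposition and the PCA collective-variable basis.

Every conformer is least-squares fitted to a fixed reference sub-structure
(e.g. the Calpha atoms of one domain of the first NMR model): with fit-atom
centroid Q of the conformer and P of the reference, the cross-covariance

    A_ab = sum_nu (r_nu - Q)_a (s_nu - P)_b

determines the optimal proper rotation R, and every atom is mapped to
r' = R (r - Q).  Principal component analysis of the fitted coordinates over
the ensemble yields eigenvectors c_n and eigenvalues lambda_n of the
covariance matrix; the collective variables are the projections
v_n = c_n . (X' - <X'>).

The closed form R = (A^T A)^{1/2} A^{-1} is valid when det(A) > 0; the
implementation uses the SVD construction with a determinant correction so
that reflected or nearly singular inputs still produce a proper rotation.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from dcfel.structure_io import ConformationEnsemble


class DegenerateFitError(ValueError):
    """Raised when the fit-atom geometry does not determine a rotation."""


@dataclasses.dataclass
class FitReference:
    """Fixed reference sub-structure used for superposition.

    ``ref_coords`` are the reference fit-atom positions s_nu (in angstroms),
    ``fit_indices`` the positions of those atoms in the full atom table, and
    ``P`` their centroid.
    """

    ref_coords: np.ndarray
    fit_indices: np.ndarray

    def __post_init__(self) -> None:
        self.ref_coords = np.asarray(self.ref_coords, dtype=float)
        self.fit_indices = np.asarray(self.fit_indices, dtype=int)
        if len(self.fit_indices) < 3:
            raise DegenerateFitError(
                f"need at least 3 fit atoms, got {len(self.fit_indices)}"
            )
        if self.ref_coords.shape != (len(self.fit_indices), 3):
            raise ValueError("ref_coords must be (n_fit, 3)")

    @property
    def P(self) -> np.ndarray:
        return self.ref_coords.mean(axis=0)

    @property
    def centered(self) -> np.ndarray:
        """Reference fit atoms relative to their centroid, s_nu - P."""
        return self.ref_coords - self.P


def make_fit_reference(
    ens: ConformationEnsemble,
    fit_indices: np.ndarray,
    model_index: int = 0,
) -> FitReference:
    """Build a :class:`FitReference` from one model of an ensemble."""
    return FitReference(
        ref_coords=ens.models[model_index][fit_indices],
        fit_indices=fit_indices,
    )


@dataclasses.dataclass
class FitResult:
    """Result of superposing one conformer onto the reference."""

    R: np.ndarray
    Q: np.ndarray
    fitted_coords: np.ndarray


def cross_covariance(model_fit_coords: np.ndarray, ref: FitReference) -> np.ndarray:
    """3x3 cross-covariance A between a conformer's fit atoms and the reference."""
    r = np.asarray(model_fit_coords, dtype=float)
    if r.shape != ref.ref_coords.shape:
        raise ValueError(
            f"fit-atom count mismatch: {r.shape[0]} vs {ref.ref_coords.shape[0]}"
        )
    if r.shape[0] < 3:
        raise DegenerateFitError("need at least 3 fit atoms")
    x = r - r.mean(axis=0)
    return x.T @ ref.centered


def optimal_rotation(A: np.ndarray, rcond: float = 1e-9) -> np.ndarray:
    """Proper rotation minimizing the fit-atom RMSD, from the 3x3 matrix A.

    Computed as R = V diag(1, 1, det(V U^T)) U^T with A = U S V^T, which
    equals (A^T A)^{1/2} A^{-1} whenever det(A) > 0 and remains a proper
    rotation otherwise.
    """
    A = np.asarray(A, dtype=float)
    if A.shape != (3, 3):
        raise ValueError("A must be 3x3")
    U, s, Vt = np.linalg.svd(A)
    if s[1] <= rcond * max(s[0], 1.0):
        raise DegenerateFitError(
            "fit atoms are (near-)collinear: rotation is not determined"
        )
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d if d != 0 else 1.0])
    return Vt.T @ D @ U.T


def fit_model(model_coords: np.ndarray, ref: FitReference) -> FitResult:
    """Superpose a full conformer onto the reference.

    The fit atoms alone define the centroid Q and rotation R; the map
    r' = R (r - Q) is then applied to every atom.
    """
    model_coords = np.asarray(model_coords, dtype=float)
    fit = model_coords[ref.fit_indices]
    Q = fit.mean(axis=0)
    R = optimal_rotation(cross_covariance(fit, ref))
    fitted = (model_coords - Q) @ R.T
    return FitResult(R=R, Q=Q, fitted_coords=fitted)


@dataclasses.dataclass
class PCABasis:
    """PCA of fitted coordinates: modes c_n and variances lambda_n.

    ``mean_coords`` is the ensemble mean of the fitted coordinates as a 3N
    vector; ``eigenvectors`` has one orthonormal 3N row per mode, sorted by
    descending eigenvalue; ``eigenvalues`` are in A^2.
    """

    mean_coords: np.ndarray
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    fit_reference: FitReference

    def __post_init__(self) -> None:
        self.mean_coords = np.asarray(self.mean_coords, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)

    @property
    def n_components(self) -> int:
        return self.eigenvectors.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.mean_coords.size // 3


def _fix_signs(eigenvectors: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude coordinate of each mode positive."""
    out = eigenvectors.copy()
    for row in out:
        k = int(np.argmax(np.abs(row)))
        if row[k] < 0:
            row *= -1.0
    return out


def build_pca_basis(ens: ConformationEnsemble, ref: FitReference) -> PCABasis:
    """Fit every model to the reference and diagonalize the covariance.

    The covariance is the population (1/M) average of outer products of
    deviations of fitted coordinates from their ensemble mean.  Eigenpairs
    come from the SVD of the centered data matrix, so eigenvalues are exact
    for rank-deficient ensembles; modes are sign-fixed deterministically and
    eigenvalue ties keep SVD order.
    """
    if ens.n_models < 2:
        raise ValueError("PCA needs at least 2 models")
    fitted = np.stack(
        [fit_model(ens.models[m], ref).fitted_coords.ravel() for m in range(ens.n_models)]
    )
    mean = fitted.mean(axis=0)
    centered = fitted - mean
    _, s, Vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = s**2 / ens.n_models
    eigenvectors = _fix_signs(Vt)
    return PCABasis(
        mean_coords=mean,
        eigenvectors=eigenvectors,
        eigenvalues=eigenvalues,
        fit_reference=ref,
    )


def project(
    model_coords: np.ndarray,
    basis: PCABasis,
    ref: FitReference | None = None,
    n: int = 0,
    centered: bool = True,
) -> float:
    """Collective variable v_n of one conformer (in angstroms).

    The conformer is fitted to the reference and projected onto mode n.
    With ``centered=True`` (default) the ensemble mean is subtracted first,
    so the training ensemble projects to zero mean; ``centered=False`` gives
    the absolute (uncentered) axis, which differs by a constant offset.
    """
    v = project_many(model_coords[None, ...], basis, ref, components=(n,), centered=centered)
    return float(v[0, 0])


def project_many(
    models: np.ndarray,
    basis: PCABasis,
    ref: FitReference | None = None,
    components: tuple[int, ...] = (0, 1),
    centered: bool = True,
) -> np.ndarray:
    """Project a stack of conformers; returns shape (n_models, n_components)."""
    ref = ref if ref is not None else basis.fit_reference
    if max(components) >= basis.n_components:
        raise ValueError(
            f"component {max(components)} not available "
            f"({basis.n_components} components)"
        )
    C = basis.eigenvectors[list(components)]
    out = np.empty((len(models), len(components)))
    for i, coords in enumerate(np.asarray(models, dtype=float)):
        x = fit_model(coords, ref).fitted_coords.ravel()
        if centered:
            x = x - basis.mean_coords
        out[i] = C @ x
    return out


def cumulative_variance(basis: PCABasis, k: int) -> float:
    """Fraction of total variance captured by the first k modes."""
    if k < 1:
        raise ValueError("k must be >= 1")
    total = basis.eigenvalues.sum()
    if total <= 0:
        raise ValueError("all-zero spectrum: cumulative variance undefined")
    return float(basis.eigenvalues[:k].sum() / total)


def save_basis(basis: PCABasis, path: str | Path) -> Path:
    """Serialize a basis to a JSON file (mean, spectrum, modes, fit atoms)."""
    path = Path(path)
    payload = {
        "mean_coords": basis.mean_coords.tolist(),
        "eigenvalues": basis.eigenvalues.tolist(),
        "eigenvectors": basis.eigenvectors.tolist(),
        "fit_indices": basis.fit_reference.fit_indices.tolist(),
        "ref_coords": basis.fit_reference.ref_coords.tolist(),
    }
    path.write_text(json.dumps(payload))
    return path


def load_basis(path: str | Path) -> PCABasis:
    payload = json.loads(Path(path).read_text())
    ref = FitReference(
        ref_coords=np.array(payload["ref_coords"]),
        fit_indices=np.array(payload["fit_indices"]),
    )
    return PCABasis(
        mean_coords=np.array(payload["mean_coords"]),
        eigenvectors=np.array(payload["eigenvectors"]),
        eigenvalues=np.array(payload["eigenvalues"]),
        fit_reference=ref,
    )


def export_porcupine(basis: PCABasis, path: str | Path, components=(0, 1)) -> Path:
    """Write per-atom displacement vectors of selected modes as CSV.

    One row per atom: atom_index followed by (dx, dy, dz) for each requested
    mode — the data behind a porcupine plot of the principal motions.
    """
    import pandas as pd

    cols = {"atom_index": np.arange(basis.n_atoms)}
    for n in components:
        vec = basis.eigenvectors[n].reshape(-1, 3)
        for j, ax in enumerate("xyz"):
            cols[f"c{n + 1}_d{ax}"] = vec[:, j]
    frame = pd.DataFrame(cols)
    frame.to_csv(path, index=False)
    return Path(path)
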
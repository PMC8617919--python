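"""Flat-bottom restraint on collective variables and its Cartesian force.

The restraint confines a simulation to a rectangular sampling region of the
(v1, v2) plane without biasing its interior:

    phi(v_m) = k/2 (v_m^min - v_m)^2   for v_m <  v_m^min
             = 0                       for v_m^min <= v_m <= v_m^max
             = k/2 (v_m - v_m^max)^2   for v_m^max <  v_m

Because v_m is a projection of *fitted* coordinates, its Cartesian gradient
must account for the dependence of the fit rotation R and centroid Q on the
fit atoms.  The gradient of R is obtained by differentiating the optimality
condition of the superposition — R A symmetric, with A the 3x3
cross-covariance — which for a perturbation dA gives a 3x3 linear system for
the skew generator Omega of dR = R Omega.  The implementation folds that
system into a single adjoint vector per component, so the per-atom gradient
costs one small solve per configuration rather than per coordinate, and is
validated against central finite differences.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from dcfel.fitting import (
    DegenerateFitError,
    FitReference,
    PCABasis,
    cross_covariance,
    fit_model,
)

# Skew-symmetric generators: _SKEW[k] @ v == cross(e_k, v).
_SKEW = np.array(
    [
        [[0.0, 0.0, 0.0], [0.0, 0.0, -1.0], [0.0, 1.0, 0.0]],
        [[0.0, 0.0, 1.0], [0.0, 0.0, 0.0], [-1.0, 0.0, 0.0]],
        [[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 0.0]],
    ]
)


def _vec3(K: np.ndarray) -> np.ndarray:
    """Axial 3-vector of the antisymmetric part passed in (K must be skew)."""
    return np.array([K[2, 1], K[0, 2], K[1, 0]])


@dataclasses.dataclass(frozen=True)
class FlatBottomRestraint:
    """Quadratic-wall restraint per CV dimension.

    ``v_min``/``v_max`` are the lower/upper edges per dimension (angstroms)
    and ``k`` the spring constant in kcal mol^-1 A^-2.
    """

    k: float
    v_min: np.ndarray
    v_max: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "v_min", np.atleast_1d(np.asarray(self.v_min, float)))
        object.__setattr__(self, "v_max", np.atleast_1d(np.asarray(self.v_max, float)))
        if self.k < 0:
            raise ValueError(f"spring constant must be >= 0, got {self.k}")
        if self.v_min.shape != self.v_max.shape:
            raise ValueError("v_min and v_max must have the same shape")
        if np.any(self.v_min > self.v_max):
            raise ValueError("v_min must be <= v_max componentwise")

    @property
    def n_dims(self) -> int:
        return self.v_min.size


def flat_bottom_energy(v, restraint: FlatBottomRestraint) -> float:
    """Restraint energy in kcal/mol at CV value(s) v.

    Zero inside the closed box [v_min, v_max]; quadratic outside.  Accepts a
    single CV vector or an array of shape (n, n_dims).
    """
    v = np.asarray(v, dtype=float)
    below = np.clip(restraint.v_min - v, 0.0, None)
    above = np.clip(v - restraint.v_max, 0.0, None)
    e = 0.5 * restraint.k * (below**2 + above**2)
    return e.sum(axis=-1) if e.ndim else float(e)


def _wall_gradient(v: np.ndarray, restraint: FlatBottomRestraint) -> np.ndarray:
    """d(phi)/d(v_m): k(v - v_min) below, 0 inside, k(v - v_max) above."""
    g = np.zeros_like(v)
    lo = v < restraint.v_min
    hi = v > restraint.v_max
    g[lo] = restraint.k * (v[lo] - restraint.v_min[lo])
    g[hi] = restraint.k * (v[hi] - restraint.v_max[hi])
    return g


class _FitContext:
    """Shared per-configuration quantities for CV values and gradients."""

    def __init__(self, model_coords: np.ndarray, basis: PCABasis, ref: FitReference):
        self.coords = np.asarray(model_coords, dtype=float)
        self.basis = basis
        self.ref = ref
        fit = fit_model(self.coords, ref)
        self.R = fit.R
        self.Q = fit.Q
        self.fitted_flat = fit.fitted_coords.ravel()
        self.A = cross_covariance(self.coords[ref.fit_indices], ref)
        self._L: np.ndarray | None = None
        self.n_fit = len(ref.fit_indices)
        self.Y = ref.centered  # s_nu - P, shape (n_fit, 3)

    @property
    def L(self) -> np.ndarray:
        """3x3 map from the skew generator omega to the antisymmetric part
        of R [omega]_x A (optimality condition: R A symmetric).  Built
        lazily — only gradient evaluations need it."""
        if self._L is None:
            L = np.empty((3, 3))
            for k in range(3):
                M = self.R @ _SKEW[k] @ self.A
                L[:, k] = _vec3(M - M.T)
            cond = np.linalg.cond(L)
            if not np.isfinite(cond) or cond > 1e12:
                raise DegenerateFitError(
                    "rotation derivative is ill-conditioned (degenerate fit geometry)"
                )
            self._L = L
        return self._L

    def value(self, m: int, centered: bool = True) -> float:
        x = self.fitted_flat
        if centered:
            x = x - self.basis.mean_coords
        return float(self.basis.eigenvectors[m] @ x)

    def gradient(self, m: int) -> np.ndarray:
        """Exact gradient of v_m with respect to every Cartesian coordinate."""
        c = self.basis.eigenvectors[m].reshape(-1, 3)
        R = self.R
        grad = c @ R  # direct term: grad[i] = R^T c_i
        fit_idx = self.ref.fit_indices
        # Centroid term: every fit atom shifts Q by 1/n_fit.
        grad[fit_idx] -= (c.sum(axis=0) @ R) / self.n_fit
        # Rotation term via the adjoint of the 3x3 skew system.
        B = (self.coords - self.Q).T @ c  # tr(dR B) = sum_i c_i . dR (r_i - Q)
        g = np.array([np.trace(R @ _SKEW[k] @ B) for k in range(3)])
        h = np.linalg.solve(self.L.T, g)
        grad[fit_idx] += -np.cross(h, self.Y) @ R
        return grad


def cv_gradient(
    model_coords: np.ndarray,
    basis: PCABasis,
    ref: FitReference | None = None,
    m: int = 0,
    frozen_fit: bool = False,
) -> np.ndarray:
    """Per-atom gradient d(v_m)/d(r_i), shape (n_atoms, 3).

    Includes the dependence of the fit rotation and centroid on the fit
    atoms; sums to the zero vector over atoms (translation invariance).
    With ``frozen_fit=True`` the superposition is treated as fixed (R = I,
    Q = 0) and the gradient reduces to the eigenvector components reshaped
    per atom — the linear-map limit, mainly useful for debugging.
    """
    ref = ref if ref is not None else basis.fit_reference
    if m >= basis.n_components:
        raise ValueError(f"component {m} not available")
    if frozen_fit:
        return basis.eigenvectors[m].reshape(-1, 3).copy()
    return _FitContext(model_coords, basis, ref).gradient(m)


def cv_values_and_gradients(
    model_coords: np.ndarray,
    basis: PCABasis,
    ref: FitReference | None = None,
    components: tuple[int, ...] = (0, 1),
    centered: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """CV values and gradients for several components sharing one fit."""
    ref = ref if ref is not None else basis.fit_reference
    ctx = _FitContext(model_coords, basis, ref)
    v = np.array([ctx.value(m, centered=centered) for m in components])
    grads = np.stack([ctx.gradient(m) for m in components])
    return v, grads


def flat_bottom_force(
    model_coords: np.ndarray,
    basis: PCABasis,
    ref: FitReference | None,
    restraint: FlatBottomRestraint,
    components: tuple[int, ...] = (0, 1),
    centered: bool = True,
    return_cv: bool = False,
):
    """Per-atom force -grad(phi) of the flat-bottom restraint.

    Zero everywhere when the CV value lies inside the closed box.  With
    ``return_cv=True`` also returns the CV values (useful to samplers that
    record them every step).
    """
    ref = ref if ref is not None else basis.fit_reference
    ctx = _FitContext(model_coords, basis, ref)
    v = np.array([ctx.value(m, centered=centered) for m in components])
    dphi = _wall_gradient(v, restraint)
    force = np.zeros_like(np.asarray(model_coords, dtype=float))
    for m, d in zip(components, dphi):
        if d != 0.0:
            force -= d * ctx.gradient(m)
    if return_cv:
        return force, v
    return force
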
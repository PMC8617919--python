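"""Structure-level analyses mapped onto the landscape.

Superposed RMSD between conformers, RMSD-centroid representative structures,
minimum-RMSD search against landmark structures, residue contact detection
(any-atom distance below a cutoff, 4.5 A by default), per-pair contact
probabilities over an ensemble, and marking of contact groups on the
(v1, v2) plane.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from dcfel.fitting import FitReference, PCABasis, cross_covariance, optimal_rotation, project_many
from dcfel.structure_io import AtomRecord, ConformationEnsemble


def pairwise_rmsd(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    indices: np.ndarray | None = None,
) -> float:
    """Best-fit (superposed) RMSD in angstroms over the selected atoms."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if indices is not None:
        a = a[np.asarray(indices, dtype=int)]
        b = b[np.asarray(indices, dtype=int)]
    if a.shape != b.shape:
        raise ValueError(f"selection shapes differ: {a.shape} vs {b.shape}")
    if len(a) < 3:
        raise ValueError("RMSD superposition needs at least 3 atoms")
    ref = FitReference(ref_coords=b, fit_indices=np.arange(len(b)))
    x = a - a.mean(axis=0)
    R = optimal_rotation(cross_covariance(a, ref))
    diff = x @ R.T - ref.centered
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def representative_structure(
    ens: ConformationEnsemble, indices: np.ndarray | None = None
) -> int:
    """Index of the RMSD-centroid model: argmin_i of Delta_i = sum_j RMSD_ij.

    Ties go to the lowest model index.  The summed distance uses superposed
    RMSD over ``indices`` (all atoms when None).
    """
    if ens.n_models == 0:
        raise ValueError("empty ensemble")
    if ens.n_models == 1:
        return 0
    n = ens.n_models
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pairwise_rmsd(ens.models[i], ens.models[j], indices)
    return int(np.argmin(d.sum(axis=1)))


def min_rmsd_to_target(
    ens: ConformationEnsemble,
    target_coords: np.ndarray,
    indices: np.ndarray | None = None,
    target_indices: np.ndarray | None = None,
) -> tuple[int, float]:
    """Model with the smallest superposed RMSD to a target structure.

    ``indices`` selects atoms of the ensemble models, ``target_indices``
    (defaulting to ``indices``) the matching atoms of the target.
    """
    if ens.n_models == 0:
        raise ValueError("empty ensemble")
    target = np.asarray(target_coords, dtype=float)
    if target_indices is None:
        target_indices = indices
    tgt = target if target_indices is None else target[np.asarray(target_indices, int)]
    best_idx, best = -1, np.inf
    for i in range(ens.n_models):
        sel = ens.models[i] if indices is None else ens.models[i][np.asarray(indices, int)]
        r = pairwise_rmsd(sel, tgt)
        if r < best:
            best_idx, best = i, r
    return best_idx, float(best)


def residue_contact_pairs(
    coords: np.ndarray,
    atoms: Sequence[AtomRecord],
    cutoff: float = 4.5,
    min_seq_sep: int = 1,
    heavy_only: bool = False,
) -> set[tuple[int, int]]:
    """Residue pairs with any interatomic distance strictly below ``cutoff``.

    All atoms present are considered by default ("any atom" definition,
    hydrogens included when the file has them); ``heavy_only=True`` drops
    hydrogens.  Pairs with |i - j| < ``min_seq_sep`` are excluded (the
    default of 1 excludes only self-contacts).
    """
    coords = np.asarray(coords, dtype=float)
    keep = np.arange(len(atoms))
    if heavy_only:
        keep = np.array(
            [k for k in keep if atoms[k].element != "H"], dtype=int
        )
    if len(keep) == 0:
        return set()
    res = np.array([atoms[k].residue_index for k in keep])
    tree = cKDTree(coords[keep])
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    out: set[tuple[int, int]] = set()
    for a, b in pairs:
        ri, rj = int(res[a]), int(res[b])
        if abs(ri - rj) < min_seq_sep:
            continue
        if np.linalg.norm(coords[keep[a]] - coords[keep[b]]) < cutoff:
            out.add((min(ri, rj), max(ri, rj)))
    return out


def contact_probability(
    ens: ConformationEnsemble,
    pair: tuple[int, int],
    cutoff: float = 4.5,
    min_seq_sep: int = 1,
    heavy_only: bool = False,
) -> float:
    """Fraction of models in which the residue pair is in contact."""
    pair = (min(pair), max(pair))
    hits = sum(
        pair
        in residue_contact_pairs(
            ens.models[m], ens.atoms, cutoff, min_seq_sep, heavy_only
        )
        for m in range(ens.n_models)
    )
    return hits / ens.n_models


@dataclasses.dataclass(frozen=True)
class ContactGroup:
    """A named set of residue pairs (e.g. one inter-domain interaction group)."""

    label: str
    pairs: frozenset[tuple[int, int]]

    def __init__(self, label: str, pairs: Iterable[tuple[int, int]]):
        normalized = frozenset((min(p), max(p)) for p in pairs)
        if not normalized:
            raise ValueError("a contact group needs at least one pair")
        if any(i == j for i, j in normalized):
            raise ValueError("contact pairs must join two distinct residues")
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "pairs", normalized)


def mark_contact_groups(
    ens: ConformationEnsemble,
    groups: Sequence[ContactGroup],
    basis: PCABasis,
    ref: FitReference | None = None,
    cutoff: float = 4.5,
    mode: str = "any",
    heavy_only: bool = False,
):
    """Per-model CV coordinates plus one boolean flag per contact group.

    A model carries a group's flag when any pair of the group is in contact
    (``mode="any"``, default) or when all pairs are (``mode="all"``).
    Returns a pandas DataFrame with columns model, v1, v2 and one column per
    group label.
    """
    import pandas as pd

    if mode not in ("any", "all"):
        raise ValueError(f"mode must be 'any' or 'all', got {mode!r}")
    cvs = project_many(ens.models, basis, ref)
    rows = []
    for m in range(ens.n_models):
        contacts = residue_contact_pairs(
            ens.models[m], ens.atoms, cutoff, heavy_only=heavy_only
        )
        row = {"model": m, "v1": cvs[m, 0], "v2": cvs[m, 1]}
        for group in groups:
            formed = (
                any(p in contacts for p in group.pairs)
                if mode == "any"
                else all(p in contacts for p in group.pairs)
            )
            row[group.label] = formed
        rows.append(row)
    return pd.DataFrame(rows)
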
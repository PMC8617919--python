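"""Multi-model PDB ensemble input/output.

NMR-style PDB files hold one conformer per MODEL/ENDMDL block; X-ray files
hold a single implicit model.  :func:`read_pdb_ensemble` turns either into a
:class:`ConformationEnsemble` — a stack of coordinate arrays sharing one atom
table — and :func:`write_pdb_models` is its inverse.  Parsing is delegated to
Biopython's PDB parser.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np

from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import is_aa


class EnsembleError(ValueError):
    """Raised for malformed or inconsistent multi-model structures."""


@dataclasses.dataclass(frozen=True)
class AtomRecord:
    """Identity of one atom, shared across all models of an ensemble."""

    residue_index: int
    residue_name: str
    atom_name: str
    element: str
    chain_id: str

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise EnsembleError(
                f"residue_index must be >= 1, got {self.residue_index}"
            )
        if not self.atom_name:
            raise EnsembleError("atom_name must be non-empty")


@dataclasses.dataclass
class ConformationEnsemble:
    """Ordered conformers of one molecule.

    Parameters
    ----------
    models:
        Array of shape ``(n_models, n_atoms, 3)`` in angstroms.
    atoms:
        One :class:`AtomRecord` per atom, in the same order for every model.
    label:
        Free-text provenance tag.
    """

    models: np.ndarray
    atoms: list[AtomRecord]
    label: str = ""

    def __post_init__(self) -> None:
        self.models = np.asarray(self.models, dtype=float)
        if self.models.ndim != 3 or self.models.shape[2] != 3:
            raise EnsembleError(
                f"models must have shape (n_models, n_atoms, 3), got {self.models.shape}"
            )
        if self.models.shape[1] != len(self.atoms):
            raise EnsembleError(
                f"{self.models.shape[1]} coordinates per model but "
                f"{len(self.atoms)} atom records"
            )
        if not np.all(np.isfinite(self.models)):
            raise EnsembleError("coordinates must be finite")

    @property
    def n_models(self) -> int:
        return self.models.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.models.shape[1]

    def residue_indices(self) -> np.ndarray:
        return np.array([a.residue_index for a in self.atoms], dtype=int)


def _atom_key(atom: AtomRecord) -> tuple:
    return (atom.chain_id, atom.residue_index, atom.atom_name)


def read_pdb_ensemble(
    path: str | Path,
    chain_id: str | None = None,
    include_hetero: bool = False,
    label: str | None = None,
) -> ConformationEnsemble:
    """Read a (possibly multi-model) PDB file into an ensemble.

    Every MODEL/ENDMDL block becomes one conformer; a file without MODEL
    records yields a single-model ensemble.  For atoms with alternate
    locations only the first conformer is kept.  By default only the first
    chain containing amino-acid residues is read; pass ``chain_id`` to pick a
    chain explicitly, and ``include_hetero=True`` to keep non-water hetero
    residues (ions, ligands) of that chain.

    Raises
    ------
    EnsembleError
        If the models do not share an identical atom list (the error names
        the first offending model) or the file contains no usable atoms.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))

    models = []
    atom_tables: list[list[AtomRecord]] = []
    for model in structure:
        chain = _pick_chain(model, chain_id)
        records: list[AtomRecord] = []
        coords: list[np.ndarray] = []
        for residue in chain:
            hetfield = residue.id[0]
            if hetfield == "W":
                continue
            if hetfield != " " and not include_hetero:
                continue
            resseq = residue.id[1]
            for atom in residue:
                if atom.is_disordered():
                    atom = sorted(
                        atom.disordered_get_list(), key=lambda a: a.get_altloc()
                    )[0]
                records.append(
                    AtomRecord(
                        residue_index=resseq,
                        residue_name=residue.get_resname().strip(),
                        atom_name=atom.get_name().strip(),
                        element=(atom.element or "").strip(),
                        chain_id=chain.id,
                    )
                )
                coords.append(atom.get_coord().astype(float))
        if not records:
            raise EnsembleError(f"model {model.id + 1} of {path} has no atoms")
        models.append(np.array(coords))
        atom_tables.append(records)

    if not models:
        raise EnsembleError(f"{path} contains no models")

    reference = [_atom_key(a) for a in atom_tables[0]]
    for i, table in enumerate(atom_tables[1:], start=2):
        if [_atom_key(a) for a in table] != reference:
            raise EnsembleError(
                f"model {i} of {path} does not match model 1's atom list "
                f"({len(table)} atoms vs {len(reference)})"
            )

    return ConformationEnsemble(
        models=np.stack(models),
        atoms=atom_tables[0],
        label=label if label is not None else path.stem,
    )


def _pick_chain(model, chain_id: str | None):
    chains = list(model)
    if chain_id is not None:
        for chain in chains:
            if chain.id == chain_id:
                return chain
        raise EnsembleError(f"chain {chain_id!r} not found")
    for chain in chains:
        if any(is_aa(res) for res in chain):
            return chain
    if chains:
        return chains[0]
    raise EnsembleError("model contains no chains")


def select_atoms(
    ens: ConformationEnsemble,
    atom_name: str,
    residue_range: tuple[int, int],
) -> np.ndarray:
    """Return indices of atoms matching a name and an inclusive residue range.

    Residue numbers are the PDB sequence numbers as printed (1-based).  The
    result is ordered by position in the atom table, which is residue order
    for well-formed files.  An empty selection is an error because fitting on
    it would be undefined.
    """
    lo, hi = residue_range
    if lo > hi:
        raise ValueError(f"empty residue range {residue_range}")
    idx = [
        i
        for i, a in enumerate(ens.atoms)
        if a.atom_name == atom_name and lo <= a.residue_index <= hi
    ]
    if not idx:
        raise EnsembleError(
            f"no atoms named {atom_name!r} in residue range {lo}-{hi}"
        )
    return np.array(idx, dtype=int)


def write_pdb_models(
    ens: ConformationEnsemble,
    path: str | Path,
    remarks: Sequence[str] = (),
) -> Path:
    """Write an ensemble as a multi-model PDB file.

    Coordinates are written at the PDB fixed-point precision of 0.001 A, so
    a read/write round trip preserves them to that precision.  A single-model
    ensemble is written without MODEL/ENDMDL records.
    """
    if ens.n_models == 0:
        raise EnsembleError("cannot write an empty ensemble")
    path = Path(path)
    lines: list[str] = []
    for remark in remarks:
        lines.append(f"REMARK   6 {remark}"[:80])
    multi = ens.n_models > 1
    for m in range(ens.n_models):
        if multi:
            lines.append(f"MODEL     {m + 1:4d}")
        for serial, (atom, xyz) in enumerate(zip(ens.atoms, ens.models[m]), 1):
            name = atom.atom_name
            # PDB column alignment: 1-3 char names start in column 14.
            name_field = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {serial:5d} {name_field}{'':1s}{atom.residue_name:>3s} "
                f"{atom.chain_id:1s}{atom.residue_index:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path
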
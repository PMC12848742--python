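"""Core containers and file I/O: atoms, structure models, trajectories,
aligned FASTA and fixed-column multi-model PDB.

Conventions
-----------
* Coordinates are Angstrom throughout; residue numbering is the author (PDB)
  numbering, 1-based, never renumbered.
* The trajectory interchange format is multi-model PDB (one MODEL/ENDMDL
  block per frame). Binary trajectory formats are an explicit extension
  point, not supported here.
* Water residues are recognised by residue name in {HOH, WAT, SOL, TIP3};
  the water probe atom is its oxygen (atom name starting with 'O').
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from Bio import SeqIO

from .exceptions import (
    AlignmentLengthError,
    FormatError,
    SelectionError,
    TopologyMismatchError,
)

logger = logging.getLogger("ptpkit")

WATER_RESNAMES = frozenset({"HOH", "WAT", "SOL", "TIP3"})

#: Backbone atom names used for backbone RMSD.
BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class Atom:
    """One atom: identity plus Cartesian position in Angstrom."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"bad position for atom {self.atom_name}: {self.position}")
        if not self.residue_name:
            raise ValueError("residue_name must be non-empty")
        object.__setattr__(self, "position", pos)

    @property
    def key(self) -> tuple:
        return (self.chain_id, self.residue_number, self.atom_name)

    @property
    def is_water(self) -> bool:
        return self.residue_name in WATER_RESNAMES

    @property
    def is_water_oxygen(self) -> bool:
        return self.is_water and self.atom_name.startswith("O")


class StructureModel:
    """One conformation: an ordered list of atoms with unique
    (chain, residue number, atom name) identity."""

    def __init__(self, atoms: Sequence[Atom], model_id: int = 1):
        self.atoms = list(atoms)
        self.model_id = int(model_id)
        self._index: dict[tuple, Atom] = {}
        for atom in self.atoms:
            if atom.key in self._index:
                raise ValueError(f"duplicate atom {atom.key} in model {model_id}")
            self._index[atom.key] = atom

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def atom(self, chain_id: str, residue_number: int, atom_name: str) -> Atom:
        try:
            return self._index[(chain_id, int(residue_number), atom_name)]
        except KeyError:
            raise SelectionError(
                f"atom {chain_id}:{residue_number}:{atom_name} not in model"
            ) from None

    def has_atom(self, chain_id: str, residue_number: int, atom_name: str) -> bool:
        return (chain_id, int(residue_number), atom_name) in self._index

    def residue_atoms(self, chain_id: str, residue_number: int) -> list[Atom]:
        out = [
            a
            for a in self.atoms
            if a.chain_id == chain_id and a.residue_number == int(residue_number)
        ]
        if not out:
            raise SelectionError(f"residue {chain_id}:{residue_number} not in model")
        return out

    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered distinct (chain, residue number, residue name) triples."""
        seen: dict[tuple[str, int], str] = {}
        for a in self.atoms:
            seen.setdefault((a.chain_id, a.residue_number), a.residue_name)
        return [(c, n, r) for (c, n), r in seen.items()]

    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def topology_key(self) -> tuple:
        return tuple((a.chain_id, a.residue_number, a.residue_name, a.atom_name) for a in self.atoms)


class Trajectory:
    """Ordered sequence of models sharing one atom topology."""

    def __init__(self, models: Sequence[StructureModel], frame_interval: float = 1.0):
        models = list(models)
        if not models:
            raise ValueError("trajectory needs at least one model")
        ref = models[0].topology_key()
        for m in models[1:]:
            if m.topology_key() != ref:
                raise TopologyMismatchError(
                    f"model {m.model_id} does not share the topology of model "
                    f"{models[0].model_id}"
                )
        self.models = models
        self.frame_interval = float(frame_interval)

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    def __getitem__(self, i) -> StructureModel:
        return self.models[i]


@dataclass(frozen=True)
class ResidueSelection:
    """A chain plus a strictly increasing list of residue numbers."""

    chain_id: str
    residue_numbers: tuple = field(default_factory=tuple)

    def __post_init__(self):
        nums = tuple(int(n) for n in self.residue_numbers)
        if not nums:
            raise ValueError("empty residue selection")
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise ValueError("residue numbers must be strictly increasing")
        object.__setattr__(self, "residue_numbers", nums)

    @classmethod
    def from_string(cls, text: str) -> "ResidueSelection":
        """Parse ``chain:first-last`` or ``chain:n1,n2,...``."""
        chain, _, spec = text.partition(":")
        if not spec:
            raise ValueError(f"cannot parse selection {text!r}")
        if "-" in spec and "," not in spec:
            lo, hi = spec.split("-")
            numbers: Iterable[int] = range(int(lo), int(hi) + 1)
        else:
            numbers = (int(x) for x in spec.split(","))
        return cls(chain, tuple(numbers))


# ---------------------------------------------------------------------------
# alignments (FASTA)
# ---------------------------------------------------------------------------

def read_alignment(path) -> list[tuple[str, str]]:
    """Read an aligned FASTA file: uppercased sequences, gaps retained.

    Raises :class:`FormatError` on an empty file and
    :class:`AlignmentLengthError` when lengths differ.
    """
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    lengths = {len(s) for _, s in records}
    if len(lengths) != 1:
        raise AlignmentLengthError(
            f"alignment {path} mixes sequence lengths {sorted(lengths)}"
        )
    return records


def write_alignment(records: Sequence[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# structures (fixed-column PDB)
# ---------------------------------------------------------------------------

def _convert_gemmi_model(gm: gemmi.Model, model_id: int) -> StructureModel:
    atoms = []
    for chain in gm:
        for residue in chain:
            for atom in residue:
                atoms.append(
                    Atom(
                        chain_id=chain.name,
                        residue_number=residue.seqid.num,
                        residue_name=residue.name.strip(),
                        atom_name=atom.name.strip(),
                        element=atom.element.name,
                        position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    )
                )
    return StructureModel(atoms, model_id=model_id)


def read_structure_models(path) -> Trajectory:
    """Read a (multi-model) PDB file into a Trajectory.

    A bare coordinate block yields a single-model trajectory. Models with
    mismatched atom sets raise :class:`TopologyMismatchError`.
    """
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise FormatError(f"no coordinate models in {path}")
    models = [_convert_gemmi_model(m, i + 1) for i, m in enumerate(st)]
    if not models[0].atoms:
        raise FormatError(f"no ATOM records in {path}")
    return Trajectory(models)


def _format_atom_line(serial: int, atom: Atom) -> str:
    name = atom.atom_name
    # PDB column rule: 1-3 character names start in column 14
    name_field = name if len(name) >= 4 else f" {name:<3s}"
    record = "HETATM" if atom.is_water else "ATOM  "
    x, y, z = atom.position
    return (
        f"{record}{serial:5d} {name_field}{'':1s}{atom.residue_name:>3s} "
        f"{atom.chain_id[:1]:1s}{atom.residue_number:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{atom.element[:2]:>2s}"
    )


def write_structure_models(trajectory: Trajectory | StructureModel, path) -> None:
    """Write a trajectory (or single model) as a multi-model PDB file.

    Coordinates are written with PDB precision (3 decimals); reading the file
    back reproduces them bit-identically at that precision.
    """
    if isinstance(trajectory, StructureModel):
        trajectory = Trajectory([trajectory])
    with open(path, "w") as fh:
        for model in trajectory:
            fh.write(f"MODEL     {model.model_id:4d}\n")
            for serial, atom in enumerate(model, start=1):
                fh.write(_format_atom_line(serial, atom) + "\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")


def select_atoms(
    model: StructureModel,
    selection: ResidueSelection,
    atom_names: Iterable[str],
) -> list[Atom]:
    """Atoms of the selected residues restricted to ``atom_names``.

    Residue-major order following the selection; a residue missing a
    requested atom name is skipped with a logged warning; a residue absent
    from the model raises :class:`SelectionError`.
    """
    wanted = set(atom_names)
    out: list[Atom] = []
    for resnum in selection.residue_numbers:
        residue_atoms = model.residue_atoms(selection.chain_id, resnum)
        hit = [a for a in residue_atoms if a.atom_name in wanted]
        missing = wanted - {a.atom_name for a in residue_atoms}
        if missing:
            logger.warning(
                "residue %s:%d (%s) lacks atom(s) %s; skipped",
                selection.chain_id,
                resnum,
                residue_atoms[0].residue_name,
                ",".join(sorted(missing)),
            )
        out.extend(hit)
    return out
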
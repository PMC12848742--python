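"""Dihedral-space loop-conformation analysis.

The central quantity is an RMSD-like similarity between the backbone
(phi, psi) angles of loop residues in a trajectory frame and those in a
reference conformation:

    angleRMSD(frame, ref) = (1/N) * sum_i sqrt(d_phi_i^2 + d_psi_i^2)

with angle differences wrapped into (-180, 180] before squaring. N is the
number of loop residues considered. An alternative root-mean-square
aggregation, sqrt((1/N) * sum_i (d_phi_i^2 + d_psi_i^2)), is selectable;
both lie in [0, 180*sqrt(2)].

Frames are classified by nearest reference conformation (labels such as
"low" / "intermediate" / "high" for the active, transitional and inactive
phosphate-binding-loop states), and 2-D conformational histograms are
built over the distances to two references.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import ComputationError, ParameterError
from .geometry import dihedral, kabsch, wrap_angle
from .io import BACKBONE_ATOMS, ResidueSelection, StructureModel, Trajectory

logger = logging.getLogger("ptpkit")

MAX_ANGLE_RMSD = 180.0 * np.sqrt(2.0)


@dataclass
class DihedralSeries:
    """Per-frame, per-residue (phi, psi) in degrees, wrapped to (-180, 180]."""

    residue_numbers: tuple
    frames: np.ndarray  # shape (n_frames, n_residues, 2)

    def __post_init__(self):
        self.residue_numbers = tuple(int(n) for n in self.residue_numbers)
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 2:
            raise ParameterError("frames must have shape (n_frames, n_residues, 2)")
        if self.frames.shape[1] != len(self.residue_numbers):
            raise ParameterError("one (phi, psi) pair per residue required")
        if np.any(self.frames > 180.0) or np.any(self.frames <= -180.0):
            raise ParameterError("angles must lie in (-180, 180]")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class ReferenceConformation:
    """A labelled reference set of (phi, psi) angles, e.g. a crystal state."""

    label: str
    dihedrals: np.ndarray  # shape (n_residues, 2)

    def __post_init__(self):
        self.dihedrals = np.asarray(self.dihedrals, dtype=float)
        if self.dihedrals.ndim != 2 or self.dihedrals.shape[1] != 2:
            raise ParameterError("dihedrals must have shape (n_residues, 2)")


@dataclass
class DistanceSeries:
    """Per-frame scalar distance in Angstrom with a description of the pair."""

    frames: np.ndarray
    description: str = ""

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if np.any(self.frames < 0):
            raise ParameterError("distances must be non-negative")


# ---------------------------------------------------------------------------
# phi/psi extraction
# ---------------------------------------------------------------------------

def _phi_psi_one_residue(model: StructureModel, chain: str, num: int):
    """(phi, psi) of one residue, or None where a flanking neighbour is absent.

    phi = dihedral(C[i-1], N[i], CA[i], C[i]); psi = dihedral(N[i], CA[i],
    C[i], N[i+1]). A missing backbone atom within an existing residue is an
    error; a missing neighbouring residue makes the angle undefined.
    """
    try:
        n = model.atom(chain, num, "N").position
        ca = model.atom(chain, num, "CA").position
        c = model.atom(chain, num, "C").position
    except Exception as exc:
        raise ComputationError(
            f"residue {chain}:{num} lacks a backbone atom needed for phi/psi"
        ) from exc
    if not (model.has_atom(chain, num - 1, "C") and model.has_atom(chain, num + 1, "N")):
        return None
    c_prev = model.atom(chain, num - 1, "C").position
    n_next = model.atom(chain, num + 1, "N").position
    return dihedral(c_prev, n, ca, c), dihedral(n, ca, c, n_next)


def compute_phi_psi(trajectory: Trajectory, selection: ResidueSelection) -> DihedralSeries:
    """Backbone (phi, psi) per frame for the selected residues.

    Terminal residues lacking a flanking neighbour are dropped with a warning.
    """
    chain = selection.chain_id
    first = trajectory[0]
    kept, dropped = [], []
    for num in selection.residue_numbers:
        if _phi_psi_one_residue(first, chain, num) is None:
            dropped.append(num)
        else:
            kept.append(num)
    if dropped:
        logger.warning(
            "residues %s lack a neighbour for phi/psi and were dropped", dropped
        )
    if not kept:
        raise ComputationError("no residue in the selection has defined phi/psi")
    frames = np.empty((len(trajectory), len(kept), 2))
    for f, model in enumerate(trajectory):
        for r, num in enumerate(kept):
            pair = _phi_psi_one_residue(model, chain, num)
            if pair is None:  # topology is shared, so this cannot differ by frame
                raise ComputationError(f"phi/psi undefined for residue {num}")
            frames[f, r] = pair
    return DihedralSeries(tuple(kept), frames)


def phi_psi_of_model(model: StructureModel) -> dict[tuple[str, int], tuple[float, float]]:
    """(phi, psi) for every residue of the model that has both neighbours."""
    out: dict[tuple[str, int], tuple[float, float]] = {}
    for chain, num, resname in model.residues():
        if resname in ("HOH", "WAT", "SOL", "TIP3"):
            continue
        if not model.has_atom(chain, num, "CA"):
            continue
        try:
            pair = _phi_psi_one_residue(model, chain, num)
        except ComputationError:
            continue
        if pair is not None:
            out[(chain, num)] = pair
    return out


# ---------------------------------------------------------------------------
# the angleRMSD metric and state classification
# ---------------------------------------------------------------------------

def angle_rmsd(frame, ref, method: str = "mean") -> float:
    """Dihedral-space distance between one frame and a reference.

    ``method='mean'`` (default): mean over residues of the per-residue
    Euclidean norm of wrapped (d_phi, d_psi). ``method='rms'``: root mean
    square over all wrapped angle differences, residue-paired.
    """
    frame = np.asarray(frame, dtype=float)
    if isinstance(ref, ReferenceConformation):
        ref = ref.dihedrals
    ref = np.asarray(ref, dtype=float)
    if frame.shape != ref.shape:
        raise ParameterError(
            f"frame shape {frame.shape} != reference shape {ref.shape}"
        )
    d = wrap_angle(ref - frame)
    per_residue_sq = np.sum(np.square(d), axis=-1)
    if method == "mean":
        return float(np.mean(np.sqrt(per_residue_sq)))
    if method == "rms":
        return float(np.sqrt(np.mean(per_residue_sq)))
    raise ParameterError(f"unknown aggregation {method!r}")


def classify_state(frame, references: Sequence[ReferenceConformation],
                   method: str = "mean"):
    """Label of the nearest reference by angle_rmsd.

    Returns ``(label, distances, tied)``; exact ties go to the first-listed
    reference and are flagged.
    """
    if len(references) < 2:
        raise ParameterError("need at least two reference conformations")
    distances = np.array([angle_rmsd(frame, r, method=method) for r in references])
    best = int(np.argmin(distances))
    tied = bool(np.sum(distances == distances[best]) > 1)
    return references[best].label, distances, tied


def classify_series(series: DihedralSeries,
                    references: Sequence[ReferenceConformation],
                    method: str = "mean") -> list[str]:
    return [classify_state(f, references, method=method)[0] for f in series.frames]


def conformational_histogram(series: DihedralSeries,
                             ref_a: ReferenceConformation,
                             ref_b: ReferenceConformation,
                             bins: int = 50,
                             method: str = "mean"):
    """2-D histogram of per-frame (distance to ref_a, distance to ref_b).

    Returns ``(counts, x_edges, y_edges, d_a, d_b, ref_coords)`` where
    ``ref_coords`` gives each reference's own coordinates on the two axes
    (a reference sits at 0 on its own axis and at angle_rmsd(ref_a, ref_b)
    on the other).
    """
    if bins < 2:
        raise ParameterError("bins must be >= 2")
    d_a = np.array([angle_rmsd(f, ref_a, method=method) for f in series.frames])
    d_b = np.array([angle_rmsd(f, ref_b, method=method) for f in series.frames])
    counts, xe, ye = np.histogram2d(d_a, d_b, bins=bins,
                                    range=[[0, MAX_ANGLE_RMSD], [0, MAX_ANGLE_RMSD]])
    ab = angle_rmsd(ref_a.dihedrals, ref_b, method=method)
    ref_coords = {ref_a.label: (0.0, ab), ref_b.label: (ab, 0.0)}
    return counts, xe, ye, d_a, d_b, ref_coords


def angle_rmsd_matrix(references: Sequence[ReferenceConformation],
                      method: str = "mean") -> np.ndarray:
    """Pairwise angleRMSD between reference conformations."""
    k = len(references)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = angle_rmsd(
                references[i].dihedrals, references[j], method=method
            )
    return out


# ---------------------------------------------------------------------------
# Cartesian-space fluctuation and deviation
# ---------------------------------------------------------------------------

def _selection_coords(model: StructureModel, selection: ResidueSelection,
                      atom_names) -> np.ndarray:
    atoms = []
    for num in selection.residue_numbers:
        for name in atom_names:
            if model.has_atom(selection.chain_id, num, name):
                atoms.append(model.atom(selection.chain_id, num, name))
    return np.array([a.position for a in atoms])


def rmsf(trajectory: Trajectory, selection: ResidueSelection,
         atom_name: str = "CA", superpose: bool = False) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the time-mean position.

    With ``superpose=True`` every frame is first Kabsch-fitted on all CA
    atoms to the first frame.
    """
    if len(trajectory) < 2:
        raise ParameterError("RMSF needs at least two frames")
    coords = np.array([_selection_coords(m, selection, (atom_name,))
                       for m in trajectory])
    if coords.shape[1] == 0:
        raise ParameterError(f"no {atom_name} atoms in selection")
    if superpose:
        all_ca = [np.array([a.position for a in m if a.atom_name == "CA"])
                  for m in trajectory]
        for f in range(1, len(trajectory)):
            r, t = kabsch(all_ca[f], all_ca[0])
            coords[f] = coords[f] @ r.T + t
    mean = coords.mean(axis=0)
    return np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))


def backbone_rmsd(conf_a: StructureModel, conf_b: StructureModel,
                  selection: ResidueSelection, superpose: bool = True,
                  fit_selection: ResidueSelection | None = None,
                  atom_names=BACKBONE_ATOMS) -> float:
    """Backbone RMSD between two conformations over a residue selection.

    With ``superpose``, conf_a is first least-squares superposed onto conf_b
    using ``fit_selection`` (default: the analysis selection itself).
    """
    xa = _selection_coords(conf_a, selection, atom_names)
    xb = _selection_coords(conf_b, selection, atom_names)
    if xa.shape != xb.shape or xa.size == 0:
        raise ComputationError(
            f"backbone atom mismatch: {xa.shape} vs {xb.shape}"
        )
    if superpose:
        fit_sel = fit_selection or selection
        fa = _selection_coords(conf_a, fit_sel, atom_names)
        fb = _selection_coords(conf_b, fit_sel, atom_names)
        if fa.shape != fb.shape or fa.size == 0:
            raise ComputationError("superposition selection mismatch")
        r, t = kabsch(fa, fb)
        xa = xa @ r.T + t
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))


def reference_crosscheck(structures: Sequence[StructureModel],
                         selection: ResidueSelection,
                         method: str = "mean"):
    """Cross-check report for a set of reference structures (e.g. deposited
    crystal conformations of the phosphate-binding loop).

    Returns ``(angle_matrix, rmsd_matrix, labels)``: pairwise angleRMSD over
    the loop residues and pairwise superposed backbone RMSD.
    """
    refs = []
    for i, st in enumerate(structures):
        series = compute_phi_psi(Trajectory([st]), selection)
        refs.append(ReferenceConformation(f"model_{st.model_id}", series.frames[0]))
    k = len(structures)
    rmsd_mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            rmsd_mat[i, j] = rmsd_mat[j, i] = backbone_rmsd(
                structures[i], structures[j], selection
            )
    return angle_rmsd_matrix(refs, method=method), rmsd_mat, [r.label for r in refs]


# ---------------------------------------------------------------------------
# catalytic-backup distance statistics
# ---------------------------------------------------------------------------

_CARBOXYLATE_OXYGENS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    # mutant mode: side-chain amide oxygen
    "ASN": ("OD1",),
    "GLN": ("OE1",),
}


def carboxylate_oxygens(model: StructureModel, chain: str, num: int):
    residue_atoms = model.residue_atoms(chain, num)
    resname = residue_atoms[0].residue_name
    names = _CARBOXYLATE_OXYGENS.get(resname)
    if names is None:
        raise ComputationError(
            f"residue {chain}:{num} ({resname}) carries no carboxylate/amide oxygen"
        )
    found = [a for a in residue_atoms if a.atom_name in names]
    if not found:
        raise ComputationError(
            f"residue {chain}:{num} ({resname}) is missing side-chain oxygens"
        )
    return found


def min_carboxylate_distance(frame: StructureModel, acid_residue: tuple,
                             target_atom: tuple) -> float:
    """Minimum distance from a target atom (e.g. the phosphorus of the
    phosphoenzyme intermediate) to the carboxylate oxygens of an acidic
    side chain."""
    chain, num = acid_residue
    target = frame.atom(*target_atom)
    oxy = carboxylate_oxygens(frame, chain, num)
    return float(min(np.linalg.norm(o.position - target.position) for o in oxy))


def carboxylate_distance_series(trajectory: Trajectory, acid_residue: tuple,
                                target_atom: tuple) -> DistanceSeries:
    d = [min_carboxylate_distance(m, acid_residue, target_atom) for m in trajectory]
    return DistanceSeries(
        np.array(d),
        description=f"min {acid_residue} carboxylate O to {target_atom}",
    )


def occupancy_within(series: DistanceSeries, cutoff: float) -> float:
    """% of frames with distance <= cutoff (boundary inclusive)."""
    if cutoff <= 0:
        raise ParameterError("cutoff must be positive")
    if series.frames.size == 0:
        raise ParameterError("empty distance series")
    return float(100.0 * np.mean(series.frames <= cutoff))


def kde_1d(values, bandwidth: float | None = None, grid: np.ndarray | None = None,
           grid_points: int = 512):
    """Gaussian kernel density estimate on a stated grid.

    Bandwidth defaults to Scott's rule (std * n^(-1/5)); zero-variance input
    then raises with an instruction to pass an explicit bandwidth. Returns
    ``(grid, density)``; the density integrates to 1 within ~1e-3 on a grid
    spanning the data plus 5 bandwidths.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ParameterError("no values for KDE")
    if bandwidth is None:
        if values.size < 2:
            raise ParameterError("automatic bandwidth needs >= 2 values")
        sd = float(np.std(values, ddof=1))
        if sd == 0:
            raise ParameterError(
                "zero-variance sample: pass an explicit bandwidth"
            )
        bandwidth = sd * values.size ** (-1.0 / 5.0)
    if bandwidth <= 0:
        raise ParameterError("bandwidth must be positive")
    if grid is None:
        lo = values.min() - 5 * bandwidth
        hi = values.max() + 5 * bandwidth
        grid = np.linspace(lo, hi, grid_points)
    z = (grid[:, None] - values[None, :]) / bandwidth
    density = np.exp(-0.5 * z * z).sum(axis=1) / (
        values.size * bandwidth * np.sqrt(2 * np.pi)
    )
    return grid, density
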
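"""Per-frame noncovalent-interaction census and helix content.

Detectors use documented geometric criteria (all cutoffs configurable):

* hydrophobic contact — both residues in {Ala, Val, Leu, Ile, Met, Phe,
  Trp, Pro}, sequence separation |i-j| >= 2, any side-chain carbon pair
  within 4.5 A;
* salt bridge — basic side-chain nitrogen (Arg NH1/NH2/NE, Lys NZ, His
  ND1/NE2 — His treated as potentially cationic regardless of protonation)
  within 4.0 A of an acidic carboxylate oxygen (Asp OD1/OD2, Glu OE1/OE2);
* side-chain hydrogen bond — side-chain N/O donor to side-chain N/O
  acceptor within 3.5 A heavy-atom distance; when an explicit hydrogen is
  attached to the donor, the D-H...A angle must additionally be >= 120
  degrees; in a residue that carries explicit hydrogens, a heavy atom with
  none attached is treated as acceptor-only (the distance-only fallback
  applies only to hydrogen-free models); pairs already counted as salt
  bridges are excluded;
* cation-pi — Arg guanidinium / Lys ammonium group centroid within 6.0 A
  of an aromatic ring centroid (Phe/Tyr six-ring, Trp nine-ring);
* helix content — a residue is helical iff phi in [-100, -30] and psi in
  [-80, -5] and it belongs to a run of >= 4 consecutive such residues.

"% residues engaged" = 100 x (number of distinct residues appearing in at
least one detected pair) / (total protein residues in the frame).
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .io import StructureModel, Trajectory, WATER_RESNAMES
from .loops import phi_psi_of_model

HYDROPHOBIC_RESIDUES = frozenset({"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO"})
BASIC_NITROGENS = {"ARG": ("NH1", "NH2", "NE"), "LYS": ("NZ",), "HIS": ("ND1", "NE2")}
ACIDIC_OXYGENS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
AROMATIC_RINGS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}
CATION_GROUPS = {"ARG": ("CZ", "NH1", "NH2", "NE"), "LYS": ("NZ",)}
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})

HELIX_PHI = (-100.0, -30.0)
HELIX_PSI = (-80.0, -5.0)
HELIX_MIN_RUN = 4


@dataclass
class Residue:
    chain: str
    number: int
    name: str
    atoms: dict  # atom name -> position

    @property
    def key(self):
        return (self.chain, self.number)

    def sidechain_atoms(self):
        return {n: p for n, p in self.atoms.items()
                if n not in BACKBONE_NAMES and not n.startswith("H")}


def protein_residues(frame: StructureModel) -> list[Residue]:
    """Protein residues (waters excluded) in model order."""
    grouped: dict[tuple, Residue] = {}
    for atom in frame:
        if atom.residue_name in WATER_RESNAMES:
            continue
        key = (atom.chain_id, atom.residue_number)
        if key not in grouped:
            grouped[key] = Residue(atom.chain_id, atom.residue_number,
                                   atom.residue_name, {})
        grouped[key].atoms[atom.atom_name] = atom.position
    return list(grouped.values())


def _sequence_separation(a: Residue, b: Residue) -> int:
    if a.chain != b.chain:
        return 10**6
    return abs(a.number - b.number)


def _percent_engaged(pairs, residues) -> float:
    engaged = {r.key for pair in pairs for r in pair}
    return 100.0 * len(engaged) / len(residues) if residues else 0.0


def hydrophobic_contacts(frame: StructureModel, cutoff: float = 4.5,
                         min_separation: int = 2):
    """Side-chain carbon-carbon contacts between hydrophobic residues.

    Returns ``(pairs, percent_engaged)``.
    """
    residues = protein_residues(frame)
    candidates = [r for r in residues if r.name in HYDROPHOBIC_RESIDUES]
    pairs = []
    for a, b in combinations(candidates, 2):
        if _sequence_separation(a, b) < min_separation:
            continue
        ca = [p for n, p in a.sidechain_atoms().items() if n.startswith("C")]
        cb = [p for n, p in b.sidechain_atoms().items() if n.startswith("C")]
        if not ca or not cb:
            continue
        d = np.linalg.norm(
            np.asarray(ca)[:, None, :] - np.asarray(cb)[None, :, :], axis=2
        )
        if d.min() <= cutoff:
            pairs.append((a, b))
    return pairs, _percent_engaged(pairs, residues)


def salt_bridges(frame: StructureModel, cutoff: float = 4.0):
    """Basic nitrogen within ``cutoff`` of an acidic carboxylate oxygen."""
    residues = protein_residues(frame)
    basics = [r for r in residues if r.name in BASIC_NITROGENS]
    acids = [r for r in residues if r.name in ACIDIC_OXYGENS]
    pairs = []
    for b in basics:
        npos = [b.atoms[n] for n in BASIC_NITROGENS[b.name] if n in b.atoms]
        if not npos:
            continue
        for a in acids:
            opos = [a.atoms[n] for n in ACIDIC_OXYGENS[a.name] if n in a.atoms]
            if not opos:
                continue
            d = np.linalg.norm(
                np.asarray(npos)[:, None, :] - np.asarray(opos)[None, :, :], axis=2
            )
            if d.min() <= cutoff:
                pairs.append((b, a))
    return pairs, _percent_engaged(pairs, residues)


def _donor_hydrogens(residue: Residue, donor_pos: np.ndarray,
                     attach_cutoff: float = 1.25):
    return [
        p for n, p in residue.atoms.items()
        if n.startswith("H") and np.linalg.norm(p - donor_pos) <= attach_cutoff
    ]


def _angle_deg(a, b, c) -> float:
    v1 = a - b
    v2 = c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def sidechain_hbonds(frame: StructureModel, dist_cutoff: float = 3.5,
                     angle_cutoff: float = 120.0):
    """Side-chain/side-chain hydrogen bonds, salt-bridge pairs excluded.

    Donor and acceptor are side-chain N/O heavy atoms within
    ``dist_cutoff``; with an explicit hydrogen on the donor the D-H...A
    angle must be >= ``angle_cutoff``. The heavy-atom-only fallback applies
    when the donor residue carries no explicit hydrogens at all; a heavy
    atom with no attached hydrogen in a protonated residue is acceptor-only.
    """
    residues = protein_residues(frame)
    bridge_keys = {
        frozenset((a.key, b.key)) for a, b in salt_bridges(frame)[0]
    }
    pairs = []
    for a, b in combinations(residues, 2):
        if frozenset((a.key, b.key)) in bridge_keys:
            continue
        found = False
        for donor_res, acceptor_res in ((a, b), (b, a)):
            if found:
                break
            has_h = any(n.startswith("H") for n in donor_res.atoms)
            for dn, dp in donor_res.sidechain_atoms().items():
                if dn[0] not in "NO":
                    continue
                hydrogens = _donor_hydrogens(donor_res, dp)
                if has_h and not hydrogens:
                    continue  # acceptor-only heavy atom
                for an, ap in acceptor_res.sidechain_atoms().items():
                    if an[0] not in "NO":
                        continue
                    if np.linalg.norm(dp - ap) > dist_cutoff:
                        continue
                    if hydrogens and not any(
                        _angle_deg(dp, h, ap) >= angle_cutoff for h in hydrogens
                    ):
                        continue
                    found = True
                    break
                if found:
                    break
        if found:
            pairs.append((a, b))
    return pairs, _percent_engaged(pairs, residues)


def cation_pi(frame: StructureModel, cutoff: float = 6.0):
    """Cationic-group centroid within ``cutoff`` of an aromatic ring centroid."""
    residues = protein_residues(frame)
    cations = [r for r in residues if r.name in CATION_GROUPS]
    aromatics = [r for r in residues if r.name in AROMATIC_RINGS]
    pairs = []
    for c in cations:
        pos = [c.atoms[n] for n in CATION_GROUPS[c.name] if n in c.atoms]
        if len(pos) != len(CATION_GROUPS[c.name]):
            continue
        c_centroid = np.mean(pos, axis=0)
        for a in aromatics:
            ring = [a.atoms[n] for n in AROMATIC_RINGS[a.name] if n in a.atoms]
            if len(ring) != len(AROMATIC_RINGS[a.name]):
                continue
            if np.linalg.norm(c_centroid - np.mean(ring, axis=0)) <= cutoff:
                pairs.append((c, a))
    return pairs, _percent_engaged(pairs, residues)


# ---------------------------------------------------------------------------
# helix content
# ---------------------------------------------------------------------------

def _in_helix_window(phi: float, psi: float) -> bool:
    return HELIX_PHI[0] <= phi <= HELIX_PHI[1] and HELIX_PSI[0] <= psi <= HELIX_PSI[1]


def helix_content(phi_psi) -> float:
    """% of residues in a run of >= 4 consecutive helical (phi, psi) pairs.

    ``phi_psi`` is an (n, 2) array of consecutive residues' dihedrals.
    """
    phi_psi = np.asarray(phi_psi, dtype=float)
    if phi_psi.ndim != 2 or phi_psi.shape[1] != 2:
        raise ParameterError("phi_psi must have shape (n, 2)")
    n = phi_psi.shape[0]
    if n == 0:
        raise ParameterError("no residues with defined dihedrals")
    window = [_in_helix_window(p, s) for p, s in phi_psi]
    helical = np.zeros(n, dtype=bool)
    run_start = None
    for i, flag in enumerate([*window, False]):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            if i - run_start >= HELIX_MIN_RUN:
                helical[run_start:i] = True
            run_start = None
    return float(100.0 * helical.sum() / n)


def helix_content_of_model(frame: StructureModel) -> float:
    """Helix content from a structure's computable (phi, psi); runs break
    across chains and residue-numbering gaps."""
    dihedrals = phi_psi_of_model(frame)
    if not dihedrals:
        raise ParameterError("no residue with defined phi/psi")
    keys = sorted(dihedrals)
    segments: list[list] = []
    prev = None
    for key in keys:
        if prev is not None and key[0] == prev[0] and key[1] == prev[1] + 1:
            segments[-1].append(dihedrals[key])
        else:
            segments.append([dihedrals[key]])
        prev = key
    total = len(keys)
    helical = sum(
        helix_content(np.array(seg)) / 100.0 * len(seg) for seg in segments
    )
    return 100.0 * helical / total


# ---------------------------------------------------------------------------
# census over a trajectory
# ---------------------------------------------------------------------------

@dataclass
class InteractionCensus:
    """Per-frame percentages plus per-frame pair lists."""

    per_frame: pd.DataFrame
    pairs: list

    def means(self) -> pd.Series:
        return self.per_frame.drop(columns="frame").mean()


def census_timeseries(trajectory: Trajectory,
                      hydrophobic_cutoff: float = 4.5,
                      salt_cutoff: float = 4.0,
                      hbond_cutoff: float = 3.5,
                      hbond_angle: float = 120.0,
                      cation_pi_cutoff: float = 6.0) -> InteractionCensus:
    """Apply all detectors plus helix content per frame."""
    rows, all_pairs = [], []
    for f, model in enumerate(trajectory):
        hp, hp_pct = hydrophobic_contacts(model, hydrophobic_cutoff)
        sb, sb_pct = salt_bridges(model, salt_cutoff)
        hb, hb_pct = sidechain_hbonds(model, hbond_cutoff, hbond_angle)
        cp, _ = cation_pi(model, cation_pi_cutoff)
        try:
            helix = helix_content_of_model(model)
        except ParameterError:
            helix = float("nan")
        rows.append({
            "frame": f,
            "hydrophobic_pct": hp_pct,
            "salt_bridge_pct": sb_pct,
            "sidechain_hbond_pct": hb_pct,
            "cation_pi_pairs": len(cp),
            "helix_pct": helix,
        })
        all_pairs.append({
            "hydrophobic": hp, "salt_bridge": sb,
            "sidechain_hbond": hb, "cation_pi": cp,
        })
    return InteractionCensus(pd.DataFrame(rows), all_pairs)
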
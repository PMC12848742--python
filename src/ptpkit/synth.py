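"""Synthetic inputs with the statistical structure the analyses assume.

Every generator is a pure function of its spec and seed: identical inputs
give identical outputs, and internal random streams are derived
deterministically (per-column substreams for alignments) so enlarging a
problem does not perturb earlier draws.

What is emulated
----------------
* Alignments with controlled per-column conservation (the progenitor MSAs
  behind chimeric shuffling).
* Loop trajectories as a two-state Markov hop between reference (phi, psi)
  sets plus independent wrapped-Gaussian angular noise — a statistical
  stand-in for the active/inactive phosphate-binding-loop transitions seen
  in molecular dynamics, not a physical model.
* Active-site hydration frames with Poisson-distributed water counts inside
  a probe sphere, plus decoy waters guaranteed outside it.
* Kinetic datasets drawn from the package's own model equations
  (Michaelis-Menten, bell pH-rate, Arrhenius, pseudo-first-order
  inactivation) with multiplicative lognormal noise of stated CV.
* Exact-geometry toy active sites for distance-criterion tests.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConstructionError, ParameterError
from .geometry import place_atom, wrap_angle
from .io import Atom, StructureModel, Trajectory
from .loops import DihedralSeries

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# ideal backbone geometry used to realise dihedrals as 3-D coordinates;
# coordinates are a carrier for phi/psi signal, not physical models
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_ANGLE_N_CA_C = 109.5   # tetrahedral at CA
_ANGLE_CA_C_N = 120.0   # trigonal at carbonyl C
_ANGLE_C_N_CA = 120.0   # trigonal at amide N


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class TwoStateLoopSpec:
    """Markov two-state loop hopping in dihedral space."""

    ref_low: Sequence[tuple]
    ref_high: Sequence[tuple]
    stay_prob: float = 0.99
    angular_noise_sd: float = 5.0
    n_frames: int = 1000
    seed: int = 0
    start_state: str = "high"

    def __post_init__(self):
        if not 0.0 <= self.stay_prob <= 1.0:
            raise ParameterError("stay_prob must be in [0, 1]")
        if self.angular_noise_sd < 0:
            raise ParameterError("angular_noise_sd must be >= 0")
        if len(self.ref_low) != len(self.ref_high):
            raise ParameterError("reference conformations must have equal length")
        if self.start_state not in ("low", "high"):
            raise ParameterError("start_state must be 'low' or 'high'")


@dataclass
class HydrationSpec:
    """Poisson water occupancy inside a probe sphere."""

    mean_waters_in_sphere: float = 2.0
    sphere_radius: float = 5.0
    box_half_width: float = 15.0
    n_frames: int = 1000
    seed: int = 0
    n_decoys: int = 6

    def __post_init__(self):
        if self.sphere_radius <= 0:
            raise ParameterError("sphere_radius must be > 0")
        if self.mean_waters_in_sphere < 0:
            raise ParameterError("Poisson rate must be >= 0")
        if self.box_half_width <= self.sphere_radius + 1.0:
            raise ParameterError("box_half_width must exceed sphere_radius + 1 A")


@dataclass
class KineticSimSpec:
    """Synthetic kinetic observations from a named model with lognormal noise."""

    model: str
    true_params: dict
    design_points: Sequence[float]
    noise_cv: float = 0.0
    seed: int = 0

    MODELS = ("michaelis_menten", "bell_ph", "arrhenius", "inactivation")

    def __post_init__(self):
        if self.model not in self.MODELS:
            raise ParameterError(f"unknown model {self.model!r}; one of {self.MODELS}")
        if self.noise_cv < 0:
            raise ParameterError("noise_cv must be >= 0")
        if len(self.design_points) == 0:
            raise ParameterError("design_points must be non-empty")


@dataclass
class KineticDataset:
    """Tidy observation table plus the generating truth."""

    data: pd.DataFrame
    model: str
    true_params: dict
    predictor: str
    response: str


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def make_msa(n_seqs: int, length: int, conserved_fraction: float,
             alphabet_per_variable_column: int = 3, seed: int = 0):
    """Alignment with exactly ``round(conserved_fraction * length)``
    single-state columns, plus a per-column truth table.

    Every variable column realises exactly ``alphabet_per_variable_column``
    distinct residues (requires ``n_seqs`` at least that large).
    """
    if n_seqs < 2:
        raise ParameterError("need at least 2 sequences")
    k = int(alphabet_per_variable_column)
    if not 2 <= k <= 20:
        raise ParameterError("alphabet_per_variable_column must be in [2, 20]")
    if n_seqs < k:
        raise ParameterError(
            "n_seqs must be >= alphabet_per_variable_column so every variable "
            "column can realise its state set"
        )
    if not 0.0 <= conserved_fraction <= 1.0:
        raise ParameterError("conserved_fraction must be in [0, 1]")
    n_conserved = int(round(conserved_fraction * length))
    master = np.random.default_rng([seed, 2**20])
    conserved_cols = set(master.choice(length, size=n_conserved, replace=False).tolist())

    columns = np.empty((length, n_seqs), dtype="<U1")
    truth_rows = []
    aa = np.array(list(AMINO_ACIDS))
    for col in range(length):
        rng = np.random.default_rng([seed, col])
        if col in conserved_cols:
            state = rng.choice(aa)
            columns[col, :] = state
            truth_rows.append({"column": col, "conserved": True, "states": state})
        else:
            states = rng.choice(aa, size=k, replace=False)
            # first k sequences get each state once, the rest draw uniformly
            assign = np.concatenate([
                rng.permutation(states),
                rng.choice(states, size=n_seqs - k),
            ])
            columns[col, :] = assign
            truth_rows.append({
                "column": col,
                "conserved": False,
                "states": "".join(sorted(states)),
            })
    records = [
        (f"seq{i + 1}", "".join(columns[:, i])) for i in range(n_seqs)
    ]
    truth = pd.DataFrame(truth_rows)
    return records, truth


# ---------------------------------------------------------------------------
# loop trajectories
# ---------------------------------------------------------------------------

def make_loop_trajectory(spec: TwoStateLoopSpec):
    """Two-state dihedral trajectory plus hidden state labels.

    Frame t carries the current state's reference angles plus independent
    wrapped-Gaussian noise on each phi and psi.
    """
    refs = {
        "low": np.asarray(spec.ref_low, dtype=float),
        "high": np.asarray(spec.ref_high, dtype=float),
    }
    n_res = refs["low"].shape[0]
    rng = np.random.default_rng([spec.seed, 0])
    state = spec.start_state
    labels = []
    frames = np.empty((spec.n_frames, n_res, 2))
    for t in range(spec.n_frames):
        labels.append(state)
        noise = rng.normal(0.0, spec.angular_noise_sd, size=(n_res, 2)) \
            if spec.angular_noise_sd > 0 else 0.0
        frames[t] = wrap_angle(refs[state] + noise)
        if rng.random() >= spec.stay_prob:
            state = "low" if state == "high" else "high"
    residue_numbers = tuple(range(2, 2 + n_res))  # flanked realisation below
    return DihedralSeries(residue_numbers, frames), np.array(labels)


def build_backbone(phi_psi, chain_id: str = "A", start_resnum: int = 1,
                   model_id: int = 1) -> StructureModel:
    """Realise a (phi, psi) list as 3-D backbone coordinates.

    Ideal bond lengths/angles carry no signal; only dihedrals do. One
    flanking glycine is added on each side so every signal residue has both
    neighbours, i.e. residue numbers run ``start_resnum`` (flank),
    ``start_resnum+1 .. start_resnum+n`` (signal), ``start_resnum+n+1``
    (flank).
    """
    phi_psi = np.asarray(phi_psi, dtype=float)
    n = phi_psi.shape[0]
    flank = np.array([[-120.0, 130.0]])
    full = np.vstack([flank, phi_psi, flank])  # m = n + 2 residues
    m = full.shape[0]

    coords = np.zeros((m, 3, 3))  # residue, (N, CA, C), xyz
    coords[0, 0] = (0.0, 0.0, 0.0)
    coords[0, 1] = (_BOND_N_CA, 0.0, 0.0)
    ang = np.radians(180.0 - _ANGLE_N_CA_C)
    coords[0, 2] = coords[0, 1] + _BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(m - 1):
        n_i, ca_i, c_i = coords[i]
        psi = full[i, 1]
        n_next = place_atom(n_i, ca_i, c_i, _BOND_C_N, _ANGLE_CA_C_N, psi)
        ca_next = place_atom(ca_i, c_i, n_next, _BOND_N_CA, _ANGLE_C_N_CA, 180.0)
        phi = full[i + 1, 0]
        c_next = place_atom(c_i, n_next, ca_next, _BOND_CA_C, _ANGLE_N_CA_C, phi)
        coords[i + 1] = (n_next, ca_next, c_next)

    atoms = []
    for i in range(m):
        resnum = start_resnum + i
        resname = "GLY" if i in (0, m - 1) else "ALA"
        for name, pos in zip(("N", "CA", "C"), coords[i]):
            atoms.append(Atom(chain_id, resnum, resname, name,
                              "N" if name == "N" else "C", pos))
    return StructureModel(atoms, model_id=model_id)


def loop_trajectory_to_structures(series: DihedralSeries, chain_id: str = "A",
                                  max_frames: int | None = None) -> Trajectory:
    """Companion builder emitting backbone coordinates realising the series."""
    n = series.frames.shape[0] if max_frames is None else min(max_frames, series.n_frames)
    start = series.residue_numbers[0] - 1
    models = [
        build_backbone(series.frames[f], chain_id=chain_id,
                       start_resnum=start, model_id=f + 1)
        for f in range(n)
    ]
    return Trajectory(models)


# ---------------------------------------------------------------------------
# hydration frames
# ---------------------------------------------------------------------------

def _uniform_in_ball(rng, radius: float, n: int) -> np.ndarray:
    d = rng.normal(size=(n, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return d * r[:, None]


def _uniform_in_shell(rng, r_in: float, r_out: float, n: int) -> np.ndarray:
    d = rng.normal(size=(n, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    u = rng.random(n)
    r = (r_in**3 + u * (r_out**3 - r_in**3)) ** (1.0 / 3.0)
    return d * r[:, None]


def make_hydration_frames(spec: HydrationSpec):
    """Trajectory of one fixed probe atom (a cysteine S) plus waters.

    Per frame the number of water oxygens inside the probe sphere is
    Poisson(``mean_waters_in_sphere``); all remaining waters (including
    ``n_decoys`` permanent decoys) sit strictly outside the sphere. Returns
    ``(trajectory, in_sphere_counts)``.
    """
    rng = np.random.default_rng([spec.seed, 1])
    counts = rng.poisson(spec.mean_waters_in_sphere, size=spec.n_frames)
    n_waters = int(counts.max(initial=0)) + spec.n_decoys
    shell_in = spec.sphere_radius + 0.5
    shell_out = spec.box_half_width

    probe = Atom("A", 93, "CYS", "SG", "S", np.zeros(3))
    models = []
    for f in range(spec.n_frames):
        k = int(counts[f])
        inside = _uniform_in_ball(rng, spec.sphere_radius, k)
        outside = _uniform_in_shell(rng, shell_in, shell_out, n_waters - k)
        positions = np.vstack([inside, outside]) if k else outside
        atoms = [probe]
        for w in range(n_waters):
            atoms.append(Atom("W", 101 + w, "HOH", "O", "O", positions[w]))
        models.append(StructureModel(atoms, model_id=f + 1))
    return Trajectory(models), counts


# ---------------------------------------------------------------------------
# kinetic datasets
# ---------------------------------------------------------------------------

def _kinetic_curve(model: str, x: np.ndarray, p: dict) -> np.ndarray:
    if model == "michaelis_menten":
        return p["vmax"] * x / (p["km"] + x)
    if model == "bell_ph":
        h = 10.0 ** (-x)
        k1 = 10.0 ** (-p["pk_e1"])
        k2 = 10.0 ** (-p["pk_e2"])
        return p["kcat_lim"] / (1.0 + h / k1 + k2 / h)
    if model == "arrhenius":
        r_kcal = 1.987204258640832e-3
        return np.exp(p["ln_a"] - p["ea_kcal"] / (r_kcal * x))
    raise ParameterError(f"unknown model {model!r}")


def make_kinetics_dataset(spec: KineticSimSpec) -> KineticDataset:
    """Observations = model(design point; truth) x lognormal(mean 1, CV)."""
    rng = np.random.default_rng([spec.seed, 3])

    def noise(n):
        if spec.noise_cv == 0:
            return np.ones(n)
        sigma2 = np.log1p(spec.noise_cv**2)
        return rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size=n)

    if spec.model == "inactivation":
        required = {"k_inact", "k0", "a0", "concentrations_M"}
        missing = required - set(spec.true_params)
        if missing:
            raise ParameterError(f"inactivation spec missing {sorted(missing)}")
        p = spec.true_params
        rows = []
        times = np.asarray(spec.design_points, dtype=float)
        for conc in p["concentrations_M"]:
            k_obs = p["k0"] + p["k_inact"] * conc
            activity = p["a0"] * np.exp(-k_obs * times) * noise(times.size)
            for t, a in zip(times, activity):
                rows.append({"concentration_M": conc, "time_s": t, "activity": a})
        data = pd.DataFrame(rows)
        return KineticDataset(data, spec.model, dict(p), "time_s", "activity")

    x = np.asarray(spec.design_points, dtype=float)
    y = _kinetic_curve(spec.model, x, spec.true_params) * noise(x.size)
    names = {
        "michaelis_menten": ("substrate_mM", "rate"),
        "bell_ph": ("pH", "kcat"),
        "arrhenius": ("temperature_K", "k"),
    }[spec.model]
    data = pd.DataFrame({names[0]: x, names[1]: y})
    return KineticDataset(data, spec.model, dict(spec.true_params), *names)


# ---------------------------------------------------------------------------
# toy active sites
# ---------------------------------------------------------------------------

def make_toy_active_site(geometry: dict | None = None, seed: int = 0) -> StructureModel:
    """Exact-geometry fixture: a thiolate-like S probe, a phosphorus atom,
    carboxylate oxygens, and waters at requested distances.

    ``geometry`` keys (all Angstrom, defaults in parentheses):

    * ``p_from_s`` (5.0) — S to P distance.
    * ``carboxylate_o_from_p`` ((4.0, 6.0)) — OE1/OE2 distances from P.
    * ``waters_from_s`` (()) — distances of free waters from the S probe.
    * ``bridging_waters`` (()) — (distance to nearest carboxylate O,
      distance to P) pairs, realised exactly by sphere intersection.
    """
    g = {
        "p_from_s": 5.0,
        "carboxylate_o_from_p": (4.0, 6.0),
        "waters_from_s": (),
        "bridging_waters": (),
    }
    g.update(geometry or {})
    rng = np.random.default_rng([seed, 7])

    s_pos = np.zeros(3)
    p_pos = np.array([g["p_from_s"], 0.0, 0.0])
    if g["p_from_s"] <= 0:
        raise ConstructionError("p_from_s must be positive")

    atoms = [
        Atom("A", 93, "CYS", "SG", "S", s_pos),
        Atom("A", 200, "PO4", "P", "P", p_pos),
    ]
    o_names = ("OE1", "OE2")
    d_oxy = sorted(g["carboxylate_o_from_p"])
    for name, d in zip(o_names, d_oxy):
        if d <= 0:
            raise ConstructionError("carboxylate distances must be positive")
        atoms.append(Atom("A", 132, "GLU", name, "O",
                          p_pos + np.array([d, 0.0, 0.0])))
    oe1_pos = p_pos + np.array([d_oxy[0], 0.0, 0.0])

    water_num = 301
    for d in g["waters_from_s"]:
        direction = rng.normal(size=3)
        direction[0] = -abs(direction[0]) - 0.5  # keep away from the P/O axis
        direction /= np.linalg.norm(direction)
        atoms.append(Atom("W", water_num, "HOH", "O", "O", s_pos + d * direction))
        water_num += 1

    base = d_oxy[0]  # |P - OE1|
    for d_acid, d_p in g["bridging_waters"]:
        if not abs(d_p - d_acid) <= base <= d_p + d_acid:
            raise ConstructionError(
                f"bridging water at {d_acid} A from the carboxylate O and "
                f"{d_p} A from P is not realizable with |P-O| = {base} A"
            )
        x = (d_p**2 - d_acid**2 + base**2) / (2.0 * base)
        rho_sq = d_p**2 - x**2
        rho = np.sqrt(max(rho_sq, 0.0))
        theta = rng.uniform(0, 2 * np.pi)
        pos = p_pos + np.array([x, rho * np.cos(theta), rho * np.sin(theta)])
        assert abs(np.linalg.norm(pos - p_pos) - d_p) < 1e-9
        assert abs(np.linalg.norm(pos - oe1_pos) - d_acid) < 1e-9
        atoms.append(Atom("W", water_num, "HOH", "O", "O", pos))
        water_num += 1

    return StructureModel(atoms, model_id=1)
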
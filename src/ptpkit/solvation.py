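"""Active-site hydration statistics and scalar-grid sphere integration.

Hydration is summarised as the distribution over frames of the number of
water oxygens inside a probe sphere (default radius 5 A) centred on a
target atom, typically the S atom of the nucleophilic cysteine: a
histogram plus tail probabilities P(count >= k). Externally produced
solvation free-energy grids (e.g. from inhomogeneous solvation theory)
are consumed, never generated; their values are integrated over voxels
whose centres fall inside an analysis sphere. A bridging-water criterion
(default 3.5 A to both an acidic side chain's carboxylate oxygen and a
target phosphorus) scores catalytic-water positioning per frame.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import CoverageError, ParameterError
from .io import StructureModel, Trajectory
from .loops import carboxylate_oxygens

DEFAULT_SPHERE_RADIUS = 5.0
DEFAULT_BRIDGE_CUTOFF = 3.5


@dataclass
class ScalarGrid:
    """Regular 3-D voxel grid of free-energy density (kcal/mol per voxel)."""

    origin: np.ndarray
    spacing: float
    dims: tuple
    values: np.ndarray  # flattened, C order (x fastest last)

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.dims = tuple(int(d) for d in self.dims)
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.spacing <= 0:
            raise ParameterError("grid spacing must be > 0")
        if self.values.size != int(np.prod(self.dims)):
            raise ParameterError("value count must equal product of dims")

    def voxel_centers(self) -> np.ndarray:
        nx, ny, nz = self.dims
        ix, iy, iz = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        idx = np.column_stack([ix.ravel(), iy.ravel(), iz.ravel()])
        return self.origin + self.spacing * idx


def write_grid(grid: ScalarGrid, path) -> None:
    """Plain-text x/y/z/value table plus a JSON sidecar (origin/spacing/dims)."""
    path = Path(path)
    centers = grid.voxel_centers()
    with open(path, "w") as fh:
        fh.write("# x y z value\n")
        for (x, y, z), v in zip(centers, grid.values):
            fh.write(f"{x:.6f} {y:.6f} {z:.6f} {v:.10g}\n")
    sidecar = {
        "origin": grid.origin.tolist(),
        "spacing": grid.spacing,
        "dims": list(grid.dims),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar) + "\n")


def read_grid(path) -> ScalarGrid:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    table = np.loadtxt(path, comments="#", ndmin=2)
    if table.shape[1] != 4:
        raise ParameterError(f"grid table {path} must have 4 columns (x y z value)")
    return ScalarGrid(meta["origin"], meta["spacing"], meta["dims"], table[:, 3])


# ---------------------------------------------------------------------------
# hydration
# ---------------------------------------------------------------------------

def waters_in_sphere(frame: StructureModel, center_atom: tuple,
                     radius: float = DEFAULT_SPHERE_RADIUS) -> int:
    """Number of water oxygens within ``radius`` of a center atom
    (boundary inclusive)."""
    if radius <= 0:
        raise ParameterError("radius must be > 0")
    center = frame.atom(*center_atom).position
    count = 0
    for atom in frame:
        if atom.is_water_oxygen and np.linalg.norm(atom.position - center) <= radius:
            count += 1
    return count


@dataclass
class HydrationSummary:
    """Distribution over frames of in-sphere water counts."""

    counts: np.ndarray
    histogram: dict            # count -> frequency (sums to 1)

    @property
    def mean(self) -> float:
        return float(np.mean(self.counts))

    def prob_at_least(self, k: int) -> float:
        return float(np.mean(self.counts >= k))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"count": list(self.histogram), "frequency": list(self.histogram.values())}
        )


def hydration_summary(trajectory: Trajectory, center_atom: tuple,
                      radius: float = DEFAULT_SPHERE_RADIUS) -> HydrationSummary:
    counts = np.array([waters_in_sphere(m, center_atom, radius) for m in trajectory])
    values, freq = np.unique(counts, return_counts=True)
    histogram = {int(v): float(f) / counts.size for v, f in zip(values, freq)}
    return HydrationSummary(counts, histogram)


# ---------------------------------------------------------------------------
# grid integration
# ---------------------------------------------------------------------------

def integrate_grid_in_sphere(grid: ScalarGrid, center, radius: float):
    """Sum of grid values over voxels whose centres lie inside the sphere.

    Membership is voxel-centre-in-sphere (inclusive); no partial-volume
    weighting. Returns ``(total, n_voxels, coverage_fraction)`` where the
    coverage fraction compares the covered voxel volume with the sphere
    volume. Raises :class:`CoverageError` when no voxel centre is inside
    and the sphere lies outside the grid's bounding box.
    """
    if radius <= 0:
        raise ParameterError("radius must be > 0")
    center = np.asarray(center, dtype=float)
    centers = grid.voxel_centers()
    inside = np.linalg.norm(centers - center, axis=1) <= radius
    n_in = int(inside.sum())
    if n_in == 0:
        lo = grid.origin - radius
        hi = grid.origin + grid.spacing * (np.array(grid.dims) - 1) + radius
        if np.any(center < lo) or np.any(center > hi):
            raise CoverageError("analysis sphere lies entirely outside the grid")
    total = float(grid.values[inside].sum())
    sphere_volume = 4.0 / 3.0 * np.pi * radius**3
    coverage = n_in * grid.spacing**3 / sphere_volume
    return total, n_in, coverage


# ---------------------------------------------------------------------------
# bridging waters
# ---------------------------------------------------------------------------

def frame_has_bridging_water(frame: StructureModel, acid_residue: tuple,
                             target_atom: tuple,
                             cutoff: float = DEFAULT_BRIDGE_CUTOFF) -> bool:
    """Does any water oxygen sit within ``cutoff`` of both (any) carboxylate
    oxygen of the acidic residue and the target atom (inclusive)?"""
    target = frame.atom(*target_atom).position
    oxy = [o.position for o in carboxylate_oxygens(frame, *acid_residue)]
    for atom in frame:
        if not atom.is_water_oxygen:
            continue
        if np.linalg.norm(atom.position - target) > cutoff:
            continue
        if any(np.linalg.norm(atom.position - o) <= cutoff for o in oxy):
            return True
    return False


def bridging_water_occupancy(trajectory: Trajectory, acid_residue: tuple,
                             target_atom: tuple,
                             cutoff: float = DEFAULT_BRIDGE_CUTOFF) -> float:
    """% of frames containing at least one bridging water."""
    if cutoff <= 0:
        raise ParameterError("cutoff must be > 0")
    hits = [
        frame_has_bridging_water(m, acid_residue, target_atom, cutoff)
        for m in trajectory
    ]
    return float(100.0 * np.mean(hits))
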
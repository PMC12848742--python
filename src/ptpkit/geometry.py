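"""Low-level vector geometry: angle wrapping, dihedrals, NeRF atom placement
and Kabsch superposition.

Angles are in degrees everywhere; the canonical wrapped interval is
(-180, 180], matching the PDB phi/psi convention.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_angle",
    "dihedral",
    "place_atom",
    "kabsch",
    "superpose",
]


def wrap_angle(a):
    """Wrap angle(s) in degrees into the half-open interval (-180, 180]."""
    a = np.asarray(a, dtype=float)
    w = ((a + 180.0) % 360.0) - 180.0
    # modulo maps exact -180 to -180; convention puts it at +180
    w = np.where(w == -180.0, 180.0, w)
    if w.ndim == 0:
        return float(w)
    return w


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    # components orthogonal to the central bond
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D given chain A-B-C with |CD| = bond, angle(B,C,D) and
    torsion(A,B,C,D) — the natural extension reference frame (NeRF) step."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def kabsch(mobile: np.ndarray, target: np.ndarray):
    """Optimal rotation/translation superposing ``mobile`` onto ``target``.

    Returns ``(R, t)`` such that ``mobile @ R.T + t`` is the least-squares
    fit. Proper rotation enforced (determinant +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    s = np.diag([1.0, 1.0, d])
    r = vt.T @ s @ u.T
    t = tc - r @ mc
    return r, t


def superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Return ``mobile`` rigidly superposed onto ``target`` (Kabsch)."""
    r, t = kabsch(mobile, target)
    return mobile @ r.T + t
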
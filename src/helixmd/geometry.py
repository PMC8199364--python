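"""Low-level vector geometry shared by the builder and the analysis modules.

All coordinates are in nm, all angles in degrees unless noted. Dihedral signs
follow the IUPAC convention (right-handed, cis = 0).
"""

from __future__ import annotations

import numpy as np

__all__ = ["dihedral", "dihedrals", "bond_angle", "place_atom", "wrap_angle"]


def wrap_angle(a):
    """Wrap angle(s) in degrees into (-180, 180]."""
    a = np.asarray(a, dtype=float)
    w = -((-a + 180.0) % 360.0 - 180.0)
    return w if w.ndim else float(w)


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees, IUPAC convention.

    Returns NaN for degenerate (collinear) geometries.
    """
    return float(dihedrals(p0[None], p1[None], p2[None], p3[None])[0])


def dihedrals(p0, p1, p2, p3) -> np.ndarray:
    """Vectorised signed dihedrals over leading axes; inputs (..., 3)."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    nb1 = np.linalg.norm(b1, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        b1u = b1 / nb1
        v = b0 - np.sum(b0 * b1u, axis=-1, keepdims=True) * b1u
        w = b2 - np.sum(b2 * b1u, axis=-1, keepdims=True) * b1u
        x = np.sum(v * w, axis=-1)
        y = np.sum(np.cross(b1u, v) * w, axis=-1)
        out = np.degrees(np.arctan2(y, x))
    # collinear: either in-plane component vanishes
    bad = (np.linalg.norm(v, axis=-1) < 1e-12) | (np.linalg.norm(w, axis=-1) < 1e-12)
    bad |= (nb1[..., 0] < 1e-12)
    out = np.where(bad, np.nan, out)
    return out


def bond_angle(a, b, c) -> float:
    """Angle a-b-c at vertex b, degrees."""
    u = np.asarray(a, float) - b
    v = np.asarray(c, float) - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d with |c-d| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion (degrees), the NeRF construction.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise ValueError("reference atoms a, b, c are collinear")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n
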
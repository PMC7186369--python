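"""Small vector-geometry helpers shared by the builder, DSSP-lite and features.

All angles at this layer are in degrees; coordinates in Angstrom.
"""

from __future__ import annotations

import numpy as np

__all__ = ["unit", "bond_angle", "dihedral", "place_atom"]


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    return v / n


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u, w = unit(a - b), unit(c - b)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, w), -1.0, 1.0))))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1u = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d so that |c-d| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion (NeRF internal-to-Cartesian step).

    `angle` and `torsion` in degrees.
    """
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = unit(np.asarray(c) - np.asarray(b))
    n = unit(np.cross(np.asarray(b) - np.asarray(a), bc))
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ]
    )
    return np.asarray(c) + d_local[0] * bc + d_local[1] * m + d_local[2] * n
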
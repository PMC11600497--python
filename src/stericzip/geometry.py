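"""Low-level vector geometry: torsions, NeRF atom placement, axis fits.

All coordinates are orthonormal Angstroms; all angles are degrees unless a
name says otherwise.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "normalize",
    "dihedral",
    "bond_angle",
    "place_atom",
    "rotation_about_axis",
    "fit_direction",
    "wrap_deg",
]


def normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = normalize(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def bond_angle(p0, p1, p2) -> float:
    """Angle p0-p1-p2 in degrees."""
    u = normalize(np.asarray(p0) - np.asarray(p1))
    v = normalize(np.asarray(p2) - np.asarray(p1))
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: position d with |cd| = bond, angle(b,c,d) = angle and
    torsion(a,b,c,d) = torsion (degrees)."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    ang = np.radians(angle)
    tor = np.radians(torsion)
    # local displacement in the frame of bond c->d
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ]
    )
    bc = normalize(c - b)
    n = normalize(np.cross(b - a, bc))
    m = np.column_stack([bc, np.cross(n, bc), n])
    return c + m @ d_local


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about a (unit) axis through the origin."""
    axis = normalize(np.asarray(axis, dtype=float))
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    x, y, z = axis
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(axis, axis)


def fit_direction(points: np.ndarray, hint: np.ndarray | None = None) -> np.ndarray:
    """Principal direction of a point cloud (unit vector).

    If `hint` is given the sign is chosen to have a positive dot with it.
    """
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    d = vt[0]
    if hint is not None and np.dot(d, hint) < 0:
        d = -d
    return normalize(d)


def wrap_deg(a) -> np.ndarray | float:
    """Wrap angle(s) to (-180, 180]."""
    w = -((-np.asarray(a) + 180.0) % 360.0 - 180.0)
    return float(w) if np.isscalar(a) else w
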
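"""Low-level vector geometry shared by the torsion, Ringer and builder code."""

from __future__ import annotations

import numpy as np


def dihedral(p1, p2, p3, p4) -> float:
    """IUPAC-signed torsion angle in degrees, range (−180, 180].

    Raises ``ValueError`` when three consecutive points are collinear (the
    torsion is then undefined).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9 or nb2 < 1e-12:
        raise ValueError("collinear points: torsion undefined")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / nb2)
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if ang <= -180.0 else float(ang)


def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    """Rotation matrix about a (not necessarily unit) axis, right-handed."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    x, y, z = axis
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(axis, axis)


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Internal-coordinate (NeRF) placement of atom d.

    Returns d such that |c−d| = ``bond``, the b–c–d angle equals
    ``angle_deg``, and the a–b–c–d torsion equals ``torsion_deg``.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    d_local = bond * np.array([
        -np.cos(theta),
        np.sin(theta) * np.cos(chi),
        np.sin(theta) * np.sin(chi),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.column_stack([bc, np.cross(n, bc), n])
    return c + m @ d_local


def wrap_angle(angle: float) -> float:
    """Wrap degrees into (−180, 180]."""
    a = (float(angle) + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def angular_difference(a: float, b: float) -> float:
    """Unsigned circular distance between two angles in degrees, in [0, 180]."""
    return abs(wrap_angle(a - b))
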
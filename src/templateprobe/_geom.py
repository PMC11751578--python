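"""Low-level vector geometry: dihedrals, internal-coordinate atom placement, rotations.

All angles are in degrees at the API surface; coordinates in Angstrom.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "dihedral",
    "bond_angle",
    "place_atom",
    "rotation_about_axis",
    "random_rotation",
    "wrap_angle",
]


def wrap_angle(deg: float | np.ndarray) -> float | np.ndarray:
    """Wrap an angle (degrees) into (-180, 180]."""
    wrapped = -((-np.asarray(deg) + 180.0) % 360.0 - 180.0)
    return float(wrapped) if np.isscalar(deg) else wrapped


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees, IUPAC sign convention, in (-180, 180]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle_deg: float,
    torsion_deg: float,
) -> np.ndarray:
    """Place atom D bonded to c with |cD| = bond, angle(b, c, D) = angle_deg and
    dihedral(a, b, c, D) = torsion_deg (natural-extension / NeRF construction)."""
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise ValueError("reference atoms a, b, c are collinear; torsion frame undefined")
    n = n / norm
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(chi), -np.sin(theta) * np.sin(chi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about a (not necessarily unit) axis through the origin."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    x, y, z = axis
    k = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) * c + s * k + (1.0 - c) * np.outer(axis, axis)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (via normalized quaternion)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
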
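"""Internal-coordinate geometry: distances, angles, dihedrals and their
Cartesian gradients.

All angles are in radians. Gradients are exact except within the guard
band of the angle singularity (|sin(theta)| < SIN_GUARD), where the
gradient of the angle itself diverges; there the returned gradient is
zero, which equals the gradient of any harmonic well centered at the
singular geometry (0 or pi) evaluated at its minimum.
"""

from __future__ import annotations

import numpy as np

SIN_GUARD = 1e-8


def distance(p1: np.ndarray, p2: np.ndarray) -> float:
    return float(np.linalg.norm(p1 - p2))


def distance_grad(p1, p2):
    """Distance and its gradients wrt the two endpoints."""
    d = p1 - p2
    r = float(np.linalg.norm(d))
    if r < 1e-12:
        # direction undefined at coincidence; any subgradient works
        return r, np.zeros(3), np.zeros(3)
    u = d / r
    return r, u, -u


def angle(p1, p2, p3) -> float:
    """Bond angle p1-p2-p3 in [0, pi]."""
    u = p1 - p2
    v = p3 - p2
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    c = float(np.dot(u, v) / (nu * nv))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def angle_grad(p1, p2, p3):
    """Angle and gradients wrt p1, p2, p3 (zero inside the guard band)."""
    u = p1 - p2
    v = p3 - p2
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    c = float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
    theta = float(np.arccos(c))
    s = np.sqrt(max(0.0, 1.0 - c * c))
    if s < SIN_GUARD:
        z = np.zeros(3)
        return theta, z, z, z
    dc1 = (v / (nu * nv)) - c * u / (nu * nu)
    dc3 = (u / (nu * nv)) - c * v / (nv * nv)
    g1 = -dc1 / s
    g3 = -dc3 / s
    return theta, g1, -(g1 + g3), g3


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion p1-p2-p3-p4 in (-pi, pi], IUPAC sign convention."""
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m, n2))
    return float(np.arctan2(y, x))


def dihedral_grad(p1, p2, p3, p4):
    """Dihedral and gradients wrt the four atoms.

    Uses the standard normal-vector formulation; exact away from the
    colinear degeneracy of either bond angle (where the torsion itself
    is undefined and zeros are returned).
    """
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = float(np.linalg.norm(b2))
    sn1 = float(np.dot(n1, n1))
    sn2 = float(np.dot(n2, n2))
    m = np.cross(n1, b2 / nb2)
    phi = float(np.arctan2(float(np.dot(m, n2)), float(np.dot(n1, n2))))
    if sn1 < SIN_GUARD or sn2 < SIN_GUARD:
        z = np.zeros(3)
        return phi, z, z, z, z
    g1 = (nb2 / sn1) * n1
    g4 = -(nb2 / sn2) * n2
    c1 = float(np.dot(b1, b2)) / (nb2 * nb2)
    c2 = float(np.dot(b3, b2)) / (nb2 * nb2)
    g2 = -(1.0 + c1) * g1 + c2 * g4
    g3 = c1 * g1 - (1.0 + c2) * g4
    return phi, g1, g2, g3, g4


def wrap_angle(x: float) -> float:
    """Wrap an angular deviation to (-pi, pi]."""
    return float(np.arctan2(np.sin(x), np.cos(x)))


def wrap_angles(x: np.ndarray) -> np.ndarray:
    return np.arctan2(np.sin(x), np.cos(x))


def angle_grad_batch(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray):
    """Vectorized :func:`angle_grad` over (n, 3) position arrays."""
    u = p1 - p2
    v = p3 - p2
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    c = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
    theta = np.arccos(c)
    s = np.sqrt(np.maximum(0.0, 1.0 - c * c))
    safe = s >= SIN_GUARD
    s_div = np.where(safe, s, 1.0)
    dc1 = v / (nu * nv)[:, None] - (c / (nu * nu))[:, None] * u
    dc3 = u / (nu * nv)[:, None] - (c / (nv * nv))[:, None] * v
    g1 = np.where(safe[:, None], -dc1 / s_div[:, None], 0.0)
    g3 = np.where(safe[:, None], -dc3 / s_div[:, None], 0.0)
    return theta, g1, -(g1 + g3), g3


def dihedral_grad_batch(p1, p2, p3, p4):
    """Vectorized :func:`dihedral_grad` over (n, 3) position arrays."""
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    sn1 = np.einsum("ij,ij->i", n1, n1)
    sn2 = np.einsum("ij,ij->i", n2, n2)
    m = np.cross(n1, b2 / nb2[:, None])
    phi = np.arctan2(np.einsum("ij,ij->i", m, n2), np.einsum("ij,ij->i", n1, n2))
    safe = (sn1 >= SIN_GUARD) & (sn2 >= SIN_GUARD)
    sn1d = np.where(safe, sn1, 1.0)
    sn2d = np.where(safe, sn2, 1.0)
    g1 = (nb2 / sn1d)[:, None] * n1
    g4 = -(nb2 / sn2d)[:, None] * n2
    c1 = np.einsum("ij,ij->i", b1, b2) / (nb2 * nb2)
    c2 = np.einsum("ij,ij->i", b3, b2) / (nb2 * nb2)
    g2 = -(1.0 + c1)[:, None] * g1 + c2[:, None] * g4
    g3 = c1[:, None] * g1 - (1.0 + c2)[:, None] * g4
    z = safe[:, None]
    return phi, np.where(z, g1, 0.0), np.where(z, g2, 0.0), np.where(z, g3, 0.0), np.where(z, g4, 0.0)


def place_atom(a, b, c, bond: float, theta: float, phi: float) -> np.ndarray:
    """Place atom d from internal coordinates (NeRF construction).

    Returns d with |d-c| = bond, angle(b,c,d) = theta and dihedral
    (a,b,c,d) = phi, angles in radians.
    """
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        # a,b,c colinear: any normal will do
        trial = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(trial, bc)) > 0.9:
            trial = np.array([0.0, 1.0, 0.0])
        n = np.cross(trial, bc)
        nn = np.linalg.norm(n)
    n = n / nn
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(phi),
            -bond * np.sin(theta) * np.sin(phi),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n
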
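"""Vector geometry primitives shared across the package.

All coordinates are in nanometres; angles are in radians unless a function
name says otherwise.  Functions accept batched inputs (leading axes are
broadcast) wherever that is cheap to support.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "bond_lengths",
    "bending_angles",
    "dihedral_angles",
    "nerf_place",
    "reflect_through_plane",
    "signed_volume",
    "minimum_image",
]

_EPS = 1e-12


def bond_lengths(vectors: np.ndarray) -> np.ndarray:
    """Euclidean norms of bond vectors, shape ``(..., 3) -> (...)``."""
    return np.linalg.norm(vectors, axis=-1)


def bending_angles(positions: np.ndarray, triples: np.ndarray) -> np.ndarray:
    """Interior angle at the middle atom of each ``(i, j, k)`` triple.

    Parameters
    ----------
    positions:
        Array ``(..., n_atoms, 3)``.
    triples:
        Integer array ``(n_angles, 3)``; the angle is measured at ``j``.

    Returns
    -------
    Angles in ``[0, pi]``, shape ``(..., n_angles)``.  Triples with a
    zero-length arm yield ``nan`` (undefined, never silently zero).
    """
    triples = np.asarray(triples)
    p = np.asarray(positions)
    u = p[..., triples[:, 0], :] - p[..., triples[:, 1], :]
    v = p[..., triples[:, 2], :] - p[..., triples[:, 1], :]
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    denom = nu * nv
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.einsum("...i,...i->...", u, v) / denom
    c = np.clip(c, -1.0, 1.0)
    ang = np.arccos(c)
    return np.where(denom < _EPS, np.nan, ang)


def dihedral_angles(positions: np.ndarray, quadruples: np.ndarray) -> np.ndarray:
    """Signed dihedral angle for each bonded 4-path ``(i, j, k, l)``.

    Uses the two-plane normal construction with a full-quadrant arctangent;
    range ``(-pi, pi]``.  A degenerate (collinear) central bond gives ``nan``.
    """
    quadruples = np.asarray(quadruples)
    p = np.asarray(positions)
    b1 = p[..., quadruples[:, 1], :] - p[..., quadruples[:, 0], :]
    b2 = p[..., quadruples[:, 2], :] - p[..., quadruples[:, 1], :]
    b3 = p[..., quadruples[:, 3], :] - p[..., quadruples[:, 2], :]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.maximum(np.linalg.norm(b2, axis=-1, keepdims=True), _EPS))
    x = np.einsum("...i,...i->...", n1, n2)
    y = np.einsum("...i,...i->...", m1, n2)
    phi = np.arctan2(y, x)
    bad = (np.linalg.norm(n1, axis=-1) < _EPS) | (np.linalg.norm(n2, axis=-1) < _EPS)
    return np.where(bad, np.nan, phi)


def nerf_place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               length: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom ``d`` bonded to ``c`` by internal coordinates.

    ``length`` is the c-d bond length, ``angle`` the b-c-d bending angle and
    ``torsion`` the a-b-c-d dihedral; the placed atom satisfies
    ``dihedral_angles([a, b, c, d]) == torsion`` exactly (signed convention).
    """
    bc = c - b
    bc /= max(np.linalg.norm(bc), _EPS)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < _EPS:
        # collinear reference: pick any perpendicular
        helper = np.array([1.0, 0.0, 0.0]) if abs(bc[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        n = np.cross(helper, bc)
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array([
        -length * np.cos(angle),
        length * np.sin(angle) * np.cos(torsion),
        -length * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def reflect_through_plane(points: np.ndarray, p0: np.ndarray, p1: np.ndarray,
                          p2: np.ndarray) -> np.ndarray:
    """Mirror ``points`` through the plane containing ``p0, p1, p2``.

    Raises ``ValueError`` when the three anchor points are (near) collinear,
    in which case the plane is undefined.
    """
    n = np.cross(p1 - p0, p2 - p0)
    nn = np.linalg.norm(n)
    if nn < 1e-9:
        raise ValueError("reflection plane is degenerate: anchor points are collinear")
    n = n / nn
    d = (np.asarray(points) - p0) @ n
    return points - 2.0 * d[..., None] * n


def signed_volume(v1: np.ndarray, v2: np.ndarray, v3: np.ndarray) -> float:
    """Scalar triple product ``v1 . (v2 x v3)`` (chirality determinant)."""
    return float(np.dot(v1, np.cross(v2, v3)))


def minimum_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors ``d``."""
    box = np.asarray(box)
    return d - box * np.round(d / box)
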
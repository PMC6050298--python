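"""Low-level backbone geometry: torsions, NeRF atom placement, superposition.

The inner loops operate on plain float tuples rather than ndarrays: chain
reconstruction is strictly sequential, and tuple arithmetic is an order of
magnitude faster than per-atom numpy calls, which matters for the
inverse-kinematic closure used by the fixture generator.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial.transform import Rotation

Vec3 = tuple[float, float, float]

__all__ = [
    "dihedral",
    "bond_angle",
    "place_atom",
    "superpose",
    "rmsd",
    "GeometryError",
]


class GeometryError(ValueError):
    """Degenerate geometry (collinear points, undefined torsion, ...)."""


def _as_tuple(p) -> Vec3:
    return (float(p[0]), float(p[1]), float(p[2]))


def _sub(a: Vec3, b: Vec3) -> Vec3:
    return (a[0] - b[0], a[1] - b[1], a[2] - b[2])


def _dot(a: Vec3, b: Vec3) -> float:
    return a[0] * b[0] + a[1] * b[1] + a[2] * b[2]


def _cross(a: Vec3, b: Vec3) -> Vec3:
    return (
        a[1] * b[2] - a[2] * b[1],
        a[2] * b[0] - a[0] * b[2],
        a[0] * b[1] - a[1] * b[0],
    )


def _norm(a: Vec3) -> float:
    return math.sqrt(_dot(a, a))


def _unit(a: Vec3) -> Vec3:
    n = _norm(a)
    if n < 1e-12:
        raise GeometryError("zero-length vector in torsion/placement geometry")
    return (a[0] / n, a[1] / n, a[2] / n)


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, IUPAC convention.

    Returns a value in (-180, 180]; exact trans is reported as +180.
    Raises GeometryError when three consecutive points are collinear
    (torsion undefined).
    """
    p1, p2, p3, p4 = map(_as_tuple, (p1, p2, p3, p4))
    b0 = _sub(p1, p2)
    b1 = _sub(p3, p2)
    b2 = _sub(p4, p3)
    nb1 = _norm(b1)
    if nb1 < 1e-12:
        raise GeometryError("coincident central atoms")
    b1 = (b0_ := b1[0] / nb1, b1[1] / nb1, b1[2] / nb1)
    # components of b0/b2 perpendicular to the central bond
    v = _sub(b0, (b1[0] * _dot(b0, b1), b1[1] * _dot(b0, b1), b1[2] * _dot(b0, b1)))
    w = _sub(b2, (b1[0] * _dot(b2, b1), b1[1] * _dot(b2, b1), b1[2] * _dot(b2, b1)))
    if _norm(v) < 1e-9 or _norm(w) < 1e-9:
        raise GeometryError("collinear points: torsion undefined")
    x = _dot(v, w)
    y = _dot(_cross(b1, v), w)
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def bond_angle(p1, p2, p3) -> float:
    """Angle at p2 between p1 and p3, in degrees."""
    p1, p2, p3 = map(_as_tuple, (p1, p2, p3))
    u = _unit(_sub(p1, p2))
    v = _unit(_sub(p3, p2))
    c = max(-1.0, min(1.0, _dot(u, v)))
    return math.degrees(math.acos(c))


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> Vec3:
    """Place atom x so that |c-x| = bond, angle(b,c,x) = angle and
    dihedral(a,b,c,x) = torsion (degrees).  Natural-extension (NeRF) step."""
    a, b, c = map(_as_tuple, (a, b, c))
    bc = _unit(_sub(c, b))
    n = _unit(_cross(_sub(b, a), bc))
    m = _cross(bc, n)
    th = math.radians(angle)
    ta = math.radians(torsion)
    d = bond * math.sin(th)
    d0 = -bond * math.cos(th)
    d1 = -d * math.cos(ta)
    d2 = d * math.sin(ta)
    return (
        c[0] + d0 * bc[0] + d1 * m[0] + d2 * n[0],
        c[1] + d0 * bc[1] + d1 * m[1] + d2 * n[1],
        c[2] + d0 * bc[2] + d1 * m[2] + d2 * n[2],
    )


def superpose(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of point set ``b`` onto ``a`` (Kabsch).

    Parameters
    ----------
    a, b : (n, 3) arrays of matched coordinates, n >= 3.

    Returns
    -------
    rotation : (3, 3) proper rotation matrix (det = +1)
    translation : (3,) vector
    rmsd : float, RMSD after applying ``x -> rotation @ x + translation`` to b.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("superpose expects two equal-shape (n, 3) arrays")
    n = a.shape[0]
    if n < 3:
        raise GeometryError("superposition needs at least 3 points")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    if np.linalg.matrix_rank(a0, tol=1e-8) < 2 or np.linalg.matrix_rank(b0, tol=1e-8) < 2:
        raise GeometryError("degenerate (collinear) point set")
    rot, _ = Rotation.align_vectors(a0, b0)
    rmat = rot.as_matrix()
    trans = ca - rmat @ cb
    # compute the rmsd from the applied rotation: the solver's residual
    # norm loses ~1e-6 absolute precision to cancellation near zero
    dev = b0 @ rmat.T - a0
    return rmat, trans, float(math.sqrt((dev * dev).sum() / n))


def rmsd(a: np.ndarray, b: np.ndarray, superposed: bool = True) -> float:
    """CA-style RMSD between matched coordinate sets; superposes first unless
    ``superposed`` is False (then plain coordinate RMSD)."""
    if superposed:
        return superpose(a, b)[2]
    d = np.asarray(a, float) - np.asarray(b, float)
    return float(math.sqrt((d * d).sum() / len(d)))
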
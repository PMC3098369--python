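"""Low-level 3D geometry: dihedrals, internal-coordinate placement, rigid maps.

All angles are in degrees on the IUPAC convention: a torsion is positive when,
looking from the second to the third atom, the far bond is rotated clockwise
from the near bond; values lie in (-180, 180].
"""

from __future__ import annotations

import numpy as np

from .errors import UndefinedTorsionError

_EPS = 1e-10


def _cross3(a, b):
    # np.cross carries large overhead for single 3-vectors; hand-rolled
    return np.array(
        [
            a[1] * b[2] - a[2] * b[1],
            a[2] * b[0] - a[0] * b[2],
            a[0] * b[1] - a[1] * b[0],
        ]
    )


def _norm3(a):
    return float(np.sqrt(a[0] * a[0] + a[1] * a[1] + a[2] * a[2]))


def wrap_angle(angle_deg: float) -> float:
    """Wrap an angle into (-180, 180]."""
    a = (np.asarray(angle_deg) + 180.0) % 360.0 - 180.0
    a = np.where(a <= -180.0, a + 360.0, a)
    # map -180 -> 180
    a = np.where(np.isclose(a, -180.0), 180.0, a)
    return float(a) if np.ndim(angle_deg) == 0 else a


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle (degrees) of the chain p1-p2-p3-p4.

    Uses the plane-normal atan2 formulation; raises UndefinedTorsionError when
    consecutive points coincide or p1/p4 is collinear with the p2-p3 axis.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    if min(_norm3(b1), _norm3(b2), _norm3(b3)) < _EPS:
        raise UndefinedTorsionError("coincident consecutive points")
    n1 = _cross3(b1, b2)
    n2 = _cross3(b2, b3)
    if _norm3(n1) < _EPS or _norm3(n2) < _EPS:
        raise UndefinedTorsionError("collinear points: torsion undefined")
    b2h = b2 / _norm3(b2)
    y = np.dot(_cross3(n1, n2), b2h)
    x = np.dot(n1, n2)
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if ang <= -180.0 + 1e-13 else float(ang)


def angle(p1, p2, p3) -> float:
    """Bond angle p1-p2-p3 in degrees."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    a = p1 - p2
    b = p3 - p2
    cosang = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom x bonded to c with |x-c| = bond, angle(b,c,x) = angle_deg and
    dihedral(a,b,c,x) = torsion_deg (natural-extension reference frame)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    th = np.radians(angle_deg)
    ph = np.radians(torsion_deg)
    d2 = bond * np.array(
        [-np.cos(th), np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph)]
    )
    bc = c - b
    bc = bc / _norm3(bc)
    ab = b - a
    n = _cross3(ab, bc)
    nn = _norm3(n)
    if nn < _EPS:
        raise UndefinedTorsionError("reference atoms are collinear")
    n = n / nn
    m = _cross3(n, bc)
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def frame_map(src: np.ndarray, dst: np.ndarray):
    """Rigid transform (R, t) mapping the 3 points `src` exactly onto `dst`.

    The point triples must be congruent (same pairwise distances); returns
    (rotation matrix, translation) such that x @ R.T + t maps src -> dst.
    """

    def _frame(p):
        e1 = p[1] - p[0]
        e1 = e1 / _norm3(e1)
        v = p[2] - p[0]
        e2 = v - np.dot(v, e1) * e1
        e2 = e2 / _norm3(e2)
        e3 = _cross3(e1, e2)
        return np.column_stack([e1, e2, e3])

    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    rs, rd = _frame(src), _frame(dst)
    rot = rd @ rs.T
    t = dst[0] - rot @ src[0]
    return rot, t


def rotate_about_bond(points: np.ndarray, origin, axis, angle_deg: float) -> np.ndarray:
    """Rotate `points` by angle_deg about the axis through `origin` along `axis`."""
    from scipy.spatial.transform import Rotation

    origin = np.asarray(origin, dtype=float)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    rot = Rotation.from_rotvec(np.radians(angle_deg) * axis)
    return rot.apply(points - origin) + origin
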
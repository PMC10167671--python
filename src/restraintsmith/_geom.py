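"""Small vector-geometry helpers shared by model building, link
disambiguation, hydrogen placement and the regularizer."""

from __future__ import annotations

import numpy as np


def normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("cannot normalize a zero vector")
    return v / n


def angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u = a - b
    v = c - b
    cosang = np.dot(u, v)
    sinang = np.linalg.norm(np.cross(u, v))
    return float(np.degrees(np.arctan2(sinang, cosang)))


def torsion_deg(a, b, c, d) -> float:
    """Dihedral a-b-c-d in degrees, in (-180, 180]."""
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    t = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if t <= -180.0 else t


def wrap_deg(x: float) -> float:
    """Wrap an angle difference into (-180, 180]."""
    r = (x + 180.0) % 360.0 - 180.0
    return 180.0 if r == -180.0 else r


def periodic_delta(value: float, ideal: float, period: int = 1) -> float:
    """Smallest angular distance (degrees) between value and the set of
    period-equivalent ideals {ideal + k*360/period}."""
    step = 360.0 / max(period, 1)
    d = (value - ideal) % step
    if d > step / 2:
        d -= step
    return d


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               dist: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom X bonded to ``c`` with |X-c| = dist, angle X-c-b = angle
    and dihedral X-c-b-a = torsion (NERF construction; angles in degrees)."""
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = normalize(c - b)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        # a,b,c collinear: any perpendicular works; pick deterministically
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ref, bc)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        n = np.cross(ref, bc)
        nn = np.linalg.norm(n)
    n = n / nn
    m = np.cross(n, bc)
    # component signs chosen so that torsion_deg(x, c, b, a) == torsion
    d2 = np.array([
        -dist * np.cos(ang),
        dist * np.sin(ang) * np.cos(tor),
        -dist * np.sin(ang) * np.sin(tor),
    ])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def chiral_volume(centre, p1, p2, p3) -> float:
    """Signed scalar triple product of the three centre->neighbor vectors."""
    return float(np.dot(p1 - centre, np.cross(p2 - centre, p3 - centre)))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
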
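"""Small vector-geometry helpers shared across modules."""

from __future__ import annotations

import numpy as np


def angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in radians."""
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Torsion angle over four points, radians in (-pi, pi]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.arctan2(y, x))


def place_from_internal(
    p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
    bond: float, theta: float, phi: float,
) -> np.ndarray:
    """NeRF-style placement: a point at distance ``bond`` from ``p2``, with
    angle ``theta`` at p2 (p1-p2-new) and torsion ``phi`` over p0-p1-p2-new."""
    b1 = p2 - p1
    b1 /= np.linalg.norm(b1)
    b0 = p1 - p0
    n = np.cross(b0, b1)
    n /= np.linalg.norm(n)
    m = np.cross(n, b1)
    d = np.array([
        -bond * np.cos(theta),
        bond * np.sin(theta) * np.cos(phi),
        -bond * np.sin(theta) * np.sin(phi),
    ])
    return p2 + d[0] * b1 + d[1] * m + d[2] * n


def orthonormal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic right-handed frame with ``e1`` along ``axis``."""
    e1 = axis / np.linalg.norm(axis)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(e1, ref)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    e2 = np.cross(e1, ref)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    return e1, e2, e3


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, sign-fixed)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def wrap_degrees(delta: np.ndarray | float) -> np.ndarray | float:
    """Wrap an angle difference in degrees to (-180, 180]."""
    return -((-np.asarray(delta) + 180.0) % 360.0 - 180.0)
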
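"""Analytic solid primitives with vectorized point-membership tests.

Phantoms are assembled from these solids with a painter's algorithm
(later solids override earlier ones), so every primitive only needs to
answer "is this point inside?" for arrays of points, plus a conservative
axis-aligned bounding box used to prune candidate lattice nodes.

All coordinates are in millimetres.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Solid",
    "Ellipsoid",
    "BulgedEllipsoid",
    "Sphere",
    "Cylinder",
    "Tube",
    "Box",
    "HalfSpace",
    "Intersection",
    "Difference",
    "Union",
    "orthonormal_frame",
]


def _as_points(pts: np.ndarray) -> np.ndarray:
    pts = np.asarray(pts, dtype=float)
    if pts.ndim == 1:
        pts = pts[None, :]
    return pts


def orthonormal_frame(z_axis, x_hint) -> np.ndarray:
    """Rotation matrix whose *columns* are a right-handed frame.

    The third column equals the normalized ``z_axis``; the first column is
    the component of ``x_hint`` orthogonal to it.
    """
    z = np.asarray(z_axis, float)
    z = z / np.linalg.norm(z)
    x = np.asarray(x_hint, float)
    x = x - (x @ z) * z
    nx = np.linalg.norm(x)
    if nx < 1e-12:
        raise ValueError("x_hint is parallel to z_axis")
    x = x / nx
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


class Solid:
    """Base class: an oriented solid region of 3-space."""

    def contains(self, pts: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:  # pragma: no cover
        raise NotImplementedError


class Ellipsoid(Solid):
    """Ellipsoid with semi-axes ``semi`` in a local frame ``R`` (columns)."""

    def __init__(self, center, semi, R: np.ndarray | None = None):
        self.center = np.asarray(center, float)
        self.semi = np.asarray(semi, float)
        if np.any(self.semi <= 0):
            raise ValueError("ellipsoid semi-axes must be positive")
        self.R = np.eye(3) if R is None else np.asarray(R, float)

    def _local(self, pts):
        return (_as_points(pts) - self.center) @ self.R

    def contains(self, pts):
        q = self._local(pts) / self.semi
        return np.einsum("ij,ij->i", q, q) <= 1.0

    def bounds(self):
        # extent of rotated ellipsoid along world axis k: sqrt(sum_j (R[k,j]*s_j)^2)
        ext = np.sqrt(((self.R * self.semi) ** 2).sum(axis=1))
        return self.center - ext, self.center + ext


class Sphere(Ellipsoid):
    def __init__(self, center, radius):
        super().__init__(center, (radius, radius, radius))
        self.radius = float(radius)


class BulgedEllipsoid(Solid):
    """Axisymmetric solid of revolution about the local z axis.

    Radius profile  r(z) = a * sqrt(1 - (z/c)^2) * (1 + amp * cos(pi z / (2 c))^2)

    With ``amp = 0`` this is a prolate ellipsoid of revolution (a, a, c).
    The cosine-squared bump applies full dilation at the equator and tapers
    smoothly to zero at the apex and base poles; it is used to model dilated
    (DCM) ventricular cavities where apical/basal dilation is attenuated.
    """

    def __init__(self, center, a, c, amp=0.0, R: np.ndarray | None = None):
        self.center = np.asarray(center, float)
        self.a = float(a)
        self.c = float(c)
        self.amp = float(amp)
        if self.a <= 0 or self.c <= 0:
            raise ValueError("semi-axes must be positive")
        self.R = np.eye(3) if R is None else np.asarray(R, float)

    def radius_at(self, z):
        """Profile radius at local height z (vectorized; 0 outside |z|>c)."""
        z = np.asarray(z, float)
        u = np.clip(z / self.c, -1.0, 1.0)
        base = self.a * np.sqrt(np.maximum(0.0, 1.0 - u * u))
        return base * (1.0 + self.amp * np.cos(0.5 * np.pi * u) ** 2)

    def contains(self, pts):
        loc = (_as_points(pts) - self.center) @ self.R
        z = loc[:, 2]
        inside_z = np.abs(z) <= self.c
        r = self.radius_at(z)
        rho2 = loc[:, 0] ** 2 + loc[:, 1] ** 2
        return inside_z & (rho2 <= r * r)

    def bounds(self):
        ext_local = np.array([self.a * (1 + max(self.amp, 0.0))] * 2 + [self.c])
        ext = np.sqrt(((self.R * ext_local) ** 2).sum(axis=1))
        return self.center - ext, self.center + ext


class Cylinder(Solid):
    """Finite right circular cylinder with flat caps, axis p0 -> p1."""

    def __init__(self, p0, p1, radius):
        self.p0 = np.asarray(p0, float)
        self.p1 = np.asarray(p1, float)
        self.radius = float(radius)
        d = self.p1 - self.p0
        self.length = float(np.linalg.norm(d))
        if self.length < 1e-12:
            raise ValueError("degenerate cylinder axis")
        self.axis = d / self.length

    def contains(self, pts):
        v = _as_points(pts) - self.p0
        t = v @ self.axis
        inside_t = (t >= 0.0) & (t <= self.length)
        perp = v - t[:, None] * self.axis
        return inside_t & (np.einsum("ij,ij->i", perp, perp) <= self.radius**2)

    def bounds(self):
        lo = np.minimum(self.p0, self.p1) - self.radius
        hi = np.maximum(self.p0, self.p1) + self.radius
        return lo, hi


class Tube(Solid):
    """Capsule of given radius around a polyline (used for coil electrodes)."""

    def __init__(self, points, radius):
        self.points = np.asarray(points, float)
        if self.points.ndim != 2 or self.points.shape[0] < 2:
            raise ValueError("polyline needs at least two points")
        self.radius = float(radius)
        self._a = self.points[:-1]
        d = self.points[1:] - self._a
        self._len = np.linalg.norm(d, axis=1)
        if np.any(self._len < 1e-12):
            raise ValueError("degenerate polyline segment")
        self._dir = d / self._len[:, None]

    @property
    def length(self):
        return float(self._len.sum())

    def contains(self, pts):
        pts = _as_points(pts)
        r2 = self.radius**2
        out = np.zeros(len(pts), dtype=bool)
        for a, u, L in zip(self._a, self._dir, self._len):
            v = pts - a
            t = np.clip(v @ u, 0.0, L)
            perp = v - t[:, None] * u
            out |= np.einsum("ij,ij->i", perp, perp) <= r2
        return out

    def bounds(self):
        return self.points.min(axis=0) - self.radius, self.points.max(axis=0) + self.radius


class Box(Solid):
    def __init__(self, lo, hi):
        self.lo = np.asarray(lo, float)
        self.hi = np.asarray(hi, float)
        if np.any(self.hi <= self.lo):
            raise ValueError("box upper corner must exceed lower corner")

    def contains(self, pts):
        pts = _as_points(pts)
        return np.all((pts >= self.lo) & (pts <= self.hi), axis=1)

    def bounds(self):
        return self.lo.copy(), self.hi.copy()


class HalfSpace(Solid):
    """Points x with (x - point) . normal <= 0."""

    def __init__(self, point, normal):
        self.point = np.asarray(point, float)
        n = np.asarray(normal, float)
        self.normal = n / np.linalg.norm(n)

    def contains(self, pts):
        return (_as_points(pts) - self.point) @ self.normal <= 0.0

    def bounds(self):
        big = 1e6
        return np.full(3, -big), np.full(3, big)


class Intersection(Solid):
    def __init__(self, *solids):
        if not solids:
            raise ValueError("empty intersection")
        self.solids = list(solids)

    def contains(self, pts):
        out = self.solids[0].contains(pts)
        for s in self.solids[1:]:
            out = out & s.contains(pts)
        return out

    def bounds(self):
        los, his = zip(*(s.bounds() for s in self.solids))
        return np.max(los, axis=0), np.min(his, axis=0)


class Difference(Solid):
    """Points in ``base`` but not in any of ``cut``."""

    def __init__(self, base: Solid, *cut: Solid):
        self.base = base
        self.cut = list(cut)

    def contains(self, pts):
        out = self.base.contains(pts)
        for s in self.cut:
            out = out & ~s.contains(pts)
        return out

    def bounds(self):
        return self.base.bounds()


class Union(Solid):
    def __init__(self, *solids):
        if not solids:
            raise ValueError("empty union")
        self.solids = list(solids)

    def contains(self, pts):
        out = self.solids[0].contains(pts)
        for s in self.solids[1:]:
            out = out | s.contains(pts)
        return out

    def bounds(self):
        los, his = zip(*(s.bounds() for s in self.solids))
        return np.min(los, axis=0), np.max(his, axis=0)
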
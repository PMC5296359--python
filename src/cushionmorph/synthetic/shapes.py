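"""Implicit solid geometry for synthetic endocardial cells.

A synthetic cell is a rigid ellipsoid body with optional spikes —
cylinders with hemispherical caps (capsules) anchored at random surface
points and pointing along the outward normal — emulating the filopodial
projections of cells undergoing endothelial-to-mesenchymal transition.
The implicit (inside/outside) representation gives exact membership tests
at any resolution, which is what makes brute-force ground truth possible.

Analytic references used as oracles: exact ellipsoid volume, the Legendre
elliptic-integral surface area, and the uniform-solid-ellipsoid covariance
eigenvalues (semi-axes squared over five).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ellipkinc, ellipeinc

__all__ = [
    "Ellipsoid",
    "Capsule",
    "ImplicitCell",
    "ellipsoid_volume",
    "ellipsoid_surface_area",
    "ellipsoid_covariance_eigenvalues",
    "random_rotation",
]


def ellipsoid_volume(a: float, b: float, c: float) -> float:
    """Volume of an ellipsoid with semi-axes a, b, c."""
    return 4.0 / 3.0 * np.pi * a * b * c


def ellipsoid_surface_area(a: float, b: float, c: float) -> float:
    """Exact surface area of a triaxial ellipsoid (Legendre form).

    Reduces to 4πr² for a sphere; valid for any ordering of the semi-axes.
    """
    a, b, c = sorted((float(a), float(b), float(c)), reverse=True)
    if (a - c) < 1e-12 * a:
        return 4.0 * np.pi * a * a
    phi = np.arccos(c / a)
    k2 = (a * a * (b * b - c * c)) / (b * b * (a * a - c * c))
    F = ellipkinc(phi, k2)
    E = ellipeinc(phi, k2)
    s = np.sin(phi)
    return float(2 * np.pi * c * c + (2 * np.pi * a * b / s) * (E * s * s + F * np.cos(phi) ** 2))


def ellipsoid_covariance_eigenvalues(a: float, b: float, c: float) -> tuple[float, float, float]:
    """Covariance eigenvalues of a uniform solid ellipsoid, descending.

    For a uniform solid the positional covariance is diag(a², b², c²) / 5
    in the principal frame, so the elongation factor (medium/largest) is
    the squared ratio of the corresponding semi-axes.
    """
    vals = sorted((a * a / 5.0, b * b / 5.0, c * c / 5.0), reverse=True)
    return (vals[0], vals[1], vals[2])


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3x3 rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


@dataclass(frozen=True)
class Ellipsoid:
    """Ellipsoid body: center (z, y, x) µm, semi-axes µm, rotation matrix.

    ``rotation`` maps body-frame coordinates to world frame.
    """

    center: np.ndarray
    semi_axes: np.ndarray  # (a, b, c) along body axes
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership for an (N, 3) array of world points."""
        local = (points - self.center) @ self.rotation  # world -> body
        return np.sum((local / self.semi_axes) ** 2, axis=-1) <= 1.0

    def surface_point_and_normal(self, direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Surface point along a body-frame direction, with outward normal (world)."""
        d = direction / np.linalg.norm(direction)
        t = 1.0 / np.sqrt(np.sum((d / self.semi_axes) ** 2))
        local = t * d
        normal_local = local / self.semi_axes**2
        normal_local /= np.linalg.norm(normal_local)
        return (
            self.center + self.rotation @ local,
            self.rotation @ normal_local,
        )

    @property
    def bbox_radius(self) -> float:
        return float(np.max(self.semi_axes))


@dataclass(frozen=True)
class Capsule:
    """Cylinder with hemispherical caps between two world points."""

    p0: np.ndarray
    p1: np.ndarray
    radius: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        axis = self.p1 - self.p0
        denom = float(axis @ axis)
        if denom == 0:
            d2 = np.sum((points - self.p0) ** 2, axis=-1)
            return d2 <= self.radius**2
        t = np.clip(((points - self.p0) @ axis) / denom, 0.0, 1.0)
        nearest = self.p0 + t[..., None] * axis
        d2 = np.sum((points - nearest) ** 2, axis=-1)
        return d2 <= self.radius**2


@dataclass(frozen=True)
class ImplicitCell:
    """Union of an ellipsoid body and spike capsules."""

    body: Ellipsoid
    spikes: tuple[Capsule, ...] = ()

    def contains(self, points: np.ndarray) -> np.ndarray:
        inside = self.body.contains(points)
        for s in self.spikes:
            inside |= s.contains(points)
        return inside

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Conservative axis-aligned world bounding box (lo, hi)."""
        r = self.body.bbox_radius
        lo = self.body.center - r
        hi = self.body.center + r
        for s in self.spikes:
            for p in (s.p0, s.p1):
                lo = np.minimum(lo, p - s.radius)
                hi = np.maximum(hi, p + s.radius)
        return lo, hi
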
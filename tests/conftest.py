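"""Shared geometry helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from cushionmorph.morphometry import LabelVolume


def voxelized_sphere(radius_vox: float, spacing: float = 1.0, pad: int = 3) -> LabelVolume:
    """Single digitized ball (label 1) centered in its grid."""
    n = int(2 * radius_vox) + 2 * pad
    c = n / 2.0
    z, y, x = np.mgrid[:n, :n, :n]
    mask = (z + 0.5 - c) ** 2 + (y + 0.5 - c) ** 2 + (x + 0.5 - c) ** 2 <= radius_vox**2
    return LabelVolume(mask.astype(np.int32), (spacing,) * 3)


def voxelized_ellipsoid(
    semi_axes, spacing: float = 1.0, pad_um: float = 1.0
) -> LabelVolume:
    """Single axis-aligned digitized ellipsoid (semi-axes in µm)."""
    a = np.asarray(semi_axes, dtype=float)
    n = np.ceil(2 * (a + pad_um) / spacing).astype(int)
    axes = [(np.arange(k) + 0.5) * spacing - k * spacing / 2 for k in n]
    Z, Y, X = np.meshgrid(*axes, indexing="ij")
    mask = (Z / a[0]) ** 2 + (Y / a[1]) ** 2 + (X / a[2]) ** 2 <= 1.0
    return LabelVolume(mask.astype(np.int32), (spacing,) * 3)


@pytest.fixture(scope="session")
def sphere_r20():
    return voxelized_sphere(20.0)
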
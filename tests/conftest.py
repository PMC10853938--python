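"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from gbsolv import Molecule


@pytest.fixture()
def h2():
    return Molecule(("H", "H"), np.array([[0.0, 0.0, 0.0], [0.74, 0.0, 0.0]]))


@pytest.fixture()
def hcl():
    return Molecule(("H", "Cl"), np.array([[0.0, 0.0, 0.0], [1.27, 0.0, 0.0]]))


@pytest.fixture()
def water_like():
    # bent H-O-H, O at origin, ~0.96 A bonds, ~104.5 deg
    return Molecule(
        ("O", "H", "H"),
        np.array([
            [0.0, 0.0, 0.0],
            [0.9572, 0.0, 0.0],
            [-0.2400, 0.9266, 0.0],
        ]),
    )


@pytest.fixture()
def methane():
    b = 1.09 / np.sqrt(3.0)
    return Molecule(
        ("C", "H", "H", "H", "H"),
        np.array([
            [0.0, 0.0, 0.0],
            [b, b, b],
            [b, -b, -b],
            [-b, b, -b],
            [-b, -b, b],
        ]),
    )


def random_rotation(rng):
    """Uniform random 3x3 rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def mc_exposed_area(R_I, R_J, r_IJ, n_samples, seed):
    """Monte-Carlo oracle: exposed area of sphere I overlapped by J.

    Samples points uniformly on sphere I (center origin, J on the +x axis)
    and counts those outside J.  Returns (area, binomial sigma).
    """
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n_samples, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    pts = R_I * v
    center_j = np.array([r_IJ, 0.0, 0.0])
    outside = np.linalg.norm(pts - center_j, axis=1) >= R_J
    p = outside.mean()
    total = 4.0 * np.pi * R_I * R_I
    sigma = total * np.sqrt(max(p * (1 - p), 1e-12) / n_samples)
    return total * p, sigma


def mc_retained_volume(R_I, R_J, r_IJ, n_samples, seed):
    """Monte-Carlo oracle: plane-partitioned retained volume of sphere I.

    The overlap lens is split between the two spheres by the crossing plane
    at offset a = (r^2 + R_I^2 - R_J^2) / (2r) from I's center, so sphere I
    retains the part of its ball on I's side of the plane (everything when
    the spheres do not overlap, nothing when I is contained in J).
    """
    rng = np.random.default_rng(seed)
    pts = rng.uniform(-R_I, R_I, size=(n_samples, 3))
    inside_i = (pts**2).sum(axis=1) <= R_I * R_I
    a = (r_IJ * r_IJ + R_I * R_I - R_J * R_J) / (2.0 * r_IJ)
    keep = inside_i & (pts[:, 0] <= a)
    p = keep.mean()
    box = (2.0 * R_I) ** 3
    sigma = box * np.sqrt(max(p * (1 - p), 1e-12) / n_samples)
    return box * p, sigma
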
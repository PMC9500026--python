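"""Laminar velocity profile in a square duct.

Classical Fourier-series solution of fully developed pressure-driven flow
in a duct of square cross-section (side ``a``, no-slip walls), used both as
synthetic ground truth for the particle-tracking pipeline and to convert
observed midplane velocities into a volumetric flow rate.  The boundary
layer's momentum-flux deficit relative to plug flow is what makes the
centerline velocity exceed the mean by a factor of ~2.096.

Coordinates: ``y`` and ``z`` both in [0, a]; in the imaging convention ``y``
is the in-plane cross-channel coordinate and ``z`` the depth coordinate
(the camera focuses on the midplane z = a/2).
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

__all__ = [
    "duct_shape",
    "square_duct_profile",
    "midplane_profile",
    "centerline_to_mean_ratio",
]


def _series(y, z, side_a: float, n_terms: int):
    """Unnormalized series sum over odd harmonics."""
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    out = np.zeros(np.broadcast(y, z).shape)
    for j in range(n_terms):
        n = 2 * j + 1
        out += (
            (1.0 / n**3)
            * (1.0 - np.cosh(n * math.pi * (z - side_a / 2) / side_a)
               / math.cosh(n * math.pi / 2))
            * np.sin(n * math.pi * y / side_a)
        )
    return out


@lru_cache(maxsize=64)
def _mean_factor(n_terms: int) -> float:
    """Cross-section average of the unnormalized series (analytic integrals)."""
    total = 0.0
    for j in range(n_terms):
        n = 2 * j + 1
        total += (1.0 / n**3) * (2.0 / (n * math.pi)) * (
            1.0 - (2.0 / (n * math.pi)) * math.tanh(n * math.pi / 2.0)
        )
    return total


def duct_shape(y, z, side_a: float, n_terms: int = 50):
    """Velocity shape normalized to unit cross-sectional mean.

    ``duct_shape * (Q / a^2)`` is the local velocity for flow rate ``Q``.
    """
    if n_terms < 10:
        raise ValueError("n_terms must be >= 10 for an accurate profile")
    return _series(y, z, side_a, n_terms) / _mean_factor(n_terms)


def square_duct_profile(y, z, flow_rate: float, side_a: float, n_terms: int = 50):
    """Local streamwise velocity u(y, z) for volumetric flow rate ``flow_rate``.

    Units follow the inputs (e.g. um and um^3/s give um/s).
    """
    return duct_shape(y, z, side_a, n_terms) * (flow_rate / side_a**2)


def midplane_profile(y, flow_rate: float, side_a: float, n_terms: int = 50):
    """u(y, z = a/2): the profile seen by midplane-focused imaging."""
    return square_duct_profile(y, side_a / 2.0, flow_rate, side_a, n_terms)


def centerline_to_mean_ratio(n_terms: int = 50) -> float:
    """Ratio of centerline velocity u(a/2, a/2) to the mean velocity."""
    return float(duct_shape(0.5, 0.5, 1.0, n_terms))
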
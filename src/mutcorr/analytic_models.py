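"""Closed-form two-orbital toy model used as the analytic oracle.

A singlet, symmetry-restricted state of two electrons in two orbitals,

    |psi(theta)> = cos(theta) |20> + sin(theta) |02>,

admits closed forms for the subsystem correlation of either orbital and the
mutual correlation between them:

    C_A(theta) = C_B(theta) = cos^4(theta) sin^4(theta)
    M_AB(theta) = (1/8) (5 - cos(4 theta)) sin^2(2 theta)

Both vanish at theta = k pi/2 (single determinants) and peak at
theta = pi/4 + k pi/2 (Bell-type geminals) with values 1/16 and 3/4; the
total C_S = 2 C_A + M_AB peaks at 7/8.
"""

from __future__ import annotations

import numpy as np

from .fock_space import CIVector, parse_state

__all__ = ["toy_state", "toy_CA", "toy_MAB", "toy_CS"]


def toy_state(theta: float) -> CIVector:
    """The two-determinant state cos(theta)|20> + sin(theta)|02>."""
    c, s = np.cos(theta), np.sin(theta)
    terms = []
    if abs(c) > 1e-300:
        terms.append(("20", c))
    if abs(s) > 1e-300:
        terms.append(("02", s))
    return parse_state(terms, normalize=True)


def toy_CA(theta: float) -> float:
    """Subsystem correlation of either orbital fragment."""
    return float(np.cos(theta) ** 4 * np.sin(theta) ** 4)


def toy_MAB(theta: float) -> float:
    """Mutual correlation between the two orbital fragments."""
    return float(
        (5.0 - np.cos(4.0 * theta)) * np.sin(2.0 * theta) ** 2 / 8.0
    )


def toy_CS(theta: float) -> float:
    """Total correlation C_S = 2 C_A + M_AB."""
    return 2.0 * toy_CA(theta) + toy_MAB(theta)
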
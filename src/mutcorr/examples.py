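"""Worked-example states: four-electron singlets in four orbitals.

These two-up/two-down states all saturate the total-correlation bound of
their sector (C = 1.75 on the unique-pair scale) while the eigenvalue-based
metrics rank them very differently, which makes them useful end-to-end
checks of the tensor conventions.
"""

from __future__ import annotations

import math

from .fock_space import CIVector, parse_state

__all__ = ["bell_singlet_open", "bell_singlet_paired", "interpolated_singlet",
           "six_term_singlet", "EXAMPLES"]

_S2 = math.sqrt(2.0)


def bell_singlet_open() -> CIVector:
    """(|ud d u> - |du u d>)/sqrt2 with singly occupied orbitals."""
    return parse_state([("uddu", 1 / _S2), ("duud", -1 / _S2)])


def bell_singlet_paired() -> CIVector:
    """(|0220> - |2002>)/sqrt2, a Bell-type geminal superposition."""
    return parse_state([("0220", 1 / _S2), ("2002", -1 / _S2)])


def interpolated_singlet() -> CIVector:
    """Four-determinant state with coefficient ratio 1 : (1 + sqrt2)."""
    w = 1.0 + _S2
    return parse_state(
        [("0022", 1.0), ("2200", -1.0), ("0202", w), ("2020", -w)]
    )


def six_term_singlet() -> CIVector:
    """Equal-weight six-determinant seniority-zero state."""
    return parse_state(
        [("2200", 1), ("2002", 1), ("0220", 1), ("0022", 1),
         ("2020", -1), ("0202", -1)]
    )


EXAMPLES = {
    "bell_open": bell_singlet_open,
    "bell_paired": bell_singlet_paired,
    "interpolated": interpolated_singlet,
    "six_term": six_term_singlet,
}
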
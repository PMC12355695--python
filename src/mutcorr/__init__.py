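"""Correlation analysis of many-electron states via the 2-RDM cumulant.

The package computes the lambda2-norm total correlation, its decomposition
into subsystem and mutual contributions, orbital-pair mutual correlation,
orbital entropies and mutual information, and maximally correlated orbitals,
from CI vectors, FCIDUMP integrals, or imported spin-resolved RDMs.
"""

from .fock_space import (
    CIVector,
    DeterminantSpace,
    HubbardModel,
    build_hubbard_hamiltonian,
    enumerate_determinants,
    lowest_states,
    parse_state,
    product_state,
)
from .density import (
    MetricReport,
    cumulant,
    matricize_geminal,
    matricize_ph,
    metrics,
    natural_orbitals,
    one_rdm,
    raw_frobenius_sq,
    two_rdm,
)

__version__ = "0.1.0"


def cumulant_of(psi: CIVector):
    """Convenience: CI vector -> (g1, g2, lambda2)."""
    g1 = one_rdm(psi)
    g2 = two_rdm(psi)
    return g1, g2, cumulant(g1, g2)
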
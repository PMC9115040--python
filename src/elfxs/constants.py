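"""Physical constants and unit conversions.

Internal convention: Hartree atomic units everywhere (energies in hartree,
momenta in 1/bohr, lengths in bohr).  Public interfaces speak eV for energies
and atomic units for momentum transfer; cross-section outputs are converted to
nm-based units at the boundary.
"""

HARTREE_EV = 27.211386
"""1 hartree in eV (single source of truth for the energy conversion)."""

BOHR_NM = 0.0529177
"""1 bohr in nm."""

BOHR_ANGSTROM = 0.529177

EV_HARTREE = 1.0 / HARTREE_EV


def ev_to_hartree(e_ev):
    return e_ev * EV_HARTREE


def hartree_to_ev(e_ha):
    return e_ha * HARTREE_EV
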
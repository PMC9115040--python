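"""Closed-form Lindhard response of the homogeneous electron gas.

The free-electron gas is the analytic oracle for the RPA pipeline: its
non-interacting density-density response chi0(q, E) has a closed form at
complex frequency E + i*eta, the RPA dielectric function is
eps = 1 - v(q) * chi0, and the ELF follows as Im[-1/eps].  All quantities in
Hartree atomic units per unit volume; the broadening eta must be > 0 so that
all logarithms stay on the principal branch.
"""

from __future__ import annotations

import numpy as np

from .constants import EV_HARTREE

__all__ = [
    "fermi_wavevector",
    "plasma_frequency",
    "lindhard_chi0",
    "lindhard_elf",
]


def fermi_wavevector(density: float) -> float:
    """k_F = (3*pi^2*n)^(1/3) in a.u."""
    return (3.0 * np.pi**2 * density) ** (1.0 / 3.0)


def plasma_frequency(density: float) -> float:
    """omega_p = sqrt(4*pi*n) in hartree."""
    return np.sqrt(4.0 * np.pi * density)


def lindhard_chi0(density: float, q, energy_ev, eta_ev: float) -> np.ndarray:
    """Closed-form chi0(q, E + i*eta) of the free gas (a.u., per volume).

    Parameters are the electron density (per bohr^3), momentum transfer q
    (a.u.), energy loss (eV, scalar or array) and broadening eta (eV, > 0).
    Spin factor 2 included: the static long-wavelength limit is -k_F/pi^2.
    """
    if eta_ev <= 0:
        raise ValueError("eta must be positive")
    kf = fermi_wavevector(density)
    q = float(q)
    w = (np.asarray(energy_ev, dtype=float) + 1j * eta_ev) * EV_HARTREE
    z = q / (2.0 * kf)
    u = w / (q * kf)

    def F(x):
        return (1.0 - x**2) / (4.0 * z) * np.log((x + 1.0) / (x - 1.0))

    return -(kf / (2.0 * np.pi**2)) * (1.0 + F(z - u) + F(z + u))


def lindhard_elf(density: float, q, energy_ev, eta_ev: float) -> np.ndarray:
    """RPA ELF of the free gas: Im[-1/eps] with eps = 1 - 4*pi/q^2 * chi0."""
    chi0 = lindhard_chi0(density, q, energy_ev, eta_ev)
    eps = 1.0 - (4.0 * np.pi / float(q) ** 2) * chi0
    return np.imag(-1.0 / eps)
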
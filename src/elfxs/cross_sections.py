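"""Born-approximation inelastic cross sections from a Bethe surface.

Given a tabulated ELF(E, q), the non-relativistic plane-wave Born
approximation yields, for an incident electron of kinetic energy T:

    d2S/dE dq = ELF(E, q) / (pi * a0 * T * q)                 (DDCS)
    dS/dE     = 1/(pi a0 T) * int_{q-}^{q+} ELF(E, q)/q dq    (SDCS)
    S(T)      = int_{E_min}^{E_max} dS/dE dE                  (inverse IMFP)
    S_e(T)    = int_{E_min}^{E_max} E * dS/dE dE              (stopping power)

with momentum-conservation limits q-/+ = sqrt(2m)(sqrt(T) -/+ sqrt(T-E))
and E_max = min[(T + E_gap)/2, T - E_F].  E_min defaults to 0 (excitation is
possible below the nominal gap); ``emin_mode='gap'`` applies the threshold
E_min = E_gap instead.

Internal arithmetic is in hartree atomic units (a0 = 1); tabulated outputs
are converted to the nm-based units used by track-structure codes:
the total cross section per unit path length in 1/nm, IMFP in nm, stopping
power in eV/nm, SDCS in 1/(eV nm).

The q integration runs on a logarithmic grid (trapezoid in ln q); values of
q below the tabulated range use the optical column, values above it are
extrapolated log-log from the last two columns, and the fraction of the SDCS
integral obtained from extrapolated values is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import BOHR_NM, EV_HARTREE, HARTREE_EV
from .surfaces import BetheSurfaceInterpolator, ELFSurface

__all__ = [
    "KinematicLimits",
    "SDCSCurve",
    "CrossSectionTable",
    "kinematic_limits",
    "ddcs",
    "sdcs",
    "total_cross_section",
    "stopping_power",
    "channel_cross_sections",
    "AU_INV_LENGTH_PER_NM",
    "AU_SDCS_PER_EV_NM",
]

#: 1/bohr in 1/nm and 1/(hartree*bohr) in 1/(eV*nm).
AU_INV_LENGTH_PER_NM = 1.0 / BOHR_NM
AU_SDCS_PER_EV_NM = 1.0 / (HARTREE_EV * BOHR_NM)
AU_STOPPING_PER_EV_NM = HARTREE_EV / BOHR_NM


@dataclass(frozen=True)
class KinematicLimits:
    """Momentum-conservation limits for energy loss E at incident energy T.

    q_min * q_max = 2mE is an algebraic identity of the closed forms.
    """

    T: float  # eV
    E: float  # eV
    q_min: float  # a.u.
    q_max: float  # a.u.


def kinematic_limits(T_ev: float, E_ev: float) -> KinematicLimits:
    """q-/+ = sqrt(2m) (sqrt(T) -/+ sqrt(T - E)) in atomic units (m = 1)."""
    if E_ev < 0 or T_ev <= 0:
        raise ValueError("need T > 0 and E >= 0")
    if E_ev > T_ev:
        raise ValueError(f"energy loss E = {E_ev:g} eV exceeds T = {T_ev:g} eV")
    t = T_ev * EV_HARTREE
    e = E_ev * EV_HARTREE
    s, d = np.sqrt(2.0 * t), np.sqrt(2.0 * (t - e))
    q_max = s + d
    # rationalized form of s - d: avoids cancellation at E << T and makes
    # the q_min*q_max = 2mE identity hold to round-off
    q_min = 2.0 * e / q_max
    return KinematicLimits(T=T_ev, E=E_ev, q_min=float(q_min), q_max=float(q_max))


def ddcs(elf: ELFSurface, T_ev: float, E_ev: float, q: float) -> float:
    """Double-differential cross section at (E, q), in 1/(eV nm a.u.).

    (The q axis stays in atomic units, matching the surface grid.)
    """
    lim = kinematic_limits(T_ev, E_ev)
    if not (lim.q_min <= q <= lim.q_max):
        return 0.0
    val = elf.interpolator()(E_ev, q)
    t = T_ev * EV_HARTREE
    return float(val / (np.pi * t * q)) * AU_SDCS_PER_EV_NM


@dataclass
class SDCSCurve:
    """Single-differential cross section dS/dE at one incident energy."""

    T: float  # eV
    energies: np.ndarray  # eV
    values: np.ndarray  # 1/(eV nm)
    extrapolated_fraction: float = 0.0
    n_excluded: int = 0
    channel: str | None = None


def sdcs(
    elf: ELFSurface,
    T_ev: float,
    energy_grid_ev=None,
    n_q: int = 200,
    high_q: str = "loglog",
) -> SDCSCurve:
    """dS/dE by trapezoid quadrature of ELF(E, q)/q in ln q between the
    kinematic limits; grid points with E > T are excluded with a warning.

    ``high_q`` selects the above-grid extrapolation policy (see
    :class:`~elfxs.surfaces.BetheSurfaceInterpolator`)."""
    if T_ev <= 0:
        raise ValueError("T must be positive")
    energies = (
        np.asarray(energy_grid_ev, dtype=float)
        if energy_grid_ev is not None
        else elf.energy_grid
    )
    keep = energies <= T_ev
    n_excluded = int(np.count_nonzero(~keep))
    if n_excluded:
        warnings.warn(
            f"{n_excluded} energy grid point(s) above T = {T_ev:g} eV excluded "
            "from the SDCS",
            stacklevel=2,
        )
    energies = energies[keep]
    interp = elf.interpolator(high_q=high_q)
    t_ha = T_ev * EV_HARTREE
    values = np.zeros(energies.size)
    pos = energies > 0
    frac = 0.0
    if np.any(pos):
        e_ha = energies[pos] * EV_HARTREE
        s, d = np.sqrt(2.0 * t_ha), np.sqrt(np.maximum(2.0 * (t_ha - e_ha), 0.0))
        lo, hi_lim = np.log(s - d), np.log(s + d)
        t = np.linspace(0.0, 1.0, n_q)
        lnq = lo[:, None] + t[None, :] * (hi_lim - lo)[:, None]
        q = np.exp(lnq)
        f = interp(energies[pos][:, None], q)
        # int ELF/q dq = int ELF d(ln q)
        integral = np.trapezoid(f, lnq, axis=1)
        values[pos] = integral / (np.pi * t_ha) * AU_SDCS_PER_EV_NM
        hi = q > elf.q_grid[-1]
        extrap = np.abs(np.trapezoid(np.where(hi, f, 0.0), lnq, axis=1))
        total = np.sum(np.abs(integral))
        frac = float(np.sum(extrap) / total) if total > 0 else 0.0
    return SDCSCurve(
        T=T_ev,
        energies=energies,
        values=values,
        extrapolated_fraction=float(frac),
        n_excluded=n_excluded,
    )


@dataclass
class CrossSectionTable:
    """Integrated cross-section quantities on an incident-energy grid."""

    T_grid: np.ndarray  # eV
    sigma_total: np.ndarray | None = None  # 1/nm
    imfp: np.ndarray | None = None  # nm (inf where sigma = 0)
    stopping: np.ndarray | None = None  # eV/nm
    sdcs: dict = field(default_factory=dict)  # T -> SDCSCurve
    channel: str | None = None
    emin_mode: str = "zero"
    E_gap: float = 0.0
    E_F: float = 0.0
    imfp_infinite: np.ndarray | None = None
    extrapolated_fraction: float = 0.0


def _energy_loss_limits(T_ev, emin_mode, E_gap, E_F):
    if emin_mode not in ("zero", "gap"):
        raise ValueError(f"unknown emin_mode {emin_mode!r}")
    e_min = E_gap if emin_mode == "gap" else 0.0
    e_max = min((T_ev + E_gap) / 2.0, T_ev - E_F)
    return e_min, e_max


def _integrate(elf, T_ev, emin_mode, E_gap, E_F, n_q, moment):
    """int E^moment dS/dE dE over [E_min, E_max] in a.u., plus the
    extrapolated fraction of the underlying SDCS."""
    e_min, e_max = _energy_loss_limits(T_ev, emin_mode, E_gap, E_F)
    e_max = min(e_max, float(elf.energy_grid[-1]), T_ev)
    if e_max <= e_min:
        return 0.0, 0.0
    grid = elf.energy_grid
    inner = grid[(grid > e_min) & (grid < e_max)]
    energies = np.concatenate([[e_min] if e_min > 0 else [], inner, [e_max]])
    if energies.size < 2:
        return 0.0, 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        curve = sdcs(elf, T_ev, energies, n_q=n_q)
    e_ha = curve.energies * EV_HARTREE
    dsde_au = curve.values / AU_SDCS_PER_EV_NM
    val = np.trapezoid(dsde_au * e_ha**moment, e_ha)
    return float(val), curve.extrapolated_fraction


def total_cross_section(
    elf: ELFSurface,
    T_grid_ev,
    emin_mode: str = "zero",
    E_gap: float = 0.0,
    E_F: float = 0.0,
    n_q: int = 200,
) -> CrossSectionTable:
    """Total inelastic cross section per unit path length S(T) (1/nm) and
    IMFP = 1/S (nm; infinite where S = 0, flagged)."""
    T_grid = np.atleast_1d(np.asarray(T_grid_ev, dtype=float))
    if np.any(T_grid <= 0):
        raise ValueError("incident energies must be positive")
    sig = np.zeros(T_grid.size)
    fracs = []
    for i, t in enumerate(T_grid):
        val, fr = _integrate(elf, t, emin_mode, E_gap, E_F, n_q, moment=0)
        sig[i] = val * AU_INV_LENGTH_PER_NM
        fracs.append(fr)
    infinite = sig <= 0.0
    with np.errstate(divide="ignore"):
        imfp = np.where(infinite, np.inf, 1.0 / np.where(infinite, 1.0, sig))
    return CrossSectionTable(
        T_grid=T_grid,
        sigma_total=sig,
        imfp=imfp,
        emin_mode=emin_mode,
        E_gap=E_gap,
        E_F=E_F,
        imfp_infinite=infinite,
        extrapolated_fraction=float(np.mean(fracs)) if fracs else 0.0,
    )


def stopping_power(
    elf: ELFSurface,
    T_grid_ev,
    emin_mode: str = "zero",
    E_gap: float = 0.0,
    E_F: float = 0.0,
    n_q: int = 200,
) -> CrossSectionTable:
    """Electronic stopping power S_e(T) = int E dS/dE dE, in eV/nm."""
    T_grid = np.atleast_1d(np.asarray(T_grid_ev, dtype=float))
    if np.any(T_grid <= 0):
        raise ValueError("incident energies must be positive")
    stop = np.zeros(T_grid.size)
    fracs = []
    for i, t in enumerate(T_grid):
        val, fr = _integrate(elf, t, emin_mode, E_gap, E_F, n_q, moment=1)
        stop[i] = val * AU_STOPPING_PER_EV_NM
        fracs.append(fr)
    return CrossSectionTable(
        T_grid=T_grid,
        stopping=stop,
        emin_mode=emin_mode,
        E_gap=E_gap,
        E_F=E_F,
        extrapolated_fraction=float(np.mean(fracs)) if fracs else 0.0,
    )


def channel_cross_sections(
    channel_elfs: dict[str, ELFSurface],
    T_ev: float,
    energy_grid_ev=None,
    n_q: int = 200,
    high_q: str = "hold",
) -> dict[str, SDCSCurve]:
    """Per-molecular-orbital SDCS curves; channels must share grids, and the
    curves sum to the SDCS of the summed surface (linearity of the q
    integral).

    Defaults to the value-linear 'hold' extrapolation policy: channel
    components are signed, so the log-log policy is undefined for them and
    would break the exact channel sum."""
    labels = list(channel_elfs)
    ref = channel_elfs[labels[0]]
    for lab in labels[1:]:
        s = channel_elfs[lab]
        if not (
            np.array_equal(s.energy_grid, ref.energy_grid)
            and np.array_equal(s.q_grid, ref.q_grid)
        ):
            raise ValueError(f"channel {lab!r} grid differs from {labels[0]!r}")
    out = {}
    for lab in labels:
        curve = sdcs(channel_elfs[lab], T_ev, energy_grid_ev, n_q=n_q,
                     high_q=high_q)
        curve.channel = lab
        out[lab] = curve
    return out
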
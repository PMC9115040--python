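"""Tabulated energy-loss-function (ELF) surfaces on an (E, q) grid.

The Bethe surface ELF(E, q) = Im[-1/eps_M(E, q)] is the central observable:
either computed from a model system by the RPA response machinery, or built
parametrically from damped-oscillator (Drude) peaks as a stand-in for
optical-data models.  Surfaces carry their grids (energy loss in eV, momentum
transfer in atomic units), a marker for the column treated as the optical
limit, and free-text provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ELFSurface",
    "DrudePeakSet",
    "make_drude_elf",
    "fsum_rule",
    "BetheSurfaceInterpolator",
]


@dataclass
class ELFSurface:
    """ELF values on a rectangular (energy loss, momentum transfer) grid.

    Parameters
    ----------
    energy_grid : array, eV
        Strictly increasing, uniformly spaced energy-loss values.
    q_grid : array, atomic units
        Strictly increasing momentum-transfer magnitudes.
    values : array, shape (n_E, n_q), dimensionless
        Non-negative ELF values; ``values[i, j]`` is ELF(E_i, q_j).
    optical_q : float
        The q column treated as the optical limit (defaults to the smallest
        grid q, the same convention used for periodic-cell calculations where
        q cannot be smaller than the k-point spacing).
    provenance : str
        Free-text description of where the surface came from.
    """

    energy_grid: np.ndarray
    q_grid: np.ndarray
    values: np.ndarray
    optical_q: float | None = None
    provenance: str = ""
    allow_negative: bool = False
    """Permit locally negative values (additive channel components of a
    decomposition; only their sum is sign-constrained)."""

    def __post_init__(self) -> None:
        self.energy_grid = np.asarray(self.energy_grid, dtype=float)
        self.q_grid = np.asarray(self.q_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.energy_grid.ndim != 1 or self.q_grid.ndim != 1:
            raise ValueError("grids must be one-dimensional")
        if self.values.shape != (self.energy_grid.size, self.q_grid.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match grids "
                f"({self.energy_grid.size}, {self.q_grid.size})"
            )
        if np.any(np.diff(self.energy_grid) <= 0) or (
            self.q_grid.size > 1 and np.any(np.diff(self.q_grid) <= 0)
        ):
            raise ValueError("grids must be strictly increasing")
        de = np.diff(self.energy_grid)
        if de.size and not np.allclose(de, de[0], rtol=1e-8, atol=1e-12):
            raise ValueError("energy grid spacing must be uniform")
        if not self.allow_negative and np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative ELF value at E={self.energy_grid[i]:g} eV, "
                f"q={self.q_grid[j]:g} a.u."
            )
        if self.optical_q is None:
            self.optical_q = float(self.q_grid[0])

    @property
    def de(self) -> float:
        """Energy grid spacing in eV."""
        return float(self.energy_grid[1] - self.energy_grid[0])

    def column(self, q: float) -> np.ndarray:
        """ELF(E) at the grid column closest to ``q``."""
        j = int(np.argmin(np.abs(self.q_grid - q)))
        return self.values[:, j]

    def interpolator(self, high_q: str = "loglog") -> "BetheSurfaceInterpolator":
        return BetheSurfaceInterpolator(self, high_q=high_q)


@dataclass
class DrudePeakSet:
    """Damped-oscillator peaks defining a parametric ELF.

    Each peak is (position E_i in eV, width gamma_i in eV, weight A_i in
    eV^2).  The weight is the squared plasmon energy carried by the peak: a
    single peak integrates to (pi/2) * A_i under the f-sum rule
    integral E * ELF dE, independently of position and width.  With
    ``dispersion_mode='quadratic'`` the peak position follows the free-electron
    recoil ridge E_i(q) = E_i + q^2/2 (q in a.u., the shift converted to eV).
    """

    peaks: list[tuple[float, float, float]]
    dispersion_mode: str = "quadratic"

    def __post_init__(self) -> None:
        if self.dispersion_mode not in ("none", "quadratic"):
            raise ValueError(f"unknown dispersion_mode {self.dispersion_mode!r}")
        for (e, g, a) in self.peaks:
            if e <= 0 or g <= 0 or a <= 0:
                raise ValueError("peak positions, widths and weights must be > 0")

    @property
    def total_weight(self) -> float:
        """Sum of peak weights = model omega_p^2 in eV^2."""
        return float(sum(a for (_, _, a) in self.peaks))


def _drude_positions(peaks: DrudePeakSet, q: float) -> np.ndarray:
    from .constants import HARTREE_EV

    e0 = np.array([p[0] for p in peaks.peaks])
    if peaks.dispersion_mode == "quadratic":
        return e0 + 0.5 * q * q * HARTREE_EV
    return e0


def drude_elf_values(peaks: DrudePeakSet, energies: np.ndarray, q: float) -> np.ndarray:
    """Closed-form Drude ELF column at momentum transfer ``q``.

    ELF(E, q) = sum_i A_i gamma_i E / [(E^2 - E_i(q)^2)^2 + gamma_i^2 E^2].
    """
    energies = np.asarray(energies, dtype=float)
    out = np.zeros_like(energies)
    eq = _drude_positions(peaks, q)
    for (pos, (_, gamma, weight)) in zip(eq, peaks.peaks):
        denom = (energies**2 - pos**2) ** 2 + (gamma * energies) ** 2
        out += weight * gamma * energies / denom
    return out


def make_drude_elf(
    peaks: DrudePeakSet,
    energy_grid: np.ndarray,
    q_grid: np.ndarray,
    optical_q: float | None = None,
) -> ELFSurface:
    """Tabulate a Drude peak set on an (E, q) grid."""
    energy_grid = np.asarray(energy_grid, dtype=float)
    q_grid = np.asarray(q_grid, dtype=float)
    values = np.column_stack([drude_elf_values(peaks, energy_grid, q) for q in q_grid])
    return ELFSurface(
        energy_grid,
        q_grid,
        values,
        optical_q=optical_q,
        provenance=f"Drude model, {len(peaks.peaks)} peak(s), "
        f"dispersion={peaks.dispersion_mode}",
    )


def fsum_rule(surface: ELFSurface, q: float | None = None) -> float:
    """Trapezoidal f-sum integral  S(q) = int E * ELF(E, q) dE  in eV^2.

    For an ELF normalised to electron density n the exact value is
    (pi/2) * omega_p^2 with omega_p^2 = 4*pi*n (atomic units); Drude weights
    are defined so the model total weight plays the role of omega_p^2.
    """
    col = surface.column(q if q is not None else surface.optical_q)
    return float(np.trapezoid(surface.energy_grid * col, surface.energy_grid))


class BetheSurfaceInterpolator:
    """Bilinear evaluation of a tabulated Bethe surface with explicit
    out-of-grid policy.

    - E outside the tabulated range -> 0 (no tabulated loss channel there);
    - q below the smallest grid q -> clamped to the optical column (periodic
      cells cannot represent smaller q, and the surface is flattest there);
    - q above the largest grid q: with ``high_q='loglog'`` (default) linear
      extrapolation in (ln ELF, ln q) from the last two columns, floored at
      0; with ``high_q='hold'`` the last column is held constant.

    'loglog' follows the physical large-q decay of a loss peak but is
    nonlinear in the tabulated values; 'hold' is exactly linear, which is
    what additive channel decompositions need (their curves then sum to the
    curve of the summed surface identically), and is the only well-defined
    choice for signed channel components.

    The fraction of evaluations that hit the large-q extrapolation branch is
    tracked so integration routines can report it.
    """

    def __init__(self, surface: ELFSurface, high_q: str = "loglog"):
        if high_q not in ("loglog", "hold"):
            raise ValueError(f"unknown high-q policy {high_q!r}")
        self.high_q = high_q
        self.surface = surface
        self._E = surface.energy_grid
        self._q = surface.q_grid
        self._V = surface.values
        self.n_eval = 0
        self.n_extrapolated = 0

    @property
    def extrapolated_fraction(self) -> float:
        return self.n_extrapolated / self.n_eval if self.n_eval else 0.0

    def __call__(self, E, q):
        """Evaluate ELF at energy loss E (eV) and momentum transfer q (a.u.).

        Broadcasts over array input; E and q must be broadcastable.
        """
        E = np.asarray(E, dtype=float)
        q = np.asarray(q, dtype=float)
        E, q = np.broadcast_arrays(E, q)
        out = np.zeros(E.shape)
        self.n_eval += E.size

        inside_E = (E >= self._E[0]) & (E <= self._E[-1])
        qc = np.clip(q, self._q[0], self._q[-1])
        high_q = q > self._q[-1]
        self.n_extrapolated += int(np.count_nonzero(high_q & inside_E))

        if np.any(inside_E):
            iE = np.clip(np.searchsorted(self._E, E, side="right") - 1, 0, self._E.size - 2)
            tE = (E - self._E[iE]) / (self._E[iE + 1] - self._E[iE])
            tE = np.clip(tE, 0.0, 1.0)
            if self._q.size == 1:
                vals = self._V[iE, 0] * (1 - tE) + self._V[iE + 1, 0] * tE
            else:
                iq = np.clip(
                    np.searchsorted(self._q, qc, side="right") - 1, 0, self._q.size - 2
                )
                tq = (qc - self._q[iq]) / (self._q[iq + 1] - self._q[iq])
                tq = np.clip(tq, 0.0, 1.0)
                v00 = self._V[iE, iq]
                v01 = self._V[iE, iq + 1]
                v10 = self._V[iE + 1, iq]
                v11 = self._V[iE + 1, iq + 1]
                vals = (
                    v00 * (1 - tE) * (1 - tq)
                    + v01 * (1 - tE) * tq
                    + v10 * tE * (1 - tq)
                    + v11 * tE * tq
                )
            out[inside_E] = vals[inside_E]

        if self.high_q == "loglog" and np.any(high_q & inside_E) and self._q.size >= 2:
            sel = high_q & inside_E
            iE = np.clip(
                np.searchsorted(self._E, E[sel], side="right") - 1, 0, self._E.size - 2
            )
            tE = np.clip((E[sel] - self._E[iE]) / (self._E[iE + 1] - self._E[iE]), 0, 1)
            # last two columns, interpolated in E first
            tiny = 1e-300
            v_last = self._V[iE, -1] * (1 - tE) + self._V[iE + 1, -1] * tE
            v_prev = self._V[iE, -2] * (1 - tE) + self._V[iE + 1, -2] * tE
            with np.errstate(divide="ignore", invalid="ignore"):
                slope = (np.log(v_last + tiny) - np.log(v_prev + tiny)) / (
                    np.log(self._q[-1]) - np.log(self._q[-2])
                )
                vals = v_last * np.exp(slope * (np.log(q[sel]) - np.log(self._q[-1])))
            vals = np.where(v_last <= 0, 0.0, vals)
            out[sel] = np.maximum(vals, 0.0)

        return out if out.shape else float(out)
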
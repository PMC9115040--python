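"""Non-interacting response, RPA Dyson equation and the macroscopic ELF.

The pipeline: from a :class:`~elfxs.models.KSModel` build the
non-interacting density-density response matrix

    chi0_{GG'}(E, q) = (1/N_k) sum_{n,m,k} (f_{n,k} - f_{m,k+q})
                       U^G_{nm,k}(q) conj(U^G'_{nm,k}(q))
                       / (E - (E_{m,k+q} - E_{n,k}) + i*eta),

couple it to the bare Coulomb kernel v_G(q) = 4*pi/|q+G|^2 through the Dyson
equation chi = chi0 [I - v chi0]^{-1} (RPA: no exchange-correlation kernel),
and read off the energy loss function

    ELF(E, q) = -(4*pi/q^2) Im chi_{00}(E, q).

Local-field effects (LFE) are the off-diagonal G components retained in the
matrix solve; the NLFE variant screens the head alone,
ELF = Im[-1/(1 - v_0 chi0_{00})].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import EV_HARTREE
from .models import KSModel
from .surfaces import ELFSurface

__all__ = [
    "ResponseMatrix",
    "KernelMatrix",
    "SingularResponseError",
    "coulomb_kernel",
    "plane_wave_matrix_elements",
    "chi0",
    "chi0_array",
    "dyson_solve",
    "elf_with_lfe",
    "elf_without_lfe",
    "elf_surface",
    "PairTable",
    "pair_table",
]


class SingularResponseError(np.linalg.LinAlgError):
    """[I - K chi0] is singular to working precision (plasmon pole hit at a
    real energy with too small a broadening)."""


@dataclass
class ResponseMatrix:
    """Complex G x G' response-type matrix at one (E, q).

    ``kind`` is one of 'noninteracting', 'interacting', 'inverse_dielectric'.
    """

    q: float  # a.u.
    energy: float  # eV
    matrix: np.ndarray
    kind: str
    gvectors: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("response matrix must be square")


@dataclass
class KernelMatrix:
    """Diagonal bare-Coulomb kernel v_G(q) = 4*pi/|q+G|^2 (a.u.)."""

    q: float
    matrix: np.ndarray

    @property
    def diag(self) -> np.ndarray:
        return np.diagonal(self.matrix)


def coulomb_kernel(
    model: KSModel, q_mag: float, direction=(1, 0, 0), glist: np.ndarray | None = None
) -> KernelMatrix:
    if q_mag <= 0:
        raise ValueError("q must be positive")
    g = model.gvectors if glist is None else np.asarray(glist)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    qplusg = q_mag * d[None, :] + g * model.b
    norms2 = np.sum(qplusg**2, axis=1)
    if np.any(norms2 < 1e-20):
        bad = g[int(np.argmin(norms2))]
        raise ValueError(
            f"q = {q_mag:g} a.u. coincides with reciprocal-lattice vector "
            f"{tuple(-bad)} (Coulomb kernel diverges); such q is equivalent "
            "to the optical point and must be excluded"
        )
    diag = 4.0 * np.pi / norms2
    return KernelMatrix(q=q_mag, matrix=np.diag(diag))


# ---------------------------------------------------------------------------
# plane-wave matrix elements and electron-hole pair bookkeeping
# ---------------------------------------------------------------------------


def _shift_maps(model: KSModel, glist: np.ndarray, gshift: np.ndarray) -> np.ndarray:
    """Index maps: maps[g, i] = internal index of internal_g[i] + glist[g] +
    gshift, or -1 when outside the internal basis."""
    ngi = model.internal_g.shape[0]
    maps = np.full((len(glist), ngi), -1, dtype=int)
    for gi, g in enumerate(glist):
        tgt = model.internal_g + g[None, :] + gshift[None, :]
        for i in range(ngi):
            maps[gi, i] = model.g_index(tgt[i])
    return maps


def plane_wave_matrix_elements(
    model: KSModel, ik: int, qfrac: np.ndarray, n: int, m: int,
    glist: np.ndarray | None = None,
) -> np.ndarray:
    """U^G_{nm,k}(q) = (1/V_uc) <psi_{n,k}| e^{-i(G+q)r} |psi_{m,k+q}>
    for every G in the response basis.

    Exact contraction of the stored plane-wave coefficients; the state at
    k+q is resolved by folding back into the mesh.
    """
    glist = model.gvectors if glist is None else np.asarray(glist)
    c1 = model.coeffs[ik]
    if not np.allclose(np.sum(np.abs(c1[n]) ** 2), 1.0, atol=1e-8):
        raise ValueError("state (n, k) is not normalized")
    ik2, gshift = model.fold_to_mesh(model.kpoints[ik] + qfrac)
    c2 = model.coeffs[ik2]
    if not np.allclose(np.sum(np.abs(c2[m]) ** 2), 1.0, atol=1e-8):
        raise ValueError("state (m, k+q) is not normalized")
    maps = _shift_maps(model, glist, gshift)
    out = np.empty(len(glist), dtype=complex)
    for gi in range(len(glist)):
        idx = maps[gi]
        valid = idx >= 0
        out[gi] = np.sum(np.conj(c1[n, valid]) * c2[m, idx[valid]])
    return out


@dataclass
class PairTable:
    """Flattened electron-hole pair data at fixed q.

    Arrays over pairs p = (n, m, k) with f_{n,k} != f_{m,k+q}:
    ``weight`` = (f_n - f_m)/(N_k * V_uc) so that chi0 comes out per unit
    volume (states are cell-normalized, making the U overlaps dimensionless),
    ``delta_e`` = E_{m,k+q} - E_{n,k} (hartree),
    ``U`` = U^G vectors (P, Ng), ``occ_energy`` the energy of whichever index
    is occupied, ``occ_band``/``occ_k`` its band and k indices, ``index`` the
    (n, m, ik) triples.
    """

    q: float
    qfrac: np.ndarray
    glist: np.ndarray
    weight: np.ndarray
    delta_e: np.ndarray
    U: np.ndarray
    occ_energy: np.ndarray
    occ_band: np.ndarray
    occ_k: np.ndarray
    index: np.ndarray


def pair_table(
    model: KSModel,
    q_mag: float,
    direction=(1, 0, 0),
    glist: np.ndarray | None = None,
) -> PairTable:
    """Enumerate all electron-hole pairs contributing to chi0 at this q and
    precompute their plane-wave matrix elements."""
    glist = model.gvectors if glist is None else np.asarray(glist)
    qfrac = model.q_fractional(q_mag, direction)
    nk = model.n_kpoints
    ws, des, Us, occE, occB, occK, idxs = [], [], [], [], [], [], []
    map_cache: dict[tuple, np.ndarray] = {}
    for ik in range(nk):
        ik2, gshift = model.fold_to_mesh(model.kpoints[ik] + qfrac)
        f1, f2 = model.occupations[ik], model.occupations[ik2]
        e1, e2 = model.band_energies[ik], model.band_energies[ik2]
        nsel, msel = np.nonzero(np.abs(f1[:, None] - f2[None, :]) > 1e-12)
        if nsel.size == 0:
            continue
        key = tuple(gshift)
        if key not in map_cache:
            map_cache[key] = _shift_maps(model, glist, gshift)
        maps = map_cache[key]
        c1 = model.coeffs[ik]
        c2 = model.coeffs[ik2]
        # U for all band pairs at once, per response G
        Uall = np.empty((len(glist), model.n_bands, model.n_bands), dtype=complex)
        for gi in range(len(glist)):
            idx = maps[gi]
            valid = idx >= 0
            c2s = np.zeros_like(c2)
            c2s[:, valid] = c2[:, idx[valid]]
            Uall[gi] = np.conj(c1) @ c2s.T
        ws.append((f1[nsel] - f2[msel]) / (nk * model.cell_volume))
        des.append(e2[msel] - e1[nsel])
        Us.append(Uall[:, nsel, msel].T)
        n_is_occ = f1[nsel] > f2[msel]
        occE.append(np.where(n_is_occ, e1[nsel], e2[msel]))
        occB.append(np.where(n_is_occ, nsel, msel))
        occK.append(np.where(n_is_occ, ik, ik2))
        idxs.append(np.column_stack([nsel, msel, np.full(nsel.size, ik)]))
    if not ws:
        ngz = len(glist)
        return PairTable(
            q_mag, qfrac, glist,
            np.zeros(0), np.zeros(0), np.zeros((0, ngz), dtype=complex),
            np.zeros(0), np.zeros(0, dtype=int), np.zeros(0, dtype=int),
            np.zeros((0, 3), dtype=int),
        )
    return PairTable(
        q_mag, qfrac, glist,
        np.concatenate(ws), np.concatenate(des), np.vstack(Us),
        np.concatenate(occE), np.concatenate(occB).astype(int),
        np.concatenate(occK).astype(int), np.vstack(idxs),
    )


# ---------------------------------------------------------------------------
# chi0 and the Dyson equation
# ---------------------------------------------------------------------------


def _check_eta(eta_ev: float, energy_grid_ev: np.ndarray) -> None:
    if eta_ev <= 0:
        raise ValueError("eta must be positive")
    e = np.asarray(energy_grid_ev, dtype=float)
    if e.size >= 2:
        de = float(e[1] - e[0])
        if eta_ev < 2.0 * de - 1e-12:
            warnings.warn(
                f"eta = {eta_ev:g} eV is below twice the energy resolution "
                f"(2*dE = {2 * de:g} eV); spectra may be under-resolved",
                stacklevel=3,
            )


def chi0_array(
    pairs: PairTable, energy_grid_ev, eta_ev: float
) -> np.ndarray:
    """chi0 matrices on an energy grid from a precomputed pair table.

    Returns a complex array of shape (n_E, Ng, Ng).
    """
    e_ha = np.atleast_1d(np.asarray(energy_grid_ev, dtype=float)) * EV_HARTREE
    eta_ha = eta_ev * EV_HARTREE
    ng = pairs.U.shape[1]
    out = np.empty((e_ha.size, ng, ng), dtype=complex)
    Uc = np.conj(pairs.U)
    for i, e in enumerate(e_ha):
        coef = pairs.weight / (e - pairs.delta_e + 1j * eta_ha)
        out[i] = (pairs.U * coef[:, None]).T @ Uc
    return out


def chi0(
    model: KSModel,
    q_mag: float,
    energy_grid_ev,
    eta_ev: float,
    direction=(1, 0, 0),
    glist: np.ndarray | None = None,
) -> list[ResponseMatrix]:
    """Non-interacting response chi0_{GG'}(E, q) over an energy grid."""
    _check_eta(eta_ev, energy_grid_ev)
    pt = pair_table(model, q_mag, direction, glist)
    arr = chi0_array(pt, energy_grid_ev, eta_ev)
    energies = np.atleast_1d(np.asarray(energy_grid_ev, dtype=float))
    return [
        ResponseMatrix(q=q_mag, energy=float(e), matrix=m, kind="noninteracting",
                       gvectors=pt.glist)
        for e, m in zip(energies, arr)
    ]


def _dyson_matrix(chi0_m: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """A = I - K chi0, with a singularity check."""
    if chi0_m.shape != kernel.shape:
        raise ValueError("chi0 and kernel are not conformable")
    a = np.eye(chi0_m.shape[0], dtype=complex) - kernel @ chi0_m
    cond = np.linalg.cond(a)
    if not np.isfinite(cond) or 1.0 / cond < 1e-12:
        raise SingularResponseError(
            f"[I - K chi0] singular to working precision (cond = {cond:.3e}); "
            "a plasmon pole was hit at real energy with too small eta"
        )
    return a


def dyson_solve(chi0_m: ResponseMatrix, kernel: KernelMatrix) -> ResponseMatrix:
    """Interacting response chi = chi0 [I - K chi0]^{-1} by linear solve."""
    a = _dyson_matrix(chi0_m.matrix, kernel.matrix)
    chi = np.linalg.solve(a.T, chi0_m.matrix.T).T
    return ResponseMatrix(
        q=chi0_m.q, energy=chi0_m.energy, matrix=chi, kind="interacting",
        gvectors=chi0_m.gvectors,
    )


# ---------------------------------------------------------------------------
# ELF columns
# ---------------------------------------------------------------------------


def elf_with_lfe(
    model: KSModel,
    q_mag: float,
    energy_grid_ev,
    eta_ev: float,
    direction=(1, 0, 0),
    glist: np.ndarray | None = None,
) -> np.ndarray:
    """ELF(E, q) = -(4*pi/q^2) Im chi_{00} with the full G x G' Dyson solve,
    retaining local-field effects."""
    _check_eta(eta_ev, energy_grid_ev)
    pt = pair_table(model, q_mag, direction, glist)
    arr = chi0_array(pt, energy_grid_ev, eta_ev)
    kern = coulomb_kernel(model, q_mag, direction, pt.glist).matrix
    out = np.empty(arr.shape[0])
    for i in range(arr.shape[0]):
        a = _dyson_matrix(arr[i], kern)
        chi = np.linalg.solve(a.T, arr[i].T).T
        out[i] = -(4.0 * np.pi / q_mag**2) * chi[0, 0].imag
    return out


def elf_without_lfe(
    model: KSModel,
    q_mag: float,
    energy_grid_ev,
    eta_ev: float,
    direction=(1, 0, 0),
    glist: np.ndarray | None = None,
) -> np.ndarray:
    """ELF without local-field effects: Im[-1/eps_00] with head-only
    screening eps_00 = 1 - v_0 chi0_{00}."""
    _check_eta(eta_ev, energy_grid_ev)
    pt = pair_table(model, q_mag, direction, glist)
    arr = chi0_array(pt, energy_grid_ev, eta_ev)
    v0 = coulomb_kernel(model, q_mag, direction, pt.glist).diag[
        int(np.argwhere((pt.glist == 0).all(axis=1))[0, 0])
    ]
    eps00 = 1.0 - v0 * arr[:, 0, 0]
    return np.imag(-1.0 / eps00)


def elf_surface(
    model: KSModel,
    q_list,
    energy_grid_ev,
    eta_ev: float,
    lfe: bool = True,
    direction=(1, 0, 0),
    glist: np.ndarray | None = None,
    average_directions: bool = False,
) -> ELFSurface:
    """Assemble ELF columns over a q grid into an :class:`ELFSurface`.

    With ``average_directions`` the column is averaged over the three cubic
    axes (the response of a disordered target is isotropic; for a cubic toy
    cell the axis average is the cheap proxy)."""
    fun = elf_with_lfe if lfe else elf_without_lfe
    dirs = [(1, 0, 0), (0, 1, 0), (0, 0, 1)] if average_directions else [direction]
    cols = []
    for q in q_list:
        col = np.mean([fun(model, q, energy_grid_ev, eta_ev, d, glist) for d in dirs],
                      axis=0)
        cols.append(np.maximum(col, 0.0))  # clip -eta-induced round-off
    values = np.column_stack(cols)
    return ELFSurface(
        np.asarray(energy_grid_ev, dtype=float),
        np.asarray(q_list, dtype=float),
        values,
        provenance=f"RPA {'LFE' if lfe else 'NLFE'} ELF, eta={eta_ev} eV, "
        f"model={model.spec.get('kind', 'custom')}",
    )
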
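"""Toy periodic Kohn-Sham model systems.

Two families of models feed the response machinery:

* **Jellium** (homogeneous electron gas in a cubic box): plane-wave
  eigenstates E = |k+G|^2/2, occupations filled to the Fermi level of the
  requested density.  Its response has a closed form (the Lindhard function),
  which makes it the analytic oracle for the RPA pipeline.

* **LCAO toys**: a handful of bands built as fixed linear combinations of
  Gaussian atomic orbitals carrying (atom, species, angular-momentum) labels,
  with prescribed band centres, cosine dispersion and occupations.  The
  water-like default places the four occupied band centres at the
  experimental liquid-water molecular-orbital binding energies (2a1, 1b2,
  3a1, 1b1) below the vacuum level, with one empty band above the gap.

All states are stored as plane-wave coefficient vectors over an internal
reciprocal-lattice basis, so the plane-wave matrix elements U^G_{nm,k}(q)
reduce to exact finite contractions for both families.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import EV_HARTREE, HARTREE_EV

__all__ = [
    "OrbitalLabel",
    "KSModel",
    "CommensurabilityError",
    "make_jellium",
    "make_lcao_model",
    "make_toy_water",
    "jellium_fermi_energy",
    "density_of_states",
    "WATER_MO_BINDING_EV",
    "WATER_MO_LABELS",
]

#: Liquid-water molecular-orbital binding energies (eV below vacuum),
#: from photoemission: 2a1, 1b2, 3a1, 1b1.
WATER_MO_BINDING_EV = (30.90, 17.34, 13.50, 11.16)
WATER_MO_LABELS = ("2a1", "1b2", "3a1", "1b1")

#: Volume per molecule of liquid water at 0.995 g/cm^3, in bohr^3.
WATER_MOLECULAR_VOLUME_BOHR3 = 202.2


class CommensurabilityError(ValueError):
    """Momentum transfer does not connect k-mesh points."""


@dataclass(frozen=True)
class OrbitalLabel:
    atom: int
    species: str
    l: str  # 's' | 'p' | 'd'


@dataclass
class KSModel:
    """A periodic model system in a cubic cell.

    All energies in hartree; lengths in bohr.  ``coeffs[ik, n, i]`` is the
    plane-wave coefficient of band ``n`` at k-point ``ik`` on internal
    reciprocal vector ``internal_g[i]`` (integer coordinates, cartesian value
    ``2*pi/a * g``).  ``orbital_coeffs``, when present, expresses each band in
    an orthonormal labelled atomic-orbital basis (Lowdin convention), so
    Mulliken weights are plain |C|^2.
    """

    a: float  # cubic lattice constant, bohr
    kmesh: tuple[int, int, int]
    kpoints: np.ndarray  # (Nk, 3) fractional
    kweights: np.ndarray  # (Nk,)
    gvectors: np.ndarray  # (Ng, 3) int, response basis
    internal_g: np.ndarray  # (Ngi, 3) int, coefficient basis
    band_energies: np.ndarray  # (Nk, Nb) hartree
    occupations: np.ndarray  # (Nk, Nb) in [0, 2]
    coeffs: np.ndarray  # (Nk, Nb, Ngi) complex
    fermi_energy: float  # hartree
    band_gap: float  # hartree
    orbital_coeffs: np.ndarray | None = None  # (Nb, Na) band templates
    orbital_labels: list[OrbitalLabel] | None = None
    spec: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.occupations < -1e-12) or np.any(self.occupations > 2 + 1e-12):
            raise ValueError("occupations must lie in [0, 2]")
        if not np.isclose(self.kweights.sum(), 1.0):
            raise ValueError("k-point weights must sum to 1")
        norms = np.sum(np.abs(self.coeffs) ** 2, axis=-1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("states are not normalized in the plane-wave basis")
        self._gidx = {tuple(g): i for i, g in enumerate(np.asarray(self.internal_g))}
        self._kidx = {}
        n = np.asarray(self.kmesh)
        for ik, kf in enumerate(self.kpoints):
            key = tuple(np.round(kf * n).astype(int) % n)
            self._kidx[key] = ik

    # --- geometry helpers -------------------------------------------------
    @property
    def cell_volume(self) -> float:
        return self.a**3

    @property
    def b(self) -> float:
        """Reciprocal lattice constant 2*pi/a (a.u.)."""
        return 2.0 * np.pi / self.a

    @property
    def n_kpoints(self) -> int:
        return self.kpoints.shape[0]

    @property
    def n_bands(self) -> int:
        return self.band_energies.shape[1]

    def min_q(self, direction: int = 0) -> float:
        """Smallest non-zero commensurate q magnitude along a cubic axis."""
        return self.b / self.kmesh[direction]

    def q_fractional(self, q_mag: float, direction=(1, 0, 0)) -> np.ndarray:
        """Fractional q for a magnitude along ``direction``; must connect
        k-mesh points, else :class:`CommensurabilityError` naming the nearest
        commensurate magnitude."""
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        qfrac = q_mag * d / self.b
        n = np.asarray(self.kmesh)
        m = np.round(qfrac * n)
        if not np.allclose(qfrac * n, m, atol=1e-8):
            near = float(np.linalg.norm((m / n) * self.b))
            raise CommensurabilityError(
                f"q={q_mag:g} a.u. along {tuple(direction)} does not connect "
                f"k-mesh points of the {self.kmesh} mesh; nearest commensurate "
                f"magnitude is {near:g} a.u. (grid step {self.min_q():g})"
            )
        return m / n

    def fold_to_mesh(self, kfrac: np.ndarray) -> tuple[int, np.ndarray]:
        """Fold a fractional vector into the mesh: returns (k index, integer
        G shift) with kfrac = kpoints[ik] + gshift."""
        n = np.asarray(self.kmesh)
        m = np.round(kfrac * n).astype(int)
        if not np.allclose(kfrac * n, m, atol=1e-8):
            raise CommensurabilityError(f"{kfrac} is not on the k-mesh")
        key = tuple(m % n)
        ik = self._kidx[key]
        gshift = (m - np.round(self.kpoints[ik] * n).astype(int)) // n
        return ik, gshift

    def g_index(self, g) -> int:
        """Index of an integer G in the internal basis, or -1."""
        return self._gidx.get(tuple(int(x) for x in g), -1)

    # --- bookkeeping ------------------------------------------------------
    def has_empty_states(self) -> bool:
        return bool(np.any(self.occupations < 2 - 1e-9))

    def occupied_mask(self) -> np.ndarray:
        return self.occupations > 1e-9

    def label_weights(self, grouping: str) -> tuple[list, np.ndarray]:
        """Mulliken weights of each band on label groups.

        Returns (group keys, W) with ``W[g, n]`` the weight of band ``n`` on
        group ``g``; columns sum to 1.  Groupings: 'species',
        'angular_momentum', 'species_by_l', 'atom'.
        """
        if self.orbital_coeffs is None or self.orbital_labels is None:
            raise ValueError(
                f"model carries no orbital labels; grouping {grouping!r} unavailable"
            )
        keyfun = {
            "species": lambda lab: lab.species,
            "angular_momentum": lambda lab: lab.l,
            "species_by_l": lambda lab: f"{lab.species}_{lab.l}",
            "atom": lambda lab: lab.atom,
        }.get(grouping)
        if keyfun is None:
            raise ValueError(f"unknown grouping {grouping!r}")
        keys = []
        for lab in self.orbital_labels:
            k = keyfun(lab)
            if k not in keys:
                keys.append(k)
        W = np.zeros((len(keys), self.n_bands))
        pop = np.abs(self.orbital_coeffs) ** 2  # (Nb, Na), Lowdin populations
        for a, lab in enumerate(self.orbital_labels):
            W[keys.index(keyfun(lab))] += pop[:, a]
        W /= W.sum(axis=0, keepdims=True)
        return keys, W


# ---------------------------------------------------------------------------
# shared construction helpers
# ---------------------------------------------------------------------------


def _gamma_centered_mesh(kmesh) -> tuple[np.ndarray, np.ndarray]:
    n1, n2, n3 = kmesh
    pts = np.array(
        [(i / n1, j / n2, k / n3) for i in range(n1) for j in range(n2) for k in range(n3)]
    )
    w = np.full(len(pts), 1.0 / len(pts))
    return pts, w


def _g_ball(max_norm2: float) -> np.ndarray:
    """Integer reciprocal vectors with |g|^2 <= max_norm2, ordered by norm."""
    r = int(np.floor(np.sqrt(max_norm2)))
    gs = [
        (i, j, k)
        for i in range(-r, r + 1)
        for j in range(-r, r + 1)
        for k in range(-r, r + 1)
        if i * i + j * j + k * k <= max_norm2 + 1e-9
    ]
    gs.sort(key=lambda g: (g[0] ** 2 + g[1] ** 2 + g[2] ** 2, g))
    return np.array(gs, dtype=int)


def _response_g_set(b: float, gcutoff: float | None) -> np.ndarray:
    """Response-basis G vectors within kinetic cutoff |G|^2/2 <= gcutoff.

    Default keeps shells through (1,1,0): 19 vectors, enough off-diagonal
    structure for non-trivial local-field effects."""
    if gcutoff is None:
        max_norm2 = 2.0
    else:
        max_norm2 = 2.0 * gcutoff / b**2
    g = _g_ball(max_norm2)
    if len(g) < 9:
        raise ValueError(
            f"G cutoff retains only {len(g)} vectors; need >= 9 for a useful "
            "local-field basis"
        )
    return g


def jellium_fermi_energy(density: float) -> float:
    """Free-electron-gas Fermi energy (hartree) at the given density
    (electrons per bohr^3): E_F = (3*pi^2*n)^(2/3) / 2."""
    return 0.5 * (3.0 * np.pi**2 * density) ** (2.0 / 3.0)


# ---------------------------------------------------------------------------
# jellium
# ---------------------------------------------------------------------------


def make_jellium(
    electron_density: float,
    kmesh=(8, 8, 8),
    n_bands: int = 15,
    gcutoff: float | None = None,
    electrons_per_cell: float = 2.0,
) -> KSModel:
    """Homogeneous electron gas in a cubic box.

    Parameters
    ----------
    electron_density : float
        Electrons per bohr^3 (r_s relation: n = 3/(4*pi*r_s^3)).
    kmesh : 3 ints
        Gamma-centred Brillouin-zone sampling.
    n_bands : int
        Plane-wave bands kept per k-point (lowest |k+G|^2/2).
    gcutoff : float, hartree
        Kinetic cutoff for the response G basis (default: 19 vectors).
    electrons_per_cell : float
        Sets the box size via a^3 = N_e / n.
    """
    if electron_density <= 0:
        raise ValueError("density must be positive")
    if min(kmesh) < 1:
        raise ValueError("kmesh must be positive")
    a = (electrons_per_cell / electron_density) ** (1.0 / 3.0)
    b = 2.0 * np.pi / a
    kpts, kw = _gamma_centered_mesh(kmesh)

    # internal basis: generous ball so that n_bands lowest states fit at any k
    max_norm2 = 2.0
    while len(_g_ball(max_norm2)) < 4 * n_bands + 19:
        max_norm2 += 1.0
    internal_g = _g_ball(max_norm2)
    gvectors = _response_g_set(b, gcutoff)

    ef = jellium_fermi_energy(electron_density)
    nk, nb, ngi = len(kpts), n_bands, len(internal_g)
    energies = np.empty((nk, nb))
    coeffs = np.zeros((nk, nb, ngi), dtype=complex)
    occ = np.zeros((nk, nb))
    for ik, kf in enumerate(kpts):
        pvec = (kf[None, :] + internal_g) * b
        e_all = 0.5 * np.sum(pvec**2, axis=1)
        order = np.argsort(e_all, kind="stable")[:nb]
        energies[ik] = e_all[order]
        coeffs[ik, np.arange(nb), order] = 1.0
        occ[ik] = np.where(energies[ik] <= ef + 1e-12, 2.0, 0.0)

    model = KSModel(
        a=a,
        kmesh=tuple(kmesh),
        kpoints=kpts,
        kweights=kw,
        gvectors=gvectors,
        internal_g=internal_g,
        band_energies=energies,
        occupations=occ,
        coeffs=coeffs,
        fermi_energy=ef,
        band_gap=0.0,
        spec={
            "kind": "jellium",
            "electron_density": electron_density,
            "kmesh": list(kmesh),
            "n_bands": n_bands,
            "gcutoff": gcutoff,
            "electrons_per_cell": electrons_per_cell,
        },
    )
    if not model.has_empty_states():
        raise ValueError(
            "n_bands too small: every retained band is occupied, so the model "
            "admits no electron-hole excitations"
        )
    return model


# ---------------------------------------------------------------------------
# LCAO toys
# ---------------------------------------------------------------------------


def _orbital_pw_coeffs(p: np.ndarray, l: str, m_idx: int, sigma: float, tau: np.ndarray):
    """Plane-wave amplitude of a Gaussian atomic orbital at wavevector p."""
    p2 = np.sum(p**2, axis=-1)
    env = np.exp(-0.5 * sigma**2 * p2)
    phase = np.exp(-1j * (p @ tau))
    if l == "s":
        return env * phase
    if l == "p":
        return 1j * p[..., m_idx] * sigma * env * phase
    raise ValueError(f"unsupported angular momentum {l!r}")


def _lowdin(mat: np.ndarray) -> np.ndarray:
    """Symmetric orthonormalisation of the columns of ``mat``."""
    s = mat.conj().T @ mat
    w, v = np.linalg.eigh(s)
    if np.min(w) < 1e-10 * np.max(w):
        raise ValueError("basis is numerically linearly dependent")
    x = (v / np.sqrt(w)) @ v.conj().T
    return mat @ x


def make_lcao_model(
    a: float,
    kmesh,
    orbitals: list[tuple[OrbitalLabel, np.ndarray, float, int]],
    band_templates: np.ndarray,
    band_centers_ev: np.ndarray,
    band_halfwidths_ev: np.ndarray,
    band_occupations: np.ndarray,
    gcutoff: float | None = None,
    internal_norm2: float = 12.0,
    spec: dict | None = None,
) -> KSModel:
    """Generic labelled LCAO toy crystal.

    ``orbitals``: (label, position bohr, gaussian width bohr, p-component
    index) per atomic orbital.  ``band_templates``: (Nb, Na) real/complex
    amplitudes of each band on the orbitals; Lowdin-orthonormalised, so the
    realised Mulliken weights track the templates but close exactly.
    Band energies: center + halfwidth * mean_i cos(2*pi*k_i), in eV on the
    below-vacuum scale (negative = bound).
    """
    b = 2.0 * np.pi / a
    kpts, kw = _gamma_centered_mesh(kmesh)
    internal_g = _g_ball(internal_norm2)
    gvectors = _response_g_set(b, gcutoff)

    band_templates = np.asarray(band_templates, dtype=complex)
    nb, na = band_templates.shape
    if na != len(orbitals):
        raise ValueError("template width must match number of orbitals")
    C = _lowdin(band_templates.T).T  # orthonormal band vectors, (Nb, Na)

    centers = np.asarray(band_centers_ev, dtype=float) * EV_HARTREE
    halfw = np.asarray(band_halfwidths_ev, dtype=float) * EV_HARTREE
    occ_vec = np.asarray(band_occupations, dtype=float)

    nk, ngi = len(kpts), len(internal_g)
    energies = np.empty((nk, nb))
    coeffs = np.empty((nk, nb, ngi), dtype=complex)
    for ik, kf in enumerate(kpts):
        disp = np.mean(np.cos(2.0 * np.pi * kf))
        energies[ik] = centers + halfw * disp
        pvec = (kf[None, :] + internal_g) * b
        B = np.empty((ngi, na), dtype=complex)
        for ia, (lab, tau, sigma, midx) in enumerate(orbitals):
            B[:, ia] = _orbital_pw_coeffs(pvec, lab.l, midx, sigma, tau)
        Bt = _lowdin(B)  # orthonormal labelled basis at this k
        coeffs[ik] = (Bt @ C.T).T

    occ = np.broadcast_to(occ_vec, (nk, nb)).copy()
    occ_centers = centers[occ_vec > 0]
    emp_centers = centers[occ_vec == 0]
    homo = float(np.max(energies[:, occ_vec > 0])) if occ_centers.size else -np.inf
    lumo = (
        float(np.min(energies[:, occ_vec == 0])) if emp_centers.size else np.inf
    )
    gap = max(lumo - homo, 0.0)
    ef = 0.5 * (homo + lumo) if np.isfinite(lumo) else homo

    return KSModel(
        a=a,
        kmesh=tuple(kmesh),
        kpoints=kpts,
        kweights=kw,
        gvectors=gvectors,
        internal_g=internal_g,
        band_energies=energies,
        occupations=occ,
        coeffs=coeffs,
        fermi_energy=ef,
        band_gap=gap,
        orbital_coeffs=C,
        orbital_labels=[o[0] for o in orbitals],
        spec=spec or {},
    )


_DEFAULT_MO_WEIGHTS = {
    # (species, l) composition templates for the four occupied MOs + LUMO
    "2a1": {("O", "s"): 0.80, ("H", "s"): 0.20},
    "1b2": {("O", "p"): 0.55, ("H", "s"): 0.45},
    "3a1": {("O", "p"): 0.60, ("O", "s"): 0.10, ("H", "s"): 0.30},
    # small antisymmetric H-s admixture: a pure out-of-plane O_p lone pair
    # would be dark along the cubic axes by parity, which no disordered
    # liquid band is
    "1b1": {("O", "p"): 0.90, ("H", "s"): 0.10},
    "4a1": {("O", "s"): 0.20, ("O", "p"): 0.20, ("H", "s"): 0.60},
}

#: Which O p component each MO uses (molecule in the xz plane, C2 axis z):
#: b2-like bands the in-plane antisymmetric px, a1-like the pz, b1 the
#: out-of-plane py.  Keeps the symmetry-distinct bands near-orthogonal so
#: Lowdin orthonormalisation barely moves the supplied weights.
_MO_P_SLOT = {"2a1": "pz", "1b2": "px", "3a1": "pz", "1b1": "py", "4a1": "pz"}

#: Slots with a flipped sign per MO: antisymmetric H combination for b2
#: symmetry, antibonding O phase for the empty 4a1, O_s node in 3a1.
_MO_FLIPPED = {
    "2a1": set(),
    "1b2": {"H2_s", "H2_p"},
    "3a1": {"O_s"},
    "1b1": {"H2_s"},
    "4a1": {"O_s", "O_p"},
}


def make_toy_water(
    mo_energies=WATER_MO_BINDING_EV,
    mo_widths=(0.5, 0.5, 0.5, 0.5),
    gap: float = 8.7,
    kmesh=(3, 3, 3),
    species_weights: dict | None = None,
    a: float | None = None,
    lumo_width: float = 1.0,
    gcutoff: float | None = None,
) -> KSModel:
    """Water-like gapped four-band toy crystal.

    One molecule per cubic cell at the liquid-water molecular volume
    (a ~ 5.87 bohr), four occupied bands centred at the liquid-water
    molecular-orbital binding energies (eV below vacuum) with small cosine
    dispersion, one empty band a ``gap`` above the highest occupied band
    centre.  Orbitals: O s/p and H s/p Gaussians carrying species and
    angular-momentum labels.

    ``species_weights`` overrides the per-MO (species, l) composition, as a
    mapping MO-label -> {(species, l): weight}.
    """
    mo_energies = tuple(float(e) for e in mo_energies)
    mo_widths = tuple(float(w) for w in mo_widths)
    if len(mo_energies) != 4 or len(mo_widths) != 4:
        raise ValueError("exactly four occupied molecular orbitals are expected")
    order = np.argsort(mo_energies)[::-1]  # deepest (largest binding) first
    centers_occ = [-mo_energies[i] for i in order]
    widths_occ = [mo_widths[i] for i in order]
    labels_occ = [WATER_MO_LABELS[i] for i in order]

    # occupied windows must not overlap (channel windows would be ill-defined)
    intervals = sorted(
        (c - w, c + w, lab) for c, w, lab in zip(centers_occ, widths_occ, labels_occ)
    )
    for (lo1, hi1, l1), (lo2, hi2, l2) in zip(intervals, intervals[1:]):
        if hi1 >= lo2:
            raise ValueError(
                f"occupied bands {l1} and {l2} overlap in energy "
                f"([{lo1:g},{hi1:g}] vs [{lo2:g},{hi2:g}] eV); "
                "molecular-orbital channel windows would be ill-defined"
            )

    homo_center = max(centers_occ)
    lumo_center = homo_center + float(gap)
    if lumo_center - lumo_width <= homo_center + widths_occ[int(np.argmax(centers_occ))]:
        raise ValueError("gap too small: empty band overlaps the highest occupied band")

    if a is None:
        a = WATER_MOLECULAR_VOLUME_BOHR3 ** (1.0 / 3.0)

    # geometry: O at the cell centre, two H at r_OH = 1.81 bohr, 104.5 deg,
    # molecule in the xz plane with the C2 axis along z
    center = 0.5 * a * np.ones(3)
    r_oh = 1.81
    half = np.deg2rad(104.5 / 2.0)
    h1 = center + r_oh * np.array([np.sin(half), 0.0, np.cos(half)])
    h2 = center + r_oh * np.array([-np.sin(half), 0.0, np.cos(half)])
    orbitals = [
        (OrbitalLabel(0, "O", "s"), center, 1.1, 0),
        (OrbitalLabel(0, "O", "p"), center, 1.1, 0),  # px
        (OrbitalLabel(0, "O", "p"), center, 1.1, 1),  # py
        (OrbitalLabel(0, "O", "p"), center, 1.1, 2),  # pz
        (OrbitalLabel(1, "H", "s"), h1, 1.3, 0),
        (OrbitalLabel(1, "H", "p"), h1, 1.3, 1),  # py, out of plane
        (OrbitalLabel(2, "H", "s"), h2, 1.3, 0),
        (OrbitalLabel(2, "H", "p"), h2, 1.3, 1),
    ]
    slot_names = ["O_s", "O_px", "O_py", "O_pz", "H1_s", "H1_p", "H2_s", "H2_p"]

    weights = dict(_DEFAULT_MO_WEIGHTS)
    if species_weights:
        for mo, comp in species_weights.items():
            weights[mo] = {tuple(k): v for k, v in comp.items()}

    band_order = labels_occ + ["4a1"]
    templates = np.zeros((5, 8))
    for ib, mo in enumerate(band_order):
        comp = weights[mo]
        flipped = _MO_FLIPPED.get(mo, set())
        for key, wt in comp.items():
            sp, l = key
            if sp == "O" and l == "s":
                slots = ["O_s"]
            elif sp == "O" and l == "p":
                slots = ["O_" + _MO_P_SLOT.get(mo, "pz")]
            elif sp == "H":
                slots = [f"H1_{l}", f"H2_{l}"]
            else:
                raise ValueError(f"no orbital of kind {key} in the toy basis")
            amp = np.sqrt(wt / len(slots))
            for name in slots:
                sign = -1.0 if (name in flipped or name[:3] in flipped) else 1.0
                templates[ib, slot_names.index(name)] += sign * amp

    model = make_lcao_model(
        a=a,
        kmesh=kmesh,
        orbitals=orbitals,
        band_templates=templates,
        band_centers_ev=np.array(centers_occ + [lumo_center]),
        band_halfwidths_ev=np.array(widths_occ + [lumo_width]),
        band_occupations=np.array([2.0, 2.0, 2.0, 2.0, 0.0]),
        gcutoff=gcutoff,
        spec={
            "kind": "toy_water",
            "mo_energies": list(mo_energies),
            "mo_widths": list(mo_widths),
            "gap": float(gap),
            "kmesh": list(kmesh),
            "a": float(a),
            "lumo_width": float(lumo_width),
        },
    )
    model.band_labels = band_order  # type: ignore[attr-defined]
    return model


def density_of_states(model: KSModel, energy_grid_ev: np.ndarray, sigma_ev: float = 0.3):
    """Gaussian-broadened DOS (states/eV/cell) on the below-vacuum eV scale."""
    e = np.asarray(energy_grid_ev, dtype=float)
    bands = model.band_energies.ravel() * HARTREE_EV
    w = np.repeat(model.kweights, model.n_bands)
    dos = np.zeros_like(e)
    for eb, wb in zip(bands, w):
        dos += wb * np.exp(-0.5 * ((e - eb) / sigma_ev) ** 2)
    return dos / (sigma_ev * np.sqrt(2.0 * np.pi))
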
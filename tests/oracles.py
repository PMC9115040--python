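"""Independent brute-force oracles for the response machinery.

Everything here is deliberately naive: explicit Python loops, index searches
by scanning, no shared code with the library's vectorized implementations.
"""

import numpy as np

from elfxs.constants import EV_HARTREE


def naive_fold(model, kfrac):
    """Find (ik, gshift) with kfrac = kpoints[ik] + gshift by scanning."""
    for ik, kp in enumerate(model.kpoints):
        diff = np.asarray(kfrac) - kp
        rounded = np.round(diff)
        if np.allclose(diff, rounded, atol=1e-8):
            return ik, rounded.astype(int)
    raise AssertionError(f"{kfrac} not on the mesh")


def naive_g_lookup(model, g):
    for i, gi in enumerate(model.internal_g):
        if all(int(gi[d]) == int(g[d]) for d in range(3)):
            return i
    return -1


def naive_U(model, ik, qfrac, n, m, G):
    """U^G_{nm,k}(q) by looping over every internal plane-wave component."""
    ik2, gshift = naive_fold(model, model.kpoints[ik] + qfrac)
    s = 0.0 + 0.0j
    for i, gi in enumerate(model.internal_g):
        target = [int(gi[d]) + int(G[d]) + int(gshift[d]) for d in range(3)]
        j = naive_g_lookup(model, target)
        if j >= 0:
            s += np.conj(model.coeffs[ik, n, i]) * model.coeffs[ik2, m, j]
    return s


def naive_chi0(model, q_mag, direction, energy_ev, eta_ev, glist):
    """chi0_{GG'}(E, q) by a triple loop over (n, m, k) and a double loop
    over (G, G')."""
    qfrac = model.q_fractional(q_mag, direction)
    e = energy_ev * EV_HARTREE
    eta = eta_ev * EV_HARTREE
    ng = len(glist)
    out = np.zeros((ng, ng), dtype=complex)
    nk = model.n_kpoints
    for ik in range(nk):
        ik2, _ = naive_fold(model, model.kpoints[ik] + qfrac)
        for n in range(model.n_bands):
            for m in range(model.n_bands):
                df = model.occupations[ik, n] - model.occupations[ik2, m]
                if abs(df) < 1e-12:
                    continue
                denom = e - (
                    model.band_energies[ik2, m] - model.band_energies[ik, n]
                ) + 1j * eta
                for a in range(ng):
                    ua = naive_U(model, ik, qfrac, n, m, glist[a])
                    for b in range(ng):
                        ub = naive_U(model, ik, qfrac, n, m, glist[b])
                        out[a, b] += df * ua * np.conj(ub) / denom
    return out / (nk * model.cell_volume)


def quadrature_U(model, ik, qfrac, n, m, G, ngrid=24):
    """U^G by real-space quadrature of the defining cell integral
    (1/V) int psi*_{n,k} exp(-i(G+q)r) psi_{m,k+q} d^3r on a uniform grid."""
    ik2, _ = naive_fold(model, model.kpoints[ik] + qfrac)
    a = model.a
    x = np.arange(ngrid) * (a / ngrid)
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    r = np.stack([X, Y, Z], axis=-1)  # (N,N,N,3)

    def psi(ikk, band, kfrac):
        wav = np.zeros(X.shape, dtype=complex)
        for i, gi in enumerate(model.internal_g):
            c = model.coeffs[ikk, band, i]
            if abs(c) < 1e-14:
                continue
            kvec = (np.asarray(kfrac) + gi) * model.b
            wav += c * np.exp(1j * (r @ kvec))
        return wav

    p1 = psi(ik, n, model.kpoints[ik])
    # periodic gauge: the state at Bloch vector k+q is the stored state at
    # the folded mesh point ik2 (same function of r)
    p2 = psi(ik2, m, model.kpoints[ik2])
    gq = (np.asarray(G) + qfrac) * model.b
    integrand = np.conj(p1) * np.exp(-1j * (r @ gq)) * p2
    return integrand.mean()
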
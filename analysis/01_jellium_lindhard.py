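#!/usr/bin/env python
"""Validate the RPA response machinery against the analytic Lindhard gas.

Builds an r_s = 2 jellium on successively finer k-meshes, compares the
discrete chi0 head against the closed-form Lindhard function, and writes the
small-q ELF next to the analytic RPA ELF (plasmon at omega_p = sqrt(4 pi n)).

Outputs: results/jellium_lindhard_convergence.tsv,
         results/jellium_elf_vs_lindhard.tsv
"""

from pathlib import Path

import numpy as np

from elfxs.constants import HARTREE_EV
from elfxs.lindhard import lindhard_chi0, lindhard_elf, plasma_frequency
from elfxs.models import make_jellium
from elfxs.response import chi0_array, elf_with_lfe, pair_table

RS = 2.0
DENSITY = 3.0 / (4.0 * np.pi * RS**3)
HEAD = np.array([[0, 0, 0]])
ETA = 1.5  # eV

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    wp = plasma_frequency(DENSITY) * HARTREE_EV
    print(f"jellium r_s = {RS}: omega_p = {wp:.2f} eV, "
          f"E_F = {make_jellium(DENSITY, (2, 2, 2), 8).fermi_energy * HARTREE_EV:.2f} eV")

    rows = []
    for nk in (8, 12, 16):
        m = make_jellium(DENSITY, kmesh=(nk,) * 3, n_bands=15)
        errs = []
        for mult, e_ev in [(2, 5.0), (2, 15.0), (3, 10.0), (3, 20.0), (4, 25.0)]:
            q = mult * m.min_q()
            got = chi0_array(pair_table(m, q, glist=HEAD), [e_ev], ETA)[0, 0, 0]
            ref = lindhard_chi0(DENSITY, q, e_ev, ETA)
            errs.append(abs(got - ref) / abs(ref))
        rows.append((nk, max(errs)))
        print(f"  {nk}^3 mesh: max |chi0 - Lindhard|/|Lindhard| = {max(errs):.4f}")

    with (OUT / "jellium_lindhard_convergence.tsv").open("w") as fh:
        fh.write("# chi0 head vs closed-form Lindhard, eta = 1.5 eV\n")
        fh.write("n_k\tmax_rel_err\n")
        for nk, err in rows:
            fh.write(f"{nk}\t{err:.6e}\n")

    m = make_jellium(DENSITY, kmesh=(16,) * 3, n_bands=15)
    q = m.min_q()
    e = np.arange(0.5, 40.0, 0.1)
    elf = elf_with_lfe(m, q, e, 1.0, glist=HEAD)
    ref = lindhard_elf(DENSITY, q, e, 1.0)
    peak = e[np.argmax(elf)]
    print(f"  ELF(q = {q:.3f} a.u.) peak at {peak:.1f} eV "
          f"(omega_p = {wp:.2f} eV, deviation {abs(peak - wp) / wp:.1%})")
    with (OUT / "jellium_elf_vs_lindhard.tsv").open("w") as fh:
        fh.write(f"# 16^3 mesh, q = {q:.6g} a.u., eta = 1.0 eV\n")
        fh.write("E_eV\tELF_mesh\tELF_lindhard\n")
        for ei, a, b in zip(e, elf, ref):
            fh.write(f"{ei:.6g}\t{a:.8e}\t{b:.8e}\n")


if __name__ == "__main__":
    main()
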
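#!/usr/bin/env python
"""Track-structure quantities: SDCS, IMFP and stopping power.

Two stages:
1. A water-like plasmon-pole Drude Bethe surface (valence density of liquid
   water, peak at 21 eV) integrated into the total inelastic cross section,
   IMFP and electronic stopping power over 10 eV - 100 keV: the IMFP shows
   the familiar U-shape with a minimum near 0.6 nm around 85 eV, and the
   stopping follows the Bethe ln(T)/T fall-off at high energy.
2. Per-molecular-orbital SDCS of the toy-water model at T = 100 and 500 eV:
   losses below ~10 eV are carried almost entirely by the 1b1 (HOMO)
   channel; deeper channels take over at higher losses.

Outputs: results/water_drude_imfp.tsv, results/water_drude_stopping.tsv,
         results/toy_water_sdcs_T{100,500}.tsv
"""

from pathlib import Path

import numpy as np

from elfxs.constants import HARTREE_EV
from elfxs.cross_sections import (
    channel_cross_sections,
    sdcs,
    stopping_power,
    total_cross_section,
)
from elfxs.io import write_sdcs_table, write_xs_table
from elfxs.models import WATER_MOLECULAR_VOLUME_BOHR3, make_toy_water
from elfxs.partition import mo_channel_elf
from elfxs.surfaces import DrudePeakSet, ELFSurface, make_drude_elf

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def water_drude_surface() -> "ELFSurface":
    n_val = 8.0 / WATER_MOLECULAR_VOLUME_BOHR3  # valence electrons per bohr^3
    wp2 = 4.0 * np.pi * n_val * HARTREE_EV**2  # (19.2 eV)^2
    peaks = DrudePeakSet([(21.0, 10.0, wp2)], dispersion_mode="quadratic")
    e = np.arange(0.5, 2000.0, 0.5)
    q = np.geomspace(0.05, 13.0, 60)
    return make_drude_elf(peaks, e, q)


def main() -> None:
    surf = water_drude_surface()
    t_grid = np.geomspace(10.0, 1e5, 60)
    tot = total_cross_section(surf, t_grid)
    stop = stopping_power(surf, t_grid)
    write_xs_table(tot, OUT / "water_drude_imfp.tsv", "imfp")
    write_xs_table(tot, OUT / "water_drude_sigma.tsv", "sigma")
    write_xs_table(stop, OUT / "water_drude_stopping.tsv", "stopping")
    imin = int(np.argmin(tot.imfp))
    print(f"water-like Drude surface: IMFP minimum {tot.imfp[imin]:.2f} nm at "
          f"T = {t_grid[imin]:.0f} eV; "
          f"S_e(100 eV) = {stop.stopping[np.argmin(abs(t_grid - 100)):][0]:.1f} eV/nm; "
          f"extrapolated-q fraction {tot.extrapolated_fraction:.2e}")

    m = make_toy_water()
    e_grid = np.arange(0.25, 55.0, 0.25)
    qs = [m.min_q() * k for k in (1, 2, 4)]
    _, surfs = mo_channel_elf(m, None, qs, e_grid, 0.3, average_directions=True)
    for T in (100.0, 500.0):
        per = channel_cross_sections(surfs, T)
        curves = list(per.values())
        write_sdcs_table(curves, OUT / f"toy_water_sdcs_T{T:g}.tsv")
        total = sum(c.values for c in curves)
        low = curves[0].energies < 10.0
        share = np.sum(per["1b1"].values[low]) / np.sum(total[low])
        print(f"  T = {T:g} eV: sub-10-eV losses {share:.0%} from the 1b1 "
              f"(HOMO) channel")


if __name__ == "__main__":
    main()
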
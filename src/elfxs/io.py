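"""Plain-text table and configuration formats.

All tables are UTF-8 TSV with '#'-prefixed metadata header lines; the dialect
mirrors common ELF / IMFP data releases and parses with any spreadsheet or
``pandas.read_csv(comment='#')``.  Model descriptions and run configurations
use TOML.
"""

from __future__ import annotations

import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import HARTREE_EV
from .surfaces import ELFSurface

__all__ = [
    "write_elf_table",
    "read_elf_table",
    "write_partition_table",
    "read_partition_table",
    "write_xs_table",
    "write_sdcs_table",
    "model_to_config",
    "model_from_config",
    "read_toml",
    "write_toml",
    "RunLog",
]

_FMT = "%.17g"  # round-trips float64 exactly


def write_elf_table(surface: ELFSurface, path, energy_unit: str = "eV") -> None:
    """Write an ELF surface; columns are q values, rows energy losses."""
    if energy_unit not in ("eV", "hartree"):
        raise ValueError("energy_unit must be 'eV' or 'hartree'")
    scale = 1.0 if energy_unit == "eV" else 1.0 / HARTREE_EV
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("# elfxs elf-table v1\n")
        fh.write(f"# energy_unit: {energy_unit}\n")
        fh.write("# q_unit: au\n")
        fh.write(f"# optical_q: {_FMT % surface.optical_q}\n")
        if surface.allow_negative:
            fh.write("# allow_negative: true\n")
        if surface.provenance:
            fh.write(f"# provenance: {surface.provenance}\n")
        fh.write("# columns: E\t" + "\t".join(f"q={_FMT % q}" for q in surface.q_grid) + "\n")
        for i, e in enumerate(surface.energy_grid):
            row = "\t".join(_FMT % v for v in surface.values[i])
            fh.write(f"{_FMT % (e * scale)}\t{row}\n")


def read_elf_table(path) -> ELFSurface:
    """Read an ELF surface written by :func:`write_elf_table`.

    The declared energy unit is honoured (hartree tables are converted to the
    in-memory eV convention); negative cells and non-uniform energy spacing
    are rejected with the offending location.
    """
    path = Path(path)
    meta = {}
    qcols = None
    rows = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            parts = line.split("\t")
            vals = [float(x) for x in parts]
            rows.append((lineno, vals))
    if "columns" in meta:
        qcols = [
            float(tok.split("=", 1)[1])
            for tok in meta["columns"].split("\t")[1:]
        ]
    if qcols is None:
        raise ValueError(f"{path}: missing '# columns:' header declaring q columns")
    unit = meta.get("energy_unit", "eV")
    if unit not in ("eV", "hartree"):
        raise ValueError(f"{path}: unsupported energy_unit {unit!r}")
    if meta.get("q_unit", "au") != "au":
        raise ValueError(f"{path}: unsupported q_unit {meta.get('q_unit')!r}")
    allow_negative = meta.get("allow_negative", "").lower() == "true"
    scale = 1.0 if unit == "eV" else HARTREE_EV
    energies = np.array([r[1][0] for r in rows]) * scale
    values = np.array([r[1][1:] for r in rows])
    if not allow_negative and np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(
            f"{path}: negative ELF value at line {rows[i][0]}, column q={qcols[j]:g}"
        )
    de = np.diff(energies)
    if de.size and not np.allclose(de, de[0], rtol=1e-8, atol=1e-12):
        bad = int(np.argmax(np.abs(de - de[0]))) + 1
        raise ValueError(
            f"{path}: non-uniform energy spacing near line {rows[bad][0]}"
        )
    optical_q = float(meta["optical_q"]) if "optical_q" in meta else None
    return ELFSurface(
        energies,
        np.asarray(qcols, dtype=float),
        values,
        optical_q=optical_q,
        provenance=meta.get("provenance", f"read from {path.name}"),
        allow_negative=allow_negative,
    )


# ---------------------------------------------------------------------------
# partition and cross-section tables
# ---------------------------------------------------------------------------


def write_partition_table(part, path, q_grid=None, energy_grid=None) -> None:
    """Long-format (label, E, q, value) table of a PartitionResult whose
    components are (n_E, n_q) arrays; includes the reference total as label
    'total'."""
    q_grid = np.asarray(q_grid if q_grid is not None else part.meta["q_grid"])
    energy_grid = np.asarray(
        energy_grid if energy_grid is not None else part.meta["energy_grid_ev"]
    )
    recs = []
    items = list(part.components.items()) + [("total", part.total)]
    for lab, vals in items:
        vals = np.asarray(vals)
        for iq, q in enumerate(q_grid):
            for ie, e in enumerate(energy_grid):
                recs.append((str(lab), e, q, vals[ie, iq]))
    df = pd.DataFrame(recs, columns=["label", "E_eV", "q_au", "elf"])
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("# elfxs partition-table v1\n")
        fh.write(f"# scheme: {part.scheme}\n")
        fh.write("# energy_unit: eV\n# q_unit: au\n")
        df.to_csv(fh, sep="\t", index=False, float_format=_FMT)


def read_partition_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_xs_table(table, path, quantity: str) -> None:
    """(T, quantity) two-column table; quantity in {'imfp', 'sigma', 'stopping'}."""
    col = {
        "imfp": ("IMFP_nm", table.imfp),
        "sigma": ("Sigma_per_nm", table.sigma_total),
        "stopping": ("Se_eV_per_nm", table.stopping),
    }[quantity]
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("# elfxs cross-section table v1\n")
        fh.write(f"# quantity: {col[0]}\n")
        fh.write(f"# emin_mode: {table.emin_mode}\tE_gap_eV: {table.E_gap}\t"
                 f"E_F_eV: {table.E_F}\n")
        fh.write(f"T_eV\t{col[0]}\n")
        for t, v in zip(table.T_grid, col[1]):
            fh.write(f"{_FMT % t}\t{_FMT % v}\n")


def write_sdcs_table(curves, path) -> None:
    """Per-T SDCS table: column E plus one dS/dE column per curve (total
    and/or molecular-orbital channels)."""
    if not isinstance(curves, (list, tuple)):
        curves = [curves]
    e = curves[0].energies
    for c in curves[1:]:
        if not np.array_equal(c.energies, e):
            raise ValueError("SDCS curves must share the energy grid")
    names = [c.channel or "total" for c in curves]
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("# elfxs sdcs-table v1\n")
        fh.write(f"# T_eV: {_FMT % curves[0].T}\n")
        fh.write("# units: E in eV, dS/dE in 1/(eV nm)\n")
        for c in curves:
            fh.write(
                f"# extrapolated_fraction[{c.channel or 'total'}]: "
                f"{c.extrapolated_fraction:.6g}\n"
            )
        fh.write("E_eV\t" + "\t".join(f"dSdE_{n}" for n in names) + "\n")
        for i, ei in enumerate(e):
            fh.write(
                f"{_FMT % ei}\t" + "\t".join(_FMT % c.values[i] for c in curves) + "\n"
            )


# ---------------------------------------------------------------------------
# TOML-style configs
# ---------------------------------------------------------------------------


def read_toml(path) -> dict:
    import tomllib

    with open(path, "rb") as fh:
        return tomllib.load(fh)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def write_toml(data: dict, path) -> None:
    """Minimal TOML writer for flat dicts and one level of sub-tables."""
    lines = []
    subtables = {}
    for k, v in data.items():
        if isinstance(v, dict):
            subtables[k] = v
        elif v is not None:
            lines.append(f"{k} = {_toml_value(v)}")
    for name, tbl in subtables.items():
        lines.append(f"\n[{name}]")
        for k, v in tbl.items():
            if v is not None:
                lines.append(f"{k} = {_toml_value(v)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def model_to_config(model, path) -> None:
    """Serialize a model's construction recipe (not its arrays)."""
    if not model.spec:
        raise ValueError("model carries no construction spec to serialize")
    write_toml({"model": model.spec}, path)


def model_from_config(path):
    from . import models

    cfg = read_toml(path)
    spec = dict(cfg["model"] if "model" in cfg else cfg)
    kind = spec.pop("kind")
    if kind == "jellium":
        spec["kmesh"] = tuple(spec.get("kmesh", (8, 8, 8)))
        return models.make_jellium(**spec)
    if kind == "toy_water":
        spec["kmesh"] = tuple(spec.get("kmesh", (3, 3, 3)))
        return models.make_toy_water(**spec)
    raise ValueError(f"unknown model kind {kind!r}")


class RunLog:
    """Single structured log per CLI run: numerical policies triggered
    (extrapolation fractions, exclusions, warnings) plus the serialized
    configuration, written next to the outputs."""

    def __init__(self) -> None:
        self.entries: list[str] = []

    def add(self, msg: str) -> None:
        stamp = datetime.datetime.now().isoformat(timespec="seconds")
        self.entries.append(f"{stamp}  {msg}")

    def write(self, path) -> None:
        Path(path).write_text("\n".join(self.entries) + "\n", encoding="utf-8")
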
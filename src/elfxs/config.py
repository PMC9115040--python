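"""Run configuration: validated parameter bundle for the pipeline stages.

Defaults follow the numerical conventions used throughout: energy resolution
dE = 0.15 eV, broadening eta = 0.3 eV (kept >= 2 dE), momentum-transfer grid
on [0.1, 2.0] a.u., optical limit at the smallest grid q.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .io import read_toml, write_toml


@dataclass
class RunConfig:
    model_config: str | None = None  # path to a model TOML
    elf_table: str | None = None  # or a tabulated ELF
    e_max: float = 60.0  # eV, top of the energy-loss grid
    de: float = 0.15  # eV
    eta: float = 0.3  # eV
    q_min: float = 0.1  # a.u.
    q_max: float = 2.0
    n_q: int = 20
    optical_q: float | None = None
    lfe: bool = True
    scheme: str = "species"
    windows: dict | None = None  # label -> [lo, hi] binding energy, eV
    T_grid: list = field(default_factory=lambda: [100.0, 500.0])
    emin_mode: str = "zero"
    e_gap: float = 0.0
    e_fermi: float = 0.0
    outdir: str = "."
    seed: int = 0

    def validate(self) -> "RunConfig":
        if self.de <= 0 or self.e_max <= self.de:
            raise ValueError("need 0 < de < e_max")
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.q_min <= 0 or self.q_max < self.q_min or self.n_q < 1:
            raise ValueError("invalid q grid")
        if self.emin_mode not in ("zero", "gap"):
            raise ValueError("emin_mode must be 'zero' or 'gap'")
        if any(t <= 0 for t in self.T_grid):
            raise ValueError("incident energies must be positive")
        return self

    def energy_grid(self) -> np.ndarray:
        return np.arange(self.de, self.e_max + 0.5 * self.de, self.de)

    def q_grid(self) -> np.ndarray:
        if self.n_q == 1:
            return np.array([self.q_min])
        return np.linspace(self.q_min, self.q_max, self.n_q)

    def to_toml(self, path) -> None:
        d = asdict(self)
        windows = d.pop("windows", None)
        data = {"run": {k: v for k, v in d.items() if v is not None}}
        if windows:
            data["windows"] = {k: list(v) for k, v in windows.items()}
        write_toml(data, path)

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        data = read_toml(path)
        run = dict(data.get("run", {}))
        if "windows" in data:
            run["windows"] = {k: tuple(v) for k, v in data["windows"].items()}
        return cls(**run).validate()
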
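"""Photophysical and nucleic-acid binding parameters of intercalating dyes.

Dyes such as SYTOX Green or propidium iodide are membrane-impermeant and
almost non-fluorescent in solution; intercalation into DNA/RNA enhances
their emission several-hundred-fold (SYTOX Green) or ~30-fold (PI). The
packaged parameter sets live in ``data/dyes.yaml`` and are loaded lazily.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import yaml

from .errors import ArgumentError

__all__ = ["DyeParams", "load_dye_library", "get_dye"]


@dataclass(frozen=True)
class DyeParams:
    """Binding kinetics and brightness of one intercalating dye.

    Parameters
    ----------
    k_on : float
        Bimolecular binding rate constant, per µM per s.
    k_off : float
        Unbinding rate constant, per s.
    brightness_free, brightness_bound : float
        Emission coefficients (a.u. per µM) of free and bound dye.
    quench_conc : float
        Extracellular concentration (µM) at which self-quenching halves the
        bound-dye brightness; ``inf`` disables quenching.
    """

    name: str
    k_on: float
    k_off: float
    brightness_free: float
    brightness_bound: float
    quench_conc: float = math.inf

    def __post_init__(self) -> None:
        for field in ("k_on", "k_off", "brightness_free", "brightness_bound"):
            value = getattr(self, field)
            if not np.isfinite(value) or value < 0:
                raise ArgumentError(f"{self.name}: {field} must be finite and >= 0")
        if self.brightness_free <= 0:
            raise ArgumentError(f"{self.name}: brightness_free must be > 0")
        if self.quench_conc <= 0:
            raise ArgumentError(f"{self.name}: quench_conc must be > 0")

    @property
    def enhancement(self) -> float:
        """Bound/free brightness ratio (the binding fluorescence enhancement)."""
        return self.brightness_bound / self.brightness_free

    def quench_factor(self, c_ext: float) -> float:
        """Divisive self-quenching factor 1 / (1 + C_ext / quench_conc)."""
        if math.isinf(self.quench_conc):
            return 1.0
        return 1.0 / (1.0 + c_ext / self.quench_conc)

    def with_rate(self, k_on: float) -> "DyeParams":
        """Copy of this dye with a different effective binding rate constant."""
        return replace(self, k_on=k_on)


def load_dye_library() -> dict[str, DyeParams]:
    """Load the packaged dye library from ``data/dyes.yaml``."""
    text = resources.files("sonokinetics").joinpath("data/dyes.yaml").read_text()
    raw = yaml.safe_load(text)
    return {name: DyeParams(name=name, **params) for name, params in raw.items()}


def get_dye(name: str) -> DyeParams:
    """Return one packaged dye parameter set by name."""
    library = load_dye_library()
    if name not in library:
        raise ArgumentError(f"unknown dye {name!r}; packaged: {sorted(library)}")
    return library[name]
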
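"""Permeabilization, illumination and cell-line parameter records.

Membrane permeabilization is described by a time-dependent first-order
permeability rate P(t) (per s): after sonoporation the membrane pore
reseals within seconds up to a minute, modelled as a single exponential;
detergent (Triton) permeabilization leaves a constant permeability.

Illumination enters the kinetics only through an effective first-order
photobleaching rate of bound dye, linear in the laser duty cycle:
``k_pb(DC) = k_dark + k_laser * DC``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ArgumentError

__all__ = [
    "PermeabilizationProtocol",
    "IlluminationProtocol",
    "CellLineParams",
    "permeability_at",
    "PULSED_DUTY_CYCLE",
    "CONTINUOUS_DUTY_CYCLE",
]

#: Duty cycle of pulsed acquisition (laser off between frames).
PULSED_DUTY_CYCLE = 0.033
#: Duty cycle of continuous illumination.
CONTINUOUS_DUTY_CYCLE = 1.0

_MODES = ("usmb", "chemical", "none")


@dataclass(frozen=True)
class PermeabilizationProtocol:
    """Membrane permeabilization time course.

    mode
        ``"usmb"`` — exponentially resealing pore, ``P(t) = P0 exp(-(t-onset)/tau_pore)``;
        ``"chemical"`` — constant permeability ``P_chem`` from onset on;
        ``"none"`` — intact membrane, zero permeability.
    """

    mode: str
    P0: float = 0.0          # per s, initial pore permeability (usmb)
    tau_pore: float = 5.0    # s, pore resealing time constant (usmb)
    P_chem: float = 0.0      # per s, constant permeability (chemical)
    onset_time: float = 0.0  # s

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ArgumentError(f"unknown permeabilization mode {self.mode!r}")
        if self.mode == "usmb" and not (0.0 < self.tau_pore <= 60.0):
            raise ArgumentError("tau_pore must lie in (0, 60] s")
        for field in ("P0", "P_chem"):
            if getattr(self, field) < 0:
                raise ArgumentError(f"{field} must be >= 0")
        if self.onset_time < 0:
            raise ArgumentError("onset_time must be >= 0")


def permeability_at(protocol: PermeabilizationProtocol, t):
    """Membrane permeability rate (per s) at time(s) ``t`` (s).

    Vectorized over ``t``; negative times are rejected.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ArgumentError("t must be >= 0")
    if protocol.mode == "none":
        out = np.zeros_like(t)
    elif protocol.mode == "chemical":
        out = np.where(t >= protocol.onset_time, protocol.P_chem, 0.0)
    else:
        dt = t - protocol.onset_time
        out = np.where(dt >= 0, protocol.P0 * np.exp(-np.maximum(dt, 0.0) / protocol.tau_pore), 0.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class IlluminationProtocol:
    """Acquisition timing and duty-cycle-dependent photobleaching."""

    duty_cycle: float        # fraction of time the laser is on, in [0, 1]
    k_dark: float = 0.0      # per s, duty-cycle independent decay
    k_laser: float = 0.0     # per s, bleach rate at 100 % duty cycle
    frame_interval: float = 30.0  # s
    duration: float = 1800.0      # s

    def __post_init__(self) -> None:
        if not 0.0 <= self.duty_cycle <= 1.0:
            raise ArgumentError("duty_cycle must lie in [0, 1]")
        if self.k_dark < 0 or self.k_laser < 0:
            raise ArgumentError("bleach rates must be >= 0")
        if self.frame_interval <= 0 or self.duration <= 0:
            raise ArgumentError("frame_interval and duration must be > 0")

    @property
    def bleach_rate(self) -> float:
        """Effective photobleaching rate k_pb(DC) = k_dark + k_laser * DC (per s)."""
        return self.k_dark + self.k_laser * self.duty_cycle


@dataclass(frozen=True)
class CellLineParams:
    """Cell-line dependent kinetic parameters.

    Site densities are µM-equivalent totals of nucleic-acid binding sites in
    each compartment (volumes normalized to 1); ``k_cn`` is the free-dye
    exchange rate between cytosol and nucleus; ``rate_multiplier`` scales the
    effective binding kinetics of the line relative to a reference line.
    """

    name: str
    site_density_cytosol: float  # µM-equivalent
    site_density_nucleus: float  # µM-equivalent
    k_cn: float                  # per s
    rate_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.site_density_nucleus <= self.site_density_cytosol:
            raise ArgumentError("nuclear site density must exceed cytosolic site density")
        if min(self.site_density_cytosol, self.k_cn) < 0:
            raise ArgumentError("site densities and k_cn must be >= 0")
        if self.rate_multiplier <= 0:
            raise ArgumentError("rate_multiplier must be > 0")
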
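"""Mechanistic single-cell / well-average model of intercalating-dye kinetics.

The cell is two well-mixed compartments (cytosol, nucleus; volumes
normalized to 1) exchanging free dye at rate ``k_cn``. Free dye enters the
cytosol through the permeabilized membrane at rate ``P(t) (C_ext - C_cyt)``
(Fick-type influx), binds reversibly to nucleic-acid sites in each
compartment (bimolecular ``k_on``, unbinding ``k_off``), and bound dye is
photobleached at the illumination-dependent rate ``k_pb``. State variables
(all µM, volumes normalized):

    C_cyt, B_cyt   free / bound dye in the cytosol
    C_nuc, B_nuc   free / bound dye in the nucleus
    Q              cumulative photobleached bound dye

Mass conservation: cumulative membrane influx equals
``C_cyt + B_cyt + C_nuc + B_nuc + Q`` at every time (tracked as an extra
integrated state and exposed for verification).

The reported fluorescence intensity is

    I(t) = b_free (C_cyt + C_nuc) + b_bound (B_cyt + B_nuc) / (1 + C_ext/quench)

i.e. bound-dye emission self-quenches divisively at high extracellular
concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .dyes import DyeParams
from .errors import ArgumentError, NumericalError
from .protocols import CellLineParams, IlluminationProtocol, PermeabilizationProtocol, permeability_at

__all__ = [
    "CellState",
    "CellStateSeries",
    "UptakeTrace",
    "simulate_cell_trace",
    "simulate_well_trace",
    "lognormal_multipliers",
    "DEFAULT_FCFM_TIMES",
    "DEFAULT_WELL_TIMES",
]

#: FCFM population acquisition grid: one snapshot per 30 s for 30 min,
#: first frame 30 s after the ultrasound exposure window.
DEFAULT_FCFM_TIMES = np.arange(30.0, 1801.0 + 30.0, 30.0)

#: Spectrofluorometer well grid: one reading per 2 min for 180 min.
DEFAULT_WELL_TIMES = np.arange(0.0, 10801.0, 120.0)

# Negative excursions smaller than this are integrator noise and clipped.
_NEG_TOL = 1e-9


@dataclass(frozen=True)
class CellState:
    """Instantaneous compartment state (µM; volumes normalized to 1)."""

    C_cyt: float
    B_cyt: float
    C_nuc: float
    B_nuc: float
    Q: float

    @property
    def total(self) -> float:
        return self.C_cyt + self.B_cyt + self.C_nuc + self.B_nuc + self.Q

    def as_array(self) -> np.ndarray:
        return np.array([self.C_cyt, self.B_cyt, self.C_nuc, self.B_nuc, self.Q])


@dataclass(frozen=True)
class CellStateSeries:
    """Compartment state time series plus the cumulative membrane influx."""

    times: np.ndarray
    C_cyt: np.ndarray
    B_cyt: np.ndarray
    C_nuc: np.ndarray
    B_nuc: np.ndarray
    Q: np.ndarray
    influx: np.ndarray

    @property
    def total(self) -> np.ndarray:
        """Total intracellular dye (free + bound + bleached)."""
        return self.C_cyt + self.B_cyt + self.C_nuc + self.B_nuc + self.Q

    def intensity(self, dye: DyeParams, c_ext: float) -> np.ndarray:
        """Whole-cell fluorescence intensity under ``dye``'s observation model."""
        qf = dye.quench_factor(c_ext)
        return (dye.brightness_free * (self.C_cyt + self.C_nuc)
                + dye.brightness_bound * (self.B_cyt + self.B_nuc) * qf)

    def cytosol_intensity(self, dye: DyeParams, c_ext: float) -> np.ndarray:
        qf = dye.quench_factor(c_ext)
        return dye.brightness_free * self.C_cyt + dye.brightness_bound * self.B_cyt * qf

    def nucleus_intensity(self, dye: DyeParams, c_ext: float) -> np.ndarray:
        qf = dye.quench_factor(c_ext)
        return dye.brightness_free * self.C_nuc + dye.brightness_bound * self.B_nuc * qf


@dataclass(frozen=True)
class UptakeTrace:
    """Time-stamped fluorescence intensity series for one cell or well."""

    times: np.ndarray
    intensities: np.ndarray
    cell_id: str = "cell_0"
    condition: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        intensities = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "intensities", intensities)
        if times.shape != intensities.shape or times.ndim != 1:
            raise ArgumentError("times and intensities must be 1-D and equal length")
        if times.size and times[0] < 0:
            raise ArgumentError("first time must be >= 0")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ArgumentError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


def _validate_parameters(dye: DyeParams, cell: CellLineParams, c_ext: float) -> None:
    values = [dye.k_on, dye.k_off, cell.site_density_cytosol,
              cell.site_density_nucleus, cell.k_cn, cell.rate_multiplier, c_ext]
    if not np.all(np.isfinite(values)):
        raise ArgumentError("non-finite model parameter")
    if c_ext < 0:
        raise ArgumentError("C_ext must be >= 0")


def _integrate(dye: DyeParams, cell: CellLineParams, perm: PermeabilizationProtocol,
               c_ext: float, times: np.ndarray, k_pb: float,
               initial_state: CellState | None,
               rtol: float = 1e-10, atol: float = 1e-13) -> CellStateSeries:
    k_on = dye.k_on * cell.rate_multiplier
    k_off = dye.k_off
    s_c = cell.site_density_cytosol
    s_n = cell.site_density_nucleus
    k_cn = cell.k_cn

    def rhs(t: float, y: np.ndarray) -> list[float]:
        c_c, b_c, c_n, b_n, _q, _m = y
        p = permeability_at(perm, t)
        influx = p * (c_ext - c_c)
        bind_c = k_on * c_c * (s_c - b_c) - k_off * b_c
        bind_n = k_on * c_n * (s_n - b_n) - k_off * b_n
        exch = k_cn * (c_c - c_n)
        return [
            influx - bind_c - exch,
            bind_c - k_pb * b_c,
            exch - bind_n,
            bind_n - k_pb * b_n,
            k_pb * (b_c + b_n),
            influx,
        ]

    if initial_state is None:
        y0 = np.zeros(6)
    else:
        y0 = np.append(initial_state.as_array(), initial_state.total)

    t_end = float(times[-1])
    # Split at the permeabilization onset: P(t) is discontinuous there.
    breakpoints = [0.0]
    if 0.0 < perm.onset_time < t_end:
        breakpoints.append(perm.onset_time)
    breakpoints.append(t_end)

    ys: list[np.ndarray] = []
    y = y0
    for a, b in zip(breakpoints[:-1], breakpoints[1:]):
        wanted = times[(times > a) & (times <= b)]
        if times[0] == a == 0.0:
            wanted = np.concatenate([[0.0], wanted])
        # always evaluate the segment end so the state can be handed over
        t_eval = wanted if wanted.size and wanted[-1] == b else np.append(wanted, b)
        sol = solve_ivp(rhs, (a, b), y, method="LSODA", t_eval=t_eval,
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise NumericalError(f"ODE integration failed on [{a}, {b}]: {sol.message}")
        y = sol.y[:, -1]
        ys.append(sol.y[:, : wanted.size])

    out = np.concatenate(ys, axis=1)
    if out.shape[1] != times.size:  # pragma: no cover - defensive
        raise NumericalError("integrator returned wrong number of output points")
    if np.min(out[:5]) < -_NEG_TOL:
        raise NumericalError(f"state went negative beyond tolerance: min={np.min(out[:5]):.3e}")
    out[:5] = np.clip(out[:5], 0.0, None)
    return CellStateSeries(times=times.copy(), C_cyt=out[0], B_cyt=out[1],
                           C_nuc=out[2], B_nuc=out[3], Q=out[4], influx=out[5])


def simulate_cell_trace(
    dye: DyeParams,
    cell: CellLineParams,
    perm: PermeabilizationProtocol,
    illum: IlluminationProtocol | None,
    c_ext: float,
    times: Sequence[float],
    cell_id: str = "cell_0",
    initial_state: CellState | None = None,
    condition: Mapping[str, object] | None = None,
) -> tuple[UptakeTrace, CellStateSeries]:
    """Integrate the compartment ODE for one cell and report its intensity trace.

    ``illum=None`` disables photobleaching. ``initial_state`` allows
    pre-loaded cells (e.g. stained fixed cells for bleaching calibration).
    Returns the trace together with the full compartment state series.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2 or not np.all(np.diff(times) > 0):
        raise ArgumentError("times must be a strictly increasing 1-D vector")
    if times[0] < 0:
        raise ArgumentError("times must be >= 0")
    _validate_parameters(dye, cell, c_ext)
    k_pb = illum.bleach_rate if illum is not None else 0.0
    states = _integrate(dye, cell, perm, c_ext, times, k_pb, initial_state)
    meta = dict(condition or {})
    meta.setdefault("dye", dye.name)
    meta.setdefault("concentration_uM", c_ext)
    meta.setdefault("cell_line", cell.name)
    meta.setdefault("permeabilization", perm.mode)
    meta.setdefault("duty_cycle", illum.duty_cycle if illum is not None else 0.0)
    trace = UptakeTrace(times=times, intensities=states.intensity(dye, c_ext),
                        cell_id=cell_id, condition=meta)
    return trace, states


def simulate_well_trace(
    dye: DyeParams,
    cell: CellLineParams,
    perm: PermeabilizationProtocol,
    c_ext: float,
    times: Sequence[float] | None = None,
    cell_id: str = "well_0",
    condition: Mapping[str, object] | None = None,
) -> UptakeTrace:
    """Well-averaged monolayer trace for chemically permeabilized cells.

    The spectrofluorometer protocol has no meaningful photobleaching
    (k_pb = 0); traces are negative-control subtracted, so the baseline
    before dye entry is zero.
    """
    if perm.mode != "chemical":
        raise ArgumentError("simulate_well_trace requires chemical permeabilization")
    if times is None:
        times = DEFAULT_WELL_TIMES
    trace, _states = simulate_cell_trace(dye, cell, perm, None, c_ext, times,
                                         cell_id=cell_id, condition=condition)
    return trace


def lognormal_multipliers(n: int, log_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Median-one lognormal multipliers modelling cell-to-cell rate variability."""
    if n < 0:
        raise ArgumentError("n must be >= 0")
    return np.exp(rng.normal(0.0, log_sd, size=n))
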
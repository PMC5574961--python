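"""Mechanistic compartment model: conservation, limits, oracle agreement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sonokinetics.dyes import DyeParams, get_dye
from sonokinetics.errors import ArgumentError
from sonokinetics.fitting import fit_trace
from sonokinetics.model import simulate_cell_trace, simulate_well_trace
from sonokinetics.presets import condition_preset, simulate_condition
from sonokinetics.protocols import CellLineParams, PermeabilizationProtocol

TOY_DYE = DyeParams(name="toy", k_on=5e-3, k_off=2e-3, brightness_free=1.0,
                    brightness_bound=600.0)
TOY_CELL = CellLineParams(name="toy", site_density_cytosol=1.0,
                          site_density_nucleus=2.0, k_cn=0.01)


def euler_oracle(dye, cell, perm, c_ext, times, k_pb=0.0, dt=1e-3):
    """Brute-force explicit-Euler integration of the same ODE system."""
    from sonokinetics.protocols import permeability_at
    k_on = dye.k_on * cell.rate_multiplier
    y = np.zeros(6)  # C_c, B_c, C_n, B_n, Q, influx
    out = np.empty((len(times), 6))
    t = 0.0
    idx = 0
    n_steps = int(round(times[-1] / dt))
    for _ in range(n_steps + 1):
        while idx < len(times) and t >= times[idx] - dt / 2:
            out[idx] = y
            idx += 1
        p = permeability_at(perm, t)
        influx = p * (c_ext - y[0])
        bind_c = k_on * y[0] * (cell.site_density_cytosol - y[1]) - dye.k_off * y[1]
        bind_n = k_on * y[2] * (cell.site_density_nucleus - y[3]) - dye.k_off * y[3]
        exch = cell.k_cn * (y[0] - y[2])
        dy = np.array([influx - bind_c - exch, bind_c - k_pb * y[1],
                       exch - bind_n, bind_n - k_pb * y[3],
                       k_pb * (y[1] + y[3]), influx])
        y = y + dt * dy
        t += dt
    return out


class TestBasicBehaviour:
    def test_no_permeabilization_no_signal(self):
        perm = PermeabilizationProtocol(mode="none")
        trace, states = simulate_cell_trace(TOY_DYE, TOY_CELL, perm, None, 2.0,
                                            np.arange(0.0, 301.0, 30.0))
        assert np.all(trace.intensities == 0.0)
        assert np.all(states.total == 0.0)

    def test_zero_concentration_zero_trace(self):
        perm = PermeabilizationProtocol(mode="chemical", P_chem=0.2)
        trace = simulate_well_trace(TOY_DYE, TOY_CELL, perm, 0.0,
                                    times=np.arange(0.0, 601.0, 60.0))
        assert np.all(trace.intensities == 0.0)

    def test_well_trace_requires_chemical_mode(self):
        perm = PermeabilizationProtocol(mode="usmb", P0=0.1)
        with pytest.raises(ArgumentError):
            simulate_well_trace(TOY_DYE, TOY_CELL, perm, 1.0)

    def test_times_must_increase(self):
        perm = PermeabilizationProtocol(mode="none")
        with pytest.raises(ArgumentError):
            simulate_cell_trace(TOY_DYE, TOY_CELL, perm, None, 1.0, [0.0, 10.0, 5.0])

    def test_nonfinite_parameters_rejected(self):
        perm = PermeabilizationProtocol(mode="chemical", P_chem=0.1)
        with pytest.raises(ArgumentError):
            simulate_cell_trace(TOY_DYE, TOY_CELL, perm, None, np.nan,
                                np.arange(0.0, 100.0, 10.0))


class TestConservationAndBounds:
    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(p0=st.floats(0.01, 1.0), tau=st.floats(1.0, 60.0),
           c_ext=st.floats(0.1, 20.0), k_pb=st.floats(0.0, 5e-3))
    def test_mass_conservation_and_nonnegativity(self, p0, tau, c_ext, k_pb):
        """Cumulative influx equals total intracellular dye at every output time."""
        from sonokinetics.protocols import IlluminationProtocol
        perm = PermeabilizationProtocol(mode="usmb", P0=p0, tau_pore=tau)
        illum = IlluminationProtocol(duty_cycle=1.0, k_dark=0.0, k_laser=k_pb)
        _, states = simulate_cell_trace(TOY_DYE, TOY_CELL, perm, illum, c_ext,
                                        np.arange(0.0, 1801.0, 100.0))
        scale = max(states.influx.max(), 1e-30)
        assert np.max(np.abs(states.total - states.influx)) / scale < 1e-8
        for field in (states.C_cyt, states.B_cyt, states.C_nuc, states.B_nuc, states.Q):
            assert np.all(field >= 0.0)

    def test_monotone_intensity_and_site_bound_without_bleaching(self):
        perm = PermeabilizationProtocol(mode="chemical", P_chem=0.1)
        trace, states = simulate_cell_trace(TOY_DYE, TOY_CELL, perm, None, 5.0,
                                            np.arange(0.0, 3601.0, 60.0))
        assert np.all(np.diff(trace.intensities) >= -1e-9 * trace.intensities.max())
        bound = states.B_cyt + states.B_nuc
        assert np.all(bound <= TOY_CELL.site_density_cytosol
                      + TOY_CELL.site_density_nucleus + 1e-12)

    def test_binding_isotherm_equilibrium(self):
        """Chemical mode converges to the closed-form binding steady state."""
        c_ext = 2.0
        preset = condition_preset("chem_fadu", c_ext)
        times = np.arange(0.0, 200001.0, 5000.0)
        _, states = simulate_cell_trace(preset.dye, preset.cell, preset.perm,
                                        None, c_ext, times)
        s_n = preset.cell.site_density_nucleus
        b_eq = s_n * preset.dye.k_on * c_ext / (preset.dye.k_on * c_ext + preset.dye.k_off)
        assert states.B_nuc[-1] == pytest.approx(b_eq, rel=1e-4)


class TestOracleAgreement:
    def test_lsoda_matches_fine_step_euler(self):
        """Adaptive integration agrees with a brute-force explicit-Euler run."""
        dye = DyeParams(name="slow", k_on=5e-3, k_off=2e-3, brightness_free=1.0,
                        brightness_bound=600.0)
        cell = CellLineParams(name="slow", site_density_cytosol=0.5,
                              site_density_nucleus=2.0, k_cn=0.01)
        perm = PermeabilizationProtocol(mode="chemical", P_chem=0.02)
        times = np.arange(0.0, 61.0, 10.0)
        _, states = simulate_cell_trace(dye, cell, perm, None, 2.0, times)
        ref = euler_oracle(dye, cell, perm, 2.0, times)
        sim = np.stack([states.C_cyt, states.B_cyt, states.C_nuc,
                        states.B_nuc, states.Q, states.influx])
        for got, want in zip(sim, ref.T):
            scale = max(np.max(np.abs(want)), 1e-12)
            assert np.max(np.abs(got - want)) / scale < 1e-4


class TestPresetKinetics:
    def test_fitted_rate_increases_with_concentration(self):
        """Doubling C_ext in the linear range speeds up the fitted rise."""
        rates = []
        for c_ext in (1.0, 2.0, 4.0, 8.0):
            trace, _ = simulate_condition("usmb_fadu", c_ext)
            rates.append(fit_trace(trace, "2cm").k_f)
        assert np.all(np.diff(rates) > 0)

    def test_cytosol_plateau_and_nuclear_rise(self):
        """Fast cytosolic plateau, sustained nuclear accumulation (single cell)."""
        c_ext = 2.0
        times = np.arange(1.0, 541.0, 1.0)
        preset = condition_preset("usmb_fadu", c_ext)
        _, states = simulate_condition("usmb_fadu", c_ext, times=times)
        cyt = states.cytosol_intensity(preset.dye, c_ext)
        nuc = states.nucleus_intensity(preset.dye, c_ext)
        i30 = cyt[np.searchsorted(times, 30.0)]
        assert i30 >= 0.95 * cyt.max()
        assert nuc[-1] > nuc[np.searchsorted(times, 520.0)]  # still rising at 540 s
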
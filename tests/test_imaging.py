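"""Synthetic imaging: rendering, ground truth, noise, drift, spatial model."""

import numpy as np
import pytest

from sonokinetics.errors import ArgumentError, SceneError
from sonokinetics.imaging import (SceneConfig, apply_drift, apply_noise,
                                  default_spatial_cell, generate_population_stack,
                                  generate_single_cell_stack)
from sonokinetics.presets import condition_preset
from sonokinetics.protocols import PermeabilizationProtocol


class TestPopulationStack:
    def test_empty_scene_is_background_only(self):
        config = SceneConfig(n_cells=0, background=1.5)
        stack, truth = generate_population_stack(config, seed=0)
        assert np.all(stack.frames == 1.5)
        assert truth.cells == []

    def test_fcfm_preset_pixel_grid(self):
        config = SceneConfig(n_cells=0)
        stack, _ = generate_population_stack(config, seed=0)
        assert stack.shape == (424, 424)  # 593 µm / 1.4 µm per px, rounded
        assert stack.fov_um[0] == pytest.approx(593.0, abs=1.0)

    def test_default_timing_61_frames_30s_interval(self):
        config = SceneConfig(n_cells=0)
        stack, _ = generate_population_stack(config, seed=0)
        assert stack.n_frames == 61
        assert np.allclose(np.diff(stack.timestamps), 30.0)

    def test_roi_mean_equals_generating_trace(self, small_scene):
        """Noiseless rendering identity: mask mean reproduces the clean trace."""
        stack, truth = small_scene
        cell = truth.cells[0]
        roi = stack.frames[:, cell.mask].mean(axis=1)
        assert np.max(np.abs(roi - cell.trace.intensities)) < 1e-9

    def test_ground_truth_reconstructs_stack_and_rendering_is_linear(self, small_scene):
        """The sidecar suffices to re-render the clean frames; rendering is linear."""
        stack, truth = small_scene
        rebuilt = np.full_like(stack.frames, truth.background)
        for cell in truth.cells:
            rebuilt[:, cell.mask] = cell.trace.intensities[:, None]
        assert np.array_equal(rebuilt, stack.frames)
        doubled = np.full_like(stack.frames, truth.background)
        for cell in truth.cells:
            doubled[:, cell.mask] = 2.0 * cell.trace.intensities[:, None]
        assert np.allclose(doubled - truth.background,
                           2.0 * (stack.frames - truth.background))

    def test_masks_disjoint_and_ids_unique(self, small_scene):
        _, truth = small_scene
        total = np.zeros_like(truth.cells[0].mask, dtype=int)
        for cell in truth.cells:
            total += cell.mask
        assert total.max() == 1
        ids = [c.cell_id for c in truth.cells]
        assert len(set(ids)) == len(ids)

    def test_infeasible_packing_raises(self):
        config = SceneConfig(n_cells=100, fov_um=80.0, max_placement_tries=20)
        with pytest.raises(SceneError):
            generate_population_stack(config, seed=0)


class TestNoise:
    def test_infinite_snr_is_identity(self, small_scene):
        stack, _ = small_scene
        out = apply_noise(stack, np.inf, seed=3)
        assert np.array_equal(out.frames, stack.frames)

    def test_fixed_seed_is_deterministic(self, small_scene):
        stack, _ = small_scene
        a = apply_noise(stack, 20.0, seed=5, read_noise=0.5)
        b = apply_noise(stack, 20.0, seed=5, read_noise=0.5)
        assert np.array_equal(a.frames, b.frames)

    def test_noise_is_unbiased_on_bright_pixel(self, small_scene):
        """Law of large numbers: the noisy mean approaches the clean value."""
        stack, truth = small_scene
        rows, cols = np.nonzero(truth.cells[0].mask)
        r, c = rows[0], cols[0]
        clean = stack.frames[-1, r, c]
        values = [apply_noise(stack, 10.0, seed=s).frames[-1, r, c] for s in range(1000)]
        assert np.mean(values) == pytest.approx(clean, rel=0.01)

    def test_nonpositive_snr_rejected(self, small_scene):
        stack, _ = small_scene
        with pytest.raises(ArgumentError):
            apply_noise(stack, 0.0)


class TestDrift:
    def test_zero_velocity_is_identity(self, small_scene):
        stack, _ = small_scene
        out, _ = apply_drift(stack, 0.0)
        assert np.array_equal(out.frames, stack.frames)

    def test_total_shift_arithmetic(self, small_scene):
        stack, _ = small_scene
        out, _ = apply_drift(stack, 0.1)  # 0.1 µm/s x 1800 s at 1.4 µm/px
        dr, dc = out.metadata["drift_offsets_px"][-1]
        assert (dr, dc) == (0, 128)

    def test_truth_masks_follow_the_image(self, small_scene):
        stack, truth = small_scene
        out, truth_d = apply_drift(stack, (0.05, 0.08), truth)
        cell = truth_d.cells[0]
        final_value = cell.trace.intensities[-1]
        rendered = np.isclose(out.frames[-1], final_value)
        overlap = (rendered & cell.mask).sum()
        union = (rendered & cell.mask).sum() + (~rendered & cell.mask).sum()
        assert overlap / max(union, 1) > 0.99

    def test_drift_beyond_fov_rejected(self, small_scene):
        stack, _ = small_scene
        with pytest.raises(ArgumentError):
            apply_drift(stack, 1.0)  # 1 µm/s x 1800 s > 593 µm


class TestSingleCellSpatial:
    def test_zero_permeability_gives_zero_field(self):
        spatial = default_spatial_cell()
        dye = condition_preset("usmb_fadu", 2.0).dye
        perm = PermeabilizationProtocol(mode="none")
        stack, diag = generate_single_cell_stack(spatial, dye, perm, c_ext=2.0,
                                                 duration=20.0)
        assert np.all(stack.frames == 0.0)
        assert diag["influx_total_per_px"] == 0.0

    def test_pore_local_entry_asymmetry(self):
        """Early frames are brighter next to the pore than diametrically opposite."""
        spatial = default_spatial_cell()
        preset = condition_preset("usmb_fadu", 2.0)
        stack, _ = generate_single_cell_stack(spatial, preset.dye, preset.perm,
                                              c_ext=2.0, duration=10.0)
        r, c = spatial.pore_rc
        far_c = int(np.min(np.nonzero(spatial.cell_mask[r])[0]))
        near = stack.frames[-1][r, c - 3]
        far = stack.frames[-1][r, far_c + 3]
        assert near > far

    def test_conservation_and_compartment_pattern(self):
        """Closed-boundary conservation; cytosol plateau, nuclear accumulation."""
        spatial = default_spatial_cell()
        preset = condition_preset("usmb_fadu", 2.0)
        stack, diag = generate_single_cell_stack(spatial, preset.dye, preset.perm,
                                                 c_ext=2.0)
        rel = abs(diag["total_dye_per_px"] - diag["influx_total_per_px"])
        rel /= max(diag["influx_total_per_px"], 1e-30)
        assert rel < 1e-6

        cyt = spatial.cell_mask & ~spatial.nucleus_mask
        nuc = spatial.nucleus_mask
        cyt_trace = stack.frames[:, cyt].mean(axis=1)
        nuc_trace = stack.frames[:, nuc].mean(axis=1)
        t = stack.timestamps
        assert cyt_trace[np.searchsorted(t, 30.0)] >= 0.95 * cyt_trace.max()
        assert np.all(np.diff(nuc_trace) >= -1e-9 * nuc_trace.max())
        assert nuc_trace[-1] > nuc_trace[np.searchsorted(t, 520.0)]
        assert nuc_trace[-1] > cyt_trace[-1]

    def test_pore_must_be_on_cell_boundary_outside_nucleus(self):
        spatial = default_spatial_cell()
        with pytest.raises(ArgumentError):
            default_spatial_cell().__class__(
                cell_mask=spatial.cell_mask, nucleus_mask=spatial.nucleus_mask,
                pore_rc=(0, 0))
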
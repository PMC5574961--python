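"""Synthetic time-lapse fluorescence stacks with ground truth.

Two acquisition modes are emulated:

* population FCFM — a 593 x 593 µm field of view sampled every 30 s for
  30 min. The probe does not resolve subcellular compartments, so each cell
  is rendered as an elliptical region carrying its whole-cell mean
  intensity from the mechanistic kinetics (with lognormal cell-to-cell rate
  variability);
* single-cell swept-field — a 9-min, 1-s-interval recording of one cell as
  a 2-D reaction-diffusion simulation: dye enters locally at the membrane
  pore, diffuses through the cytosol, crosses a reduced-permeability
  nuclear envelope, and binds nucleic-acid sites (nucleus >> cytosol).

Noise is multiplicative Gaussian (sigma = signal / SNR) plus additive read
noise; focal drift is surrogated by an accumulating integer-pixel lateral
translation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from .dyes import DyeParams
from .errors import ArgumentError, SceneError
from .model import DEFAULT_FCFM_TIMES, UptakeTrace
from .presets import apparent_rate_preset, simulate_condition
from .protocols import IlluminationProtocol, PermeabilizationProtocol, permeability_at

__all__ = [
    "ImageStack", "CellTruth", "SceneGroundTruth", "SceneConfig",
    "SpatialCellModel", "default_spatial_cell", "generate_population_stack",
    "generate_single_cell_stack", "apply_noise", "apply_drift",
    "FCFM_FOV_UM", "FCFM_PIXEL_UM",
]

FCFM_FOV_UM = 593.0
FCFM_PIXEL_UM = 1.4


@dataclass
class ImageStack:
    """Time-lapse frame stack with physical calibration and metadata."""

    frames: np.ndarray            # (T, H, W), a.u., >= 0
    pixel_size: float             # µm per pixel
    timestamps: np.ndarray        # s, strictly increasing
    illumination: IlluminationProtocol | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ArgumentError("frames must be a (T, H, W) array")
        if self.timestamps.shape != (self.frames.shape[0],):
            raise ArgumentError("one timestamp per frame required")
        if self.timestamps.size > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ArgumentError("timestamps must be strictly increasing")
        if self.pixel_size <= 0:
            raise ArgumentError("pixel_size must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def fov_um(self) -> tuple[float, float]:
        return (self.shape[0] * self.pixel_size, self.shape[1] * self.pixel_size)


@dataclass
class CellTruth:
    """Ground truth for one rendered cell."""

    cell_id: int
    center_um: tuple[float, float]        # (row, col) µm from top-left
    mask: np.ndarray                      # boolean (H, W), whole cell
    nucleus_mask: np.ndarray              # boolean (H, W)
    rate_multiplier: float
    k_f_true: float                       # per s, generating apparent rate
    trace: UptakeTrace                    # clean whole-cell intensity


@dataclass
class SceneGroundTruth:
    """Per-cell ground truth of a synthetic scene."""

    cells: list[CellTruth]
    background: float

    def trace_of(self, cell_id: int) -> UptakeTrace:
        for cell in self.cells:
            if cell.cell_id == cell_id:
                return cell.trace
        raise ArgumentError(f"no ground-truth cell {cell_id}")


@dataclass(frozen=True)
class SceneConfig:
    """Geometry of a synthetic FCFM population scene."""

    n_cells: int
    fov_um: float = FCFM_FOV_UM
    pixel_size: float = FCFM_PIXEL_UM
    cell_axis_um: tuple[float, float] = (15.0, 25.0)  # semi-axis range x2 -> 15-25 µm axes
    nucleus_area_fraction: float = 0.4
    background: float = 0.0
    log_sd: float = 0.5          # lognormal sd of per-cell rate multipliers
    min_gap_px: int = 2          # keeps neighbouring cells resolvable
    max_placement_tries: int = 200

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ArgumentError("n_cells must be >= 0")
        if not 0 < self.nucleus_area_fraction < 1:
            raise ArgumentError("nucleus_area_fraction must lie in (0, 1)")


def _frame_shape(config: SceneConfig) -> tuple[int, int]:
    n = int(round(config.fov_um / config.pixel_size))
    return (n, n)


def _place_cells(config: SceneConfig, rng: np.random.Generator):
    """Rejection-sample non-overlapping ellipses; raises SceneError if packing fails."""
    shape = _frame_shape(config)
    occupied = np.zeros(shape, dtype=bool)
    lo, hi = config.cell_axis_um
    placements = []
    for i in range(config.n_cells):
        for _try in range(config.max_placement_tries):
            a_um = rng.uniform(lo, hi) / 2.0   # semi-axes in µm (axes 15-25 µm)
            b_um = rng.uniform(lo, hi) / 2.0
            a = a_um / config.pixel_size
            b = b_um / config.pixel_size
            gap = config.min_gap_px
            margin = max(a, b) + gap + 1
            r = rng.uniform(margin, shape[0] - margin)
            c = rng.uniform(margin, shape[1] - margin)
            theta = rng.uniform(0, math.pi)
            # test with a gap-dilated footprint so neighbours stay separable
            rr_t, cc_t = draw_ellipse(r, c, a + gap, b + gap, shape=shape, rotation=theta)
            if not occupied[rr_t, cc_t].any():
                occupied[rr_t, cc_t] = True
                placements.append((r, c, a, b, theta))
                break
        else:
            raise SceneError(
                f"could not place cell {i + 1}/{config.n_cells} after "
                f"{config.max_placement_tries} tries; reduce density")
    return placements, shape


def generate_population_stack(
    config: SceneConfig,
    condition: str = "usmb_fadu",
    c_ext: float = 2.0,
    seed: int | np.random.Generator = 0,
    timestamps: Sequence[float] | None = None,
    kinetics_rng: np.random.Generator | None = None,
) -> tuple[ImageStack, SceneGroundTruth]:
    """Render a population FCFM stack plus its ground-truth sidecar.

    ``kinetics_rng`` lets callers decouple the cell-to-cell kinetic
    variability stream from the geometric placement stream (e.g. to pair
    conditions with common random numbers).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    krng = kinetics_rng if kinetics_rng is not None else rng
    times = np.asarray(DEFAULT_FCFM_TIMES if timestamps is None else timestamps, dtype=float)

    placements, shape = _place_cells(config, rng)
    multipliers = np.exp(krng.normal(0.0, config.log_sd, size=config.n_cells))

    frames = np.full((times.size, *shape), config.background, dtype=float)
    cells: list[CellTruth] = []
    for i, (r, c, a, b, theta) in enumerate(placements):
        trace, _ = simulate_condition(condition, c_ext, times=times,
                                      rate_multiplier=multipliers[i],
                                      cell_id=f"cell_{i}")
        mask = np.zeros(shape, dtype=bool)
        rr, cc = draw_ellipse(r, c, a, b, shape=shape, rotation=theta)
        mask[rr, cc] = True
        nuc = np.zeros(shape, dtype=bool)
        s = math.sqrt(config.nucleus_area_fraction)
        rr_n, cc_n = draw_ellipse(r, c, a * s, b * s, shape=shape, rotation=theta)
        nuc[rr_n, cc_n] = True
        frames[:, mask] = trace.intensities[:, None]
        cells.append(CellTruth(
            cell_id=i,
            center_um=(r * config.pixel_size, c * config.pixel_size),
            mask=mask, nucleus_mask=nuc,
            rate_multiplier=float(multipliers[i]),
            k_f_true=apparent_rate_preset(condition, c_ext) * float(multipliers[i]),
            trace=trace))

    stack = ImageStack(frames=frames, pixel_size=config.pixel_size, timestamps=times,
                       metadata={"condition": condition, "concentration_uM": c_ext,
                                 "background": config.background, "mode": "fcfm"})
    return stack, SceneGroundTruth(cells=cells, background=config.background)


# ---------------------------------------------------------------------------
# Single-cell reaction-diffusion model

@dataclass
class SpatialCellModel:
    """Spatially resolved single cell on a pixel grid.

    The nuclear envelope is modelled as a diffusion barrier: edges crossing
    the cytosol/nucleus boundary carry ``envelope_factor`` of the cytosolic
    diffusivity, which is what makes nuclear accumulation slow (minutes)
    while the cytosol equilibrates in seconds.
    """

    cell_mask: np.ndarray        # boolean (H, W)
    nucleus_mask: np.ndarray     # boolean (H, W), strictly inside cell
    pore_rc: tuple[int, int]     # boundary pixel where dye enters
    pixel_size: float = 1.0      # µm
    D_cyt: float = 40.0          # µm²/s
    envelope_factor: float = 5e-4
    site_density_cytosol: float = 0.05  # µM-equivalent, per pixel
    site_density_nucleus: float = 50.0  # µM-equivalent, per pixel
    k_on: float = 0.5            # per µM per s (fast local intercalation)
    pore_gain: float = 40.0      # converts whole-cell permeability to a pore-pixel rate

    def __post_init__(self) -> None:
        if not self.cell_mask[self.pore_rc]:
            raise ArgumentError("pore must lie on the cell mask")
        if self.nucleus_mask[self.pore_rc]:
            raise ArgumentError("pore must lie outside the nucleus")
        if (self.nucleus_mask & ~self.cell_mask).any():
            raise ArgumentError("nucleus must lie strictly inside the cell")


def default_spatial_cell(shape: tuple[int, int] = (64, 64),
                         pixel_size: float = 1.0) -> SpatialCellModel:
    """Elliptical cell (30 x 22 µm axes) with a concentric 40 %-area nucleus
    and a pore on the +column boundary."""
    h, w = shape
    r0, c0 = h / 2.0, w / 2.0
    a = 11.0 / pixel_size   # semi-axes px
    b = 15.0 / pixel_size
    cell = np.zeros(shape, dtype=bool)
    rr, cc = draw_ellipse(r0, c0, a, b, shape=shape)
    cell[rr, cc] = True
    nuc = np.zeros(shape, dtype=bool)
    s = math.sqrt(0.4)
    rr, cc = draw_ellipse(r0, c0, a * s, b * s, shape=shape)
    nuc[rr, cc] = True
    row = int(round(r0))
    pore_col = int(np.max(np.nonzero(cell[row])[0]))
    return SpatialCellModel(cell_mask=cell, nucleus_mask=nuc,
                            pore_rc=(row, pore_col), pixel_size=pixel_size)


def generate_single_cell_stack(
    spatial: SpatialCellModel,
    dye: DyeParams,
    perm: PermeabilizationProtocol,
    c_ext: float = 2.0,
    duration: float = 540.0,
    frame_interval: float = 1.0,
    seed: int = 0,
) -> tuple[ImageStack, dict]:
    """Explicit reaction-diffusion simulation of pore-local dye entry.

    Returns the intensity stack and a diagnostics dict with the free/bound
    fields at the final time, cumulative pore influx, and the sub-stepped
    time step actually used (the step is chosen below the diffusion CFL
    limit and kept stable against the influx and binding rates).
    """
    mask = spatial.cell_mask
    h2 = spatial.pixel_size ** 2
    d = spatial.D_cyt

    # symmetric edge weights (flux form conserves mass exactly); nuclear
    # envelope edges are attenuated
    def edge_weights(axis: int) -> np.ndarray:
        inside = mask & np.roll(mask, -1, axis=axis)
        crossing = spatial.nucleus_mask != np.roll(spatial.nucleus_mask, -1, axis=axis)
        w = inside * np.where(crossing, spatial.envelope_factor, 1.0)
        # forbid wrap-around edges
        if axis == 0:
            w[-1, :] = 0.0
        else:
            w[:, -1] = 0.0
        return w * d / h2

    w0 = edge_weights(0)
    w1 = edge_weights(1)

    sites = np.where(spatial.nucleus_mask, spatial.site_density_nucleus,
                     np.where(mask, spatial.site_density_cytosol, 0.0))

    n_frames = int(round(duration / frame_interval)) + 1
    times = np.arange(n_frames) * frame_interval
    kappa0 = perm.P0 * spatial.pore_gain if perm.mode == "usmb" else (
        perm.P_chem * spatial.pore_gain if perm.mode == "chemical" else 0.0)

    # stability: diffusion CFL, influx relaxation and binding
    dt_max = 0.8 / max(4.0 * d / h2, kappa0, spatial.k_on * max(c_ext, 1e-12), 1e-9)
    n_sub = max(int(math.ceil(frame_interval / dt_max)), 1)
    dt = frame_interval / n_sub

    conc = np.zeros(mask.shape)
    bound = np.zeros(mask.shape)
    influx_total = 0.0
    qf = dye.quench_factor(c_ext)
    frames = np.empty((n_frames, *mask.shape))
    frames[0] = 0.0
    pore = spatial.pore_rc

    t = 0.0
    for f in range(1, n_frames):
        for _ in range(n_sub):
            lap = np.zeros_like(conc)
            d0 = w0 * (np.roll(conc, -1, axis=0) - conc)
            lap += d0
            lap -= np.roll(d0, 1, axis=0)
            d1 = w1 * (np.roll(conc, -1, axis=1) - conc)
            lap += d1
            lap -= np.roll(d1, 1, axis=1)

            kappa = float(permeability_at(perm, t)) * spatial.pore_gain
            j = kappa * (c_ext - conc[pore])
            react = spatial.k_on * conc * (sites - bound) - dye.k_off * bound

            conc += dt * (lap - react)
            conc[pore] += dt * j
            bound += dt * react
            influx_total += dt * j
            t += dt
        frames[f] = (dye.brightness_free * conc
                     + dye.brightness_bound * bound * qf)

    diag = {
        "free": conc, "bound": bound,
        "influx_total_per_px": influx_total,
        "total_dye_per_px": float((conc + bound).sum()),
        "dt": dt, "n_sub": n_sub,
    }
    stack = ImageStack(frames=frames, pixel_size=spatial.pixel_size, timestamps=times,
                       metadata={"mode": "swept_field", "concentration_uM": c_ext})
    return stack, diag


# ---------------------------------------------------------------------------
# Degradations

def apply_noise(stack: ImageStack, snr: float, seed: int = 0,
                read_noise: float = 0.0) -> ImageStack:
    """Multiplicative Gaussian noise (sigma = signal/snr) plus read noise.

    Clipped at zero; deterministic under a fixed seed. ``snr = inf`` with
    zero read noise is the identity.
    """
    if not snr > 0:
        raise ArgumentError("snr must be > 0")
    rng = np.random.default_rng(seed)
    frames = stack.frames.astype(float)
    if math.isfinite(snr):
        frames = frames * (1.0 + rng.standard_normal(frames.shape) / snr)
    if read_noise > 0:
        frames = frames + read_noise * rng.standard_normal(frames.shape)
    frames = np.clip(frames, 0.0, None)
    return ImageStack(frames=frames, pixel_size=stack.pixel_size,
                      timestamps=stack.timestamps.copy(),
                      illumination=stack.illumination,
                      metadata={**stack.metadata, "snr": snr, "read_noise": read_noise})


def _drift_offset_px(velocity: tuple[float, float], t: float, pixel_size: float) -> tuple[int, int]:
    return (int(velocity[0] * t / pixel_size), int(velocity[1] * t / pixel_size))


def apply_drift(stack: ImageStack, velocity: float | tuple[float, float],
                truth: SceneGroundTruth | None = None,
                fill: float | None = None) -> tuple[ImageStack, SceneGroundTruth | None]:
    """Accumulating integer-pixel lateral translation (focal-drift surrogate).

    ``velocity`` is µm/s, either scalar (column direction) or (row, col).
    Ground-truth masks and centers, when supplied, are shifted consistently.
    """
    v = (0.0, float(velocity)) if np.isscalar(velocity) else (float(velocity[0]), float(velocity[1]))
    duration = stack.timestamps[-1] - stack.timestamps[0]
    for vi, extent in zip(v, stack.fov_um):
        if abs(vi) * duration >= extent:
            raise ArgumentError("drift exceeds the field of view")
    if fill is None:
        fill = float(stack.metadata.get("background", 0.0))

    t0 = stack.timestamps[0]
    frames = np.full_like(stack.frames, fill, dtype=float)
    offsets = [_drift_offset_px(v, t - t0, stack.pixel_size) for t in stack.timestamps]
    h, w = stack.shape
    for i, (dr, dc) in enumerate(offsets):
        src = stack.frames[i]
        r_src = slice(max(0, -dr), min(h, h - dr))
        c_src = slice(max(0, -dc), min(w, w - dc))
        r_dst = slice(max(0, dr), min(h, h + dr))
        c_dst = slice(max(0, dc), min(w, w + dc))
        frames[i][r_dst, c_dst] = src[r_src, c_src]

    out = ImageStack(frames=frames, pixel_size=stack.pixel_size,
                     timestamps=stack.timestamps.copy(), illumination=stack.illumination,
                     metadata={**stack.metadata, "drift_um_per_s": v,
                               "drift_offsets_px": offsets})
    if truth is None:
        return out, None

    # ground truth after drift: per-frame shifted centers; masks are reported
    # at the final frame's position so late-frame segmentation can be scored
    dr_f, dc_f = offsets[-1]
    cells = []
    for cell in truth.cells:
        mask = np.full_like(cell.mask, False)
        nuc = np.full_like(cell.nucleus_mask, False)
        r_src = slice(max(0, -dr_f), min(h, h - dr_f))
        c_src = slice(max(0, -dc_f), min(w, w - dc_f))
        r_dst = slice(max(0, dr_f), min(h, h + dr_f))
        c_dst = slice(max(0, dc_f), min(w, w + dc_f))
        mask[r_dst, c_dst] = cell.mask[r_src, c_src]
        nuc[r_dst, c_dst] = cell.nucleus_mask[r_src, c_src]
        cells.append(replace(cell,
                             center_um=(cell.center_um[0] + dr_f * stack.pixel_size,
                                        cell.center_um[1] + dc_f * stack.pixel_size),
                             mask=mask, nucleus_mask=nuc))
    return out, SceneGroundTruth(cells=cells, background=truth.background)
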
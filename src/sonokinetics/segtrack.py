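"""Cell segmentation, frame-to-frame tracking, and trace extraction.

Cells stained by an intercalating dye are invisible before uptake, so
detection quality improves over the movie. The tracker therefore links
whatever is detectable per frame (greedy nearest-centroid with a gating
distance) and back-propagates each track's earliest mask to the frames
before its first detection, translating it by the globally estimated drift,
so that extracted traces cover the full acquisition including the dim
pre-uptake frames that carry the early rise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import disk, opening

from .errors import ArgumentError, DegenerateDataError
from .imaging import ImageStack, SceneGroundTruth
from .model import UptakeTrace

__all__ = [
    "Detection", "CellTrack", "segment_frame", "track", "extract_traces",
    "track_stack", "match_to_ground_truth",
]


@dataclass
class Detection:
    """One segmented component in one frame."""

    label: int
    centroid_px: tuple[float, float]
    pixels: tuple[np.ndarray, np.ndarray]  # (rows, cols)
    touches_border: bool


@dataclass
class CellTrack:
    """One cell followed across frames.

    ``frames`` are stack frame indices; per frame the track stores a
    centroid (µm) and the pixel set of its mask. Back-filled frames (mask
    propagated before the first detection) are listed in ``backfilled``.
    """

    track_id: int
    frames: list[int] = field(default_factory=list)
    centroids_um: list[tuple[float, float]] = field(default_factory=list)
    masks: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    touches_border: bool = False
    backfilled: list[int] = field(default_factory=list)

    @property
    def first_frame(self) -> int:
        return self.frames[0]

    @property
    def last_frame(self) -> int:
        return self.frames[-1]

    def centroid_at(self, frame: int) -> tuple[float, float]:
        return self.centroids_um[self.frames.index(frame)]


def segment_frame(frame: np.ndarray, pixel_size: float,
                  min_area_um2: float = 50.0,
                  threshold: str = "otsu",
                  fixed_value: float | None = None) -> list[Detection]:
    """Segment bright cells in one frame.

    Median background subtraction, global threshold (``"otsu"`` or
    ``"fixed"``), morphological opening (radius 1 px), connected components
    and an area filter. An all-background frame yields no detections.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ArgumentError("empty frame")
    sub = frame - np.median(frame)
    np.clip(sub, 0.0, None, out=sub)
    if threshold == "otsu":
        positive = sub[sub > 0]
        if positive.size < 2 or np.ptp(sub) == 0:
            return []
        thr = threshold_otsu(sub)
    elif threshold == "fixed":
        if fixed_value is None:
            raise ArgumentError("fixed threshold requires fixed_value")
        thr = fixed_value
    else:
        raise ArgumentError(f"unknown threshold mode {threshold!r}")

    binary = opening(sub > thr, disk(1))
    labels = cc_label(binary)
    min_px = min_area_um2 / pixel_size**2
    detections = []
    h, w = frame.shape
    for prop in regionprops(labels):
        if prop.area < min_px:
            continue
        rows, cols = np.nonzero(labels == prop.label)
        border = bool(rows.min() == 0 or cols.min() == 0
                      or rows.max() == h - 1 or cols.max() == w - 1)
        detections.append(Detection(label=prop.label, centroid_px=tuple(prop.centroid),
                                    pixels=(rows, cols), touches_border=border))
    return detections


def _greedy_match(prev: list[tuple[float, float]], curr: list[tuple[float, float]],
                  gate: float) -> list[tuple[int, int]]:
    """Greedy nearest-pair assignment under a gating distance."""
    if not prev or not curr:
        return []
    p = np.asarray(prev)
    c = np.asarray(curr)
    dist = np.linalg.norm(p[:, None, :] - c[None, :, :], axis=2)
    pairs = []
    used_p: set[int] = set()
    used_c: set[int] = set()
    order = np.dstack(np.unravel_index(np.argsort(dist, axis=None), dist.shape))[0]
    for i, j in order:
        if dist[i, j] > gate:
            break
        if i in used_p or j in used_c:
            continue
        used_p.add(int(i))
        used_c.add(int(j))
        pairs.append((int(i), int(j)))
    return pairs


def track(detections_per_frame: list[list[Detection]], pixel_size: float,
          max_step_um: float = 10.0, min_length: int = 10,
          backfill: bool = True,
          frame_shape: tuple[int, int] | None = None) -> list[CellTrack]:
    """Link detections into tracks by greedy nearest-centroid matching.

    Unmatched detections start new tracks; matches beyond the gate are not
    made (so two cells swapping positions terminate rather than swap).
    Tracks with fewer than ``min_length`` detections are dropped. With
    ``backfill`` the earliest mask of each track is propagated to all
    earlier frames, translated by the cumulative global drift estimated
    from matched centroid displacements.
    """
    n_frames = len(detections_per_frame)
    if n_frames < 2:
        raise ArgumentError("tracking requires at least 2 frames")

    tracks: list[CellTrack] = []
    active: dict[int, CellTrack] = {}  # detection index in current frame -> track
    next_id = 0
    drift_per_frame = np.zeros((n_frames, 2))

    for f, dets in enumerate(detections_per_frame):
        cents = [d.centroid_px for d in dets]
        if f == 0:
            pairs = []
        else:
            prev_cents = [active_track.centroids_um[-1] for active_track in prev_tracks]
            prev_cents_px = [(r / pixel_size, c / pixel_size) for r, c in prev_cents]
            pairs = _greedy_match(prev_cents_px, cents, max_step_um / pixel_size)
            if pairs:
                deltas = [np.subtract(cents[j], prev_cents_px[i]) for i, j in pairs]
                drift_per_frame[f] = np.median(deltas, axis=0)

        matched_curr = {}
        for i, j in pairs:
            matched_curr[j] = prev_tracks[i]
        new_active: list[CellTrack] = []
        seen: list[CellTrack] = []
        for j, det in enumerate(dets):
            tr = matched_curr.get(j)
            if tr is None:
                tr = CellTrack(track_id=next_id)
                next_id += 1
                tracks.append(tr)
            tr.frames.append(f)
            tr.centroids_um.append((det.centroid_px[0] * pixel_size,
                                    det.centroid_px[1] * pixel_size))
            tr.masks.append(det.pixels)
            tr.touches_border = tr.touches_border or det.touches_border
            seen.append(tr)
        prev_tracks = seen

    tracks = [t for t in tracks if len(t.frames) >= min_length]

    if backfill:
        cum_drift = np.cumsum(drift_per_frame, axis=0)  # px
        for tr in tracks:
            f0 = tr.first_frame
            if f0 == 0:
                continue
            rows0, cols0 = tr.masks[0]
            r0, c0 = tr.centroids_um[0]
            pre_frames, pre_cents, pre_masks = [], [], []
            for f in range(f0):
                d = cum_drift[f] - cum_drift[f0]  # px offset relative to first detection
                dr, dc = int(round(d[0])), int(round(d[1]))
                rows = rows0 + dr
                cols = cols0 + dc
                if frame_shape is not None:
                    keep = ((rows >= 0) & (rows < frame_shape[0])
                            & (cols >= 0) & (cols < frame_shape[1]))
                    rows, cols = rows[keep], cols[keep]
                pre_frames.append(f)
                pre_cents.append((r0 + dr * pixel_size, c0 + dc * pixel_size))
                pre_masks.append((rows, cols))
            tr.frames = pre_frames + tr.frames
            tr.centroids_um = pre_cents + tr.centroids_um
            tr.masks = pre_masks + tr.masks
            tr.backfilled = pre_frames
    return tracks


def extract_traces(stack: ImageStack, tracks: list[CellTrack]) -> list[UptakeTrace]:
    """Per-track mean-intensity traces over the tracked masks.

    Frames with an empty mask are linearly interpolated from neighbours and
    flagged in the trace's condition record; traces are NaN-free.
    """
    traces = []
    for tr in tracks:
        frames = np.asarray(tr.frames)
        values = np.full(frames.size, np.nan)
        for i, (rows, cols) in enumerate(tr.masks):
            if rows.size:
                values[i] = stack.frames[tr.frames[i]][rows, cols].mean()
        flagged = np.nonzero(np.isnan(values))[0]
        if flagged.size == values.size:
            raise DegenerateDataError(f"track {tr.track_id} has no non-empty masks")
        if flagged.size:
            ok = ~np.isnan(values)
            values = np.interp(np.arange(values.size), np.nonzero(ok)[0], values[ok])
        traces.append(UptakeTrace(
            times=stack.timestamps[frames], intensities=values,
            cell_id=f"track_{tr.track_id}",
            condition={**stack.metadata, "track_id": tr.track_id,
                       "touches_border": tr.touches_border,
                       "interpolated_frames": [int(frames[i]) for i in flagged]}))
    return traces


def track_stack(stack: ImageStack, min_area_um2: float = 50.0,
                threshold: str = "otsu", max_step_um: float = 10.0,
                min_length: int = 10,
                exclude_border: bool = True) -> tuple[list[CellTrack], list[UptakeTrace]]:
    """Segment every frame, track, back-fill and extract traces."""
    dets = [segment_frame(f, stack.pixel_size, min_area_um2, threshold)
            for f in stack.frames]
    tracks = track(dets, stack.pixel_size, max_step_um=max_step_um,
                   min_length=min_length, frame_shape=stack.shape)
    if exclude_border:
        tracks = [t for t in tracks if not t.touches_border]
    return tracks, extract_traces(stack, tracks)


def match_to_ground_truth(tracks: list[CellTrack], truth: SceneGroundTruth,
                          pixel_size: float, max_dist_um: float = 15.0,
                          frame: int = -1) -> dict[int, int]:
    """Map track_id -> ground-truth cell_id by final-frame centroid proximity."""
    t_cents = []
    t_ids = []
    for tr in tracks:
        t_cents.append(tr.centroids_um[frame])
        t_ids.append(tr.track_id)
    g_cents = [c.center_um for c in truth.cells]
    pairs = _greedy_match(t_cents, g_cents, max_dist_um) if t_cents and g_cents else []
    return {t_ids[i]: truth.cells[j].cell_id for i, j in pairs}
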
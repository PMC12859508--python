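"""Object detection (difference of Gaussians), extent estimation (flood
fill) and memory-based frame-to-frame tracking."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max


class DegenerateExtentError(ValueError):
    """Seed pixel below the flood-fill threshold; object skipped this frame."""


@dataclass
class ImagingConfig:
    """Detection, boundary and tracking parameters for one experiment."""

    min_intensity: float = 0.3  # fraction of frame maximum
    min_size: float = 10.0  # approximate object diameter, px
    max_size: float = 40.0
    fill_threshold: float = 0.5  # fraction of the object's local peak
    smoothing_width: float = 1.0
    track_distance: float = 15.0
    track_memory: int = 10
    boundary_mode: str = "condensate"
    continuity_max_step: float = 3.0

    def __post_init__(self) -> None:
        if not 0 < self.min_size < self.max_size:
            raise ValueError("require 0 < min_size < max_size")
        if not 0 < self.min_intensity <= 1:
            raise ValueError("min_intensity must be in (0, 1]")
        if not 0 < self.fill_threshold <= 1:
            raise ValueError("fill_threshold must be in (0, 1]")
        if self.track_distance <= 0:
            raise ValueError("track_distance must be positive")
        if self.track_memory < 0:
            raise ValueError("track_memory must be non-negative")
        if self.boundary_mode not in ("condensate", "vesicle"):
            raise ValueError("boundary_mode must be 'condensate' or 'vesicle'")

    @property
    def bbox_pad(self) -> int:
        # enough to enclose the diffuse tanh interface plus blur support
        return int(max(5, np.ceil(3 * self.smoothing_width)))


@dataclass
class Detection:
    """One object in one frame: center, extent mask and bounding box."""

    frame_index: int
    center: tuple[float, float]  # (x, y), 0-based pixel coordinates
    extent_mask: np.ndarray  # bool, cropped to bbox
    bbox: tuple[int, int, int, int]  # (x0, y0, x1, y1), half-open

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.bbox
        cx, cy = self.center
        if not (x0 <= cx < x1 and y0 <= cy < y1):
            raise ValueError("center must lie inside bbox")
        if self.extent_mask.shape != (y1 - y0, x1 - x0):
            raise ValueError("extent_mask must match bbox shape")


def detect_centers(frame: np.ndarray, config: ImagingConfig) -> list[tuple[float, float]]:
    """DoG blob centers, brightest response first.

    The band-pass is the difference of Gaussian blurs with sd min_size/(2*sqrt(2))
    and max_size/(2*sqrt(2)); maxima are kept when the *original* pixel
    intensity is at least min_intensity times the frame maximum.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("frame must be a single-channel 2-D image")
    peak = img.max()
    if peak <= 0:
        return []
    s1 = config.min_size / (2.0 * np.sqrt(2.0))
    s2 = config.max_size / (2.0 * np.sqrt(2.0))
    dog = ndimage.gaussian_filter(img, s1) - ndimage.gaussian_filter(img, s2)
    coords = peak_local_max(
        dog,
        min_distance=max(1, int(round(config.min_size / 2))),
        threshold_abs=1e-9,
        exclude_border=False,
    )
    centers = []
    for row, col in coords:  # returned in descending DoG response order
        if img[row, col] >= config.min_intensity * peak:
            centers.append((float(col), float(row)))
    return centers


def estimate_extent(
    frame: np.ndarray, center: tuple[float, float], config: ImagingConfig, frame_index: int = 0
) -> Detection:
    """4-connected flood fill above fill_threshold times the local peak.

    The threshold is relative to the object's own peak (a 5x5 window around
    the center), not the frame maximum, so background variations between
    cells do not change the extent.
    """
    img = np.asarray(frame, dtype=float)
    cx, cy = center
    row, col = int(round(cy)), int(round(cx))
    ny, nx = img.shape
    if not (0 <= row < ny and 0 <= col < nx):
        raise DegenerateExtentError("center outside the frame")
    window = img[max(0, row - 2) : row + 3, max(0, col - 2) : col + 3]
    threshold = config.fill_threshold * window.max()
    if img[row, col] < threshold:
        raise DegenerateExtentError("seed intensity below flood-fill threshold")
    above = img >= threshold
    labels, _ = ndimage.label(above, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    mask = labels == labels[row, col]
    if mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any():
        # a background seed floods the whole dark region; a genuine object
        # must be enclosed by the frame for its boundary to be traceable
        raise DegenerateExtentError("flood-filled extent reaches the frame border")
    rows = np.any(mask, axis=1).nonzero()[0]
    cols = np.any(mask, axis=0).nonzero()[0]
    pad = config.bbox_pad
    x0 = max(0, int(cols[0]) - pad)
    x1 = min(nx, int(cols[-1]) + 1 + pad)
    y0 = max(0, int(rows[0]) - pad)
    y1 = min(ny, int(rows[-1]) + 1 + pad)
    return Detection(frame_index, (cx, cy), mask[y0:y1, x0:x1], (x0, y0, x1, y1))


@dataclass
class TrackerState:
    """Remembered object positions, missing-frame countdowns and next ID."""

    positions: dict[int, tuple[float, float]] = field(default_factory=dict)
    countdowns: dict[int, int] = field(default_factory=dict)
    next_id: int = 0


def advance_tracker(
    state: TrackerState,
    detections: list[tuple[float, float]],
    frame_index: int = 0,
    track_distance: float = 15.0,
    track_memory: int = 10,
) -> tuple[TrackerState, dict[int, int]]:
    """One tracking step; returns (state, detection index -> object ID).

    Matching is positional and greedy in ascending distance (ties broken by
    lower detection index, then lower ID), restricted to pairs within
    ``track_distance``.  Unmatched detections get fresh sequential IDs; a
    remembered object missing this frame starts (or decrements) a countdown
    from ``track_memory`` and is forgotten when it reaches zero.
    """
    del frame_index
    pairs = []
    for d_idx, (dx, dy) in enumerate(detections):
        for obj_id, (px, py) in state.positions.items():
            dist = np.hypot(dx - px, dy - py)
            if dist <= track_distance:
                pairs.append((dist, d_idx, obj_id))
    pairs.sort()

    assignment: dict[int, int] = {}
    matched_ids: set[int] = set()
    for _, d_idx, obj_id in pairs:
        if d_idx in assignment or obj_id in matched_ids:
            continue
        assignment[d_idx] = obj_id
        matched_ids.add(obj_id)

    positions = dict(state.positions)
    countdowns = dict(state.countdowns)
    next_id = state.next_id

    for d_idx, obj_id in assignment.items():
        positions[obj_id] = detections[d_idx]
        countdowns.pop(obj_id, None)
    for d_idx in range(len(detections)):
        if d_idx not in assignment:
            positions[next_id] = detections[d_idx]
            assignment[d_idx] = next_id
            next_id += 1
    for obj_id in list(positions):
        if obj_id in matched_ids or obj_id >= state.next_id:
            continue
        if obj_id not in state.countdowns:
            countdowns[obj_id] = track_memory  # newly missing
        else:
            countdowns[obj_id] = state.countdowns[obj_id] - 1
        if countdowns[obj_id] <= 0:
            del countdowns[obj_id]
            del positions[obj_id]

    return TrackerState(positions, countdowns, next_id), assignment


def track_video(
    per_frame_detections: list[list[tuple[float, float]]],
    track_distance: float = 15.0,
    track_memory: int = 10,
) -> list[dict[int, int]]:
    """Run the tracker over a whole video; one assignment dict per frame."""
    state = TrackerState()
    assignments = []
    for t, dets in enumerate(per_frame_detections):
        state, assignment = advance_tracker(state, dets, t, track_distance, track_memory)
        assignments.append(assignment)
    return assignments


def filter_new_tracks(assignments: list[dict[int, int]]) -> pd.DataFrame:
    """Per-ID frame spans: first frame, last frame, frames present.

    Objects re-detected after their memory expired appear as separate IDs;
    the downstream minimum-frames filter uses ``n_frames`` to drop the
    resulting short fragments.
    """
    first: dict[int, int] = {}
    last: dict[int, int] = {}
    count: dict[int, int] = {}
    for t, assignment in enumerate(assignments):
        for obj_id in assignment.values():
            first.setdefault(obj_id, t)
            last[obj_id] = t
            count[obj_id] = count.get(obj_id, 0) + 1
    ids = sorted(first)
    return pd.DataFrame(
        {
            "object": ids,
            "first_frame": [first[i] for i in ids],
            "last_frame": [last[i] for i in ids],
            "n_frames": [count[i] for i in ids],
        }
    )
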
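"""Population-level filtering, summaries, file I/O and the experiment driver.

An experiment is one YAML configuration file naming one or more videos.
Stages: per-video detection + tracking + boundary tracing, per-object
spectrum accumulation, spectrum fitting, population filtering, and a single
HDF5 aggregate output readable with any generic HDF5 tooling.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import boundary, localize, spectrum
from .constants import DEFAULT_TEMPERATURE
from .fitting import FitResult, fit_spectrum
from .localize import ImagingConfig

log = logging.getLogger("flickerspec")

SCHEMA_VERSION = "1"


class MissingPixelSizeError(ValueError):
    """Pixel size absent from both file metadata and configuration."""


@dataclass
class FrameStack:
    """Time-ordered stack of single-channel frames with physical pixel size."""

    frames: np.ndarray  # (T, H, W)
    pixel_size: float  # um per pixel
    timestamps: np.ndarray | None = None
    bit_depth: int = 8
    path: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or len(self.frames) < 1:
            raise ValueError("frames must be a non-empty (T, H, W) stack")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive (um per pixel)")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def write_frame_stack(path: str | Path, frames: np.ndarray, pixel_size: float) -> None:
    """Write a (T, H, W) stack as OME-TIFF with the pixel size embedded."""
    path = Path(path)
    tifffile.imwrite(
        path,
        np.asarray(frames),
        ome=True,
        metadata={
            "axes": "TYX",
            "PhysicalSizeX": pixel_size,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": pixel_size,
            "PhysicalSizeYUnit": "µm",
        },
    )


def _ome_pixel_size(tf: tifffile.TiffFile) -> float | None:
    if not tf.ome_metadata:
        return None
    try:
        root = ET.fromstring(tf.ome_metadata)
    except ET.ParseError:
        return None
    for elem in root.iter():
        if elem.tag.endswith("Pixels") and "PhysicalSizeX" in elem.attrib:
            return float(elem.attrib["PhysicalSizeX"])
    return None


def read_frame_stack(path: str | Path, pixel_size_override: float | None = None) -> FrameStack:
    """Load a TIFF / OME-TIFF video.

    Pixel size comes from the OME metadata when present, else from the
    override; plain TIFFs carry no physical pixel size, so an override is
    mandatory for them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.series[0].asarray()
        pixel_size = _ome_pixel_size(tf)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"expected a single-channel (T, H, W) video, got shape {data.shape}")
    if pixel_size is None:
        pixel_size = pixel_size_override
    if pixel_size is None:
        raise MissingPixelSizeError(
            f"{path.name}: no pixel size in TIFF metadata; plain .tif files do not "
            "record it, so 'pixel_size' must be provided in the configuration"
        )
    bit_depth = 16 if data.dtype.itemsize > 1 else 8
    name = path.stem
    if name.endswith(".ome"):
        name = name[:-4]
    return FrameStack(data, float(pixel_size), bit_depth=bit_depth, path=str(path), name=name)


@dataclass
class FilterSpec:
    """Population filters applied before any distribution-level statistics."""

    min_sigma: float = 1e-10  # N/m
    min_continuity_fraction: float = 0.60
    max_epsilon: float = 0.5
    min_delta_epsilon: float = 0.03
    min_frames: int = 200

    ORDER = ("sigma", "continuity", "epsilon", "delta_epsilon", "n_frames")

    def failing(self, record: "PopulationRecord") -> str | None:
        """Name of the first failing filter in the canonical order, or None."""
        fit = record.fit
        if not fit.sigma > self.min_sigma:
            return "sigma"
        if not record.continuity_fraction > self.min_continuity_fraction:
            return "continuity"
        if not fit.epsilon < self.max_epsilon:
            return "epsilon"
        if not fit.delta_epsilon > self.min_delta_epsilon:
            return "delta_epsilon"
        if not record.n_frames >= self.min_frames:
            return "n_frames"
        return None


@dataclass
class PopulationRecord:
    """One fitted object with its provenance."""

    fit: FitResult
    video: str = ""
    object_id: int = 0
    n_frames: int = 0
    continuity_fraction: float = 1.0
    mean_intensity: float = float("nan")
    centroid: tuple[float, float] = (float("nan"), float("nan"))
    experiment: str = ""
    timestamp: str = ""


def apply_population_filters(
    records: list[PopulationRecord], spec: FilterSpec | None = None
) -> tuple[list[PopulationRecord], dict[str, int]]:
    """Split records into passing and per-filter rejection tallies.

    A record is tallied against the first filter it fails, in the order
    sigma, continuity, epsilon, delta_epsilon, n_frames; pass/fail itself is
    order-independent (conjunction of all filters).
    """
    spec = spec or FilterSpec()
    tallies = {name: 0 for name in FilterSpec.ORDER}
    passing = []
    for record in records:
        reason = spec.failing(record)
        if reason is None:
            passing.append(record)
        else:
            tallies[reason] += 1
    return passing, tallies


def summarize(values: np.ndarray, scale: str = "lognormal") -> tuple[float, float]:
    """(center, spread): geometric mean/SD for lognormal, mean/SD for linear."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("no values to summarize")
    if scale == "lognormal":
        if np.any(x <= 0):
            raise ValueError("lognormal summary requires positive values")
        logs = np.log(x)
        return float(np.exp(logs.mean())), float(np.exp(logs.std(ddof=1) if x.size > 1 else 0.0))
    if scale == "linear":
        return float(x.mean()), float(x.std(ddof=1) if x.size > 1 else 0.0)
    raise ValueError("scale must be 'lognormal' or 'linear'")


_AGGREGATE_DTYPE = np.dtype(
    [
        ("object_id", np.int64),
        ("video", h5py.string_dtype(), ),
        ("experiment", h5py.string_dtype()),
        ("timestamp", h5py.string_dtype()),
        ("sigma", np.float64),
        ("sigma_err", np.float64),
        ("kappa", np.float64),
        ("kappa_err", np.float64),
        ("sigma_bar", np.float64),
        ("radius_um", np.float64),
        ("epsilon", np.float64),
        ("epsilon_sigma_only", np.float64),
        ("delta_epsilon", np.float64),
        ("durbin_watson", np.float64),
        ("n_frames", np.int64),
        ("continuity_fraction", np.float64),
        ("mean_intensity", np.float64),
        ("centroid_x", np.float64),
        ("centroid_y", np.float64),
        ("converged", np.bool_),
    ]
)


def _record_row(r: PopulationRecord) -> tuple:
    f = r.fit
    return (
        r.object_id, r.video, r.experiment, r.timestamp,
        f.sigma, f.sigma_err, f.kappa, f.kappa_err, f.sigma_bar, f.radius_um,
        f.epsilon, f.epsilon_sigma_only, f.delta_epsilon, f.durbin_watson,
        r.n_frames, r.continuity_fraction, r.mean_intensity,
        r.centroid[0], r.centroid[1], f.converged,
    )


def write_aggregate(records: list[PopulationRecord], path: str | Path) -> None:
    """Aggregate fittings file: one structured-array row per object."""
    rows = np.array([_record_row(r) for r in records], dtype=_AGGREGATE_DTYPE)
    if not records:
        rows = np.empty(0, dtype=_AGGREGATE_DTYPE)
    with h5py.File(path, "w") as h5:
        h5.attrs["schema_version"] = SCHEMA_VERSION
        h5.create_dataset("objects", data=rows)


def read_aggregate(path: str | Path) -> pd.DataFrame:
    with h5py.File(path, "r") as h5:
        rows = h5["objects"][()]
    df = pd.DataFrame(rows)
    for col in ("video", "experiment", "timestamp"):
        df[col] = df[col].str.decode("utf-8")
    return df


def export_aggregate(path: str | Path, out: str | Path, fmt: str = "csv") -> None:
    df = read_aggregate(path)
    if fmt == "csv":
        df.to_csv(out, index=False)
    elif fmt == "tsv":
        df.to_csv(out, index=False, sep="\t")
    else:
        raise ValueError("format must be 'csv' or 'tsv'")


# ---------------------------------------------------------------------------
# experiment configuration

_DETECTION_KEYS = {
    "minimum_intensity": "min_intensity",
    "min_size": "min_size",
    "max_size": "max_size",
    "fill_threshold": "fill_threshold",
    "smoothing_width": "smoothing_width",
    "tracking_threshold": "track_distance",
    "tracking_memory": "track_memory",
    "boundary_mode": "boundary_mode",
    "continuity_max_step": "continuity_max_step",
}
_FILTER_KEYS = {
    "min_sigma", "min_continuity_fraction", "max_epsilon", "min_delta_epsilon", "min_frames",
}
_TOP_KEYS = {
    "experiment_name", "videos", "pixel_size", "temperature", "q_max", "detection",
    "filters", "output",
}


@dataclass
class ExperimentConfig:
    """Validated contents of an experiment YAML file."""

    experiment_name: str
    videos: list[str]
    pixel_size: float | None = None  # um/px; overrides absent TIFF metadata
    temperature: float = DEFAULT_TEMPERATURE
    q_max: int = spectrum.Q_MAX_DEFAULT
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    filters: FilterSpec = field(default_factory=FilterSpec)
    output: str = "aggregate_fittings.h5"


def load_config(path: str | Path) -> ExperimentConfig:
    """Parse and validate an experiment YAML file; unknown keys are errors."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ValueError("configuration must be a YAML mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    if not raw.get("videos"):
        raise ValueError("configuration must name at least one video")

    det_raw = raw.get("detection", {}) or {}
    unknown = set(det_raw) - set(_DETECTION_KEYS)
    if unknown:
        raise ValueError(f"unknown detection keys: {sorted(unknown)}")
    imaging = ImagingConfig(**{_DETECTION_KEYS[k]: v for k, v in det_raw.items()})

    filt_raw = raw.get("filters", {}) or {}
    unknown = set(filt_raw) - _FILTER_KEYS
    if unknown:
        raise ValueError(f"unknown filter keys: {sorted(unknown)}")
    filters = FilterSpec(**filt_raw)

    videos = [str((path.parent / v)) if not Path(v).is_absolute() else str(v) for v in raw["videos"]]
    return ExperimentConfig(
        experiment_name=str(raw.get("experiment_name", path.parent.name)),
        videos=videos,
        pixel_size=raw.get("pixel_size"),
        temperature=float(raw.get("temperature", DEFAULT_TEMPERATURE)),
        q_max=int(raw.get("q_max", spectrum.Q_MAX_DEFAULT)),
        imaging=imaging,
        filters=filters,
        output=str(raw.get("output", "aggregate_fittings.h5")),
    )


# ---------------------------------------------------------------------------
# pipeline driver

def analyze_video(
    stack: FrameStack, config: ImagingConfig, q_max: int = spectrum.Q_MAX_DEFAULT
) -> list[dict]:
    """Stages 1-2 for one video.

    Returns one dict per tracked object with its SpectrumRecord and
    provenance (id, frames present, continuity fraction, mean intensity,
    centroid).  Objects with zero continuous frames are dropped.
    """
    per_frame_modes: dict[int, list[spectrum.ModeSet]] = {}
    frames_present: dict[int, int] = {}
    intensities: dict[int, list[float]] = {}
    centroids: dict[int, list[tuple[float, float]]] = {}

    state = localize.TrackerState()
    for t, frame in enumerate(stack.frames):
        centers = localize.detect_centers(frame, config)
        state, assignment = localize.advance_tracker(
            state, centers, t, config.track_distance, config.track_memory
        )
        for d_idx, obj_id in assignment.items():
            frames_present[obj_id] = frames_present.get(obj_id, 0) + 1
            try:
                detection = localize.estimate_extent(frame, centers[d_idx], config, t)
            except localize.DegenerateExtentError:
                continue
            contour = extract_contour(frame, detection, config)
            if contour is None or not contour.valid:
                continue
            modes = spectrum.contour_modes(contour, q_max=q_max, frame_index=t)
            per_frame_modes.setdefault(obj_id, []).append(modes)
            x0, y0, _, _ = detection.bbox
            sub = np.asarray(frame, dtype=float)[y0 : detection.bbox[3], x0 : detection.bbox[2]]
            intensities.setdefault(obj_id, []).append(float(sub[detection.extent_mask].mean()))
            centroids.setdefault(obj_id, []).append(contour.center)

    results = []
    for obj_id, mode_sets in sorted(per_frame_modes.items()):
        record = spectrum.accumulate(
            mode_sets, pixel_size_um=stack.pixel_size, n_expected_frames=frames_present[obj_id]
        )
        cents = np.array(centroids[obj_id])
        results.append(
            {
                "object_id": obj_id,
                "record": record,
                "n_frames": frames_present[obj_id],
                "continuity_fraction": record.continuity_fraction,
                "mean_intensity": float(np.mean(intensities[obj_id])),
                "centroid": (float(cents[:, 0].mean()), float(cents[:, 1].mean())),
            }
        )
    return results


def extract_contour(
    frame: np.ndarray, detection: localize.Detection, config: ImagingConfig
) -> boundary.ContourCurve | None:
    """Crop around a detection, refine the center, trace and validate."""
    x0, y0, x1, y1 = detection.bbox
    sub = np.asarray(frame, dtype=float)[y0:y1, x0:x1]
    ys, xs = np.nonzero(detection.extent_mask)
    if len(xs) == 0:
        return None
    center = (float(xs.mean()), float(ys.mean()))  # flood-fill centroid
    field = boundary.build_field(sub, center, config.smoothing_width, config.boundary_mode)
    try:
        contour = boundary.trace_boundary(field, center)
    except boundary.DegenerateContourError:
        return None
    boundary.validate_contour(contour, config.continuity_max_step)
    # report the contour in full-frame coordinates
    contour.center = (contour.center[0] + x0, contour.center[1] + y0)
    return contour


def fit_objects(
    analyzed: list[dict],
    video: str,
    experiment: str,
    temperature: float = DEFAULT_TEMPERATURE,
    q_max: int = spectrum.Q_MAX_DEFAULT,
) -> list[PopulationRecord]:
    """Stage 3: fit every accumulated object spectrum."""
    records = []
    for entry in analyzed:
        try:
            fit = fit_spectrum(entry["record"], temperature, q_range=(2, q_max))
        except (ValueError, np.linalg.LinAlgError) as exc:
            log.warning("object %s in %s not fitted: %s", entry["object_id"], video, exc)
            continue
        records.append(
            PopulationRecord(
                fit=fit,
                video=video,
                object_id=entry["object_id"],
                n_frames=entry["n_frames"],
                continuity_fraction=entry["continuity_fraction"],
                mean_intensity=entry["mean_intensity"],
                centroid=entry["centroid"],
                experiment=experiment,
            )
        )
    return records


def run_experiment(config: ExperimentConfig | str | Path, out_dir: str | Path | None = None) -> Path:
    """Run the full pipeline for an experiment; returns the aggregate path.

    Unreadable videos are skipped with a logged warning; the run continues
    with the remaining videos.
    """
    if not isinstance(config, ExperimentConfig):
        config = load_config(config)
    all_records: list[PopulationRecord] = []
    counts = []
    for video_path in config.videos:
        try:
            stack = read_frame_stack(video_path, config.pixel_size)
        except MissingPixelSizeError:
            raise
        except (FileNotFoundError, ValueError, OSError) as exc:
            log.warning("skipping unreadable video %s: %s", video_path, exc)
            continue
        analyzed = analyze_video(stack, config.imaging, config.q_max)
        records = fit_objects(
            analyzed, stack.name, config.experiment_name, config.temperature, config.q_max
        )
        counts.append((stack.name, stack.n_frames, len(analyzed), len(records)))
        all_records.extend(records)

    passing, tallies = apply_population_filters(all_records, config.filters)
    out_dir = Path(out_dir) if out_dir is not None else Path(".")
    out_path = out_dir / config.output
    write_aggregate(passing, out_path)
    log_path = out_path.with_suffix(".log")
    with open(log_path, "w") as fh:
        fh.write(f"experiment: {config.experiment_name}\n")
        for name, n_frames, n_obj, n_fit in counts:
            fh.write(f"video {name}: {n_frames} frames, {n_obj} objects, {n_fit} fitted\n")
        fh.write(f"fitted: {len(all_records)}  passing: {len(passing)}\n")
        for name, n in tallies.items():
            fh.write(f"rejected by {name}: {n}\n")
    return out_path
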
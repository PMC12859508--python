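"""Contour Fourier modes and their per-object accumulation.

Each contour is recentered on its centroid (removing the translational
q = 1 content), normalized by its mean radius (removing the size q = 0
content) and Fourier transformed with the 1/N forward convention, so
V_0 = 1 and the two-sided power <|V_q|^2> matches the theoretical
equatorial spectrum.  Per-object averages over frames yield the corrected
fluctuation power |F_q|^2 = <|V_q|^2> - |<V_q>|^2, which removes any static
base shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boundary import ContourCurve

Q_MAX_DEFAULT = 15

#: Boundary displacements below this (pixels) are at the detection
#: resolution floor; affected modes are flagged but still reported.
RESOLUTION_FLOOR_PX = 1.0 / 15.0


@dataclass
class ModeSet:
    """Complex Fourier amplitudes V_q of one contour, q = 0..q_max."""

    vq: np.ndarray
    mean_radius: float  # contour units (pixels for traced contours)
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.vq = np.asarray(self.vq, dtype=complex)
        if len(self.vq) < 3:
            raise ValueError("q_max must be >= 2")

    @property
    def q_max(self) -> int:
        return len(self.vq) - 1


def _recenter(contour: ContourCurve, n_iter: int = 2) -> tuple[np.ndarray, tuple[float, float]]:
    """Re-grid radii onto uniform angles about the contour centroid.

    Iterating twice makes the residual q = 1 amplitude quadratically small
    in the original center offset.
    """
    angles = contour.angles
    radii = contour.radii.copy()
    cx, cy = contour.center
    for _ in range(n_iter):
        px = cx + radii * np.cos(angles)
        py = cy + radii * np.sin(angles)
        nx, ny = float(np.mean(px)), float(np.mean(py))
        psi = np.mod(np.arctan2(py - ny, px - nx), 2.0 * np.pi)
        rho = np.hypot(px - nx, py - ny)
        order = np.argsort(psi)
        radii = np.interp(angles, psi[order], rho[order], period=2.0 * np.pi)
        cx, cy = nx, ny
    return radii, (cx, cy)


def contour_modes(
    contour: ContourCurve, q_max: int = Q_MAX_DEFAULT, frame_index: int = 0
) -> ModeSet:
    """Normalized Fourier modes V_q = (1/N) sum_j r~(phi_j) exp(-i q phi_j)."""
    radii, _ = _recenter(contour)
    mean_r = float(np.mean(radii))
    if mean_r <= 0:
        raise ValueError("degenerate contour: non-positive mean radius")
    r_norm = radii / mean_r
    vq = np.fft.fft(r_norm) / len(r_norm)
    return ModeSet(vq[: q_max + 1], mean_r, frame_index)


@dataclass
class SpectrumRecord:
    """Accumulated per-object Fourier statistics."""

    mean_sq: np.ndarray  # <|V_q|^2>, q = 0..q_max
    mean_v: np.ndarray  # <V_q>, complex
    n_frames: int
    mean_radius_um: float
    mean_radius_px: float
    se_sq: np.ndarray  # standard error of <|V_q|^2>
    continuity_fraction: float = 1.0
    clamped: np.ndarray = field(default=None)  # type: ignore[assignment]
    resolution_flagged: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def q_max(self) -> int:
        return len(self.mean_sq) - 1

    def corrected(self) -> np.ndarray:
        """|F_q|^2 for q = 0..q_max (use corrected_spectrum for a q slice)."""
        return shape_correct(self)

    def corrected_spectrum(self, q_range: tuple[int, int] = (2, Q_MAX_DEFAULT)) -> np.ndarray:
        lo, hi = q_range
        if lo < 0 or hi > self.q_max:
            raise ValueError("q_range outside accumulated modes")
        return self.corrected()[lo : hi + 1]


def accumulate(
    mode_sets: list[ModeSet],
    pixel_size_um: float = 1.0,
    n_expected_frames: int | None = None,
) -> SpectrumRecord:
    """Average mode sets of one object over its contributing frames."""
    if not mode_sets:
        raise ValueError("no contributing frames to accumulate")
    q_max = mode_sets[0].q_max
    if any(m.q_max != q_max for m in mode_sets):
        raise ValueError("inconsistent q_max across frames")
    v = np.array([m.vq for m in mode_sets])
    sq = np.abs(v) ** 2
    n = len(mode_sets)
    mean_sq = sq.mean(axis=0)
    se_sq = sq.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(q_max + 1)
    mean_r_px = float(np.mean([m.mean_radius for m in mode_sets]))
    frac = n / n_expected_frames if n_expected_frames else 1.0
    return SpectrumRecord(
        mean_sq=mean_sq,
        mean_v=v.mean(axis=0),
        n_frames=n,
        mean_radius_um=mean_r_px * pixel_size_um,
        mean_radius_px=mean_r_px,
        se_sq=se_sq,
        continuity_fraction=float(frac),
    )


def shape_correct(record: SpectrumRecord) -> np.ndarray:
    """|F_q|^2 = <|V_q|^2> - |<V_q>|^2, with negative-value clamping.

    Finite sampling can push individual modes slightly negative; those are
    clamped to 1e-3 times the smallest positive corrected value and flagged
    in ``record.clamped``.  Modes whose implied boundary displacement falls
    below the 1/15 px resolution floor are flagged in
    ``record.resolution_flagged`` but not altered.
    """
    f = record.mean_sq - np.abs(record.mean_v) ** 2
    positive = f[1:][f[1:] > 0]
    floor = 1e-3 * positive.min() if positive.size else np.finfo(float).tiny
    record.clamped = f <= 0
    record.clamped[0] = False
    f = np.where(record.clamped, floor, f)
    f[0] = max(f[0], 0.0)
    # rms boundary displacement per mode, in pixels: R_px * sqrt(2 |F_q|^2)
    disp = record.mean_radius_px * np.sqrt(2.0 * np.abs(f))
    record.resolution_flagged = disp < RESOLUTION_FLOOR_PX
    return f
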
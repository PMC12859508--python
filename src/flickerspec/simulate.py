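"""Synthetic fluctuating-droplet generator.

Draws quasi-spherical interface shapes whose spherical-harmonic amplitudes
carry the equilibrium (equipartition) statistics

    <|u_lm|^2> = k_B T / [ kappa (l+2)(l-1)(l(l+1) + sigma_bar) ],

cuts them with an imaging plane to obtain equatorial (or off-equator)
contours, and renders the contours as confocal-like frames with a tanh
radial intensity profile, additive Gaussian noise and quantization.  Frames
are independent equilibrium samples: the model supplies no relaxation
dynamics, so frame-rate effects cannot be emulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import sph_harm_y

from .boundary import ContourCurve, uniform_angles
from .constants import DEFAULT_TEMPERATURE, thermal_energy


@dataclass
class SimulationParams:
    """Ground-truth physical and imaging parameters for one simulation.

    ``kappa`` is in units of k_B*T, ``sigma`` in N/m, ``radius`` in um.
    ``zeta`` (interface width) and the intensity settings are in pixels and
    intensity levels of the chosen bit depth.
    """

    sigma: float
    kappa: float
    radius: float
    temperature: float = DEFAULT_TEMPERATURE
    l_max: int = 75
    zeta: float = 0.8
    pixel_size: float = 0.1  # um per pixel
    noise_sd: float = 0.02  # fraction of amplitude
    bit_depth: int = 8
    plane_offset: float = 0.0  # fraction of radius
    amplitude: float | None = None  # default 200 of 255, scaled to bit depth
    background: float | None = None  # default 10 of 255, scaled to bit depth

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.l_max < 2:
            raise ValueError("l_max must be at least 2")
        if not abs(self.plane_offset) < 1:
            raise ValueError("|plane_offset| must be < 1")
        if self.zeta <= 0:
            raise ValueError("zeta must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @classmethod
    def from_sigma_bar(
        cls, sigma_bar: float, kappa: float, radius: float, temperature: float = DEFAULT_TEMPERATURE, **kwargs
    ) -> "SimulationParams":
        """Build params from the reduced tension sigma_bar = sigma R^2 / kappa."""
        r_m = radius * 1e-6
        sigma = sigma_bar * kappa * thermal_energy(temperature) / r_m**2
        return cls(sigma=sigma, kappa=kappa, radius=radius, temperature=temperature, **kwargs)

    @property
    def sigma_bar(self) -> float:
        """Reduced tension sigma * R^2 / kappa (dimensionless)."""
        r_m = self.radius * 1e-6
        return self.sigma * r_m**2 / (self.kappa * thermal_energy(self.temperature))

    @property
    def max_level(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def render_amplitude(self) -> float:
        if self.amplitude is not None:
            return self.amplitude
        return 200.0 * self.max_level / 255.0

    @property
    def render_background(self) -> float:
        if self.background is not None:
            return self.background
        return 10.0 * self.max_level / 255.0

    @property
    def radius_px(self) -> float:
        return self.radius / self.pixel_size


@dataclass
class HarmonicShape:
    """Spherical-harmonic amplitudes u_lm for m >= 0, plus mean radius (um).

    ``amplitudes[l - 2, m]`` holds u_lm for 2 <= l <= l_max, 0 <= m <= l
    (entries with m > l are zero).  Negative-m coefficients follow from the
    reality constraint u_{l,-m} = (-1)^m conj(u_{l,m}).
    """

    amplitudes: np.ndarray
    radius: float
    l_max: int

    def amplitude(self, l: int, m: int) -> complex:
        if not 2 <= l <= self.l_max or abs(m) > l:
            raise ValueError("index out of range")
        if m >= 0:
            return complex(self.amplitudes[l - 2, m])
        return (-1) ** (-m) * np.conj(complex(self.amplitudes[l - 2, -m]))


def mode_variances(params: SimulationParams) -> np.ndarray:
    """<|u_lm|^2> for l = 2..l_max (independent of m)."""
    l = np.arange(2, params.l_max + 1, dtype=float)
    sb = params.sigma_bar
    return 1.0 / (params.kappa * (l + 2.0) * (l - 1.0) * (l * (l + 1.0) + sb))


def sample_shape(
    params: SimulationParams, seed: int | None = None, rng: np.random.Generator | None = None
) -> HarmonicShape:
    """Draw one equilibrium shape.

    m = 0 coefficients are real Gaussian with variance <|u_lm|^2>; m > 0 are
    complex Gaussian with that total variance split evenly between real and
    imaginary parts, so the full real field has the correct equatorial
    two-sided Fourier spectrum (verified by the equipartition tests).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n_l = params.l_max - 1
    n_m = params.l_max + 1
    sd = np.sqrt(mode_variances(params))
    u = np.zeros((n_l, n_m), dtype=complex)
    u[:, 0] = rng.normal(size=n_l) * sd
    re = rng.normal(size=(n_l, n_m - 1))
    im = rng.normal(size=(n_l, n_m - 1))
    u[:, 1:] = (re + 1j * im) * (sd[:, None] / np.sqrt(2.0))
    # zero out m > l
    ls = np.arange(2, params.l_max + 1)[:, None]
    ms = np.arange(n_m)[None, :]
    u[ms > ls] = 0.0
    return HarmonicShape(u, params.radius, params.l_max)


@lru_cache(maxsize=64)
def _section_table(l_max: int, plane_offset: float) -> np.ndarray:
    """Real Y_lm(theta0, 0) = N_lm P_lm(cos theta0) for l=2..l_max, m=0..l_max."""
    theta0 = float(np.arccos(plane_offset))
    ls = np.arange(2, l_max + 1)[:, None]
    ms = np.arange(l_max + 1)[None, :]
    l_grid = np.broadcast_to(ls, (l_max - 1, l_max + 1))
    m_grid = np.broadcast_to(ms, (l_max - 1, l_max + 1))
    table = np.zeros((l_max - 1, l_max + 1))
    mask = m_grid <= l_grid
    table[mask] = np.real(sph_harm_y(l_grid[mask], m_grid[mask], theta0, 0.0))
    return table


def cross_section_contour(
    shape: HarmonicShape, plane_offset: float = 0.0, n_angles: int = 400
) -> ContourCurve:
    """Contour of the shape cut by the plane z = plane_offset * R.

    Radii are in the same unit as ``shape.radius`` (um), measured from the
    symmetry axis; the surface is evaluated to first order in the
    fluctuation amplitudes at the polar angle of the cutting plane.
    """
    if not abs(plane_offset) < 1:
        raise ValueError("|plane_offset| must be < 1")
    table = _section_table(shape.l_max, float(plane_offset))
    b = np.sum(shape.amplitudes * table, axis=0)  # per-m sums, m = 0..l_max
    phi = uniform_angles(n_angles)
    m = np.arange(1, shape.l_max + 1)
    osc = np.exp(1j * np.outer(phi, m)) @ b[1:]
    r_rel = 1.0 + np.real(b[0]) + 2.0 * np.real(osc)
    radii = shape.radius * np.sqrt(1.0 - plane_offset**2) * r_rel
    return ContourCurve(phi, radii, (0.0, 0.0))


def render_frame(
    contour: ContourCurve,
    params: SimulationParams,
    frame_shape: tuple[int, int],
    center: tuple[float, float],
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one contour as a noisy quantized image.

    ``contour`` radii must be in pixels.  Intensity follows the tanh
    interface profile I(d) = A (1/2 - 1/2 tanh((d - r(phi))/zeta)) plus
    background; Gaussian noise of sd noise_sd*A is added before clipping
    and quantization to the configured bit depth.
    """
    field = _render_intensity(contour, params, frame_shape, center)
    if rng is None:
        rng = np.random.default_rng(seed)
    if params.noise_sd > 0:
        field = field + rng.normal(0.0, params.noise_sd * params.render_amplitude, field.shape)
    return _quantize(field, params)


def _render_intensity(
    contour: ContourCurve,
    params: SimulationParams,
    frame_shape: tuple[int, int],
    center: tuple[float, float],
    check_margin: bool = True,
) -> np.ndarray:
    cx, cy = center
    ny, nx = frame_shape
    r_max = float(np.max(contour.radii))
    if check_margin and (
        cx - r_max < 5 or cy - r_max < 5 or cx + r_max > nx - 6 or cy + r_max > ny - 6
    ):
        raise ValueError("contour does not fit in the frame with a 5-pixel margin")
    yy, xx = np.mgrid[0:ny, 0:nx]
    d = np.hypot(xx - cx, yy - cy)
    phi = np.mod(np.arctan2(yy - cy, xx - cx), 2.0 * np.pi)
    # periodic linear interpolation of the contour radius at each pixel angle
    wrapped_phi = np.append(contour.angles, 2.0 * np.pi)
    wrapped_r = np.append(contour.radii, contour.radii[0])
    r_phi = np.interp(phi.ravel(), wrapped_phi, wrapped_r).reshape(phi.shape)
    a = params.render_amplitude
    profile = 0.5 - 0.5 * np.tanh((d - r_phi) / params.zeta)
    return params.render_background + a * profile


def _quantize(field: np.ndarray, params: SimulationParams) -> np.ndarray:
    top = params.max_level
    out = np.clip(np.rint(field), 0, top)
    return out.astype(np.uint8 if params.bit_depth == 8 else np.uint16)


def _layout_centers(n_objects: int, radius_px: float) -> tuple[list[tuple[float, float]], tuple[int, int]]:
    cell = int(np.ceil(2.0 * radius_px * 1.35)) + 12
    cols = int(np.ceil(np.sqrt(n_objects))) if n_objects else 1
    rows = int(np.ceil(n_objects / cols)) if n_objects else 1
    centers = [
        ((i % cols + 0.5) * cell, (i // cols + 0.5) * cell) for i in range(n_objects)
    ]
    return centers, (rows * cell, cols * cell)


def generate_video(
    params: SimulationParams,
    n_frames: int,
    n_objects: int,
    seed: int,
    centers: list[tuple[float, float]] | None = None,
    frame_shape: tuple[int, int] | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Stack of independent equilibrium frames plus the ground-truth table.

    Objects sit at fixed centers; every frame draws fresh shapes for every
    object.  Returns (frames array [n_frames, ny, nx], truth DataFrame with
    per-object sigma, kappa, radius and center).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if centers is None:
        centers, auto_shape = _layout_centers(n_objects, params.radius_px)
        if frame_shape is None:
            frame_shape = auto_shape
    elif frame_shape is None:
        raise ValueError("frame_shape is required when centers are given")
    if n_objects and len(centers) != n_objects:
        raise ValueError("need one center per object")
    min_sep = 2.0 * params.radius_px * 1.3
    for i in range(n_objects):
        for j in range(i + 1, n_objects):
            d = np.hypot(centers[i][0] - centers[j][0], centers[i][1] - centers[j][1])
            if d < min_sep:
                raise ValueError(f"objects {i} and {j} overlap (separation {d:.1f} px)")

    rng = np.random.default_rng(seed)
    ny, nx = frame_shape
    frames = np.empty((n_frames, ny, nx), dtype=np.uint8 if params.bit_depth == 8 else np.uint16)
    bg = params.render_background
    for t in range(n_frames):
        field = np.full((ny, nx), bg)
        for c in centers:
            shape = sample_shape(params, rng=rng)
            contour = cross_section_contour(shape, params.plane_offset)
            px_contour = replace_radii(contour, contour.radii / params.pixel_size)
            field += _render_intensity(px_contour, params, frame_shape, c) - bg
        if params.noise_sd > 0:
            field += rng.normal(0.0, params.noise_sd * params.render_amplitude, field.shape)
        frames[t] = _quantize(field, params)

    truth = pd.DataFrame(
        {
            "object": np.arange(n_objects, dtype=int),
            "center_x": [c[0] for c in centers],
            "center_y": [c[1] for c in centers],
            "sigma": params.sigma,
            "kappa": params.kappa,
            "radius_um": params.radius,
            "radius_px": params.radius_px,
            "sigma_bar": params.sigma_bar,
        }
    )
    return frames, truth


def replace_radii(contour: ContourCurve, radii: np.ndarray) -> ContourCurve:
    """Copy of a contour with rescaled radii (unit conversion helper)."""
    return ContourCurve(contour.angles.copy(), np.asarray(radii, dtype=float), contour.center)
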
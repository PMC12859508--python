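"""Self-contained parameter-recovery benchmarks.

These routines exercise the package end to end against known ground truth
from the synthetic droplet generator; they back both the acceptance test
suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from . import boundary, fitting, localize, population, simulate, spectrum


def resolution_reciprocal(
    zeta: float = 0.8, n_levels: int = 10, levels: int = 255
) -> float:
    """1/alpha for the analytic boundary-resolution bound."""
    alpha = boundary.resolution_limit(boundary.ResolutionParams(zeta, n_levels, levels))
    return 1.0 / alpha


def simulate_spectrum_record(
    params: simulate.SimulationParams,
    n_shapes: int,
    rng: np.random.Generator,
    plane_offset: float | None = None,
) -> spectrum.SpectrumRecord:
    """Accumulated mode statistics of independent equilibrium cross-sections."""
    offset = params.plane_offset if plane_offset is None else plane_offset
    mode_sets = []
    for i in range(n_shapes):
        shape = simulate.sample_shape(params, rng=rng)
        contour = simulate.cross_section_contour(shape, offset)
        mode_sets.append(spectrum.contour_modes(contour, frame_index=i))
    return spectrum.accumulate(mode_sets)  # radii already in um


def equipartition_check(
    seed: int,
    n_shapes: int = 2000,
    sigma_bar: float = 300.0,
    kappa: float = 5.0,
    radius_um: float = 2.0,
    q_range: tuple[int, int] = (2, 15),
) -> dict:
    """Empirical equatorial <|V_q|^2> vs the closed-form spectrum.

    Returns per-mode empirical means, standard errors, theory values and the
    per-mode deviation in units of the Monte-Carlo standard error.
    """
    params = simulate.SimulationParams.from_sigma_bar(sigma_bar, kappa, radius_um)
    rng = np.random.default_rng(seed)
    record = simulate_spectrum_record(params, n_shapes, rng)
    lo, hi = q_range
    empirical = record.mean_sq[lo : hi + 1]
    se = record.se_sq[lo : hi + 1]
    theory = fitting.theoretical_spectrum(
        fitting.TheorySpec(sigma_bar=params.sigma_bar, kappa=kappa, q_range=q_range)
    )
    return {
        "empirical": empirical,
        "se": se,
        "theory": theory,
        "deviation_se": (empirical - theory) / se,
    }


def offplane_recovery(
    seed: int,
    n_droplets: int = 20,
    n_shapes: int = 1000,
    plane_offset: float = 0.34,
    kappa: float = 5.0,
    radius_um: float = 2.0,
    sigma_bar_range: tuple[float, float] = (10.0, 1000.0),
) -> dict:
    """Recovery error when droplets are cross-sectioned off the equator.

    For each droplet sigma_bar is drawn log-uniformly, ``n_shapes``
    equilibrium shapes are cut at ``plane_offset`` radii from the equator,
    and the corrected spectrum is fitted with the (equatorial) model.
    Returns per-droplet relative errors and their medians in percent.
    """
    rng = np.random.default_rng(seed)
    sigma_errors, kappa_errors = [], []
    for _ in range(n_droplets):
        sigma_bar = 10.0 ** rng.uniform(*np.log10(sigma_bar_range))
        params = simulate.SimulationParams.from_sigma_bar(sigma_bar, kappa, radius_um)
        record = simulate_spectrum_record(params, n_shapes, rng, plane_offset=plane_offset)
        fit = fitting.fit_spectrum(record, params.temperature)
        sigma_errors.append(abs(fit.sigma - params.sigma) / params.sigma)
        kappa_errors.append(abs(fit.kappa - kappa) / kappa)
    return {
        "sigma_errors": np.array(sigma_errors),
        "kappa_errors": np.array(kappa_errors),
        "median_sigma_err_pct": 100.0 * float(np.median(sigma_errors)),
        "median_kappa_err_pct": 100.0 * float(np.median(kappa_errors)),
        "n_droplets": n_droplets,
        "n_shapes": n_shapes,
    }


def end_to_end_recovery(
    seed: int,
    n_frames: int = 1000,
    sigma_bar: float = 300.0,
    kappa: float = 5.0,
    radius_um: float = 2.0,
    pixel_size: float = 0.05,
    frame_counts: tuple[int, ...] = (200, 1000),
) -> dict:
    """Render -> detect -> track -> boundary -> spectrum -> fit recovery.

    One droplet, ``n_frames`` independent rendered frames; the fit is
    repeated on truncations of the video at each entry of ``frame_counts``.
    Returns relative errors of sigma and kappa per frame count.
    """
    params = simulate.SimulationParams.from_sigma_bar(
        sigma_bar, kappa, radius_um, pixel_size=pixel_size
    )
    frames, truth = simulate.generate_video(params, n_frames, 1, seed)
    diameter_px = 2.0 * params.radius_px
    config = localize.ImagingConfig(
        min_intensity=0.3,
        min_size=0.6 * diameter_px,
        max_size=1.4 * diameter_px,
        smoothing_width=0.6,
    )
    results = {}
    for n in frame_counts:
        stack = population.FrameStack(frames[: min(n, n_frames)], pixel_size)
        analyzed = population.analyze_video(stack, config)
        if len(analyzed) != 1:
            raise RuntimeError(f"expected 1 tracked object, found {len(analyzed)}")
        fit = fitting.fit_spectrum(analyzed[0]["record"], params.temperature)
        results[n] = {
            "sigma_err": abs(fit.sigma - params.sigma) / params.sigma,
            "kappa_err": abs(fit.kappa - kappa) / kappa,
            "fit": fit,
        }
    return results
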
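"""Theoretical fluctuation spectrum and its fit to measured spectra.

The equatorial power spectrum of a quasi-spherical interface governed by
tension sigma and bending rigidity kappa is

    <|V_q|^2> = (k_B T / kappa) * sum_{l=q}^{l_max}
                N_lq^2 P_lq(0)^2 / [(l+2)(l-1)(l(l+1) + sigma_bar)]

with sigma_bar = sigma R^2 / kappa and N_lq the orthonormal spherical
harmonic prefactor.  Fitting minimizes the summed squared log10 ratio of
theory to experiment, initialized on a 14-decade logarithmic grid and
refined with a downhill least-squares step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares
from scipy.special import gammaln

from .constants import DEFAULT_TEMPERATURE, thermal_energy

Q_RANGE_DEFAULT = (2, 15)
L_MAX_DEFAULT = 75

# 14-decade logarithmic search windows (grid initialization), 8 points/decade
GRID_LOG_SIGMA_BAR = (-4.0, 10.0)
GRID_LOG_KAPPA = (-3.0, 11.0)
GRID_POINTS_PER_DECADE = 8

_LOG2 = np.log(2.0)


def equatorial_legendre(l: int, q: int) -> float:
    """Orthonormalized associated Legendre value N_lq * P_lq(0).

    Zero exactly when l + q is odd (equatorial parity).  Evaluated in log
    space so it is stable far beyond l = 75.
    """
    if q < 0 or l < 0 or q > l:
        raise ValueError("require 0 <= q <= l")
    if (l + q) % 2 == 1:
        return 0.0
    # N_lq = sqrt((2l+1)/(4 pi) (l-q)!/(l+q)!)
    log_n = 0.5 * (
        np.log((2 * l + 1) / (4.0 * np.pi)) + gammaln(l - q + 1) - gammaln(l + q + 1)
    )
    # |P_lq(0)| = (l+q-1)!! / (l-q)!!, sign (-1)^((l+q)/2) (Condon-Shortley)
    a = (l + q) // 2
    b = (l - q) // 2
    log_p = (gammaln(l + q + 1) - a * _LOG2 - gammaln(a + 1)) - (b * _LOG2 + gammaln(b + 1))
    sign = -1.0 if a % 2 else 1.0
    return sign * float(np.exp(log_n + log_p))


@lru_cache(maxsize=256)
def _legendre_sq_table(q: int, l_max: int) -> np.ndarray:
    """[N_lq P_lq(0)]^2 for l = q..l_max (cached)."""
    return np.array([equatorial_legendre(l, q) ** 2 for l in range(q, l_max + 1)])


@dataclass
class TheorySpec:
    """Parameters of the theoretical equatorial spectrum."""

    sigma_bar: float
    kappa: float  # k_B T units
    q_range: tuple[int, int] = Q_RANGE_DEFAULT
    l_max: int = L_MAX_DEFAULT

    def __post_init__(self) -> None:
        if self.sigma_bar < 0:
            raise ValueError("sigma_bar must be non-negative")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.q_range[0] < 2 or self.q_range[1] < self.q_range[0]:
            raise ValueError("q_range must satisfy 2 <= q_min <= q_max")
        if self.l_max < self.q_range[1]:
            raise ValueError("l_max must be >= max q")


def _mode_sums(sigma_bar: np.ndarray, qs: np.ndarray, l_max: int) -> np.ndarray:
    """sum_l N^2 P^2 / [(l+2)(l-1)(l(l+1)+sigma_bar)], shape (len(sb), len(qs))."""
    sb = np.atleast_1d(np.asarray(sigma_bar, dtype=float))
    out = np.empty((len(sb), len(qs)))
    for j, q in enumerate(qs):
        l = np.arange(q, l_max + 1)
        num = _legendre_sq_table(int(q), l_max) / ((l + 2.0) * (l - 1.0))
        out[:, j] = np.sum(num[None, :] / (l * (l + 1.0) + sb[:, None]), axis=1)
    return out


def theoretical_spectrum(spec: TheorySpec, temperature: float = DEFAULT_TEMPERATURE) -> np.ndarray:
    """<|V_q|^2> for q in spec.q_range (inclusive).

    With kappa expressed in k_B T units the thermal prefactor k_B T / kappa
    reduces to 1/kappa, so the result is temperature-independent; the
    argument is kept for interface symmetry with the fit entry points.
    """
    del temperature
    qs = np.arange(spec.q_range[0], spec.q_range[1] + 1)
    return _mode_sums(np.array([spec.sigma_bar]), qs, spec.l_max)[0] / spec.kappa


def tension_only_spectrum(
    sigma_r2: float, q_range: tuple[int, int] = Q_RANGE_DEFAULT, l_max: int = L_MAX_DEFAULT
) -> np.ndarray:
    """kappa -> 0 limit: <|V_q|^2> = (1/sigma_r2) sum_l N^2 P^2 / [(l+2)(l-1)].

    ``sigma_r2`` is sigma R^2 / k_B T (dimensionless).
    """
    if sigma_r2 <= 0:
        raise ValueError("sigma_r2 must be positive")
    qs = np.arange(q_range[0], q_range[1] + 1)
    sums = np.empty(len(qs))
    for j, q in enumerate(qs):
        l = np.arange(q, l_max + 1)
        sums[j] = np.sum(_legendre_sq_table(int(q), l_max) / ((l + 2.0) * (l - 1.0)))
    return sums / sigma_r2


def spectral_error(theory: np.ndarray, experiment: np.ndarray) -> float:
    """epsilon = sum_q [log10(theory_q / experiment_q)]^2."""
    theory = np.asarray(theory, dtype=float)
    experiment = np.asarray(experiment, dtype=float)
    if theory.shape != experiment.shape:
        raise ValueError("spectra must share q_range")
    if np.any(theory <= 0) or np.any(experiment <= 0):
        raise ValueError("spectra must be strictly positive")
    return float(np.sum(np.log10(theory / experiment) ** 2))


def durbin_watson(residuals: np.ndarray) -> float:
    """Lag-1 residual autocorrelation statistic, in [0, 4]."""
    e = np.asarray(residuals, dtype=float)
    if e.size < 2:
        raise ValueError("need at least two residuals")
    denom = np.sum(e**2)
    if denom == 0:
        raise ValueError("Durbin-Watson undefined for all-zero residuals")
    return float(np.sum(np.diff(e) ** 2) / denom)


@dataclass
class FitResult:
    """Fitted interface parameters and fit diagnostics for one object."""

    sigma: float  # N/m
    kappa: float  # k_B T
    sigma_bar: float
    epsilon: float
    epsilon_sigma_only: float
    delta_epsilon: float
    durbin_watson: float
    sigma_err: float
    kappa_err: float
    converged: bool
    radius_um: float
    n_frames: int = 0
    residuals: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def sigma_uN_per_m(self) -> float:
        return self.sigma * 1e6


def _log_residuals(x: np.ndarray, qs: np.ndarray, log_f: np.ndarray, l_max: int) -> np.ndarray:
    log_sb, log_kappa = x
    sums = _mode_sums(np.array([10.0**log_sb]), qs, l_max)[0]
    return np.log10(sums) - log_kappa - log_f


def _grid_axis(bounds: tuple[float, float]) -> np.ndarray:
    n = int(round((bounds[1] - bounds[0]) * GRID_POINTS_PER_DECADE)) + 1
    return np.linspace(bounds[0], bounds[1], n)


def fit_spectrum(
    record,
    temperature: float = DEFAULT_TEMPERATURE,
    q_range: tuple[int, int] = Q_RANGE_DEFAULT,
    l_max: int = L_MAX_DEFAULT,
) -> FitResult:
    """Fit (sigma_bar, kappa) to a corrected spectrum record.

    ``record`` needs ``corrected_spectrum(q_range)`` and ``mean_radius_um``
    (a :class:`~flickerspec.spectrum.SpectrumRecord`, or anything matching).
    Stage 1 evaluates epsilon on a log grid spanning 14 decades in both
    parameters; stage 2 refines (log10 sigma_bar, log10 kappa) by
    least-squares on the per-mode log ratios.  sigma is recovered as
    sigma_bar * kappa / R^2.
    """
    f_exp = np.asarray(record.corrected_spectrum(q_range), dtype=float)
    qs = np.arange(q_range[0], q_range[1] + 1)
    if np.sum(f_exp > 0) < 2:
        raise ValueError("need at least two positive modes to fit")
    radius_um = float(record.mean_radius_um)
    if radius_um <= 0:
        raise ValueError("mean radius must be known and positive")
    log_f = np.log10(f_exp)

    # stage 1: grid initialization
    sb_axis = _grid_axis(GRID_LOG_SIGMA_BAR)
    kap_axis = _grid_axis(GRID_LOG_KAPPA)
    log_sums = np.log10(_mode_sums(10.0**sb_axis, qs, l_max))  # (n_sb, n_q)
    res_grid = log_sums[:, None, :] - kap_axis[None, :, None] - log_f[None, None, :]
    eps_grid = np.sum(res_grid**2, axis=2)
    i, j = np.unravel_index(np.argmin(eps_grid), eps_grid.shape)
    x0 = np.array([sb_axis[i], kap_axis[j]])
    eps0 = float(eps_grid[i, j])

    # stage 2: downhill refinement in log space
    sol = least_squares(_log_residuals, x0, args=(qs, log_f, l_max))
    eps_ref = float(2.0 * sol.cost)
    converged = bool(sol.success)
    if eps_ref <= eps0:
        x, eps, residuals, jac = sol.x, eps_ref, sol.fun, sol.jac
    else:  # downhill contract: never report worse than the grid start
        x, eps = x0, eps0
        residuals = _log_residuals(x0, qs, log_f, l_max)
        jac = None
        converged = False

    sigma_bar = float(10.0 ** x[0])
    kappa = float(10.0 ** x[1])
    r_m = radius_um * 1e-6
    sigma = sigma_bar * kappa * thermal_energy(temperature) / r_m**2

    # linearized covariance of (log10 sb, log10 kappa)
    sigma_err = kappa_err = float("nan")
    if jac is not None and len(qs) > 2:
        try:
            cov = np.linalg.inv(jac.T @ jac) * eps / (len(qs) - 2)
            se_log = np.sqrt(np.abs(np.diag(cov)))
            ln10 = np.log(10.0)
            kappa_err = kappa * ln10 * se_log[1]
            # sigma = sb*kappa*kT/R^2; relative errors add in quadrature
            sigma_err = sigma * ln10 * float(np.hypot(se_log[0], se_log[1]))
        except np.linalg.LinAlgError:
            pass

    try:
        dw = durbin_watson(residuals)
    except ValueError:
        dw = float("nan")

    eps_sigma, _ = fit_tension_only_spectrum(f_exp, q_range=q_range, l_max=l_max)
    return FitResult(
        sigma=sigma,
        kappa=kappa,
        sigma_bar=sigma_bar,
        epsilon=eps,
        epsilon_sigma_only=eps_sigma,
        delta_epsilon=abs(eps - eps_sigma),
        durbin_watson=dw,
        sigma_err=sigma_err,
        kappa_err=kappa_err,
        converged=converged,
        radius_um=radius_um,
        n_frames=getattr(record, "n_frames", 0),
        residuals=np.asarray(residuals),
    )


def fit_tension_only_spectrum(
    f_exp: np.ndarray,
    q_range: tuple[int, int] = Q_RANGE_DEFAULT,
    l_max: int = L_MAX_DEFAULT,
) -> tuple[float, float]:
    """Best epsilon of the one-parameter tension-only model.

    The model is theory_q = S_q / s with s = sigma R^2 / k_B T, so the log
    residuals are affine in log10(s) and the optimum is the mean offset.
    Returns (epsilon_sigma_only, fitted s).
    """
    f_exp = np.asarray(f_exp, dtype=float)
    base = tension_only_spectrum(1.0, q_range=q_range, l_max=l_max)
    offsets = np.log10(base) - np.log10(f_exp)
    log_s = float(np.mean(offsets))
    eps = float(np.sum((offsets - log_s) ** 2))
    return eps, 10.0**log_s


def fit_tension_only(
    record,
    temperature: float = DEFAULT_TEMPERATURE,
    q_range: tuple[int, int] = Q_RANGE_DEFAULT,
    l_max: int = L_MAX_DEFAULT,
) -> tuple[float, float]:
    """(epsilon_sigma_only, delta_epsilon) for a spectrum record."""
    full = fit_spectrum(record, temperature, q_range=q_range, l_max=l_max)
    return full.epsilon_sigma_only, full.delta_epsilon
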
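"""Lexicographic Bayesian selection of detection parameters.

Two objectives over a sampled subset of (video, frame) pairs:

    F1 = sum over videos of the per-video minimum count of usable objects
    F2 = -(mean over videos of the mean per-frame count of unusable objects)

Stage 1 maximizes F1 (yielding n_max); stage 2 maximizes F2 subject to
F1 >= constraint_fraction * n_max, enforced by an additive penalty.  Both
stages use a Gaussian-process surrogate with expected-improvement
acquisition.  "Usable" means detected with a non-degenerate extent and a
boundary passing the continuity check; "unusable" means detected but
failing either.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern

from . import localize, population
from .localize import ImagingConfig

PARAM_NAMES = ("min_intensity", "min_size", "max_size")

_INFEASIBLE_PENALTY = 1e3


@dataclass
class OptimizerSpec:
    """Search box and budget for the two-stage optimization."""

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "min_intensity": (0.05, 0.95),
            "min_size": (4.0, 30.0),
            "max_size": (20.0, 80.0),
        }
    )
    n_videos_subsample: int = 12
    n_frames_per_video: int = 2
    constraint_fraction: float = 0.9
    budget: int = 40
    n_initial: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.bounds) != set(PARAM_NAMES):
            raise ValueError(f"bounds must cover exactly {PARAM_NAMES}")
        for name, (lo, hi) in self.bounds.items():
            if not np.isfinite([lo, hi]).all() or lo >= hi:
                raise ValueError(f"invalid bounds for {name}")
        if not 0 < self.constraint_fraction <= 1:
            raise ValueError("constraint_fraction must be in (0, 1]")
        if self.budget < self.n_initial:
            raise ValueError("budget must be at least n_initial")


def sample_subset(
    videos: list, spec: OptimizerSpec, seed: int | None = None
) -> list[tuple[int, int]]:
    """Uniform without-replacement choice of (video index, frame index) pairs.

    Up to ``n_videos_subsample`` videos, ``n_frames_per_video`` distinct
    frames each.  ``videos`` is a list of FrameStacks (or anything with
    ``n_frames``).
    """
    if not videos:
        raise ValueError("need at least one video")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n_vid = min(spec.n_videos_subsample, len(videos))
    chosen = sorted(rng.choice(len(videos), size=n_vid, replace=False).tolist())
    pairs = []
    for v in chosen:
        n_frames = videos[v].n_frames
        k = min(spec.n_frames_per_video, n_frames)
        for f in sorted(rng.choice(n_frames, size=k, replace=False).tolist()):
            pairs.append((v, f))
    return pairs


def evaluate_frame(
    frame: np.ndarray, config: ImagingConfig
) -> tuple[int, int]:
    """(usable, unusable) object counts for one frame under one theta."""
    usable = unusable = 0
    for center in localize.detect_centers(frame, config):
        try:
            detection = localize.estimate_extent(frame, center, config)
        except localize.DegenerateExtentError:
            unusable += 1
            continue
        contour = population.extract_contour(frame, detection, config)
        if contour is not None and contour.valid:
            usable += 1
        else:
            unusable += 1
    return usable, unusable


def _counts_by_video(
    videos: list, subset: list[tuple[int, int]], config: ImagingConfig
) -> dict[int, list[tuple[int, int]]]:
    out: dict[int, list[tuple[int, int]]] = {}
    for v, f in subset:
        out.setdefault(v, []).append(evaluate_frame(videos[v].frames[f], config))
    return out


def objective_usable(counts: dict[int, list[tuple[int, int]]]) -> float:
    """F1: sum over videos of the minimum usable count among its frames."""
    return float(sum(min(u for u, _ in frames) for frames in counts.values()))


def objective_unusable(counts: dict[int, list[tuple[int, int]]]) -> float:
    """F2: negative mean over videos of the mean per-frame unusable count."""
    per_video = [np.mean([x for _, x in frames]) for frames in counts.values()]
    return float(-np.mean(per_video))


@dataclass
class OptimizationReport:
    """Chosen parameters plus full audit trail of both stages."""

    theta: dict[str, float]
    n_max: float
    f1: float
    f2: float
    subset: list[tuple[int, int]]
    stage1_trace: list[tuple[dict[str, float], float]]
    stage2_trace: list[tuple[dict[str, float], float]]


@dataclass
class LexicographicResult:
    """Outcome of a generic two-stage lexicographic maximization."""

    theta: dict[str, float]
    n_max: float
    f1: float
    f2: float
    stage1_trace: list[tuple[dict[str, float], float]]
    stage2_trace: list[tuple[dict[str, float], float]]


def lexicographic_maximize(
    f1,
    f2,
    bounds: dict[str, tuple[float, float]],
    budget: int = 40,
    n_initial: int = 10,
    constraint_fraction: float = 0.9,
    seed: int = 0,
) -> LexicographicResult:
    """Maximize f1, then f2 subject to f1 >= constraint_fraction * max(f1).

    ``f1`` and ``f2`` map a parameter dict to a scalar.  Works for any
    number of parameters; used both for the full detection-parameter search
    and for low-dimensional audits against exhaustive grids.
    """
    rng = np.random.default_rng(seed)
    names = list(bounds)

    def to_theta(x: np.ndarray) -> dict[str, float]:
        return {
            n: float(lo + (hi - lo) * xi) for (n, (lo, hi)), xi in zip(bounds.items(), x)
        }

    x1, n_max, trace1 = _bayes_maximize(
        lambda x: f1(to_theta(x)), len(names), budget, n_initial, rng
    )
    if n_max <= 0:
        raise RuntimeError("no usable objects at any tested parameter set")
    floor = constraint_fraction * n_max

    def stage2(x: np.ndarray) -> float:
        theta = to_theta(x)
        return f2(theta) if f1(theta) >= floor else f2(theta) - _INFEASIBLE_PENALTY

    # seed stage 2 with the stage-1 optimum, which is feasible by construction
    x2, _, trace2 = _bayes_maximize(stage2, len(names), budget, n_initial, rng, x_start=x1)
    if f1(to_theta(x2)) < floor:  # fall back to the stage-1 optimum
        x2 = x1
        trace2.append((x1, f2(to_theta(x1))))
    theta = to_theta(x2)
    return LexicographicResult(
        theta=theta,
        n_max=float(n_max),
        f1=f1(theta),
        f2=f2(theta),
        stage1_trace=[(to_theta(x), y) for x, y in trace1],
        stage2_trace=[(to_theta(x), y) for x, y in trace2],
    )


def _theta_to_config(theta: dict[str, float], base: ImagingConfig) -> ImagingConfig:
    min_size = min(theta["min_size"], theta["max_size"] * 0.9)
    return replace(base, min_intensity=theta["min_intensity"], min_size=min_size, max_size=theta["max_size"])


def _expected_improvement(gp: GaussianProcessRegressor, x: np.ndarray, best: float) -> np.ndarray:
    mu, sd = gp.predict(x, return_std=True)
    sd = np.maximum(sd, 1e-12)
    z = (mu - best) / sd
    return (mu - best) * norm.cdf(z) + sd * norm.pdf(z)


def _bayes_maximize(
    func,
    dim: int,
    budget: int,
    n_initial: int,
    rng: np.random.Generator,
    x_start: np.ndarray | None = None,
) -> tuple[np.ndarray, float, list[tuple[np.ndarray, float]]]:
    """Simple GP + expected-improvement loop over the unit cube."""
    xs = [rng.random(dim) for _ in range(n_initial)]
    if x_start is not None:
        xs[0] = np.asarray(x_start, dtype=float)
    ys = [func(x) for x in xs]
    trace = list(zip(xs, ys))
    kernel = ConstantKernel(1.0, (1e-3, 1e6)) * Matern(
        length_scale=np.full(dim, 0.3), length_scale_bounds=(0.03, 10.0), nu=2.5
    )
    for _ in range(budget - n_initial):
        gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, alpha=1e-6, random_state=int(rng.integers(2**31))
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # GP hyperparameter bound chatter
            gp.fit(np.array(xs), np.array(ys))
        candidates = rng.random((512, dim))
        ei = _expected_improvement(gp, candidates, max(ys))
        x_next = candidates[int(np.argmax(ei))]
        xs.append(x_next)
        y = func(x_next)
        ys.append(y)
        trace.append((x_next, y))
    best = int(np.argmax(ys))
    return xs[best], ys[best], trace


def optimize_parameters(
    videos: list,
    spec: OptimizerSpec | None = None,
    base_config: ImagingConfig | None = None,
) -> OptimizationReport:
    """Two-stage lexicographic Bayesian optimization of detection parameters."""
    spec = spec or OptimizerSpec()
    base_config = base_config or ImagingConfig()
    rng = np.random.default_rng(spec.seed)
    subset = sample_subset(videos, spec, seed=int(rng.integers(2**31)))

    cache: dict[tuple[float, ...], dict[int, list[tuple[int, int]]]] = {}

    def counts_for(theta: dict[str, float]) -> dict[int, list[tuple[int, int]]]:
        key = tuple(round(theta[n], 10) for n in PARAM_NAMES)
        if key not in cache:
            cache[key] = _counts_by_video(videos, subset, _theta_to_config(theta, base_config))
        return cache[key]

    result = lexicographic_maximize(
        lambda t: objective_usable(counts_for(t)),
        lambda t: objective_unusable(counts_for(t)),
        spec.bounds,
        budget=spec.budget,
        n_initial=spec.n_initial,
        constraint_fraction=spec.constraint_fraction,
        seed=int(rng.integers(2**31)),
    )
    return OptimizationReport(
        theta=result.theta,
        n_max=result.n_max,
        f1=result.f1,
        f2=result.f2,
        subset=subset,
        stage1_trace=result.stage1_trace,
        stage2_trace=result.stage2_trace,
    )
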
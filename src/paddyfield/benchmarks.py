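"""Desk-scale benchmark objectives and the evaluation harness.

Three objective families exercise the optimizer:

* a two-dimensional bimodal surface with a broad local peak at (0.5, 0.5)
  and a steep global peak at (0.6, 0.1); a run "succeeds" when it scores
  above 0.81, which only the global peak exceeds;
* interpolation of the Gramacy & Lee function
  ``f(x) = sin(10*pi*x)/(2x) + (x-1)**4`` on [-0.5, 2.5] by a 32nd-degree
  trigonometric polynomial with 65 coefficients in [-1, 1], scored by mean
  squared error on a 3001-point grid;
* Tversky set similarity over integer bit indices (Tanimoto when
  alpha = beta = 1), the fitness used for fingerprint-matching objectives.

A uniform random-search baseline and a repeat-level harness with preset
configurations round out the module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Set

import numpy as np

from .engine import RunnerConfig, run_trial
from .param_space import ParameterSpec

__all__ = [
    "BimodalSurface",
    "bimodal",
    "gramacy_lee",
    "GL_GRID",
    "TrigPolynomial",
    "trig_poly_eval",
    "interpolation_mse",
    "tversky",
    "RepeatRecord",
    "BenchmarkResult",
    "random_search",
    "run_benchmark",
    "BIMODAL_SUCCESS_THRESHOLD",
    "bimodal_specs",
    "gramacy_lee_specs",
    "BIMODAL_PRESET",
    "GRAMACY_LEE_PRESET",
]

BIMODAL_SUCCESS_THRESHOLD = 0.81


@dataclass(frozen=True)
class BimodalSurface:
    """Sum of two isotropic Gaussian bumps on the unit square.

    The local peak is broad (easy to find, below the success threshold);
    the global peak is steep and narrow, so uninformed sampling rarely
    lands on it.  Defaults keep the 0.81 threshold between the two peak
    heights.
    """

    local_center: tuple = (0.5, 0.5)
    local_amplitude: float = 0.80
    local_width: float = 0.15
    global_center: tuple = (0.6, 0.1)
    global_amplitude: float = 1.00
    global_width: float = 0.05

    def __call__(self, x: float, y: float) -> float:
        return bimodal(x, y, self)


def bimodal(x: float, y: float, surface: Optional[BimodalSurface] = None) -> float:
    """Evaluate the reconstructed bimodal test surface at (x, y)."""
    s = surface or BimodalSurface()
    lx, ly = s.local_center
    gx, gy = s.global_center
    local = s.local_amplitude * math.exp(
        -((x - lx) ** 2 + (y - ly) ** 2) / (2 * s.local_width**2)
    )
    glob = s.global_amplitude * math.exp(
        -((x - gx) ** 2 + (y - gy) ** 2) / (2 * s.global_width**2)
    )
    return local + glob


def gramacy_lee(x):
    """Gramacy & Lee function sin(10*pi*x)/(2x) + (x-1)**4.

    The sinc-like term has a removable singularity at x = 0, filled by its
    limit 5*pi (so f(0) = 5*pi + 1).  Accepts scalars or arrays.
    """
    x = np.asarray(x, dtype=float)
    quartic = (x - 1.0) ** 4
    with np.errstate(divide="ignore", invalid="ignore"):
        osc = np.where(
            x == 0.0, 5.0 * np.pi, np.sin(10.0 * np.pi * x) / (2.0 * x)
        )
    out = osc + quartic
    return float(out) if out.ndim == 0 else out


#: inclusive 3001-point evaluation grid from -0.5 to 2.5, step 0.001
GL_GRID = np.linspace(-0.5, 2.5, 3001)
_GL_TARGET = gramacy_lee(GL_GRID)

#: number of harmonics in the interpolating trigonometric polynomial
TRIG_DEGREE = 32
N_COEFFS = 1 + 2 * TRIG_DEGREE
#: base angular frequency of the harmonic basis.  The classical degree-n
#: trigonometric polynomial uses unit angular frequency (harmonics of
#: cos(kx), sin(kx)); with this basis, box-constrained least squares can
#: drive the interpolation error on the evaluation window to ~0 with all
#: 65 coefficients inside [-1, 1], so near-perfect fits are attainable.
TRIG_OMEGA = 1.0


@dataclass(frozen=True)
class TrigPolynomial:
    """T(x) = c0 + sum_k a_k cos(k*omega*x) + b_k sin(k*omega*x), k=1..32.

    ``coeffs`` is the flat 65-vector (c0, a_1, b_1, ..., a_32, b_32).
    """

    coeffs: tuple
    omega: float = TRIG_OMEGA

    def __post_init__(self) -> None:
        if len(self.coeffs) != N_COEFFS:
            raise ValueError(f"expected {N_COEFFS} coefficients")


def _basis(x: np.ndarray, omega: float) -> np.ndarray:
    """(len(x), 65) design matrix [1, cos(kwx), sin(kwx), ...]."""
    x = np.asarray(x, dtype=float)
    k = np.arange(1, TRIG_DEGREE + 1)
    phase = np.outer(x, k) * omega
    cols = [np.ones_like(x)]
    for j in range(TRIG_DEGREE):
        cols.append(np.cos(phase[:, j]))
        cols.append(np.sin(phase[:, j]))
    return np.column_stack(cols)


_GL_BASIS = _basis(GL_GRID, TRIG_OMEGA)


def trig_poly_eval(p: TrigPolynomial, x) -> float:
    """Evaluate a trigonometric polynomial at x (scalar or array)."""
    scalar = np.isscalar(x)
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    vals = _basis(arr, p.omega) @ np.asarray(p.coeffs, dtype=float)
    return float(vals[0]) if scalar else vals


def interpolation_mse(coeffs) -> float:
    """MSE between the trig polynomial and Gramacy & Lee on the 3001 grid."""
    c = np.asarray(coeffs, dtype=float)
    if c.shape != (N_COEFFS,):
        raise ValueError(f"expected {N_COEFFS} coefficients")
    resid = _GL_BASIS @ c - _GL_TARGET
    return float(np.mean(resid * resid))


def tversky(X: Set, Y: Set, alpha: float = 0.5, beta: float = 0.01) -> float:
    """Tversky similarity |X∩Y| / (|X∩Y| + a|X\\Y| + b|Y\\X|) in [0, 1].

    With alpha = beta = 1 this is the Tanimoto coefficient.  Two empty
    sets return 0 by convention (0/0 case).
    """
    X, Y = set(X), set(Y)
    inter = len(X & Y)
    denom = inter + alpha * len(X - Y) + beta * len(Y - X)
    if denom == 0:
        return 0.0
    return inter / denom


# ---------------------------------------------------------------------------
# harness


@dataclass
class RepeatRecord:
    """One repeat of a benchmark: best score, per-generation trajectories."""

    seed: int
    best_score: float
    n_evaluations: int
    best_trajectory: List[float] = field(default_factory=list)
    mean_trajectory: List[float] = field(default_factory=list)


@dataclass
class BenchmarkResult:
    """Repeat-level summary of a benchmark run."""

    name: str
    algorithm: str
    repeats: List[RepeatRecord]

    @property
    def best_scores(self) -> np.ndarray:
        return np.array([r.best_score for r in self.repeats])

    @property
    def mean_best(self) -> float:
        return float(self.best_scores.mean())

    @property
    def sd_best(self) -> float:
        return float(self.best_scores.std(ddof=1)) if len(self.repeats) > 1 else 0.0

    def success_count(self, threshold: float) -> int:
        return int((self.best_scores > threshold).sum())

    def to_frame(self):
        import pandas as pd

        rows = []
        for r in self.repeats:
            means = r.mean_trajectory or [float("nan")] * len(r.best_trajectory)
            for gen, (b, m) in enumerate(zip(r.best_trajectory, means)):
                rows.append(
                    {
                        "name": self.name,
                        "algorithm": self.algorithm,
                        "seed": r.seed,
                        "generation": gen,
                        "best": b,
                        "mean": m,
                        "best_score": r.best_score,
                        "n_evaluations": r.n_evaluations,
                    }
                )
        return pd.DataFrame(rows)


def random_search(
    objective: Callable[[np.ndarray], float],
    specs: Sequence[ParameterSpec],
    n_evals: int,
    rng: np.random.Generator,
) -> RepeatRecord:
    """I.i.d. uniform draws over the box limits, keeping the running best."""
    if n_evals < 1:
        raise ValueError("n_evals must be >= 1")
    lo = np.array([s.lower for s in specs], dtype=float)
    hi = np.array([s.upper for s in specs], dtype=float)
    if np.any(~np.isfinite(lo)) or np.any(~np.isfinite(hi)):
        raise ValueError("random_search requires two-sided limits")
    best = -math.inf
    trajectory = []
    for _ in range(n_evals):
        x = rng.uniform(lo, hi)
        y = float(objective(x))
        if y > best:
            best = y
        trajectory.append(best)
    return RepeatRecord(
        seed=-1,
        best_score=best,
        n_evaluations=n_evals,
        best_trajectory=trajectory,
        mean_trajectory=[],
    )


def pollination_factor_isolated_value() -> float:
    """The density bonus of a plant with no neighbors, to three decimals.

    Independent of nu_max: exp(0/nu_max - 1) = 1/e for any selection size.
    """
    from .engine import pollination_factor

    values = {round(pollination_factor(0, nu_max), 3) for nu_max in range(1, 11)}
    assert len(values) == 1
    return values.pop()


def bimodal_specs() -> List[ParameterSpec]:
    """(x, y) on [0, 1] with 0.01 sow resolution."""
    return [
        ParameterSpec(
            name=n,
            lower=0.0,
            upper=1.0,
            init_range=(0.0, 1.0),
            init_resolution=0.01,
        )
        for n in ("x", "y")
    ]


def gramacy_lee_specs() -> List[ParameterSpec]:
    """65 trig coefficients on [-1, 1] with 0.05 sow resolution."""
    return [
        ParameterSpec(
            name=f"c{i}",
            lower=-1.0,
            upper=1.0,
            init_range=(-1.0, 1.0),
            init_resolution=0.05,
        )
        for i in range(N_COEFFS)
    ]


#: documented preset for the bimodal maxima search
BIMODAL_PRESET = dict(
    n_random_seeds=50,
    threshold=50,
    s_max=100,
    radius=0.02,
    iterations=5,
    mode="generational",
    gaussian="scaled",
)

#: documented preset for the Gramacy & Lee interpolation benchmark
GRAMACY_LEE_PRESET = dict(
    n_random_seeds=25,
    threshold=25,
    s_max=25,
    radius=0.02,
    iterations=10,
    mode="generational",
    gaussian="default",
)

#: random-search evaluation budget for Gramacy & Lee
GL_RANDOM_BUDGET = 5000


def _paddy_repeat(
    objective: Callable[[np.ndarray], float],
    specs: Sequence[ParameterSpec],
    preset: dict,
    seed: int,
) -> RepeatRecord:
    config = RunnerConfig(rng_seed=seed, **preset)
    state = run_trial(objective, specs, config)
    best_traj, mean_traj = [], []
    running_best = -math.inf
    for gen in range(state.current_iteration + 1):
        plants = state.plants_of_generation(gen)
        if not plants:
            break
        fits = np.array([p.fitness for p in plants])
        running_best = max(running_best, float(fits.max()))
        best_traj.append(running_best)
        mean_traj.append(float(fits.mean()))
    return RepeatRecord(
        seed=seed,
        best_score=running_best,
        n_evaluations=len(state.population),
        best_trajectory=best_traj,
        mean_trajectory=mean_traj,
    )


def run_benchmark(
    name: str,
    algorithm: str,
    repeats: int,
    seed: int = 0,
    config_overrides: Optional[dict] = None,
    random_budget: Optional[int] = None,
) -> BenchmarkResult:
    """Run a named benchmark with Paddy or random search over seeded repeats.

    ``name`` is ``"bimodal"`` (score = surface value, success > 0.81) or
    ``"gramacy_lee"`` (score = negative interpolation MSE, so higher is
    better and ``-mean_best`` is the mean best MSE).  Repeat ``i`` uses
    rng seed ``seed + i``.  For random search on the bimodal surface a
    ``random_budget`` must be given (matched-budget comparisons take it
    from a paired Paddy run's evaluation count).
    """
    if name == "bimodal":
        surface = BimodalSurface()
        objective = lambda v: bimodal(v[0], v[1], surface)
        specs = bimodal_specs()
        preset = dict(BIMODAL_PRESET)
        default_budget = None
    elif name == "gramacy_lee":
        objective = lambda v: -interpolation_mse(v)
        specs = gramacy_lee_specs()
        preset = dict(GRAMACY_LEE_PRESET)
        default_budget = GL_RANDOM_BUDGET
    else:
        raise ValueError(f"unknown benchmark {name!r}")
    if config_overrides:
        preset.update(config_overrides)

    records = []
    for i in range(repeats):
        run_seed = seed + i
        if algorithm == "paddy":
            rec = _paddy_repeat(objective, specs, preset, run_seed)
        elif algorithm == "random":
            budget = random_budget or default_budget
            if budget is None:
                raise ValueError(
                    f"random search on {name!r} needs an explicit budget"
                )
            rec = random_search(
                objective, specs, budget, np.random.default_rng(run_seed)
            )
            rec.seed = run_seed
        else:
            raise ValueError(f"unknown algorithm {algorithm!r}")
        records.append(rec)
    return BenchmarkResult(name=name, algorithm=algorithm, repeats=records)
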
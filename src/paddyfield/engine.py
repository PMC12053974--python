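"""Five-phase Paddy field algorithm engine.

The Paddy field algorithm (PFA) is a derivative-free evolutionary optimizer
that maximizes an objective ``y = f(x)`` through repeated rounds of

a. **sowing** — random parameter vectors form the initial seed population;
b. **selection** — the top plants by fitness are retained (from the whole
   archive in *population* mode, from the previous generation only in
   *generational* mode);
c. **seeding** — each selected plant is awarded potential seeds
   ``s = s_max * (y* - y_t) / (y_max - y_t)`` from its min-max normalized
   fitness, where ``y_t`` is the fitness of the lowest-ranked selected
   plant;
d. **pollination** — a density bonus ``U = exp(nu/nu_max - 1)`` in
   ``[1/e, 1]`` scales each plant's seeds by how many selected plants lie
   within radius ``r`` of it (Euclidean distance in parameter space), so
   dense clusters of good solutions are reinforced;
e. **dispersion** — children are sampled per-dimension from a Gaussian
   centered on the parent (sd 0.2 by default, or a heritable
   ``sigma = (0.2**10)**delta`` in scaled mode), clamped to limits.

The loop terminates when the iteration budget is exhausted or when the
selected plants' fitness range collapses (``y_t == y_max``).
"""

from __future__ import annotations

import json
import math
import os
import tempfile
from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .param_space import (
    ParameterSpec,
    clamp,
    denormalize,
    normalize,
    random_sow,
    round_half_away,
)

__all__ = [
    "Plant",
    "RunnerConfig",
    "SelectionResult",
    "PollinationPlan",
    "TrialState",
    "ObjectiveError",
    "CheckpointError",
    "select_plants",
    "seed_count",
    "count_neighbors",
    "adaptive_radius",
    "pollination_factor",
    "pollinate",
    "disperse",
    "check_termination",
    "run_trial",
    "resume_trial",
    "save_trial",
    "load_trial",
]

CHECKPOINT_FORMAT_VERSION = 1

#: absolute tolerance treating a fitness plateau as converged
CONVERGENCE_ATOL = 1e-12

#: dispersal standard deviation in default Gaussian mode
DEFAULT_SIGMA = 0.2

#: base of the scaled-Gaussian sd, sigma = SCALED_BASE ** delta
SCALED_BASE = 0.2 ** 10


class ObjectiveError(RuntimeError):
    """An objective returned a non-finite fitness or raised."""


class CheckpointError(RuntimeError):
    """A trial checkpoint could not be deserialized."""


@dataclass
class Plant:
    """An evaluated candidate: parameter vector ``x`` with fitness ``y``.

    ``delta`` is the heritable Gaussian scaling term (0 for generation-0
    plants and in default-Gaussian mode).
    """

    id: int
    params: np.ndarray
    fitness: float
    delta: float = 0.0
    generation: int = 0
    parent_id: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "params": [float(v) for v in self.params],
            "fitness": self.fitness,
            "delta": self.delta,
            "generation": self.generation,
            "parent_id": self.parent_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Plant":
        return cls(
            id=int(d["id"]),
            params=np.asarray(d["params"], dtype=float),
            fitness=float(d["fitness"]),
            delta=float(d["delta"]),
            generation=int(d["generation"]),
            parent_id=d.get("parent_id"),
        )


@dataclass(frozen=True)
class RunnerConfig:
    """PFA hyperparameters.

    ``threshold`` is the *count* of plants selected each iteration (the
    integer sense of y_t); ``s_max`` is the maximum seeds awarded to the
    best selected plant (called Q_max in some PFA codebases); ``radius``
    is the neighborhood radius r for the pollination density bonus.
    """

    n_random_seeds: int = 25
    threshold: int = 25
    s_max: int = 25
    radius: float = 0.02
    iterations: int = 10
    mode: str = "generational"
    gaussian: str = "default"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name, floor in (
            ("n_random_seeds", 1), ("threshold", 1), ("s_max", 1),
            ("iterations", 0),
        ):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < floor:
                raise ValueError(
                    f"config field {name!r} must be an integer >= {floor}"
                )
        if not self.radius > 0:
            raise ValueError("config field 'radius' must be > 0")
        if self.mode not in ("population", "generational"):
            raise ValueError("config field 'mode' must be population|generational")
        if self.gaussian not in ("default", "scaled"):
            raise ValueError("config field 'gaussian' must be default|scaled")

    def to_dict(self) -> dict:
        return {
            "n_random_seeds": self.n_random_seeds,
            "threshold": self.threshold,
            "s_max": self.s_max,
            "radius": self.radius,
            "iterations": self.iterations,
            "mode": self.mode,
            "gaussian": self.gaussian,
            "rng_seed": self.rng_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunnerConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown runner config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class SelectionResult:
    """Selected plants sorted ascending by fitness.

    ``pivot_fitness`` (the fitness sense of y_t) anchors the seeding
    normalization; ``best_fitness`` is y_max.
    """

    selected: List[Plant]
    pivot_fitness: float
    best_fitness: float


@dataclass
class PollinationPlan:
    """Per-selected-plant seeding/pollination bookkeeping for one iteration."""

    s_raw: List[float]
    neighbors: List[int]
    pollination_factor: List[float]
    n_children: List[int]
    effective_radius: float
    radius_fallback: bool


@dataclass
class TrialState:
    """The full resumable state of a PFA trial."""

    config: RunnerConfig
    specs: List[ParameterSpec]
    population: List[Plant]
    current_iteration: int = 0
    rng: Optional[np.random.Generator] = None
    terminated: bool = False
    termination_reason: Optional[str] = None
    iteration_log: List[dict] = field(default_factory=list)

    @property
    def best(self) -> Plant:
        return max(self.population, key=lambda p: (p.fitness, -p.id))

    def plants_of_generation(self, gen: int) -> List[Plant]:
        return [p for p in self.population if p.generation == gen]


# ---------------------------------------------------------------------------
# phase operations


def select_plants(state: TrialState) -> SelectionResult:
    """Selection phase: top-k plants by fitness from the mode's pool.

    ``k`` is the configured threshold when the pool is large enough;
    otherwise (e.g. right after initiation) the threshold falls back to
    round(0.75 * pool size), minimum 1.  Fitness ties break toward the
    older plant (lower id).
    """
    if state.config.mode == "population":
        pool = list(state.population)
    else:
        pool = state.plants_of_generation(state.current_iteration)
    if not pool:
        raise RuntimeError("selection pool is empty")
    if len(pool) >= state.config.threshold:
        k = state.config.threshold
    else:
        k = max(1, int(round_half_away(0.75 * len(pool))))
    ranked = sorted(pool, key=lambda p: (-p.fitness, p.id))[:k]
    selected = ranked[::-1]  # ascending fitness
    return SelectionResult(
        selected=selected,
        pivot_fitness=selected[0].fitness,
        best_fitness=selected[-1].fitness,
    )


def seed_count(y_star: float, pivot: float, best: float, s_max: int) -> float:
    """Seeding phase: potential seeds s = s_max * (y* - y_t)/(y_max - y_t)."""
    if best == pivot:
        raise ZeroDivisionError(
            "seed_count with y_max == y_t: the trial should have terminated "
            "as converged before seeding"
        )
    s = s_max * (y_star - pivot) / (best - pivot)
    # clip float roundoff so 0 <= s <= s_max holds exactly
    return min(max(s, 0.0), float(s_max))


def count_neighbors(
    coords: np.ndarray, radius: float
) -> np.ndarray:
    """Number of other plants strictly within ``radius`` of each plant.

    ``coords`` is an (n, d) array of plant positions (normalized
    coordinates when every dimension normalizes, else raw units).
    A pair at distance exactly ``radius`` is *not* a neighbor pair.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    d = cdist(coords, coords)
    within = d < radius
    np.fill_diagonal(within, False)
    return within.sum(axis=1).astype(int)


def adaptive_radius(
    coords: np.ndarray, radius: float
) -> Tuple[np.ndarray, float, bool]:
    """Neighbor counts with the quantile-ladder fallback radius.

    The user radius is tried first.  If no plant has any neighbor, the
    0.75 quantile of the pairwise-distance distribution replaces the
    radius; the quantile is lowered by 0.05 while counts stay all-zero,
    down to 0.05.  If that still yields no neighbors (or there is a single
    plant), every plant is assigned exactly one neighbor, which makes
    ``nu = nu_max`` and drops the pollination penalty for the iteration.

    Returns ``(counts, effective_radius, fallback_used)``.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = coords.shape[0]
    counts = count_neighbors(coords, radius)
    if counts.any():
        return counts, radius, False
    if n > 1:
        d = cdist(coords, coords)
        pair_dists = d[~np.eye(n, dtype=bool)]  # ordered pairs, both directions
        q = 0.75
        while q >= 0.05 - 1e-9:
            r_q = float(np.quantile(pair_dists, q))
            counts = count_neighbors(coords, r_q)
            if counts.any():
                return counts, r_q, True
            q -= 0.05
    return np.ones(n, dtype=int), radius, True


def pollination_factor(nu: int, nu_max: int) -> float:
    """Density bonus U = exp(nu/nu_max - 1), from 1/e (isolated) to 1."""
    if nu_max < 1:
        raise ValueError("nu_max must be >= 1")
    if not 0 <= nu <= nu_max:
        raise ValueError("nu must satisfy 0 <= nu <= nu_max")
    return math.exp(nu / nu_max - 1.0)


def pollinate(
    selection: SelectionResult,
    neighbor_counts: Sequence[int],
    s_max: int,
    effective_radius: float,
    radius_fallback: bool,
) -> PollinationPlan:
    """Combine seeding and the density bonus into integer child counts.

    ``S = round(U * s)`` (half away from zero), floored at 0; the best
    selected plant always emits at least one child so an iteration can
    never go extinct.
    """
    selected = selection.selected
    nu_max = max(int(v) for v in neighbor_counts)
    if nu_max < 1:
        # adaptive_radius guarantees a nonzero count or all-ones
        raise RuntimeError("pollinate called with all-zero neighbor counts")
    s_raw, factors, n_children = [], [], []
    for plant, nu in zip(selected, neighbor_counts):
        s = seed_count(
            plant.fitness, selection.pivot_fitness, selection.best_fitness, s_max
        )
        u = pollination_factor(int(nu), nu_max)
        n = max(0, int(round_half_away(u * s)))
        s_raw.append(s)
        factors.append(u)
        n_children.append(n)
    if s_max >= 1 and n_children[-1] < 1:
        n_children[-1] = 1  # best plant (last in ascending order)
    return PollinationPlan(
        s_raw=s_raw,
        neighbors=[int(v) for v in neighbor_counts],
        pollination_factor=factors,
        n_children=n_children,
        effective_radius=effective_radius,
        radius_fallback=radius_fallback,
    )


def disperse(
    parent: Plant,
    n_children: int,
    specs: Sequence[ParameterSpec],
    gaussian: str,
    rng: np.random.Generator,
) -> List[Tuple[np.ndarray, float]]:
    """Dispersion phase: Gaussian children around a parent.

    Each child's value per dimension is drawn from Normal(parent value,
    sigma), in normalized coordinates when the dimension normalizes (then
    denormalized), clamped to limits and rounded for integer kinds.

    Default mode uses sigma = 0.2.  Scaled mode first mutates the heritable
    scaling term, delta_child ~ Normal(parent delta, 0.2), then uses
    sigma = (0.2**10) ** delta_child — so delta 0 gives sigma 1 (wide
    exploration) and delta 1 gives sigma ~1e-7 (fine refinement).

    Returns ``(params, delta)`` pairs.
    """
    children: List[Tuple[np.ndarray, float]] = []
    for _ in range(n_children):
        if gaussian == "scaled":
            delta_child = float(rng.normal(parent.delta, 0.2))
            sigma = SCALED_BASE ** delta_child
        else:
            delta_child = 0.0
            sigma = DEFAULT_SIGMA
        values = np.empty(len(specs))
        for i, spec in enumerate(specs):
            if spec.normalize:
                mean = normalize(parent.params[i], spec)
                raw = denormalize(float(rng.normal(mean, sigma)), spec)
            else:
                raw = float(rng.normal(parent.params[i], sigma))
            values[i] = clamp(raw, spec)
        children.append((values, delta_child))
    return children


def check_termination(
    selection: SelectionResult, state: TrialState
) -> Optional[str]:
    """Convergence (y_t == y_max within tolerance) or exhausted budget."""
    if abs(selection.best_fitness - selection.pivot_fitness) <= CONVERGENCE_ATOL:
        return "converged_yt_equals_ymax"
    if state.current_iteration >= state.config.iterations:
        return "iterations_exhausted"
    return None


# ---------------------------------------------------------------------------
# trial driver


def _neighbor_coords(
    plants: Sequence[Plant], specs: Sequence[ParameterSpec]
) -> np.ndarray:
    """Plant coordinates for density counting.

    Normalized when every dimension normalizes (scale-free radii for
    heterogeneous parameters), raw units otherwise.
    """
    X = np.array([p.params for p in plants], dtype=float)
    if specs and all(s.normalize for s in specs):
        lo = np.array([s.lower for s in specs])
        hi = np.array([s.upper for s in specs])
        X = (X - lo) / (hi - lo)
    return X


def _evaluate(
    objective: Callable[[np.ndarray], float], params: np.ndarray
) -> float:
    try:
        y = float(objective(params))
    except Exception as exc:  # re-raise with plant context
        raise ObjectiveError(
            f"objective raised at x={np.asarray(params).tolist()}: {exc}"
        ) from exc
    if not math.isfinite(y):
        raise ObjectiveError(
            f"objective returned non-finite fitness {y!r} at "
            f"x={np.asarray(params).tolist()}"
        )
    return y


def run_trial(
    objective: Callable[[np.ndarray], float],
    specs: Sequence[ParameterSpec],
    config: RunnerConfig,
) -> TrialState:
    """Run a full PFA trial: sow, then iterate the five phases.

    The trial is fully reproducible under a fixed ``config.rng_seed``: one
    PCG64 stream drives sowing, delta inheritance and dispersion.
    """
    rng = np.random.default_rng(config.rng_seed)
    state = TrialState(
        config=config, specs=list(specs), population=[], rng=rng
    )
    X = random_sow(config.n_random_seeds, specs, rng)
    for row in X:
        state.population.append(
            Plant(
                id=len(state.population),
                params=row,
                fitness=_evaluate(objective, row),
                delta=0.0,
                generation=0,
            )
        )
    return _advance(state, objective)


def resume_trial(
    state: TrialState,
    objective: Callable[[np.ndarray], float],
    extra_iterations: int = 0,
) -> TrialState:
    """Continue a (possibly reloaded) trial for ``extra_iterations`` more.

    Resuming a converged trial is a no-op.  With a checkpoint written
    mid-trial, resume-then-run matches an uninterrupted run exactly.
    """
    if extra_iterations:
        state.config = replace(
            state.config, iterations=state.config.iterations + extra_iterations
        )
        if state.terminated and state.termination_reason == "iterations_exhausted":
            state.terminated = False
            state.termination_reason = None
    if state.terminated:
        return state
    return _advance(state, objective)


def _advance(
    state: TrialState, objective: Callable[[np.ndarray], float]
) -> TrialState:
    """Iterate select -> seed -> pollinate -> disperse -> evaluate."""
    config = state.config
    while not state.terminated:
        selection = select_plants(state)
        reason = check_termination(selection, state)
        if reason is not None:
            state.terminated = True
            state.termination_reason = reason
            break
        coords = _neighbor_coords(selection.selected, state.specs)
        counts, eff_r, fallback = adaptive_radius(coords, config.radius)
        plan = pollinate(selection, counts, config.s_max, eff_r, fallback)
        state.current_iteration += 1
        n_children = 0
        for parent, n in zip(selection.selected, plan.n_children):
            for params, delta_child in disperse(
                parent, n, state.specs, config.gaussian, state.rng
            ):
                state.population.append(
                    Plant(
                        id=len(state.population),
                        params=params,
                        fitness=_evaluate(objective, params),
                        delta=delta_child,
                        generation=state.current_iteration,
                        parent_id=parent.id,
                    )
                )
                n_children += 1
        state.iteration_log.append(
            {
                "iteration": state.current_iteration,
                "pool_size": len(selection.selected),
                "pivot_fitness": selection.pivot_fitness,
                "best_fitness": selection.best_fitness,
                "effective_radius": plan.effective_radius,
                "radius_fallback": plan.radius_fallback,
                "children": n_children,
            }
        )
    return state


# ---------------------------------------------------------------------------
# persistence


def _state_to_dict(state: TrialState) -> dict:
    return {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "config": state.config.to_dict(),
        "specs": [s.to_dict() for s in state.specs],
        "population": [p.to_dict() for p in state.population],
        "current_iteration": state.current_iteration,
        "rng_state": state.rng.bit_generator.state if state.rng else None,
        "terminated": state.terminated,
        "termination_reason": state.termination_reason,
        "iteration_log": state.iteration_log,
    }


def _state_from_dict(doc: dict) -> TrialState:
    version = doc.get("format_version")
    if version != CHECKPOINT_FORMAT_VERSION:
        raise CheckpointError(
            f"checkpoint format_version {version!r} not supported "
            f"(expected {CHECKPOINT_FORMAT_VERSION})"
        )
    rng = None
    if doc.get("rng_state") is not None:
        rng = np.random.default_rng(0)
        rng.bit_generator.state = doc["rng_state"]
    return TrialState(
        config=RunnerConfig.from_dict(doc["config"]),
        specs=[ParameterSpec.from_dict(d) for d in doc["specs"]],
        population=[Plant.from_dict(d) for d in doc["population"]],
        current_iteration=int(doc["current_iteration"]),
        rng=rng,
        terminated=bool(doc["terminated"]),
        termination_reason=doc.get("termination_reason"),
        iteration_log=list(doc.get("iteration_log", [])),
    )


def save_trial(state: TrialState, path: str) -> None:
    """Write a single-JSON checkpoint atomically (temp file + rename)."""
    doc = _state_to_dict(state)
    directory = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            json.dump(doc, fh)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def load_trial(path: str) -> TrialState:
    """Load a checkpoint; corrupt or truncated files raise CheckpointError."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise CheckpointError(f"cannot read checkpoint {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise CheckpointError(f"checkpoint {path} is not a JSON object")
    try:
        return _state_from_dict(doc)
    except CheckpointError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise CheckpointError(f"malformed checkpoint {path}: {exc}") from exc
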
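"""Sequential experimental planning over a finite condition grid.

The planner drives the Paddy field algorithm over a table of discrete
experimental conditions (e.g. a full-factorial assay screen): categorical
factor levels are embedded as evenly spaced coordinates in [0, 1], PFA
proposes points in that continuous space, and each proposal is mapped to
the nearest condition that has not yet been run.  After every round the
observed conditions' multi-metric readouts are re-normalized (1 = best,
0 = worst per metric, orientation-aware) and each condition is scored by
its negative Euclidean distance to the all-ones ideal point — only seen
experiments enter the normalization, so no information leaks from
unperformed conditions.

A campaign runs until the condition that is globally best under the
full-table ideal-point score has been performed (or the grid is
exhausted); its figure of merit is how many experiments that took.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .engine import (
    Plant,
    RunnerConfig,
    adaptive_radius,
    check_termination,
    disperse,
    pollinate,
    select_plants,
    TrialState,
)
from .param_space import ParameterSpec, random_sow, round_half_away

__all__ = [
    "ConditionTable",
    "CampaignState",
    "embed_levels",
    "nearest_unseen",
    "ideal_distance",
    "run_campaign",
    "synth_screen",
    "grid_scan",
]


def embed_levels(levels: Sequence) -> np.ndarray:
    """Map categorical levels (in table order) to evenly spaced [0, 1]."""
    n = len(levels)
    if n == 1:
        return np.array([0.5])
    return np.linspace(0.0, 1.0, n)


@dataclass
class ConditionTable:
    """A discrete experiment grid with per-condition metric readouts.

    ``conditions`` holds the categorical factor levels (one row per
    condition), ``embedding`` the numeric coordinates (one [0, 1] axis per
    factor), ``metrics`` the (condition x metric) readout matrix, and
    ``orientation`` whether each metric is to be maximized or minimized.
    """

    conditions: pd.DataFrame
    embedding: np.ndarray
    metrics: np.ndarray
    orientation: List[str]
    metric_names: List[str]

    def __post_init__(self) -> None:
        n = len(self.conditions)
        if self.embedding.shape[0] != n or self.metrics.shape[0] != n:
            raise ValueError("conditions, embedding and metrics row counts differ")
        if self.metrics.shape[1] != len(self.orientation):
            raise ValueError("one orientation per metric required")
        for o in self.orientation:
            if o not in ("maximize", "minimize"):
                raise ValueError(f"orientation must be maximize|minimize, got {o!r}")

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def n_factors(self) -> int:
        return self.embedding.shape[1]

    def global_best_index(self) -> int:
        """Best condition under ideal-point scoring of the *full* table.

        Used only to score a finished campaign, never inside one.
        """
        fitness = ideal_distance(self.metrics, self.orientation)
        return int(np.argmax(fitness))

    @classmethod
    def from_csv(
        cls,
        conditions_csv: str,
        metrics_csv: str,
        orientation: Sequence[str],
    ) -> "ConditionTable":
        """Build a table from ``index,factor...`` and ``index,metric...`` CSVs."""
        cond = pd.read_csv(conditions_csv)
        metr = pd.read_csv(metrics_csv)
        if "index" not in cond.columns or "index" not in metr.columns:
            raise ValueError("both CSVs need an 'index' column")
        cond = cond.set_index("index")
        metr = metr.set_index("index")
        if not cond.index.equals(metr.index):
            raise ValueError(
                "conditions and metrics CSVs have mismatched 'index' values"
            )
        factors = list(cond.columns)
        coords = np.zeros((len(cond), len(factors)))
        for j, f in enumerate(factors):
            levels = list(dict.fromkeys(cond[f]))  # order of appearance
            pos = dict(zip(levels, embed_levels(levels)))
            coords[:, j] = [pos[v] for v in cond[f]]
        return cls(
            conditions=cond.reset_index(drop=True),
            embedding=coords,
            metrics=metr.to_numpy(dtype=float),
            orientation=list(orientation),
            metric_names=list(metr.columns),
        )


@dataclass
class CampaignState:
    """Record of one planning campaign."""

    seen: List[int] = field(default_factory=list)
    history: List[dict] = field(default_factory=list)
    experiments_to_best: Optional[int] = None
    target_index: Optional[int] = None

    def observed_metrics(self, table: ConditionTable) -> np.ndarray:
        return table.metrics[self.seen]


def nearest_unseen(
    point: np.ndarray, table: ConditionTable, seen: Sequence[int]
) -> int:
    """Index of the unseen condition whose embedding is closest to ``point``.

    Euclidean distance; ties break toward the lower index.  Raises when
    every condition has been seen.
    """
    mask = np.ones(table.n_conditions, dtype=bool)
    mask[list(seen)] = False
    if not mask.any():
        raise LookupError("condition grid exhausted: every condition seen")
    candidates = np.flatnonzero(mask)
    diffs = table.embedding[candidates] - np.asarray(point, dtype=float)
    d2 = np.einsum("ij,ij->i", diffs, diffs)
    return int(candidates[np.argmin(d2)])


def ideal_distance(
    observed: np.ndarray, orientation: Sequence[str]
) -> np.ndarray:
    """Negative distance to the ideal point over min-max normalized metrics.

    Each metric column is normalized over the given rows so that 1 is best
    and 0 is worst (orientation-aware).  A metric constant across rows
    normalizes to 1 for everyone (it cannot discriminate, so it adds no
    distance).  Returns one fitness per row: 0 for a row best on every
    metric, ``-sqrt(m)`` for a row worst on all ``m`` metrics.
    """
    observed = np.atleast_2d(np.asarray(observed, dtype=float))
    norm = np.empty_like(observed)
    for j, orient in enumerate(orientation):
        col = observed[:, j]
        lo, hi = col.min(), col.max()
        if hi == lo:
            norm[:, j] = 1.0
        elif orient == "maximize":
            norm[:, j] = (col - lo) / (hi - lo)
        else:
            norm[:, j] = (hi - col) / (hi - lo)
    dist = np.sqrt(((norm - 1.0) ** 2).sum(axis=1))
    return -dist


def _campaign_specs(n_factors: int) -> List[ParameterSpec]:
    return [
        ParameterSpec(
            name=f"factor{j}",
            lower=0.0,
            upper=1.0,
            init_range=(0.0, 1.0),
            init_resolution=0.01,
        )
        for j in range(n_factors)
    ]


def run_campaign(
    table: ConditionTable,
    threshold: int = 5,
    s_max: int = 10,
    n_random_seeds: int = 10,
    radius: float = 0.02,
    gaussian: str = "default",
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> Tuple[int, CampaignState]:
    """Run one planning campaign; return (experiments_to_best, state).

    PFA proposals are mapped to unique unseen conditions; after each batch
    the whole pool of seen conditions is re-scored by :func:`ideal_distance`
    before selection, so plant fitnesses shift as evidence accrues
    (population-mode selection over the re-scored archive).  If selection
    degenerates (all selected scores equal), a fresh random batch is sown,
    which guarantees termination by exhaustion.  ``experiments_to_best``
    is the 1-based position at which the globally best condition entered
    the seen set (the initial sow counts).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    target = table.global_best_index()
    specs = _campaign_specs(table.n_factors)
    config = RunnerConfig(
        n_random_seeds=n_random_seeds,
        threshold=threshold,
        s_max=s_max,
        radius=radius,
        iterations=table.n_conditions,  # effectively unbounded; exhaustion stops first
        mode="population",
        gaussian=gaussian,
        rng_seed=seed,
    )
    campaign = CampaignState(target_index=target)
    plants: List[Plant] = []
    iteration = 0

    def sow_batch(n: int) -> int:
        added = 0
        for point in random_sow(n, specs, rng):
            if len(campaign.seen) >= table.n_conditions:
                break
            idx = nearest_unseen(point, table, campaign.seen)
            campaign.seen.append(idx)
            plants.append(
                Plant(
                    id=len(plants), params=table.embedding[idx],
                    fitness=0.0, generation=iteration,
                )
            )
            campaign.history.append(
                {"iteration": iteration, "condition": idx, "kind": "sow"}
            )
            added += 1
        return added

    sow_batch(n_random_seeds)

    while target not in campaign.seen and len(campaign.seen) < table.n_conditions:
        # re-score every seen condition from the enlarged pool (no leakage:
        # only observed rows enter the normalization)
        scores = ideal_distance(campaign.observed_metrics(table), table.orientation)
        for plant, sc in zip(plants, scores):
            plant.fitness = float(sc)
        state = TrialState(
            config=config, specs=specs, population=plants,
            current_iteration=iteration,
        )
        selection = select_plants(state)
        degenerate = (
            abs(selection.best_fitness - selection.pivot_fitness) <= 1e-12
        )
        iteration += 1
        added = 0
        if degenerate:
            added = sow_batch(n_random_seeds)
        else:
            coords = np.array([p.params for p in selection.selected])
            counts, eff_r, fb = adaptive_radius(coords, radius)
            plan = pollinate(selection, counts, s_max, eff_r, fb)
            for parent, n in zip(selection.selected, plan.n_children):
                for params, delta_child in disperse(
                    parent, n, specs, gaussian, rng
                ):
                    if len(campaign.seen) >= table.n_conditions:
                        break
                    idx = nearest_unseen(params, table, campaign.seen)
                    campaign.seen.append(idx)
                    plants.append(
                        Plant(
                            id=len(plants), params=table.embedding[idx],
                            fitness=0.0, delta=delta_child,
                            generation=iteration, parent_id=parent.id,
                        )
                    )
                    campaign.history.append(
                        {"iteration": iteration, "condition": idx,
                         "kind": "disperse", "parent": parent.id}
                    )
                    added += 1
        if added == 0 and len(campaign.seen) < table.n_conditions:
            # dispersal produced nothing new this round; sow to keep moving
            added = sow_batch(n_random_seeds)
            if added == 0:
                break

    campaign.experiments_to_best = (
        campaign.seen.index(target) + 1 if target in campaign.seen
        else len(campaign.seen)
    )
    return campaign.experiments_to_best, campaign


def synth_screen(
    factors: Sequence[int] = (6, 5, 6, 2),
    n_metrics: int = 10,
    noise_sd: float = 0.5,
    interaction_sd: float = 0.5,
    best_margin: float = 1.0,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> ConditionTable:
    """Synthetic full-factorial screen emulating a multi-metric assay panel.

    Builds every combination of the given factor level counts (default
    6 x 5 x 6 x 2 = 360 conditions, mirroring an electrochemiluminescence
    assay screen over anti-ID pairs, formats and antigen concentrations)
    with ``n_metrics`` readouts.  Each metric follows an additive
    per-factor effect model (level effects ~ N(0, 1)) plus a pairwise
    interaction between the first two factors (~ N(0, interaction_sd))
    and i.i.d. Gaussian measurement noise.

    The designated best condition is the argmax of the ideal-point score
    of the *noise-free* effect structure, additionally shifted by
    ``best_margin`` in each metric's favorable direction so it stays the
    unique global optimum under noise.  Placing the best at the
    structural optimum (rather than at an arbitrary cell) mirrors real
    screens, where the winning condition combines good factor levels and
    is therefore discoverable through the factor structure; with zero
    noise it is the global ideal-point optimum by construction.  The
    first half of the metrics are maximized, the rest minimized.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    combos = list(itertools.product(*(range(k) for k in factors)))
    n = len(combos)
    factor_names = [f"factor{j}" for j in range(len(factors))]
    conditions = pd.DataFrame(
        [[f"F{j}L{lvl}" for j, lvl in enumerate(c)] for c in combos],
        columns=factor_names,
    )
    embeddings = [embed_levels(range(k)) for k in factors]
    coords = np.array(
        [[embeddings[j][lvl] for j, lvl in enumerate(c)] for c in combos]
    )

    base = np.zeros((n, n_metrics))
    effects = [rng.normal(0.0, 1.0, size=(k, n_metrics)) for k in factors]
    inter = rng.normal(0.0, interaction_sd, size=(factors[0], factors[1], n_metrics))
    for i, combo in enumerate(combos):
        row = sum(effects[j][lvl] for j, lvl in enumerate(combo))
        base[i] = row + inter[combo[0], combo[1]]

    orientation = ["maximize"] * (n_metrics - n_metrics // 2) + [
        "minimize"
    ] * (n_metrics // 2)
    planted = int(np.argmax(ideal_distance(base, orientation)))
    metrics = base + rng.normal(0.0, noise_sd, size=base.shape)
    signs = np.where(np.array(orientation) == "maximize", 1.0, -1.0)
    metrics[planted] += best_margin * signs

    return ConditionTable(
        conditions=conditions,
        embedding=coords,
        metrics=metrics,
        orientation=orientation,
        metric_names=[f"metric{j}" for j in range(n_metrics)],
    )


def grid_scan(
    table: ConditionTable,
    thresholds: Sequence[int],
    s_max_values: Sequence[int],
    repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean experiments-to-best across a (threshold, s_max) grid.

    Each cell averages ``repeats`` campaigns with distinct derived seeds.
    Returns a tidy frame with columns threshold, s_max, mean_experiments, sd.
    """
    if not thresholds or not s_max_values:
        raise ValueError("threshold and s_max value lists must be nonempty")
    rows = []
    for ti, t in enumerate(thresholds):
        for si, s in enumerate(s_max_values):
            counts = []
            for r in range(repeats):
                run_seed = seed + 100_000 * ti + 1000 * si + r
                n_exp, _ = run_campaign(
                    table, threshold=t, s_max=s, seed=run_seed
                )
                counts.append(n_exp)
            counts = np.array(counts, dtype=float)
            rows.append(
                {
                    "threshold": t,
                    "s_max": s,
                    "mean_experiments": float(counts.mean()),
                    "sd": float(counts.std(ddof=1)) if repeats > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)
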
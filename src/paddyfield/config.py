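"""JSON configuration parsing and the built-in objective registry.

A run config is a single JSON document::

    {
      "parameters": [
        {"name": "x", "kind": "continuous", "lower": 0.0, "upper": 1.0,
         "init_range": [0.0, 1.0], "init_resolution": 0.01,
         "normalize": false},
        ...
      ],
      "runner": {"n_random_seeds": 25, "threshold": 25, "s_max": 25,
                 "radius": 0.02, "iterations": 10,
                 "mode": "generational", "gaussian": "default",
                 "rng_seed": 0}
    }

Validation errors name the offending key so CLI users can fix configs
without reading tracebacks.
"""

from __future__ import annotations

import json
from typing import Callable, List, Sequence, Set, Tuple

import numpy as np

from .benchmarks import bimodal, interpolation_mse, tversky, N_COEFFS
from .engine import RunnerConfig
from .param_space import ParameterSpec

__all__ = [
    "ConfigError",
    "load_config",
    "parse_config",
    "resolve_objective",
    "registered_objectives",
    "load_bitset",
]


class ConfigError(ValueError):
    """A config document failed validation; the message names the key."""


def parse_config(doc: dict) -> Tuple[List[ParameterSpec], RunnerConfig]:
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a JSON object")
    if "parameters" not in doc or not doc["parameters"]:
        raise ConfigError("config key 'parameters' missing or empty")
    specs = []
    for i, pd_ in enumerate(doc["parameters"]):
        try:
            specs.append(ParameterSpec.from_dict(pd_))
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"parameters[{i}]: {exc}") from exc
    runner = doc.get("runner", {})
    try:
        config = RunnerConfig.from_dict(runner)
    except (TypeError, ValueError) as exc:
        # surface the offending field name when the dataclass names it
        raise ConfigError(f"runner: {exc}") from exc
    return specs, config


def load_config(path: str) -> Tuple[List[ParameterSpec], RunnerConfig]:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ConfigError(f"config {path} is not valid JSON: {exc}") from exc
    return parse_config(doc)


def load_bitset(path: str) -> Set[int]:
    """Read a set of integer bit indices (JSON array or one-per-line text)."""
    with open(path) as fh:
        text = fh.read().strip()
    if text.startswith("["):
        return {int(v) for v in json.loads(text)}
    return {int(line) for line in text.splitlines() if line.strip()}


def _sphere(v: np.ndarray) -> float:
    return -float(np.dot(v, v))


def _bimodal_objective(v: np.ndarray) -> float:
    if len(v) != 2:
        raise ConfigError("objective 'bimodal' needs exactly 2 parameters")
    return bimodal(v[0], v[1])


def _gramacy_objective(v: np.ndarray) -> float:
    if len(v) != N_COEFFS:
        raise ConfigError(
            f"objective 'gramacy_lee' needs exactly {N_COEFFS} parameters"
        )
    return -interpolation_mse(v)


def registered_objectives() -> List[str]:
    return ["bimodal", "gramacy_lee", "sphere", "tversky-target"]


def resolve_objective(
    name: str, bits_path: str | None = None
) -> Callable[[np.ndarray], float]:
    """Map an objective name to a callable over parameter vectors.

    ``tversky-target`` scores the on-bits of a 0/1 integer parameter
    vector against a target bit set loaded from ``bits_path``
    (alpha 0.5, beta 0.01).  Planner workflows use the ``plan`` and
    ``scan`` subcommands rather than a registered objective.
    """
    if name == "bimodal":
        return _bimodal_objective
    if name == "gramacy_lee":
        return _gramacy_objective
    if name == "sphere":
        return _sphere
    if name == "tversky-target":
        if bits_path is None:
            raise ConfigError(
                "objective 'tversky-target' requires --bits with the target "
                "bit-set file"
            )
        target = load_bitset(bits_path)

        def _tversky_objective(v: np.ndarray) -> float:
            on = {i for i, x in enumerate(v) if round(x) >= 1}
            return tversky(on, target, alpha=0.5, beta=0.01)

        return _tversky_objective
    raise ConfigError(
        f"unknown objective {name!r}; registered objectives: "
        f"{', '.join(registered_objectives())} "
        "(use the 'plan'/'scan' subcommands for planner workflows)"
    )
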
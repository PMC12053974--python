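"""Parameter-space declarations for the Paddy field algorithm.

Each optimizable dimension is declared as a :class:`ParameterSpec` carrying
its kind (continuous or integer), optional one- or two-sided limits, the
range and resolution used for the initial random sow, and whether dispersal
should operate in min-max normalized coordinates.  The engine only ever
touches dimensions through the operations here: clamping, normalization,
integer rounding and grid sowing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ParameterSpec",
    "clamp",
    "normalize",
    "denormalize",
    "sow_grid",
    "random_sow",
    "round_half_away",
]


def round_half_away(value: float) -> float:
    """Round to the nearest whole number, halves away from zero.

    Symmetric and locale-independent, unlike Python's banker's rounding.
    """
    return math.copysign(math.floor(abs(value) + 0.5), value)


@dataclass(frozen=True)
class ParameterSpec:
    """One optimizable dimension.

    Parameters
    ----------
    name
        Identifier used in configs and reports.
    kind
        ``"continuous"`` or ``"integer"``; integer values are rounded
        (half away from zero) after clamping.
    lower, upper
        Optional limits; either side may be absent.  Values generated
        outside the limits are clamped to the limit value.
    init_range
        ``(low, high)`` interval sampled during the initial random sow.
        May be narrower than the limits.  Required for sowing.
    init_resolution
        Positive grid step for the initial sow; candidate values are drawn
        uniformly from ``{low, low+step, ...}`` up to ``high``.
    normalize
        If true, dispersal operates in min-max normalized [0, 1]
        coordinates.  Requires two-sided limits.
    """

    name: str
    kind: str = "continuous"
    lower: Optional[float] = None
    upper: Optional[float] = None
    init_range: Optional[tuple] = None
    init_resolution: Optional[float] = None
    normalize: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "integer"):
            raise ValueError(f"unknown parameter kind {self.kind!r}")
        if self.lower is not None and self.upper is not None:
            if not self.lower < self.upper:
                raise ValueError(
                    f"{self.name}: lower limit must be < upper limit"
                )
        if self.normalize and (self.lower is None or self.upper is None):
            raise ValueError(
                f"{self.name}: normalization requires two-sided limits"
            )
        if self.init_range is not None:
            lo, hi = self.init_range
            if lo > hi:
                raise ValueError(f"{self.name}: init_range low > high")
            if self.lower is not None and lo < self.lower:
                raise ValueError(f"{self.name}: init_range below lower limit")
            if self.upper is not None and hi > self.upper:
                raise ValueError(f"{self.name}: init_range above upper limit")
            if self.init_resolution is not None:
                if self.init_resolution <= 0:
                    raise ValueError(f"{self.name}: init_resolution must be > 0")
                span = hi - lo
                if span > 0 and self.init_resolution > span:
                    raise ValueError(
                        f"{self.name}: init_resolution exceeds init_range span"
                    )

    @property
    def two_sided(self) -> bool:
        return self.lower is not None and self.upper is not None

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "kind": self.kind,
            "lower": self.lower,
            "upper": self.upper,
            "init_range": list(self.init_range) if self.init_range else None,
            "init_resolution": self.init_resolution,
            "normalize": self.normalize,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSpec":
        ir = d.get("init_range")
        return cls(
            name=d["name"],
            kind=d.get("kind", "continuous"),
            lower=d.get("lower"),
            upper=d.get("upper"),
            init_range=tuple(ir) if ir is not None else None,
            init_resolution=d.get("init_resolution"),
            normalize=bool(d.get("normalize", False)),
        )


def clamp(value: float, spec: ParameterSpec) -> float:
    """Clamp ``value`` to the spec's limits; round integer kinds.

    Total function: values inside the limits pass through unchanged,
    violations are replaced by the violated limit.  Rounding happens after
    clamping so an integer dimension never escapes its bounds.
    """
    v = float(value)
    if spec.lower is not None and v < spec.lower:
        v = spec.lower
    if spec.upper is not None and v > spec.upper:
        v = spec.upper
    if spec.kind == "integer":
        v = round_half_away(v)
        # rounding can step back over a non-integer limit
        if spec.lower is not None and v < spec.lower:
            v = math.ceil(spec.lower)
        if spec.upper is not None and v > spec.upper:
            v = math.floor(spec.upper)
    return v


def normalize(value: float, spec: ParameterSpec) -> float:
    """Min-max normalize ``value`` onto [0, 1] using the spec's limits."""
    if not spec.two_sided:
        raise ValueError(
            f"{spec.name}: cannot normalize without two-sided limits"
        )
    return (float(value) - spec.lower) / (spec.upper - spec.lower)


def denormalize(unit: float, spec: ParameterSpec) -> float:
    """Inverse of :func:`normalize`."""
    if not spec.two_sided:
        raise ValueError(
            f"{spec.name}: cannot denormalize without two-sided limits"
        )
    return spec.lower + float(unit) * (spec.upper - spec.lower)


def sow_grid(spec: ParameterSpec) -> np.ndarray:
    """Inclusive grid of candidate values for the initial sow.

    Points are ``low, low+step, ...``; the upper endpoint is included when
    the span is an exact multiple of the step (within floating tolerance),
    otherwise the last grid point below ``high`` is the maximum.
    """
    if spec.init_range is None:
        raise ValueError(f"{spec.name}: init_range required for sowing")
    lo, hi = spec.init_range
    if spec.init_resolution is None:
        raise ValueError(f"{spec.name}: init_resolution required for sowing")
    step = spec.init_resolution
    span = hi - lo
    if span == 0:
        return np.array([lo])
    n_steps = int(math.floor(span / step + 1e-9))
    return lo + step * np.arange(n_steps + 1)


def random_sow(
    n: int,
    specs: Sequence[ParameterSpec],
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` parameter vectors uniformly from each dimension's sow grid.

    Returns an ``(n, len(specs))`` array; every value is clamped and, for
    integer kinds, rounded.  Reproducible under a fixed generator state.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cols = []
    for spec in specs:
        grid = sow_grid(spec)
        draws = grid[rng.integers(0, len(grid), size=n)]
        cols.append([clamp(v, spec) for v in draws])
    return np.array(cols, dtype=float).T
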
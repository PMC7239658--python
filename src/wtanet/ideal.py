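"""Idealized winner-take-all oracle.

Exact implementation of the two-line selection rule: the option with the
largest norm maps to f(x) at the output, all others map to exactly zero.
Used as ground truth against which circuit behavior is verified.  Ties are
reported as tie-sets rather than silently broken.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = ["WtaResult", "ideal_wta", "flexible_boundary", "discriminability"]


@dataclass(frozen=True)
class WtaResult:
    winner: Optional[int]  # unique argmax channel (0-based), None on tie
    tie_set: tuple[int, ...]  # all argmax channels
    winning_input: float  # x* = max(x)
    outputs: np.ndarray  # y_i = f(x_i) for winners, 0 otherwise
    flexible_boundary: float  # boundary value that exactly the winner meets

    @property
    def is_tie(self) -> bool:
        return self.winner is None


def ideal_wta(norms: Sequence[float], f: Callable[[float], float] = None) -> WtaResult:
    """Apply the idealized WTA rule to a norm vector.

    ``f`` is a monotone non-decreasing output map (identity by default; only
    monotonicity matters for the winner's identity).
    """
    x = np.asarray(norms, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("norms must be a non-empty 1-D vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("norms must be finite")
    if f is None:
        f = lambda v: v  # noqa: E731

    x_star = float(x.max())
    tie_set = tuple(int(i) for i in np.flatnonzero(x == x_star))
    winner = tie_set[0] if len(tie_set) == 1 else None
    y = np.zeros_like(x)
    for i in tie_set:
        y[i] = f(x[i])
    return WtaResult(
        winner=winner,
        tie_set=tie_set,
        winning_input=x_star,
        outputs=y,
        flexible_boundary=x_star,
    )


def flexible_boundary(norms: Sequence[float]) -> float:
    """The category-boundary value that exactly the winning norm meets: max(x).

    Defined for two or more options (a boundary separates a winner from at
    least one competitor).
    """
    x = np.asarray(norms, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("flexible_boundary requires at least 2 options")
    if not np.all(np.isfinite(x)):
        raise ValueError("norms must be finite")
    return float(x.max())


def discriminability(mean_a: float, sd_a: float, mean_b: float, sd_b: float) -> float:
    """d' = |mean_a - mean_b| / sqrt((sd_a^2 + sd_b^2) / 2).

    Undefined (raises) when both standard deviations are zero.
    """
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd_a == 0 and sd_b == 0:
        raise ValueError("d' is undefined when both standard deviations are zero")
    return abs(mean_a - mean_b) / np.sqrt((sd_a**2 + sd_b**2) / 2.0)
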
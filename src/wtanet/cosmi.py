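"""Combinatorial inhibitory coding: multilobe receptive-field codes.

A code assigns each inhibitory unit a set of channels (its receptive-field
"lobes"); under the donut rule the unit projects inhibition to exactly the
channels *outside* its receptive field.  A code is *covering* when, for every
ordered channel pair (i, j), some unit is driven by i and inhibits j — the
condition for the circuit to compare every pair of options.  Codes are scored
by a combined metabolic cost (active units per single-stimulus presentation)
and wiring cost (input plus projection connections), and searched either
exhaustively (globally optimal, small L) or greedily.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "CosmiCode",
    "CodeCost",
    "InfeasibleCodeError",
    "copy_paste_code",
    "sperner_code",
    "coverage_ok",
    "code_cost",
    "search_min_cost_code",
]


class InfeasibleCodeError(ValueError):
    """No covering code exists within the allowed number of units."""


@dataclass(frozen=True)
class CosmiCode:
    """Receptive-field assignment for the inhibitory population.

    ``rfs[u]`` is the sorted tuple of channels in unit u's receptive field;
    the unit inhibits the complement of that set.
    """

    n_channels: int
    rfs: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("a code needs at least 2 channels")
        if not self.rfs:
            raise ValueError("a code needs at least one inhibitory unit")
        norm = []
        for rf in self.rfs:
            rf = tuple(sorted(set(int(c) for c in rf)))
            if not rf:
                raise ValueError("receptive fields must be non-empty")
            if any(c < 0 or c >= self.n_channels for c in rf):
                raise ValueError("receptive-field channel out of range")
            if len(rf) == self.n_channels:
                raise ValueError("receptive fields must be strict subsets of channels")
            norm.append(rf)
        object.__setattr__(self, "rfs", tuple(norm))

    @property
    def n_units(self) -> int:
        return len(self.rfs)

    def projection(self, unit: int) -> tuple[int, ...]:
        """Channels inhibited by ``unit`` (complement of its receptive field)."""
        rf = set(self.rfs[unit])
        return tuple(c for c in range(self.n_channels) if c not in rf)

    # -- structured-text round trip -------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_channels": self.n_channels,
            "rfs": {str(u): list(rf) for u, rf in enumerate(self.rfs)},
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CosmiCode":
        rfs = [tuple(rf) for _, rf in sorted(data["rfs"].items(), key=lambda kv: int(kv[0]))]
        return cls(n_channels=int(data["n_channels"]), rfs=tuple(rfs))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "CosmiCode":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class CodeCost:
    metabolic: float
    wiring: float
    alpha: float
    beta: float

    @property
    def total(self) -> float:
        return self.alpha * self.metabolic + self.beta * self.wiring


def copy_paste_code(n_channels: int) -> CosmiCode:
    """One single-channel inhibitory unit per channel (the baseline layout)."""
    return CosmiCode(n_channels, tuple((c,) for c in range(n_channels)))


def sperner_code(n_channels: int, n_units: int) -> CosmiCode:
    """Multilobe covering code built from an antichain of unit subsets.

    Assigns each channel a distinct ``floor(n_units/2)``-element subset of
    units as its covering set; the receptive field of a unit is the set of
    channels whose subset contains it.  Requires C(n_units, n_units//2) >=
    n_channels.  For L=6 this yields the classic 4-unit multilobe code.
    """
    k = n_units // 2 if n_units > 1 else 1
    signatures = list(itertools.combinations(range(n_units), k))
    if len(signatures) < n_channels:
        raise InfeasibleCodeError(
            f"C({n_units},{k}) = {len(signatures)} < {n_channels} channels"
        )
    rfs = []
    for u in range(n_units):
        rf = tuple(c for c in range(n_channels) if u in signatures[c])
        if not rf:
            raise InfeasibleCodeError("construction left a unit with an empty RF")
        rfs.append(rf)
    return CosmiCode(n_channels, tuple(rfs))


def coverage_ok(code: CosmiCode) -> tuple[bool, list[tuple[int, int]]]:
    """Check that every ordered channel pair (i, j), i != j, is served.

    Pair (i, j) is covered when some unit has i in its receptive field and j
    outside it, so that a stimulus in channel i delivers inhibition to j.
    Returns (verdict, list of uncovered ordered pairs).
    """
    L = code.n_channels
    rf_sets = [set(rf) for rf in code.rfs]
    uncovered = [
        (i, j)
        for i in range(L)
        for j in range(L)
        if i != j and not any(i in rf and j not in rf for rf in rf_sets)
    ]
    return (not uncovered, uncovered)


def code_cost(
    code: CosmiCode,
    alpha: float = 1.0,
    beta: float = 1.0,
    firing_cost: float = 1.0,
) -> CodeCost:
    """Metabolic + wiring cost of operating a code.

    Metabolic: expected number of active inhibitory units under the
    single-stimulus activity model (one stimulated channel at a time,
    uniformly), summed over channels and weighted by ``firing_cost``:
    sum_i |{u : i in RF_u}|.  Wiring: per unit, one input connection per
    receptive-field channel plus one projection connection per inhibited
    channel, i.e. |RF| + (L - |RF|) = L.
    """
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be non-negative")
    metabolic = firing_cost * float(sum(len(rf) for rf in code.rfs))
    wiring = float(code.n_units * code.n_channels)
    return CodeCost(metabolic=metabolic, wiring=wiring, alpha=alpha, beta=beta)


# ---------------------------------------------------------------------------
# search


def _code_from_signatures(L: int, n: int, sigs: list[int]) -> Optional[CosmiCode]:
    """Build a code from per-channel unit-signature bitmasks; None if invalid."""
    rfs = []
    for u in range(n):
        rf = tuple(c for c in range(L) if sigs[c] >> u & 1)
        if not rf:
            return None  # unused unit: equivalent code exists at smaller n
        if len(rf) == L:
            return None  # full RF covers nothing; cheaper equivalent exists
        rfs.append(rf)
    return CosmiCode(L, tuple(rfs))


def _exhaustive(L: int, max_units: int, alpha: float, beta: float):
    """Globally optimal covering code via signature-space branch and bound.

    Coverage of all ordered pairs is equivalent to the per-channel signature
    sets S_i = {units driven by channel i} forming an antichain of L distinct,
    pairwise-incomparable non-empty subsets of the units; the metabolic count
    equals sum_i |S_i| and the wiring cost is n_units * L.
    """
    best_code = copy_paste_code(L)
    best_cost = code_cost(best_code, alpha, beta)
    if L <= max_units:
        best = best_cost.total
    else:
        best_code, best = None, np.inf

    for n in range(1, max_units + 1):
        # cheapest conceivable cost at this unit count
        if beta * n * L + alpha * L >= best:
            continue
        subsets = sorted(range(1, 1 << n), key=lambda m: (bin(m).count("1"), m))
        sizes = [bin(m).count("1") for m in subsets]
        chosen: list[int] = []

        def dfs(start: int, size_sum: int) -> None:
            nonlocal best, best_code
            if len(chosen) == L:
                cost = alpha * size_sum + beta * n * L
                if cost < best:
                    code = _code_from_signatures(L, n, chosen)
                    if code is not None:
                        best, best_code = cost, code
                return
            remaining = L - len(chosen)
            for idx in range(start, len(subsets)):
                m = subsets[idx]
                lb = alpha * (size_sum + remaining * sizes[idx]) + beta * n * L
                if lb >= best:
                    return  # later subsets are at least as large
                if any((m & c) == m or (m & c) == c for c in chosen):
                    continue  # comparable with an already-chosen signature
                chosen.append(m)
                dfs(idx + 1, size_sum + sizes[idx])
                chosen.pop()

        dfs(0, 0)

    if best_code is None:
        raise InfeasibleCodeError(
            f"no covering code with at most {max_units} units for L={L}"
        )
    return best_code, code_cost(best_code, alpha, beta)


def _greedy(L: int, max_units: int, alpha: float, beta: float, rng: np.random.Generator):
    """Greedy covering: repeatedly add the RF with the best ratio of newly
    covered ordered pairs to marginal cost; the result is never worse than
    the copy-and-paste baseline when that baseline fits the unit budget."""
    candidates = [
        tuple(rf)
        for r in range(1, L)
        for rf in itertools.combinations(range(L), r)
    ]
    order = rng.permutation(len(candidates))
    candidates = [candidates[i] for i in order]

    uncovered = {(i, j) for i in range(L) for j in range(L) if i != j}
    rfs: list[tuple[int, ...]] = []
    while uncovered and len(rfs) < max_units:
        best_rf, best_score = None, -np.inf
        for rf in candidates:
            rf_set = set(rf)
            gained = sum(1 for (i, j) in uncovered if i in rf_set and j not in rf_set)
            if gained == 0:
                continue
            score = gained / (alpha * len(rf) + beta * L + 1e-12)
            if score > best_score:
                best_rf, best_score = rf, score
        if best_rf is None:
            break
        rfs.append(best_rf)
        rf_set = set(best_rf)
        uncovered = {
            (i, j) for (i, j) in uncovered if not (i in rf_set and j not in rf_set)
        }
    if uncovered:
        raise InfeasibleCodeError(
            f"greedy search found no covering code within {max_units} units for L={L}"
        )
    code = CosmiCode(L, tuple(rfs))
    cost = code_cost(code, alpha, beta)
    if L <= max_units:
        cp = copy_paste_code(L)
        cp_cost = code_cost(cp, alpha, beta)
        if cp_cost.total < cost.total:
            code, cost = cp, cp_cost
    return code, cost


def search_min_cost_code(
    n_channels: int,
    max_units: int,
    alpha: float = 1.0,
    beta: float = 1.0,
    mode: str = "exhaustive",
    seed: int = 0,
):
    """Find a covering code minimizing ``alpha*metabolic + beta*wiring``.

    ``mode='exhaustive'`` is globally optimal and guarded to L <= 6 and
    max_units <= 6; ``mode='greedy'`` scales further but is only heuristic.
    Raises :class:`InfeasibleCodeError` when no covering code fits.
    """
    if n_channels < 2:
        raise ValueError("search requires at least 2 channels")
    if max_units < 1:
        raise ValueError("max_units must be >= 1")
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be non-negative")
    if mode == "exhaustive":
        if n_channels > 6 or max_units > 6:
            raise ValueError("exhaustive mode is limited to L <= 6 and max_units <= 6")
        return _exhaustive(n_channels, max_units, alpha, beta)
    if mode == "greedy":
        return _greedy(n_channels, max_units, alpha, beta, np.random.default_rng(seed))
    raise ValueError("mode must be 'exhaustive' or 'greedy'")
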
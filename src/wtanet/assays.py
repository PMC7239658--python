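"""Measurement protocols over a selection network.

Each assay runs seeded, batched simulations of a :class:`~wtanet.circuit.Network`
and summarizes behavior the way the corresponding experiment would:

* :func:`measure_crp` — competitor-strength response profile (CRP) of one
  channel's output unit while the rival's norm is swept from below to above
  the probed channel's norm;
* :func:`categorization_index` — how step-like a CRP is across the selection
  boundary, accounting for response variability;
* :func:`transition_norm` / :func:`flexibility_assay` — where the CRP drops,
  and whether that boundary shifts with the probed channel's own norm;
* :func:`multi_option_assay` — winner identification and output strength as
  the number of simultaneous options grows;
* :func:`unitary_choice_assay` — first-to-threshold choice statistics.

A single master seed determines every noise stream deterministically, so
conditions compared "at matched seeds" (e.g. before/after a perturbation, or
the two halves of the flexibility assay) see identical noise draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .circuit import Network
from .dynamics import DEFAULT_DT_MS, _Engine, first_threshold_crossing
from .ideal import discriminability, ideal_wta

__all__ = [
    "CRPCurve",
    "FlexibilityResult",
    "MultiOptionResult",
    "MultiOptionCondition",
    "ChoiceStats",
    "TransitionOutOfRangeError",
    "measure_crp",
    "categorization_index",
    "transition_norm",
    "flexibility_assay",
    "multi_option_assay",
    "unitary_choice_assay",
]


class TransitionOutOfRangeError(ValueError):
    """The CRP has no midpoint crossing within the sampled competitor range."""


@dataclass(frozen=True)
class CRPCurve:
    norm_A: float
    competitor_norms: np.ndarray  # ascending, spanning norm_A
    mean_response: np.ndarray  # (n_points,) spikes/s
    sd_response: np.ndarray  # (n_points,)
    n_trials: int
    channel_probed: int

    def __post_init__(self) -> None:
        comps = np.asarray(self.competitor_norms, dtype=float)
        if not np.all(np.diff(comps) > 0):
            raise ValueError("competitor_norms must be strictly ascending")
        if not (comps[0] < self.norm_A < comps[-1]):
            raise ValueError("competitor_norms must span values below and above norm_A")
        object.__setattr__(self, "competitor_norms", comps)


@dataclass(frozen=True)
class FlexibilityResult:
    norm_A_low: float
    norm_A_high: float
    transition_norm_1: float
    transition_norm_2: float

    @property
    def delta_A(self) -> float:
        return self.norm_A_high - self.norm_A_low

    @property
    def shift_ratio(self) -> float:
        return (self.transition_norm_2 - self.transition_norm_1) / self.delta_A


@dataclass(frozen=True)
class MultiOptionCondition:
    norms: tuple[float, ...]
    n_active: int
    oracle_winner: int
    accuracy: float
    winner_mean_output: float
    transition_norm: Optional[float] = None


@dataclass(frozen=True)
class MultiOptionResult:
    conditions: tuple[MultiOptionCondition, ...]


@dataclass(frozen=True)
class ChoiceStats:
    p_unitary: float
    accuracy: float
    rt_mean: float
    rt_sd: float
    n_trials: int
    n_no_choice: int


# ---------------------------------------------------------------------------


def measure_crp(
    net: Network,
    norm_A: float,
    competitor_norms: Sequence[float],
    n_trials: int = 20,
    seed: int = 0,
    channel_probed: int = 0,
    competitor_channel: int = 1,
    duration: float = 300.0,
    window: float = 50.0,
    dt: float = DEFAULT_DT_MS,
    noise: bool = True,
) -> CRPCurve:
    """Response of ``channel_probed``'s output unit versus competitor norm.

    For each competitor norm the probed option (fixed at ``norm_A``) and the
    competitor are presented together for ``duration`` ms, over ``n_trials``
    seeded noisy trials; responses are mean rates over the trailing
    ``window`` ms of the stimulus epoch (a steady-state proxy).
    """
    comps = np.asarray(competitor_norms, dtype=float)
    L = net.n_channels
    if not 0 <= channel_probed < L:
        raise ValueError(f"invalid probe channel {channel_probed}")
    if not 0 <= competitor_channel < L or competitor_channel == channel_probed:
        raise ValueError(f"invalid competitor channel {competitor_channel}")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")

    n_pts = len(comps)
    norms = np.zeros((n_pts * n_trials, L))
    norms[:, channel_probed] = norm_A
    norms[:, competitor_channel] = np.repeat(comps, n_trials)

    eng = _Engine(net, dt)
    res = eng.run(
        norms, duration=duration, seed=seed, offset=duration,
        noise=noise, window=window,
    )
    resp = res["window_mean"][:, channel_probed].reshape(n_pts, n_trials)
    mean = resp.mean(axis=1)
    sd = resp.std(axis=1, ddof=1) if n_trials >= 2 else np.zeros(n_pts)
    return CRPCurve(
        norm_A=float(norm_A),
        competitor_norms=comps,
        mean_response=mean,
        sd_response=sd,
        n_trials=n_trials,
        channel_probed=channel_probed,
    )


def categorization_index(crp: CRPCurve, sd_floor: float = 0.1) -> float:
    """Discriminability-aware index of how step-like a CRP is.

    The boundary sits at competitor norm = norm_A.  Along the ascending
    competitor axis (samples exactly at the boundary excluded), d' is
    computed between each pair of *consecutive* response distributions and
    normalized by the norm spacing of the pair (a discriminability density,
    so uneven sampling does not bias the contrast); the index contrasts the
    mean normalized d' of pairs straddling the boundary against the mean of
    pairs within either side:

        CatI = (between - within) / (between + within)   in [-1, 1].

    A perfect step gives 1 (within-side d' = 0); a linear profile with equal
    spacing and equal sds gives 0 (all consecutive d' equal).  Standard
    deviations are floored at ``sd_floor`` so that noiseless plateaus do not
    make d' undefined; a profile whose total modulation does not exceed
    ``sd_floor`` (e.g. a silenced channel) carries no categorical structure
    and yields 0.
    """
    if crp.n_trials < 2:
        raise ValueError("categorization_index requires n_trials >= 2 (sd available)")
    keep = crp.competitor_norms != crp.norm_A
    comps = crp.competitor_norms[keep]
    means = crp.mean_response[keep]
    sds = np.maximum(crp.sd_response[keep], sd_floor)
    below = comps < crp.norm_A
    if below.sum() < 2 or (~below).sum() < 2:
        raise ValueError(
            "need at least 2 competitor norms strictly on each side of the boundary"
        )
    if means.max() - means.min() <= sd_floor:
        return 0.0
    between, within = [], []
    for k in range(len(comps) - 1):
        d = discriminability(means[k], sds[k], means[k + 1], sds[k + 1])
        d /= comps[k + 1] - comps[k]
        (within if below[k] == below[k + 1] else between).append(d)
    b = float(np.mean(between))
    w = float(np.mean(within))
    if b + w == 0:
        return 0.0
    return (b - w) / (b + w)


def transition_norm(crp: CRPCurve, min_drop: float = 1e-6) -> float:
    """Competitor norm where the mean CRP crosses the midpoint between its
    upper and lower plateaus, by linear interpolation between the bracketing
    samples.  Raises :class:`TransitionOutOfRangeError` when the profile is
    flat or never crosses within the sampled range."""
    m = crp.mean_response
    upper = float(m.max())
    lower = float(m.min())
    if upper - lower < min_drop:
        raise TransitionOutOfRangeError("CRP is flat; no transition in range")
    mid = (upper + lower) / 2.0
    comps = crp.competitor_norms
    for k in range(len(m) - 1):
        if m[k] >= mid > m[k + 1]:
            frac = (m[k] - mid) / (m[k] - m[k + 1])
            return float(comps[k] + frac * (comps[k + 1] - comps[k]))
    raise TransitionOutOfRangeError(
        "mean response never drops through the plateau midpoint in the sampled range"
    )


def flexibility_assay(
    net: Network,
    norm_A_low: float,
    norm_A_high: float,
    competitor_norms: Sequence[float],
    n_trials: int = 20,
    seed: int = 0,
    **crp_kwargs,
) -> FlexibilityResult:
    """Measure the CRP transition norm at two values of the probed option's
    norm, under one seed schedule (identical noise draws for both), and
    report how far the boundary shifts relative to the change in norm_A."""
    if not norm_A_high > norm_A_low:
        raise ValueError("norm_A_high must exceed norm_A_low")
    crp_lo = measure_crp(
        net, norm_A_low, competitor_norms, n_trials=n_trials, seed=seed, **crp_kwargs
    )
    crp_hi = measure_crp(
        net, norm_A_high, competitor_norms, n_trials=n_trials, seed=seed, **crp_kwargs
    )
    return FlexibilityResult(
        norm_A_low=float(norm_A_low),
        norm_A_high=float(norm_A_high),
        transition_norm_1=transition_norm(crp_lo),
        transition_norm_2=transition_norm(crp_hi),
    )


def multi_option_assay(
    net: Network,
    conditions: Sequence[Sequence[float]],
    n_trials: int = 20,
    seed: int = 0,
    duration: float = 300.0,
    dt: float = DEFAULT_DT_MS,
    noise: bool = True,
    window: Optional[float] = None,
    transition_grid: Optional[Sequence[float]] = None,
) -> MultiOptionResult:
    """Winner identification across conditions with varying option counts.

    Per condition: accuracy of the per-trial winner (argmax of the mean
    output over the stimulus epoch) against the idealized-WTA oracle, and the
    winner channel's mean output.  The response window spans the whole
    stimulus epoch so that competition transients — which deepen as more
    options are added — are reflected in the summary, as they are in
    trial-averaged firing rates.  With ``transition_grid`` given, the winner
    channel's CRP transition norm is also measured against the strongest
    distracter, with the remaining options as fixed context.  Passing an
    explicit trailing ``window`` (ms) restricts the summary to the
    steady-state proxy used by :func:`measure_crp` instead.
    """
    window = duration if window is None else window
    eng = _Engine(net, dt)
    out_conditions = []
    for ci, norms in enumerate(conditions):
        norms = np.asarray(norms, dtype=float)
        oracle = ideal_wta(norms)
        if oracle.winner is None:
            raise ValueError(f"condition {ci} has no unique oracle winner: {norms}")
        # one shared seed: conditions of equal trial count see identical noise
        # draws, so across-condition comparisons are paired
        batch = np.tile(norms, (n_trials, 1))
        res = eng.run(
            batch, duration=duration, seed=seed, offset=duration,
            noise=noise, window=window,
        )
        epoch_mean = res["window_mean"]  # (n_trials, L)
        winners = epoch_mean.argmax(axis=1)
        accuracy = float(np.mean(winners == oracle.winner))
        winner_out = float(epoch_mean[:, oracle.winner].mean())

        trans = None
        if transition_grid is not None:
            distracters = [c for c in range(len(norms)) if c != oracle.winner and norms[c] > 0]
            if distracters:
                comp = max(distracters, key=lambda c: norms[c])
                grid = np.asarray(transition_grid, dtype=float)
                n_pts = len(grid)
                sweep = np.tile(norms, (n_pts * n_trials, 1))
                sweep[:, comp] = np.repeat(grid, n_trials)
                res2 = eng.run(
                    sweep, duration=duration, seed=seed, offset=duration,
                    noise=noise, window=window,
                )
                resp = res2["window_mean"][:, oracle.winner].reshape(n_pts, n_trials)
                crp = CRPCurve(
                    norm_A=float(norms[oracle.winner]),
                    competitor_norms=grid,
                    mean_response=resp.mean(axis=1),
                    sd_response=resp.std(axis=1, ddof=1) if n_trials >= 2 else np.zeros(n_pts),
                    n_trials=n_trials,
                    channel_probed=oracle.winner,
                )
                trans = transition_norm(crp)

        out_conditions.append(
            MultiOptionCondition(
                norms=tuple(float(x) for x in norms),
                n_active=int(np.sum(norms > 0)),
                oracle_winner=oracle.winner,
                accuracy=accuracy,
                winner_mean_output=winner_out,
                transition_norm=trans,
            )
        )
    return MultiOptionResult(conditions=tuple(out_conditions))


def unitary_choice_assay(
    net: Network,
    norms: Sequence[float],
    threshold: float,
    n_trials: int = 100,
    seed: int = 0,
    duration: float = 400.0,
    dt: float = DEFAULT_DT_MS,
    noise: bool = True,
) -> ChoiceStats:
    """First-to-threshold choice statistics over noisy trials.

    ``p_unitary`` is the fraction of trials in which exactly one channel's
    output ever exceeds the threshold; ``accuracy`` compares the readout
    winner against the idealized-WTA oracle; RT statistics are over correct
    trials.
    """
    r_max = net.config.nonlinearity.r_max
    if not 0 < threshold < r_max:
        raise ValueError(f"threshold must lie in (0, {r_max})")
    norms = np.asarray(norms, dtype=float)
    oracle = ideal_wta(norms)
    if oracle.winner is None:
        raise ValueError("unitary_choice_assay requires a unique oracle winner")

    eng = _Engine(net, dt)
    res = eng.run(
        np.tile(norms, (n_trials, 1)),
        duration=duration, seed=seed, offset=duration,
        noise=noise, record=("output",),
    )
    traces = res["traces"]["output"]  # (n_trials, T, L)

    unitary = 0
    correct_rts = []
    n_correct = 0
    n_no_choice = 0
    for b in range(n_trials):
        ev = first_threshold_crossing(traces[b], threshold, dt=dt)
        if ev.n_crossers == 1:
            unitary += 1
        if ev.winner is None:
            n_no_choice += 1
        elif ev.winner == oracle.winner:
            n_correct += 1
            correct_rts.append(ev.crossing_time)

    rts = np.asarray(correct_rts)
    return ChoiceStats(
        p_unitary=unitary / n_trials,
        accuracy=n_correct / n_trials,
        rt_mean=float(rts.mean()) if rts.size else float("nan"),
        rt_sd=float(rts.std(ddof=1)) if rts.size > 1 else float("nan"),
        n_trials=n_trials,
        n_no_choice=n_no_choice,
    )
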
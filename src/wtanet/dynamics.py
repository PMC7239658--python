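"""Time evolution of network rates and choice readouts.

Dynamics are the standard leaky rate equation

    tau * dr/dt = -r + f(total input + noise),

integrated with explicit Euler steps (default tau = 10 ms, dt = 0.1 ms).
Input units relay the stimulus norm linearly (clipped to [0, r_max]); all
other populations pass their summed drive through a saturating tanh
nonlinearity.  Inhibition converging on a target from several sources is
combined according to the config's combination rule before entering the
target's input: ``linear`` sums the contributions, ``max`` takes the largest,
and ``softmax`` (the default) applies the zero-preserving smoothed maximum

    combined = T * log(1 + sum_u (exp(c_u / T) - 1)),

which reduces to a single contribution exactly, approaches the maximum for
one dominant source, and grows gently with the number of comparable sources.

Noise is an independent Gaussian perturbation of every unit's input drive at
each step, scaled internally by sqrt(tau/dt) so that the stationary rate
variability is independent of the integration step; rates are rectified to
[0, r_max] after every update.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .circuit import Network

__all__ = [
    "StimulusTimeline",
    "SimulationTrace",
    "SteadyStateResult",
    "ChoiceEvent",
    "simulate",
    "steady_state",
    "first_threshold_crossing",
]

DEFAULT_DT_MS = 0.1


@dataclass(frozen=True)
class StimulusTimeline:
    """Per-channel norm drive as a step function of time (ms)."""

    norms: tuple[float, ...]
    onset: float = 0.0
    offset: float = 300.0

    def __post_init__(self) -> None:
        norms = tuple(float(x) for x in self.norms)
        if any(x < 0 for x in norms):
            raise ValueError("norms must be non-negative")
        if not self.offset > self.onset:
            raise ValueError("offset must be greater than onset")
        object.__setattr__(self, "norms", norms)

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class SimulationTrace:
    """Rates of every unit on a regular time grid."""

    time: np.ndarray  # (T,) ms
    rates: dict[str, np.ndarray]  # population -> (T, n_units)
    dt: float
    seed: Optional[int]
    config_hash: str

    @property
    def output(self) -> np.ndarray:
        return self.rates["output"]

    def to_frame(self):
        """Tidy (time, unit, rate) table; round-trips losslessly via TSV."""
        import pandas as pd

        from .circuit import _PREFIX

        frames = []
        for pop, arr in self.rates.items():
            n = arr.shape[1]
            frames.append(
                pd.DataFrame(
                    {
                        "time_ms": np.repeat(self.time, n),
                        "unit": np.tile(
                            [f"{_PREFIX[pop]}{i}" for i in range(n)], len(self.time)
                        ),
                        "rate": arr.ravel(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class SteadyStateResult:
    rates: np.ndarray  # (n_channels,) output-layer rates
    converged: bool
    n_steps: int
    all_rates: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass(frozen=True)
class ChoiceEvent:
    """First-to-threshold readout of a trace."""

    winner: Optional[int]
    crossing_time: Optional[float]
    margin: Optional[float]
    n_crossers: int
    tie_broken: bool = False


# ---------------------------------------------------------------------------
# engine


class _Engine:
    """Vectorized Euler integrator over a batch of independent trials.

    State arrays have shape (batch, n_units); the batch dimension carries
    either repeated noisy trials of one stimulus or distinct norm vectors.
    """

    def __init__(self, net: Network, dt: float):
        if dt <= 0:
            raise ValueError("dt must be positive")
        cfg = net.config
        self.net = net
        self.dt = float(dt)
        self.tau = cfg.tau_ms
        self.a = self.dt / self.tau
        self.L = net.n_channels
        self.U = net.n_inhibitory
        self.r_max = cfg.nonlinearity.r_max

        self.W_in_out = net.weight("input", "output")
        self.W_in_inh = net.weight("input", "inhibitory")
        self.W_out_inh = net.weight("output", "inhibitory")
        self.W_out_amp = net.weight("output", "amplifier")
        self.W_amp_out = net.weight("amplifier", "output")
        # inhibitory projections as non-negative magnitudes
        self.G_out = -net.weight("inhibitory", "output")
        self.G_amp = -net.weight("inhibitory", "amplifier")
        self.G_inh = -net.weight("inhibitory", "inhibitory")
        self.has_amp = cfg.motifs.amplifiers

        nl = cfg.nonlinearity
        inl = cfg.inhibitory_nonlinearity
        self._theta = {"inhibitory": inl.threshold, "amplifier": nl.threshold,
                       "output": nl.threshold}
        self._slope = {"inhibitory": inl.slope, "amplifier": nl.slope,
                       "output": nl.slope}
        self.rule = cfg.combination_rule
        self.T = cfg.softmax_temperature
        self.sigma0 = cfg.noise.sigma0
        self.noise_scaling = cfg.noise.scaling
        # per-step input noise sd giving dt-invariant stationary rate variance
        self.sigma_step = self.sigma0 * np.sqrt(self.tau / self.dt)

    def f(self, pop: str, u: np.ndarray) -> np.ndarray:
        z = np.maximum(u - self._theta[pop], 0.0)
        return self.r_max * np.tanh(self._slope[pop] * z)

    def combine(self, rates: np.ndarray, G: np.ndarray) -> np.ndarray:
        """Combine inhibitory contributions c[b,u,t] = rates[b,u] * G[u,t]."""
        if not np.any(G):
            return np.zeros((rates.shape[0], G.shape[1]))
        if self.rule == "linear":
            return rates @ G
        c = rates[:, :, None] * G[None, :, :]
        if self.rule == "max":
            return c.max(axis=1)
        z = np.clip(c / self.T, 0.0, 500.0)
        return self.T * np.log1p(np.expm1(z).sum(axis=1))

    def run(
        self,
        norms: np.ndarray,  # (B, L)
        duration: float,
        seed: Optional[int],
        onset: float = 0.0,
        offset: Optional[float] = None,
        noise: bool = True,
        record: Sequence[str] = (),
        window: Optional[float] = None,
        check_convergence_tol: Optional[float] = None,
        init: Optional[dict[str, np.ndarray]] = None,
    ) -> dict:
        """Integrate the batch for ``duration`` ms.

        Returns a dict with final per-population rates, optional recorded
        traces, optional mean output rates over the trailing ``window`` ms of
        the stimulus epoch, and a per-trial convergence flag when
        ``check_convergence_tol`` (spikes/s per ms) is given.
        """
        norms = np.atleast_2d(np.asarray(norms, dtype=float))
        B = norms.shape[0]
        if norms.shape[1] != self.L:
            raise ValueError(f"norms must have {self.L} channels")
        offset = duration if offset is None else offset
        n_steps = int(round(duration / self.dt))
        rng = np.random.default_rng(seed) if (noise and self.sigma0 > 0) else None

        rI = np.zeros((B, self.L))
        rG = np.zeros((B, self.U))
        rA = np.zeros((B, self.L))
        rO = np.zeros((B, self.L))
        if init:
            rI = init.get("input", rI).copy()
            rG = init.get("inhibitory", rG).copy()
            rA = init.get("amplifier", rA).copy()
            rO = init.get("output", rO).copy()

        traces = {
            pop: np.empty((B, n_steps + 1, self.L if pop != "inhibitory" else self.U))
            for pop in record
        }
        state = {"input": rI, "inhibitory": rG, "amplifier": rA, "output": rO}
        for pop in record:
            traces[pop][:, 0] = state[pop]

        win_steps = 0
        win_sum = np.zeros((B, self.L))
        if window is not None:
            win_start = offset - window

        converged = np.zeros(B, dtype=bool)
        n_units = 2 * self.L + self.U + (self.L if self.has_amp else 0)

        for k in range(n_steps):
            t = k * self.dt
            x = norms if (onset <= t < offset) else np.zeros_like(norms)

            dI = x
            dG = rI @ self.W_in_inh + rO @ self.W_out_inh - self.combine(rG, self.G_inh)
            dO = rI @ self.W_in_out + rA @ self.W_amp_out - self.combine(rG, self.G_out)
            if self.has_amp:
                dA = rO @ self.W_out_amp - self.combine(rG, self.G_amp)

            if rng is not None:
                eps = rng.standard_normal((B, n_units))
                iI = slice(0, self.L)
                iG = slice(self.L, self.L + self.U)
                iO = slice(self.L + self.U, 2 * self.L + self.U)
                if self.noise_scaling == "sqrt-mean":
                    dI = dI + self.sigma_step * np.sqrt(np.maximum(dI, 0)) * eps[:, iI]
                    dG = dG + self.sigma_step * np.sqrt(np.maximum(dG, 0)) * eps[:, iG]
                    dO = dO + self.sigma_step * np.sqrt(np.maximum(dO, 0)) * eps[:, iO]
                    if self.has_amp:
                        eA = eps[:, 2 * self.L + self.U:]
                        dA = dA + self.sigma_step * np.sqrt(np.maximum(dA, 0)) * eA
                else:
                    dI = dI + self.sigma_step * eps[:, iI]
                    dG = dG + self.sigma_step * eps[:, iG]
                    dO = dO + self.sigma_step * eps[:, iO]
                    if self.has_amp:
                        dA = dA + self.sigma_step * eps[:, 2 * self.L + self.U:]

            new_I = rI + self.a * (-rI + np.clip(dI, 0.0, self.r_max))
            new_G = rG + self.a * (-rG + self.f("inhibitory", dG))
            new_O = rO + self.a * (-rO + self.f("output", dO))
            if self.has_amp:
                new_A = rA + self.a * (-rA + self.f("amplifier", dA))
            else:
                new_A = rA

            if not (np.all(np.isfinite(new_O)) and np.all(np.isfinite(new_G))):
                raise FloatingPointError(
                    f"non-finite rates at step {k} (t = {t:.3f} ms); "
                    "the integration diverged"
                )

            if check_convergence_tol is not None:
                delta = max(
                    np.abs(new_I - rI).max(),
                    np.abs(new_G - rG).max(),
                    np.abs(new_A - rA).max(),
                    np.abs(new_O - rO).max(),
                )
                if delta / self.dt < check_convergence_tol:
                    converged[:] = True
                    rI = np.clip(new_I, 0.0, self.r_max)
                    rG = np.clip(new_G, 0.0, self.r_max)
                    rA = np.clip(new_A, 0.0, self.r_max)
                    rO = np.clip(new_O, 0.0, self.r_max)
                    n_steps = k + 1
                    break

            rI = np.clip(new_I, 0.0, self.r_max)
            rG = np.clip(new_G, 0.0, self.r_max)
            rA = np.clip(new_A, 0.0, self.r_max)
            rO = np.clip(new_O, 0.0, self.r_max)

            state = {"input": rI, "inhibitory": rG, "amplifier": rA, "output": rO}
            for pop in record:
                traces[pop][:, k + 1] = state[pop]
            if window is not None and win_start <= t < offset:
                win_sum += rO
                win_steps += 1

        out = {
            "final": {"input": rI, "inhibitory": rG, "amplifier": rA, "output": rO},
            "n_steps": n_steps,
            "converged": converged,
        }
        if record:
            out["traces"] = {pop: traces[pop][:, : n_steps + 1] for pop in record}
        if window is not None:
            out["window_mean"] = win_sum / max(win_steps, 1)
        return out


# ---------------------------------------------------------------------------
# public operations


def simulate(
    net: Network,
    stim: StimulusTimeline,
    duration: float,
    dt: float = DEFAULT_DT_MS,
    seed: int = 0,
) -> SimulationTrace:
    """Integrate one trial and return the full rate trace of every unit."""
    if duration < stim.offset:
        raise ValueError("duration must cover the stimulus offset")
    eng = _Engine(net, dt)
    res = eng.run(
        np.asarray(stim.norms)[None, :],
        duration=duration,
        seed=seed,
        onset=stim.onset,
        offset=stim.offset,
        noise=True,
        record=("input", "inhibitory", "amplifier", "output"),
    )
    n = res["n_steps"]
    time = np.arange(n + 1) * dt
    rates = {pop: arr[0] for pop, arr in res["traces"].items()}
    return SimulationTrace(
        time=time, rates=rates, dt=dt, seed=seed, config_hash=net.config.config_hash()
    )


def steady_state(
    net: Network,
    norms,
    seed: int = 0,
    tol: float = 1e-4,
    dt: float = DEFAULT_DT_MS,
    max_steps: int = 50_000,
) -> SteadyStateResult:
    """Noise-free relaxation to a fixed point of the rate equations.

    Integrates until the largest rate change per ms falls below ``tol`` or a
    step cap is reached; non-convergence (e.g. sustained oscillation) is
    flagged explicitly and the partial result retained.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    eng = _Engine(net, dt)
    res = eng.run(
        np.asarray(norms, dtype=float)[None, :],
        duration=max_steps * dt,
        seed=seed,
        noise=False,
        check_convergence_tol=tol,
    )
    return SteadyStateResult(
        rates=res["final"]["output"][0].copy(),
        converged=bool(res["converged"][0]),
        n_steps=res["n_steps"],
        all_rates={pop: arr[0].copy() for pop, arr in res["final"].items()},
    )


def steady_state_batch(
    net: Network,
    norms: np.ndarray,
    duration: float = 800.0,
    dt: float = DEFAULT_DT_MS,
) -> np.ndarray:
    """Noise-free output rates after ``duration`` ms for a batch of norm
    vectors (rows), integrated jointly for speed.  A fixed-horizon companion
    to :func:`steady_state` for parameter sweeps."""
    eng = _Engine(net, dt)
    res = eng.run(
        np.atleast_2d(np.asarray(norms, dtype=float)),
        duration=duration,
        seed=None,
        noise=False,
    )
    return res["final"]["output"]


def first_threshold_crossing(
    trace_or_outputs, threshold: float, dt: Optional[float] = None
) -> ChoiceEvent:
    """First-to-threshold choice readout.

    The winner is the channel whose output rate first reaches ``threshold``;
    ties at the same time step are broken by the larger rate at that step and
    then by the lower channel index (recorded via ``tie_broken``).
    ``winner=None`` when no channel ever crosses.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if isinstance(trace_or_outputs, SimulationTrace):
        out = trace_or_outputs.output
        dt = trace_or_outputs.dt
    else:
        out = np.asarray(trace_or_outputs)
        if dt is None:
            raise ValueError("dt is required when passing a raw output array")

    crossed = out >= threshold
    ever = crossed.any(axis=0)
    n_crossers = int(ever.sum())
    if n_crossers == 0:
        return ChoiceEvent(winner=None, crossing_time=None, margin=None, n_crossers=0)

    first_step = np.where(ever, crossed.argmax(axis=0), out.shape[0])
    t0 = int(first_step.min())
    at_front = np.flatnonzero(first_step == t0)
    tie_broken = len(at_front) > 1
    if tie_broken:
        rates_then = out[t0, at_front]
        at_front = at_front[rates_then == rates_then.max()]
    winner = int(at_front[0])

    others = np.delete(out[t0], winner)
    margin = float(out[t0, winner] - others.max()) if others.size else float(out[t0, winner])
    return ChoiceEvent(
        winner=winner,
        crossing_time=t0 * dt,
        margin=margin,
        n_crossers=n_crossers,
        tie_broken=tie_broken,
    )
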
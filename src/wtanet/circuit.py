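"""Construction, validation and perturbation of the canonical selection circuit.

The network has four populations — input, inhibitory, amplifier, output —
with one unit per channel in each excitatory population and one inhibitory
unit per receptive field (one per channel in the default copy-and-paste
layout, or fewer multilobe units under a combinatorial code).  Each motif
contributes an independent connection block:

* feedforward inhibition: input -> inhibitory drive and inhibitory ->
  output/amplifier projections (global, i.e. including the source channel,
  unless the donut motif masks the within-channel entries to exactly zero);
* donut: zeroes the within-channel diagonal of the inhibitory projections;
* feedback inhibition: reciprocal inhibition between inhibitory units of
  distinct channels (direct inhibition-of-inhibition), or, in the
  ``indirect`` variant, an output -> inhibitory excitatory loop;
* amplifiers: strictly point-to-point recurrent excitation between each
  channel's output and amplifier unit.

All inhibitory weights are stored with negative sign (Dale-consistent);
perturbation operations return new ``Network`` objects and append to the
provenance trail.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import NetworkConfig
from .cosmi import CosmiCode, coverage_ok

__all__ = [
    "Network",
    "ValidationReport",
    "CheckResult",
    "build_network",
    "validate_network",
    "add_self_inhibition",
    "silence_feedback",
    "set_amplifier_gain",
    "to_edgelist",
]

POPULATIONS = ("input", "inhibitory", "amplifier", "output")
_PREFIX = {"input": "in", "inhibitory": "inh", "amplifier": "amp", "output": "out"}


@dataclass(frozen=True)
class Network:
    """A concrete wiring of the selection circuit.

    ``weights[(src, dst)]`` is an (n_src, n_dst) signed matrix; absent keys
    mean no connections.  ``rfs[u]`` lists the channels driving inhibitory
    unit u (its channel membership).
    """

    config: NetworkConfig
    rfs: tuple[tuple[int, ...], ...]
    weights: dict[tuple[str, str], np.ndarray]
    provenance: tuple[str, ...] = ()

    @property
    def n_channels(self) -> int:
        return self.config.n_channels

    @property
    def n_inhibitory(self) -> int:
        return len(self.rfs)

    def population_units(self, pop: str) -> list[str]:
        n = self.n_inhibitory if pop == "inhibitory" else self.n_channels
        return [f"{_PREFIX[pop]}{i}" for i in range(n)]

    def weight(self, src: str, dst: str) -> np.ndarray:
        """Connection block (zeros if the motif is absent)."""
        key = (src, dst)
        if key in self.weights:
            return self.weights[key]
        n_src = self.n_inhibitory if src == "inhibitory" else self.n_channels
        n_dst = self.n_inhibitory if dst == "inhibitory" else self.n_channels
        return np.zeros((n_src, n_dst))

    def _replace_weights(self, updates, note: str) -> "Network":
        new = dict(self.weights)
        new.update(updates)
        return dataclasses.replace(
            self, weights=new, provenance=self.provenance + (note,)
        )


@dataclass(frozen=True)
class CheckResult:
    name: str
    passed: bool
    offenders: tuple = ()


@dataclass(frozen=True)
class ValidationReport:
    checks: tuple[CheckResult, ...]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def __str__(self) -> str:
        lines = []
        for c in self.checks:
            status = "ok" if c.passed else "FAIL"
            extra = f"  offenders: {list(c.offenders)}" if c.offenders else ""
            lines.append(f"[{status}] {c.name}{extra}")
        return "\n".join(lines)


def _projection_mask(rfs, L: int, donut: bool) -> np.ndarray:
    """(n_units, L) boolean mask of channels each inhibitory unit projects to."""
    mask = np.ones((len(rfs), L), dtype=bool)
    if donut:
        for u, rf in enumerate(rfs):
            mask[u, list(rf)] = False
    return mask


def build_network(config: NetworkConfig) -> Network:
    """Realize a :class:`NetworkConfig` as concrete connection matrices.

    With all motifs disabled the channels are independent input -> output
    feedforward chains.  A supplied combinatorial code must pass pairwise
    coverage; otherwise the first uncovered ordered pair is reported.
    """
    L = config.n_channels
    g = config.gains
    gamma = config.inhibition_gain_multiplier

    if config.cosmi_code is not None:
        code = CosmiCode(L, config.cosmi_code)
        ok, uncovered = coverage_ok(code)
        if not ok:
            i, j = uncovered[0]
            raise ValueError(
                f"cosmi_code fails pairwise coverage: no inhibitory unit driven by "
                f"channel {i} projects to channel {j} "
                f"({len(uncovered)} uncovered ordered pairs)"
            )
        rfs = code.rfs
    else:
        rfs = tuple((c,) for c in range(L))
    U = len(rfs)

    weights: dict[tuple[str, str], np.ndarray] = {}
    weights[("input", "output")] = g.w_in * np.eye(L)

    if config.motifs.feedforward_inhibition:
        drive = np.zeros((L, U))
        for u, rf in enumerate(rfs):
            drive[list(rf), u] = g.w_ei
        weights[("input", "inhibitory")] = drive

        mask = _projection_mask(rfs, L, config.motifs.donut)
        w_io = np.where(mask, -g.w_ie * gamma, 0.0)
        if config.self_inhibition_fraction > 0 and config.motifs.donut:
            for u, rf in enumerate(rfs):
                off = w_io[u][mask[u]]
                mean_off = np.abs(off).mean() if off.size else 0.0
                w_io[u, list(rf)] = -config.self_inhibition_fraction * mean_off
        weights[("inhibitory", "output")] = w_io

        if config.motifs.amplifiers:
            w_ia = np.where(mask, -g.w_ia * gamma, 0.0)
            if config.self_inhibition_fraction > 0 and config.motifs.donut:
                for u, rf in enumerate(rfs):
                    off = w_ia[u][mask[u]]
                    mean_off = np.abs(off).mean() if off.size else 0.0
                    w_ia[u, list(rf)] = -config.self_inhibition_fraction * mean_off
            weights[("inhibitory", "amplifier")] = w_ia

    if config.motifs.feedback_inhibition:
        if config.feedback_variant == "direct":
            w_ii = np.zeros((U, U))
            for u in range(U):
                for v in range(U):
                    if u != v and not set(rfs[u]) & set(rfs[v]):
                        w_ii[u, v] = -g.w_ii
            weights[("inhibitory", "inhibitory")] = w_ii
        else:  # indirect: inhibition-of-inhibition routed through the output layer
            loop = np.zeros((L, U))
            for u, rf in enumerate(rfs):
                loop[list(rf), u] = g.w_ei
            weights[("output", "inhibitory")] = loop

    if config.motifs.amplifiers:
        weights[("output", "amplifier")] = g.w_amp * np.eye(L)
        weights[("amplifier", "output")] = g.w_amp * np.eye(L)

    for w in weights.values():
        w.setflags(write=False)
    return Network(config=config, rfs=rfs, weights=weights)


def validate_network(net: Network) -> ValidationReport:
    """Report each structural invariant with pass/fail and offending entries."""
    cfg = net.config
    checks: list[CheckResult] = []

    # Dale-like sign consistency
    bad_sign = []
    for (src, dst), w in net.weights.items():
        if src == "inhibitory":
            rows, cols = np.nonzero(w > 0)
        else:
            rows, cols = np.nonzero(w < 0)
        bad_sign.extend(
            (f"{_PREFIX[src]}{r}", f"{_PREFIX[dst]}{c}", float(w[r, c]))
            for r, c in zip(rows, cols)
        )
    checks.append(CheckResult("sign_consistency", not bad_sign, tuple(bad_sign)))

    # Donut zero-diagonal (expected pristine unless the config itself asks
    # for self-inhibition)
    if cfg.motifs.donut and cfg.motifs.feedforward_inhibition:
        expect_zero = cfg.self_inhibition_fraction == 0
        offenders = []
        if expect_zero:
            for dst in ("output", "amplifier"):
                if ("inhibitory", dst) not in net.weights:
                    continue
                w = net.weights[("inhibitory", dst)]
                for u, rf in enumerate(net.rfs):
                    for ch in rf:
                        if w[u, ch] != 0:
                            offenders.append((f"inh{u}", f"{_PREFIX[dst]}{ch}"))
        checks.append(CheckResult("donut_zero_diagonal", not offenders, tuple(offenders)))

    # Feedback block structure
    if cfg.motifs.feedback_inhibition and cfg.feedback_variant == "direct":
        w = net.weight("inhibitory", "inhibitory")
        offenders = []
        silenced = not np.any(w)
        if not silenced:
            for u in range(net.n_inhibitory):
                for v in range(net.n_inhibitory):
                    distinct = u != v and not set(net.rfs[u]) & set(net.rfs[v])
                    if distinct and w[u, v] == 0:
                        offenders.append((f"inh{u}", f"inh{v}", "missing"))
                    if not distinct and w[u, v] != 0:
                        offenders.append((f"inh{u}", f"inh{v}", "forbidden"))
        checks.append(
            CheckResult("feedback_reciprocity", not offenders, tuple(offenders))
        )
    else:
        w = net.weight("inhibitory", "inhibitory")
        offenders = tuple(
            (f"inh{u}", f"inh{v}")
            for u, v in zip(*np.nonzero(w))
        )
        checks.append(CheckResult("feedback_absent", not offenders, offenders))

    # Amplifier point-to-point
    offenders = []
    for src, dst in (("output", "amplifier"), ("amplifier", "output")):
        if (src, dst) in net.weights:
            w = net.weights[(src, dst)]
            off = w - np.diag(np.diag(w))
            offenders.extend(
                (f"{_PREFIX[src]}{r}", f"{_PREFIX[dst]}{c}")
                for r, c in zip(*np.nonzero(off))
            )
    checks.append(CheckResult("amplifier_point_to_point", not offenders, tuple(offenders)))

    return ValidationReport(tuple(checks))


def add_self_inhibition(net: Network, fraction: float) -> Network:
    """Fill in the donut: route a channel's own inhibitory drive back onto
    its output/amplifier units at ``fraction`` times the mean off-channel
    inhibitory weight.  Off-channel weights are untouched."""
    if not (net.config.motifs.donut and net.config.motifs.feedforward_inhibition):
        raise ValueError("add_self_inhibition requires the donut motif to be enabled")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    updates = {}
    for dst in ("output", "amplifier"):
        key = ("inhibitory", dst)
        if key not in net.weights:
            continue
        w = net.weights[key].copy()
        for u, rf in enumerate(net.rfs):
            off = [w[u, c] for c in range(net.n_channels) if c not in rf]
            mean_off = float(np.mean(np.abs(off))) if off else 0.0
            w[u, list(rf)] = -fraction * mean_off
        w.setflags(write=False)
        updates[key] = w
    return net._replace_weights(updates, f"add_self_inhibition(fraction={fraction})")


def silence_feedback(net: Network) -> Network:
    """Zero all inhibitory->inhibitory weights (leaving the inhibitory units
    and every other connection intact).  Idempotent."""
    if not net.config.motifs.feedback_inhibition:
        raise ValueError("silence_feedback requires feedback_inhibition to be enabled")
    updates = {}
    for key in (("inhibitory", "inhibitory"), ("output", "inhibitory")):
        if key in net.weights:
            z = np.zeros_like(net.weights[key])
            z.setflags(write=False)
            updates[key] = z
    return net._replace_weights(updates, "silence_feedback()")


def set_amplifier_gain(net: Network, channel: int, multiplier: float) -> Network:
    """Scale one channel's recurrent output<->amplifier weights."""
    if not net.config.motifs.amplifiers:
        raise ValueError("set_amplifier_gain requires amplifiers to be enabled")
    if not 0 <= channel < net.n_channels:
        raise ValueError(f"invalid channel id {channel}")
    if multiplier < 0:
        raise ValueError("multiplier must be non-negative")
    updates = {}
    for key in (("output", "amplifier"), ("amplifier", "output")):
        w = net.weights[key].copy()
        w[channel, channel] *= multiplier
        w.setflags(write=False)
        updates[key] = w
    return net._replace_weights(
        updates, f"set_amplifier_gain(channel={channel}, multiplier={multiplier})"
    )


def to_edgelist(net: Network) -> pd.DataFrame:
    """Edge-list view (source, target, weight, sign) of all nonzero connections."""
    rows = []
    for (src, dst), w in sorted(net.weights.items()):
        for r, c in zip(*np.nonzero(w)):
            rows.append(
                {
                    "source": f"{_PREFIX[src]}{r}",
                    "target": f"{_PREFIX[dst]}{c}",
                    "weight": float(w[r, c]),
                    "sign": int(np.sign(w[r, c])),
                }
            )
    return pd.DataFrame(rows, columns=["source", "target", "weight", "sign"])
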
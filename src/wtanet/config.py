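"""Network configuration: the declarative description of a selection circuit.

A :class:`NetworkConfig` specifies how many option channels exist, which
circuit motifs are wired in (global feedforward inhibition, donut-like
inhibition, reciprocal inhibition-of-inhibition feedback, point-to-point
recurrent amplifiers), the synaptic gains, the rate nonlinearity, and the
noise model.  Configs are plain data: hashable, serializable to YAML/JSON,
and deterministic inputs to :func:`wtanet.circuit.build_network`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import yaml

SCHEMA_VERSION = 1

_COMBINATION_RULES = ("linear", "max", "softmax")
_NOISE_SCALINGS = ("constant", "sqrt-mean")
_FEEDBACK_VARIANTS = ("direct", "indirect")


@dataclass(frozen=True)
class MotifFlags:
    """Independent on/off switches for the four circuit motifs."""

    feedforward_inhibition: bool = True
    donut: bool = True
    feedback_inhibition: bool = True
    amplifiers: bool = True


@dataclass(frozen=True)
class Gains:
    """Non-negative connection gains.

    w_in   input -> output excitation
    w_ei   input -> inhibitory excitation
    w_ie   inhibitory -> output inhibition (magnitude)
    w_ii   inhibitory -> inhibitory inhibition (magnitude)
    w_amp  output <-> amplifier recurrent excitation
    w_ia   inhibitory -> amplifier inhibition (magnitude)
    """

    w_in: float = 1.0
    w_ei: float = 1.0
    w_ie: float = 1.0
    w_ii: float = 1.0
    w_amp: float = 0.8
    w_ia: float = 1.0


@dataclass(frozen=True)
class Nonlinearity:
    """Saturating rate nonlinearity f(u) = r_max * tanh(slope * max(u - threshold, 0))."""

    threshold: float = 0.0
    slope: float = 0.01
    r_max: float = 100.0


@dataclass(frozen=True)
class InhibitoryNonlinearity:
    """Threshold/slope override for inhibitory units (r_max is shared globally).

    Inhibitory units need a higher threshold and a steeper slope than the
    excitatory relay so that (a) with feedback silenced, competitive
    inhibition switches on at a fixed drive level (a fixed category
    boundary), and (b) with feedback intact, the reciprocal
    inhibition-of-inhibition race is strongly winner-take-all.
    """

    threshold: float = 4.0
    slope: float = 0.1


@dataclass(frozen=True)
class NoiseModel:
    """Per-step Gaussian perturbation of each unit's input drive.

    ``sigma0`` is the stationary input-noise scale; internally the per-step
    standard deviation is ``sigma0 * sqrt(tau / dt)`` so that the variance of
    the filtered rate noise is independent of the integration step.  Under
    ``scaling='sqrt-mean'`` the sd additionally scales with the square root
    of the (rectified) mean drive.
    """

    sigma0: float = 0.2
    scaling: str = "constant"


@dataclass(frozen=True)
class NetworkConfig:
    n_channels: int = 2
    motifs: MotifFlags = field(default_factory=MotifFlags)
    gains: Gains = field(default_factory=Gains)
    inhibition_gain_multiplier: float = 1.0
    nonlinearity: Nonlinearity = field(default_factory=Nonlinearity)
    inhibitory_nonlinearity: InhibitoryNonlinearity = field(
        default_factory=InhibitoryNonlinearity
    )
    noise: NoiseModel = field(default_factory=NoiseModel)
    combination_rule: str = "softmax"
    softmax_temperature: float = 5.0
    # Receptive fields for inhibitory units, one tuple of channel indices per
    # unit.  None -> one single-channel inhibitory unit per channel (the
    # copy-and-paste layout).
    cosmi_code: Optional[tuple[tuple[int, ...], ...]] = None
    self_inhibition_fraction: float = 0.0
    feedback_variant: str = "direct"
    tau_ms: float = 10.0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        for name in ("w_in", "w_ei", "w_ie", "w_ii", "w_amp", "w_ia"):
            if getattr(self.gains, name) < 0:
                raise ValueError(f"gain {name} must be non-negative")
        if self.inhibition_gain_multiplier < 0:
            raise ValueError("inhibition_gain_multiplier must be non-negative")
        if self.nonlinearity.r_max <= 0:
            raise ValueError("r_max must be positive")
        if self.noise.sigma0 < 0:
            raise ValueError("sigma0 must be non-negative")
        if self.noise.scaling not in _NOISE_SCALINGS:
            raise ValueError(f"noise scaling must be one of {_NOISE_SCALINGS}")
        rule = self.combination_rule
        if rule == "softmax-weighted":  # accepted alias
            object.__setattr__(self, "combination_rule", "softmax")
        elif rule not in _COMBINATION_RULES:
            raise ValueError(f"combination_rule must be one of {_COMBINATION_RULES}")
        if self.softmax_temperature <= 0:
            raise ValueError("softmax_temperature must be positive")
        if not 0.0 <= self.self_inhibition_fraction <= 1.0:
            raise ValueError("self_inhibition_fraction must lie in [0, 1]")
        if self.feedback_variant not in _FEEDBACK_VARIANTS:
            raise ValueError(f"feedback_variant must be one of {_FEEDBACK_VARIANTS}")
        if self.tau_ms <= 0:
            raise ValueError("tau_ms must be positive")
        if self.cosmi_code is not None:
            code = tuple(tuple(sorted(int(c) for c in rf)) for rf in self.cosmi_code)
            if not code:
                raise ValueError("cosmi_code must contain at least one unit")
            for rf in code:
                if not rf:
                    raise ValueError("cosmi_code receptive fields must be non-empty")
                if any(c < 0 or c >= self.n_channels for c in rf):
                    raise ValueError("cosmi_code channel index out of range")
                if len(set(rf)) == self.n_channels:
                    raise ValueError(
                        "cosmi_code receptive fields must be strict subsets of channels"
                    )
            object.__setattr__(self, "cosmi_code", code)

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schema_version"] = SCHEMA_VERSION
        if d["cosmi_code"] is not None:
            d["cosmi_code"] = [list(rf) for rf in d["cosmi_code"]]
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "NetworkConfig":
        data = dict(data)
        data.pop("schema_version", None)
        kwargs: dict = {}
        for key, sub in (
            ("motifs", MotifFlags),
            ("gains", Gains),
            ("nonlinearity", Nonlinearity),
            ("inhibitory_nonlinearity", InhibitoryNonlinearity),
            ("noise", NoiseModel),
        ):
            if key in data:
                val = data.pop(key)
                kwargs[key] = sub(**val) if isinstance(val, dict) else val
        code = data.pop("cosmi_code", None)
        if code is not None:
            code = tuple(tuple(rf) for rf in code)
        kwargs["cosmi_code"] = code
        kwargs.update(data)
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "NetworkConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **changes) -> "NetworkConfig":
        return dataclasses.replace(self, **changes)

    def config_hash(self) -> str:
        """Stable content hash used for provenance stamping."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def default_config(n_channels: int = 2, **changes) -> NetworkConfig:
    """The full canonical circuit (all four motifs enabled) at default gains."""
    return NetworkConfig(n_channels=n_channels).replace(**changes)
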
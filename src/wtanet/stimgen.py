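"""Synthetic norm protocols, experiment configuration, and result bundles.

Protocols are lists of per-channel norm vectors (one per trial/condition);
experiments bind a network config to a registered assay, run it under a
master seed, and write tidy tables plus a structured summary with full
provenance (config hash, seed, package version).  Reruns of a deterministic
experiment are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .circuit import build_network, to_edgelist, validate_network
from .config import NetworkConfig
from .assays import (
    categorization_index,
    flexibility_assay,
    measure_crp,
    multi_option_assay,
    transition_norm,
    unitary_choice_assay,
    TransitionOutOfRangeError,
)

log = logging.getLogger("wtanet")

REGISTERED_ASSAYS = ("crp", "flexibility", "multi_option", "unitary_choice")


def _to_native(obj):
    """Recursively convert numpy scalars/arrays into plain Python types so
    that configs and summaries serialize cleanly to YAML/JSON."""
    if isinstance(obj, np.ndarray):
        return [_to_native(v) for v in obj.tolist()]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _to_native(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_native(v) for v in obj]
    return obj


def make_norm_protocol(kind: str, params: dict, seed: int = 0) -> list[np.ndarray]:
    """Generate a seeded list of per-channel norm vectors.

    kinds:
      ``pair_sweep``  — fixed ``norm_A`` against an ascending competitor grid
                        (``comp_start``, ``comp_stop``, ``comp_step`` or an
                        explicit ``competitor_norms`` list);
      ``multi_option``— ``n_options`` vectors with a ``winner_norm`` and
                        ``distracter_norm`` (optionally jittered by
                        ``jitter`` uniform noise, seeded), winner in
                        channel 0;
      ``single``      — one-option trials from a ``norms`` list.
    """
    rng = np.random.default_rng(seed)
    if kind == "pair_sweep":
        norm_A = float(params["norm_A"])
        if "competitor_norms" in params:
            comps = np.asarray(params["competitor_norms"], dtype=float)
        else:
            comps = np.arange(
                float(params["comp_start"]),
                float(params["comp_stop"]) + 1e-9,
                float(params.get("comp_step", 1.0)),
            )
        return [np.array([norm_A, c]) for c in comps]
    if kind == "multi_option":
        n = int(params["n_options"])
        if n < 2:
            raise ValueError("multi_option requires n_options >= 2")
        winner = float(params["winner_norm"])
        distracter = float(params["distracter_norm"])
        jitter = float(params.get("jitter", 0.0))
        n_repeats = int(params.get("n_repeats", 1))
        out = []
        for _ in range(n_repeats):
            v = np.full(n, distracter)
            if jitter > 0:
                v = v + rng.uniform(-jitter, jitter, size=n)
            v[0] = winner
            out.append(np.clip(v, 0.0, None))
        return out
    if kind == "single":
        return [np.array([float(x)]) for x in params["norms"]]
    raise ValueError(f"unknown protocol kind {kind!r}")


@dataclass(frozen=True)
class ExperimentConfig:
    network: NetworkConfig
    assay: str
    assay_params: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self) -> None:
        if self.assay not in REGISTERED_ASSAYS:
            raise ValueError(
                f"unknown assay {self.assay!r}; registered: {REGISTERED_ASSAYS}"
            )
        if not (isinstance(self.seed, (int, np.integer)) and self.seed >= 0):
            raise ValueError("seed must be a non-negative integer")

    def to_dict(self) -> dict:
        return {
            "network": self.network.to_dict(),
            "assay": self.assay,
            "assay_params": _to_native(self.assay_params),
            "seed": int(self.seed),
            "outdir": self.outdir,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        data = dict(data)
        data["network"] = NetworkConfig.from_dict(data["network"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _provenance(cfg: ExperimentConfig) -> dict:
    return {
        "config_hash": cfg.network.config_hash(),
        "seed": int(cfg.seed),
        "package_version": __version__,
        "assay": cfg.assay,
    }


def run_experiment(cfg: ExperimentConfig) -> Path:
    """Build the network, run the configured assay, and write a result bundle.

    The bundle directory holds ``config.yaml`` (round-trippable), a tidy
    ``table.tsv`` with one row per condition/point, and ``summary.json``
    embedding the config hash and master seed.  Failures are logged with the
    stage name; partial outputs are preserved.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)

    stage = "build_network"
    try:
        net = build_network(cfg.network)
        p = cfg.assay_params
        stage = f"assay:{cfg.assay}"
        summary: dict = _provenance(cfg)
        if cfg.assay == "crp":
            crp = measure_crp(
                net,
                norm_A=p["norm_A"],
                competitor_norms=p["competitor_norms"],
                n_trials=p.get("n_trials", 20),
                seed=cfg.seed,
            )
            table = pd.DataFrame(
                {
                    "competitor_norm": crp.competitor_norms,
                    "mean_response": crp.mean_response,
                    "sd_response": crp.sd_response,
                }
            )
            summary["norm_A"] = crp.norm_A
            summary["n_trials"] = crp.n_trials
            try:
                summary["categorization_index"] = categorization_index(crp)
            except ValueError as exc:
                summary["categorization_index"] = None
                log.warning("categorization index unavailable: %s", exc)
            try:
                summary["transition_norm"] = transition_norm(crp)
            except TransitionOutOfRangeError:
                summary["transition_norm"] = None
        elif cfg.assay == "flexibility":
            res = flexibility_assay(
                net,
                norm_A_low=p["norm_A_low"],
                norm_A_high=p["norm_A_high"],
                competitor_norms=p["competitor_norms"],
                n_trials=p.get("n_trials", 20),
                seed=cfg.seed,
            )
            table = pd.DataFrame(
                {
                    "norm_A": [res.norm_A_low, res.norm_A_high],
                    "transition_norm": [res.transition_norm_1, res.transition_norm_2],
                }
            )
            summary.update(
                {
                    "transition_norm_1": res.transition_norm_1,
                    "transition_norm_2": res.transition_norm_2,
                    "delta_A": res.delta_A,
                    "shift_ratio": res.shift_ratio,
                }
            )
        elif cfg.assay == "multi_option":
            res = multi_option_assay(
                net,
                conditions=p["conditions"],
                n_trials=p.get("n_trials", 20),
                seed=cfg.seed,
            )
            table = pd.DataFrame([dataclasses.asdict(c) for c in res.conditions])
            summary["n_conditions"] = len(res.conditions)
            summary["accuracies"] = [c.accuracy for c in res.conditions]
        else:  # unitary_choice
            stats = unitary_choice_assay(
                net,
                norms=p["norms"],
                threshold=p["threshold"],
                n_trials=p.get("n_trials", 100),
                seed=cfg.seed,
            )
            table = pd.DataFrame([dataclasses.asdict(stats)])
            summary.update(dataclasses.asdict(stats))

        stage = "write_outputs"
        table.to_csv(outdir / "table.tsv", sep="\t", index=False)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(_to_native(summary), fh, indent=2, sort_keys=True, allow_nan=True)
            fh.write("\n")
    except Exception:
        log.error("experiment failed at stage %s (partial outputs in %s)", stage, outdir)
        raise
    return outdir
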
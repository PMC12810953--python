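"""Strictly validated YAML configuration for the command-line interface.

Every tunable decision (filter widths, sparsity weights, optimizer settings,
escape temperature, surrogate shape, stopping mode, perturbation amplitudes)
is a named key; unknown keys are rejected so a typo cannot silently fall back
to a default.
"""

from __future__ import annotations

import hashlib
import json
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class NetworkConfig(_Strict):
    area_sizes: list[tuple[int, int]] = [(200, 50), (200, 50)]
    dt_ms: float = 1.0
    tau_exc_ms: float = 30.0
    tau_inh_ms: float = 10.0
    v_thr: float = 1.0
    v0: float = 0.2
    beta: float = 0.14
    refractory_ms: float = 4.0
    delays_ms: list[float] = [2.0, 3.0]
    dale: bool = True
    local_inhibition: bool = True
    dynamics: Literal["spiking", "sigmoid"] = "spiking"
    sigmoid_reset: bool = False
    surrogate_dampening: float = 0.3
    in_scale: float = 4.0


class TrainingConfig(_Strict):
    steps: int = 4000
    learning_rate: float = 1e-3
    batch_size: int = 32
    mode: Literal["reference", "reconstruction", "real"] = "reconstruction"
    psth_width_ms: float = 8.0
    pop_width_ms: float = 32.0
    lam1: float = 0.0
    lam2: float = 0.0
    lam3: float = 0.0
    eps_frac: float = 0.1
    use_trial_matching: bool = True
    prune: Optional[bool] = None
    select: Literal["last", "best"] = "last"
    seed: int = 0


class RefCircConfig(_Strict):
    hypothesis: Literal[1, 2] = 1
    n_trials: int = 2000
    duration_ms: float = 200.0
    onset_ms: float = 50.0
    peak_hz: float = 20.0
    hit_window_ms: float = 60.0
    seed: int = 0


class PerturbationConfig(_Strict):
    kind: Literal["activation", "inactivation"] = "inactivation"
    area: int = 1
    n_trials: int = 500
    power: float = 1.0
    activation_amp: float = 0.08
    inactivation_amp: float = 1.0
    ramp_fraction: float = 0.5
    seed: int = 0


class MicroConfig(_Strict):
    mode: Literal["high", "low", "zero_norm", "shuffled"] = "high"
    n_episodes: int = 100
    amplitude: float = 0.1
    window_ms: float = 100.0
    databank_trials: int = 200
    t_star_ms: float = 200.0
    seed: int = 0


class RunConfig(_Strict):
    network: NetworkConfig = NetworkConfig()
    training: TrainingConfig = TrainingConfig()
    refcirc: RefCircConfig = RefCircConfig()
    perturbation: PerturbationConfig = PerturbationConfig()
    micro: MicroConfig = MicroConfig()


def load_config(path: Optional[str]) -> RunConfig:
    if path is None:
        return RunConfig()
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    return RunConfig(**raw)


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
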
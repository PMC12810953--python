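"""Sensitivity maps of the jaw movement and gradient-targeted µ-perturbations.

For a model with a jaw readout, the integrated movement is Y = sum_t y_t.
The gradient map g_i^t = dY/du_i^t (computed by backpropagation through time,
with the surrogate derivative for spiking models and the true derivative for
the sigmoidal variant) predicts the effect of a small injected current
through the first-order expansion

    Delta Y = sum_{i, t in I} g_i^t Delta u_i^t + eps,

where I is the perturbed index set and eps vanishes as the current shrinks.
The closed-loop protocol exploits this: record an experimental preparation up
to a stimulation time t*, retrieve the most similar simulated trial from a
databank of model rollouts, and deliver the µ-perturbation to the neurons
with the most extreme gradients of the retrieved trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .backprop import backward
from .losses import TraceKit
from .network import NetworkModel, simulate

__all__ = [
    "GradientMap",
    "Databank",
    "movement_gradient",
    "verify_taylor",
    "select_target_neurons",
    "build_databank",
    "closed_loop_protocol",
    "micro_current",
]

MICRO_AMPLITUDE = 0.1   # default µ-perturbation current (10% of an inactivation)
MICRO_WINDOW_MS = 100.0


@dataclass
class GradientMap:
    """Per-neuron per-timestep sensitivities of the integrated movement."""

    g: np.ndarray          # (T, N) dY/du_i^t
    Y: float
    seed: int
    trial_id: int
    dt: float

    def __post_init__(self) -> None:
        if self.g.ndim != 2:
            raise ValueError("gradient map must be (T, N)")

    def binned(
        self, groups: Sequence[np.ndarray], window_steps: int
    ) -> np.ndarray:
        """Aggregate over (group x time-window) cells by summation."""
        T = self.g.shape[0]
        edges = list(range(0, T, window_steps)) + [T]
        out = np.zeros((len(groups), len(edges) - 1))
        for gi, sel in enumerate(groups):
            for wi in range(len(edges) - 1):
                out[gi, wi] = self.g[edges[wi] : edges[wi + 1], sel].sum()
        return out


def movement_gradient(
    model: NetworkModel, protocol, seed: int, trial_id: int = 0
) -> GradientMap:
    """dY/du for every neuron and timestep of one simulated trial."""
    if model.jaw is None:
        raise ValueError("model has no jaw readout")
    sim = simulate(
        model, protocol, 1, seed=seed, trial_ids=np.array([trial_id]), cache=True
    )
    gz = np.zeros_like(sim.z)
    gy = np.ones_like(sim.y)
    _, gv = backward(model, sim, gz, gy, return_gv=True)
    g = (gv[0] * (1.0 - model.neurons.alpha))  # du enters v through (1 - alpha)
    if not np.all(np.isfinite(g)):
        raise FloatingPointError("non-finite gradients in movement map")
    return GradientMap(
        g=g, Y=float(sim.y.sum()), seed=seed, trial_id=trial_id, dt=model.neurons.dt
    )


def verify_taylor(
    model: NetworkModel,
    gradmap: GradientMap,
    du: np.ndarray,
    protocol,
) -> tuple[float, float, float]:
    """Compare the actual movement change with the first-order prediction.

    Returns (Delta Y, prediction, residual).  The perturbed and unperturbed
    trials share the counter-based noise of the gradient map's trial.
    """
    sim_u = simulate(
        model, protocol, 1, seed=gradmap.seed, trial_ids=np.array([gradmap.trial_id])
    )
    sim_p = simulate(
        model,
        protocol,
        1,
        seed=gradmap.seed,
        trial_ids=np.array([gradmap.trial_id]),
        extra_current=du,
    )
    dY = float(sim_p.y.sum() - sim_u.y.sum())
    pred = float((gradmap.g * du).sum())
    return dY, pred, dY - pred


def select_target_neurons(
    gradmap: GradientMap,
    window_steps: tuple[int, int],
    mode: str = "high",
    k: int = 20,
    seed: int = 0,
    candidates: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Pick µ-perturbation targets from summed gradients within a window.

    Modes: ``high``/``low`` take the k most extreme summed gradients,
    ``zero_norm`` the k smallest absolute sums, ``shuffled`` a uniform
    random subset (seeded).
    """
    N = gradmap.g.shape[1]
    pool = np.arange(N) if candidates is None else np.asarray(candidates)
    if k > pool.size:
        raise ValueError("k exceeds candidate population size")
    sums = gradmap.g[window_steps[0] : window_steps[1], pool].sum(axis=0)
    if mode == "high":
        order = np.argsort(sums)[::-1]
    elif mode == "low":
        order = np.argsort(sums)
    elif mode == "zero_norm":
        order = np.argsort(np.abs(sums))
    elif mode == "shuffled":
        order = np.random.default_rng([seed, 1231]).permutation(pool.size)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pool[order[:k]]


def micro_current(
    n_steps: int,
    n_neurons: int,
    neuron_idx: np.ndarray,
    window_steps: tuple[int, int],
    amplitude: float = MICRO_AMPLITUDE,
) -> np.ndarray:
    """(T, N) current for a µ-perturbation confined to an index set."""
    du = np.zeros((n_steps, n_neurons))
    du[window_steps[0] : window_steps[1], np.asarray(neuron_idx)] = amplitude
    return du


@dataclass
class Databank:
    """Simulated trials with precomputed gradient maps and a retrieval index.

    The retrieval key is the 32 ms-filtered, per-area-normalized population
    trace truncated at the stimulation time t*; nearest neighbors are found
    with a KD-tree over those keys.
    """

    model: NetworkModel
    protocol: object
    t_star_step: int
    seed: int
    spikes: np.ndarray                   # (n, T, N)
    jaw: np.ndarray                      # (n, T)
    gradmaps: list = field(default_factory=list)
    keys: Optional[np.ndarray] = None
    _nn: object = None
    _kit: object = None
    _stats: object = None

    @property
    def n_trials(self) -> int:
        return self.spikes.shape[0]

    def key_of(self, spikes: np.ndarray) -> np.ndarray:
        """Retrieval key for (K, T', N) activity truncated at/after t*."""
        tr = self._kit.normalized_pop(spikes[:, : self.t_star_step, :], self._stats)
        return tr.reshape(tr.shape[0], -1)

    def query(self, spikes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Nearest stored trial for each query; returns (indices, distances)."""
        if self.n_trials == 0:
            raise ValueError("retrieval on empty databank")
        q = self.key_of(spikes)
        dist, idx = self._nn.kneighbors(q, n_neighbors=1)
        return idx[:, 0], dist[:, 0] ** 2


def build_databank(
    model: NetworkModel,
    protocol,
    n_trials: int,
    t_star_ms: float,
    seed: int = 0,
) -> Databank:
    """Simulate trials, compute their gradient maps, and index them."""
    from sklearn.neighbors import NearestNeighbors

    t_star = int(round(t_star_ms / model.neurons.dt))
    sim = simulate(model, protocol, n_trials, seed=seed)
    maps = [
        movement_gradient(model, protocol, seed=seed, trial_id=i)
        for i in range(n_trials)
    ]
    kit = TraceKit(t_star, model.neurons.dt, model.neurons.area)
    stats = kit.pop_stats(sim.z[:, :t_star, :])
    bank = Databank(
        model=model,
        protocol=protocol,
        t_star_step=t_star,
        seed=seed,
        spikes=sim.z,
        jaw=sim.y,
        gradmaps=maps,
        _kit=kit,
        _stats=stats,
    )
    bank.keys = bank.key_of(sim.z)
    bank._nn = NearestNeighbors(n_neighbors=1).fit(bank.keys)
    return bank


def closed_loop_protocol(
    preparation: NetworkModel,
    databank: Databank,
    mode: str,
    n_episodes: int,
    seed: int = 0,
    *,
    k: Optional[int] = None,
    amplitude: float = MICRO_AMPLITUDE,
    window_ms: float = MICRO_WINDOW_MS,
) -> "pd.DataFrame":
    """Gradient-targeted µ-perturbation of an experimental preparation.

    Per episode: simulate the preparation up to t*, retrieve the closest
    databank trial, select targets from its gradient map (``high``, ``low``,
    ``zero_norm`` with k = 40, or ``shuffled`` with k = 20), deliver the
    µ-perturbation at t* with matched noise, and record the movement change.
    """
    import pandas as pd

    if k is None:
        k = 40 if mode == "zero_norm" else 20
    proto = databank.protocol
    T = proto.n_steps
    t0 = databank.t_star_step
    t1 = min(T, t0 + int(round(window_ms / preparation.neurons.dt)))
    rows = []
    for ep in range(n_episodes):
        tid = np.array([1_000_000 + ep])
        sim_u = simulate(preparation, proto, 1, seed=seed, trial_ids=tid)
        idx, dist = databank.query(sim_u.z)
        gmap = databank.gradmaps[int(idx[0])]
        targets = select_target_neurons(
            gmap, (t0, t1), mode=mode, k=k, seed=seed + ep
        )
        du = micro_current(T, preparation.n, targets, (t0, t1), amplitude)
        sim_p = simulate(preparation, proto, 1, seed=seed, trial_ids=tid, extra_current=du)
        Y_u = float(sim_u.y.sum())
        Y_p = float(sim_p.y.sum())
        rows.append(
            {
                "episode": ep,
                "mode": mode,
                "retrieved": int(idx[0]),
                "retrieval_dist": float(dist[0]),
                "Y_unpert": Y_u,
                "Y_pert": Y_p,
                "dY": Y_p - Y_u,
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)
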
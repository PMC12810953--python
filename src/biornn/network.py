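"""Recurrent circuit models: stochastic leaky integrate-and-fire and sigmoidal rate
networks with synaptic delays, cell-type sign constraints and a jaw readout.

The membrane voltage of neuron ``j`` follows

    v_j^t = alpha_j v_j^{t-1} + (1 - alpha_j) u_j^t - v_thr_j z_j^{t-1} + xi_j^t
    u_j^t = sum_{d,i} W^rec,d_{ij} z_i^{t-d} / dt + sum_i W^in_{ij} x_i^t / dt

with ``alpha_j = exp(-dt / tau_m_j)``, Gaussian voltage noise ``xi`` of standard
deviation ``beta_j v_thr_j sqrt(dt)``, and binary spikes sampled from a Bernoulli
with escape rate ``min(1, exp((v - v_thr)/v_0))`` followed by an absolute
refractory period.  The sigmoidal variant replaces the Bernoulli draw by the
deterministic rate ``sigmoid((v - v_thr)/v_0)`` with no refractoriness and,
by default, no reset.

Noise is counter based: each (trial, neuron, step) draw is fixed by the trial
seed alone, so a perturbation current changes the simulation only through the
injected current and never through the noise stream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

EXC = 1
INH = -1

__all__ = [
    "EXC",
    "INH",
    "NeuronParams",
    "ConnectivitySpec",
    "JawReadout",
    "StimulusProtocol",
    "SessionMap",
    "NetworkModel",
    "SimResult",
    "default_neuron_params",
    "make_connectivity",
    "initialize_weights",
    "simulate",
    "save_model",
    "load_model",
]


def round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class NeuronParams:
    """Per-neuron membrane parameters.

    ``cell_type`` is +1 for excitatory and -1 for inhibitory neurons; ``area``
    is an integer area label per neuron.  ``alpha`` is always derived from the
    current ``dt`` and ``tau_m`` so it can never go stale.
    """

    dt: float
    tau_m: np.ndarray
    v_thr: np.ndarray
    v0: float
    beta: np.ndarray
    cell_type: np.ndarray
    area: np.ndarray
    refractory_ms: float = 4.0

    def __post_init__(self) -> None:
        for name in ("tau_m", "v_thr", "beta", "cell_type", "area"):
            setattr(self, name, np.asarray(getattr(self, name)))
        if self.v0 <= 0:
            raise ValueError("escape temperature v0 must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if np.any(self.tau_m <= 0):
            raise ValueError("membrane time constants must be positive")
        alpha = self.alpha
        if np.any((alpha <= 0) | (alpha >= 1)):
            raise ValueError("alpha must lie strictly in (0, 1)")
        if not np.all(np.isin(self.cell_type, (EXC, INH))):
            raise ValueError("cell_type entries must be +1 or -1")

    @property
    def n(self) -> int:
        return self.tau_m.shape[0]

    @property
    def alpha(self) -> np.ndarray:
        return np.exp(-self.dt / self.tau_m)

    @property
    def refractory_steps(self) -> int:
        return round_half_up(self.refractory_ms / self.dt)

    @property
    def excitatory(self) -> np.ndarray:
        return self.cell_type == EXC

    @property
    def inhibitory(self) -> np.ndarray:
        return self.cell_type == INH


def default_neuron_params(
    area_sizes: Sequence[tuple[int, int]],
    dt: float,
    *,
    tau_exc: float = 30.0,
    tau_inh: float = 10.0,
    v_thr: float = 1.0,
    v0: float = 0.2,
    beta: float = 0.14,
    refractory_ms: float = 4.0,
) -> NeuronParams:
    """Build neuron parameters for areas of ``(n_excitatory, n_inhibitory)`` sizes.

    Within each area excitatory neurons come first.  The default escape
    temperature is 0.2 in units of the initial threshold (v_thr = 1).
    """
    cell_type, area = [], []
    for a, (n_e, n_i) in enumerate(area_sizes):
        cell_type.extend([EXC] * n_e + [INH] * n_i)
        area.extend([a] * (n_e + n_i))
    cell_type = np.array(cell_type)
    area = np.array(area)
    tau = np.where(cell_type == EXC, tau_exc, tau_inh).astype(float)
    n = len(cell_type)
    return NeuronParams(
        dt=dt,
        tau_m=tau,
        v_thr=np.full(n, float(v_thr)),
        v0=float(v0),
        beta=np.full(n, float(beta)),
        cell_type=cell_type,
        area=area,
        refractory_ms=refractory_ms,
    )


@dataclass
class ConnectivitySpec:
    """Sign-constrained delayed connectivity.

    ``efficacy[d, i, j]`` is the non-negative synaptic efficacy from presynaptic
    neuron ``i`` to postsynaptic ``j`` in delay bin ``d``; each synapse lives in
    exactly one delay bin (``delay_mask`` is one-hot across ``d`` on allowed
    entries).  The effective weight is ``efficacy * sign[i]`` when Dale's law is
    enforced; otherwise ``efficacy`` may carry either sign and ``sign`` is +1.
    """

    efficacy: np.ndarray            # (D, N, N), row = presynaptic
    sign: np.ndarray                # (N,) +-1
    delay_steps: tuple[int, ...]    # per delay bin, in simulation steps
    delay_mask: np.ndarray          # (D, N, N) bool
    in_weights: np.ndarray          # (C, N) non-negative
    allowed: np.ndarray             # (N, N) bool structural mask
    pruned: np.ndarray              # (N, N) bool, permanently removed synapses
    dale: bool = True
    local_inhibition: bool = True
    prune_threshold: float = 1e-7

    @property
    def n(self) -> int:
        return self.efficacy.shape[1]

    @property
    def n_delays(self) -> int:
        return self.efficacy.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.in_weights.shape[0]

    def effective_weights(self) -> np.ndarray:
        """Signed weight matrices, shape (D, N, N)."""
        w = self.efficacy * self.delay_mask
        if self.dale:
            w = w * self.sign[None, :, None]
        return w

    def total_weights(self) -> np.ndarray:
        """Signed weights summed over delay bins, shape (N, N)."""
        return self.effective_weights().sum(axis=0)

    def project_(self, prune: bool = False) -> None:
        """Re-impose all constraints in place (sign, masks, pruning).

        Called after every optimizer update; idempotent.
        """
        if self.dale:
            np.clip(self.efficacy, 0.0, None, out=self.efficacy)
        self.efficacy *= self.delay_mask
        self.efficacy *= self.allowed[None, :, :]
        if prune:
            below = self.efficacy.sum(axis=0) < self.prune_threshold
            self.pruned |= below & self.allowed
        self.efficacy *= ~self.pruned[None, :, :]
        if self.dale:
            np.clip(self.in_weights, 0.0, None, out=self.in_weights)

    def check_dale(self) -> None:
        """Raise if any effective weight violates the sign constraints."""
        if not self.dale:
            return
        w = self.total_weights()
        bad_exc = (w[self.sign == EXC] < 0).any()
        bad_inh = (w[self.sign == INH] > 0).any()
        if bad_exc or bad_inh:
            raise AssertionError("Dale's law violated in effective weights")


def make_connectivity(
    neurons: NeuronParams,
    n_inputs: int = 1,
    *,
    delays_ms: Sequence[float] = (2.0, 3.0),
    dale: bool = True,
    local_inhibition: bool = True,
    no_feedback: Optional[tuple[int, int]] = None,
    autapses: bool = False,
    seed: int = 0,
) -> ConnectivitySpec:
    """Create the structural scaffold: masks, signs and random delay assignment.

    ``no_feedback=(src, dst)`` structurally zeroes every synapse from area
    ``src`` to area ``dst`` (the feedforward reference-circuit constraint).
    Delays are drawn per synapse uniformly from ``delays_ms`` with the given
    seed; at coarse ``dt`` they round half-up to integer steps (3 ms at
    dt = 2 ms maps to 2 steps).
    """
    n = neurons.n
    rng = np.random.default_rng([seed, 2971]) if np.isscalar(seed) else np.random.default_rng(seed)
    allowed = np.ones((n, n), dtype=bool)
    if not autapses:
        np.fill_diagonal(allowed, False)
    if local_inhibition:
        inh = neurons.inhibitory
        cross = neurons.area[:, None] != neurons.area[None, :]
        allowed &= ~(inh[:, None] & cross)
    if no_feedback is not None:
        src, dst = no_feedback
        allowed &= ~((neurons.area[:, None] == src) & (neurons.area[None, :] == dst))

    steps = tuple(max(1, round_half_up(d / neurons.dt)) for d in delays_ms)
    d_bins = len(steps)
    choice = rng.integers(0, d_bins, size=(n, n))
    delay_mask = np.zeros((d_bins, n, n), dtype=bool)
    for d in range(d_bins):
        delay_mask[d] = (choice == d) & allowed

    sign = neurons.cell_type.copy() if dale else np.ones(n, dtype=int)
    return ConnectivitySpec(
        efficacy=np.zeros((d_bins, n, n)),
        sign=sign,
        delay_steps=steps,
        delay_mask=delay_mask,
        in_weights=np.zeros((n_inputs, n)),
        allowed=allowed,
        pruned=np.zeros((n, n), dtype=bool),
        dale=dale,
        local_inhibition=local_inhibition,
    )


def initialize_weights(
    conn: ConnectivitySpec,
    neurons: NeuronParams,
    seed: int = 0,
    *,
    in_scale: float = 4.0,
    cross_gain: float = 1.0,
) -> ConnectivitySpec:
    """Random weight initialization with balance and spectral normalization.

    For sign-constrained networks, incoming excitation and inhibition are
    balanced to zero sum per target neuron; the signed matrix (summed over
    delays) is then rescaled by the modulus of its largest eigenvalue so that
    all eigenvalue moduli are at most 1.  Unconstrained networks skip the
    balancing and only receive the spectral normalization.

    ``cross_gain`` scales the cross-area blocks before balancing, making
    inter-area projections dynamically effective relative to local ones
    (used by the reference-circuit benchmark, whose whole point is that
    inter-area coupling carries signal).
    """
    rng = np.random.default_rng([seed, 7919])
    n = conn.n
    mag = np.abs(rng.normal(0.0, 1.0, size=(conn.n_delays, n, n)))
    if not conn.dale:
        mag = rng.normal(0.0, 1.0, size=(conn.n_delays, n, n))
    if cross_gain != 1.0:
        cross = neurons.area[:, None] != neurons.area[None, :]
        mag *= np.where(cross[None], cross_gain, 1.0)
    mag *= conn.delay_mask
    conn.efficacy = mag

    if conn.dale:
        total = conn.efficacy.sum(axis=0)  # unsigned efficacies, (N, N)
        exc = neurons.excitatory
        inh = neurons.inhibitory
        sum_e = total[exc].sum(axis=0)
        sum_i = total[inh].sum(axis=0)
        no_inh = (sum_i <= 0) & (sum_e > 0)
        if no_inh.any():
            raise ValueError(
                "cannot balance input weights: neurons with no incoming "
                f"inhibitory synapses: {np.flatnonzero(no_inh).tolist()}"
            )
        scale = np.ones(n)
        ok = sum_i > 0
        scale[ok] = sum_e[ok] / sum_i[ok]
        conn.efficacy[:, inh, :] *= scale[None, None, :]

    w = conn.total_weights()
    radius = np.max(np.abs(np.linalg.eigvals(w)))
    if radius > 0:
        conn.efficacy /= radius
    conn.in_weights = in_scale * rng.random((conn.n_inputs, n))
    conn.project_()
    return conn


@dataclass
class JawReadout:
    """Exponential linear readout of the jaw trace from excitatory spikes.

    ``y_t = exp(ytilde_t) + b`` with ``ytilde`` a leaky integrator (time
    constant ``tau_jaw``) of delayed excitatory spiking weighted by ``w``.
    Weights of inhibitory neurons are structurally zero.
    """

    w: np.ndarray                # (N,), zero on inhibitory neurons
    b: float
    tau_jaw: float               # ms
    delay_steps: np.ndarray      # (N,) per-neuron synaptic delay in steps
    exc_mask: np.ndarray         # (N,) bool

    def alpha(self, dt: float) -> float:
        return float(np.exp(-dt / self.tau_jaw))

    def project_(self) -> None:
        self.w[~self.exc_mask] = 0.0


def make_jaw_readout(
    neurons: NeuronParams,
    *,
    tau_jaw: float = 5.0,
    scale: float = 0.01,
    b: float = 0.0,
    seed: int = 0,
) -> JawReadout:
    rng = np.random.default_rng([seed, 6673])
    n = neurons.n
    exc = neurons.excitatory
    w = rng.normal(0.0, scale, size=n)
    w[~exc] = 0.0
    delays = np.array(
        [max(1, round_half_up(d / neurons.dt)) for d in rng.choice([2.0, 3.0], size=n)]
    )
    return JawReadout(w=w, b=float(b), tau_jaw=tau_jaw, delay_steps=delays, exc_mask=exc)


@dataclass
class StimulusProtocol:
    """Binary pulse input channels (10 ms pulses by default)."""

    dt: float
    duration_ms: float
    onsets_ms: dict[str, float] = field(default_factory=dict)
    pulse_ms: float = 10.0

    @property
    def n_steps(self) -> int:
        return int(round(self.duration_ms / self.dt))

    @property
    def channels(self) -> list[str]:
        return list(self.onsets_ms)

    def signal(self) -> np.ndarray:
        """(T, C) binary pulse array; each pulse spans ceil(pulse/dt) steps."""
        T = self.n_steps
        x = np.zeros((T, max(1, len(self.onsets_ms))), dtype=np.uint8)
        width = int(np.ceil(self.pulse_ms / self.dt))
        for c, (_, onset) in enumerate(self.onsets_ms.items()):
            start = int(round(onset / self.dt))
            if start < 0 or start >= T:
                raise ValueError(f"stimulus onset {onset} ms outside trial")
            x[start : min(T, start + width), c] = 1
        return x

    def step_of(self, t_ms: float) -> int:
        return int(round(t_ms / self.dt))


@dataclass
class FixedStimulus:
    """A precomputed (T, C) binary stimulus array acting as a protocol."""

    dt: float
    x: np.ndarray

    @property
    def n_steps(self) -> int:
        return self.x.shape[0]

    def signal(self) -> np.ndarray:
        return np.asarray(self.x)

    def step_of(self, t_ms: float) -> int:
        return int(round(t_ms / self.dt))


@dataclass
class SessionMap:
    """Injective map from model neurons to recorded units across sessions."""

    session: np.ndarray   # (N,) session id per model neuron
    unit: np.ndarray      # (N,) recorded unit id within the session

    def __post_init__(self) -> None:
        pairs = list(zip(self.session.tolist(), self.unit.tolist()))
        if len(set(pairs)) != len(pairs):
            raise ValueError("session map must be injective")

    def neurons_of(self, session) -> np.ndarray:
        return np.flatnonzero(self.session == session)


@dataclass
class NetworkModel:
    """One recurrent circuit model: parameters, connectivity and readout."""

    neurons: NeuronParams
    conn: ConnectivitySpec
    jaw: Optional[JawReadout] = None
    dynamics: str = "spiking"            # "spiking" | "sigmoid"
    sigmoid_reset: bool = False
    surrogate_dampening: float = 0.3
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dynamics not in ("spiking", "sigmoid"):
            raise ValueError(f"unknown dynamics {self.dynamics!r}")
        if self.conn.n != self.neurons.n:
            raise ValueError("connectivity and neuron parameter sizes differ")

    @property
    def n(self) -> int:
        return self.neurons.n

    def copy(self) -> "NetworkModel":
        import copy as _copy

        return _copy.deepcopy(self)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


@dataclass
class SimResult:
    """Output of a batched rollout.

    ``z`` holds binary spikes (spiking dynamics) or rates in [0, 1]
    (sigmoidal dynamics), shape (K, T, N).  When built with ``cache=True``
    the result carries everything the backward pass needs.
    """

    z: np.ndarray
    dt: float
    seed: int
    trial_ids: np.ndarray
    y: Optional[np.ndarray] = None        # (K, T) jaw trace
    ytilde: Optional[np.ndarray] = None
    v: Optional[np.ndarray] = None        # (K, T, N)
    psi: Optional[np.ndarray] = None      # surrogate dz/dv
    eps: Optional[np.ndarray] = None      # standard-normal noise draws
    x: Optional[np.ndarray] = None        # (T, C) stimulus
    extra_current: Optional[np.ndarray] = None

    @property
    def n_trials(self) -> int:
        return self.z.shape[0]

    def rates_hz(self, window: Optional[tuple[int, int]] = None) -> np.ndarray:
        """Per-neuron firing rate in Hz, optionally within a step window."""
        z = self.z if window is None else self.z[:, window[0] : window[1], :]
        return z.mean(axis=1) * (1000.0 / self.dt)


def escape_probability(v: np.ndarray, neurons: NeuronParams) -> np.ndarray:
    """Bernoulli spike probability min(1, exp((v - v_thr)/v_0))."""
    arg = (v - neurons.v_thr) / neurons.v0
    return np.exp(np.minimum(arg, 0.0))


def sample_spikes(
    v: np.ndarray,
    neurons: NeuronParams,
    refractory: np.ndarray,
    uniforms: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample binary spikes from the escape probability.

    Spikes are forced to zero while the refractory countdown is positive; a
    spike resets the countdown to the refractory duration in steps.  Returns
    (spikes, updated countdown).
    """
    prob = escape_probability(v, neurons)
    ok = refractory <= 0
    z = ((uniforms < prob) & ok).astype(float)
    new_refrac = np.where(z > 0, neurons.refractory_steps, np.maximum(refractory - 1, 0))
    return z, new_refrac


def _draw_noise(n_trials: int, T: int, n: int, seed: int, trial_ids: np.ndarray):
    """Counter-based draws: stream fixed by (seed, trial id), not call order."""
    eps = np.empty((n_trials, T, n))
    uni = np.empty((n_trials, T, n))
    for k, tid in enumerate(trial_ids):
        rng = np.random.default_rng([int(seed), int(tid)])
        eps[k] = rng.standard_normal((T, n))
        uni[k] = rng.random((T, n))
    return eps, uni


def simulate(
    model: NetworkModel,
    protocol: StimulusProtocol,
    n_trials: int,
    seed: int,
    *,
    trial_ids: Optional[np.ndarray] = None,
    extra_current: Optional[np.ndarray] = None,
    cache: bool = False,
    record_voltage: bool = False,
) -> SimResult:
    """Roll out ``n_trials`` independent trials of the network.

    Reproducibility contract: identical (model, protocol, seed, trial_ids)
    give bit-identical spike trains; ``extra_current`` (a perturbation, shape
    (T, N)) alters the outcome only through the injected current because the
    noise is counter based.
    """
    p = model.neurons
    conn = model.conn
    if conn.n != p.n:
        raise ValueError("model dimension mismatch")
    T = protocol.n_steps
    n = p.n
    if abs(protocol.dt - p.dt) > 1e-12:
        raise ValueError("protocol and model dt differ")
    if extra_current is not None:
        extra_current = np.asarray(extra_current, dtype=float)
        if extra_current.shape != (T, n):
            raise ValueError(
                f"extra_current shape {extra_current.shape} != (T={T}, N={n})"
            )
    if trial_ids is None:
        trial_ids = np.arange(n_trials)
    trial_ids = np.asarray(trial_ids)

    x = protocol.signal().astype(float)
    if x.shape[1] != conn.n_inputs:
        if conn.n_inputs == 1 and x.shape[1] > 1:
            x = x.sum(axis=1, keepdims=True)
        else:
            raise ValueError("stimulus channel count does not match input weights")

    eps, uni = _draw_noise(n_trials, T, n, seed, trial_ids)
    alpha = p.alpha
    v_thr = p.v_thr
    noise_sd = p.beta * v_thr * np.sqrt(p.dt)
    xi = eps * noise_sd  # (K, T, N)

    weff = model.conn.effective_weights()  # (D, N, N)
    dsteps = conn.delay_steps
    w_stack = np.concatenate(list(weff), axis=0)  # (D*N, N)
    in_drive = (x @ conn.in_weights) / p.dt  # (T, N)
    if extra_current is not None:
        in_drive = in_drive + extra_current

    spiking = model.dynamics == "spiking"
    z = np.zeros((n_trials, T, n))
    v = np.zeros((n_trials, T, n)) if (cache or record_voltage) else None
    psi = np.zeros((n_trials, T, n)) if cache else None
    v_prev = np.zeros((n_trials, n))
    refrac = np.zeros((n_trials, n), dtype=np.int64)
    damp = model.surrogate_dampening

    zin = np.zeros((n_trials, len(dsteps) * n))
    for t in range(T):
        for d, ds in enumerate(dsteps):
            src = z[:, t - ds, :] if t - ds >= 0 else 0.0
            zin[:, d * n : (d + 1) * n] = src
        u = zin @ w_stack / p.dt + in_drive[t]
        z_prev = z[:, t - 1, :] if t > 0 else 0.0
        reset = v_thr * z_prev if (spiking or model.sigmoid_reset) else 0.0
        v_t = alpha * v_prev + (1.0 - alpha) * u - reset + xi[:, t, :]
        if not np.all(np.isfinite(v_t)):
            bad = np.argwhere(~np.isfinite(v_t))
            raise FloatingPointError(
                f"non-finite voltage at step {t}, neuron index {bad[0][1]}"
            )
        arg = (v_t - v_thr) / p.v0
        if spiking:
            if cache:
                tri = np.maximum(0.0, 1.0 - np.abs(arg)) * (damp / p.v0)
                tri[refrac > 0] = 0.0
                psi[:, t, :] = tri
            z_t, refrac = sample_spikes(v_t, p, refrac, uni[:, t, :])
        else:
            sig = 1.0 / (1.0 + np.exp(-np.clip(arg, -60.0, 60.0)))
            z_t = sig
            if cache:
                psi[:, t, :] = sig * (1.0 - sig) / p.v0
        z[:, t, :] = z_t
        if v is not None:
            v[:, t, :] = v_t
        v_prev = v_t

    y = ytilde = None
    if model.jaw is not None:
        y, ytilde = _jaw_forward(model, z)

    return SimResult(
        z=z,
        dt=p.dt,
        seed=int(seed),
        trial_ids=trial_ids,
        y=y,
        ytilde=ytilde,
        v=v,
        psi=psi,
        eps=eps if cache else None,
        x=x,
        extra_current=extra_current,
    )


def _jaw_forward(model: NetworkModel, z: np.ndarray):
    jaw = model.jaw
    p = model.neurons
    K, T, n = z.shape
    aj = jaw.alpha(p.dt)
    drive = np.zeros((K, T))
    for ds in np.unique(jaw.delay_steps):
        sel = (jaw.delay_steps == ds) & jaw.exc_mask
        if not sel.any():
            continue
        shifted = np.zeros((K, T))
        shifted[:, ds:] = z[:, : T - ds, sel] @ jaw.w[sel]
        drive += shifted
    ytilde = np.zeros((K, T))
    prev = np.zeros(K)
    for t in range(T):
        prev = aj * prev + (1.0 - aj) * drive[:, t]
        ytilde[:, t] = prev
    y = np.exp(ytilde) + jaw.b
    return y, ytilde


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_SCALARS = {
    "dt",
    "v0",
    "refractory_ms",
    "dynamics",
    "sigmoid_reset",
    "surrogate_dampening",
    "dale",
    "local_inhibition",
    "prune_threshold",
    "jaw_b",
    "jaw_tau",
    "meta",
    "delay_steps",
    "rng_scheme",
}


def save_model(model: NetworkModel, path) -> None:
    """Lossless single-file archive (NPZ) of every matrix, mask and scalar."""
    p, c = model.neurons, model.conn
    scalars = {
        "dt": p.dt,
        "v0": p.v0,
        "refractory_ms": p.refractory_ms,
        "dynamics": model.dynamics,
        "sigmoid_reset": model.sigmoid_reset,
        "surrogate_dampening": model.surrogate_dampening,
        "dale": c.dale,
        "local_inhibition": c.local_inhibition,
        "prune_threshold": c.prune_threshold,
        "delay_steps": list(c.delay_steps),
        "rng_scheme": "counter:philox-seedseq(seed,trial)",
        "meta": model.meta,
    }
    arrays = dict(
        tau_m=p.tau_m,
        v_thr=p.v_thr,
        beta=p.beta,
        cell_type=p.cell_type,
        area=p.area,
        efficacy=c.efficacy,
        sign=c.sign,
        delay_mask=c.delay_mask,
        in_weights=c.in_weights,
        allowed=c.allowed,
        pruned=c.pruned,
    )
    if model.jaw is not None:
        scalars["jaw_b"] = model.jaw.b
        scalars["jaw_tau"] = model.jaw.tau_jaw
        arrays["jaw_w"] = model.jaw.w
        arrays["jaw_delay_steps"] = model.jaw.delay_steps
        arrays["jaw_exc_mask"] = model.jaw.exc_mask
    np.savez(path, _scalars=json.dumps(scalars), **arrays)


def load_model(path) -> NetworkModel:
    with np.load(path, allow_pickle=False) as f:
        s = json.loads(str(f["_scalars"]))
        a = {k: f[k] for k in f.files if k != "_scalars"}
    neurons = NeuronParams(
        dt=s["dt"],
        tau_m=a["tau_m"],
        v_thr=a["v_thr"],
        v0=s["v0"],
        beta=a["beta"],
        cell_type=a["cell_type"],
        area=a["area"],
        refractory_ms=s["refractory_ms"],
    )
    conn = ConnectivitySpec(
        efficacy=a["efficacy"],
        sign=a["sign"],
        delay_steps=tuple(s["delay_steps"]),
        delay_mask=a["delay_mask"].astype(bool),
        in_weights=a["in_weights"],
        allowed=a["allowed"].astype(bool),
        pruned=a["pruned"].astype(bool),
        dale=bool(s["dale"]),
        local_inhibition=bool(s["local_inhibition"]),
        prune_threshold=s["prune_threshold"],
    )
    jaw = None
    if "jaw_w" in a:
        jaw = JawReadout(
            w=a["jaw_w"],
            b=s["jaw_b"],
            tau_jaw=s["jaw_tau"],
            delay_steps=a["jaw_delay_steps"],
            exc_mask=a["jaw_exc_mask"].astype(bool),
        )
    return NetworkModel(
        neurons=neurons,
        conn=conn,
        jaw=jaw,
        dynamics=s["dynamics"],
        sigmoid_reset=bool(s["sigmoid_reset"]),
        surrogate_dampening=s["surrogate_dampening"],
        meta=s.get("meta", {}),
    )
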
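"""Loss functions for network reconstruction.

Two data-fitting terms are used throughout:

* the trial-averaged (PSTH) loss: per-neuron trial-averaged spiking is
  smoothed with an 8 ms boxcar, z-scored against the *recorded* trace's
  time mean and time standard deviation, and compared by summed squared error;
* the trial-matching loss: per-trial population-average traces per area are
  smoothed with a 32 ms boxcar, normalized by the recorded traces' trial mean
  and trial standard deviation at each time point, concatenated across areas
  (plus the jaw as an extra area when present), and compared under the best
  one-to-one assignment between model and data trials (Hungarian algorithm).

Each loss returns both its value and its exact gradient with respect to the
simulated activity, which the backward pass propagates through time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "boxcar_matrix",
    "TraceKit",
    "surrogate_derivative",
    "sparsity_penalty",
    "prune",
    "match_trial_counts",
]


def boxcar_matrix(T: int, width_steps: int) -> np.ndarray:
    """Dense (T, T) centered boxcar filter with edge replication.

    Row t averages the ``width_steps`` samples centered on t; indices falling
    outside the trace are clipped to the edges (replication), which keeps each
    row summing to one.  A dense matrix keeps the adjoint exact and trivial.
    """
    if width_steps < 1:
        raise ValueError("filter width must be at least one step")
    F = np.zeros((T, T))
    half = (width_steps - 1) // 2
    for t in range(T):
        idx = np.clip(np.arange(t - half, t - half + width_steps), 0, T - 1)
        np.add.at(F[t], idx, 1.0 / width_steps)
    return F


def surrogate_derivative(
    v: np.ndarray, v_thr: np.ndarray, v0: float, dampening: float = 0.3
) -> np.ndarray:
    """Piecewise-linear (triangular) pseudo-derivative of the spike function.

    Evaluated on the linear argument (v - v_thr)/v0 (not its exponential):
    max(0, 1 - |(v - v_thr)/v0|) * dampening / v0.
    """
    arg = (v - v_thr) / v0
    return np.maximum(0.0, 1.0 - np.abs(arg)) * (dampening / v0)


def match_trial_counts(
    k_model: int, k_data: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded subsampling of the larger side so both sides have equal K."""
    rng = np.random.default_rng([seed, 4409])
    k = min(k_model, k_data)
    if k == 0:
        raise ValueError("trial matching needs at least one trial per side")
    im = np.arange(k_model) if k_model == k else rng.choice(k_model, k, replace=False)
    idd = np.arange(k_data) if k_data == k else rng.choice(k_data, k, replace=False)
    return im, idd


@dataclass
class _Stats:
    mu: np.ndarray
    sd: np.ndarray
    zero_variance: np.ndarray  # flagged entries where the floor was applied


class TraceKit:
    """Filtering, normalization and loss evaluation for one session layout.

    Normalization statistics are computed once from the recorded data and
    frozen (the Eq.-style denominators are dataset statistics, not minibatch
    statistics).  Zero-variance entries are floored at ``eps_frac`` times the
    mean positive standard deviation and flagged.
    """

    def __init__(
        self,
        T: int,
        dt: float,
        area: np.ndarray,
        *,
        psth_width_ms: float = 8.0,
        pop_width_ms: float = 32.0,
        eps_frac: float = 0.1,
    ) -> None:
        self.T = T
        self.dt = dt
        self.area = np.asarray(area)
        self.area_ids = np.arange(int(self.area.max()) + 1)
        self.members = [np.flatnonzero(self.area == a) for a in self.area_ids]
        if any(len(m) == 0 for m in self.members):
            raise ValueError("area with zero neurons")
        self.F_psth = boxcar_matrix(T, max(1, round(psth_width_ms / dt)))
        self.F_pop = boxcar_matrix(T, max(1, round(pop_width_ms / dt)))
        self.eps_frac = eps_frac

    # -- PSTH (trial-averaged) side -------------------------------------

    def psth(self, z: np.ndarray) -> np.ndarray:
        """Filtered trial-averaged activity, (T, N)."""
        return self.F_psth @ z.mean(axis=0)

    def _floor(self, sd: np.ndarray) -> _Stats:
        pos = sd[sd > 0]
        eps = self.eps_frac * pos.mean() if pos.size else 1.0
        zero = sd < eps
        return _Stats(mu=None, sd=np.maximum(sd, eps), zero_variance=zero)

    def neuron_stats(self, data_z: np.ndarray) -> _Stats:
        """Per-neuron time mean/sd of the recorded filtered PSTH."""
        tn = self.psth(data_z)
        st = self._floor(tn.std(axis=0))
        st.mu = tn.mean(axis=0)
        return st

    def normalized_psth(self, z: np.ndarray, stats: _Stats) -> np.ndarray:
        return (self.psth(z) - stats.mu) / stats.sd

    def neuron_loss(
        self,
        z_model: np.ndarray,
        data_norm_psth: np.ndarray,
        stats: _Stats,
        neuron_idx: Optional[np.ndarray] = None,
    ) -> tuple[float, np.ndarray]:
        """Summed squared PSTH error and its gradient w.r.t. model spikes.

        ``neuron_idx`` restricts the comparison to a mapped subset (session
        stitching); the returned gradient is full sized with zeros elsewhere.
        """
        K, T, N = z_model.shape
        zm = z_model if neuron_idx is None else z_model[:, :, neuron_idx]
        tn = self.F_psth @ zm.mean(axis=0)
        tnn = (tn - stats.mu) / stats.sd
        diff = tnn - data_norm_psth
        loss = float((diff**2).sum())
        g_tn = 2.0 * diff / stats.sd
        g_mean = self.F_psth.T @ g_tn
        gz = np.zeros_like(z_model)
        if neuron_idx is None:
            gz += g_mean[None] / K
        else:
            gz[:, :, neuron_idx] = g_mean[None] / K
        return loss, gz

    # -- population (single-trial) side ---------------------------------

    def pop_traces(
        self, z: np.ndarray, jaw: Optional[np.ndarray] = None
    ) -> np.ndarray:
        """Filtered per-trial population traces, (K, T, A[+1])."""
        K, T, N = z.shape
        cols = [z[:, :, m].mean(axis=2) for m in self.members]
        if jaw is not None:
            cols.append(jaw)
        P = np.stack(cols, axis=2)
        return np.tensordot(P, self.F_pop, axes=(1, 1)).transpose(0, 2, 1)

    def pop_stats(self, data_z: np.ndarray, jaw: Optional[np.ndarray] = None) -> _Stats:
        """Trial mean/sd of the recorded filtered population traces, (T, A)."""
        P = self.pop_traces(data_z, jaw)
        st = self._floor(P.std(axis=0))
        st.mu = P.mean(axis=0)
        return st

    def normalized_pop(
        self, z: np.ndarray, stats: _Stats, jaw: Optional[np.ndarray] = None
    ) -> np.ndarray:
        return (self.pop_traces(z, jaw) - stats.mu) / stats.sd

    def trial_matching_loss(
        self, traces_model: np.ndarray, traces_data: np.ndarray
    ) -> tuple[float, np.ndarray, np.ndarray]:
        """Optimal-assignment distance between two sets of trial traces.

        Returns (loss, gradient w.r.t. model traces, assignment pi) where
        ``pi[k]`` is the data trial matched to model trial ``k``.  The solver
        is exact (Hungarian), so the result equals the brute-force minimum
        over all permutations.
        """
        Km, Kd = traces_model.shape[0], traces_data.shape[0]
        if Km != Kd:
            raise ValueError("equal trial counts required (see match_trial_counts)")
        if Km == 0:
            raise ValueError("empty trial set")
        flat_m = traces_model.reshape(Km, -1)
        flat_d = traces_data.reshape(Kd, -1)
        cost = (
            (flat_m**2).sum(1)[:, None]
            - 2.0 * flat_m @ flat_d.T
            + (flat_d**2).sum(1)[None, :]
        )
        rows, cols = linear_sum_assignment(cost)
        pi = np.empty(Km, dtype=int)
        pi[rows] = cols
        loss = float(cost[rows, cols].sum())
        grad = 2.0 * (traces_model - traces_data[pi])
        return loss, grad, pi

    def pop_grad_to_activity(
        self, g_traces: np.ndarray, n_neurons: int, has_jaw: bool
    ) -> tuple[np.ndarray, Optional[np.ndarray]]:
        """Adjoint of ``pop_traces`` (with normalization applied by caller)."""
        g_pre = np.tensordot(g_traces, self.F_pop, axes=(1, 0)).transpose(0, 2, 1)
        K = g_traces.shape[0]
        gz = np.zeros((K, self.T, n_neurons))
        for a, m in enumerate(self.members):
            gz[:, :, m] = g_pre[:, :, a, None] / len(m)
        gy = g_pre[:, :, -1] if has_jaw else None
        return gz, gy


# ---------------------------------------------------------------------------
# sparsity regularization
# ---------------------------------------------------------------------------


def sparsity_penalty(
    conn,
    area: np.ndarray,
    lam1: float = 0.0,
    lam2: float = 0.0,
    lam3: float = 0.0,
) -> tuple[float, np.ndarray, np.ndarray]:
    """p = 1/2 norm penalty on efficacies above the pruning threshold.

    Returns (value, gradient w.r.t. efficacy, gradient w.r.t. input weights).
    lam1 weighs the input weights, lam2 all recurrent efficacies, lam3 the
    cross-area blocks.  Entries below the pruning threshold contribute neither
    value nor gradient (this sidesteps the |w|^{-1/2} singularity).
    """
    if min(lam1, lam2, lam3) < 0:
        raise ValueError("sparsity weights must be non-negative")
    alpha = conn.prune_threshold
    eff = conn.efficacy
    mag = np.abs(eff)
    active = mag >= alpha
    root = np.sqrt(np.where(active, mag, 1.0))
    cross = (area[:, None] != area[None, :])[None, :, :]

    w_rec = lam2 + lam3 * cross
    value = float((w_rec * root)[active].sum()) if (lam2 or lam3) else 0.0
    g_eff = np.where(active, w_rec * np.sign(eff) * 0.5 / root, 0.0)

    g_in = np.zeros_like(conn.in_weights)
    if lam1:
        magi = np.abs(conn.in_weights)
        acti = magi >= alpha
        rooti = np.sqrt(np.where(acti, magi, 1.0))
        value += float(rooti[acti].sum()) * lam1
        g_in = np.where(acti, lam1 * np.sign(conn.in_weights) * 0.5 / rooti, 0.0)
    return value, g_eff, g_in


def prune(conn) -> int:
    """Permanently remove synapses whose efficacy fell below the threshold.

    Returns the number of newly pruned synapses.  Pruned synapses stay at
    exactly zero for the rest of the optimization.
    """
    before = int(conn.pruned.sum())
    conn.project_(prune=True)
    return int(conn.pruned.sum()) - before
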
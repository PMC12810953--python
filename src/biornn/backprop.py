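"""Backpropagation through time for the circuit models.

The forward pass (``network.simulate`` with ``cache=True``) stores spikes,
surrogate derivatives and the standard-normal noise draws.  Given direct
gradients of a scalar loss with respect to the activity ``z`` (and optionally
the jaw trace ``y``), :func:`backward` propagates them through the voltage
recursion and returns gradients for every trainable parameter:

* recurrent efficacies (per delay bin) and input weights,
* per-neuron threshold ``v_thr`` (through the reset, the spike-function
  argument and the noise amplitude) and noise scale ``beta``
  (reparameterized through the cached noise draws),
* jaw readout weights and offset.

For spiking dynamics the non-differentiable Bernoulli draw is replaced by the
triangular surrogate derivative evaluated on (v - v_thr)/v0 and zeroed during
the refractory period; for the sigmoidal variant the true derivative is used,
so gradients are exact (finite-difference checkable) given frozen noise.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .network import NetworkModel, SimResult

__all__ = ["Gradients", "backward"]


class Gradients(dict):
    """Parameter gradients keyed by name, with vector-space helpers."""

    def global_norm(self, keys=None) -> float:
        keys = keys or self.keys()
        return float(np.sqrt(sum(np.sum(self[k] ** 2) for k in keys)))

    def scaled(self, factor: float) -> "Gradients":
        return Gradients({k: v * factor for k, v in self.items()})

    def add_(self, other: "Gradients") -> "Gradients":
        for k, v in other.items():
            self[k] = self[k] + v if k in self else v
        return self


def backward(
    model: NetworkModel,
    sim: SimResult,
    gz_direct: np.ndarray,
    gy_direct: Optional[np.ndarray] = None,
    *,
    return_gv: bool = False,
):
    """Reverse-mode gradients of a scalar loss through a cached rollout.

    Parameters
    ----------
    gz_direct : (K, T, N) direct dLoss/dz (zero where the loss does not read z).
    gy_direct : (K, T) direct dLoss/dy for models with a jaw readout.
    return_gv : additionally return dLoss/dv (used for input-current
        sensitivity maps, dLoss/du = gv * (1 - alpha)).
    """
    if sim.psi is None or sim.eps is None:
        raise ValueError("simulation must be run with cache=True for backward()")
    p = model.neurons
    conn = model.conn
    K, T, N = sim.z.shape
    alpha = p.alpha
    v_thr = p.v_thr
    dt = p.dt
    weff = conn.effective_weights()
    dsteps = conn.delay_steps
    reset_on = model.dynamics == "spiking" or model.sigmoid_reset

    gz_extra = np.zeros((K, T, N))
    g_jaw_w = None
    g_jaw_b = None
    if model.jaw is not None and gy_direct is not None:
        jaw = model.jaw
        aj = jaw.alpha(dt)
        g_yt = gy_direct * np.exp(sim.ytilde)  # dL/dytilde direct part
        g_ytilde = np.zeros((K, T))
        acc = np.zeros(K)
        for t in range(T - 1, -1, -1):
            acc = g_yt[:, t] + aj * acc
            g_ytilde[:, t] = acc
        g_jaw_w = np.zeros(N)
        for ds in np.unique(jaw.delay_steps):
            sel = (jaw.delay_steps == ds) & jaw.exc_mask
            if not sel.any():
                continue
            gsh = g_ytilde[:, ds:]  # pairs with z[:, :T-ds]
            gz_extra[:, : T - ds, sel] += (1.0 - aj) * gsh[:, :, None] * jaw.w[sel]
            g_jaw_w[sel] = (1.0 - aj) * np.einsum(
                "kt,ktn->n", gsh, sim.z[:, : T - ds, sel]
            )
        g_jaw_b = float(gy_direct.sum())

    # reverse sweep over time: gv[t] = gz_tot[t] * psi[t] + alpha * gv[t+1]
    gv = np.zeros((K, T, N))
    gz_tot = np.zeros((K, T, N))
    wT = [w.T.copy() for w in weff]
    for t in range(T - 1, -1, -1):
        g = gz_direct[:, t, :] + gz_extra[:, t, :]
        for d, ds in enumerate(dsteps):
            if t + ds < T:
                g = g + (gv[:, t + ds, :] * (1.0 - alpha)) @ wT[d] / dt
        if reset_on and t + 1 < T:
            g = g - gv[:, t + 1, :] * v_thr
        gz_tot[:, t, :] = g
        gv_t = g * sim.psi[:, t, :]
        if t + 1 < T:
            gv_t = gv_t + gv[:, t + 1, :] * alpha
        gv[:, t, :] = gv_t

    gu = gv * (1.0 - alpha)  # dL/du, (K, T, N)

    # parameter gradients
    g_eff = np.zeros_like(conn.efficacy)
    flat_gu = gu.reshape(K * T, N) / dt
    for d, ds in enumerate(dsteps):
        z_shift = np.zeros((K, T, N))
        z_shift[:, ds:, :] = sim.z[:, : T - ds, :]
        g_signed = z_shift.reshape(K * T, N).T @ flat_gu
        if conn.dale:
            g_signed = g_signed * conn.sign[:, None]
        g_eff[d] = g_signed * conn.delay_mask[d]

    g_in = sim.x.T @ gu.sum(axis=0) / dt  # (C, N)

    noise_sd_unit = np.sqrt(dt)
    g_thr = np.zeros(N)
    if reset_on:
        z_prev = np.zeros((K, T, N))
        z_prev[:, 1:, :] = sim.z[:, :-1, :]
        g_thr -= np.einsum("ktn,ktn->n", gv, z_prev)
    g_thr -= (gz_tot * sim.psi).sum(axis=(0, 1))          # spike-argument path
    g_thr += np.einsum("ktn,ktn->n", gv, sim.eps) * p.beta * noise_sd_unit
    g_beta = np.einsum("ktn,ktn->n", gv, sim.eps) * v_thr * noise_sd_unit

    grads = Gradients(
        efficacy=g_eff, in_weights=g_in, v_thr=g_thr, beta=g_beta
    )
    if g_jaw_w is not None:
        grads["jaw_w"] = g_jaw_w
        grads["jaw_b"] = np.asarray(g_jaw_b)
    if return_gv:
        return grads, gv
    return grads
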
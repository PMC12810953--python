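"""Network reconstruction as a model/results pair.

:class:`NetworkReconstruction` holds the recorded data (one or several
sessions), the circuit model being fitted, and the frozen normalization
statistics; :meth:`NetworkReconstruction.fit` runs surrogate-gradient BPTT
with Adam, parameter-free multi-task reweighting of the PSTH and
trial-matching gradients, Dale's-law/locality projection after every update,
and optional p=1/2 sparsity with pruning.  It returns a
:class:`ReconstructionResults` carrying the fitted model, the training log and
summary diagnostics.

Fitting modes
-------------
``reference``       train recurrent + input weights, thresholds and noise
                    scales (used to build reference circuits from target
                    statistics);
``reconstruction``  train the recurrent weights only (the network
                    reconstruction setting);
``real``            additionally train the jaw readout weights and offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .backprop import Gradients, backward
from .data import TrialBatch
from .losses import TraceKit, sparsity_penalty
from .network import FixedStimulus, NetworkModel, simulate

logger = logging.getLogger(__name__)

__all__ = [
    "LossConfig",
    "LossReport",
    "NetworkReconstruction",
    "ReconstructionResults",
    "evaluate_losses",
    "grid_search_lambda3",
]

_MODE_PARAMS = {
    "reference": ("efficacy", "in_weights", "v_thr", "beta"),
    "reconstruction": ("efficacy",),
    "real": ("efficacy", "in_weights", "v_thr", "beta", "jaw_w", "jaw_b"),
}


@dataclass
class LossConfig:
    """Loss/optimization hyperparameters (all widths in ms)."""

    psth_width_ms: float = 8.0
    pop_width_ms: float = 32.0
    lam1: float = 0.0
    lam2: float = 0.0
    lam3: float = 0.0
    eps_frac: float = 0.1
    use_trial_matching: bool = True
    prune: Optional[bool] = None  # None = auto (prune iff any lambda > 0)

    def prune_enabled(self) -> bool:
        if self.prune is not None:
            return self.prune
        return (self.lam1 + self.lam2 + self.lam3) > 0


@dataclass
class LossReport:
    """Loss components of one evaluation (sums and normalized variants)."""

    neuron: float
    trial: float
    sparsity: float
    neuron_norm: float
    trial_norm: float
    per_session_trial: dict = field(default_factory=dict)
    assignment: Optional[np.ndarray] = None

    @property
    def total(self) -> float:
        return self.neuron + self.trial + self.sparsity


class _Adam:
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, params: dict, grads: Gradients) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(g, dtype=float)
                self.v[k] = np.zeros_like(g, dtype=float)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            update = self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
            params[k] -= update


class _Session:
    """Frozen data-side statistics and traces for one recorded session."""

    def __init__(self, batch: TrialBatch, neuron_idx: np.ndarray, config: LossConfig):
        self.batch = batch
        self.neuron_idx = neuron_idx
        self.kit = TraceKit(
            batch.n_steps,
            batch.dt,
            batch.area,
            psth_width_ms=config.psth_width_ms,
            pop_width_ms=config.pop_width_ms,
            eps_frac=config.eps_frac,
        )
        z = batch.spikes
        self.neuron_stats = self.kit.neuron_stats(z)
        self.data_psth = self.kit.normalized_psth(z, self.neuron_stats)
        self.pop_stats = self.kit.pop_stats(z, batch.jaw)
        self.data_pop = self.kit.normalized_pop(z, self.pop_stats, batch.jaw)
        self.has_jaw = batch.jaw is not None
        if self.has_jaw:
            jt = self.kit.F_psth @ batch.jaw.mean(axis=0)
            sd = max(jt.std(), 1e-6)
            self.jaw_mu, self.jaw_sd = jt.mean(), sd
            self.data_jaw_psth = (jt - jt.mean()) / sd


def _get_params(model: NetworkModel) -> dict:
    p = {
        "efficacy": model.conn.efficacy,
        "in_weights": model.conn.in_weights,
        "v_thr": model.neurons.v_thr,
        "beta": model.neurons.beta,
    }
    if model.jaw is not None:
        p["jaw_w"] = model.jaw.w
        p["jaw_b"] = np.atleast_1d(np.asarray(model.jaw.b, dtype=float))
    return p


def _project(model: NetworkModel, prune: bool, beta_floor: float = 0.05) -> None:
    # the noise scale keeps a floor: escape noise drives both the spike
    # sampling and the surrogate-gradient flow, and a collapsed beta stalls
    # the optimization (see docs/methods.md)
    model.conn.project_(prune=prune)
    np.clip(model.neurons.beta, beta_floor, None, out=model.neurons.beta)
    np.clip(model.neurons.v_thr, 0.05, None, out=model.neurons.v_thr)
    if model.jaw is not None:
        model.jaw.project_()


class NetworkReconstruction:
    """Fit a circuit model neuron-to-neuron to trial-based spike recordings."""

    def __init__(
        self,
        data: TrialBatch | Sequence[TrialBatch],
        model: NetworkModel,
        *,
        protocol=None,
        config: Optional[LossConfig] = None,
        session_neurons: Optional[Sequence[np.ndarray]] = None,
    ) -> None:
        batches = [data] if isinstance(data, TrialBatch) else list(data)
        self.config = config or LossConfig()
        self.model = model
        if protocol is None:
            stim = batches[0].stimulus
            if stim is None:
                raise ValueError("need a stimulus protocol or data with stimulus")
            protocol = FixedStimulus(batches[0].dt, stim)
        self.protocol = protocol
        if session_neurons is None:
            if len(batches) > 1:
                raise ValueError("multi-session data requires session_neurons maps")
            session_neurons = [np.arange(model.n)]
        self.sessions = [
            _Session(b, np.asarray(idx), self.config)
            for b, idx in zip(batches, session_neurons)
        ]
        for s in self.sessions:
            if s.batch.n_steps != protocol.n_steps:
                raise ValueError("data and protocol trial lengths differ")

    # -- loss evaluation -------------------------------------------------

    def _losses_and_grads(
        self, sim, data_trial_idx: dict, want_grads: bool = True
    ):
        """Evaluate both losses on a simulated batch; return values + gz/gy."""
        model = self.model
        K = sim.n_trials
        gz_n = np.zeros_like(sim.z)
        gz_t = np.zeros_like(sim.z)
        gy_n = np.zeros_like(sim.y) if sim.y is not None else None
        gy_t = np.zeros_like(sim.y) if sim.y is not None else None
        L_n = 0.0
        L_t = 0.0
        per_session = {}
        n_points_t = 0
        n_points_n = 0
        pi = None
        for s in self.sessions:
            zm = sim.z if s.neuron_idx.size == model.n else sim.z[:, :, s.neuron_idx]
            ln, g = s.kit.neuron_loss(zm, s.data_psth, s.neuron_stats)
            if s.neuron_idx.size == model.n:
                gz_n += g
            else:
                gz_n[:, :, s.neuron_idx] += g
            L_n += ln
            n_points_n += s.data_psth.size
            if s.has_jaw and sim.y is not None:
                jt = s.kit.F_psth @ sim.y.mean(axis=0)
                jtn = (jt - s.jaw_mu) / s.jaw_sd
                diff = jtn - s.data_jaw_psth
                L_n += float((diff**2).sum())
                gy_n += (s.kit.F_psth.T @ (2.0 * diff / s.jaw_sd))[None] / K

            jaw_m = sim.y if s.has_jaw and sim.y is not None else None
            tr_m = s.kit.normalized_pop(zm, s.pop_stats, jaw_m)
            idx = data_trial_idx[s.batch.session]
            tr_d = s.data_pop[idx]
            lt, g_tr, pi = s.kit.trial_matching_loss(tr_m, tr_d)
            g_tr = g_tr / s.pop_stats.sd
            gzs, gys = s.kit.pop_grad_to_activity(
                g_tr, len(s.neuron_idx), jaw_m is not None
            )
            if s.neuron_idx.size == model.n:
                gz_t += gzs
            else:
                gz_t[:, :, s.neuron_idx] += gzs
            if gys is not None:
                gy_t += gys
            L_t += lt
            per_session[s.batch.session] = lt / tr_m.size
            n_points_t += tr_m.size
        L_t /= len(self.sessions)
        if len(self.sessions) > 1:
            gz_t /= len(self.sessions)
            if gy_t is not None:
                gy_t /= len(self.sessions)
        report = LossReport(
            neuron=L_n,
            trial=L_t,
            sparsity=0.0,
            neuron_norm=L_n / max(n_points_n, 1),
            trial_norm=L_t / max(n_points_t / len(self.sessions), 1),
            per_session_trial=per_session,
            assignment=pi,
        )
        if not want_grads:
            return report, None
        return report, ((gz_n, gy_n), (gz_t, gy_t))

    # -- fitting ---------------------------------------------------------

    def fit(
        self,
        *,
        mode: str = "reconstruction",
        steps: int = 4000,
        lr: float = 1e-3,
        batch_size: int = 32,
        seed: int = 0,
        test_data: Optional[TrialBatch] = None,
        eval_every: int = 50,
        select: str = "last",
        trial_type_fn: Optional[Callable] = None,
        callback: Optional[Callable] = None,
        beta_floor: float = 0.05,
    ) -> "ReconstructionResults":
        """Run the optimization loop.

        ``select='best'`` keeps the checkpoint whose trial-type accuracy is
        closest to the data's, ties broken by the trial-matched correlation
        (the real-data stopping rule); ``'last'`` runs the fixed number of
        steps (the synthetic-dataset rule).
        """
        if mode not in _MODE_PARAMS:
            raise ValueError(f"unknown mode {mode!r}")
        cfg = self.config
        model = self.model
        trainable = [
            k for k in _MODE_PARAMS[mode] if not k.startswith("jaw") or model.jaw
        ]
        opt = _Adam(lr)
        rng = np.random.default_rng([seed, 911])
        rows = []
        best = None
        last_good = {k: v.copy() for k, v in _get_params(model).items()}
        prune_on = cfg.prune_enabled()

        for step in range(steps):
            data_idx = {
                s.batch.session: rng.choice(
                    s.batch.n_trials, min(batch_size, s.batch.n_trials), replace=False
                )
                for s in self.sessions
            }
            k_batch = min(batch_size, min(len(v) for v in data_idx.values()))
            data_idx = {k: v[:k_batch] for k, v in data_idx.items()}
            sim = simulate(
                model,
                self.protocol,
                k_batch,
                seed=seed,
                trial_ids=step * batch_size + np.arange(k_batch),
                cache=True,
            )
            report, grads_zy = self._losses_and_grads(sim, data_idx)
            sp_val, g_sp_eff, g_sp_in = sparsity_penalty(
                model.conn, model.neurons.area, cfg.lam1, cfg.lam2, cfg.lam3
            )
            report.sparsity = sp_val
            if not np.isfinite(report.neuron + report.trial):
                logger.warning("divergence at step %d; restoring last checkpoint", step)
                params = _get_params(model)
                for k in params:
                    params[k][...] = last_good[k]
                if model.jaw is not None:
                    model.jaw.b = float(last_good["jaw_b"][0])
                break

            (gz_n, gy_n), (gz_t, gy_t) = grads_zy
            g_n = backward(model, sim, gz_n, gy_n)
            total = Gradients()
            norm_n = g_n.global_norm(trainable)
            if norm_n > 0:
                total.add_(Gradients({k: g_n[k] / norm_n for k in trainable if k in g_n}))
            if cfg.use_trial_matching:
                g_t = backward(model, sim, gz_t, gy_t)
                norm_t = g_t.global_norm(trainable)
                if norm_t > 0:
                    total.add_(
                        Gradients({k: g_t[k] / norm_t for k in trainable if k in g_t})
                    )
            if "efficacy" in trainable:
                total.add_(Gradients(efficacy=g_sp_eff))
            if "in_weights" in trainable:
                total.add_(Gradients(in_weights=g_sp_in))

            params = _get_params(model)
            opt.step(params, Gradients({k: total[k] for k in trainable if k in total}))
            if model.jaw is not None:
                model.jaw.b = float(params["jaw_b"][0])
            _project(model, prune=prune_on, beta_floor=beta_floor)
            if model.conn.dale:
                model.conn.check_dale()
            last_good = {k: v.copy() for k, v in _get_params(model).items()}

            row = {
                "step": step,
                "L_neuron": report.neuron,
                "L_trial": report.trial,
                "sparsity": report.sparsity,
                "L_all": report.total,
                "L_trial_norm": report.trial_norm,
            }
            for k, v in report.per_session_trial.items():
                row[f"L_trial_{k}"] = v
            if select == "best" and test_data is not None and (
                step % eval_every == 0 or step == steps - 1
            ):
                score = self._selection_score(test_data, trial_type_fn, seed + 1)
                row["selection_score"] = score
                if best is None or score > best[0]:
                    best = (score, {k: v.copy() for k, v in _get_params(model).items()})
            rows.append(row)
            if callback is not None:
                callback(step, report, model)

        if select == "best" and best is not None:
            params = _get_params(model)
            for k in params:
                params[k][...] = best[1][k]
            if model.jaw is not None:
                model.jaw.b = float(best[1]["jaw_b"][0])
        log = pd.DataFrame(rows)
        return ReconstructionResults(
            model=model, log=log, mode=mode, config=cfg, reconstruction=self
        )

    def _selection_score(self, test_data, trial_type_fn, seed) -> float:
        """Trial-type-accuracy closeness plus trial-matched correlation."""
        k = min(128, test_data.n_trials)
        sim = simulate(self.model, self.protocol, k, seed=seed)
        s = self.sessions[0]
        jaw_m = sim.y if s.has_jaw else None
        tr_m = s.kit.normalized_pop(sim.z, s.pop_stats, jaw_m)
        tr_d = s.kit.normalized_pop(
            test_data.spikes[:k], s.pop_stats, None if test_data.jaw is None else test_data.jaw[:k]
        )
        _, _, pi = s.kit.trial_matching_loss(tr_m, tr_d)
        r = np.corrcoef(tr_m.ravel(), tr_d[pi].ravel())[0, 1]
        score = float(r)
        if trial_type_fn is not None and test_data.labels is not None:
            acc_model = float(np.mean(trial_type_fn(sim)))
            acc_data = float(np.mean(test_data.labels[:k]))
            score -= abs(acc_model - acc_data)
        return score


@dataclass
class ReconstructionResults:
    """Fitted model, training log and evaluation utilities."""

    model: NetworkModel
    log: pd.DataFrame
    mode: str
    config: LossConfig
    reconstruction: NetworkReconstruction

    def simulate(self, n_trials: int, seed: int, **kw):
        return simulate(self.model, self.reconstruction.protocol, n_trials, seed, **kw)

    def evaluate(self, data: TrialBatch, n_trials: int = 128, seed: int = 123) -> LossReport:
        return evaluate_losses(
            self.model, data, self.reconstruction.protocol, self.config, n_trials, seed
        )

    def summary(self, data: Optional[TrialBatch] = None) -> str:
        lines = [
            "Network reconstruction results",
            "=" * 46,
            f"mode:              {self.mode}",
            f"dynamics:          {self.model.dynamics}",
            f"neurons:           {self.model.n}",
            f"Dale's law:        {self.model.conn.dale}",
            f"local inhibition:  {self.model.conn.local_inhibition}",
            f"training steps:    {len(self.log)}",
        ]
        if len(self.log):
            last = self.log.iloc[-1]
            lines += [
                f"final L_neuron:    {last['L_neuron']:.4g}",
                f"final L_trial:     {last['L_trial']:.4g}",
                f"final L_trial/pt:  {last['L_trial_norm']:.4g}",
                f"sparsity penalty:  {last['sparsity']:.4g}",
            ]
        if data is not None:
            rep = self.evaluate(data)
            lines += [
                "-" * 46,
                f"held-out L_neuron/pt: {rep.neuron_norm:.4g}",
                f"held-out L_trial/pt:  {rep.trial_norm:.4g}",
            ]
        return "\n".join(lines)

    def plot_training(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.log["step"], self.log["L_neuron"], label="L_neuron")
        ax.plot(self.log["step"], self.log["L_trial"], label="L_trial")
        ax.set_xlabel("step")
        ax.set_ylabel("loss")
        ax.legend()
        return ax

    def save(self, path) -> None:
        from .network import save_model

        save_model(self.model, path)


def evaluate_losses(
    model: NetworkModel,
    data: TrialBatch,
    protocol,
    config: Optional[LossConfig] = None,
    n_trials: int = 128,
    seed: int = 123,
) -> LossReport:
    """Held-out loss report: simulate fresh trials and compare with ``data``."""
    recon = NetworkReconstruction(data, model, protocol=protocol, config=config)
    k = min(n_trials, data.n_trials)
    sim = simulate(model, protocol, k, seed=seed, trial_ids=10_000_000 + np.arange(k))
    idx = {data.session: np.arange(k)}
    report, _ = recon._losses_and_grads(sim, idx, want_grads=False)
    return report


def grid_search_lambda3(
    fit_fn: Callable[[float], float],
    grid: Sequence[float],
    tolerance: float = 0.05,
) -> tuple[float, dict]:
    """Pick the largest cross-area sparsity weight that keeps performance.

    ``fit_fn(lam3)`` must return a held-out trial-matching loss.  The chosen
    value is the maximum lam3 whose loss stays within ``tolerance`` (relative)
    of the lam3 = 0 loss.
    """
    grid = sorted(set(float(g) for g in grid) | {0.0})
    scores = {g: float(fit_fn(g)) for g in grid}
    base = scores[0.0]
    ok = [g for g in grid if scores[g] <= base * (1.0 + tolerance)]
    return max(ok), scores
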
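"""In-silico optogenetic perturbations and perturbation testing.

An optogenetic *inactivation* of a cortical area is modeled as a strong
current injected into that area's inhibitory neurons (which silences their
local neighborhood); an *activation* injects current into the excitatory
population.  Perturbed and unperturbed simulations share counter-based noise,
so the injected current is the only difference between the paired trials and
per-trial differences (delta hit rate, delta movement) are exact.

Reconstruction quality on perturbed trials is scored by (i) the change of
hit/lick probability relative to the reference circuit or recorded behavior
and (ii) the trial-matching distance between perturbed model and perturbed
reference activity restricted to the areas not directly targeted by the
light.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .losses import TraceKit
from .network import EXC, INH, NetworkModel, simulate
from .refcirc import RefCircSpec, classify_hit

__all__ = [
    "PerturbationSpec",
    "PerturbationResult",
    "make_synthetic_perturbation",
    "make_real_perturbation",
    "perturbation_test",
    "light_power_sweep",
    "train_lick_classifier",
    "classify_lick",
]

SYNTH_ACTIVATION_AMP = 0.08   # current into excitatory cells
SYNTH_INACTIVATION_AMP = 1.0  # current into inhibitory cells


@dataclass
class PerturbationSpec:
    """One optogenetic intervention: who, when, how strong."""

    area: int
    population: int                  # EXC = activation, INH = inactivation
    window_ms: tuple[float, float]
    amplitude: float
    ramp: bool = False               # linear ramp-down over the window tail
    power: float = 1.0               # light-power scale factor (a.u.)
    ramp_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.power < 0:
            raise ValueError("amplitude and power must be non-negative")
        if self.window_ms[1] < self.window_ms[0]:
            raise ValueError("empty perturbation window")

    def scaled(self, power: float) -> "PerturbationSpec":
        return PerturbationSpec(
            area=self.area,
            population=self.population,
            window_ms=self.window_ms,
            amplitude=self.amplitude,
            ramp=self.ramp,
            power=power,
            ramp_fraction=self.ramp_fraction,
        )

    def target_mask(self, model: NetworkModel) -> np.ndarray:
        mask = (model.neurons.area == self.area) & (
            model.neurons.cell_type == self.population
        )
        if not mask.any():
            raise ValueError("perturbation targets no neurons in the model")
        return mask

    def current(self, model: NetworkModel, n_steps: int) -> np.ndarray:
        """(T, N) injected current Delta u."""
        dt = model.neurons.dt
        t0 = int(round(self.window_ms[0] / dt))
        t1 = int(round(self.window_ms[1] / dt))
        if t0 < 0 or t1 > n_steps:
            raise ValueError("perturbation window exceeds trial duration")
        profile = np.zeros(n_steps)
        profile[t0:t1] = 1.0
        if self.ramp and t1 > t0:
            n_ramp = max(1, int(round((t1 - t0) * self.ramp_fraction)))
            ramp = np.linspace(1.0, 0.0, n_ramp, endpoint=False)
            profile[t1 - n_ramp : t1] = ramp
        du = np.zeros((n_steps, model.n))
        du[:, self.target_mask(model)] = (
            self.amplitude * self.power * profile[:, None]
        )
        return du


def make_synthetic_perturbation(
    kind: str, area: int, stimulus_onset_ms: float
) -> PerturbationSpec:
    """40 ms square pulse from 20 ms before to 20 ms after stimulus onset."""
    if kind not in ("activation", "inactivation"):
        raise ValueError("kind must be 'activation' or 'inactivation'")
    if stimulus_onset_ms < 20.0:
        raise ValueError("stimulus onset must be at least 20 ms into the trial")
    if kind == "activation":
        pop, amp = EXC, SYNTH_ACTIVATION_AMP
    else:
        pop, amp = INH, SYNTH_INACTIVATION_AMP
    return PerturbationSpec(
        area=area,
        population=pop,
        window_ms=(stimulus_onset_ms - 20.0, stimulus_onset_ms + 20.0),
        amplitude=amp,
    )


def make_real_perturbation(
    window_id: str,
    protocol,
    area: int = 0,
    amplitude: float = SYNTH_INACTIVATION_AMP,
) -> PerturbationSpec:
    """Inactivation windows of the in-vivo protocol.

    ``stimulus``: whisker onset +- 100 ms; ``delay``: whisker + 100 ms to
    auditory cue - 100 ms; ``choice``: cue to trial end.  The stimulus and
    delay windows ramp down linearly to avoid rebound excitation; the choice
    window does not.
    """
    whisker = protocol.onsets_ms["whisker"]
    cue = protocol.onsets_ms["auditory"]
    end = protocol.duration_ms
    windows = {
        "stimulus": (whisker - 100.0, whisker + 100.0, True),
        "delay": (whisker + 100.0, cue - 100.0, True),
        "choice": (cue, end, False),
    }
    if window_id not in windows:
        raise ValueError(f"unknown window {window_id!r}")
    w0, w1, ramp = windows[window_id]
    if w1 <= w0:
        raise ValueError(f"{window_id} window is empty for this protocol")
    return PerturbationSpec(
        area=area, population=INH, window_ms=(w0, w1), amplitude=amplitude, ramp=ramp
    )


@dataclass
class PerturbationResult:
    """Measured effect of one perturbation on a model vs its reference."""

    p_unpert: float
    p_pert: float
    dp_model: float
    dp_reference: Optional[float]
    abs_error: Optional[float]
    trial_loss_light: Optional[float]
    n_trials: int
    seed: int
    stderr: float = 0.0
    spec: Optional[PerturbationSpec] = None

    def __post_init__(self) -> None:
        for p in (self.p_unpert, self.p_pert):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def _hit_fraction(sim, targets) -> np.ndarray:
    return classify_hit(sim.z, targets)


def perturbation_test(
    model: NetworkModel,
    reference,
    spec: PerturbationSpec,
    n_trials: int = 500,
    seed: int = 0,
    *,
    targets=None,
    min_trials: int = 20,
    lick_fn=None,
) -> PerturbationResult:
    """Run matched perturbed/unperturbed simulations and score the model.

    ``reference`` is either a :class:`RefCircSpec` (synthetic mode: the
    reference's own perturbed response provides dp and the perturbed
    trial-matching distance on non-targeted areas) or a recorded change of
    lick probability (float, real mode).  ``lick_fn`` maps a simulated jaw
    trace batch to boolean lick decisions for real-mode behavior readout.
    """
    if n_trials < min_trials:
        raise ValueError(f"need at least {min_trials} trials for stable frequencies")
    if targets is None:
        if not isinstance(reference, RefCircSpec):
            raise ValueError("targets required when reference is not a RefCircSpec")
        targets = reference.targets
    proto = targets.protocol()
    du = spec.current(model, proto.n_steps)

    sim_u = simulate(model, proto, n_trials, seed=seed)
    sim_p = simulate(model, proto, n_trials, seed=seed, extra_current=du)
    if lick_fn is not None:
        dec_u = np.asarray(lick_fn(sim_u.y), dtype=bool)
        dec_p = np.asarray(lick_fn(sim_p.y), dtype=bool)
    else:
        dec_u = _hit_fraction(sim_u, targets)
        dec_p = _hit_fraction(sim_p, targets)
    p_u, p_p = float(dec_u.mean()), float(dec_p.mean())
    dp_model = p_p - p_u
    stderr = float(np.sqrt(p_p * (1 - p_p) / n_trials + p_u * (1 - p_u) / n_trials))

    dp_ref = None
    loss_light = None
    if isinstance(reference, RefCircSpec):
        ref_model = reference.model
        du_ref = spec.current(ref_model, proto.n_steps)
        ref_u = simulate(ref_model, proto, n_trials, seed=seed + 1)
        ref_p = simulate(ref_model, proto, n_trials, seed=seed + 1, extra_current=du_ref)
        ref_dec_u = _hit_fraction(ref_u, targets)
        ref_dec_p = _hit_fraction(ref_p, targets)
        dp_ref = float(ref_dec_p.mean() - ref_dec_u.mean())
        loss_light = trial_distance_off_target(
            sim_p.z, ref_p.z, targets, spec.area, ref_unpert=ref_u.z
        )
    elif reference is not None:
        dp_ref = float(reference)

    return PerturbationResult(
        p_unpert=p_u,
        p_pert=p_p,
        dp_model=dp_model,
        dp_reference=dp_ref,
        abs_error=None if dp_ref is None else abs(dp_ref - dp_model),
        trial_loss_light=loss_light,
        n_trials=n_trials,
        seed=seed,
        stderr=stderr,
        spec=spec,
    )


def trial_distance_off_target(
    z_model: np.ndarray,
    z_ref: np.ndarray,
    targets,
    targeted_area: int,
    ref_unpert: Optional[np.ndarray] = None,
) -> float:
    """Trial-matching distance restricted to non-targeted areas, per point.

    Traces are normalized with statistics from the reference's *unperturbed*
    activity (frozen, as during fitting); ``ref_unpert`` defaults to the
    reference batch itself.
    """
    keep = targets.area != targeted_area
    if not keep.any():
        raise ValueError("no non-targeted area left")
    area_sub = np.unique(targets.area[keep], return_inverse=True)[1]
    kit = TraceKit(z_model.shape[1], targets.dt, area_sub)
    stats = kit.pop_stats((ref_unpert if ref_unpert is not None else z_ref)[:, :, keep])
    k = min(z_model.shape[0], z_ref.shape[0])
    tr_m = kit.normalized_pop(z_model[:k][:, :, keep], stats)
    tr_r = kit.normalized_pop(z_ref[:k][:, :, keep], stats)
    loss, _, _ = kit.trial_matching_loss(tr_m, tr_r)
    return loss / tr_m.size


def light_power_sweep(
    model: NetworkModel,
    reference: RefCircSpec,
    spec: PerturbationSpec,
    powers: Sequence[float],
    n_trials: int = 200,
    seed: int = 0,
) -> "pd.DataFrame":
    """Perturbed trial-matching distance as a function of light power.

    The grid should include 0; the 0-power point equals the unperturbed
    distance by construction.
    """
    import pandas as pd

    rows = []
    for p in powers:
        res = perturbation_test(
            model, reference, spec.scaled(p), n_trials=n_trials, seed=seed
        )
        rows.append(
            {
                "power": p,
                "trial_loss_light": res.trial_loss_light,
                "dp_model": res.dp_model,
                "dp_reference": res.dp_reference,
                "abs_error": res.abs_error,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# lick classification (real-mode behavior readout)
# ---------------------------------------------------------------------------


def train_lick_classifier(
    jaw_traces: np.ndarray, lick_labels: np.ndarray, seed: int = 0, **mlp_kwargs
):
    """Multilayer perceptron with two hidden layers of 128 units each."""
    from sklearn.neural_network import MLPClassifier

    labels = np.asarray(lick_labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("need both lick and no-lick examples to train")
    mlp_kwargs.setdefault("early_stopping", True)
    clf = MLPClassifier(
        hidden_layer_sizes=(128, 128),
        max_iter=500,
        random_state=seed,
        **mlp_kwargs,
    )
    clf.fit(np.asarray(jaw_traces), labels)
    return clf


def classify_lick(classifier, jaw_trace: np.ndarray) -> np.ndarray:
    """Boolean lick decision per trace; accepts a single trace or a batch."""
    arr = np.atleast_2d(np.asarray(jaw_trace))
    return classifier.predict(arr).astype(bool)
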
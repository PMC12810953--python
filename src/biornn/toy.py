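"""Analytic two-area toy model of the feedforward/recurrent causal dilemma.

Two binary variables A and B mark the activation of two areas.  Under the
feedforward hypothesis H1, A fires with probability p0 and drives B
deterministically.  Under the recurrent hypothesis H2, each area receives an
independent external input with probability p1 = 1 - sqrt(1 - p0) and either
input activates both areas.  The observational joint distribution p(A, B) is
identical under the two hypotheses (p(1,1) = p0, p(0,0) = 1 - p0), so no
amount of passive recording separates them; clamping B to zero (the do
operator) does: p(A=1 | do(B=0)) is p0 under H1 but p1 under H2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ToyModel", "joint_distribution", "do_intervention", "simulate_toy"]


@dataclass
class ToyModel:
    hypothesis: str  # "H1" | "H2"
    p0: float

    def __post_init__(self) -> None:
        if self.hypothesis not in ("H1", "H2"):
            raise ValueError("hypothesis must be 'H1' or 'H2'")
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError("p0 must lie in [0, 1]")
        p1 = self.p1
        if abs(2 * p1 - p1**2 - self.p0) > 1e-12:
            raise AssertionError("identity 2*p1 - p1^2 = p0 violated")

    @property
    def p1(self) -> float:
        return 1.0 - np.sqrt(1.0 - self.p0)


def joint_distribution(model: ToyModel) -> np.ndarray:
    """2x2 table p(A, B), indexed [a, b]; identical for H1 and H2."""
    p = np.zeros((2, 2))
    p[1, 1] = model.p0
    p[0, 0] = 1.0 - model.p0
    return p


def do_intervention(model: ToyModel, action: str = "inactivate_B") -> float:
    """p(A=1 | do(B=0)): p0 under H1, p1 under H2."""
    if action != "inactivate_B":
        raise ValueError(f"unsupported action {action!r}")
    return model.p0 if model.hypothesis == "H1" else model.p1


def simulate_toy(
    model: ToyModel, n: int, seed: int, intervention: bool = False
) -> dict:
    """Monte-Carlo frequencies of the (A, B) outcomes.

    Under H2 the latent inputs a, b are i.i.d. Bernoulli(p1); either input
    activates both areas.  With the intervention, B is clamped to 0 before
    propagation, so under H2 A follows its own input only.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng([seed, 31337])
    if model.hypothesis == "H1":
        A = rng.random(n) < model.p0
        B = A.copy()
        if intervention:
            B = np.zeros(n, dtype=bool)  # A unaffected by clamping B
    else:
        a = rng.random(n) < model.p1
        b = rng.random(n) < model.p1
        if intervention:
            A = a  # with B clamped, A follows its own input only
            B = np.zeros(n, dtype=bool)
        else:
            A = a | b
            B = A.copy()
    table = np.zeros((2, 2))
    for av in (0, 1):
        for bv in (0, 1):
            table[av, bv] = np.mean((A == av) & (B == bv))
    return {
        "table": table,
        "p_A1": float(A.mean()),
        "p_B1": float(B.mean()),
        "n": n,
    }
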
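"""Shared fixtures: small circuit instances reused across the suite.

Heavy objects (trained reference circuits) are session scoped so their cost
is paid once; sizes are scaled-down study conditions (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np
import pytest

from biornn import (
    NetworkModel,
    default_neuron_params,
    generate_target_statistics,
    initialize_weights,
    make_connectivity,
)
from biornn.network import make_jaw_readout

MICRO_AREAS = ((40, 10), (40, 10))


@pytest.fixture(scope="session")
def micro_targets():
    return generate_target_statistics(area_sizes=MICRO_AREAS, seed=0)


def make_micro_model(
    *,
    dynamics: str = "spiking",
    dale: bool = True,
    local_inhibition: bool = True,
    no_feedback=None,
    jaw: bool = False,
    seed: int = 0,
    dt: float = 1.0,
    areas=MICRO_AREAS,
    in_scale: float = 4.0,
    v_thr: float = 1.0,
) -> NetworkModel:
    neurons = default_neuron_params(areas, dt, v_thr=v_thr)
    conn = make_connectivity(
        neurons,
        n_inputs=1,
        dale=dale,
        local_inhibition=local_inhibition,
        no_feedback=no_feedback,
        seed=seed,
    )
    initialize_weights(conn, neurons, seed=seed, in_scale=in_scale)
    j = make_jaw_readout(neurons, scale=0.05, seed=seed) if jaw else None
    return NetworkModel(neurons=neurons, conn=conn, jaw=j, dynamics=dynamics)


@pytest.fixture()
def tiny_sigmoid_model():
    """10-neuron differentiable model for finite-difference checks."""
    neurons = default_neuron_params([(8, 2)], dt=1.0)
    conn = make_connectivity(neurons, seed=1)
    initialize_weights(conn, neurons, seed=2)
    jaw = make_jaw_readout(neurons, scale=0.05, seed=3)
    return NetworkModel(neurons=neurons, conn=conn, jaw=jaw, dynamics="sigmoid")


@pytest.fixture(scope="session")
def refcirc_pair(micro_targets):
    """Feedforward (H1) and recurrent (H2) reference circuits, micro scale."""
    from biornn import build_refcirc

    kw = dict(steps=1200, batch_size=32, n_target_trials=256)
    c1 = build_refcirc(1, micro_targets, seed=0, **kw)
    c2 = build_refcirc(2, micro_targets, seed=0, **kw)
    return c1, c2
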
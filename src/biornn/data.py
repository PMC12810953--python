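"""Trial-based dataset containers shared by fitting, perturbation testing and I/O."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["TrialBatch", "save_trial_record", "load_trial_record"]


@dataclass
class TrialBatch:
    """A set of trials from one session.

    ``spikes`` is a (trials, time, neurons) array of binary spike counts
    (or rates for rate models); ``labels`` holds trial types (hit = 1,
    miss = 0, unknown = -1); ``area`` and ``cell_type`` label the units.
    """

    spikes: np.ndarray
    dt: float
    area: np.ndarray
    cell_type: np.ndarray
    labels: Optional[np.ndarray] = None
    jaw: Optional[np.ndarray] = None
    stimulus: Optional[np.ndarray] = None
    session: str = "s0"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes)
        if self.spikes.ndim != 3:
            raise ValueError("spikes must be (trials, time, neurons)")
        if self.area.shape[0] != self.spikes.shape[2]:
            raise ValueError("area labels do not match neuron count")

    @property
    def n_trials(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_steps(self) -> int:
        return self.spikes.shape[1]

    @property
    def n_neurons(self) -> int:
        return self.spikes.shape[2]

    def subset(self, idx: np.ndarray) -> "TrialBatch":
        return TrialBatch(
            spikes=self.spikes[idx],
            dt=self.dt,
            area=self.area,
            cell_type=self.cell_type,
            labels=None if self.labels is None else self.labels[idx],
            jaw=None if self.jaw is None else self.jaw[idx],
            stimulus=self.stimulus,
            session=self.session,
            meta=dict(self.meta),
        )

    def train_test_split(self) -> tuple["TrialBatch", "TrialBatch"]:
        """Split along stored indices (first half train, second half test)."""
        tr = self.meta.get("train_idx")
        te = self.meta.get("test_idx")
        if tr is None:
            k = self.n_trials // 2
            tr, te = np.arange(k), np.arange(k, self.n_trials)
        return self.subset(np.asarray(tr)), self.subset(np.asarray(te))


def save_trial_record(batch: TrialBatch, path, seed: Optional[int] = None) -> None:
    """NPZ export: spikes (uint8), jaw, stimulus plus dt/seed attributes."""
    payload = dict(
        spikes=batch.spikes.astype(np.uint8)
        if np.array_equal(batch.spikes, batch.spikes.astype(bool))
        else batch.spikes,
        area=batch.area,
        cell_type=batch.cell_type,
        _attrs=json.dumps({"dt": batch.dt, "seed": seed, "session": batch.session}),
    )
    if batch.labels is not None:
        payload["labels"] = batch.labels
    if batch.jaw is not None:
        payload["jaw"] = batch.jaw
    if batch.stimulus is not None:
        payload["stimulus"] = batch.stimulus.astype(np.uint8)
    np.savez(path, **payload)


def load_trial_record(path) -> TrialBatch:
    with np.load(path, allow_pickle=False) as f:
        attrs = json.loads(str(f["_attrs"]))
        return TrialBatch(
            spikes=f["spikes"].astype(float),
            dt=attrs["dt"],
            area=f["area"],
            cell_type=f["cell_type"],
            labels=f["labels"] if "labels" in f.files else None,
            jaw=f["jaw"] if "jaw" in f.files else None,
            stimulus=f["stimulus"] if "stimulus" in f.files else None,
            session=attrs.get("session", "s0"),
            meta={"seed": attrs.get("seed")},
        )
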
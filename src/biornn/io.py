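"""Dataset bundles, HDF5 schema and session stitching.

HDF5 layout::

    /sessions/<id>/spikes    uint8  (trials, time, units)
    /sessions/<id>/jaw       float  (trials, time)      [optional]
    /sessions/<id>/labels    int    (trials,)           [optional]
    /units                   table: unit, session, area, cell_type
    /protocol                uint8  (time, channels) binary pulses
    /meta                    attributes: dt, seeds, provenance, splits

Multi-session recordings are stitched into one composite network by
assigning each model neuron to exactly one recorded unit (area and cell-type
quotas respected); the assignment is fixed before any optimization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .data import TrialBatch
from .network import SessionMap

__all__ = ["DatasetBundle", "read_dataset", "write_dataset", "build_session_map"]


class SchemaError(ValueError):
    """Raised with the offending HDF5 path when the layout is invalid."""


@dataclass
class DatasetBundle:
    """All sessions of one experiment plus unit metadata and provenance."""

    sessions: dict[str, TrialBatch]
    units: pd.DataFrame          # columns: unit, session, area, cell_type
    protocol: Optional[np.ndarray] = None
    dt: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"unit", "session", "area", "cell_type"}
        missing = required - set(self.units.columns)
        if missing:
            raise SchemaError(f"/units: missing columns {sorted(missing)}")
        for sid, b in self.sessions.items():
            if abs(b.dt - self.dt) > 1e-12:
                raise SchemaError(f"/sessions/{sid}: dt differs from /meta dt")
            n_units = int((self.units["session"] == sid).sum())
            if n_units != b.n_neurons:
                raise SchemaError(
                    f"/sessions/{sid}/spikes: {b.n_neurons} units but "
                    f"{n_units} rows in /units"
                )


def write_dataset(bundle: DatasetBundle, path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("sessions")
        for sid, b in bundle.sessions.items():
            sg = g.create_group(str(sid))
            sg.create_dataset("spikes", data=b.spikes.astype(np.uint8))
            if b.jaw is not None:
                sg.create_dataset("jaw", data=b.jaw)
            if b.labels is not None:
                sg.create_dataset("labels", data=b.labels.astype(np.int64))
        u = f.create_group("units")
        for col in ("unit", "session", "area", "cell_type"):
            data = bundle.units[col].to_numpy()
            if data.dtype.kind in "OU":
                data = data.astype("S")
            u.create_dataset(col, data=data)
        if bundle.protocol is not None:
            f.create_dataset("protocol", data=bundle.protocol.astype(np.uint8))
        m = f.create_group("meta")
        m.attrs["dt"] = bundle.dt
        m.attrs["meta_json"] = json.dumps(bundle.meta, default=_json_default)


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    raise TypeError(type(o))


def read_dataset(path) -> DatasetBundle:
    with h5py.File(path, "r") as f:
        if "meta" not in f:
            raise SchemaError("/meta: group missing")
        dt = float(f["meta"].attrs["dt"])
        meta = json.loads(f["meta"].attrs.get("meta_json", "{}"))
        if "units" not in f:
            raise SchemaError("/units: group missing")
        cols = {}
        for col in ("unit", "session", "area", "cell_type"):
            if col not in f["units"]:
                raise SchemaError(f"/units/{col}: dataset missing")
            arr = f["units"][col][()]
            if arr.dtype.kind == "S":
                arr = arr.astype(str)
            cols[col] = arr
        units = pd.DataFrame(cols)
        protocol = f["protocol"][()] if "protocol" in f else None
        sessions = {}
        if "sessions" not in f:
            raise SchemaError("/sessions: group missing")
        for sid in f["sessions"]:
            sg = f["sessions"][sid]
            if "spikes" not in sg:
                raise SchemaError(f"/sessions/{sid}/spikes: dataset missing")
            rows = units[units["session"] == sid]
            sessions[sid] = TrialBatch(
                spikes=sg["spikes"][()].astype(float),
                dt=dt,
                area=rows["area"].to_numpy(),
                cell_type=rows["cell_type"].to_numpy(),
                labels=sg["labels"][()] if "labels" in sg else None,
                jaw=sg["jaw"][()] if "jaw" in sg else None,
                stimulus=protocol,
                session=sid,
            )
    return DatasetBundle(
        sessions=sessions, units=units, protocol=protocol, dt=dt, meta=meta
    )


def convert_external_deposit(path, dt: float, *, jaw_key: str = "jaw") -> DatasetBundle:
    """Best-effort converter from an externally deposited HDF5 recording.

    Expects one group per session containing a binned spike tensor
    (``spikes``: trials x time x units, any integer/bool dtype, binarized
    here), optional per-trial traces under ``jaw_key``, optional ``labels``,
    and per-unit ``area`` / ``cell_type`` arrays (cell types as +1/-1 or as
    strings starting with 'e'/'i').  Public deposits vary in layout and
    binning conventions; this converter is a starting point to adapt, not a
    tested contract — verify trial alignment and binning against the
    deposit's own documentation before fitting.
    """
    sessions, rows = {}, []
    with h5py.File(path, "r") as f:
        for sid in f:
            g = f[sid]
            if "spikes" not in g:
                continue
            spikes = (np.asarray(g["spikes"]) > 0).astype(float)
            area = np.asarray(g["area"]) if "area" in g else np.zeros(spikes.shape[2], int)
            ct = np.asarray(g["cell_type"]) if "cell_type" in g else np.ones(spikes.shape[2], int)
            if ct.dtype.kind in "SU":
                ct = np.where(np.char.startswith(ct.astype(str).astype("U1"), "e"), 1, -1)
            sessions[sid] = TrialBatch(
                spikes=spikes,
                dt=dt,
                area=area.astype(int),
                cell_type=ct.astype(int),
                labels=np.asarray(g["labels"]) if "labels" in g else None,
                jaw=np.asarray(g[jaw_key]) if jaw_key in g else None,
                session=sid,
            )
            for u in range(spikes.shape[2]):
                rows.append(
                    {"unit": u, "session": sid, "area": int(area[u]), "cell_type": int(ct[u])}
                )
    if not sessions:
        raise SchemaError("no session group with a 'spikes' dataset found")
    return DatasetBundle(
        sessions=sessions,
        units=pd.DataFrame(rows),
        dt=dt,
        meta={"provenance": "external-deposit (best-effort conversion)"},
    )


def build_session_map(
    bundle: DatasetBundle,
    quotas: Optional[dict[int, tuple[int, int]]] = None,
    seed: int = 0,
) -> SessionMap:
    """Randomly assign model neurons to recorded units respecting quotas.

    ``quotas`` maps each area label to (n_excitatory, n_inhibitory) model
    neurons (default 200/50 per area present in the unit table).  Every model
    neuron is bound to exactly one (session, unit) pair; the assignment is
    seeded and fixed before optimization.
    """
    rng = np.random.default_rng([seed, 887])
    units = bundle.units
    areas = sorted(units["area"].unique())
    if quotas is None:
        quotas = {a: (200, 50) for a in areas}
    sessions, unit_ids = [], []
    for a in areas:
        for ct, want in ((1, quotas[a][0]), (-1, quotas[a][1])):
            pool = units[(units["area"] == a) & (units["cell_type"] == ct)]
            if len(pool) < want:
                kind = "excitatory" if ct == 1 else "inhibitory"
                raise ValueError(
                    f"area {a}: need {want} {kind} units, have {len(pool)}"
                )
            pick = pool.iloc[rng.choice(len(pool), want, replace=False)]
            sessions.extend(pick["session"].tolist())
            unit_ids.extend(pick["unit"].tolist())
    return SessionMap(session=np.array(sessions), unit=np.array(unit_ids))
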
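"""Session-bundle persistence (HDF5) and text exports (CSV, SWC, TIFF)."""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import TimeSeries, SpikeTrain, StimulusProtocol, BoutTable
from .synth import Session, BehaviorSim, SyntheticCell, GeneratorConfig

__all__ = ["write_session", "read_session", "write_bouts_csv",
           "read_bouts_csv", "write_spikes_csv", "read_spikes_csv",
           "write_swc", "read_swc", "write_config_text"]


def _write_df(group: h5py.Group, name: str, df: pd.DataFrame) -> None:
    g = group.create_group(name)
    g.attrs["columns"] = json.dumps(list(df.columns))
    for c in df.columns:
        col = df[c]
        if col.dtype == object:
            g.create_dataset(c, data=col.astype(str).to_numpy().astype("S"))
        else:
            g.create_dataset(c, data=col.to_numpy())


def _read_df(group: h5py.Group, name: str) -> pd.DataFrame:
    g = group[name]
    cols = json.loads(g.attrs["columns"])
    data = {}
    for c in cols:
        a = g[c][()]
        data[c] = a.astype(str) if a.dtype.kind == "S" else a
    return pd.DataFrame(data, columns=cols)


def _write_ts(group: h5py.Group, name: str, ts: TimeSeries) -> None:
    d = group.create_dataset(name, data=ts.data)
    d.attrs["rate"] = ts.rate
    d.attrs["t0"] = ts.t0


def _read_ts(group: h5py.Group, name: str) -> TimeSeries:
    d = group[name]
    return TimeSeries(d[()], float(d.attrs["rate"]), float(d.attrs["t0"]))


def write_session(path, session: Session) -> None:
    """Write a synthetic session bundle: /stimulus, /vr, /eyes, /cells/<id>,
    /ground_truth, and the generator config as JSON text."""
    with h5py.File(path, "w") as f:
        stim = f.create_group("stimulus")
        _write_df(stim, "epochs", session.protocol.epochs)
        _write_df(stim, "trials", session.protocol.trials)
        stim.attrs["ambient_luminance"] = session.protocol.ambient_luminance
        _write_ts(f, "vr", session.behavior.vr)
        _write_ts(f, "vigor", session.behavior.vigor)
        eyes = f.create_group("eyes")
        _write_ts(eyes, "left", session.behavior.eyes[0])
        _write_ts(eyes, "right", session.behavior.eyes[1])
        _write_df(f, "bout_truth", session.behavior.bouts.bouts)
        cells = f.create_group("cells")
        for c in session.cells:
            g = cells.create_group(c.cell_id)
            g.create_dataset("cs", data=c.cs.times)
            g.create_dataset("ss", data=c.ss.times)
            g.attrs["phenotype"] = c.phenotype
            g.attrs["position"] = c.position
            g.attrs["hemisphere"] = c.hemisphere
            g.attrs["preferred"] = str(c.preferred_direction)
            g.attrs["ground_truth"] = json.dumps(c.ground_truth, default=str)
        f.attrs["config"] = json.dumps(session.config.as_dict(), default=str)
        f.attrs["behavior_truth"] = json.dumps(session.behavior.ground_truth)


def read_session(path) -> Session:
    with h5py.File(path, "r") as f:
        stim = f["stimulus"]
        protocol = StimulusProtocol(
            epochs=_read_df(stim, "epochs"), trials=_read_df(stim, "trials"),
            ambient_luminance=float(stim.attrs["ambient_luminance"]))
        behavior = BehaviorSim(
            vr=_read_ts(f, "vr"), vigor=_read_ts(f, "vigor"),
            bouts=BoutTable(_read_df(f, "bout_truth")),
            eyes=(_read_ts(f["eyes"], "left"), _read_ts(f["eyes"], "right")),
            cycle_hz=json.loads(f.attrs["behavior_truth"])["cycle_hz"],
            ground_truth=json.loads(f.attrs["behavior_truth"]))
        cells = []
        for cid in sorted(f["cells"]):
            g = f["cells"][cid]
            ss_label = "granule" if str(g.attrs["phenotype"]) == "granule" else "simple"
            pref = str(g.attrs["preferred"])
            cells.append(SyntheticCell(
                cell_id=cid, phenotype=str(g.attrs["phenotype"]),
                position=tuple(g.attrs["position"]),
                hemisphere=str(g.attrs["hemisphere"]),
                preferred_direction=None if pref == "None" else pref,
                cs=SpikeTrain(g["cs"][()], "complex"),
                ss=SpikeTrain(g["ss"][()], ss_label),
                ground_truth=json.loads(g.attrs["ground_truth"])))
        cfg_raw = json.loads(f.attrs["config"])
    for key in ("lum_latency_range", "motor_cs_latency_range", "eye_latency_range",
                "bout_duration_range", "volume_shape"):
        if key in cfg_raw:
            cfg_raw[key] = tuple(cfg_raw[key])
    config = GeneratorConfig(**cfg_raw)
    return Session(config, protocol, behavior, cells)


def write_bouts_csv(path, table: BoutTable) -> None:
    table.bouts.to_csv(path, index=False)


def read_bouts_csv(path) -> BoutTable:
    return BoutTable(pd.read_csv(path))


def write_spikes_csv(path, trains: list[SpikeTrain]) -> None:
    rows = [{"time_s": t, "label": tr.label} for tr in trains for t in tr.times]
    df = pd.DataFrame(rows, columns=["time_s", "label"]).sort_values("time_s")
    df.to_csv(path, index=False)


def read_spikes_csv(path) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    return [SpikeTrain(np.sort(df[df["label"] == lab]["time_s"].to_numpy()), lab)
            for lab in df["label"].unique()]


def write_swc(path, points: np.ndarray) -> None:
    """Point cloud as a minimal SWC file (type 5 = fork point unused;
    all nodes parentless samples of the dendritic arbor)."""
    pts = np.asarray(points, dtype=float)
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for i, (x, y, z) in enumerate(pts, start=1):
            fh.write(f"{i} 3 {x:.4f} {y:.4f} {z:.4f} 0.5 -1\n")


def read_swc(path) -> np.ndarray:
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        rows.append([float(parts[2]), float(parts[3]), float(parts[4])])
    return np.asarray(rows)


def write_config_text(path, config: GeneratorConfig) -> None:
    """Flat key-value (TOML-style) dump of the generator configuration."""
    with open(path, "w") as fh:
        for k, v in config.as_dict().items():
            fh.write(f"{k} = {json.dumps(v, default=str)}\n")
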
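"""Delimited-text input/output for recordings and analysis products.

A dataset directory holds, per participant, one EMG CSV (time column +
one column per muscle), one force CSV (time + newtons) and a YAML
metadata sidecar with the sampling rates, muscle order, condition label
and signal type.  Synthetic datasets add a ground-truth YAML sidecar.
Analysis products (cycle tensors, events, modules, primitives, metrics,
classification) are written as tidy CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocessing import EmgCycleTensor, GaitEvents, RawRecording
from .synthetic import Bump, SyntheticGroundTruth, SyntheticRecording

__all__ = [
    "write_recording", "read_recording",
    "write_truth", "read_truth",
    "write_tensor", "read_tensor",
    "write_events", "read_events",
]


def write_recording(directory: str | Path, rec: SyntheticRecording | RawRecording,
                    condition: str | None = None) -> Path:
    """Write emg.csv, force.csv and meta.yaml into ``directory``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    if isinstance(rec, SyntheticRecording):
        emg, force = rec.emg, rec.force
        emg_rate, force_rate = rec.emg_rate, rec.force_rate
        muscles = rec.muscle_names
        cond = condition or rec.truth.condition
        signal_type = "envelope"
    else:
        emg, force = rec.emg, rec.force
        emg_rate, force_rate = rec.emg_rate, rec.force_rate
        muscles = rec.muscle_names
        cond = condition or rec.condition
        signal_type = rec.signal_type

    t_emg = np.arange(emg.shape[1]) / emg_rate
    df = pd.DataFrame({"time_s": t_emg})
    for i, name in enumerate(muscles):
        df[name] = emg[i]
    df.to_csv(d / "emg.csv", index=False, float_format="%.6g")

    t_f = np.arange(len(force)) / force_rate
    pd.DataFrame({"time_s": t_f, "force_N": force}).to_csv(
        d / "force.csv", index=False, float_format="%.6g")

    meta = {
        "emg_rate_hz": float(emg_rate),
        "force_rate_hz": float(force_rate),
        "muscles": list(muscles),
        "condition": str(cond),
        "signal_type": signal_type,
    }
    (d / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    return d


def read_recording(directory: str | Path) -> RawRecording:
    """Read emg.csv + force.csv + meta.yaml into a RawRecording."""
    d = Path(directory)
    meta = yaml.safe_load((d / "meta.yaml").read_text())
    emg_df = pd.read_csv(d / "emg.csv")
    force_df = pd.read_csv(d / "force.csv")
    muscles = tuple(meta["muscles"])
    missing = [m for m in muscles if m not in emg_df.columns]
    if missing:
        raise ValueError(f"EMG file lacks muscle columns: {missing}")
    emg = emg_df[list(muscles)].to_numpy().T
    return RawRecording(
        emg=emg, emg_rate=float(meta["emg_rate_hz"]),
        force=force_df["force_N"].to_numpy(),
        force_rate=float(meta["force_rate_hz"]),
        muscle_names=muscles, condition=str(meta.get("condition", "")),
        signal_type=str(meta.get("signal_type", "raw")),
    )


def write_truth(path: str | Path, truth: SyntheticGroundTruth) -> Path:
    path = Path(path)
    doc = {
        "seed": int(truth.seed),
        "n_cycles": int(truth.n_cycles),
        "noise_sigma": float(truth.noise_sigma),
        "persistence_H": float(truth.persistence_H),
        "modulation_amp": float(truth.modulation_amp),
        "muscles": list(truth.muscle_names),
        "condition": truth.condition,
        "stance_s": float(truth.stance_s),
        "flight_s": float(truth.flight_s),
        "emg_rate": float(truth.emg_rate),
        "force_rate": float(truth.force_rate),
        "modules": [[float(v) for v in row] for row in truth.modules],
        "primitives": [
            [{"center": float(b.center), "width": float(b.width),
              "amplitude": float(b.amplitude)} for b in bumps]
            for bumps in truth.primitives
        ],
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def read_truth(path: str | Path) -> SyntheticGroundTruth:
    doc = yaml.safe_load(Path(path).read_text())
    return SyntheticGroundTruth(
        modules=np.array(doc["modules"], dtype=float),
        primitives=[[Bump(**b) for b in bumps] for bumps in doc["primitives"]],
        n_cycles=int(doc["n_cycles"]),
        noise_sigma=float(doc["noise_sigma"]),
        persistence_H=float(doc["persistence_H"]),
        modulation_amp=float(doc["modulation_amp"]),
        seed=int(doc["seed"]),
        muscle_names=tuple(doc["muscles"]),
        stance_s=float(doc["stance_s"]),
        flight_s=float(doc["flight_s"]),
        emg_rate=float(doc["emg_rate"]),
        force_rate=float(doc["force_rate"]),
        condition=str(doc["condition"]),
    )


def write_tensor(path: str | Path, tensor: EmgCycleTensor) -> Path:
    """Cycle tensor as tidy CSV (muscle, cycle, point, value)."""
    m, p, C = tensor.values.shape
    muscle = np.repeat(tensor.muscle_names, p * C)
    cycle = np.tile(np.repeat(np.arange(1, C + 1), p), m)
    point = np.tile(np.arange(1, p + 1), m * C)
    value = tensor.values.transpose(0, 2, 1).reshape(-1)
    df = pd.DataFrame({"muscle": muscle, "cycle": cycle, "point": point,
                       "value": value})
    df.to_csv(path, index=False, float_format="%.8g")
    return Path(path)


def read_tensor(path: str | Path, condition: str = "") -> EmgCycleTensor:
    df = pd.read_csv(path)
    muscles = list(dict.fromkeys(df["muscle"]))
    C = int(df["cycle"].max())
    p = int(df["point"].max())
    vals = np.empty((len(muscles), p, C))
    for i, mus in enumerate(muscles):
        sub = df[df["muscle"] == mus].sort_values(["cycle", "point"])
        vals[i] = sub["value"].to_numpy().reshape(C, p).T
    return EmgCycleTensor(vals, tuple(muscles), condition)


def write_events(path: str | Path, events: GaitEvents) -> Path:
    pd.DataFrame({"touchdown": events.touchdowns,
                  "toeoff": events.toeoffs}).to_csv(path, index=False)
    return Path(path)


def read_events(path: str | Path) -> GaitEvents:
    df = pd.read_csv(path)
    return GaitEvents(df["touchdown"].to_numpy(), df["toeoff"].to_numpy())
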
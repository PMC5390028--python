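"""Text-based I/O: model/orthosis configs (YAML), strength tables,
trajectories, ground reaction forces and solution bundles (CSV/JSON)."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import (COORD_NAMES, NDOF, PlanarModel, SegmentSpec,
                    build_default_model)
from .mtg import StrengthTable
from .ocp import ReferenceGait, Solution
from .orthosis import OrthosisParams

__all__ = [
    "save_model", "load_model", "save_strength_table", "load_strength_table",
    "save_orthosis_params", "load_orthosis_params", "save_trajectory",
    "load_trajectory", "save_grf", "load_grf", "save_solution",
    "load_solution", "save_reference_gait", "load_reference_gait",
]

_TRAJ_COLUMNS = (["time"] + [f"q_{n}" for n in COORD_NAMES]
                 + [f"qd_{n}" for n in COORD_NAMES])
_GRF_COLUMNS = ["time", "L_fx", "L_fz", "L_cop_x", "R_fx", "R_fz", "R_cop_x"]


# -- model -------------------------------------------------------------

def save_model(model: PlanarModel, path) -> None:
    data = {
        "gravity": float(model.gravity),
        "segments": {n: {k: float(v) for k, v in asdict(s).items() if k != "name"}
                     for n, s in model.segments.items()},
        "contact_points": {p: [float(x) for x in xy]
                           for p, xy in model.contact_points.items()},
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def load_model(path) -> PlanarModel:
    data = yaml.safe_load(Path(path).read_text())
    segments = {n: SegmentSpec(name=n, **fields)
                for n, fields in data["segments"].items()}
    contact = {p: tuple(xy) for p, xy in data["contact_points"].items()}
    return PlanarModel(segments=segments, gravity=data["gravity"],
                       contact_points=contact)


# -- strength table ----------------------------------------------------

def save_strength_table(table: StrengthTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def load_strength_table(path) -> StrengthTable:
    df = pd.read_csv(path, dtype={"side": str}, keep_default_na=False)
    entries = {}
    population = "custom"
    for _, row in df.iterrows():
        side = row["side"] or None
        entries[(row["joint"], side, row["direction"])] = float(row["tau_max"])
        population = str(row.get("population", population))
    return StrengthTable(entries, population=population)


# -- orthosis ----------------------------------------------------------

def save_orthosis_params(params: dict, path) -> None:
    """``params`` maps side -> OrthosisParams."""
    data = {side: {k: (float(v) if isinstance(v, (int, float)) else v)
                   for k, v in asdict(p).items()}
            for side, p in params.items()}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def load_orthosis_params(path) -> dict:
    data = yaml.safe_load(Path(path).read_text())
    return {side: OrthosisParams(**fields) for side, fields in data.items()}


# -- trajectories and forces -------------------------------------------

def save_trajectory(path, times, q, qdot) -> None:
    arr = np.column_stack([np.asarray(times), np.asarray(q), np.asarray(qdot)])
    pd.DataFrame(arr, columns=_TRAJ_COLUMNS).to_csv(path, index=False)


def load_trajectory(path):
    df = pd.read_csv(path)
    times = df["time"].to_numpy()
    q = df[[f"q_{n}" for n in COORD_NAMES]].to_numpy()
    qd = df[[f"qd_{n}" for n in COORD_NAMES]].to_numpy()
    return times, q, qd


def save_grf(path, times, grf: dict) -> None:
    """``grf`` maps side -> (T, 3) array of fx, fz, cop_x."""
    T = np.asarray(times).size
    cols = [np.asarray(times)]
    for side in ("L", "R"):
        arr = np.asarray(grf.get(side, np.zeros((T, 3))))
        cols.extend([arr[:, 0], arr[:, 1], arr[:, 2]])
    pd.DataFrame(np.column_stack(cols), columns=_GRF_COLUMNS).to_csv(
        path, index=False)


def load_grf(path):
    df = pd.read_csv(path)
    times = df["time"].to_numpy()
    grf = {side: df[[f"{side}_fx", f"{side}_fz", f"{side}_cop_x"]].to_numpy()
           for side in ("L", "R")}
    return times, grf


# -- solutions ----------------------------------------------------------

def save_solution(sol: Solution, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "mode": sol.mode,
        "objective": float(sol.objective),
        "durations": [float(d) for d in sol.durations],
        "stiffness": ([float(k) for k in sol.stiffness]
                      if sol.stiffness is not None else None),
        "status": sol.status,
        "success": bool(sol.success),
        "constr_violation": float(sol.constr_violation),
        "walking_speed": float(sol.walking_speed),
        "r_T": float(sol.r_T),
    }
    (directory / "solution.json").write_text(json.dumps(meta, indent=2))
    save_trajectory(directory / "states.csv", sol.times,
                    sol.q(), sol.qdot())
    act_cols = [f"a_{i}" for i in range(sol.act().shape[1])]
    exc_cols = [f"e_{i}" for i in range(sol.controls.shape[1])]
    pd.DataFrame(np.column_stack([sol.times, sol.act(), sol.controls]),
                 columns=["time"] + act_cols + exc_cols).to_csv(
        directory / "activations.csv", index=False)


def load_solution(directory) -> Solution:
    directory = Path(directory)
    meta = json.loads((directory / "solution.json").read_text())
    times, q, qd = load_trajectory(directory / "states.csv")
    df = pd.read_csv(directory / "activations.csv")
    n_mus = sum(c.startswith("a_") for c in df.columns)
    act = df[[f"a_{i}" for i in range(n_mus)]].to_numpy()
    controls = df[[f"e_{i}" for i in range(n_mus)]].to_numpy()
    return Solution(
        times=times, states=np.column_stack([q, qd, act]), controls=controls,
        durations=np.asarray(meta["durations"]),
        objective=meta["objective"], mode=meta["mode"],
        stiffness=(np.asarray(meta["stiffness"])
                   if meta["stiffness"] is not None else None),
        status=meta["status"], success=meta["success"],
        constr_violation=meta["constr_violation"],
    )


# -- reference gaits ----------------------------------------------------

def save_reference_gait(ref: ReferenceGait, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {"durations": [float(d) for d in ref.durations]}
    (directory / "reference.json").write_text(json.dumps(meta, indent=2))
    pd.DataFrame(np.column_stack([ref.times, ref.q_meas]),
                 columns=["time"] + [f"q_{n}" for n in COORD_NAMES]).to_csv(
        directory / "kinematics.csv", index=False)
    if ref.grf:
        times_grf = ref.grf.get("times", ref.times)
        save_grf(directory / "grf.csv", times_grf,
                 {s: ref.grf[s] for s in ("L", "R") if s in ref.grf})


def load_reference_gait(directory) -> ReferenceGait:
    directory = Path(directory)
    meta = json.loads((directory / "reference.json").read_text())
    df = pd.read_csv(directory / "kinematics.csv")
    times = df["time"].to_numpy()
    q = df[[f"q_{n}" for n in COORD_NAMES]].to_numpy()
    grf = {}
    if (directory / "grf.csv").exists():
        gt, g = load_grf(directory / "grf.csv")
        grf = {"times": gt, **g}
    return ReferenceGait(times=times, q_meas=q,
                         durations=np.asarray(meta["durations"]), grf=grf)
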
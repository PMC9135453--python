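"""Configuration parsing, trajectory containers, and tabular output.

Run configs are YAML with four blocks::

    scenario:  {name: ..., <generator arguments>}
    step:      {h, kbt, brownian, collision_buffer, solver_tol, ...}
    run:       {duration, seed}
    output:    {cadence, trajectory, log, record_motors}

Trajectories are stored in one structured HDF5 file (per-frame groups hold
filament configurations, optional motor state, and solver diagnostics); a
plain-text columnar state table (one row per filament) round-trips exactly
and is convenient for debugging and fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .boundaries import Boundary, make_boundary
from .geometry import ConfigurationError, FilamentSet, KBT_ROOM
from .integrator import StepConfig
from .state import SystemState


# ----------------------------------------------------------------------------
# Config schema
# ----------------------------------------------------------------------------

_STEP_KEYS = {
    "h", "kbt", "brownian", "collision_buffer", "solver_tol", "solver_max_iter",
    "check_residuals",
}
_RUN_KEYS = {"duration", "seed"}
_OUTPUT_KEYS = {"cadence", "trajectory", "log", "record_motors", "text_frames"}


@dataclass
class RunConfig:
    scenario: dict
    step: StepConfig
    duration: float
    seed: int
    cadence: float = 0.1
    trajectory: str = None
    log: str = None
    record_motors: bool = False

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.step.h))


def parse_config(doc: dict) -> RunConfig:
    """Validate a config mapping; raise ConfigurationError naming bad keys."""
    if not isinstance(doc, dict):
        raise ConfigurationError("config root must be a mapping")
    unknown = set(doc) - {"scenario", "step", "run", "output"}
    if unknown:
        raise ConfigurationError(f"unknown top-level config keys: {sorted(unknown)}")
    if "scenario" not in doc:
        raise ConfigurationError("config is missing the 'scenario' block")
    if "run" not in doc:
        raise ConfigurationError("config is missing the 'run' block")
    step_doc = doc.get("step", {})
    bad = set(step_doc) - _STEP_KEYS
    if bad:
        raise ConfigurationError(f"unknown 'step' keys: {sorted(bad)} (accepted: {sorted(_STEP_KEYS)})")
    run_doc = doc["run"]
    bad = set(run_doc) - _RUN_KEYS
    if bad:
        raise ConfigurationError(f"unknown 'run' keys: {sorted(bad)} (accepted: {sorted(_RUN_KEYS)})")
    out_doc = doc.get("output", {})
    bad = set(out_doc) - _OUTPUT_KEYS
    if bad:
        raise ConfigurationError(f"unknown 'output' keys: {sorted(bad)} (accepted: {sorted(_OUTPUT_KEYS)})")
    if "duration" not in run_doc:
        raise ConfigurationError("'run' block needs a 'duration' (seconds)")
    return RunConfig(
        scenario=dict(doc["scenario"]),
        step=StepConfig(**step_doc),
        duration=float(run_doc["duration"]),
        seed=int(run_doc.get("seed", 0)),
        cadence=float(out_doc.get("cadence", 0.1)),
        trajectory=out_doc.get("trajectory"),
        log=out_doc.get("log"),
        record_motors=bool(out_doc.get("record_motors", False)),
    )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return parse_config(doc)


# ----------------------------------------------------------------------------
# Trajectory container and recorder
# ----------------------------------------------------------------------------

@dataclass
class Trajectory:
    """In-memory trajectory: unwrapped centers, quaternions, optional motors."""

    times: np.ndarray
    centers: np.ndarray          # (F, N, 3) unwrapped
    quats: np.ndarray            # (F, N, 4)
    lengths: np.ndarray
    diameters: np.ndarray
    boundary: Boundary
    motor_frames: list = None    # per frame: list over populations of dicts
    diagnostics: list = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def frame_filaments(self, k: int, wrapped: bool = True) -> FilamentSet:
        centers = self.centers[k]
        if wrapped:
            centers = self.boundary.wrap(centers)
        return FilamentSet(
            centers=centers.copy(), quats=self.quats[k].copy(),
            lengths=self.lengths.copy(), diameters=self.diameters.copy(),
            mobile=np.ones(len(self.lengths), dtype=bool),
            bindable=np.ones(len(self.lengths), dtype=bool),
        )


class TrajectoryRecorder:
    """Recorder callback: snapshots the state every `cadence` seconds."""

    def __init__(self, cadence: float, record_motors: bool = False, record_first: bool = True):
        self.cadence = cadence
        self.record_motors = record_motors
        self._next = 0.0 if record_first else cadence
        self._times = []
        self._centers = []
        self._quats = []
        self._motors = [] if record_motors else None
        self._diags = []
        self._static = None

    def snapshot(self, state: SystemState, diag: dict = None) -> None:
        if self._static is None:
            self._static = (
                state.filaments.lengths.copy(),
                state.filaments.diameters.copy(),
                state.boundary,
            )
        self._times.append(state.time)
        self._centers.append(state.filaments.unwrapped_centers(state.boundary))
        self._quats.append(state.filaments.quats.copy())
        if self.record_motors:
            self._motors.append(
                [
                    {"state": pop.state.copy(), "fil": pop.fil.copy(),
                     "arc": pop.arc.copy(), "x": pop.x.copy()}
                    for pop in state.motors
                ]
            )
        keep = {}
        if diag:
            keep = {k: diag[k] for k in ("n_unilateral", "n_bilateral", "iterations", "residual") if k in diag}
        self._diags.append(keep)

    def __call__(self, state: SystemState, diag: dict) -> None:
        if state.time + 1e-12 >= self._next:
            self.snapshot(state, diag)
            self._next += self.cadence

    def build(self) -> Trajectory:
        lengths, diameters, boundary = self._static
        return Trajectory(
            times=np.asarray(self._times),
            centers=np.asarray(self._centers),
            quats=np.asarray(self._quats),
            lengths=lengths,
            diameters=diameters,
            boundary=boundary,
            motor_frames=self._motors,
            diagnostics=self._diags,
        )


# ----------------------------------------------------------------------------
# HDF5 trajectory files
# ----------------------------------------------------------------------------

def _boundary_to_doc(b: Boundary) -> dict:
    if b.kind == "free":
        return {"kind": "free"}
    if b.kind == "periodic_box":
        return {"kind": "periodic_box", "lengths": [float(x) for x in b.lengths]}
    if b.kind == "sphere":
        return {"kind": "sphere", "radius": float(b.radius)}
    if b.kind == "spherical_shell":
        return {"kind": "spherical_shell", "r_in": float(b.r_in), "r_out": float(b.r_out)}
    if b.kind == "cylinder_periodic_x":
        return {"kind": "cylinder_periodic_x", "diameter": float(b.diameter), "period": float(b.period)}
    raise ConfigurationError(f"cannot serialize boundary kind '{b.kind}'")


def write_trajectory_h5(traj: Trajectory, path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["boundary"] = json.dumps(_boundary_to_doc(traj.boundary))
        fh.create_dataset("times", data=traj.times)
        fh.create_dataset("lengths", data=traj.lengths)
        fh.create_dataset("diameters", data=traj.diameters)
        fh.create_dataset("centers", data=traj.centers)
        fh.create_dataset("quats", data=traj.quats)
        if traj.diagnostics:
            fh.attrs["diagnostics"] = json.dumps(traj.diagnostics)
        if traj.motor_frames is not None:
            g = fh.create_group("motors")
            for k, frame in enumerate(traj.motor_frames):
                gf = g.create_group(f"{k:06d}")
                for p, pop in enumerate(frame):
                    gp = gf.create_group(f"pop{p}")
                    for key, arr in pop.items():
                        gp.create_dataset(key, data=arr)


def read_trajectory_h5(path) -> Trajectory:
    import h5py

    with h5py.File(path, "r") as fh:
        boundary = make_boundary(json.loads(fh.attrs["boundary"]))
        motor_frames = None
        if "motors" in fh:
            motor_frames = []
            for k in sorted(fh["motors"]):
                frame = []
                for p in sorted(fh["motors"][k]):
                    gp = fh["motors"][k][p]
                    frame.append({key: gp[key][...] for key in gp})
                motor_frames.append(frame)
        diags = json.loads(fh.attrs["diagnostics"]) if "diagnostics" in fh.attrs else []
        return Trajectory(
            times=fh["times"][...],
            centers=fh["centers"][...],
            quats=fh["quats"][...],
            lengths=fh["lengths"][...],
            diameters=fh["diameters"][...],
            boundary=boundary,
            motor_frames=motor_frames,
            diagnostics=diags,
        )


# ----------------------------------------------------------------------------
# Plain-text state tables
# ----------------------------------------------------------------------------

_TABLE_COLUMNS = [
    "id", "x", "y", "z", "qs", "qx", "qy", "qz", "length", "diameter", "mobile", "bindable",
]


def write_state_table(filset: FilamentSet, path) -> None:
    """Columnar text table, one row per filament; full double precision."""
    with open(path, "w") as fh:
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        for i in range(filset.n):
            row = [str(i)]
            row += [format(v, ".17g") for v in filset.centers[i]]
            row += [format(v, ".17g") for v in filset.quats[i]]
            row += [format(filset.lengths[i], ".17g"), format(filset.diameters[i], ".17g")]
            row += [str(int(filset.mobile[i])), str(int(filset.bindable[i]))]
            fh.write("\t".join(row) + "\n")


def read_state_table(path, eta: float = 0.01) -> FilamentSet:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"state table is missing columns: {sorted(missing)}")
    return FilamentSet(
        centers=df[["x", "y", "z"]].to_numpy(float),
        quats=df[["qs", "qx", "qy", "qz"]].to_numpy(float),
        lengths=df["length"].to_numpy(float),
        diameters=df["diameter"].to_numpy(float),
        mobile=df["mobile"].to_numpy(bool),
        bindable=df["bindable"].to_numpy(bool),
        eta=eta,
    )


# ----------------------------------------------------------------------------
# Run driver and analysis dispatch
# ----------------------------------------------------------------------------

def run_config(cfg: RunConfig, seed: int = None, progress: bool = False):
    """Build the scenario, run the timestep loop, write requested outputs.

    Returns (final_state, trajectory)."""
    from .integrator import run as run_loop
    from .scenarios import build_scenario

    seed = cfg.seed if seed is None else seed
    state = build_scenario(cfg.scenario, seed=seed)
    rec = TrajectoryRecorder(cfg.cadence, record_motors=cfg.record_motors)
    rec.snapshot(state)
    log = run_loop(state, cfg.step, cfg.n_steps, recorders=(rec,))
    traj = rec.build()
    if cfg.trajectory:
        write_trajectory_h5(traj, cfg.trajectory)
    if cfg.log:
        with open(cfg.log, "w") as fh:
            for entry in log:
                fh.write(json.dumps(entry) + "\n")
    return state, traj


def analyze(traj: Trajectory, which: str, **kwargs):
    """Dispatch to an observable; returns a tidy DataFrame."""
    import pandas as pd

    from . import observables as obs

    known = {"velocity", "rdf_minus_ends", "axial_order", "straining_velocity"}
    if which not in known:
        raise ConfigurationError(f"unknown observable '{which}' (available: {sorted(known)})")
    if which == "velocity":
        dt = traj.times[-1] - traj.times[0]
        if dt <= 0:
            raise ConfigurationError("trajectory too short for velocities")
        v = (traj.centers[-1] - traj.centers[0]) / dt
        return pd.DataFrame(
            {"filament": np.arange(v.shape[0]), "vx": v[:, 0], "vy": v[:, 1], "vz": v[:, 2]}
        )
    if which == "rdf_minus_ends":
        r_max = kwargs.get("r_max", 0.3)
        dr = kwargs.get("dr", 0.002)
        frames = kwargs.get("frames", [traj.n_frames - 1])
        pts = []
        for k in frames:
            fs = traj.frame_filaments(k)
            pts.append(fs.minus_ends())
        r, g = obs.rdf_minus_ends(pts, traj.boundary, r_max, dr)
        return pd.DataFrame({"r": r, "g": g})
    if which == "axial_order":
        nbin = kwargs.get("n_bins", 30)
        period = traj.boundary.period_vector()[0]
        edges = np.linspace(0, period, nbin + 1)
        fs = traj.frame_filaments(kwargs.get("frame", traj.n_frames - 1))
        centers, prof, wsum = obs.axial_order_profile(fs, edges, traj.boundary)
        return pd.DataFrame({"x": centers, "S_x": prof, "weight": wsum})
    if which == "straining_velocity":
        return obs.plane_straining_velocity(traj, **kwargs)
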
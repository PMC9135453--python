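"""SystemState: the single source of truth advanced each timestep."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boundaries import Boundary
from .geometry import KBT_ROOM, FilamentSet
from .kinetics import MotorPopulation


@dataclass
class SystemState:
    """Filaments + crosslinkers + boundary + time + RNG state."""

    filaments: FilamentSet
    motors: list[MotorPopulation] = field(default_factory=list)
    boundary: Boundary = field(default_factory=Boundary)
    time: float = 0.0
    step_index: int = 0
    kbt: float = KBT_ROOM
    rng: np.random.Generator = None
    external_force: np.ndarray = None  # optional constant 6N non-constraint force
    warm_start: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rng is None:
            self.rng = np.random.default_rng(0)
        if self.external_force is not None:
            self.external_force = np.asarray(self.external_force, dtype=float)

    @property
    def n_filaments(self) -> int:
        return self.filaments.n

    def n_motors(self) -> int:
        return sum(pop.n for pop in self.motors)

    def motor_state_counts(self) -> dict[str, int]:
        from .kinetics import STATE_NAMES

        out = {"U": 0, "SA": 0, "SB": 0, "D": 0}
        for pop in self.motors:
            for code, name in STATE_NAMES.items():
                out[name] += int(np.sum(pop.state == code))
        return out

    def copy(self) -> "SystemState":
        return SystemState(
            filaments=self.filaments.copy(),
            motors=[pop.copy() for pop in self.motors],
            boundary=self.boundary,
            time=self.time,
            step_index=self.step_index,
            kbt=self.kbt,
            rng=np.random.default_rng(),  # caller must reseed for determinism
            external_force=None if self.external_force is None else self.external_force.copy(),
        )
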
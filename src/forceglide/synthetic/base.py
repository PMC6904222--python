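"""Shared containers for the synthetic-assay generators."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ROLE_UNBOUND = 0
ROLE_DRIVE = 1
ROLE_RESIST = 2
ROLE_STUCK = 3  # roadblock-stalled (a resisting motor pinned on the lattice)

ROLE_NAMES = {ROLE_UNBOUND: "unbound", ROLE_DRIVE: "drive",
              ROLE_RESIST: "resist", ROLE_STUCK: "stuck"}


@dataclass
class SimulationOutput:
    """Ground-truthed output of a synthetic gliding run.

    All series share the single time base ``time`` (seconds).  Positions are
    1-D lab coordinates along the gliding axis, in nm.  ``positions`` carry
    the observation (localization) noise; ``true_positions`` do not.
    ``roles`` give the per-frame truth label for every motor
    (0 unbound, 1 drive, 2 resist, 3 stuck-at-roadblock).
    """

    time: np.ndarray                      # (T,)
    positions: np.ndarray                 # (M, T) observed motor positions, nm
    true_positions: np.ndarray            # (M, T) noise-free positions, nm
    bound: np.ndarray                     # (M, T) bool
    roles: np.ndarray                     # (M, T) int8 role codes
    anchor_positions: np.ndarray          # (M,) nm
    mt_position: np.ndarray               # (T,) nm
    mt_velocity: np.ndarray               # (T,) nm/s
    mt_length: float                      # nm
    roadblocks: np.ndarray = field(default_factory=lambda: np.empty(0))
    rupture_events: list = field(default_factory=list)
    events: pd.DataFrame | None = None    # truth event table (event generator)
    config: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        T = self.time.shape[0]
        for name in ("positions", "true_positions", "bound", "roles"):
            arr = getattr(self, name)
            if arr.shape[-1] != T:
                raise ValueError(f"{name} does not share the common time base")
        for name in ("mt_position", "mt_velocity"):
            if getattr(self, name).shape[0] != T:
                raise ValueError(f"{name} does not share the common time base")

    @property
    def n_motors(self) -> int:
        return self.positions.shape[0]

    @property
    def frame_interval(self) -> float:
        return float(self.time[1] - self.time[0]) if self.time.size > 1 else 0.0

    def displacements(self, observed: bool = True) -> np.ndarray:
        """Per-motor displacement from anchor, (M, T) nm, signed."""
        pos = self.positions if observed else self.true_positions
        return pos - self.anchor_positions[:, None]

    def save(self, out_dir) -> dict:
        """Write traces and truth tables as CSV; return the path map."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        M = self.n_motors
        traces = pd.DataFrame({"time_s": np.tile(self.time, M),
                               "kinesin": np.repeat(np.arange(M), self.time.size),
                               "position_nm": self.positions.ravel(),
                               "true_position_nm": self.true_positions.ravel(),
                               "bound": self.bound.ravel().astype(int),
                               "role": self.roles.ravel()})
        paths["traces"] = out / "motor_traces.csv"
        traces.to_csv(paths["traces"], index=False)
        mt = pd.DataFrame({"time_s": self.time,
                           "mt_position_nm": self.mt_position,
                           "mt_velocity_nm_s": self.mt_velocity})
        paths["microtubule"] = out / "microtubule.csv"
        mt.to_csv(paths["microtubule"], index=False)
        if self.events is not None:
            paths["events"] = out / "truth_events.csv"
            self.events.to_csv(paths["events"], index=False)
        return paths
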
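"""Single-kinesin load responses: force–velocity and force-dependent unbinding.

Kinesin-1 responds asymmetrically to load.  Stepping is roughly load-
insensitive over a plateau around zero load (about +/-2 pN), slows linearly
to stall (~6 pN) under hindering load, and speeds up only modestly (and
saturating) under assisting load.  Detachment follows a Bell law
k(F) = k0 exp(F/Fd) with role-dependent parameters: the resisting motor —
which carries assisting load — lets go more readily than the driving motor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MotorConfig", "force_velocity", "unbinding_rate"]


@dataclass(frozen=True)
class MotorConfig:
    """Kinesin stepping and unbinding parameters.

    The force–velocity defaults put the unloaded plateau between -2 and
    +2 pN, stall at 6 pN hindering load for the mean-speed motor
    (hindered_slope = 830/4 nm/s/pN) and a modest assisted speed-up
    saturating at 6 pN.  The hindered branch scales with the motor's own
    unloaded speed so the stall force is speed-independent.

    Bell unbinding defaults give mean engaged lifetimes near 3 s (drive) and
    2 s (resist) at the 1–2 pN tensions the gliding simulator operates at,
    with the resisting role detaching faster at any force.
    """

    unloaded_speed_mean: float = 830.0      # nm/s
    unloaded_speed_sd: float = 400.0        # nm/s, natural motor-to-motor spread
    hindered_slope: float = 207.5           # (nm/s)/pN beyond the plateau
    hindered_plateau_threshold: float = 2.0  # pN
    assisted_slope: float = 17.0            # (nm/s)/pN beyond the plateau
    assisted_saturation: float = 6.0        # pN
    unbind_rate_drive_0: float = 0.25       # 1/s at zero force
    detach_force_drive: float = 3.0         # pN Bell force scale
    unbind_rate_resist_0: float = 0.35      # 1/s at zero force
    detach_force_resist: float = 2.5        # pN Bell force scale
    bind_rate: float = 0.8                  # 1/s when the lattice is in reach
    capture_radius: float = 400.0           # nm anchor-to-lattice reach
    roadblock_detach_rate: float = 1.0      # 1/s extra release at an obstacle

    def __post_init__(self) -> None:
        positive = (
            "unloaded_speed_mean", "unloaded_speed_sd", "hindered_slope",
            "hindered_plateau_threshold", "assisted_saturation",
            "unbind_rate_drive_0", "detach_force_drive",
            "unbind_rate_resist_0", "detach_force_resist",
            "bind_rate", "capture_radius",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.assisted_slope < 0:
            raise ValueError("assisted response must never lower speed")
        if self.roadblock_detach_rate < 0:
            raise ValueError("roadblock_detach_rate must be non-negative")
        if self.assisted_saturation < self.hindered_plateau_threshold:
            raise ValueError("assisted_saturation must lie beyond the plateau")


def force_velocity(load, base_speed, motor: MotorConfig = MotorConfig()):
    """Walking speed (nm/s) under signed load (pN; negative = hindering).

    Piecewise linear and continuous: ``base_speed`` on the plateau
    [-threshold, +threshold]; linear decrease to zero at stall under
    hindering load; linear modest increase under assisting load, saturating
    at ``assisted_saturation``.  Loads beyond stall clamp to zero — the
    speed is never negative.
    """
    load = np.asarray(load, dtype=float)
    base = np.asarray(base_speed, dtype=float)
    if np.any(base <= 0):
        raise ValueError("base_speed must be strictly positive")
    thr = motor.hindered_plateau_threshold
    # hindered slope scales with the motor's own speed -> common stall force
    slope_h = motor.hindered_slope * base / motor.unloaded_speed_mean
    hindered = base - slope_h * (np.abs(load) - thr)
    assisted = base + motor.assisted_slope * np.minimum(
        load - thr, motor.assisted_saturation - thr
    )
    v = np.where(load < -thr, hindered, np.where(load > thr, assisted, base))
    v = np.maximum(v, 0.0)
    return v if v.ndim else float(v)


def unbinding_rate(force, role: str, motor: MotorConfig = MotorConfig()):
    """Bell detachment rate k(F) = k0_role exp(F/Fd_role), 1/s.

    ``force`` is the unsigned tether tension; ``role`` is "drive" or
    "resist".  With default calibration the resisting rate exceeds the
    driving rate at any common force.
    """
    f = np.asarray(force, dtype=float)
    if np.any(f < 0):
        raise ValueError("force must be non-negative (unsigned tension)")
    if role == "drive":
        k0, fd = motor.unbind_rate_drive_0, motor.detach_force_drive
    elif role == "resist":
        k0, fd = motor.unbind_rate_resist_0, motor.detach_force_resist
    else:
        raise ValueError(f"unknown role {role!r}; expected 'drive' or 'resist'")
    k = k0 * np.exp(f / fd)
    return k if k.ndim else float(k)
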
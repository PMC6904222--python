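"""Event-level trace generator calibrated to published ensemble statistics.

Rather than integrating motor mechanics, this generator emits each kinesin's
on-axis displacement trace directly as a renewal sequence of drive/resist
events with the canonical ramp / plateau / return shape:

* the displacement ramps away from equilibrium at the initial relative
  speed ``|v_motor - v_MT|`` (driving motors outrun the cargo and move
  backwards in the lab; resisting motors lag and are carried forward),
* plateaus once the DNA tether is taut, and
* returns to equilibrium — within the event for driving motors (the taut
  tether drags the slowing motor back before release), by instantaneous
  recoil at detachment for resisting motors.

Exponential durations, a configurable role process (independent Bernoulli or
a Markov chain matched to the published transition-type mix) and Gaussian
localization noise complete the model.  Ground truth (role, boundaries, run
length as the exact integral of relative velocity) is retained per event.

A kinematic identity worth knowing: because ``d(t) = position - anchor``
integrates the lab velocity, an event's run length
``∫(v_MT - v_k) dt = v_MT·τ - Δd``.  Driving events close their displacement
loop (Δd = 0), pinning their mean run length at ``v_MT × mean duration``;
resisting events end displaced, and the resist plateau amplitude is solved
at construction so the resist-role mean run length equals its calibration
target exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from forceglide.synthetic.base import (
    ROLE_DRIVE,
    ROLE_RESIST,
    ROLE_UNBOUND,
    SimulationOutput,
)

__all__ = ["EventCalibration", "generate_event_traces"]


@dataclass(frozen=True)
class EventCalibration:
    """Published summary statistics used as generator parameters.

    ``p_drive`` is the per-frame (duration-weighted) probability that an
    engaged motor is driving; the per-event role prior is derived from it
    and the two mean durations.  ``transition_mix`` orders the four
    transition types (drive-drive, drive-resist, resist-drive,
    resist-resist); it is honoured only when ``role_process='markov'``,
    where consecutive roles follow the Markov chain whose stationary pair
    distribution equals the mix.
    """

    p_drive: float = 0.65
    mean_duration_drive: float = 3.0       # s
    mean_duration_resist: float = 2.15     # s
    mean_runlength_drive: float = 2.31     # µm (see module docstring)
    mean_runlength_resist: float = 1.42    # µm
    transition_rate: float = 4.9           # events per kinesin-minute
    transition_mix: tuple = (0.52, 0.16, 0.16, 0.16)  # DD, DR, RD, RR
    mt_speed_mean: float = 830.0           # nm/s bulk (unloaded) gliding speed
    localization_noise_sd: float = 20.0    # nm
    v_rel_drive_init: float = 1300.0       # nm/s initial relative speed, drive
    v_rel_resist_init: float = 500.0       # nm/s initial relative speed, resist
    drive_plateau: float = 450.0           # nm plateau displacement magnitude
    drive_return_speed: float = 1000.0     # nm/s recoil rate closing the loop
    min_event_duration: float = 0.6        # s, shortest resolvable event
    role_process: str = "independent"      # or "markov"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_drive <= 1.0:
            raise ValueError("p_drive must lie in [0, 1]")
        if abs(sum(self.transition_mix) - 1.0) > 1e-9:
            raise ValueError("transition_mix must sum to 1")
        if any(m < 0 for m in self.transition_mix):
            raise ValueError("transition_mix fractions must be non-negative")
        for name in ("mean_duration_drive", "mean_duration_resist",
                     "mean_runlength_drive", "mean_runlength_resist",
                     "transition_rate", "mt_speed_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.role_process not in ("independent", "markov"):
            raise ValueError("role_process must be 'independent' or 'markov'")

    @property
    def event_prior_drive(self) -> float:
        """Per-event drive probability giving p_drive as the frame fraction.

        Weighting by the (floored) expected event durations makes the
        duration-weighted fraction of engaged frames equal p_drive exactly.
        """
        p = self.p_drive
        e_d, e_r = self.expected_duration("drive"), self.expected_duration("resist")
        return p * e_r / ((1.0 - p) * e_d + p * e_r)

    @property
    def markov_matrix(self) -> np.ndarray:
        """Role transition matrix [[P(D->D), P(D->R)], [P(R->D), P(R->R)]]."""
        dd, dr, rd, rr = self.transition_mix
        from_d, from_r = dd + dr, rd + rr
        return np.array([[dd / from_d, dr / from_d],
                         [rd / from_r, rr / from_r]])

    def expected_duration(self, role: str) -> float:
        """E[max(Exp(µ_role), c)] = c + µ exp(-c/µ) with the duration floor c."""
        mu = (self.mean_duration_drive if role == "drive"
              else self.mean_duration_resist)
        c = self.min_event_duration
        return c + mu * np.exp(-c / mu)

    @property
    def engaged_mt_speed(self) -> float:
        """Cargo speed while an analyzed motor is engaged, nm/s.

        For a driving event whose displacement starts and ends at
        equilibrium, run length = cargo speed x duration identically, so the
        published drive run length and duration fix the engaged-cargo speed:
        v_e = mean_runlength_drive / E[duration].  (~756 nm/s at defaults —
        below the bulk gliding speed, as expected for a cargo under tug-of-
        war load.)
        """
        return self.mean_runlength_drive * 1000.0 / self.expected_duration("drive")

    @property
    def resist_plateau(self) -> float:
        """Resist plateau amplitude D (nm) calibrating the resist run length.

        A resisting event ends displaced by min(D, r·duration) with
        r = v_e - v_rel_resist_init, so
        E[run] = v_e·E[duration] - E[min(D, r·max(Exp(µ), c))]; with the
        floored-exponential duration the expectation is
        r·c + r·µ·(exp(-c/µ) - exp(-D/(r·µ))), solved for D in closed form.
        """
        v = self.engaged_mt_speed
        mu, c = self.mean_duration_resist, self.min_event_duration
        r = v - self.v_rel_resist_init
        if r <= 0:
            raise ValueError("resisting motors must be slower than the cargo")
        e_target = v * self.expected_duration("resist") - 1000.0 * self.mean_runlength_resist
        arg = np.exp(-c / mu) - (e_target - r * c) / (r * mu)
        if not 0.0 < arg < np.exp(-c / mu) or e_target < r * c:
            raise ValueError(
                "resist run-length calibration infeasible for these "
                "durations/speeds"
            )
        return float(-r * mu * np.log(arg))

    @property
    def mean_idle(self) -> float:
        """Mean unbound gap (s) so the event rate matches transition_rate."""
        if self.role_process == "markov":
            pi_d = self.markov_matrix[1, 0] / (
                self.markov_matrix[0, 1] + self.markov_matrix[1, 0]
            )
        else:
            pi_d = self.event_prior_drive
        mean_dur = (pi_d * self.expected_duration("drive")
                    + (1 - pi_d) * self.expected_duration("resist"))
        idle = 60.0 / self.transition_rate - mean_dur
        if idle <= 0:
            raise ValueError("transition_rate too high for the mean durations")
        return idle


def _drive_shape(t: np.ndarray, tau: float, cal: EventCalibration,
                 v_mt: float) -> np.ndarray:
    """Driving displacement (negative): ramp out, plateau, ramp back to 0."""
    r_out = cal.v_rel_drive_init - v_mt
    r_ret = cal.drive_return_speed
    D = cal.drive_plateau
    t_out, t_ret = D / r_out, D / r_ret
    if t_out + t_ret >= tau:  # triangle: scale the peak down
        t_peak = tau * r_ret / (r_out + r_ret)
        peak = r_out * t_peak
        d = np.where(t < t_peak, -r_out * t, -(peak - r_ret * (t - t_peak)))
    else:
        d = np.where(
            t < t_out, -r_out * t,
            np.where(t < tau - t_ret, -D, -(r_ret * (tau - t)))
        )
    return np.minimum(d, 0.0)


def _resist_shape(t: np.ndarray, tau: float, cal: EventCalibration,
                  v_mt: float) -> np.ndarray:
    """Resisting displacement (positive): ramp out, plateau, end displaced."""
    r_out = v_mt - cal.v_rel_resist_init
    return np.minimum(r_out * t, cal.resist_plateau)


def generate_event_traces(
    cal: EventCalibration = EventCalibration(),
    n_kinesins: int = 10,
    duration: float = 600.0,
    seed: int | np.random.Generator = 0,
    frame_interval: float = 0.2,
) -> SimulationOutput:
    """Generate ground-truthed on-axis traces for ``n_kinesins`` motors.

    Each motor emits an alternating renewal sequence of exponential idle
    gaps and drive/resist events; displacement shapes follow the module
    docstring, localization noise is added, and full truth (role,
    boundaries, exact run length) is recorded per event.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_frames = int(round(duration / frame_interval))
    time = np.arange(n_frames) * frame_interval
    v_mt = cal.engaged_mt_speed

    anchors = (np.arange(n_kinesins, dtype=float) + 1.0) * 2000.0
    true_disp = np.zeros((n_kinesins, n_frames))
    roles = np.full((n_kinesins, n_frames), ROLE_UNBOUND, dtype=np.int8)
    records = []

    P = cal.markov_matrix if cal.role_process == "markov" else None
    q = cal.event_prior_drive

    for k in range(n_kinesins):
        t = float(rng.exponential(cal.mean_idle))
        prev_role = None
        while t < duration:
            if cal.role_process == "markov":
                if prev_role is None:
                    pi_d = P[1, 0] / (P[0, 1] + P[1, 0])
                    role = ROLE_DRIVE if rng.random() < pi_d else ROLE_RESIST
                else:
                    row = P[0 if prev_role == ROLE_DRIVE else 1]
                    role = ROLE_DRIVE if rng.random() < row[0] else ROLE_RESIST
            else:
                role = ROLE_DRIVE if rng.random() < q else ROLE_RESIST
            mu = (cal.mean_duration_drive if role == ROLE_DRIVE
                  else cal.mean_duration_resist)
            tau = float(rng.exponential(mu))
            tau = max(tau, cal.min_event_duration)  # resolvable by the camera
            end = min(t + tau, duration)
            tau_eff = end - t

            i0, i1 = np.searchsorted(time, [t, end])
            tt = time[i0:i1] - t
            shape = (_drive_shape(tt, tau_eff, cal, v_mt) if role == ROLE_DRIVE
                     else _resist_shape(tt, tau_eff, cal, v_mt))
            true_disp[k, i0:i1] = shape
            roles[k, i0:i1] = role

            if role == ROLE_DRIVE:
                d_start = d_end = 0.0
            else:
                d_start = 0.0
                d_end = float(_resist_shape(np.array([tau_eff]), tau_eff,
                                            cal, v_mt)[0])
            run_nm = v_mt * tau_eff - (d_end - d_start)
            records.append({
                "kinesin": k,
                "role": "drive" if role == ROLE_DRIVE else "resist",
                "start_s": t,
                "end_s": end,
                "duration_s": tau_eff,
                "run_length_um": run_nm / 1000.0,
                "peak_displacement_nm": float(shape.min() if role == ROLE_DRIVE
                                              else shape.max()) if shape.size
                else 0.0,
            })
            prev_role = role
            t = end + float(rng.exponential(cal.mean_idle))

    noise = rng.normal(0.0, cal.localization_noise_sd, true_disp.shape)
    positions = anchors[:, None] + true_disp + noise
    # the filament must span every anchor for the whole run: its minus end
    # trails the field at t=0 and its lattice is long enough to cover the
    # anchors until the end of the recording
    mt_length = (n_kinesins + 2) * 2000.0 + v_mt * duration
    mt_position = v_mt * (time - duration)
    mt_velocity = np.full(n_frames, v_mt)

    return SimulationOutput(
        time=time,
        positions=positions,
        true_positions=anchors[:, None] + true_disp,
        bound=roles != ROLE_UNBOUND,
        roles=roles,
        anchor_positions=anchors,
        mt_position=mt_position,
        mt_velocity=mt_velocity,
        mt_length=mt_length,
        events=pd.DataFrame.from_records(records),
        config={"calibration": cal.__dict__.copy(),
                "n_kinesins": n_kinesins, "duration": duration,
                "frame_interval": frame_interval},
        seed=None if isinstance(seed, np.random.Generator) else int(seed),
    )
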
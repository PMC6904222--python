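"""Mechanistic multi-kinesin gliding simulator (1-D tug-of-war).

Geometry is reduced to the gliding axis.  Anchored motors bind the
microtubule lattice at zero tether tension, step toward the lattice minus
direction at a load-dependent speed (propelling the microtubule forward),
stretch their dsDNA tethers, and unbind stochastically with Bell kinetics
whose parameters depend on their current role.  The microtubule position is
advanced each step to the unique root of the quasi-static balance

    sum(signed tether forces on the microtubule) - gamma * V = 0,

which exists and is unique because every tether force is monotone in the
microtubule position and the drag term is strictly decreasing.

Sign conventions (lab axis = gliding direction): a motor whose head lies
behind its anchor (negative displacement) is driving and its taut tether
pulls the microtubule forward (positive force); a motor displaced forward is
resisting and pulls backward.  Roadblocks are lattice-fixed points that stall
stepping (the motor keeps its force-dependent unbinding and is labelled
stuck); bypass is not modelled.

The lattice is treated as unbounded — the microtubule is long compared with
the tether reach and the simulation emulates a cropped field of view that
the filament never leaves — with roadblocks repeated periodically at the
configured linear density (period = ``microtubule_length``).  This keeps the
configured number of kinesins within reach for the whole run, as in the
published per-filament crops.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from forceglide.synthetic.base import (
    ROLE_DRIVE,
    ROLE_RESIST,
    ROLE_STUCK,
    ROLE_UNBOUND,
    SimulationOutput,
)
from forceglide.synthetic.motors import MotorConfig, force_velocity, unbinding_rate
from forceglide.tether import ForceLookup, TetherModel

__all__ = [
    "AssayConfig",
    "simulate_gliding",
    "place_roadblocks",
    "anchor_rupture_step",
]


@dataclass(frozen=True)
class AssayConfig:
    """Geometry, densities and numerics of one synthetic gliding run.

    Either ``motor_count`` (anchors spread along the microtubule's sweep) or
    ``surface_density`` (motors/µm², converted to a linear anchor density
    over a strip two capture radii wide) determines the anchor layout when
    explicit ``anchor_positions`` are not given.
    """

    motor_count: int | None = 3
    anchor_positions: tuple | None = None   # nm, 1-D lab coordinates
    surface_density: float | None = None    # motors/µm²
    microtubule_length: float = 8.0         # µm
    roadblock_density: float = 0.0          # per µm of lattice
    drag_coefficient: float = 1e-3          # pN·s/nm
    time_step: float = 0.005                # s
    duration: float = 120.0                 # s
    localization_noise_sd: float = 20.0     # nm added to recorded positions

    def __post_init__(self) -> None:
        if self.time_step <= 0 or self.time_step > 0.01:
            raise ValueError("time_step must be in (0, 0.01] s")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.roadblock_density < 0:
            raise ValueError("densities must be non-negative")
        if (self.motor_count is None and self.anchor_positions is None
                and self.surface_density is None):
            raise ValueError("need motor_count, anchor_positions or surface_density")


def place_roadblocks(density: float, length: float,
                     seed: int | np.random.Generator = 0) -> np.ndarray:
    """Poisson point set of roadblocks on the lattice [0, length µm], nm."""
    if density < 0:
        raise ValueError("density must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = rng.poisson(density * length)
    return np.sort(rng.uniform(0.0, length * 1000.0, n))


def anchor_rupture_step(tension: float, dt: float, bond,
                        rng: np.random.Generator | None = None) -> bool:
    """One Bell–Evans survival draw for the anchoring bond.

    Returns True with probability 1 - exp(-k0 exp(F/Fb) dt).  With
    ``rng=None`` only the probability logic is exercised deterministically
    against 0.5 (useful for limits); pass a Generator for stochastic use.
    """
    if tension < 0 or dt <= 0:
        raise ValueError("tension must be >= 0 and dt > 0")
    p = -np.expm1(-bond.k0_bond * np.exp(tension / bond.fb_bond) * dt)
    if rng is None:
        return p > 0.5
    return bool(rng.random() < p)


def _resolve_anchors(assay: AssayConfig, motor: MotorConfig,
                     rng: np.random.Generator) -> np.ndarray:
    if assay.anchor_positions is not None:
        return np.asarray(assay.anchor_positions, dtype=float)
    L = assay.microtubule_length * 1000.0
    if assay.motor_count is not None:
        n = assay.motor_count
    else:
        # expected kinesins within tether reach of the filament footprint
        strip_um = 2.0 * motor.capture_radius / 1000.0
        n = max(1, rng.poisson(assay.surface_density
                               * strip_um * assay.microtubule_length))
    base = np.linspace(0.15, 0.85, n) * L
    return base + rng.uniform(-0.04 * L, 0.04 * L, n)


def simulate_gliding(
    assay: AssayConfig = AssayConfig(),
    motor: MotorConfig = MotorConfig(),
    tether: TetherModel = TetherModel(),
    seed: int | np.random.Generator = 0,
    bond=None,
    record_interval: float | None = None,
) -> SimulationOutput:
    """Run the mechanistic tug-of-war and return ground-truthed series.

    ``bond`` (a ``forceglide.rupture.BondModel``) enables anchor rupture:
    a ruptured motor translocates with the microtubule thereafter.
    ``record_interval`` subsamples the stored series (default: every step).
    The quasi-static force-balance residual of every step is recorded in
    ``config['max_balance_residual']``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dt = assay.time_step
    n_steps = int(round(assay.duration / dt))
    stride = 1 if record_interval is None else max(1, int(round(record_interval / dt)))
    lookup = ForceLookup(tether)
    L = assay.microtubule_length * 1000.0

    anchors = _resolve_anchors(assay, motor, rng)
    M = anchors.size
    # truncated to the physical kinesin-1 range: unloaded speeds far outside
    # ~250-1450 nm/s are not observed and would stretch tethers taut within
    # a frame or two of binding
    base_speed = np.clip(
        rng.normal(motor.unloaded_speed_mean, motor.unloaded_speed_sd, M),
        250.0, 1450.0,
    )
    roadblocks = place_roadblocks(assay.roadblock_density,
                                  assay.microtubule_length, rng)

    X = 0.0
    bound = np.zeros(M, dtype=bool)
    ruptured = np.zeros(M, dtype=bool)
    stuck = np.zeros(M, dtype=bool)
    s = np.zeros(M)  # lattice coordinate of each bound head

    n_rec = n_steps // stride + 1
    rec_t = np.empty(n_rec)
    rec_pos = np.empty((M, n_rec))
    rec_bound = np.zeros((M, n_rec), dtype=bool)
    rec_roles = np.full((M, n_rec), ROLE_UNBOUND, dtype=np.int8)
    rec_X = np.empty(n_rec)
    rec_V = np.empty(n_rec)
    rupture_events = []
    max_residual = 0.0

    def head_positions(x: float) -> np.ndarray:
        h = anchors.copy()
        h[bound] = x + s[bound]
        h[ruptured] = x + s[ruptured]
        return h

    def net_force(x: float, v: float) -> float:
        d = x + s[bound] - anchors[bound]
        f = lookup.force(d)
        return float(np.sum(-np.sign(d) * f) - assay.drag_coefficient * v)

    V = 0.0
    i_rec = 0
    for step in range(n_steps + 1):
        t = step * dt
        # ---- record ----------------------------------------------------
        if step % stride == 0:
            rec_t[i_rec] = t
            h = head_positions(X)
            rec_pos[:, i_rec] = h
            rec_bound[:, i_rec] = bound
            d_all = h - anchors
            role = np.where(d_all < 0, ROLE_DRIVE, ROLE_RESIST).astype(np.int8)
            role[stuck] = ROLE_STUCK
            role[~bound] = ROLE_UNBOUND
            rec_roles[:, i_rec] = role
            rec_X[i_rec] = X
            rec_V[i_rec] = V
            i_rec += 1
        if step == n_steps:
            break

        # ---- tensions and stepping ------------------------------------
        idx = np.flatnonzero(bound)
        if idx.size:
            d = X + s[idx] - anchors[idx]
            F = np.atleast_1d(lookup.force(d))
            load = np.sign(d) * F          # negative = hindering (drive side)
            w = force_velocity(load, base_speed[idx], motor)
            w = np.atleast_1d(w)
            w[stuck[idx]] = 0.0
            s_new = s[idx] - w * dt
            # roadblock encounters: clamp at the first roadblock crossed
            # (roadblock lattice repeats with period L)
            if roadblocks.size:
                for j, i_m in enumerate(idx):
                    if stuck[i_m] or w[j] == 0.0:
                        continue
                    period = np.floor((s[i_m] - 1e-9) / L)
                    k = np.searchsorted(roadblocks, s[i_m] - 1e-9 - period * L)
                    rb = (roadblocks[k - 1] + period * L if k > 0
                          else roadblocks[-1] + (period - 1) * L)
                    if s_new[j] <= rb:
                        s_new[j] = rb
                        stuck[i_m] = True
            s[idx] = s_new

            # ---- quasi-static microtubule advance ----------------------
            lo, hi = X - 5.0, X + 20.0
            width = 25.0
            while net_force(lo, (lo - X) / dt) < 0:
                lo -= width
                width *= 2.0
            width = 25.0
            while net_force(hi, (hi - X) / dt) > 0:
                hi += width
                width *= 2.0
            X_new = brentq(lambda x: net_force(x, (x - X) / dt), lo, hi,
                           xtol=1e-9)
            residual = abs(net_force(X_new, (X_new - X) / dt))
            max_residual = max(max_residual, residual)
            V = (X_new - X) / dt
            X = X_new

            # ---- unbinding / rupture -----------------------------------
            d = X + s[idx] - anchors[idx]
            F = np.atleast_1d(lookup.force(d))
            for j, i_m in enumerate(idx):
                role = "drive" if d[j] < 0 else "resist"
                if bond is not None and anchor_rupture_step(float(F[j]), dt,
                                                            bond, rng):
                    rupture_events.append(
                        {"time_s": t, "kinesin": int(i_m),
                         "tension_pN": float(F[j])})
                    ruptured[i_m] = True
                    bound[i_m] = False
                    stuck[i_m] = False
                    continue
                k = unbinding_rate(float(F[j]), role, motor)
                if stuck[i_m]:
                    # obstacle contact promotes release (detach-or-pause)
                    k += motor.roadblock_detach_rate
                if rng.random() < -np.expm1(-k * dt):
                    bound[i_m] = False
                    stuck[i_m] = False
        else:
            V = 0.0  # no engaged motor: cargo diffusive, flagged by role table

        # ---- binding ---------------------------------------------------
        p_bind = -np.expm1(-motor.bind_rate * dt)
        for i_m in np.flatnonzero(~bound & ~ruptured):
            s_cand = anchors[i_m] - X  # lattice site under the anchor
            if rng.random() < p_bind:
                if roadblocks.size and np.any(
                        np.abs(roadblocks - s_cand % L) < 8.0):
                    continue  # landing site blocked
                bound[i_m] = True
                stuck[i_m] = False
                s[i_m] = s_cand

    noise = rng.normal(0.0, assay.localization_noise_sd, rec_pos.shape)
    observed = rec_pos + noise

    return SimulationOutput(
        time=rec_t,
        positions=observed,
        true_positions=rec_pos,
        bound=rec_bound,
        roles=rec_roles,
        anchor_positions=anchors,
        mt_position=rec_X,
        mt_velocity=rec_V,
        mt_length=L,
        roadblocks=roadblocks,
        rupture_events=rupture_events,
        config={
            "assay": assay.__dict__.copy(),
            "motor": motor.__dict__.copy(),
            "tether": tether.__dict__.copy(),
            "base_speeds": base_speed.tolist(),
            "max_balance_residual": max_residual,
        },
        seed=None if isinstance(seed, np.random.Generator) else int(seed),
    )
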
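"""Drive/resist state inference from on-axis displacement traces.

This is the analytical heart of the force-gliding assay: each anchored
kinesin's on-axis displacement from its equilibrium (anchor) position tells
whether it is driving the microtubule (displaced opposite to the gliding
direction, negative by convention) or resisting it (displaced along the
motion).  From classified excursions the module derives the published
ensemble statistics: per-role attachment durations and run lengths,
transition rates and type mix, force-versus-time curves through the tether
model, the fraction of engaged motors driving, relative-velocity
convergence, and kinetics trends across surface densities.

Classification criteria: an excursion qualifies as an event when at least
two of its points lie more than 100 nm, or more than two baseline standard
deviations, from the equilibrium position (the two branches are
disjunctive); traces with more than 5 s of missing data are discarded.
Event boundaries are the first/last crossings of the 2-SD level, linearly
interpolated between frames.  Detection runs on a lightly smoothed trace
(3-frame boxcar) with the noise SD measured on the raw trace, which
suppresses isolated noise spikes without touching genuine excursions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from scipy.stats import gaussian_kde

from forceglide.synthetic.base import ROLE_DRIVE, ROLE_RESIST, ROLE_STUCK
from forceglide.tether import ForceLookup, TetherModel

__all__ = [
    "EquilibriumEstimate",
    "MotorEvent",
    "TransitionRecord",
    "find_equilibrium",
    "classify_events",
    "analyze_track",
    "analyze_simulation",
    "count_transitions",
    "event_kinetics",
    "force_vs_time",
    "fraction_driving",
    "relative_velocity_curves",
    "density_sweep",
    "events_to_role_matrix",
]


@dataclass(frozen=True)
class EquilibriumEstimate:
    """Anchor-defined rest position of one motor and its baseline noise."""

    position: float             # nm
    noise_sd: float             # nm
    fallback: bool = False      # True if the trace never looked quiescent
    degenerate: bool = False    # True if the trace was (near-)constant


@dataclass
class MotorEvent:
    """One drive or resist excursion of one kinesin."""

    kinesin: int
    role: str                       # "drive" | "resist"
    start: float                    # s (interpolated 2-SD crossing)
    end: float                      # s
    times: np.ndarray               # frame times inside the event, s
    displacement: np.ndarray        # signed on-axis displacement, nm
    force: np.ndarray               # tether tension per frame, pN
    run_length: float               # µm, integral of (v_MT - v_kinesin)
    peak_displacement: float        # signed nm
    sharp_start: bool = False       # onset jumped the threshold in one frame

    @property
    def duration(self) -> float:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("event duration must be positive")
        if self.run_length < 0:
            self.run_length = 0.0


@dataclass(frozen=True)
class TransitionRecord:
    """One ordered pair of consecutive events of the same kinesin."""

    kinesin: int
    from_role: str
    to_role: str
    time: float                     # s, between the two events


def equilibrium_candidates(series, quiescent_quantile: float = 0.5,
                           min_relative_density: float = 0.2):
    """Candidate equilibrium positions: KDE modes of the quiescent frames.

    A trace dominated by long engaged plateaus can be multi-modal (anchor
    baseline plus drive/resist plateau lobes); every mode with at least
    ``min_relative_density`` of the peak density is a candidate.  Returns a
    list of (position, relative_density) sorted by decreasing density.
    """
    x = np.asarray(series, dtype=float)
    xf = x[np.isfinite(x)]
    if xf.size < 50 or np.ptp(xf) < 1e-9:
        return [(float(xf[0]) if xf.size else 0.0, 1.0)]
    grad = np.abs(np.gradient(xf))
    quiet = grad <= np.quantile(grad, quiescent_quantile)
    sel = xf[quiet] if quiet.sum() >= 20 else xf
    if np.ptp(sel) < 1e-9:
        return [(float(sel[0]), 1.0)]
    try:
        kde = gaussian_kde(sel)
    except np.linalg.LinAlgError:
        return [(float(np.median(sel)), 1.0)]
    grid = np.linspace(sel.min(), sel.max(), 512)
    dens = kde(grid)
    peak = dens.max()
    modes = []
    for i in range(1, grid.size - 1):
        if dens[i] >= dens[i - 1] and dens[i] > dens[i + 1]:
            if dens[i] >= min_relative_density * peak:
                modes.append((float(grid[i]), float(dens[i] / peak)))
    if not modes:
        modes = [(float(grid[np.argmax(dens)]), 1.0)]
    # merge modes closer than the baseline noise scale
    modes.sort(key=lambda m: -m[1])
    merged: list[tuple[float, float]] = []
    for pos, d in modes:
        if all(abs(pos - p) > 60.0 for p, _ in merged):
            merged.append((pos, d))
    return merged


def find_equilibrium(series, engagement_hints=None,
                     quiescent_quantile: float = 0.5) -> EquilibriumEstimate:
    """Estimate the equilibrium position and baseline noise of a trace.

    The trace is restricted to its low-|gradient| half (quiescent frames;
    optionally further restricted by a boolean ``engagement_hints`` mask of
    frames known to be disengaged), and the equilibrium is the kernel
    density peak of those samples.  Noise SD comes from the median absolute
    deviation around the peak.  Falls back to the global median (flagged)
    when the trace never looks quiescent.
    """
    x = np.asarray(series, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 50:
        raise ValueError("need at least 50 frames to estimate an equilibrium")
    xf = x[finite]
    if np.ptp(xf) < 1e-9:
        return EquilibriumEstimate(float(xf[0]), 0.0, degenerate=True)

    grad = np.abs(np.gradient(xf))
    thr = np.quantile(grad, quiescent_quantile)
    quiet = grad <= thr
    if engagement_hints is not None:
        hints = np.asarray(engagement_hints, dtype=bool)[finite]
        if (quiet & ~hints).sum() >= 20:
            quiet &= ~hints
    sel = xf[quiet]
    fallback = False
    if sel.size < 20 or np.ptp(sel) < 1e-9:
        sel = xf
        fallback = True
    try:
        kde = gaussian_kde(sel)
        grid = np.linspace(sel.min(), sel.max(), 512)
        eq = float(grid[np.argmax(kde(grid))])
    except np.linalg.LinAlgError:
        eq = float(np.median(sel))
        fallback = True
    mad = np.median(np.abs(sel - eq))
    sd = float(1.4826 * mad)
    if sd < 1e-9:
        return EquilibriumEstimate(eq, max(sd, 0.0), fallback=fallback,
                                   degenerate=True)
    return EquilibriumEstimate(eq, sd, fallback=fallback)


def _boxcar(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")
    out = np.convolve(xp, kernel, mode="same")[pad:pad + x.size]
    return out


def _cross_time(t0: float, t1: float, v0: float, v1: float,
                level: float) -> float:
    """Linear interpolation of the time where a trace crosses ``level``."""
    if v1 == v0:
        return t0
    frac = (level - v0) / (v1 - v0)
    return t0 + np.clip(frac, 0.0, 1.0) * (t1 - t0)


def classify_events(
    onaxis,
    eq: EquilibriumEstimate,
    mt_velocity,
    frame_interval: float = 0.2,
    kinesin: int = 0,
    tether: TetherModel | ForceLookup | None = None,
    gliding_direction: int = 1,
    smooth_window: int = 3,
    max_missing: float = 5.0,
    amplitude_criterion: float = 100.0,
) -> list[MotorEvent]:
    """Segment a displacement trace into drive/resist events.

    ``onaxis`` is the on-axis position series (nm; NaN for missing frames)
    and ``mt_velocity`` the microtubule velocity on the same time base.
    Returns an empty list if the trace violates the missing-data criterion
    (> ``max_missing`` seconds of consecutive gap).

    Role assignment uses the excursion sign relative to the gliding
    direction — not the instantaneous microtubule velocity sign — so stuck
    episodes (V ~ 0) do not flip labels.  Run length is the exact integral
    of the relative velocity: ``integral(v_MT) - (displacement change)``
    across the event window.
    """
    if frame_interval is None or frame_interval <= 0:
        raise ValueError("frame interval must be known and positive")
    x = np.asarray(onaxis, dtype=float)
    v_mt = np.asarray(mt_velocity, dtype=float)
    if x.shape != v_mt.shape:
        raise ValueError("displacement and velocity must share one time base")

    # criterion (2): drop tracks with long runs of missing frames
    missing = ~np.isfinite(x)
    if missing.any():
        runs = np.diff(np.flatnonzero(np.diff(np.concatenate(
            [[0], missing.view(np.int8), [0]]))).reshape(-1, 2), axis=1)
        if runs.size and runs.max() * frame_interval > max_missing:
            return []
        x = pd.Series(x).interpolate(limit_direction="both").to_numpy()

    dev = (x - eq.position) * gliding_direction
    sd = max(eq.noise_sd, 1e-6)
    thr = 2.0 * sd
    sm = _boxcar(dev, smooth_window)
    t = np.arange(x.size) * frame_interval

    lookup = None
    if isinstance(tether, ForceLookup):
        lookup = tether
    elif isinstance(tether, TetherModel):
        lookup = ForceLookup(tether)
    elif tether is None:
        lookup = ForceLookup(TetherModel())

    events: list[MotorEvent] = []
    # contiguous same-sign excursions of the smoothed trace beyond 2 SD;
    # a raw-trace return to baseline strictly inside a run splits it (two
    # consecutive events separated by a gap shorter than the smoothing
    # window would otherwise merge)
    above = (np.abs(sm) > thr) & ~(np.abs(dev) < 0.5 * thr)
    sign = np.sign(sm)
    i = 0
    n = x.size
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j] and sign[j] == sign[i]:
            j += 1
        seg_dev = dev[i:j]  # criterion applies to the measured displacements
        seg_sign = sign[i]
        # inclusion criterion (1), disjunctive branches
        qualifies = ((np.abs(seg_dev) > amplitude_criterion).sum() >= 2
                     or (np.abs(seg_dev) > thr).sum() >= 2)
        if qualifies:
            # event window: raw super-threshold samples inside the segment
            # (the smoothed segment can overhang a sharp detachment recoil)
            level = min(thr, amplitude_criterion)
            hot = np.flatnonzero((np.abs(seg_dev) > level)
                                 & (np.sign(seg_dev) == seg_sign))
            if hot.size == 0:
                hot = np.arange(j - i)
            a, b = i + hot[0], i + hot[-1]
            sharp_start = (a > 0 and abs(dev[a - 1]) < level
                           and abs(dev[a]) > 3.0 * level)
            start = t[a] - frame_interval / 2 if a == 0 else _cross_time(
                t[a - 1], t[a], abs(dev[a - 1]), abs(dev[a]), level)
            # a detachment recoil crosses from deep displacement to baseline
            # within one frame; a gradual return passes through the level
            sharp_end = (b < n - 1 and abs(dev[b + 1]) < level
                         and abs(dev[b]) > 3.0 * level)
            if b == n - 1:
                end = t[b] + frame_interval / 2
            elif sharp_end:
                end = t[b] + frame_interval / 2
            else:
                end = _cross_time(t[b], t[b + 1], abs(dev[b]),
                                  abs(dev[b + 1]), level)
            if end <= start:
                end = start + frame_interval / 2
            role = "drive" if seg_sign < 0 else "resist"
            win = slice(a, b + 1)
            raw = dev[win]
            force = np.asarray(lookup.force(np.abs(raw)))
            # run length = integral of (v_MT - v_kinesin) over the attached
            # interval; the kinesin part telescopes to the displacement
            # change between boundaries.  At a gradual boundary the
            # displacement equals the crossing level; at a sharp detachment
            # the walk ends at the last displaced sample.
            v_mean = float(np.mean(v_mt[win]))
            mt_path = v_mean * (end - start)
            d_start = seg_sign * level
            d_end = raw[-1] if sharp_end else seg_sign * level
            run_nm = mt_path - gliding_direction * (d_end - d_start)
            events.append(MotorEvent(
                kinesin=kinesin, role=role, start=float(start), end=float(end),
                times=t[win].copy(), displacement=raw.copy(), force=force,
                run_length=max(run_nm, 0.0) / 1000.0,
                peak_displacement=float(raw[np.argmax(np.abs(raw))]),
                sharp_start=sharp_start,
            ))
        i = j
    return events


def analyze_track(
    onaxis,
    mt_velocity,
    frame_interval: float = 0.2,
    kinesin: int = 0,
    **kwargs,
) -> tuple[list[MotorEvent], EquilibriumEstimate]:
    """Two-pass event analysis of one displacement trace.

    When the quiescent-frame density is multi-modal (plateau-heavy traces),
    every mode is tried as the equilibrium and the one whose classified
    events have gradual onsets wins: a genuine excursion ramps away from
    the anchor as the tether stretches, whereas excursions measured from a
    false equilibrium on an engaged plateau begin with the one-frame
    unbinding recoil.  A first classification pass then flags engaged
    frames; the equilibrium and — more importantly — the baseline noise SD
    are re-estimated on the disengaged remainder (event plateaus inflate a
    single-pass MAD), and classification is repeated with the refined
    estimate.  Returns the final event list and equilibrium estimate.
    """
    x = np.asarray(onaxis, dtype=float)
    eq = find_equilibrium(x)
    candidates = equilibrium_candidates(x)
    if len(candidates) > 1:
        # primary disambiguator: detachment recoils land at the anchor, so
        # the positions just after large one-frame jumps cluster at the true
        # equilibrium.  250 nm (about half the tether reach) separates
        # recoils (full plateau amplitude in one frame) from walking steps
        # (at most ~140 nm/frame at these speeds).
        xf = x[np.isfinite(x)]
        jump = np.abs(np.diff(xf)) > 250.0
        landings = xf[1:][jump]
        if landings.size >= 3:
            target = float(np.median(landings))
            pos = min(candidates, key=lambda c: abs(c[0] - target))[0]
            eq = EquilibriumEstimate(pos, eq.noise_sd, fallback=eq.fallback)
            candidates = []
    if len(candidates) > 1:
        scored = []
        for pos, dens in candidates:
            cand = EquilibriumEstimate(pos, eq.noise_sd, fallback=eq.fallback)
            evs = classify_events(x, cand, mt_velocity, frame_interval,
                                  kinesin=kinesin, **kwargs)
            gradual = (np.mean([not e.sharp_start for e in evs])
                       if evs else -1.0)
            scored.append((gradual, dens, cand))
        # the densest mode wins unless another candidate's events are
        # decisively more ramp-like (the plateau-lock signature is a near-
        # total flip of the gradual-onset fraction, not a small difference)
        scored.sort(key=lambda s: -s[1])
        best = scored[0]
        for cand in scored[1:]:
            if cand[0] >= best[0] + 0.3:
                best = cand
        eq = best[2]
    events = classify_events(x, eq, mt_velocity, frame_interval,
                             kinesin=kinesin, **kwargs)
    if events:
        t = np.arange(x.size) * frame_interval
        engaged = np.zeros(x.size, dtype=bool)
        for e in events:
            engaged |= (t >= e.start - frame_interval) & (t <= e.end + frame_interval)
        eq2 = find_equilibrium(x, engagement_hints=engaged)
        if not eq2.degenerate:
            eq = eq2
            events = classify_events(x, eq, mt_velocity, frame_interval,
                                     kinesin=kinesin, **kwargs)
    return events, eq


def analyze_simulation(sim, **kwargs):
    """Run the two-pass event analysis over every motor of a simulation.

    Returns ``(events, events_by_kinesin, role_matrix)`` where the role
    matrix is rebuilt from the classified events on the simulation's frame
    grid (codes as in ``forceglide.synthetic``).
    """
    disp = sim.displacements()
    events: list[MotorEvent] = []
    by_k: dict[int, list[MotorEvent]] = {}
    for k in range(sim.n_motors):
        evs, _eq = analyze_track(disp[k], sim.mt_velocity,
                                 sim.frame_interval, kinesin=k, **kwargs)
        events += evs
        by_k[k] = evs
    roles = events_to_role_matrix(events, sim.n_motors, sim.time.size,
                                  sim.frame_interval)
    return events, by_k, roles


def count_transitions(events_by_kinesin, observation_minutes: float,
                      max_gap: float | None = None):
    """Transition rate (per kinesin-minute) and type mix.

    ``events_by_kinesin`` maps kinesin id -> time-ordered event list.  Each
    ordered pair of consecutive events of one kinesin is one transition
    typed drive/resist -> drive/resist; ``max_gap`` (s) optionally drops
    pairs separated by longer unbound intervals.  Returns
    ``(rate_per_min, mix, records)`` where ``mix`` maps
    "DD"/"DR"/"RD"/"RR" to fractions summing to 1 (empty dict if there are
    no transitions).
    """
    if observation_minutes <= 0:
        raise ValueError("observation time must be positive")
    records: list[TransitionRecord] = []
    code = {"drive": "D", "resist": "R"}
    for k, evs in events_by_kinesin.items():
        evs = sorted(evs, key=lambda e: e.start)
        for a, b in zip(evs[:-1], evs[1:]):
            if max_gap is not None and b.start - a.end > max_gap:
                continue
            records.append(TransitionRecord(
                kinesin=k, from_role=a.role, to_role=b.role,
                time=0.5 * (a.end + b.start)))
    rate = len(records) / observation_minutes
    mix: dict[str, float] = {}
    if records:
        for key in ("DD", "DR", "RD", "RR"):
            mix[key] = 0.0
        for r in records:
            mix[code[r.from_role] + code[r.to_role]] += 1.0
        total = sum(mix.values())
        mix = {k: v / total for k, v in mix.items()}
    return rate, mix, records


def event_kinetics(events) -> pd.DataFrame:
    """Per-role mean duration and run length with SEMs and counts."""
    rows = []
    for role in ("drive", "resist"):
        sel = [e for e in events if e.role == role]
        if not sel:
            continue
        dur = np.array([e.duration for e in sel])
        run = np.array([e.run_length for e in sel])
        n = len(sel)
        rows.append({
            "role": role, "n": n,
            "mean_duration_s": dur.mean(),
            "sem_duration_s": dur.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
            "mean_run_length_um": run.mean(),
            "sem_run_length_um": run.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
        })
    return pd.DataFrame(rows)


def force_vs_time(events, tether: TetherModel | None = None,
                  bin_width: float = 0.2, max_time: float = 8.0) -> pd.DataFrame:
    """Role-aligned mean tether tension versus time since event start.

    Forces are recomputed from |displacement| through the extensible
    Marko–Siggia relation when a ``tether`` is given; otherwise the per-event
    force series stored at classification time are used.  Events are aligned
    at their start and averaged in ``bin_width`` bins.
    """
    lookup = ForceLookup(tether) if tether is not None else None
    edges = np.arange(0.0, max_time + bin_width, bin_width)
    out = []
    for role in ("drive", "resist"):
        sums = np.zeros(edges.size - 1)
        sq = np.zeros(edges.size - 1)
        counts = np.zeros(edges.size - 1, dtype=int)
        for e in events:
            if e.role != role:
                continue
            rel_t = e.times - e.start
            f = (np.asarray(lookup.force(np.abs(e.displacement)))
                 if lookup is not None else e.force)
            idx = np.digitize(rel_t, edges) - 1
            ok = (idx >= 0) & (idx < sums.size)
            np.add.at(sums, idx[ok], f[ok])
            np.add.at(sq, idx[ok], f[ok] ** 2)
            np.add.at(counts, idx[ok], 1)
        have = counts > 0
        mean = np.full(sums.size, np.nan)
        sem = np.full(sums.size, np.nan)
        mean[have] = sums[have] / counts[have]
        var = np.zeros(sums.size)
        var[have] = sq[have] / counts[have] - mean[have] ** 2
        good = counts > 1
        sem[good] = np.sqrt(np.maximum(var[good], 0.0) / counts[good])
        for b in np.flatnonzero(have):
            out.append({"role": role, "time_s": 0.5 * (edges[b] + edges[b + 1]),
                        "mean_force_pN": mean[b], "sem_force_pN": sem[b],
                        "n": int(counts[b])})
    return pd.DataFrame(out)


def _wilson_ci(k: int, n: int, z: float = 1.96) -> tuple[float, float]:
    if n == 0:
        return (np.nan, np.nan)
    p = k / n
    denom = 1 + z ** 2 / n
    center = (p + z ** 2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z ** 2 / (4 * n ** 2)) / denom
    return (center - half, center + half)


def fraction_driving(role_matrices, max_n: int = 8,
                     min_motor_frames: int = 50) -> pd.DataFrame:
    """Fraction of engaged motors driving, binned by engaged count N.

    ``role_matrices`` is a list of (motors x frames) role-code arrays (one
    per microtubule; codes as in ``forceglide.synthetic``: 1 drive,
    2 resist, 3 stuck-counted-as-resisting, 0 unbound).  For each frame the
    engaged count N indexes the bin; the per-bin fraction pools all engaged
    motor-frames, with a Wilson binomial CI.  Bins with fewer than
    ``min_motor_frames`` motor-frames are flagged low-confidence.
    """
    drive_ct = np.zeros(max_n + 1, dtype=int)
    total_ct = np.zeros(max_n + 1, dtype=int)
    for roles in role_matrices:
        roles = np.asarray(roles)
        engaged = (roles == ROLE_DRIVE) | (roles == ROLE_RESIST) | (roles == ROLE_STUCK)
        n_per_frame = engaged.sum(axis=0)
        d_per_frame = (roles == ROLE_DRIVE).sum(axis=0)
        for N in range(1, max_n + 1):
            sel = n_per_frame == N
            drive_ct[N] += int(d_per_frame[sel].sum())
            total_ct[N] += int(N * sel.sum())
    rows = []
    for N in range(1, max_n + 1):
        if total_ct[N] == 0:
            continue
        frac = drive_ct[N] / total_ct[N]
        lo, hi = _wilson_ci(drive_ct[N], total_ct[N])
        rows.append({"n_attached": N, "motor_frames": int(total_ct[N]),
                     "fraction_driving": frac, "ci_low": lo, "ci_high": hi,
                     "low_confidence": total_ct[N] < min_motor_frames})
    return pd.DataFrame(rows)


def relative_velocity_curves(events, mt_velocity, frame_interval: float = 0.2,
                             window: int = 5, bin_width: float = 0.2,
                             max_time: float = 8.0,
                             tail_exclude: float = 0.6) -> pd.DataFrame:
    """Role-aligned mean relative velocity v_MT - v_kinesin since binding.

    The kinesin velocity is a Savitzky–Golay smoothed derivative (quadratic,
    ``window`` frames) of the event displacement; events shorter than the
    window are skipped.  ``mt_velocity`` is indexed by absolute frame.  The
    last ``tail_exclude`` seconds of each event are dropped: that window is
    dominated by the detachment/recoil return to equilibrium, which is not
    walking and would otherwise bias the surviving-event average downward.
    """
    v_mt = np.asarray(mt_velocity, dtype=float)
    edges = np.arange(0.0, max_time + bin_width, bin_width)
    out = []
    for role in ("drive", "resist"):
        sums = np.zeros(edges.size - 1)
        sq = np.zeros(edges.size - 1)
        counts = np.zeros(edges.size - 1, dtype=int)
        for e in events:
            if e.role != role or e.times.size < window:
                continue
            v_k = savgol_filter(e.displacement, window, 2, deriv=1,
                                delta=frame_interval)
            frames = np.round(e.times / frame_interval).astype(int)
            frames = np.clip(frames, 0, v_mt.size - 1)
            v_rel = v_mt[frames] - v_k
            idx = np.digitize(e.times - e.start, edges) - 1
            ok = (idx >= 0) & (idx < sums.size)
            ok &= e.times <= e.end - tail_exclude
            np.add.at(sums, idx[ok], v_rel[ok])
            np.add.at(sq, idx[ok], v_rel[ok] ** 2)
            np.add.at(counts, idx[ok], 1)
        have = counts > 0
        for b in np.flatnonzero(have):
            m = sums[b] / counts[b]
            var = max(sq[b] / counts[b] - m ** 2, 0.0)
            sem = np.sqrt(var / counts[b]) if counts[b] > 1 else np.nan
            out.append({"role": role, "time_s": 0.5 * (edges[b] + edges[b + 1]),
                        "mean_v_rel_nm_s": m, "sem_v_rel_nm_s": sem,
                        "n": int(counts[b])})
    return pd.DataFrame(out)


def events_to_role_matrix(events, n_motors: int, n_frames: int,
                          frame_interval: float = 0.2) -> np.ndarray:
    """Rebuild a (motors x frames) role-code matrix from classified events."""
    roles = np.zeros((n_motors, n_frames), dtype=np.int8)
    for e in events:
        i0 = int(np.ceil(e.start / frame_interval))
        i1 = int(np.floor(e.end / frame_interval)) + 1
        code = ROLE_DRIVE if e.role == "drive" else ROLE_RESIST
        roles[e.kinesin, max(i0, 0):min(i1, n_frames)] = code
    return roles


def density_sweep(datasets: dict) -> pd.DataFrame:
    """Per-density kinetics and engagement table.

    ``datasets`` maps surface density (motors/µm²) to a dict with keys
    ``events`` (list of MotorEvent) and optionally ``roles`` — a motors x
    frames role matrix, or a list of such matrices (one per filament), for
    the mean simultaneously-engaged count.  Returns one row per density and
    role; a single density yields a one-condition table with no trend
    interpretation attached.
    """
    if not datasets:
        raise ValueError("density_sweep needs at least one condition")
    rows = []
    for dens in sorted(datasets):
        blob = datasets[dens]
        kin = event_kinetics(blob["events"])
        engaged_mean = np.nan
        roles = blob.get("roles")
        if roles is not None:
            mats = roles if isinstance(roles, (list, tuple)) else [roles]
            engaged_mean = float(np.mean(
                [(np.asarray(m) != 0).sum(axis=0).mean() for m in mats]))
        for _, r in kin.iterrows():
            rows.append({"surface_density": dens, **r.to_dict(),
                         "mean_engaged_motors": engaged_mean})
    return pd.DataFrame(rows)
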
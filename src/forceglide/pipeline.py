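"""End-to-end orchestration: simulate -> render -> track -> analyze -> report.

A run is described by a single flat config (dict / YAML) with per-stage
blocks; every output references the config's content hash so results are
traceable to exact parameters.  ``make_fixtures`` builds the deterministic
bundle the test suite shares.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from forceglide import states
from forceglide.synthetic import (
    AssayConfig,
    EventCalibration,
    MotorConfig,
    OpticsConfig,
    generate_event_traces,
    render_frames,
    simulate_gliding,
)
from forceglide.tether import TetherModel

__all__ = ["RunConfig", "run_pipeline", "make_fixtures", "config_hash"]

_STAGES = ("simulate", "render", "track", "analyze", "mixture", "rupture")


def config_hash(cfg: dict) -> str:
    """Stable content hash: key order and container types do not matter."""
    canon = json.dumps(cfg, sort_keys=True, default=_jsonable)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    if hasattr(obj, "__dict__"):
        return obj.__dict__
    raise TypeError(f"not JSON-serializable: {type(obj)}")


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``stages`` toggles which stages run; unknown stage names are rejected
    before anything executes.  Parameter blocks are plain dicts forwarded
    to the corresponding dataclasses, so a YAML config maps 1:1.
    """

    stages: tuple = ("simulate", "analyze")
    mode: str = "events"                    # "events" | "mechanistic"
    seed: int = 0
    out_dir: str | None = None
    calibration: dict = field(default_factory=dict)
    assay: dict = field(default_factory=dict)
    motor: dict = field(default_factory=dict)
    tether: dict = field(default_factory=dict)
    optics: dict = field(default_factory=dict)
    n_kinesins: int = 10
    duration: float = 300.0
    frame_interval: float = 0.2
    input_traces: str | None = None         # CSV path for track-only runs

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.mode not in ("events", "mechanistic"):
            raise ValueError("mode must be 'events' or 'mechanistic'")
        if self.input_traces is not None and not Path(self.input_traces).exists():
            raise FileNotFoundError(f"input path missing: {self.input_traces}")
        # constructing the blocks validates them early
        EventCalibration(**self.calibration)
        AssayConfig(**self.assay)
        MotorConfig(**self.motor)
        TetherModel(**self.tether)
        OpticsConfig(**self.optics)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())


def run_pipeline(config: RunConfig, out_dir=None) -> dict:
    """Execute the configured stages in dependency order.

    Returns the run manifest (also written to ``manifest.json`` when an
    output directory is given): inputs, outputs, config hash, seeds and
    wall-clock per stage.  A stage failure is recorded in the manifest
    before the exception propagates.
    """
    out = Path(out_dir or config.out_dir or ".")
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": config.to_dict(), "config_hash": config.hash,
                "seed": config.seed, "stages": {}, "outputs": {}}
    rng_seed = config.seed
    sim = None
    events = None
    try:
        if "simulate" in config.stages:
            t0 = _time.perf_counter()
            if config.mode == "events":
                sim = generate_event_traces(
                    EventCalibration(**config.calibration),
                    n_kinesins=config.n_kinesins, duration=config.duration,
                    seed=rng_seed, frame_interval=config.frame_interval)
            else:
                sim = simulate_gliding(
                    AssayConfig(**config.assay), MotorConfig(**config.motor),
                    TetherModel(**config.tether), seed=rng_seed,
                    record_interval=config.frame_interval)
            paths = sim.save(out / "simulate")
            manifest["outputs"].update(
                {k: str(v) for k, v in paths.items()})
            manifest["stages"]["simulate"] = {
                "wall_s": _time.perf_counter() - t0, "ok": True}

        if "render" in config.stages:
            t0 = _time.perf_counter()
            if sim is None:
                raise RuntimeError("render requires the simulate stage")
            import tifffile

            motor_stack, mt_stack, truth = render_frames(
                sim, OpticsConfig(**config.optics), seed=rng_seed + 1)
            (out / "render").mkdir(exist_ok=True)
            tifffile.imwrite(out / "render" / "motors.tif",
                             motor_stack.astype(np.float32))
            tifffile.imwrite(out / "render" / "microtubule.tif",
                             mt_stack.astype(np.float32))
            truth.to_csv(out / "render" / "truth_spots.csv", index=False)
            manifest["outputs"]["movies"] = str(out / "render")
            manifest["stages"]["render"] = {
                "wall_s": _time.perf_counter() - t0, "ok": True}

        if "track" in config.stages:
            t0 = _time.perf_counter()
            from forceglide import tracking as tk
            import tifffile

            stack = tifffile.imread(out / "render" / "motors.tif")
            dets = []
            for fidx in range(stack.shape[0]):
                for _, r in tk.detect_spots(stack[fidx]).iterrows():
                    loc = tk.localize_subpixel(stack[fidx], (r.y_px, r.x_px))
                    if loc is not None:
                        dets.append({"frame": fidx, "x_nm": loc[0][0],
                                     "y_nm": loc[0][1]})
            tracks = tk.link_tracks(pd.DataFrame(dets))
            table = tk.tracks_to_table(tracks)
            table.to_csv(out / "spots.csv", index=False)
            manifest["outputs"]["spots"] = str(out / "spots.csv")
            manifest["stages"]["track"] = {
                "wall_s": _time.perf_counter() - t0, "ok": True,
                "n_tracks": len(tracks)}

        if "analyze" in config.stages:
            t0 = _time.perf_counter()
            if sim is None:
                raise RuntimeError("analyze requires simulated (or loaded) traces")
            disp = sim.displacements()
            all_events, by_k = [], {}
            for k in range(sim.n_motors):
                evs, _eq = states.analyze_track(
                    disp[k], sim.mt_velocity, sim.frame_interval, kinesin=k)
                all_events += evs
                by_k[k] = evs
            events = all_events
            kin = states.event_kinetics(all_events)
            minutes = sim.n_motors * sim.time[-1] / 60.0
            rate, mix, _recs = states.count_transitions(by_k, minutes)
            roles = states.events_to_role_matrix(
                all_events, sim.n_motors, sim.time.size, sim.frame_interval)
            frac = states.fraction_driving([roles])
            kin.to_csv(out / "kinetics.csv", index=False)
            frac.to_csv(out / "fraction_driving.csv", index=False)
            summary = {
                "config_hash": config.hash,
                "n_events": len(all_events),
                "transition_rate_per_min": rate,
                "transition_mix": mix,
                "kinetics": kin.to_dict(orient="records"),
                "pooled_fraction_driving": (
                    float((roles == 1).sum() / max((roles != 0).sum(), 1))),
            }
            with open(out / "summary.json", "w") as fh:
                json.dump(summary, fh, indent=2, default=_jsonable)
            manifest["outputs"]["summary"] = str(out / "summary.json")
            manifest["stages"]["analyze"] = {
                "wall_s": _time.perf_counter() - t0, "ok": True}
    except Exception as exc:  # record partial state, then re-raise
        manifest["error"] = repr(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=_jsonable)
        raise

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_jsonable)
    return manifest


def make_fixtures(scale: str = "small", seed: int = 0) -> dict:
    """Deterministic in-memory fixture bundle shared by the test suite.

    ``small`` keeps everything under a minute on one CPU: event-level
    traces, one short mechanistic run, one rendered movie and a pull set.
    ``standard`` enlarges the event-level statistics.
    """
    if scale not in ("small", "standard"):
        raise ValueError("scale must be 'small' or 'standard'")
    from forceglide import rupture as rp

    n_kin, dur = (6, 120.0) if scale == "small" else (30, 600.0)
    cal = EventCalibration()
    events_sim = generate_event_traces(cal, n_kinesins=n_kin, duration=dur,
                                       seed=seed)
    mech_sim = simulate_gliding(
        AssayConfig(motor_count=3, duration=30.0),
        seed=seed + 1, record_interval=0.2)
    render_sim = generate_event_traces(
        EventCalibration(localization_noise_sd=5.0), n_kinesins=3,
        duration=20.0, seed=seed + 2)
    motor_stack, mt_stack, truth = render_frames(
        render_sim, OpticsConfig(photon_budget=5000), seed=seed + 3)
    rng = np.random.default_rng(seed + 4)
    pulls = [rp.simulate_pull(rp.BondModel(), rate=10.0, seed=rng)
             for _ in range(40)]
    return {
        "calibration": cal,
        "events_sim": events_sim,
        "mech_sim": mech_sim,
        "render_sim": render_sim,
        "motor_stack": motor_stack,
        "mt_stack": mt_stack,
        "truth_spots": truth,
        "pulls": pulls,
        "seed": seed,
    }
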
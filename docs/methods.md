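# Methods

This note documents the models behind `forceglide`, the choices made where
the design was genuinely open, and what the synthetic generators do and do
not emulate.

## Tether mechanics

The dsDNA tether (persistence length L_p = 50 nm, contour length
L_c = 532 nm, 20 nm distance offset for the quantum dot and linkers) is
modelled by the extensible worm-like chain. Two functional forms coexist on
purpose:

* the **Marko–Siggia interpolation**
  F = (k_BT/L_p)[¼(1−l)⁻² − ¼ + l], with l = x/L_c − F/K₀ solved
  numerically, valid over the whole extension range and used for the
  pipeline's force traces (`displacement_to_force`);
* the **high-force series** x(F) = L_c(1 − ½√(k_BT/(F·L_p)) + F/K₀), the
  standard optical-trap fitting form, used for pull curves
  (`ewlc_extension`/`ewlc_force`).

The two printed stiffness regimes anchor the parameterization: the analytic
Marko–Siggia derivative gives 0.00066 pN/nm at 246 nm extension, and the
high-force form gives ≈0.20 pN/nm at 496 nm — a ~300-fold stiffening over
the last fifth of the contour. Neither the temperature nor K₀ is part of
the published parameter set; k_BT = 4.14 pN·nm (≈300 K) and K₀ = 1200 pN
(standard dsDNA) reproduce both printed values, and the second stiffness
moves ≤5% over K₀ ∈ [800, 1200] pN. Inverses are obtained by bracketed
root-finding (Brent, |Δx| < 10⁻⁶ nm round-trip); simulation inner loops use
a PCHIP-tabulated force lookup accurate to <10⁻³ pN.

## Event-level generator

`generate_event_traces` emits each kinesin's on-axis displacement directly
as a renewal sequence of drive/resist events with the canonical
ramp–plateau–return shape, Gaussian localization noise (20 nm), and full
ground truth. Its parameters *are* the published ensemble statistics:
durations exponential with means 3.0 s (drive) / 2.15 s (resist), run
lengths 2.31 / 1.42 µm, 4.9 events per kinesin-minute, per-frame driving
probability 0.65, transition-type mix 52/16/16/16%.

Three derived quantities make those numbers mutually consistent:

* **Engaged-cargo speed.** A driving event's displacement starts and ends
  at equilibrium, so its run length ∫(v_MT − v_k)dt telescopes to
  v_MT × duration *identically, independent of the excursion shape*. The
  drive calibration therefore fixes the cargo speed during engaged events:
  v_e = 2.31 µm / 3.056 s ≈ 756 nm/s. This sits below the 830 nm/s bulk
  gliding speed, as expected for a cargo under tug-of-war load (the
  published run/duration ratios, ≈770 and ≈660 nm/s, sit below the bulk
  speed for the same reason).
* **Resist plateau.** Resisting events end displaced (detach, then recoil),
  so E[run] = v_e·E[τ] − E[min(D, r·τ)] with r the displacement growth
  rate; the plateau amplitude D ≈ 321 nm is solved in closed form so the
  resist-role mean run length equals 1.42 µm exactly.
* **Duration floor.** Durations are floored at 0.6 s (three camera frames):
  shorter events cannot satisfy the two-point classification criterion and
  their censoring would inflate every recovered mean by 15–20%. The floor
  shifts the true means by only ~2–4% (to 3.056 / 2.226 s).

The per-event role prior is derived from the per-frame probability by
duration weighting, q = p·E[τ_R]/((1−p)E[τ_D] + p·E[τ_R]) ≈ 0.575, so the
duration-weighted fraction of engaged frames equals p_drive exactly. Two
role processes are available: independent Bernoulli draws (default; honours
p_drive) and a two-state Markov chain whose stationary pair distribution
equals the transition-type mix (the two published statistics imply slightly
different role marginals, so they cannot be honoured simultaneously by one
process). Idle gaps are exponential with mean set from the event rate.

The generator's force realism is deliberately limited: the drive plateau
(450 nm) carries only ~0.6 pN, not the multi-piconewton tensions real
events reach at late times; force–time realism lives in the mechanistic
simulator. Event traces also use a constant cargo speed per filament —
fluctuations from role switching appear only in the mechanistic model.

## Mechanistic simulator

`simulate_gliding` integrates a 1-D tug-of-war at dt = 5 ms: bound motors'
tether tensions follow from their displacements, stepping speed follows a
piecewise-linear force–velocity relation (plateau ±2 pN, stall at 6 pN
hindering load, modest assisted speed-up saturating at 6 pN), the filament
advances each step to the unique root of the quasi-static balance
Σ(signed tether forces) − γV = 0 (γ = 10⁻³ pN·s/nm; residual < 10⁻⁶ pN,
typically ~10⁻¹⁰), and motors unbind with Bell kinetics — resisting faster
than driving at any force (k₀ = 0.35 vs 0.25 s⁻¹; F_d = 2.5 vs 3 pN).
Binding places the head on the lattice site under the anchor at zero
tension. The lattice is treated as unbounded (a cropped field the filament
never leaves), with roadblocks repeated periodically at the configured
linear density; a roadblock stalls stepping (bypass is not modelled), adds
an obstacle-contact release rate (1 s⁻¹), and the stalled motor turns into
a resister whose tension grows as the team pulls — the emergent rescue
mechanism.

Per-motor unloaded speeds are drawn from N(830, 400) nm/s truncated to the
physical 250–1450 nm/s range. The 400 nm/s spread follows from the
published initial relative speeds of the two roles (~1300 and ~500 nm/s
around the cargo speed), and it is what gives speed-mismatch tensions
enough weight for the negative-cooperativity trend (per-role durations and
run lengths decreasing with surface density) to emerge; with the smaller
spreads sometimes quoted for kinesin the trend drowns in noise. The
drive-side Bell scale of 3 pN (rather than the ~6 pN stall force) is
likewise needed for 0.5–2 pN inter-motor tensions to matter to detachment,
and matches the steep load dependence of single-kinesin run length.

Calibration outcomes with these defaults, three motors, no roadblocks:
time-averaged fraction of engaged motors driving 0.69 ± 0.06 over 20 seeds;
mean engaged tension ≈ 0.7 pN (always < 4 pN); mean tension in the first
0.8 s after binding < 0.4 pN. The binding rate (0.8 s⁻¹ in reach) is set so
that three anchors co-attach often enough for a genuine tug-of-war; the
resulting per-motor duty cycle (~60–70%) is higher than the experiment's
(~20%, implied by 4.9 events/min × 2.7 s) — the event-level generator,
not the mechanistic one, owns the published event-rate statistics.

## Classification

Events are excursions of the on-axis displacement from the motor's
equilibrium. The inclusion criterion is taken literally from the
experimental method: at least two points displaced more than 100 nm *or*
more than two baseline standard deviations (the branches are disjunctive);
traces with more than 5 s of contiguous missing data are discarded.
Implementation choices the criterion leaves open:

* Candidate segments come from a 3-frame boxcar-smoothed trace (same-sign
  runs beyond 2 SD) with the SD measured on the raw trace — isolated noise
  spikes cannot form two-point segments, which keeps the false-event rate
  near zero without raising the threshold. A raw-trace return to within
  1 SD strictly inside a segment splits it (two events separated by a gap
  shorter than the smoothing window would otherwise merge).
* Boundaries are the linearly interpolated 2-SD crossings of the raw
  trace. A *sharp end* — a one-frame fall from beyond 3× the level to
  below it, the detachment-recoil signature — ends the event at the last
  displaced sample plus half a frame instead.
* Run length is the exact integral ∫(v_MT − v_k)dt over the attached
  window: the kinesin term telescopes to the displacement change between
  boundaries (crossing level at gradual boundaries, last displaced sample
  at sharp ones), which is mathematically identical to integrating a
  smoothed derivative but immune to its noise.
* Role follows the excursion sign relative to the gliding direction, not
  the instantaneous cargo velocity, so stuck episodes do not flip labels.

The equilibrium is estimated automatically (the experimental work did this
manually): kernel-density peak of the low-|gradient| half of the trace,
noise SD from the MAD. Engagement-heavy traces can be multi-modal (anchor
baseline plus engaged plateau); the disambiguation cue is physical —
detachment recoils land at the anchor, so positions one frame after jumps
larger than 250 nm (about half the tether reach; walking moves at most
~140 nm/frame) cluster at the true equilibrium. With fewer than three such
recoils the densest mode wins unless another candidate's classified events
are decisively more ramp-like. A second pass re-estimates the baseline
noise on the disengaged frames. On mechanistic fixtures the equilibrium
error is ≤ ~15 nm across all tracks; frame-level role accuracy on noisy
event fixtures exceeds 95%.

Relative-velocity curves use a Savitzky–Golay derivative (quadratic,
5-frame window) aligned at event start, excluding the last 0.6 s of each
event — that window is the detachment/recoil return, not walking, and
including it biases the surviving-event average downward. This is a simple
stand-in for a full survivor-bias weighting.

## Velocity mixtures

Microtubule velocity samples (1-s windows) are decomposed into stuck and
fast Gaussians by binned least squares on the 50 nm/s histogram, with the
stuck mean constrained to |µ| ≤ 50 nm/s and the fast mean to ≥ 400 nm/s;
initialization uses the near-zero histogram mass and the mode above
400 nm/s. Negative velocities are retained. An EM fit on raw samples
(scikit-learn) serves as an internal cross-check; the two routes agree on
weights within ±0.03 on separated mixtures. Component weights within 0.5%
of 0 or 1 flag a degenerate (single-population) fit.

## Rupture analysis

Pulls use the stiff-trap approximation (extension ramp equals trap
separation) starting where the tether carries 0.5 pN; rupture is drawn
from the Bell–Evans hazard k(F) = k₀e^{F/F_b} along the force ramp, and
curves reaching the preset 60 pN maximum intact are right-censored. The
bond defaults (k₀ = 0.0072 s⁻¹, F_b = 5.5 pN) are *calibrated, not
measured*: they put the 10 nm/s median near 30 pN through the closed-form
constant-rate median F_med = F_b·ln(1 + ln2·Ḟ/(k₀F_b)) at the eWLC
effective loading rate, and give ≈44 pN at 100 nm/s.

Because an extension ramp loads the bond at a force-dependent rate,
comparisons against the constant-rate closed form use the hazard-matched
rate (`matched_force_rate`): the hazard-weighted harmonic mean of the
ramp's loading rate, which preserves the cumulative hazard at the
comparison force. With it the simulate→detect→Kaplan–Meier round trip
reproduces the analytic median within ~1%.

Force–extension fits take residuals in the force direction — measurement
noise lives in the force channel, and regressing extension on noisy forces
produces a measurable errors-in-variables bias on the contour length. The
multi-tether flag combines a residual threshold with the fitted-Lp
signature: two parallel tethers follow the eWLC of a chain with half the
persistence length exactly, so a free-Lp fit can absorb shared load into
the parameters while an anomalously low (or otherwise distorted) Lp gives
it away. Rupture detection declares a rupture at a >50% force drop within
3 samples and reports the maximum force reached before the drop; survival
curves are Kaplan–Meier over force with right-censoring, and a median
lying on an exact S = 0.5 plateau is reported at the plateau midpoint.

## Tracking

Detection computes the scale-normalized Laplacian-of-Gaussian response at
the quantum-dot blob size (4 px at 160 nm/px) and takes robust-thresholded
local maxima. Localization is a 2-D Gaussian least-squares fit (FIONA
style) in a 7×7 window, with precision from the fit covariance; on
high-SNR synthetic spots the RMS error is a few nm. Linking solves a
frame-to-frame linear assignment on squared distance with birth/death
padding (gates: 4 px link radius), then stitches segments across gaps of
up to 20 frames within a 4 px radius. Kymographs sample intensity along a
piecewise-linear backbone with a perpendicular linewidth average;
velocities come from hysteresis-selected edge pixels whose local
space–time slope is the level-set velocity −(∂I/∂t)/(∂I/∂s), combined per
frame by least squares over a window of columns that widens until enough
edge evidence contributes. On constant-velocity synthetic kymographs the
mean is recovered within 1% and the per-frame RMS is under 5%; a stall
step is localized within 2 frames. Backbone projection uses exact
arc-length projection (curvature-safe), flagging points farther off-axis
than a capture distance.

## What the synthetic data does and does not show

The generators reproduce: the assay's sign conventions and displacement
geometry, the published per-role kinetics and their recovery, role
switching, the stuck/fast velocity structure under roadblocks, rescue of
stuck filaments by teams, camera statistics (Poisson + read noise, 160 nm
pixels, 0.2 s frames), and loading-rate-dependent rupture. They do not
reproduce: off-axis motion (noise only), microtubule bending dynamics
(backbones are polylines), photophysics beyond shot noise (no blinking),
two-channel registration error, motor–motor steric interactions, or the
late-time multi-piconewton force ramps within single events (event-level
generator). Passing tests therefore validate the *pipeline's inference*
under the stated physics, not the biology of any particular real dataset.

## Problem sizes and numerics

Default analysis scales: acceptance-style runs use ~80 tethered kinesins ×
10 min for kinetics (≥2000 drive events), 300 kinesin-minutes for the
transition rate, eight filaments carrying 1–8 motors for the fraction
driving, 5000 velocity samples for mixtures, and 400–1000 pulls per
survival curve. The test suite completes in a few minutes on one CPU.
Random state is a single `numpy` Generator per run; fixed seeds give
bit-identical outputs end to end.
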